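"""Minimal MaxEnt core: features, L1-regularized Gibbs fit, prediction.

The model estimates a probability distribution q(x) ∝ exp(λ·f(x)) over
background cells, choosing λ to maximize the penalized log-likelihood
of the presence records

    J(λ) = Σ_presence λ·f(x) − m·ln Z(λ) − Σ_j β_j |λ_j|,
    Z(λ) = Σ_background exp(λ·f(b)),

with per-feature penalties β_j scaled by the feature's background
standard deviation and the presence count (β_j = rm · β_class · s_j/√m).
Features are the classic MaxEnt classes — linear, quadratic, pairwise
product, and forward/reverse hinge ramps at quantile knots — each
min-max scaled to [0, 1] on the background sample.

Optimization is proximal gradient ascent (soft-thresholding handles the
L1 term) with a Barzilai–Borwein step and backtracking, which keeps the
penalized objective non-decreasing at every iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .grids import ClimateStack, Raster
from .occurrences import BackgroundDefinition, OccurrenceSet

__all__ = [
    "FeatureSet",
    "MaxEntModel",
    "build_features",
    "fit",
    "predict",
    "count_parameters",
    "fit_occurrence_model",
    "predict_surface",
    "permutation_importance",
]

FEATURE_CLASS_ORDER = "LQPH"

# class-level L1 penalty scale, interpolated on presence count
_BETA_BREAKPOINTS = np.array([10.0, 30.0, 100.0])
_BETA_VALUES = np.array([1.0, 0.2, 0.05])
_BETA_HINGE = 0.5


def default_class_beta(kind: str, n_presence: int) -> float:
    """Phillips-style class-level penalty as a function of presence count."""
    if kind == "hinge":
        return _BETA_HINGE
    return float(np.interp(n_presence, _BETA_BREAKPOINTS, _BETA_VALUES))


@dataclass(frozen=True)
class FeatureDef:
    kind: str  # linear | quadratic | product | hinge
    variables: tuple  # one index, or two for products
    knot: float | None = None
    direction: str | None = None  # forward | reverse (hinge only)


@dataclass
class FeatureSet:
    """Deterministic feature expansion with background-derived scaling."""

    definitions: list
    var_min: np.ndarray  # per input variable, from the background sample
    var_max: np.ndarray
    feat_min: np.ndarray  # per raw feature value (L/Q/P scaling)
    feat_max: np.ndarray
    n_variables: int

    def __len__(self) -> int:
        return len(self.definitions)

    @property
    def kinds(self) -> list:
        return [d.kind for d in self.definitions]

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Feature matrix in [0,1] for an (n_samples, n_variables) table."""
        x = np.asarray(values, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.n_variables:
            raise ValueError(
                f"expected table with {self.n_variables} variables, got {x.shape}"
            )
        out = np.empty((x.shape[0], len(self.definitions)))
        for j, d in enumerate(self.definitions):
            if d.kind == "linear":
                raw = x[:, d.variables[0]]
            elif d.kind == "quadratic":
                raw = x[:, d.variables[0]] ** 2
            elif d.kind == "product":
                raw = x[:, d.variables[0]] * x[:, d.variables[1]]
            elif d.kind == "hinge":
                v = d.variables[0]
                if d.direction == "forward":
                    denom = self.var_max[v] - d.knot
                    raw = np.maximum(0.0, x[:, v] - d.knot) / denom
                else:
                    denom = d.knot - self.var_min[v]
                    raw = np.maximum(0.0, d.knot - x[:, v]) / denom
                out[:, j] = np.clip(raw, 0.0, 1.0)
                continue
            else:  # pragma: no cover - guarded at build time
                raise ValueError(f"unknown feature kind {d.kind!r}")
            span = self.feat_max[j] - self.feat_min[j]
            scaled = (raw - self.feat_min[j]) / span if span > 0 else raw * 0.0
            out[:, j] = np.clip(scaled, 0.0, 1.0)
        return out


def build_features(
    values: np.ndarray,
    classes: str = "LQ",
    n_hinge_knots: int = 20,
) -> FeatureSet:
    """Build a FeatureSet from a background predictor table.

    ``classes`` is a subset of "LQHP".  Hinge knots sit at evenly spaced
    quantiles strictly inside each variable's background range, with one
    forward and one reverse ramp per knot.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("background table must be 2-D")
    tokens = set(classes.upper())
    unknown = tokens - set("LQHP")
    if unknown:
        raise ValueError(f"unknown feature class tokens: {sorted(unknown)}")
    n_vars = x.shape[1]
    if "P" in tokens and n_vars < 2:
        raise ValueError("product features require at least 2 variables")

    var_min, var_max = x.min(axis=0), x.max(axis=0)
    defs: list[FeatureDef] = []
    raw_cols: list[np.ndarray] = []
    if "L" in tokens:
        for v in range(n_vars):
            defs.append(FeatureDef("linear", (v,)))
            raw_cols.append(x[:, v])
    if "Q" in tokens:
        for v in range(n_vars):
            defs.append(FeatureDef("quadratic", (v,)))
            raw_cols.append(x[:, v] ** 2)
    if "P" in tokens:
        for a in range(n_vars):
            for b in range(a + 1, n_vars):
                defs.append(FeatureDef("product", (a, b)))
                raw_cols.append(x[:, a] * x[:, b])
    if "H" in tokens:
        qs = (np.arange(n_hinge_knots) + 1.0) / (n_hinge_knots + 1.0)
        for v in range(n_vars):
            knots = np.quantile(x[:, v], qs)
            for t in knots:
                for direction in ("forward", "reverse"):
                    defs.append(FeatureDef("hinge", (v,), float(t), direction))
                    raw_cols.append(np.zeros(1))  # hinge scaling is knot-based

    feat_min = np.array([c.min() for c in raw_cols])
    feat_max = np.array([c.max() for c in raw_cols])
    return FeatureSet(defs, var_min, var_max, feat_min, feat_max, n_vars)


@dataclass
class MaxEntModel:
    lambdas: np.ndarray
    feature_set: FeatureSet | None
    reg_multiplier: float
    betas: np.ndarray
    ln_z: float
    entropy: float
    n_presence: int
    n_background: int
    converged: bool
    objective_log: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "lambdas": self.lambdas.tolist(),
            "reg_multiplier": self.reg_multiplier,
            "betas": self.betas.tolist(),
            "ln_z": self.ln_z,
            "entropy": self.entropy,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "converged": self.converged,
        }


def fit(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    reg_multiplier: float = 1.0,
    feature_kinds: list | None = None,
    feature_set: FeatureSet | None = None,
    tol: float = 1e-7,
    max_iter: int = 5000,
) -> MaxEntModel:
    """Fit λ by proximal gradient ascent on the penalized log-likelihood.

    ``feature_kinds`` (one of linear/quadratic/product/hinge per column)
    sets the class-level penalty scale; it defaults to the feature set's
    kinds, or to all-linear for bare matrices.  Z is computed over the
    background matrix exactly as passed.
    """
    fp = np.asarray(presence_features, dtype=float)
    fb = np.asarray(background_features, dtype=float)
    if fp.ndim != 2 or fb.ndim != 2 or fp.shape[1] != fb.shape[1]:
        raise ValueError("presence/background feature matrices must align")
    if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fb))):
        raise ValueError("non-finite feature values")
    m, n_feat = fp.shape
    if m < 2:
        raise ValueError("need at least 2 presence records")
    if fb.shape[0] < 10 * m:
        warnings.warn(
            f"background ({fb.shape[0]}) smaller than 10x presences ({m}); "
            "expectations may be noisy"
        )

    if feature_kinds is None:
        feature_kinds = feature_set.kinds if feature_set is not None else ["linear"] * n_feat
    class_beta = np.array([default_class_beta(k, m) for k in feature_kinds])
    s = fb.std(axis=0)
    betas = reg_multiplier * class_beta * s / np.sqrt(m)

    p_bar = fp.mean(axis=0)
    lam = np.zeros(n_feat)
    beta_pp = betas / m  # per-point-scale penalty

    def smooth_and_grad(l):
        scores = fb @ l
        ln_z = logsumexp(scores)
        q = np.exp(scores - ln_z)
        g = p_bar @ l - ln_z  # per-point smooth objective
        return g, p_bar - q @ fb, ln_z, q

    def penalized(g_val, l):
        return g_val - beta_pp @ np.abs(l)

    def prox_from(point, g_point, grad_point, step):
        """Backtracked proximal step from ``point``; the majorization
        condition guarantees the penalized objective of the returned
        iterate is >= the penalized objective at ``point``."""
        for _bt in range(60):
            trial = _soft_threshold(point + step * grad_point, step * beta_pp)
            delta = trial - point
            g_t, grad_t, ln_z_t, q_t = smooth_and_grad(trial)
            if g_t >= g_point + grad_point @ delta - (delta @ delta) / (2 * step) - 1e-15:
                return trial, g_t, grad_t, ln_z_t, q_t, step
            step *= 0.5
        return point, g_point, grad_point, *smooth_and_grad(point)[2:], step

    # FISTA (accelerated proximal gradient) with a monotone restart:
    # an extrapolated step that would lower the penalized objective is
    # discarded and replaced by a plain proximal step, so the logged
    # objective never decreases.
    g_val, grad, ln_z, q = smooth_and_grad(lam)
    obj = penalized(g_val, lam)
    log = [obj]
    step = 1.0
    t_mom = 1.0
    y = lam.copy()
    g_y, grad_y = g_val, grad
    converged = False
    for _ in range(max_iter):
        z, g_z, grad_z, ln_z_t, q_t, step = prox_from(y, g_y, grad_y, step * 2.0)
        if penalized(g_z, z) < obj:
            # momentum overshoot: restart from the current iterate
            t_mom = 1.0
            z, g_z, grad_z, ln_z_t, q_t, step = prox_from(lam, g_val, grad, step)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
        y = z + ((t_mom - 1.0) / t_next) * (z - lam)
        t_mom = t_next
        lam, g_val, grad, ln_z, q = z, g_z, grad_z, ln_z_t, q_t
        g_y, grad_y = smooth_and_grad(y)[:2]
        new_obj = penalized(g_val, lam)
        log.append(new_obj)
        if abs(new_obj - obj) * m < tol:
            converged = True
            obj = new_obj
            break
        obj = new_obj

    if not converged:
        warnings.warn("MaxEnt fit did not converge; returning best iterate")
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-np.sum(np.where(q > 0, q * np.log(q), 0.0)))
    return MaxEntModel(
        lambdas=lam,
        feature_set=feature_set,
        reg_multiplier=reg_multiplier,
        betas=betas,
        ln_z=float(ln_z),
        entropy=entropy,
        n_presence=m,
        n_background=fb.shape[0],
        converged=converged,
        objective_log=np.asarray(log) * m,  # full Σ-scale objective
    )


def _soft_threshold(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def predict(model: MaxEntModel, features: np.ndarray, output: str = "cloglog") -> np.ndarray:
    """Raw (normalized over training background) or cloglog suitability."""
    f = np.asarray(features, dtype=float)
    if f.ndim != 2 or f.shape[1] != model.lambdas.size:
        raise ValueError("feature matrix does not match model")
    raw = np.exp(f @ model.lambdas - model.ln_z)
    if output == "raw":
        return raw
    if output == "cloglog":
        return 1.0 - np.exp(-np.exp(model.entropy) * raw)
    raise ValueError(f"unknown output type {output!r}")


def count_parameters(model: MaxEntModel) -> int:
    """Number of features with non-zero weight (AICc's k)."""
    return int(np.count_nonzero(model.lambdas))


# ---------------------------------------------------------------------------
# pipeline-level helpers operating on grids and occurrence sets


def occurrence_predictor_table(
    occ: OccurrenceSet, stack: ClimateStack
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predictor values at the occurrence cells (valid cells only)."""
    inside = stack.grid.contains(occ.lons, occ.lats)
    rows, cols = stack.grid.index_of(occ.lons[inside], occ.lats[inside])
    valid = stack.mask[rows, cols]
    rows, cols = rows[valid], cols[valid]
    if rows.size < len(occ):
        warnings.warn(
            f"{len(occ) - rows.size} occurrence(s) fall outside the valid grid"
        )
    if rows.size == 0:
        raise ValueError("no occurrence falls on a valid stack cell")
    return stack.table(rows, cols), rows, cols


def fit_occurrence_model(
    occ: OccurrenceSet,
    background: BackgroundDefinition,
    stack: ClimateStack,
    classes: str = "LQ",
    reg_multiplier: float = 1.0,
    n_hinge_knots: int = 20,
    **fit_kwargs,
) -> MaxEntModel:
    """Fit a MaxEnt model from records + background on a climate stack.

    Presence cells are appended to the background sample for the
    partition function (standard MaxEnt convention); feature scaling is
    derived from that combined sample.
    """
    pres, _, _ = occurrence_predictor_table(occ, stack)
    bg = stack.table(background.rows, background.cols)
    bg_all = np.vstack([bg, pres])
    fs = build_features(bg_all, classes=classes, n_hinge_knots=n_hinge_knots)
    return fit(
        fs.transform(pres),
        fs.transform(bg_all),
        reg_multiplier=reg_multiplier,
        feature_set=fs,
        **fit_kwargs,
    )


def predict_surface(
    model: MaxEntModel, stack: ClimateStack, output: str = "cloglog"
) -> Raster:
    """Suitability raster over the stack's valid cells."""
    if model.feature_set is None:
        raise ValueError("model carries no feature set; cannot predict a surface")
    rows, cols = np.nonzero(stack.mask)
    scores = predict(model, model.feature_set.transform(stack.table(rows, cols)),
                     output=output)
    out = np.full(stack.grid.shape, np.nan)
    out[rows, cols] = scores
    return Raster(out, stack.grid)


def permutation_importance(
    model: MaxEntModel,
    presence_table: np.ndarray,
    background_table: np.ndarray,
    seed: int = 0,
    n_repeats: int = 3,
) -> np.ndarray:
    """Per-variable importance as normalized AUC drop under permutation.

    Each predictor column is shuffled jointly across presence and
    background tables; the drop in presence-vs-background AUC, averaged
    over repeats, is normalized to percentages summing to 100.
    """
    from .evaluation import compute_auc

    fs = model.feature_set
    if fs is None:
        raise ValueError("permutation importance requires a model with features")
    rng = np.random.default_rng(seed)
    base = compute_auc(
        predict(model, fs.transform(presence_table), "raw"),
        predict(model, fs.transform(background_table), "raw"),
    )
    stacked = np.vstack([presence_table, background_table])
    n_p = presence_table.shape[0]
    drops = np.zeros(fs.n_variables)
    for v in range(fs.n_variables):
        for _ in range(n_repeats):
            perm = stacked.copy()
            perm[:, v] = rng.permutation(perm[:, v])
            auc = compute_auc(
                predict(model, fs.transform(perm[:n_p]), "raw"),
                predict(model, fs.transform(perm[n_p:]), "raw"),
            )
            drops[v] += max(base - auc, 0.0)
    total = drops.sum()
    return 100.0 * drops / total if total > 0 else np.zeros(fs.n_variables)
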