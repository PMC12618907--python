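"""Model tuning and evaluation: AICc grid search, AUC, null test, CBI.

The tuning grid crosses regularization multipliers (default 0.5–5.0 in
steps of 0.5) with feature-class combinations (L, Q, LQ, LQH, LQHP),
yielding 50 candidates.  Candidates are ranked by the small-sample
Akaike criterion AICc = 2k − 2lnL + 2k(k+1)/(n−k−1), with lnL computed
from raw scores renormalized over the prediction grid.  Discrimination
is measured by the rank AUC, calibration by the Continuous Boyce Index,
and AUC significance by a randomization null model: the empirical AUC
must strictly exceed at least 95% of AUCs from models refit to
uniformly placed pseudo-occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata, spearmanr

from .grids import ClimateStack
from .maxent import (
    MaxEntModel,
    build_features,
    count_parameters,
    count_parameters as _k,
    fit,
    predict,
)
from .occurrences import BackgroundDefinition, OccurrenceSet

__all__ = [
    "TuningGrid",
    "CandidateResult",
    "EvaluationReport",
    "tune",
    "aicc",
    "compute_aicc",
    "compute_auc",
    "null_model_test",
    "exceedance_significance",
    "compute_cbi",
    "split_train_test",
]

DEFAULT_REG_MULTIPLIERS = tuple(np.arange(1, 11) * 0.5)
DEFAULT_CLASS_SETS = ("L", "Q", "LQ", "LQH", "LQHP")


@dataclass(frozen=True)
class TuningGrid:
    reg_multipliers: tuple = DEFAULT_REG_MULTIPLIERS
    class_sets: tuple = DEFAULT_CLASS_SETS

    @property
    def size(self) -> int:
        return len(self.reg_multipliers) * len(self.class_sets)


@dataclass
class CandidateResult:
    classes: str
    reg_multiplier: float
    k: int
    ln_l: float
    aicc: float
    auc_train: float
    auc_test: float
    cbi_train: float
    cbi_test: float
    model: MaxEntModel = field(repr=False, default=None)


@dataclass
class EvaluationReport:
    candidates: list
    selected_index: int
    split_seed: int
    test_fraction: float
    null_test: dict | None = None

    @property
    def selected(self) -> CandidateResult:
        return self.candidates[self.selected_index]

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "classes": c.classes,
                    "rm": c.reg_multiplier,
                    "k": c.k,
                    "lnL": c.ln_l,
                    "AICc": c.aicc,
                    "AUC_train": c.auc_train,
                    "AUC_test": c.auc_test,
                    "CBI_train": c.cbi_train,
                    "CBI_test": c.cbi_test,
                    "selected": i == self.selected_index,
                }
                for i, c in enumerate(self.candidates)
            ]
        )


def aicc(ln_l: float, k: int, n: int) -> float:
    """Small-sample AIC; NaN marks the undefined cases (k=0 or k>=n-1)."""
    if k == 0 or k >= n - 1:
        return float("nan")
    return 2 * k - 2 * ln_l + 2 * k * (k + 1) / (n - k - 1)


def grid_log_likelihood(
    model: MaxEntModel, occ_features: np.ndarray, landscape_features: np.ndarray
) -> float:
    """lnL of occurrences under raw scores renormalized over the grid."""
    log_raw_occ = occ_features @ model.lambdas - model.ln_z
    log_raw_land = landscape_features @ model.lambdas - model.ln_z
    from scipy.special import logsumexp

    return float(log_raw_occ.sum() - occ_features.shape[0] * logsumexp(log_raw_land))


def compute_aicc(
    model: MaxEntModel, occ_features: np.ndarray, landscape_features: np.ndarray
) -> float:
    """AICc of a fitted model on its occurrence set over a prediction grid."""
    n = occ_features.shape[0]
    k = count_parameters(model)
    if k == 0 or k >= n - 1:
        return float("nan")
    return aicc(grid_log_likelihood(model, occ_features, landscape_features), k, n)


def compute_auc(scores_presence, scores_background) -> float:
    """Rank AUC (Mann–Whitney U / (n_p·n_b)); ties count one half."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([sp, sb]))
    u = ranks[: sp.size].sum() - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sb.size))


def compute_cbi(
    scores_presence,
    scores_landscape,
    n_windows: int = 101,
    window_width: float = 0.1,
) -> float:
    """Continuous Boyce Index.

    P/E is evaluated in ``n_windows`` overlapping suitability intervals
    of width ``window_width`` (fraction of the score range): P = share
    of presences in the window, E = share of landscape cells.  Windows
    with E = 0 are dropped; the CBI is the Spearman correlation between
    window midpoints and P/E.  NaN when fewer than 3 usable windows
    remain.

    Scores are mapped through the landscape's empirical CDF before
    windowing, so the windows hold (approximately) constant landscape
    mass and the index is exactly invariant under any strictly
    increasing transform of the scores — the rank-based reading of the
    Boyce index.
    """
    sp = np.asarray(scores_presence, dtype=float)
    sl = np.asarray(scores_landscape, dtype=float)
    if np.unique(sl).size < 2:
        return float("nan")
    order = np.sort(sl)
    sp = np.searchsorted(order, sp, side="right") / sl.size
    sl = np.searchsorted(order, sl, side="right") / sl.size
    lo, hi = sl.min(), sl.max()
    width = window_width * (hi - lo)
    starts = np.linspace(lo, hi - width, n_windows)
    mids, pe = [], []
    for a in starts:
        b = a + width
        e = np.mean((sl >= a) & (sl <= b))
        if e == 0:
            continue
        p = np.mean((sp >= a) & (sp <= b))
        mids.append(a + width / 2.0)
        pe.append(p / e)
    if len(pe) < 3:
        return float("nan")
    rho = spearmanr(mids, pe).statistic
    return float(rho)


def split_train_test(
    occ: OccurrenceSet, fraction_test: float = 0.25, seed: int = 0
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Reproducible random train/test partition of the records."""
    if not 0 < fraction_test < 1:
        raise ValueError("fraction_test must lie in (0, 1)")
    n = len(occ)
    n_test = int(round(fraction_test * n))
    perm = np.random.default_rng(seed).permutation(n)
    return occ.subset(np.sort(perm[n_test:])), occ.subset(np.sort(perm[:n_test]))


def tune(
    occ: OccurrenceSet,
    background: BackgroundDefinition,
    stack: ClimateStack,
    grid: TuningGrid = TuningGrid(),
    seed: int = 0,
    test_fraction: float = 0.25,
    n_hinge_knots: int = 20,
    **fit_kwargs,
) -> EvaluationReport:
    """Fit and score every candidate in the tuning grid.

    Each candidate is fit on the full (thinned) record set; AICc uses
    raw scores renormalized over the prediction grid (all valid stack
    cells).  AUC/CBI train and test values score the same model on a
    random record split.  The candidate with minimal finite AICc wins;
    ties break to smaller k, then smaller regularization multiplier.
    """
    from .maxent import occurrence_predictor_table

    pres_table, _, _ = occurrence_predictor_table(occ, stack)
    bg_table = stack.table(background.rows, background.cols)
    bg_all = np.vstack([bg_table, pres_table])
    land_rows, land_cols = np.nonzero(stack.mask)
    land_table = stack.table(land_rows, land_cols)

    n = pres_table.shape[0]
    n_test = int(round(test_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]

    candidates: list[CandidateResult] = []
    for classes in grid.class_sets:
        fs = build_features(bg_all, classes=classes, n_hinge_knots=n_hinge_knots)
        f_pres = fs.transform(pres_table)
        f_bg_all = fs.transform(bg_all)
        f_bg = fs.transform(bg_table)
        f_land = fs.transform(land_table)
        for rm in grid.reg_multipliers:
            model = fit(f_pres, f_bg_all, reg_multiplier=rm, feature_set=fs,
                        **fit_kwargs)
            k = _k(model)
            ln_l = grid_log_likelihood(model, f_pres, f_land)
            raw_pres = predict(model, f_pres, "raw")
            raw_bg = predict(model, f_bg, "raw")
            raw_land = predict(model, f_land, "raw")
            candidates.append(
                CandidateResult(
                    classes=classes,
                    reg_multiplier=float(rm),
                    k=k,
                    ln_l=ln_l,
                    aicc=aicc(ln_l, k, n),
                    auc_train=compute_auc(raw_pres[train_idx], raw_bg),
                    auc_test=(compute_auc(raw_pres[test_idx], raw_bg)
                              if n_test > 0 else float("nan")),
                    cbi_train=compute_cbi(raw_pres[train_idx], raw_land),
                    cbi_test=(compute_cbi(raw_pres[test_idx], raw_land)
                              if n_test > 0 else float("nan")),
                    model=model,
                )
            )

    finite = [i for i, c in enumerate(candidates) if np.isfinite(c.aicc)]
    if not finite:
        raise ValueError(
            "AICc undefined for every candidate (k >= n-1 or k = 0 "
            "everywhere); add occurrences or strengthen regularization"
        )
    selected = min(
        finite,
        key=lambda i: (
            candidates[i].aicc,
            candidates[i].k,
            candidates[i].reg_multiplier,
        ),
    )
    return EvaluationReport(
        candidates=candidates,
        selected_index=selected,
        split_seed=seed,
        test_fraction=test_fraction,
    )


def null_model_test(
    occ: OccurrenceSet,
    background: BackgroundDefinition,
    stack: ClimateStack,
    selected_settings: tuple,
    n_null: int = 100,
    seed: int = 0,
    n_hinge_knots: int = 20,
    **fit_kwargs,
) -> dict:
    """Randomization test of the empirical AUC.

    Refits models with the selected (classes, reg multiplier) settings
    to ``n_null`` pseudo-occurrence sets drawn uniformly from the
    background mask, recording each one's presence-vs-background AUC.
    The empirical AUC is significant iff it strictly exceeds at least
    ceil(0.95 * n_null) of the null AUCs (ties count against).
    """
    from .maxent import occurrence_predictor_table

    classes, rm = selected_settings
    pres_table, _, _ = occurrence_predictor_table(occ, stack)
    bg_table = stack.table(background.rows, background.cols)
    n_occ = pres_table.shape[0]

    def fit_auc(p_table):
        bg_all = np.vstack([bg_table, p_table])
        fs = build_features(bg_all, classes=classes, n_hinge_knots=n_hinge_knots)
        model = fit(fs.transform(p_table), fs.transform(bg_all),
                    reg_multiplier=rm, feature_set=fs, **fit_kwargs)
        return compute_auc(
            predict(model, fs.transform(p_table), "raw"),
            predict(model, fs.transform(bg_table), "raw"),
        )

    empirical = fit_auc(pres_table)
    rng = np.random.default_rng(seed)
    mask_rows, mask_cols = np.nonzero(background.mask & stack.mask)
    null_aucs = np.empty(n_null)
    for r in range(n_null):
        pick = rng.choice(mask_rows.size, size=n_occ, replace=False)
        null_aucs[r] = fit_auc(stack.table(mask_rows[pick], mask_cols[pick]))

    percentile, significant = exceedance_significance(empirical, null_aucs)
    return {
        "n_null": n_null,
        "empirical_auc": float(empirical),
        "null_aucs": null_aucs,
        "percentile": percentile,
        "significant": significant,
    }


def exceedance_significance(empirical: float, null_values) -> tuple[float, bool]:
    """Apply the 95%-exceedance rule to an empirical statistic.

    Returns (percentile, significant): the percentile is the share of
    null values strictly below the empirical one (in percent), and the
    result is significant iff the empirical value strictly exceeds at
    least ceil(0.95 * n_null) of them — ties count against.
    """
    nulls = np.asarray(null_values, dtype=float)
    n_below = int(np.sum(nulls < empirical))
    return 100.0 * n_below / nulls.size, n_below >= int(np.ceil(0.95 * nulls.size))
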