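"""Predictor preparation: background crop/mask and VIF collinearity filter.

Collinear predictors inflate model complexity and transfer poorly to
new regions, so variables are removed iteratively by the variance
inflation factor (VIF = 1 / (1 - R^2) of each predictor regressed on
the rest) until all remaining non-forced variables fall below a
threshold.  Ecologically central variables can be forced to stay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .grids import ClimateStack, GridSpec
from .occurrences import BackgroundDefinition

__all__ = ["VifReport", "crop_mask", "compute_vif", "select_variables"]

DEFAULT_VIF_THRESHOLD = 10.0
DEFAULT_VIF_SAMPLE = 10_000


@dataclass
class VifReport:
    iterations: list = field(default_factory=list)  # (variable, vif at removal)
    retained: list = field(default_factory=list)
    threshold: float = DEFAULT_VIF_THRESHOLD
    forced: list = field(default_factory=list)
    seed: int = 0
    sample_size: int = 0

    @property
    def removed(self) -> list:
        return [name for name, _ in self.iterations]

    def to_dict(self) -> dict:
        return {
            "iterations": [(n, float(v)) for n, v in self.iterations],
            "retained": self.retained,
            "threshold": self.threshold,
            "forced": self.forced,
            "seed": self.seed,
            "sample_size": self.sample_size,
        }


def crop_mask(stack: ClimateStack, background: BackgroundDefinition) -> ClimateStack:
    """Mask the stack to the background and trim to its bounding box.

    Cells outside the background mask become nodata; values at retained
    cells are untouched (bit-exact).
    """
    mask = background.mask & stack.mask
    if not mask.any():
        raise ValueError("background mask does not intersect the stack")
    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    data = stack.data[:, r0:r1, c0:c1].copy()
    data[:, ~mask[r0:r1, c0:c1]] = np.nan
    grid = GridSpec(
        origin_lon=stack.grid.origin_lon + c0 * stack.grid.cell_size,
        origin_lat=stack.grid.origin_lat - r0 * stack.grid.cell_size,
        cell_size=stack.grid.cell_size,
        n_rows=r1 - r0,
        n_cols=c1 - c0,
    )
    return ClimateStack(list(stack.names), data, grid)


def compute_vif(sample: np.ndarray) -> np.ndarray:
    """VIF per column of an (n_obs, n_vars) sample.

    VIF_v = 1 / (1 - R^2_v) from an OLS fit (with intercept) of column v
    on all other columns.  Perfect collinearity yields +inf rather than
    an exception.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need >= 3 observations and >= 2 variables")
    if np.any(x.std(axis=0) == 0):
        raise ValueError("constant column in VIF sample")
    vifs = np.empty(x.shape[1])
    for v in range(x.shape[1]):
        others = sm.add_constant(np.delete(x, v, axis=1))
        r2 = sm.OLS(x[:, v], others).fit().rsquared
        vifs[v] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def select_variables(
    stack: ClimateStack,
    threshold: float = DEFAULT_VIF_THRESHOLD,
    forced: list | None = None,
    sample_size: int = DEFAULT_VIF_SAMPLE,
    seed: int = 0,
) -> VifReport:
    """Iterative VIF elimination over the stack's valid cells.

    At each step the non-forced variable with the largest VIF above the
    threshold is removed (ties broken by band order).  Terminates when
    every non-forced VIF is <= threshold or only forced variables
    remain.  VIFs are computed on one fixed random sample of cells.
    """
    forced = list(forced or [])
    for name in forced:
        if name not in stack.names:
            raise ValueError(f"forced variable {name!r} not in stack")

    rows, cols = np.nonzero(stack.mask)
    rng = np.random.default_rng(seed)
    if rows.size > sample_size:
        pick = rng.choice(rows.size, size=sample_size, replace=False)
        rows, cols = rows[pick], cols[pick]
    table = stack.table(rows, cols)

    names = list(stack.names)
    report = VifReport(threshold=threshold, forced=forced, seed=seed,
                       sample_size=rows.size)
    if set(forced) == set(names):
        warnings.warn("all variables forced; VIF filtering skipped")
        report.retained = names
        return report

    col_of = {n: i for i, n in enumerate(stack.names)}
    while len(names) > 1:
        vifs = compute_vif(table[:, [col_of[n] for n in names]])
        candidates = [
            (vifs[i], i) for i, n in enumerate(names)
            if n not in forced and vifs[i] > threshold
        ]
        if not candidates:
            break
        # largest VIF; ties broken by band order (smallest index wins)
        worst_vif = max(v for v, _ in candidates)
        worst_idx = min(i for v, i in candidates if v == worst_vif)
        report.iterations.append((names[worst_idx], float(worst_vif)))
        del names[worst_idx]
        if all(n in forced for n in names):
            warnings.warn("only forced variables remain above threshold")
            break
    report.retained = names
    return report
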