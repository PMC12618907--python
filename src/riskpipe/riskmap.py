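"""Risk mapping: suitability × introduction product, Jenks classes,
zonal means, and plantation overlap fractions.

Jenks natural breaks is the exact Fisher dynamic program minimizing the
total within-class sum of squared deviations of a 1-D sample — the
standard cartographic classifier for suitability and index maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from shapely import contains_xy
from shapely.ops import unary_union

from .grids import GridSpec, Raster

__all__ = [
    "ClassifiedMap",
    "normalize_surface",
    "invasion_risk",
    "jenks_breaks",
    "classify",
    "zonal_mean",
    "plantation_overlap",
]

SUITABILITY_LABELS = ("unsuitable", "marginal", "moderate", "high")
JENKS_SAMPLE_CAP = 10_000


def normalize_surface(raster: Raster) -> Raster:
    """Min-max rescale valid cells to [0, 1]; constant input → zeros."""
    vals = raster.values()
    if vals.size == 0:
        raise ValueError("raster has no valid cells")
    lo, hi = vals.min(), vals.max()
    out = np.full(raster.grid.shape, np.nan)
    if hi == lo:
        warnings.warn("constant raster; normalized surface set to zeros")
        out[raster.mask] = 0.0
    else:
        out[raster.mask] = (raster.data[raster.mask] - lo) / (hi - lo)
    return Raster(out, raster.grid)


def _resample_bilinear(src: Raster, target: GridSpec) -> Raster:
    lon, lat = target.cell_centers()
    col = (lon - src.grid.origin_lon) / src.grid.cell_size - 0.5
    row = (src.grid.origin_lat - lat) / src.grid.cell_size - 0.5
    data = map_coordinates(
        np.nan_to_num(src.data, nan=np.nan), [row, col], order=1,
        mode="nearest",
    )
    return Raster(data, target)


def invasion_risk(suitability: Raster, introduction: Raster) -> Raster:
    """Cellwise product of suitability and the normalized introduction
    surface; the introduction layer is bilinearly resampled first when
    the grids differ.  Nodata propagates."""
    if introduction.grid != suitability.grid:
        warnings.warn("resampling introduction surface to the suitability grid")
        introduction = _resample_bilinear(introduction, suitability.grid)
    return Raster(suitability.data * introduction.data, suitability.grid)


def jenks_breaks(values, k: int) -> np.ndarray:
    """Exact Fisher–Jenks natural breaks of a 1-D sample into k classes.

    Dynamic program minimizing total within-class sum of squared
    deviations; O(k·n²).  Returns the k−1 upper boundaries of the first
    k−1 classes (the largest value in each class).
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    v = v[np.isfinite(v)]
    n = v.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(v).size < k:
        raise ValueError(f"need at least {k} distinct values for {k} classes")

    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def seg_cost(j, i):
        # within-class SSD of v[j:i] for vectors j < i
        length = i - j
        sums = s1[i] - s1[j]
        return (s2[i] - s2[j]) - sums * sums / length

    # cost[c][i]: optimal SSD of first i values in c+1 classes
    cost = np.full(n + 1, np.inf)
    idx = np.arange(1, n + 1)
    cost[1:] = seg_cost(0, idx)
    cost[0] = 0.0
    back = np.zeros((k, n + 1), dtype=np.int64)
    for c in range(1, k):
        new_cost = np.full(n + 1, np.inf)
        for i in range(c + 1, n + 1):
            j = np.arange(c, i)
            total = cost[j] + seg_cost(j, i)
            best = int(np.argmin(total))
            new_cost[i] = total[best]
            back[c, i] = j[best]
        cost = new_cost

    bounds = np.empty(k - 1)
    i = n
    for c in range(k - 1, 0, -1):
        j = back[c, i]
        bounds[c - 1] = v[j - 1]  # largest value of the class ending at j
        i = j
    return bounds


@dataclass
class ClassifiedMap:
    labels: np.ndarray  # int grid, -1 = nodata
    breaks: np.ndarray
    label_names: tuple
    grid: GridSpec

    @property
    def mask(self) -> np.ndarray:
        return self.labels >= 0

    def class_counts(self) -> dict:
        return {
            name: int(np.sum(self.labels == i))
            for i, name in enumerate(self.label_names)
        }


def classify(
    raster: Raster,
    k: int = 4,
    labels: tuple = SUITABILITY_LABELS,
    sample_cap: int = JENKS_SAMPLE_CAP,
    seed: int = 0,
) -> ClassifiedMap:
    """Jenks-classify a raster into k classes.

    Breaks come from the full cell sample (or a uniform random sample of
    ``sample_cap`` cells on large grids).  A cell equal to a break falls
    in the lower class (first interval left-closed, others right-closed).
    """
    if len(labels) != k:
        raise ValueError("need one label per class")
    vals = raster.values()
    if vals.size > sample_cap:
        rng = np.random.default_rng(seed)
        vals = rng.choice(vals, size=sample_cap, replace=False)
    breaks = jenks_breaks(vals, k)
    out = np.full(raster.grid.shape, -1, dtype=np.int16)
    out[raster.mask] = np.searchsorted(breaks, raster.data[raster.mask],
                                       side="left")
    out[raster.mask] = np.clip(out[raster.mask], 0, k - 1)
    return ClassifiedMap(out, breaks, tuple(labels), raster.grid)


def zonal_mean(suitability: Raster, municipalities) -> pd.DataFrame:
    """Mean suitability per polygon (cell-center membership rule).

    ``municipalities`` is an iterable of (muni_id, shapely polygon).
    Polygons containing no valid cell center get NaN with a warning.
    """
    lon, lat = suitability.grid.cell_centers()
    valid = suitability.mask
    records = []
    for muni_id, poly in municipalities:
        inside = contains_xy(poly, lon, lat) & valid
        n = int(inside.sum())
        if n == 0:
            warnings.warn(f"municipality {muni_id} covers no valid cell center")
            mean = float("nan")
        else:
            mean = float(suitability.data[inside].mean())
        records.append({"muni_id": muni_id, "mean_suitability": mean, "n_cells": n})
    return pd.DataFrame(records)


def plantation_overlap(
    class_map: ClassifiedMap,
    plantations,
    target_resolution: float | None = None,
) -> pd.DataFrame:
    """Share of plantation area in each suitability class.

    Plantation polygons are rasterized on a grid at ``target_resolution``
    (degrees; defaults to the class map's cell size) spanning the class
    map extent; a fine cell belongs to a plantation when its center is
    covered.  Fractions are over fine cells that fall on labelled class
    cells, and sum to 1.
    """
    res = target_resolution or class_map.grid.cell_size
    g = class_map.grid
    fine = GridSpec(
        g.origin_lon, g.origin_lat, res,
        int(round(g.n_rows * g.cell_size / res)),
        int(round(g.n_cols * g.cell_size / res)),
    )
    merged = unary_union(list(plantations))
    lon, lat = fine.cell_centers()
    covered = contains_xy(merged, lon, lat)
    if not covered.any():
        raise ValueError("no fine cell center is covered by a plantation")
    rows, cols = g.index_of(lon[covered], lat[covered])
    inb = (rows >= 0) & (rows < g.n_rows) & (cols >= 0) & (cols < g.n_cols)
    cls = class_map.labels[rows[inb], cols[inb]]
    cls = cls[cls >= 0]
    if cls.size == 0:
        raise ValueError("plantations cover no labelled class cell")
    fractions = np.bincount(cls, minlength=len(class_map.label_names)) / cls.size
    return pd.DataFrame(
        {"class": list(class_map.label_names), "area_fraction": fractions}
    )
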