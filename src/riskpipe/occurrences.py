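"""Occurrence cleaning, spatial thinning, and background delimitation.

Spatial thinning enforces a minimum great-circle distance between
retained records (the standard defence against spatial autocorrelation
in presence-only modelling).  The training background is the union of
climate zones that contain at least one occurrence, following the
zone-based background delimitation used for presence-background models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .grids import ClimateStack, ZoneRaster

__all__ = [
    "OccurrenceSet",
    "ThinningConfig",
    "BackgroundDefinition",
    "haversine_km",
    "thin_occurrences",
    "select_background",
]

EARTH_RADIUS_KM = 6371.0

# below this record count the thinning optimum is found exactly on the
# conflict graph; above it the replicated greedy heuristic is used
EXACT_THINNING_MAX_N = 25


@dataclass
class OccurrenceSet:
    """Point records (lon/lat degrees) for one species."""

    species: str
    lons: np.ndarray
    lats: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.lons = np.atleast_1d(np.asarray(self.lons, dtype=float))
        self.lats = np.atleast_1d(np.asarray(self.lats, dtype=float))
        if self.lons.shape != self.lats.shape:
            raise ValueError("lons and lats must have equal length")
        bad = np.nonzero(
            ~np.isfinite(self.lons) | ~np.isfinite(self.lats)
            | (np.abs(self.lons) > 180) | (np.abs(self.lats) > 90)
        )[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"invalid coordinates at record {i}: "
                f"(lon={self.lons[i]}, lat={self.lats[i]})"
            )

    def __len__(self) -> int:
        return self.lons.size

    def subset(self, idx) -> "OccurrenceSet":
        return OccurrenceSet(self.species, self.lons[idx], self.lats[idx],
                             self.provenance)

    def dedup(self) -> "OccurrenceSet":
        """Drop exact duplicate coordinate pairs, keeping first occurrence."""
        _, keep = np.unique(
            np.column_stack([self.lons, self.lats]), axis=0, return_index=True
        )
        return self.subset(np.sort(keep))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": self.species, "lon": self.lons, "lat": self.lats}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "") -> "OccurrenceSet":
        df = pd.read_csv(path)
        required = {"species", "lon", "lat"}
        if not required.issubset(df.columns):
            raise ValueError(f"occurrence CSV must have columns {sorted(required)}")
        species = df["species"].iloc[0] if len(df) else "unknown"
        return cls(str(species), df["lon"].to_numpy(), df["lat"].to_numpy(),
                   provenance or str(path))


@dataclass(frozen=True)
class ThinningConfig:
    min_distance_km: float = 20.0
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_distance_km <= 0:
            raise ValueError("min_distance_km must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class BackgroundDefinition:
    """Training background: selected zones, cell mask, and sampled points."""

    selected_zone_ids: set
    mask: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    report: dict = field(default_factory=dict)

    @property
    def n_background_points(self) -> int:
        return self.rows.size


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (Earth radius 6371 km); broadcasts."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _pairwise_km(occ: OccurrenceSet) -> np.ndarray:
    return haversine_km(
        occ.lons[:, None], occ.lats[:, None], occ.lons[None, :], occ.lats[None, :]
    )


def _greedy_thin(conflict: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One spThin-style run: repeatedly drop a record with the most
    neighbours inside the threshold, random tie-break.  Returns a boolean
    keep-mask."""
    alive = np.ones(conflict.shape[0], dtype=bool)
    counts = conflict.sum(axis=1).astype(int)
    while counts[alive].max(initial=0) > 0:
        live_idx = np.nonzero(alive)[0]
        worst = live_idx[counts[live_idx] == counts[live_idx].max()]
        drop = rng.choice(worst)
        alive[drop] = False
        counts[conflict[drop]] -= 1
        counts[drop] = 0
    return alive


def _exact_thin(conflict: np.ndarray) -> np.ndarray:
    """Maximum independent set of the conflict graph (exact, small n):
    maximum clique on the complement graph."""
    n = conflict.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if not conflict[i, j]:
                g.add_edge(i, j)
    clique, _ = nx.algorithms.clique.max_weight_clique(g, weight=None)
    keep = np.zeros(n, dtype=bool)
    keep[list(clique)] = True
    return keep


def thin_occurrences(occ: OccurrenceSet, cfg: ThinningConfig) -> OccurrenceSet:
    """Spatially thin records to a minimum pairwise haversine distance.

    Exact duplicates are removed first.  For small sets the maximum
    number of retainable records is found exactly; for larger sets the
    replicated greedy heuristic is run ``n_replicates`` times and the
    best run (most records retained) is returned.  The result carries a
    ``thinning_report`` attribute with input/output counts and the
    per-replicate retention counts.
    """
    if len(occ) == 0:
        raise ValueError("cannot thin an empty occurrence set")
    deduped = occ.dedup()
    d = _pairwise_km(deduped)
    conflict = d < cfg.min_distance_km
    np.fill_diagonal(conflict, False)

    replicate_counts: list[int] = []
    if not conflict.any():
        keep = np.ones(len(deduped), dtype=bool)
        method = "none-needed"
    elif len(deduped) <= EXACT_THINNING_MAX_N:
        keep = _exact_thin(conflict)
        method = "exact"
    else:
        rng = np.random.default_rng(cfg.seed)
        keep = None
        for _ in range(cfg.n_replicates):
            candidate = _greedy_thin(conflict, rng)
            replicate_counts.append(int(candidate.sum()))
            if keep is None or candidate.sum() > keep.sum():
                keep = candidate
        method = "greedy-replicates"

    thinned = deduped.subset(np.nonzero(keep)[0])
    thinned.thinning_report = {
        "n_input": len(occ),
        "n_after_dedup": len(deduped),
        "n_retained": len(thinned),
        "min_distance_km": cfg.min_distance_km,
        "method": method,
        "n_replicates": cfg.n_replicates,
        "replicate_retention_counts": replicate_counts,
        "seed": cfg.seed,
    }
    return thinned


def select_background(
    occ: OccurrenceSet,
    zones: ZoneRaster,
    stack: ClimateStack,
    n_points: int = 10_000,
    seed: int = 0,
) -> BackgroundDefinition:
    """Delimit the background as the zones containing occurrences.

    The mask is true where the zone label belongs to an occupied zone
    and all predictors are valid; ``n_points`` cells are then sampled
    uniformly without replacement from the mask (capped at the number of
    available cells, with a warning).
    """
    inside = zones.grid.contains(occ.lons, occ.lats)
    row, col = zones.grid.index_of(occ.lons[inside], occ.lats[inside])
    labels = zones.labels[row, col]
    occupied = set(int(z) for z in labels[labels != zones.nodata])
    if not occupied:
        raise ValueError("no occurrence falls on a valid zone cell")

    mask = np.isin(zones.labels, list(occupied)) & stack.mask
    rows, cols = np.nonzero(mask)
    if n_points > rows.size:
        warnings.warn(
            f"requested {n_points} background points but only {rows.size} "
            "cells available; using all of them"
        )
        n_points = rows.size
    rng = np.random.default_rng(seed)
    pick = rng.choice(rows.size, size=n_points, replace=False)
    pick.sort()
    return BackgroundDefinition(
        selected_zone_ids=occupied,
        mask=mask,
        rows=rows[pick],
        cols=cols[pick],
        report={"n_mask_cells": int(mask.sum()), "seed": seed},
    )
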