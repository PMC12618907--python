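"""Synthetic world generator: every pipeline input, with known ground truth.

The generator emulates the ingredients of a desk-scale invasion-risk
study: spatially autocorrelated climate predictor fields with designed
collinearity, a virtual species whose occurrence probability is a known
smooth function of climate, a categorical zonation of climate space
(climate-zone role), a smooth introduction-likelihood surface, and a
municipality production table with a known concentration structure.
All outputs are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box, mapping
from sklearn.cluster import KMeans

from .grids import ClimateStack, GridSpec, Raster, ZoneRaster
from .occurrences import OccurrenceSet

__all__ = [
    "WorldSpec",
    "NicheSpec",
    "generate_climate_stack",
    "generate_virtual_species",
    "sample_presences",
    "generate_zone_raster",
    "generate_production_table",
    "generate_ancillary_surfaces",
]


@dataclass(frozen=True)
class WorldSpec:
    """Geometry and statistical structure of the synthetic world.

    ``collinear_pairs`` lists (i, j, r) triples: band j is rebuilt as a
    mixture of band i and fresh noise so that their sample Pearson
    correlation lands within 0.05 of the target r.  ``smoothness`` is
    the spatial correlation length in cells (Gaussian-kernel sigma).
    """

    n_rows: int = 60
    n_cols: int = 60
    cell_size_deg: float = 0.25
    origin_lon: float = -60.0
    origin_lat: float = 0.0
    n_predictors: int = 5
    collinear_pairs: tuple = ()
    smoothness: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 10 or self.n_cols < 10:
            raise ValueError("world must be at least 10x10 cells")
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")
        if not 0 < self.smoothness < min(self.n_rows, self.n_cols):
            raise ValueError("smoothness must lie in (0, min(n_rows, n_cols))")
        for i, j, r in self.collinear_pairs:
            if not (0 <= i < self.n_predictors and 0 <= j < self.n_predictors):
                raise ValueError(f"collinear pair ({i}, {j}) out of range")
            if i == j:
                raise ValueError("collinear pair must involve two distinct bands")
            if abs(r) >= 1.0:
                raise ValueError(f"collinearity target |r|={abs(r)} must be < 1")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            self.origin_lon, self.origin_lat, self.cell_size_deg,
            self.n_rows, self.n_cols,
        )


@dataclass(frozen=True)
class NicheSpec:
    """Gaussian niche response of the virtual species.

    Occurrence probability at a cell with predictor vector x is
    ``max_prob * prod_v exp(-(x_v - optimum_v)^2 / (2 tolerance_v^2))``.
    """

    optimum: tuple
    tolerance: tuple
    max_prob: float = 1.0

    def __post_init__(self) -> None:
        if len(self.optimum) != len(self.tolerance):
            raise ValueError("optimum and tolerance must have equal length")
        if any(t <= 0 for t in self.tolerance):
            raise ValueError("tolerance must be strictly positive")
        if not 0 < self.max_prob <= 1:
            raise ValueError("max_prob must lie in (0, 1]")


def _smooth_standard_field(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    """Gaussian-smoothed white noise, standardized to zero mean/unit variance."""
    field_ = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    return (field_ - field_.mean()) / field_.std()


def generate_climate_stack(spec: WorldSpec) -> ClimateStack:
    """Spatially autocorrelated, standardized predictor bands.

    Collinear pairs are built as ``rho * base + sqrt(1 - rho^2) * noise``
    from already-smoothed standardized fields, so the achieved sample
    correlation tracks the target closely (tolerance +-0.05 by contract).
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_rows, spec.n_cols)
    bands = [_smooth_standard_field(rng, shape, spec.smoothness)
             for _ in range(spec.n_predictors)]
    for i, j, r in spec.collinear_pairs:
        noise = _smooth_standard_field(rng, shape, spec.smoothness)
        mixed = r * bands[i] + np.sqrt(1.0 - r * r) * noise
        bands[j] = (mixed - mixed.mean()) / mixed.std()
    names = [f"pred{v}" for v in range(spec.n_predictors)]
    return ClimateStack(names, np.stack(bands), spec.grid)


def generate_virtual_species(stack: ClimateStack, niche: NicheSpec) -> Raster:
    """True occurrence-probability surface of the virtual species."""
    if len(niche.optimum) != stack.n_bands:
        raise ValueError(
            f"niche defined over {len(niche.optimum)} predictors, "
            f"stack has {stack.n_bands}"
        )
    opt = np.asarray(niche.optimum, dtype=float)[:, None, None]
    tol = np.asarray(niche.tolerance, dtype=float)[:, None, None]
    log_response = -((stack.data - opt) ** 2) / (2.0 * tol**2)
    prob = niche.max_prob * np.exp(log_response.sum(axis=0))
    prob[~stack.mask] = np.nan
    return Raster(prob, stack.grid)


def sample_presences(
    surface: Raster,
    n: int,
    seed: int,
    species: str = "virtual_species",
    replace: bool = False,
) -> OccurrenceSet:
    """Presence records at cell centers, weighted by the probability surface.

    Cells are drawn without replacement (default) with probability
    proportional to the surface value; only cells with positive
    probability are eligible.
    """
    prob = np.where(surface.mask, surface.data, 0.0)
    positive = prob > 0
    if not replace and n > positive.sum():
        raise ValueError(
            f"requested {n} presences but only {int(positive.sum())} cells "
            "have positive probability"
        )
    rng = np.random.default_rng(seed)
    flat = prob.ravel()
    idx = rng.choice(flat.size, size=n, replace=replace, p=flat / flat.sum())
    rows, cols = np.unravel_index(idx, prob.shape)
    lon, lat = surface.grid.cell_centers()
    return OccurrenceSet(
        species=species,
        lons=lon[rows, cols],
        lats=lat[rows, cols],
        provenance="synthetic virtual species",
    )


def generate_zone_raster(stack: ClimateStack, n_zones: int, seed: int) -> ZoneRaster:
    """Categorical zonation of climate space (climate-zone role).

    Valid cells are clustered by k-means on their standardized predictor
    vectors; cluster indices are relabelled 1..n_zones in order of first
    appearance in row-major scan, so labels are deterministic.
    """
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    mask = stack.mask
    rows, cols = np.nonzero(mask)
    x = stack.table(rows, cols)
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    km = KMeans(n_clusters=n_zones, n_init=5, random_state=seed)
    raw = km.fit_predict(x)
    _, first_order = np.unique(raw, return_index=True)
    relabel = np.empty(n_zones, dtype=np.int16)
    relabel[raw[np.sort(first_order)]] = np.arange(1, n_zones + 1)
    labels = np.full(stack.grid.shape, -1, dtype=np.int16)
    labels[rows, cols] = relabel[raw]
    return ZoneRaster(labels, stack.grid)


def generate_production_table(
    n_municipalities: int,
    n_concentrated: int,
    concentration_share: float,
    seed: int,
    national_product_value: float = 1_000_000.0,
) -> pd.DataFrame:
    """Municipality production table with designed concentration.

    ``n_concentrated`` municipalities jointly hold ``concentration_share``
    of the national product value; every municipality's total forestry
    value is at least its product value (the product is one forestry line
    among others).  Columns: muni_id, vp_product, vp_forestry_total.
    """
    if not 0 < concentration_share < 1:
        raise ValueError("concentration_share must lie in (0, 1)")
    if not 0 < n_concentrated < n_municipalities:
        raise ValueError("n_concentrated must lie in (0, n_municipalities)")
    rng = np.random.default_rng(seed)
    top = rng.dirichlet(np.full(n_concentrated, 5.0))
    rest = rng.dirichlet(np.ones(n_municipalities - n_concentrated))
    vp_product = np.concatenate(
        [top * concentration_share, rest * (1.0 - concentration_share)]
    ) * national_product_value
    # other forestry production on top of the product itself
    other = rng.gamma(2.0, 0.5, size=n_municipalities) * vp_product.mean()
    table = pd.DataFrame(
        {
            "muni_id": [f"M{j:04d}" for j in range(n_municipalities)],
            "vp_product": vp_product,
            "vp_forestry_total": vp_product + other,
        }
    )
    return table


@dataclass
class AncillarySurfaces:
    """Introduction-likelihood surface plus municipality/plantation polygons."""

    introduction: Raster
    municipalities: list  # (muni_id, shapely Polygon)
    plantations: list  # shapely Polygons
    municipality_cells: dict = field(default_factory=dict)  # muni_id -> (rows, cols)


def generate_ancillary_surfaces(
    spec: WorldSpec,
    seed: int,
    n_muni_x: int = 4,
    n_muni_y: int = 4,
    n_plantations: int = 3,
) -> AncillarySurfaces:
    """Stand-ins for the introduction map and the vector layers.

    The introduction surface is a smooth field on an arbitrary scale
    (exercises downstream min-max normalization).  Municipalities tile a
    rectangular block of the grid with no overlaps, aligned to cell
    edges so cell-center membership is unambiguous; plantations are
    cell-aligned rectangles inside that block.
    """
    rng = np.random.default_rng(seed)
    grid = spec.grid
    intro = _smooth_standard_field(rng, grid.shape, spec.smoothness)
    intro = 12.0 + 37.0 * (intro - intro.min()) / (intro.max() - intro.min())

    # municipality block: central ~80% of the grid, split into a tiling
    r0, c0 = spec.n_rows // 10, spec.n_cols // 10
    r1, c1 = spec.n_rows - r0, spec.n_cols - c0
    row_edges = np.linspace(r0, r1, n_muni_y + 1).round().astype(int)
    col_edges = np.linspace(c0, c1, n_muni_x + 1).round().astype(int)

    def cell_box(ra, rb, ca, cb):
        west = grid.origin_lon + ca * grid.cell_size
        east = grid.origin_lon + cb * grid.cell_size
        north = grid.origin_lat - ra * grid.cell_size
        south = grid.origin_lat - rb * grid.cell_size
        return box(west, south, east, north)

    municipalities, membership = [], {}
    k = 0
    for iy in range(n_muni_y):
        for ix in range(n_muni_x):
            ra, rb = row_edges[iy], row_edges[iy + 1]
            ca, cb = col_edges[ix], col_edges[ix + 1]
            muni_id = f"M{k:04d}"
            municipalities.append((muni_id, cell_box(ra, rb, ca, cb)))
            rr, cc = np.meshgrid(np.arange(ra, rb), np.arange(ca, cb), indexing="ij")
            membership[muni_id] = (rr.ravel(), cc.ravel())
            k += 1

    plantations = []
    for _ in range(n_plantations):
        h = int(rng.integers(2, max(3, (r1 - r0) // 3)))
        w = int(rng.integers(2, max(3, (c1 - c0) // 3)))
        ra = int(rng.integers(r0, r1 - h))
        ca = int(rng.integers(c0, c1 - w))
        plantations.append(cell_box(ra, ra + h, ca, ca + w))

    return AncillarySurfaces(
        introduction=Raster(intro, grid),
        municipalities=municipalities,
        plantations=plantations,
        municipality_cells=membership,
    )


def write_geojson(path: str | Path, geometries, ids=None) -> None:
    """Write polygons as a GeoJSON FeatureCollection (plain JSON text)."""
    features = []
    for k, geom in enumerate(geometries):
        props = {"muni_id": ids[k]} if ids is not None else {}
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(geom)}
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
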