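"""Lightweight raster containers with a north-up geotransform.

All grids in the pipeline are plain numpy arrays tagged with a
:class:`GridSpec` (origin at the north-west corner, square cells in
degrees).  Continuous rasters use NaN as nodata; categorical rasters use
an integer sentinel.  On-disk exchange uses the ESRI ASCII grid format
(plain text), one file per band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "Raster", "ClimateStack", "ZoneRaster"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster: NW-corner origin and square cells."""

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Longitude/latitude of every cell center as (lon, lat) 2-D arrays."""
        lon = self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lat = self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(lon, lat)

    def index_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the given coordinates."""
        col = np.floor((np.asarray(lon) - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((self.origin_lat - np.asarray(lat)) / self.cell_size).astype(int)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.index_of(lon, lat)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


@dataclass
class Raster:
    """Single-band continuous raster; NaN marks nodata."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid of valid (non-nodata) cells."""
        return np.isfinite(self.data)

    def values(self) -> np.ndarray:
        """Valid cell values as a 1-D array."""
        return self.data[self.mask]

    def write_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        write_ascii_grid(path, self.data, self.grid, nodata=nodata)

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        data, grid = read_ascii_grid(path)
        return cls(data, grid)


@dataclass
class ZoneRaster:
    """Categorical raster of climate-zone labels 1..n; -1 marks nodata."""

    labels: np.ndarray
    grid: GridSpec
    nodata: int = -1

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")

    @property
    def mask(self) -> np.ndarray:
        return self.labels != self.nodata

    def zone_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.mask])

    def write_ascii(self, path: str | Path) -> None:
        write_ascii_grid(path, self.labels, self.grid, nodata=self.nodata, fmt="%d")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "ZoneRaster":
        data, grid = read_ascii_grid(path)
        labels = np.where(np.isfinite(data), data, -1).astype(np.int16)
        return cls(labels, grid)


@dataclass
class ClimateStack:
    """Aligned multiband predictor grid.

    ``data`` has shape (n_bands, n_rows, n_cols); all bands share the
    geotransform and the validity mask (NaN outside it).
    """

    names: list[str]
    data: np.ndarray
    grid: GridSpec
    _mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3-D (bands, rows, cols)")
        if len(self.names) != self.data.shape[0]:
            raise ValueError("one name per band required")
        if self.data.shape[1:] != self.grid.shape:
            raise ValueError("band shape does not match grid")
        if len(set(self.names)) != len(self.names):
            raise ValueError("band names must be unique")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def mask(self) -> np.ndarray:
        """Cells where every band is finite."""
        if self._mask is None:
            self._mask = np.all(np.isfinite(self.data), axis=0)
        return self._mask

    def band(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]

    def table(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Predictor values at (row, col) cells, shape (n_cells, n_bands)."""
        return self.data[:, rows, cols].T

    def subset(self, names: list[str]) -> "ClimateStack":
        idx = [self.names.index(n) for n in names]
        return ClimateStack(list(names), self.data[idx].copy(), self.grid)

    def write_dir(self, out_dir: str | Path) -> None:
        """One ASCII grid per band plus a JSON manifest of band names."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, name in enumerate(self.names):
            write_ascii_grid(out_dir / f"{name}.asc", self.data[i], self.grid)
        (out_dir / "bands.json").write_text(json.dumps({"bands": self.names}))

    @classmethod
    def read_dir(cls, in_dir: str | Path) -> "ClimateStack":
        in_dir = Path(in_dir)
        names = json.loads((in_dir / "bands.json").read_text())["bands"]
        bands, grid = [], None
        for name in names:
            data, g = read_ascii_grid(in_dir / f"{name}.asc")
            grid = grid or g
            if g != grid:
                raise ValueError(f"band {name} has inconsistent geometry")
            bands.append(data)
        return cls(names, np.stack(bands), grid)


def write_ascii_grid(path, data, grid: GridSpec, nodata=-9999.0, fmt="%.10g") -> None:
    data = np.asarray(data, dtype=float)
    out = np.where(np.isfinite(data), data, float(nodata))
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_lon!r}\n"
        f"yllcorner {grid.origin_lat - grid.n_rows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(n_rows, n_cols)
    data[data == header["nodata_value"]] = np.nan
    grid = GridSpec(
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return data, grid
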