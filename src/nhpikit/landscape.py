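"""Co-registered elevation + land-cover grids on a planar metric CRS.

The landscape is the spatial substrate of the analysis: a 100 m (by
default) raster with a continuous elevation band and a categorical
land-cover band using a fixed six-class vocabulary emulating Corine Land
Cover (arable, grassland, forest, urban, water, mosaic).  All
coordinates are planar metres; row 0 is the *southern* (bottom) edge
internally, so y increases with the row index.

Rasters are stored on disk as paired ESRI ASCII grids (plain text), one
per band, which keeps fixtures human-readable and diff-able.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Fixed land-cover vocabulary; integer codes are the positions here.
LAND_COVER_CLASSES: tuple[str, ...] = (
    "arable",
    "grassland",
    "forest",
    "urban",
    "water",
    "mosaic",
)

LAND_COVER_CODES = {name: i for i, name in enumerate(LAND_COVER_CLASSES)}


class LandscapeError(ValueError):
    """Raised for malformed or inconsistent landscape grids."""


@dataclass
class LandscapeRaster:
    """Elevation (m) and land-cover grids sharing one registration.

    Parameters
    ----------
    x0, y0
        Coordinates (m) of the lower-left *corner* of the grid.
    cell_size
        Cell edge length in metres (> 0).
    elevation
        ``(n_rows, n_cols)`` float array, metres; row 0 = bottom.
    land_cover
        ``(n_rows, n_cols)`` int array of codes into
        :data:`LAND_COVER_CLASSES`.
    """

    x0: float
    y0: float
    cell_size: float
    elevation: np.ndarray
    land_cover: np.ndarray

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.land_cover = np.asarray(self.land_cover, dtype=int)
        if self.cell_size <= 0:
            raise LandscapeError("cell_size must be positive")
        if self.elevation.shape != self.land_cover.shape:
            raise LandscapeError(
                "elevation and land_cover grids differ in shape: "
                f"{self.elevation.shape} vs {self.land_cover.shape}"
            )
        if self.elevation.ndim != 2:
            raise LandscapeError("grids must be 2-D")
        if not np.all(np.isfinite(self.elevation)):
            raise LandscapeError("elevation contains non-finite values")
        bad = (self.land_cover < 0) | (self.land_cover >= len(LAND_COVER_CLASSES))
        if bad.any():
            codes = sorted(set(self.land_cover[bad].tolist()))
            raise LandscapeError(f"unknown land-cover codes: {codes}")

    @property
    def n_rows(self) -> int:
        return self.elevation.shape[0]

    @property
    def n_cols(self) -> int:
        return self.elevation.shape[1]

    @property
    def x_max(self) -> float:
        return self.x0 + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y0 + self.n_rows * self.cell_size

    def contains(self, x, y) -> np.ndarray:
        """Vectorised point-in-raster test (open upper edge)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x0) & (x < self.x_max) & (y >= self.y0) & (y < self.y_max)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the cell containing each planar point."""
        row = np.floor((np.asarray(y, dtype=float) - self.y0) / self.cell_size).astype(int)
        col = np.floor((np.asarray(x, dtype=float) - self.x0) / self.cell_size).astype(int)
        return row, col

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y0 + (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def cell_center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """``(X, Y)`` centre-coordinate arrays of shape (n_rows, n_cols)."""
        rows = np.arange(self.n_rows)
        cols = np.arange(self.n_cols)
        cx = self.x0 + (cols + 0.5) * self.cell_size
        cy = self.y0 + (rows + 0.5) * self.cell_size
        return np.meshgrid(cx, cy)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (text)

def _write_asc(path: Path, raster: LandscapeRaster, grid: np.ndarray, fmt: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.x0:.6f}\n")
        fh.write(f"yllcorner {raster.y0:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write("NODATA_value -9999\n")
        # ASCII grids are written north-up: top row first.
        np.savetxt(fh, grid[::-1], fmt=fmt)


def write_landscape(raster: LandscapeRaster, directory: str | Path, stem: str = "landscape") -> dict[str, Path]:
    """Write elevation and land-cover as paired ``.asc`` text grids."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "elevation": directory / f"{stem}_elevation.asc",
        "land_cover": directory / f"{stem}_landcover.asc",
    }
    _write_asc(paths["elevation"], raster, raster.elevation, "%.3f")
    _write_asc(paths["land_cover"], raster, raster.land_cover, "%d")
    return paths


def _read_asc(path: Path) -> tuple[dict, np.ndarray]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0][0].isalpha():
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    grid = np.loadtxt(io.StringIO("".join(lines[n_header:])))
    grid = np.atleast_2d(grid)[::-1]  # back to row 0 = bottom
    return header, grid


def read_landscape(elevation_path: str | Path, land_cover_path: str | Path) -> LandscapeRaster:
    """Load a landscape from paired ASCII grids, validating registration."""
    h_el, elevation = _read_asc(Path(elevation_path))
    h_lc, land_cover = _read_asc(Path(land_cover_path))
    if elevation.shape != land_cover.shape:
        raise LandscapeError(
            f"grid shapes differ: {elevation.shape} vs {land_cover.shape}"
        )
    for key in ("xllcorner", "yllcorner", "cellsize"):
        if abs(h_el.get(key, np.nan) - h_lc.get(key, np.nan)) > 1e-6:
            raise LandscapeError(f"grid registration differs on {key}")
    return LandscapeRaster(
        x0=h_el["xllcorner"],
        y0=h_el["yllcorner"],
        cell_size=h_el["cellsize"],
        elevation=elevation,
        land_cover=np.rint(land_cover).astype(int),
    )
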