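"""Regular lon/lat grids and single-variable surfaces.

A :class:`GridGeometry` describes a regular grid of square cells in
geographic coordinates (WGS84) with the cell size given in arc-minutes,
matching the 2.5 arc-min working resolution of gridded bioclimatic
products.  A :class:`GridSurface` couples one value per cell with a
validity mask.  Surfaces round-trip through the ESRI ASCII grid format,
which is plain text and widely understood by GIS software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridGeometry", "GridSurface", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular geographic grid.

    ``origin_lon``/``origin_lat`` are the coordinates of the *center* of
    the upper-left cell; ``cell_size_arcmin`` is the edge length of a
    cell in arc-minutes.  Rows run north to south.
    """

    origin_lon: float
    origin_lat: float
    cell_size_arcmin: float
    n_rows: int
    n_cols: int

    @property
    def cell_size_deg(self) -> float:
        return self.cell_size_arcmin / 60.0

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols) of cell centers."""
        step = self.cell_size_deg
        lon = self.origin_lon + step * np.arange(self.n_cols)
        lat = self.origin_lat - step * np.arange(self.n_rows)
        return np.meshgrid(lon, lat)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a point; raises if outside."""
        step = self.cell_size_deg
        col = int(round((lon - self.origin_lon) / step))
        row = int(round((self.origin_lat - lat) / step))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) falls outside the grid")
        return row, col


@dataclass
class GridSurface:
    """One variable on a regular grid with a validity mask."""

    geometry: GridGeometry
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # True where valid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise ValueError("values shape does not match geometry")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match geometry")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values on unmasked cells")

    def same_geometry(self, other: "GridSurface") -> bool:
        return self.geometry == other.geometry

    def masked(self) -> np.ndarray:
        """Values with invalid cells set to NaN."""
        out = self.values.copy()
        out[~self.mask] = np.nan
        return out

    def copy_with(self, values: np.ndarray) -> "GridSurface":
        return GridSurface(self.geometry, np.asarray(values, float), self.mask.copy())


def write_ascii_grid(surface: GridSurface, path, nodata: float = -9999.0) -> None:
    """Write a surface as an ESRI ASCII grid (cell-center registration)."""
    geom = surface.geometry
    step = geom.cell_size_deg
    vals = surface.values.copy()
    vals[~surface.mask] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {geom.n_cols}\n")
        fh.write(f"nrows {geom.n_rows}\n")
        fh.write(f"xllcenter {geom.origin_lon:.17g}\n")
        # yllcenter refers to the lower-left cell center
        fh.write(f"yllcenter {geom.origin_lat - step * (geom.n_rows - 1):.17g}\n")
        fh.write(f"cellsize {step:.17g}\n")
        fh.write(f"nodata_value {nodata:.17g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_ascii_grid(path) -> GridSurface:
    """Read an ESRI ASCII grid written with cell-center registration."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcenter", "xllcorner",
                       "yllcenter", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    step = header["cellsize"]
    if "xllcenter" in header:
        x0, y0 = header["xllcenter"], header["yllcenter"]
    else:  # corner registration
        x0 = header["xllcorner"] + step / 2.0
        y0 = header["yllcorner"] + step / 2.0
    values = np.asarray(rows, dtype=float)
    if values.shape != (n_rows, n_cols):
        raise ValueError("grid body does not match declared dimensions")
    nodata = header.get("nodata_value", -9999.0)
    mask = values != nodata
    values = np.where(mask, values, 0.0)
    geom = GridGeometry(
        origin_lon=x0,
        origin_lat=y0 + step * (n_rows - 1),
        cell_size_arcmin=step * 60.0,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return GridSurface(geom, values, mask)
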