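"""Single-band raster data model and grid operations.

The raster model is deliberately minimal: a north-up grid of square cells in a
projected planar coordinate system (meters), a value matrix, and a boolean
validity mask.  The cell-center convention is used throughout: the center of
cell (row ``r``, col ``c``) sits at ``(origin_x + (c + 0.5) * cell_size,
origin_y - (r + 0.5) * cell_size)``, with ``(origin_x, origin_y)`` the outer
corner of the top-left cell.  All point-in-cell and zonal logic works on
centers, which keeps every operation exactly testable.

NDVI (Normalized Difference Vegetation Index) is ``(NIR - red)/(NIR + red)``
and lies in [-1, 1]; negative values indicate non-biomass surfaces such as
open water and are masked out before any green-space exposure is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates


@dataclass(frozen=True)
class RasterGrid:
    """A single-band georeferenced grid with a validity mask.

    Parameters
    ----------
    values : (n_rows, n_cols) float array
        Cell values; entries where ``valid`` is False are ignored.
    origin_x, origin_y : float
        Coordinates (meters) of the top-left corner of the top-left cell.
        ``y`` decreases with row index (north-up).
    cell_size : float
        Side length of the square cells, meters.
    valid : (n_rows, n_cols) bool array, optional
        False marks nodata / filtered cells.  Defaults to all-valid.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("values must be a 2-D matrix with at least one cell")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        valid = self.valid
        if valid is None:
            valid = np.ones(values.shape, dtype=bool)
        else:
            valid = np.asarray(valid, dtype=bool)
            if valid.shape != values.shape:
                raise ValueError(
                    f"valid mask shape {valid.shape} != values shape {values.shape}"
                )
        if not np.all(np.isfinite(values[valid])):
            raise ValueError("non-finite value in a valid cell")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid", valid)

    # -- geometry ----------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full cell footprint."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def geometry(self) -> tuple[int, int, float, float, float]:
        return (self.n_rows, self.n_cols, self.origin_x, self.origin_y, self.cell_size)

    def same_geometry(self, other: "RasterGrid") -> bool:
        return self.geometry() == other.geometry()

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates of cell(s) (row, col); accepts arrays."""
        row = np.asarray(row)
        col = np.asarray(col)
        cx = self.origin_x + (col + 0.5) * self.cell_size
        cy = self.origin_y - (row + 0.5) * self.cell_size
        return cx, cy

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Full matrices of cell-center x and y coordinates."""
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return self.cell_center(rows, cols)

    def with_values(self, values: np.ndarray, valid: np.ndarray | None = None) -> "RasterGrid":
        """New raster on this grid's geometry."""
        return RasterGrid(
            values=values,
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            valid=self.valid.copy() if valid is None else valid,
        )


@dataclass(frozen=True)
class NdviStack:
    """Time-ordered annual NDVI layers sharing one grid geometry."""

    years: tuple[int, ...]
    layers: tuple[RasterGrid, ...]

    def __post_init__(self):
        years = tuple(int(y) for y in self.years)
        layers = tuple(self.layers)
        if len(years) != len(layers):
            raise ValueError("one layer per year required")
        if len(years) == 0:
            raise ValueError("empty stack")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError(f"years must be strictly increasing, got {years}")
        geo = layers[0].geometry()
        for y, lay in zip(years, layers):
            if lay.geometry() != geo:
                raise ValueError(
                    f"layer {y} geometry {lay.geometry()} != first layer {geo}"
                )
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "layers", layers)

    def __len__(self) -> int:
        return len(self.years)

    def layer(self, year: int) -> RasterGrid:
        try:
            return self.layers[self.years.index(int(year))]
        except ValueError:
            raise KeyError(f"year {year} not in stack {self.years}") from None

    def map(self, fn) -> "NdviStack":
        """Apply a RasterGrid -> RasterGrid function to every layer."""
        return NdviStack(years=self.years, layers=tuple(fn(l) for l in self.layers))


# ---------------------------------------------------------------------------
# operations


def compute_ndvi(nir: RasterGrid, red: RasterGrid) -> RasterGrid:
    """NDVI = (NIR - red) / (NIR + red), cellwise.

    Cells where the denominator vanishes, or where either band is invalid,
    come out invalid.  Inputs are surface reflectances (non-negative), so the
    result is confined to [-1, 1].
    """
    if not nir.same_geometry(red):
        raise ValueError(
            f"geometry mismatch: NIR {nir.geometry()} vs red {red.geometry()}"
        )
    denom = nir.values + red.values
    valid = nir.valid & red.valid & (denom != 0)
    out = np.zeros_like(nir.values)
    np.divide(nir.values - red.values, denom, out=out, where=valid)
    out[~valid] = 0.0
    return nir.with_values(out, valid=valid)


def apply_scale(raster: RasterGrid, factor: float) -> RasterGrid:
    """Multiply every valid value by ``factor`` (e.g. the 1e-4 factor that
    converts stored integer NDVI to the physical [-1, 1] scale)."""
    if not factor > 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    out = raster.values * factor
    out[~raster.valid] = 0.0
    return raster.with_values(out)


def filter_water(raster: RasterGrid) -> RasterGrid:
    """Mask cells with NDVI strictly below zero (open water / non-biomass).

    Values are untouched; only the mask changes.  Zero itself survives.
    """
    return raster.with_values(
        raster.values.copy(), valid=raster.valid & ~(raster.values < 0)
    )


def bilinear_downscale(raster: RasterGrid, target_cell_size: float) -> RasterGrid:
    """Resample to a finer grid by bilinear interpolation of cell centers.

    The output covers the same extent.  Each output center takes the bilinear
    interpolation of the four surrounding input centers; outside the hull of
    input centers values clamp to the nearest edge (so border buffers lose no
    cells to interpolation artifacts).  Where some of the four neighbors are
    invalid their weight is redistributed over the valid ones; a cell whose
    entire neighborhood is invalid is itself invalid.
    """
    if not 0 < target_cell_size <= raster.cell_size:
        raise ValueError(
            f"target cell size {target_cell_size} must be in (0, {raster.cell_size}]"
            " — this operation only refines"
        )
    n_rows = int(round(raster.n_rows * raster.cell_size / target_cell_size))
    n_cols = int(round(raster.n_cols * raster.cell_size / target_cell_size))
    # fractional input indices of the output cell centers
    out_r = (np.arange(n_rows) + 0.5) * target_cell_size / raster.cell_size - 0.5
    out_c = (np.arange(n_cols) + 0.5) * target_cell_size / raster.cell_size - 0.5
    rr, cc = np.meshgrid(out_r, out_c, indexing="ij")
    coords = np.stack([rr, cc])

    w = raster.valid.astype(float)
    vw = np.where(raster.valid, raster.values, 0.0)
    num = map_coordinates(vw, coords, order=1, mode="nearest")
    den = map_coordinates(w, coords, order=1, mode="nearest")
    valid = den > 0
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=valid)
    return RasterGrid(
        values=out,
        origin_x=raster.origin_x,
        origin_y=raster.origin_y,
        cell_size=target_cell_size,
        valid=valid,
    )


def clip(raster: RasterGrid, xmin: float, ymin: float, xmax: float, ymax: float) -> RasterGrid:
    """Sub-grid of all cells whose centers fall inside the window (inclusive)."""
    cx = raster.origin_x + (np.arange(raster.n_cols) + 0.5) * raster.cell_size
    cy = raster.origin_y - (np.arange(raster.n_rows) + 0.5) * raster.cell_size
    keep_c = (cx >= xmin) & (cx <= xmax)
    keep_r = (cy >= ymin) & (cy <= ymax)
    if not keep_c.any() or not keep_r.any():
        raise ValueError(
            f"clip window ({xmin}, {ymin}, {xmax}, {ymax}) contains no cell center"
        )
    r0, r1 = np.flatnonzero(keep_r)[[0, -1]]
    c0, c1 = np.flatnonzero(keep_c)[[0, -1]]
    return RasterGrid(
        values=raster.values[r0 : r1 + 1, c0 : c1 + 1].copy(),
        origin_x=raster.origin_x + c0 * raster.cell_size,
        origin_y=raster.origin_y - r0 * raster.cell_size,
        cell_size=raster.cell_size,
        valid=raster.valid[r0 : r1 + 1, c0 : c1 + 1].copy(),
    )
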