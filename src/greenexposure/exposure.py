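"""Circular-buffer zonal statistics: mean NDVI around each address.

The exposure of an address is the unweighted arithmetic mean of valid raster
cells whose centers fall within a given radius of the point (center-in-disc
inclusion, boundary cells included).  Masked cells — water, nodata — carry no
weight; an address whose buffer contains no valid cell gets a missing value,
never zero.  Buffers truncated by the raster edge simply use the cells that
exist, mirroring addresses near a study-area border.

The central product is the :class:`ExposureMatrix`: a pandas DataFrame of
addresses (rows) by (year, radius) columns, the object every statistical
procedure downstream consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .raster import NdviStack, RasterGrid
from .scene import AddressSet

DEFAULT_RADII = (300.0, 600.0, 1000.0)


def buffer_cells(grid: RasterGrid, x: float, y: float, radius: float) -> set[tuple[int, int]]:
    """Indices of cells whose centers lie within ``radius`` of (x, y)."""
    rows, cols = _buffer_indices(grid, x, y, radius)
    return set(zip(rows.tolist(), cols.tolist()))


def _buffer_indices(grid: RasterGrid, x, y, radius):
    if not radius > 0:
        raise ValueError(f"radius must be positive, got {radius}")
    cs = grid.cell_size
    # candidate row/col window, then exact center-in-disc test
    c_lo = max(0, int(np.floor((x - radius - grid.origin_x) / cs - 0.5)))
    c_hi = min(grid.n_cols - 1, int(np.ceil((x + radius - grid.origin_x) / cs - 0.5)))
    r_lo = max(0, int(np.floor((grid.origin_y - y - radius) / cs - 0.5)))
    r_hi = min(grid.n_rows - 1, int(np.ceil((grid.origin_y - y + radius) / cs - 0.5)))
    if c_lo > c_hi or r_lo > r_hi:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    rr = np.arange(r_lo, r_hi + 1)
    cc = np.arange(c_lo, c_hi + 1)
    cx = grid.origin_x + (cc + 0.5) * cs
    cy = grid.origin_y - (rr + 0.5) * cs
    d2 = (cx[None, :] - x) ** 2 + (cy[:, None] - y) ** 2
    inside = d2 <= radius * radius
    ri, ci = np.nonzero(inside)
    return rr[ri], cc[ci]


def buffer_mean(grid: RasterGrid, x: float, y: float, radius: float) -> float:
    """Mean of valid cell values in the disc; NaN when no valid cell falls in it."""
    rows, cols = _buffer_indices(grid, x, y, radius)
    if rows.size == 0:
        return float("nan")
    vals = grid.values[rows, cols]
    ok = grid.valid[rows, cols]
    if not ok.any():
        return float("nan")
    return float(vals[ok].mean())


def buffer_stats(stack: NdviStack, x: float, y: float, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-year (mean, valid-cell count) for one address and radius.

    Shares one center-in-disc computation across all layers, which all sit on
    the same grid.
    """
    grid = stack.layers[0]
    rows, cols = _buffer_indices(grid, x, y, radius)
    n_years = len(stack)
    means = np.full(n_years, np.nan)
    counts = np.zeros(n_years, dtype=int)
    if rows.size == 0:
        return means, counts
    for i, layer in enumerate(stack.layers):
        ok = layer.valid[rows, cols]
        k = int(ok.sum())
        counts[i] = k
        if k:
            means[i] = layer.values[rows, cols][ok].mean()
    return means, counts


def build_exposure_matrix(
    stack: NdviStack, addresses: AddressSet, radii=DEFAULT_RADII
) -> pd.DataFrame:
    """Addresses x (year, radius) mean-NDVI table.

    Columns form the full years-by-radii cross product as a two-level
    (year, radius_m) MultiIndex; rows follow the address order.  A companion
    integer count of contributing cells is attached as ``df.attrs["counts"]``.
    """
    radii = [float(r) for r in radii]
    if len(stack) == 0 or len(addresses) == 0 or len(radii) == 0:
        raise ValueError("stack, addresses and radii must all be non-empty")
    columns = pd.MultiIndex.from_product(
        [list(stack.years), radii], names=["year", "radius_m"]
    )
    out = np.full((len(addresses), len(columns)), np.nan)
    cnt = np.zeros((len(addresses), len(columns)), dtype=int)
    n_years = len(stack)
    for i, (px, py) in enumerate(zip(addresses.x, addresses.y)):
        for j, radius in enumerate(radii):
            means, counts = buffer_stats(stack, px, py, radius)
            for t in range(n_years):
                out[i, t * len(radii) + j] = means[t]
                cnt[i, t * len(radii) + j] = counts[t]
    df = pd.DataFrame(out, index=pd.Index(addresses.ids, name="id"), columns=columns)
    df.attrs["counts"] = pd.DataFrame(cnt, index=df.index, columns=columns)
    return df


def exposure_to_csv(df: pd.DataFrame, path: str) -> None:
    """Write with flat ``<year>_<radius>`` headers; missing as empty fields."""
    flat = df.copy()
    flat.columns = [f"{int(y)}_{int(r)}" for y, r in df.columns]
    flat.to_csv(path, float_format="%.10g", na_rep="")


def exposure_from_csv(path: str) -> pd.DataFrame:
    flat = pd.read_csv(path, index_col="id")
    pairs = [tuple(c.split("_")) for c in flat.columns]
    flat.columns = pd.MultiIndex.from_tuples(
        [(int(y), float(r)) for y, r in pairs], names=["year", "radius_m"]
    )
    return flat
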