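"""GeoTIFF reading and writing for :class:`~greenexposure.raster.RasterGrid`.

Only the subset of GeoTIFF this pipeline needs is supported: one band, square
pixels, north-up, planar projected coordinates.  Georeferencing is carried by
the standard ModelPixelScale / ModelTiepoint tags; nodata cells are stored as
a sentinel recorded in the GDAL_NODATA ASCII tag, and exist in memory only as
the boolean validity mask.  Values are stored as float64, so a write/read
round trip is bit-exact.
"""

from __future__ import annotations

import os

import numpy as np
import tifffile

from .raster import RasterGrid

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


def write_geotiff(raster: RasterGrid, path: str, nodata: float = DEFAULT_NODATA) -> None:
    """Write a single-band float64 GeoTIFF; invalid cells become ``nodata``."""
    if np.any(raster.values[raster.valid] == nodata):
        raise ValueError(
            f"nodata sentinel {nodata} collides with a valid cell value; pick another"
        )
    data = np.where(raster.valid, raster.values, nodata).astype(np.float64)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (raster.cell_size, raster.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, raster.origin_x, raster.origin_y, 0.0)),
        (_GDAL_NODATA, "s", 0, repr(nodata)),
    ]
    tifffile.imwrite(path, data, photometric="minisblack", extratags=extratags)


def read_geotiff(path: str) -> RasterGrid:
    """Read a single-band square-pixel GeoTIFF into a RasterGrid."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such raster file: {path}")
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: expected a single-band (one page) GeoTIFF")
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise ValueError(f"{path}: expected one sample per pixel, got shape {data.shape}")
        tags = page.tags
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_MODEL_PIXEL_SCALE].value[:2]
        if not np.isclose(sx, sy):
            raise ValueError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
        tie = tags[_MODEL_TIEPOINT].value
        if tuple(tie[:3]) != (0.0, 0.0, 0.0):
            raise ValueError(f"{path}: tiepoint not anchored at raster origin")
        origin_x, origin_y = tie[3], tie[4]
        nodata = None
        if _GDAL_NODATA in tags:
            nodata = float(tags[_GDAL_NODATA].value)
    data = np.asarray(data, dtype=float)
    valid = np.ones(data.shape, dtype=bool) if nodata is None else data != nodata
    values = np.where(valid, data, 0.0)
    return RasterGrid(
        values=values, origin_x=float(origin_x), origin_y=float(origin_y),
        cell_size=float(sx), valid=valid,
    )
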