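"""Raster and table I/O.

Rasters are written as plain TIFF via :mod:`tifffile` with a JSON sidecar
(``<path>.aux.json``) carrying the geotransform, CRS, nodata value and band
names; reading without the sidecar is an error so georeferencing can never be
silently lost.  (GDAL/rasterio is not a dependency of this package.)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .grid import RasterGrid


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".aux.json")


def write_raster(path, array: np.ndarray, grid: RasterGrid,
                 nodata=None, band_names=None) -> Path:
    path = Path(path)
    array = np.asarray(array)
    if array.ndim == 2:
        check_shape = array.shape
    elif array.ndim == 3:
        check_shape = array.shape[1:]
    else:
        raise ValueError("array must be 2-D or (bands, rows, cols)")
    if check_shape != grid.shape:
        raise ValueError("array shape does not match grid")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, array)
    meta = {
        "transform": list(grid.transform),
        "crs": grid.crs,
        "rows": grid.rows,
        "cols": grid.cols,
        "nodata": nodata,
        "band_names": list(band_names) if band_names is not None else None,
        "dtype": str(array.dtype),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_raster(path):
    """Returns (array, grid, meta).  Missing sidecar metadata is an error."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(
            f"raster {path} has no {side.name}: geotransform/CRS would be lost")
    meta = json.loads(side.read_text())
    array = tifffile.imread(path)
    grid = RasterGrid(meta["rows"], meta["cols"],
                      tuple(meta["transform"]), meta["crs"])
    return array, grid, meta


def raster_round_trip(array: np.ndarray, grid: RasterGrid, path,
                      nodata=None, band_names=None):
    """Write-then-read; the contract is exact value/grid preservation."""
    write_raster(path, array, grid, nodata=nodata, band_names=band_names)
    return read_raster(path)
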