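"""Raster read/write on top of tifffile.

Grids are plain TIFF arrays (single- or multi-band) with georeferencing —
an affine transform, CRS string, nodata value and band names — carried as
a JSON document in the TIFF ImageDescription tag.  Writes are lossless for
float32/float64 and integer dtypes.  Co-registration of a raster set is
checked by shape and transform.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["RasterMeta", "read_raster", "write_raster",
           "check_coregistered", "nodata_mask"]

DEFAULT_TRANSFORM = (1000.0, 0.0, 0.0, 0.0, -1000.0, 0.0)  # 1-km cells,
# row-major with cell (0, 0) at the top-left corner


@dataclass
class RasterMeta:
    """Georeferencing sidecar for a grid."""

    transform: tuple = DEFAULT_TRANSFORM
    crs: str = ""
    nodata: float | None = None
    band_names: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "RasterMeta":
        d = json.loads(text)
        d["transform"] = tuple(d.get("transform", DEFAULT_TRANSFORM))
        return cls(**d)


def write_raster(path: str | Path, array: np.ndarray,
                 meta: RasterMeta | None = None) -> Path:
    """Write a (rows, cols) or (bands, rows, cols) grid with metadata."""
    path = Path(path)
    meta = meta or RasterMeta()
    arr = np.asarray(array)
    if arr.ndim not in (2, 3):
        raise ValueError("raster must be 2-D or 3-D (bands first)")
    tifffile.imwrite(path, arr, description=meta.to_json(),
                     photometric="minisblack")
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, RasterMeta]:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description or ""
    try:
        meta = RasterMeta.from_json(desc)
    except (json.JSONDecodeError, TypeError):
        meta = RasterMeta()
    return arr, meta


def check_coregistered(*named: tuple[str, np.ndarray, RasterMeta]) -> None:
    """Raise if the named rasters disagree in grid shape or transform."""
    if not named:
        return
    ref_name, ref_arr, ref_meta = named[0]
    ref_shape = ref_arr.shape[-2:]
    for name, arr, meta in named[1:]:
        if arr.shape[-2:] != ref_shape:
            raise ValueError(
                f"rasters not co-registered: {ref_name} has shape "
                f"{ref_shape}, {name} has {arr.shape[-2:]}")
        if tuple(meta.transform) != tuple(ref_meta.transform):
            raise ValueError(
                f"rasters not co-registered: {ref_name} and {name} have "
                f"different transforms")


def nodata_mask(array: np.ndarray, meta: RasterMeta) -> np.ndarray:
    """Boolean mask of nodata cells (NaN always counts as nodata)."""
    arr = np.asarray(array)
    mask = np.zeros(arr.shape, dtype=bool)
    if np.issubdtype(arr.dtype, np.floating):
        mask |= np.isnan(arr)
    if meta.nodata is not None:
        mask |= arr == meta.nodata
    return mask
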