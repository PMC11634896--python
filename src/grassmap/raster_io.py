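"""GeoTIFF input/output and the product file-naming convention.

Rasters are written as internally tiled GeoTIFFs with overview pyramids
(a cloud-optimized layout), georeferenced in EPSG:4326 through the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus the
GDAL no-data tag. Reading restores the array bit-exactly together with its
transform and no-data value.

Product filenames join ten lowercase metadata fields with underscores::

    gpw_cultiv.grassland_rf.savgol.bthr_p_30m_20220101_20221231_go_epsg.4326_v1.tif

(project, class, procedure, variable, resolution, begin date, end date,
extent, coordinate system, version).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .core import NODATA, DominantMap, GeoTransform, ProbabilityCube

# GeoTIFF / GDAL tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# Minimal GeoKeyDirectory: geographic model, pixel-is-area, EPSG:4326.
_GEO_KEYS_4326 = (
    1, 1, 0, 3,
    1024, 0, 1, 2,
    1025, 0, 1, 1,
    2048, 0, 1, 4326,
)

VALID_CLASS_NAMES = ("cultiv.grassland", "nat.semi.grassland", "grassland")
VALID_VARIABLES = ("p", "c")

_TOKEN_RE = re.compile(r"^[a-z0-9.\-]+$")
_DATE_RE = re.compile(r"^\d{8}$")


@dataclass(frozen=True)
class NamingFields:
    """The ten metadata fields of a product filename, in file order."""

    project: str = "gpw"
    class_name: str = "grassland"
    procedure: str = "rf.savgol.bthr"
    variable: str = "p"
    resolution: str = "30m"
    begin_date: str = "20220101"
    end_date: str = "20221231"
    extent: str = "go"
    crs: str = "epsg.4326"
    version: str = "v1"

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not value:
                raise ValueError(f"naming field {name!r} must be non-empty")
            if not _TOKEN_RE.match(value):
                raise ValueError(
                    f"naming field {name!r}={value!r} contains illegal characters "
                    "(lowercase alphanumerics, '.' and '-' only)"
                )
        if self.class_name not in VALID_CLASS_NAMES:
            raise ValueError(f"class_name must be one of {VALID_CLASS_NAMES}")
        if self.variable not in VALID_VARIABLES:
            raise ValueError(f"variable must be one of {VALID_VARIABLES}")
        for d in (self.begin_date, self.end_date):
            if not _DATE_RE.match(d):
                raise ValueError(f"dates must be YYYYMMDD, got {d!r}")
        if self.begin_date > self.end_date:
            raise ValueError("begin_date must not be after end_date")

    def as_tuple(self) -> tuple[str, ...]:
        return (
            self.project, self.class_name, self.procedure, self.variable,
            self.resolution, self.begin_date, self.end_date, self.extent,
            self.crs, self.version,
        )


def build_filename(fields: NamingFields) -> str:
    """Underscore-joined lowercase filename with a ``.tif`` suffix."""
    return "_".join(fields.as_tuple()) + ".tif"


def parse_filename(name: str) -> NamingFields:
    """Inverse of :func:`build_filename`; ``parse(build(f)) == f``."""
    stem = name[:-4] if name.endswith(".tif") else name
    tokens = stem.split("_")
    if len(tokens) != 10:
        raise ValueError(f"expected 10 underscore-separated fields, got {len(tokens)}")
    return NamingFields(*tokens)


def _overview_levels(shape: tuple[int, int], min_size: int = 256) -> list[int]:
    levels = []
    factor = 2
    while min(shape) // factor >= min_size:
        levels.append(factor)
        factor *= 2
    return levels


def _downsample(arr: np.ndarray, factor: int, method: str, nodata: int) -> np.ndarray:
    if method == "nearest":
        return arr[::factor, ::factor]
    # block average ignoring nodata, for probability layers
    h, w = arr.shape
    hh, ww = h // factor, w // factor
    block = arr[: hh * factor, : ww * factor].reshape(hh, factor, ww, factor)
    block = block.astype(np.float64)
    valid = block != nodata
    s = np.where(valid, block, 0.0).sum(axis=(1, 3))
    n = valid.sum(axis=(1, 3))
    out = np.full((hh, ww), nodata, dtype=arr.dtype)
    ok = n > 0
    out[ok] = np.rint(s[ok] / n[ok]).astype(arr.dtype)
    return out


def write_geotiff(
    path: str | Path,
    data: np.ndarray,
    transform: GeoTransform = GeoTransform(),
    nodata: int | None = NODATA,
    overview_resampling: str = "nearest",
    tile_size: int = 256,
) -> Path:
    """Write a 2-D or 3-D array as a tiled EPSG:4326 GeoTIFF with overviews.

    3-D arrays are written as one page per leading-axis slice; geo tags are
    attached to the first page.
    """
    path = Path(path)
    data = np.asarray(data)
    if data.ndim == 2:
        pages = data[None]
    elif data.ndim == 3:
        pages = data
    else:
        raise ValueError("data must be 2-D or 3-D")

    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (transform.px, transform.py, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.x0, transform.y0, 0.0)),
        (_TAG_GEO_KEYS, "H", len(_GEO_KEYS_4326), _GEO_KEYS_4326),
    ]
    if nodata is not None:
        nd = str(nodata)
        extratags.append((_TAG_GDAL_NODATA, "s", len(nd) + 1, nd))

    def _tile_for(shape: tuple[int, int]) -> tuple[int, int] | None:
        if min(shape) < 16:
            return None
        # TIFF tile dimensions must be multiples of 16
        return tuple(min(tile_size, ((s + 15) // 16) * 16) for s in shape)

    tile = _tile_for(pages.shape[1:])

    with tifffile.TiffWriter(path) as tif:
        for i, page in enumerate(pages):
            levels = _overview_levels(page.shape) if nodata is not None else []
            tif.write(
                page,
                tile=tile,
                extratags=extratags if i == 0 else [],
                subifds=len(levels),
            )
            for factor in levels:
                ov = _downsample(page, factor, overview_resampling,
                                 nodata if nodata is not None else 0)
                tif.write(ov, tile=_tile_for(ov.shape), subfiletype=1)
    return path


def read_geotiff(path: str | Path) -> tuple[np.ndarray, GeoTransform, int | None]:
    """Read a GeoTIFF written by :func:`write_geotiff`.

    Returns ``(array, transform, nodata)``; single-page files come back 2-D.
    """
    with tifffile.TiffFile(path) as tif:
        arrays = [page.asarray() for page in tif.pages]
        tags = tif.pages[0].tags
        px, py = 1.0, 1.0
        x0 = y0 = 0.0
        if _TAG_PIXEL_SCALE in tags:
            scale = tags[_TAG_PIXEL_SCALE].value
            px, py = float(scale[0]), float(scale[1])
        if _TAG_TIEPOINT in tags:
            tp = tags[_TAG_TIEPOINT].value
            x0, y0 = float(tp[3]), float(tp[4])
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = int(float(tags[_TAG_GDAL_NODATA].value))
    data = arrays[0] if len(arrays) == 1 else np.stack(arrays)
    return data, GeoTransform(x0, y0, px, py), nodata


def write_raster(
    raster: ProbabilityCube | DominantMap,
    fields: NamingFields,
    directory: str | Path,
) -> Path:
    """Write a probability cube or dominant map under its convention filename.

    Probability layers (variable ``p``) must hold values in [0, 100] or 255;
    class layers (``c``) values in {0, 1, 2, 255}. Violations are rejected.
    """
    data = np.asarray(raster.data)
    valid = data[data != NODATA]
    if fields.variable == "p":
        if not isinstance(raster, ProbabilityCube):
            raise ValueError("variable 'p' requires a ProbabilityCube")
        if valid.size and valid.max() > 100:
            raise ValueError("probability values must lie in [0, 100] or be 255")
        resampling = "average"
    else:
        if valid.size and not np.isin(valid, [0, 1, 2]).all():
            raise ValueError("class values must lie in {0, 1, 2, 255}")
        resampling = "nearest"
    path = Path(directory) / build_filename(fields)
    return write_geotiff(path, data, raster.transform, NODATA, resampling)
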