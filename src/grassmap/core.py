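"""Shared grid and cube containers used across the pipeline.

All rasters in the pipeline live on a single north-up grid in geographic
coordinates (EPSG:4326). Probability and class layers follow the product
encoding: unsigned 8-bit, probabilities scaled to 0-100, class codes
{0 = other land cover, 1 = cultivated grassland, 2 = natural/semi-natural
grassland}, and 255 as the no-data value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: No-data value for all uint8 product rasters.
NODATA: int = 255

#: Class codes for the dominant map legend.
CLASS_OTHER, CLASS_CULTIVATED, CLASS_NATURAL = 0, 1, 2

#: Spectral band order used by every acquisition and composite.
BAND_NAMES: tuple[str, ...] = (
    "blue", "green", "red", "nir", "swir1", "swir2", "thermal",
)

#: Default pixel size in degrees (roughly the 30 m analysis grid).
DEFAULT_PIXEL_SIZE: float = 0.00025

#: Nominal metric size of one analysis pixel, used for tile geometry.
PIXEL_SIZE_M: float = 30.0


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine georeference: ``lon = x0 + col*px``, ``lat = y0 - row*py``."""

    x0: float = 0.0
    y0: float = 0.0
    px: float = DEFAULT_PIXEL_SIZE
    py: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        if self.px <= 0 or self.py <= 0:
            raise ValueError("pixel sizes must be positive")

    def to_lonlat(self, row: float, col: float) -> tuple[float, float]:
        """Longitude/latitude of a (fractional) pixel centre."""
        return (self.x0 + (col + 0.5) * self.px, self.y0 - (row + 0.5) * self.py)

    def to_rowcol(self, lon: float, lat: float) -> tuple[float, float]:
        return ((self.y0 - lat) / self.py - 0.5, (lon - self.x0) / self.px - 0.5)


def _check_uint8_domain(data: np.ndarray, allowed_max: int, what: str) -> None:
    if data.dtype != np.uint8:
        raise ValueError(f"{what} must be uint8, got {data.dtype}")
    valid = data != NODATA
    if valid.any() and data[valid].max() > allowed_max:
        raise ValueError(
            f"{what} values must lie in [0, {allowed_max}] or be {NODATA}"
        )


@dataclass
class ProbabilityCube:
    """Annual per-class probability rasters.

    ``data`` has shape ``(n_years, rows, cols)``, dtype uint8, values 0-100
    with 255 marking excluded / no-data pixels.
    """

    class_name: str
    years: list[int]
    data: np.ndarray
    transform: GeoTransform = field(default_factory=GeoTransform)
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.years):
            raise ValueError("data must be (n_years, rows, cols)")
        _check_uint8_domain(self.data, 100, "probability")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def year_slice(self, year: int) -> np.ndarray:
        return self.data[self.years.index(year)]


@dataclass
class DominantMap:
    """Annual dominant-class rasters with codes {0, 1, 2, 255}."""

    years: list[int]
    data: np.ndarray
    transform: GeoTransform = field(default_factory=GeoTransform)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.years):
            raise ValueError("data must be (n_years, rows, cols)")
        _check_uint8_domain(self.data, CLASS_NATURAL, "class map")

    def year_slice(self, year: int) -> np.ndarray:
        return self.data[self.years.index(year)]
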