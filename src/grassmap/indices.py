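"""Spectral indices and the annual bare-soil fraction.

Seven per-period indices are derived from decoded composite reflectance:
NDVI, NDWI (NIR/SWIR1 water form), NBR2, EVI, BSI, NIRv and FAPAR (a linear
function of NDVI clipped to [0, 1]). The bare-soil fraction (BSF) of a year
is the proportion of its six bi-monthly composites in which NDVI falls below
a threshold (default 0.35).

Index rasters are float with NaN where the composite has gaps or the index
denominator vanishes; an 8-bit encoding over each index's configured
analytic range is provided for storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BAND_NAMES
from .composite import BimonthlyComposite

INDEX_NAMES: tuple[str, ...] = ("BSI", "EVI", "NBR2", "NDVI", "NDWI", "NIRv", "FAPAR")

_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "NDVI": (-1.0, 1.0),
    "NDWI": (-1.0, 1.0),
    "NBR2": (-1.0, 1.0),
    "BSI": (-1.0, 1.0),
    "NIRv": (-1.0, 1.0),
    "EVI": (-2.0, 2.0),
    "FAPAR": (0.0, 1.0),
}


@dataclass(frozen=True)
class IndexConfig:
    names: tuple[str, ...] = INDEX_NAMES
    bsf_threshold: float = 0.35
    fapar_coeffs: tuple[float, float] = (1.24, -0.168)
    encoding_ranges: dict = field(default_factory=lambda: dict(_DEFAULT_RANGES))

    def __post_init__(self) -> None:
        unknown = set(self.names) - set(INDEX_NAMES)
        if unknown:
            raise ValueError(f"unknown index names: {sorted(unknown)}")
        if not -1.0 < self.bsf_threshold < 1.0:
            raise ValueError("BSF threshold must lie in (-1, 1)")


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def compute_spectral_indices(
    composite: BimonthlyComposite, config: IndexConfig = IndexConfig()
) -> dict[str, np.ndarray]:
    """Per-period index rasters from one composite, on the analytic scale."""
    refl = composite.decoded()
    b = dict(zip(BAND_NAMES, refl))
    blue, red, nir = b["blue"], b["red"], b["nir"]
    swir1, swir2 = b["swir1"], b["swir2"]

    out: dict[str, np.ndarray] = {}
    ndvi = _safe_ratio(nir - red, nir + red)
    if "NDVI" in config.names:
        out["NDVI"] = ndvi
    if "NDWI" in config.names:
        out["NDWI"] = _safe_ratio(nir - swir1, nir + swir1)
    if "NBR2" in config.names:
        out["NBR2"] = _safe_ratio(swir1 - swir2, swir1 + swir2)
    if "EVI" in config.names:
        out["EVI"] = _safe_ratio(
            2.5 * (nir - red), nir + 6.0 * red - 7.5 * blue + 1.0
        )
    if "BSI" in config.names:
        out["BSI"] = _safe_ratio(
            (swir1 + red) - (nir + blue), (swir1 + red) + (nir + blue)
        )
    if "NIRv" in config.names:
        out["NIRv"] = ndvi * nir
    if "FAPAR" in config.names:
        a, c = config.fapar_coeffs
        out["FAPAR"] = np.clip(a * ndvi + c, 0.0, 1.0)
    return out


def compute_bsf(
    ndvi_periods: list[np.ndarray], threshold: float = 0.35
) -> np.ndarray:
    """Annual bare-soil fraction from the six per-period NDVI rasters.

    Per pixel: (periods with NDVI < threshold) / (periods with valid NDVI);
    with complete data the value is a multiple of 1/6. Pixels with no valid
    period at all are NaN.
    """
    if len(ndvi_periods) != 6:
        raise ValueError("BSF needs exactly 6 bi-monthly NDVI rasters")
    stack = np.stack([np.asarray(p, dtype=np.float64) for p in ndvi_periods])
    valid = np.isfinite(stack)
    below = (stack < threshold) & valid
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        bsf = below.sum(axis=0) / n_valid
    bsf[n_valid == 0] = np.nan
    return bsf


def encode_index(
    values: np.ndarray, name: str, config: IndexConfig = IndexConfig()
) -> np.ndarray:
    """Store an index as uint8: its analytic range mapped linearly to 0-250.

    BSF is encoded separately as ``round(BSF * 100)``. NaN maps to 255.
    """
    if name == "BSF":
        out = np.rint(np.asarray(values, dtype=np.float64) * 100.0)
    else:
        lo, hi = config.encoding_ranges[name]
        v = np.clip(np.asarray(values, dtype=np.float64), lo, hi)
        out = np.rint((v - lo) / (hi - lo) * 250.0)
    out = np.where(np.isnan(np.asarray(values, dtype=np.float64)), 255, out)
    return out.astype(np.uint8)


def decode_index(
    encoded: np.ndarray, name: str, config: IndexConfig = IndexConfig()
) -> np.ndarray:
    """Inverse of :func:`encode_index` up to quantization; 255 decodes to NaN."""
    enc = np.asarray(encoded, dtype=np.float64)
    if name == "BSF":
        out = enc / 100.0
    else:
        lo, hi = config.encoding_ranges[name]
        out = enc / 250.0 * (hi - lo) + lo
    out[np.asarray(encoded) == 255] = np.nan
    return out


@dataclass
class IndexCube:
    """Container for per-(year, period) index rasters and annual BSF."""

    config: IndexConfig = field(default_factory=IndexConfig)
    slices: dict = field(default_factory=dict)  # (year, period) -> {name: raster}
    bsf: dict = field(default_factory=dict)  # year -> raster

    def get(self, year: int, period: int, name: str) -> np.ndarray:
        return self.slices[(year, period)][name]


def build_index_cube(
    composites: dict[tuple[int, int], BimonthlyComposite],
    config: IndexConfig = IndexConfig(),
) -> IndexCube:
    """Compute every configured index plus annual BSF for a composite archive."""
    cube = IndexCube(config=config)
    years = sorted({y for (y, _p) in composites})
    for (year, period), comp in sorted(composites.items()):
        cube.slices[(year, period)] = compute_spectral_indices(comp, config)
    for year in years:
        ndvi = [cube.slices[(year, p)]["NDVI"] for p in range(1, 7)
                if (year, p) in cube.slices]
        if len(ndvi) == 6:
            cube.bsf[year] = compute_bsf(ndvi, config.bsf_threshold)
    return cube
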