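"""Bi-monthly compositing of 16-day acquisitions with seasonal gap-filling.

The chain is: (1) quality masking drops pixels whose QA code is in the
removal set; (2) reflectance is linearly rescaled to 8-bit integers 0-250;
(3) all clear observations inside a two-calendar-month window are averaged
with weight ``1 - cloud_cover`` of their acquisition; (4) remaining gaps are
imputed by a Seasonally Weighted Average Generalization (SWAG): a weighted
average over strictly earlier composites in which same-period observations
outweigh adjacent-period ones and weights decay geometrically with year lag.
Imputation never looks at later dates, so recomputing a composite can only
be affected by its past.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np

from .core import BAND_NAMES, GeoTransform

#: Provenance codes for composite pixels.
PROV_OBSERVED, PROV_IMPUTED, PROV_NODATA = 0, 1, 2


@dataclass(frozen=True)
class QAConfig:
    """Quality-band interpretation: which codes to remove, which are clear."""

    removal_codes: frozenset[int] = frozenset({3, 4, 7, 8, 9, 10})
    clear_codes: frozenset[int] = frozenset({1, 2})

    def __post_init__(self) -> None:
        if self.removal_codes & self.clear_codes:
            raise ValueError("removal and clear-sky QA code sets must be disjoint")


@dataclass
class AcquisitionStack:
    """One 16-day acquisition: 7 reflectance bands, QA band, cloud fraction.

    Bands are float arrays on the reflectance scale; voided pixels are NaN.
    """

    date: dt.date
    bands: np.ndarray  # (7, rows, cols) float
    qa: np.ndarray  # (rows, cols) int
    cloud_cover: float
    transform: GeoTransform = field(default_factory=GeoTransform)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float32)
        self.qa = np.asarray(self.qa)
        if self.bands.ndim != 3 or self.bands.shape[0] != len(BAND_NAMES):
            raise ValueError(f"bands must be ({len(BAND_NAMES)}, rows, cols)")
        if self.qa.shape != self.bands.shape[1:]:
            raise ValueError("qa raster must align with the bands")
        if not 0.0 <= self.cloud_cover <= 1.0:
            raise ValueError("cloud_cover must lie in [0, 1]")

    @property
    def year(self) -> int:
        return self.date.year

    @property
    def period(self) -> int:
        return period_of(self.date)


@dataclass
class BimonthlyComposite:
    """One bi-monthly composite: 8-bit bands, gap mask and provenance.

    ``bands`` is uint8 with values 0-250 wherever ``gap_mask`` is False.
    ``input_range`` records the reflectance interval encoded to [0, 250] so
    values can be decoded for index math.
    """

    year: int
    period: int
    bands: np.ndarray  # (7, rows, cols) uint8
    gap_mask: np.ndarray  # (rows, cols) bool
    provenance: np.ndarray  # (rows, cols) uint8
    input_range: tuple[float, float] = (0.0, 1.0)
    transform: GeoTransform = field(default_factory=GeoTransform)

    def __post_init__(self) -> None:
        if not 1 <= self.period <= 6:
            raise ValueError("period must lie in 1..6")
        self.bands = np.asarray(self.bands, dtype=np.uint8)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        self.provenance = np.asarray(self.provenance, dtype=np.uint8)
        ok = ~self.gap_mask
        if ok.any() and self.bands[:, ok].max() > 250:
            raise ValueError("composite values must lie in [0, 250] outside gaps")

    @property
    def time_key(self) -> tuple[int, int]:
        return (self.year, self.period)

    def decoded(self) -> np.ndarray:
        """Bands back on the reflectance scale, NaN at gaps."""
        lo, hi = self.input_range
        out = self.bands.astype(np.float64) / 250.0 * (hi - lo) + lo
        out[:, self.gap_mask] = np.nan
        return out


def period_of(date: dt.date) -> int:
    """Bi-monthly period index 1..6 (Jan-Feb = 1, ..., Nov-Dec = 6)."""
    return (date.month - 1) // 2 + 1


def mask_quality(stack: AcquisitionStack, qa_config: QAConfig = QAConfig()) -> AcquisitionStack:
    """Void every band at pixels whose QA code is in the removal set."""
    bad = np.isin(stack.qa, list(qa_config.removal_codes))
    bands = stack.bands.copy()
    bands[:, bad] = np.nan
    return replace(stack, bands=bands)


def normalize_to_8bit(
    values: np.ndarray, lo: float = 0.0, hi: float = 1.0
) -> np.ndarray:
    """Linear rescale of ``[lo, hi]`` to integers 0-250.

    Rounds half away from zero and clips to [0, 250]. NaN inputs map to 255.
    """
    if hi <= lo:
        raise ValueError("input range must satisfy hi > lo")
    values = np.asarray(values, dtype=np.float64)
    scaled = (values - lo) / (hi - lo) * 250.0
    rounded = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    out = np.clip(rounded, 0, 250)
    out = np.where(np.isnan(values), 255, out)
    return out.astype(np.uint8)


def aggregate_bimonthly(
    stacks: list[AcquisitionStack],
    year: int,
    period: int,
    input_range: tuple[float, float] = (0.0, 1.0),
) -> BimonthlyComposite:
    """Cloud-weighted mean of all clear observations in one bi-month window.

    Each acquisition contributes with weight ``1 - cloud_cover``; pixels with
    no clear observation at all get ``gap_mask`` True. An empty stack list
    yields an all-gap composite. If every clear observation of a pixel comes
    from fully clouded acquisitions (weight 0), the plain mean is used so an
    observation is never discarded by the weighting alone.
    """
    stacks = [s for s in stacks if (s.year, s.period) == (year, period)]
    if stacks:
        shape = stacks[0].bands.shape
        transform = stacks[0].transform
        for s in stacks:
            if s.bands.shape != shape:
                raise ValueError("all acquisitions must share one grid")
        data = np.stack([s.bands for s in stacks])  # (n, 7, r, c)
        weights = np.array([1.0 - s.cloud_cover for s in stacks])
        valid = np.isfinite(data)
        w = weights[:, None, None, None] * valid
        wsum = w.sum(axis=0)
        vsum = np.where(valid, data, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            weighted = (w * np.where(valid, data, 0.0)).sum(axis=0) / wsum
            plain = vsum.sum(axis=0) / valid.sum(axis=0)
        mean = np.where(wsum > 0, weighted, plain)
        gap = ~valid.any(axis=0).any(axis=0)
        mean[:, gap] = np.nan
    else:
        shape = (len(BAND_NAMES), 0, 0)
        transform = GeoTransform()
        mean = np.full(shape, np.nan)
        gap = np.ones(shape[1:], dtype=bool)

    bands = normalize_to_8bit(mean, *input_range)
    provenance = np.where(gap, PROV_NODATA, PROV_OBSERVED).astype(np.uint8)
    return BimonthlyComposite(
        year=year, period=period, bands=bands, gap_mask=gap,
        provenance=provenance, input_range=input_range, transform=transform,
    )


@dataclass(frozen=True)
class SwagConfig:
    """Weight model for seasonal gap imputation.

    An observed composite at year lag ``L`` receives weight ``s * r**L``
    where ``s = same_period_weight`` for the same bi-month, ``s =
    adjacent_period_weight`` for a cyclically adjacent bi-month, and 0
    otherwise.
    """

    year_decay: float = 0.5
    same_period_weight: float = 1.0
    adjacent_period_weight: float = 0.25

    def weight(self, year_lag: int, period: int, other_period: int) -> float:
        gap = abs(period - other_period)
        if gap == 0:
            s = self.same_period_weight
        elif gap == 1 or gap == 5:  # periods are cyclic (Nov-Dec vs Jan-Feb)
            s = self.adjacent_period_weight
        else:
            return 0.0
        return s * self.year_decay ** year_lag


def swag_impute(
    series: list[BimonthlyComposite],
    config: SwagConfig = SwagConfig(),
) -> tuple[BimonthlyComposite, np.ndarray]:
    """Fill the gaps of the last composite from its strictly earlier history.

    ``series`` must be time-ordered and end with the target composite. Only
    pixels that were actually observed (not themselves imputed) contribute.
    Gap pixels are replaced by the weighted average of their eligible history
    and marked as imputed; pixels with empty history stay no-data. Returns
    the imputed composite and the boolean raster of still-unfilled pixels.
    """
    keys = [c.time_key for c in series]
    if keys != sorted(keys):
        raise ValueError("composite series must be ordered in time")
    target = series[-1]
    history = [c for c in series[:-1] if c.time_key < target.time_key]

    gap = target.gap_mask
    bands = target.bands.astype(np.float64)
    wsum = np.zeros(gap.shape)
    vsum = np.zeros((bands.shape[0],) + gap.shape)
    for comp in history:
        w = config.weight(target.year - comp.year, target.period, comp.period)
        if w == 0.0:
            continue
        observed = (~comp.gap_mask) & (comp.provenance == PROV_OBSERVED) & gap
        wsum += w * observed
        vsum[:, observed] += w * comp.bands[:, observed].astype(np.float64)

    filled = gap & (wsum > 0)
    out_bands = target.bands.copy()
    avg = vsum[:, filled] / wsum[filled]
    out_bands[:, filled] = np.sign(avg) * np.floor(np.abs(avg) + 0.5)
    remaining = gap & ~filled

    provenance = target.provenance.copy()
    provenance[filled] = PROV_IMPUTED
    provenance[remaining] = PROV_NODATA
    out = replace(
        target, bands=out_bands, gap_mask=remaining, provenance=provenance
    )
    return out, remaining


def build_composite_series(
    acquisitions: list[AcquisitionStack],
    years: list[int],
    qa_config: QAConfig = QAConfig(),
    swag_config: SwagConfig = SwagConfig(),
    input_range: tuple[float, float] = (0.0, 1.0),
) -> tuple[dict[tuple[int, int], BimonthlyComposite], list[dict]]:
    """Mask, aggregate and gap-fill a full acquisition archive.

    Composites are produced in chronological order so imputation only ever
    sees earlier observed composites. Returns the composite dictionary keyed
    by ``(year, period)`` and a gap report listing, per composite, how many
    pixels were imputed and how many remain unfilled.
    """
    masked = [mask_quality(s, qa_config) for s in acquisitions]
    by_key: dict[tuple[int, int], list[AcquisitionStack]] = {}
    for s in masked:
        by_key.setdefault((s.year, s.period), []).append(s)

    composites: dict[tuple[int, int], BimonthlyComposite] = {}
    observed_history: list[BimonthlyComposite] = []
    report: list[dict] = []
    for year in sorted(years):
        for period in range(1, 7):
            raw = aggregate_bimonthly(
                by_key.get((year, period), []), year, period, input_range
            )
            if raw.bands.shape[1] == 0 and observed_history:
                # no acquisition at all in this window: all-gap on the grid
                shape = observed_history[0].gap_mask.shape
                raw = BimonthlyComposite(
                    year=year, period=period,
                    bands=np.zeros((len(BAND_NAMES),) + shape, dtype=np.uint8),
                    gap_mask=np.ones(shape, dtype=bool),
                    provenance=np.full(shape, PROV_NODATA, dtype=np.uint8),
                    input_range=input_range,
                    transform=observed_history[0].transform,
                )
            n_gaps = int(raw.gap_mask.sum())
            filled, remaining = swag_impute(observed_history + [raw], swag_config)
            report.append({
                "year": year, "period": period, "gaps": n_gaps,
                "imputed": n_gaps - int(remaining.sum()),
                "unfilled": int(remaining.sum()),
            })
            composites[(year, period)] = filled
            observed_history.append(raw)  # history keeps observed values only
    return composites, report
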