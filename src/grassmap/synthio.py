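"""Synthetic landscapes, acquisitions, reference tiles and mock products.

Every generator is a pure function of its arguments and an integer seed, so
each downstream stage can be exercised offline against known ground truth.

The synthetic world is a patchwork landscape of three classes (0 = other
land cover, 1 = cultivated grassland, 2 = natural/semi-natural grassland)
on a ~30 m analysis grid tagged EPSG:4326 (pixel size 0.00025 deg by
default). Reflectance follows per-class seasonal sinusoids per band; clouds
arrive as spatially correlated blobs so the gap-filling stage sees a
realistic gap structure. Reference tiles are 1x1 km blocks relabeled on a
10 m grid; mock land-cover products replay the truth through a
published-product-like legend with a configurable disagreement rate.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .composite import AcquisitionStack
from .core import BAND_NAMES, GeoTransform
from .sampling import TILE_CELLS, TILE_SPAN_PX, ReferenceTile

#: 16-day acquisition cadence: 23 start days per calendar year.
ACQUISITION_DOYS: tuple[int, ...] = tuple(range(1, 366, 16))

#: Legend of the mock land-cover products.
MOCK_LEGEND: dict[int, str] = {
    0: "other", 1: "urban", 2: "forest", 3: "cropland", 4: "water",
    5: "snow", 6: "wetland", 7: "grassland", 8: "short_vegetation",
    9: "herbaceous",
}
MOCK_EPOCHS: tuple[int, ...] = (2000, 2005, 2010, 2015, 2020)


@dataclass(frozen=True)
class BandSignature:
    """Seasonal reflectance curve of one (class, band): mean + amplitude *
    sin(2*pi*(doy - phase)/365), plus i.i.d. Gaussian pixel noise."""

    mean: float
    amplitude: float = 0.0
    phase_doy: float = 0.0
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    def value(self, doy: float) -> float:
        v = self.mean + self.amplitude * math.sin(
            2.0 * math.pi * (doy - self.phase_doy) / 365.0
        )
        return min(1.0, max(0.0, v))


@dataclass
class SignatureSet:
    """Per-class, per-band seasonal signatures."""

    signatures: dict[tuple[int, str], BandSignature]

    def get(self, class_code: int, band: str) -> BandSignature:
        return self.signatures[(class_code, band)]

    def save(self, path: str | Path) -> None:
        """Plain-text config: one ``class.band = mean,amp,phase,noise`` line each."""
        lines = [
            f"{c}.{b} = {s.mean},{s.amplitude},{s.phase_doy},{s.noise_sd}"
            for (c, b), s in sorted(self.signatures.items())
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SignatureSet":
        signatures = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            klass, _, band = key.strip().partition(".")
            mean, amp, phase, noise = (float(x) for x in value.split(","))
            signatures[(int(klass), band)] = BandSignature(mean, amp, phase, noise)
        return cls(signatures)


def _preset(curves: dict[int, dict[str, tuple]], noise_sd: float) -> SignatureSet:
    sigs = {}
    for klass, bands in curves.items():
        for band, (mean, amp, phase) in bands.items():
            sigs[(klass, band)] = BandSignature(mean, amp, phase, noise_sd)
    return SignatureSet(sigs)


# "easy" preset: the three classes are separable from the NDVI seasonal
# profile alone -- other land stays near NDVI 0, cultivated grassland swings
# widely through the season (management cycles), natural grassland holds a
# high, mildly seasonal NDVI.
_EASY_CURVES: dict[int, dict[str, tuple]] = {
    0: {  # other land cover: bright, aseasonal, NDVI ~ 0.05
        "blue": (0.20, 0.00, 0.0), "green": (0.24, 0.00, 0.0),
        "red": (0.27, 0.01, 90.0), "nir": (0.30, 0.01, 90.0),
        "swir1": (0.36, 0.00, 0.0), "swir2": (0.32, 0.00, 0.0),
        "thermal": (0.65, 0.05, 120.0),
    },
    1: {  # cultivated grassland: strong green-up / cut-down cycle
        "blue": (0.06, -0.02, 120.0), "green": (0.10, -0.02, 120.0),
        "red": (0.15, -0.08, 120.0), "nir": (0.42, 0.22, 120.0),
        "swir1": (0.24, -0.06, 120.0), "swir2": (0.18, -0.05, 120.0),
        "thermal": (0.55, 0.05, 120.0),
    },
    2: {  # natural/semi-natural grassland: high stable NDVI
        "blue": (0.05, 0.00, 0.0), "green": (0.09, 0.01, 150.0),
        "red": (0.08, -0.02, 150.0), "nir": (0.40, 0.06, 150.0),
        "swir1": (0.20, -0.02, 150.0), "swir2": (0.14, -0.02, 150.0),
        "thermal": (0.50, 0.05, 150.0),
    },
}

PRESETS: dict[str, dict] = {
    "easy": {"curves": _EASY_CURVES, "noise_sd": 0.01},
    "noisy": {"curves": _EASY_CURVES, "noise_sd": 0.05},
}


def signature_preset(name: str = "easy") -> SignatureSet:
    """A documented signature preset; ``easy`` is NDVI-separable by design."""
    spec = PRESETS[name]
    return _preset(spec["curves"], spec["noise_sd"])


@dataclass
class SyntheticLandscape:
    """Ground truth: class patchwork plus static covariate rasters."""

    class_map: np.ndarray  # (rows, cols) int8, codes {0, 1, 2}
    static_covariates: dict[str, np.ndarray]
    transform: GeoTransform = field(default_factory=GeoTransform)
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_map = np.asarray(self.class_map, dtype=np.int8)
        if not np.isin(self.class_map, [0, 1, 2]).all():
            raise ValueError("class codes must lie in {0, 1, 2}")
        for name, layer in self.static_covariates.items():
            if np.asarray(layer).shape != self.class_map.shape:
                raise ValueError(f"covariate {name!r} does not match class map")

    @property
    def shape(self) -> tuple[int, int]:
        return self.class_map.shape

    def class_fractions(self) -> np.ndarray:
        counts = np.bincount(self.class_map.ravel(), minlength=3)
        return counts / self.class_map.size


def generate_landscape(
    seed: int,
    shape: tuple[int, int] = (150, 150),
    class_proportions: tuple[float, float, float] = (0.4, 0.3, 0.3),
    n_patches: int = 60,
    transform: GeoTransform = GeoTransform(),
) -> SyntheticLandscape:
    """Patchwork landscape from seeded Voronoi cells.

    Patch nuclei are placed uniformly; each pixel joins its nearest nucleus;
    patches are assigned to classes greedily (largest patch to the class
    with the largest remaining area deficit), which keeps empirical class
    fractions close to ``class_proportions``.
    """
    props = np.asarray(class_proportions, dtype=float)
    if abs(props.sum() - 1.0) > 1e-6:
        raise ValueError("class proportions must sum to 1")
    if props.min() < 0:
        raise ValueError("class proportions must be non-negative")
    if shape[0] < 10 or shape[1] < 10:
        raise ValueError("shape must be at least 10x10")

    rng = np.random.default_rng(seed)
    h, w = shape
    nuclei = np.zeros(shape, dtype=bool)
    rr = rng.integers(0, h, n_patches)
    cc = rng.integers(0, w, n_patches)
    nuclei[rr, cc] = True
    _, (ir, ic) = distance_transform_edt(~nuclei, return_indices=True)
    patch_of_pixel = ir.astype(np.int64) * w + ic  # flat nucleus index
    patch_ids, patch_sizes = np.unique(patch_of_pixel, return_counts=True)

    targets = props * h * w
    assigned = np.zeros(3)
    patch_class = {}
    order = np.argsort(patch_sizes, kind="stable")[::-1]
    for i in order:
        deficit = targets - assigned
        klass = int(np.argmax(deficit))
        patch_class[patch_ids[i]] = klass
        assigned[klass] += patch_sizes[i]
    class_map = np.zeros(shape, dtype=np.int8)
    for pid, klass in patch_class.items():
        class_map[patch_of_pixel == pid] = klass

    # static covariates: smooth terrain-like fields plus one layer that
    # tracks the class map (a long-term greenness analog), so FSCS has
    # structure to cover
    def smooth_field(scale: float) -> np.ndarray:
        return gaussian_filter(rng.standard_normal(shape), sigma=scale)

    elevation = smooth_field(max(h, w) / 10.0) * 500.0 + 400.0
    gy, gx = np.gradient(elevation)
    covariates = {
        "elevation": elevation,
        "slope": np.hypot(gy, gx),
        "temp_mean": smooth_field(max(h, w) / 8.0) * 5.0 + 12.0,
        "dist_water": smooth_field(max(h, w) / 12.0) * 10.0 + 20.0,
        "greenness_longterm": (
            np.choose(class_map, [0.05, 0.55, 0.65])
            + 0.02 * rng.standard_normal(shape)
        ),
    }
    return SyntheticLandscape(
        class_map=class_map, static_covariates=covariates,
        transform=transform, seed=seed,
    )


def generate_acquisitions(
    landscape: SyntheticLandscape,
    signatures: SignatureSet,
    years: list[int],
    cloud_prob: float = 0.1,
    seed: int = 0,
    cloud_blob_sigma: float = 6.0,
    clear_code: int = 1,
    cloud_code: int = 3,
) -> list[AcquisitionStack]:
    """Synthesize the 16-day acquisition archive for the given years.

    Each year yields 23 acquisitions; each carries 7 reflectance bands, a QA
    band and a scalar cloud fraction. Clouds are correlated spatial blobs:
    a Gaussian-smoothed noise field thresholded at the acquisition's cloud
    fraction, which is jittered around ``cloud_prob``. Cloudy pixels get
    ``cloud_code`` in the QA band (a member of the default removal set).
    """
    if not years:
        raise ValueError("years list must not be empty")
    if not 0.0 <= cloud_prob <= 1.0:
        raise ValueError("cloud_prob must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    shape = landscape.shape
    class_map = landscape.class_map
    stacks: list[AcquisitionStack] = []
    for year in sorted(years):
        for doy in ACQUISITION_DOYS:
            date = dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)
            bands = np.empty((len(BAND_NAMES),) + shape, dtype=np.float32)
            for bi, band in enumerate(BAND_NAMES):
                base = np.zeros(shape)
                sd = np.zeros(shape)
                for klass in (0, 1, 2):
                    sig = signatures.get(klass, band)
                    sel = class_map == klass
                    base[sel] = sig.value(doy)
                    sd[sel] = sig.noise_sd
                layer = base + sd * rng.standard_normal(shape)
                bands[bi] = np.clip(layer, 0.0, 1.0)

            if cloud_prob <= 0.0:
                mask = np.zeros(shape, dtype=bool)
            elif cloud_prob >= 1.0:
                mask = np.ones(shape, dtype=bool)
            else:
                frac = float(np.clip(
                    rng.normal(cloud_prob, 0.25 * cloud_prob), 0.0, 1.0
                ))
                fld = gaussian_filter(rng.standard_normal(shape), cloud_blob_sigma)
                if frac >= 1.0:
                    mask = np.ones(shape, dtype=bool)
                else:
                    mask = fld > np.quantile(fld, 1.0 - frac)
            qa = np.where(mask, cloud_code, clear_code).astype(np.uint8)
            stacks.append(AcquisitionStack(
                date=date, bands=bands, qa=qa,
                cloud_cover=float(mask.mean()),
                transform=landscape.transform,
            ))
    return stacks


def generate_reference_tiles(
    landscape: SyntheticLandscape,
    n_tiles: int,
    sources: list[tuple[str, tuple[int, int]]] = (
        ("bing", (2009, 2014)), ("google", (2019, 2022)),
    ),
    seed: int = 0,
) -> list[ReferenceTile]:
    """Visually-interpreted reference tiles with known-truth labels.

    Tiles occupy disjoint 1x1 km blocks of the landscape; each tile's
    100x100 10 m label grid is the landscape class map resampled by nearest
    neighbour, identical across sources (the synthetic world is temporally
    stable). Per source, the reference date is uniform in that source's
    year range.
    """
    rng = np.random.default_rng(seed)
    h, w = landscape.shape
    block_rows = h // TILE_SPAN_PX
    block_cols = w // TILE_SPAN_PX
    n_slots = block_rows * block_cols
    if n_tiles > n_slots:
        raise ValueError(
            f"n_tiles={n_tiles} exceeds the {n_slots} tile slots of this landscape"
        )
    slots = rng.choice(n_slots, size=n_tiles, replace=False)

    tiles: list[ReferenceTile] = []
    cell_to_px = 1.0 / 3.0  # 10 m cells on a 30 m grid
    idx = np.minimum((np.arange(TILE_CELLS) * cell_to_px).astype(int),
                     TILE_SPAN_PX - 1)
    for tile_id, slot in enumerate(sorted(int(s) for s in slots)):
        r0 = (slot // block_cols) * TILE_SPAN_PX
        c0 = (slot % block_cols) * TILE_SPAN_PX
        grid = landscape.class_map[np.ix_(r0 + idx, c0 + idx)]
        labels = {}
        for source, (y_lo, y_hi) in sources:
            year = int(rng.integers(y_lo, y_hi + 1))
            doy = int(rng.integers(1, 366))
            date = dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)
            labels[source] = (grid.copy(), date)
        tiles.append(ReferenceTile(tile_id=tile_id, origin=(r0, c0), labels=labels))
    return tiles


@dataclass
class MockLCProduct:
    """A mock external land-cover product: per-epoch class rasters."""

    product_id: str
    epochs: tuple[int, ...]
    data: dict[int, np.ndarray]  # epoch -> (rows, cols) legend codes
    legend: dict[int, str] = field(default_factory=lambda: dict(MOCK_LEGEND))

    def class_name_at(self, location: tuple[float, float], epoch: int) -> str:
        row = int(round(location[0]))
        col = int(round(location[1]))
        return self.legend[int(self.data[epoch][row, col])]


#: How each mock product renders the truth: (grass legend code, other legend code).
_PRODUCT_STYLES = [
    ("product_a", 7, 3),  # grassland vs cropland
    ("product_b", 8, 2),  # short vegetation vs forest
    ("product_c", 9, 1),  # herbaceous vs urban
]


def generate_mock_lc(
    landscape: SyntheticLandscape,
    disagreement_rate: float = 0.0,
    seed: int = 0,
    epochs: tuple[int, ...] = MOCK_EPOCHS,
) -> list[MockLCProduct]:
    """Three mock land-cover product stacks over five epochs.

    At ``disagreement_rate`` 0 every product agrees with the ground truth
    under the default crosswalk (grassland classes render as grassland-like
    legend classes, other land as a conflicting class). Disagreement flips
    each (product, epoch, pixel) independently with the given probability:
    grassland pixels to a conflicting class, other pixels to grassland.
    """
    if not 0.0 <= disagreement_rate <= 1.0:
        raise ValueError("disagreement_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth_grass = np.isin(landscape.class_map, [1, 2])
    products = []
    for product_id, grass_code, other_code in _PRODUCT_STYLES:
        data = {}
        for epoch in epochs:
            base = np.where(truth_grass, grass_code, other_code).astype(np.uint8)
            if disagreement_rate > 0:
                flip = rng.random(landscape.shape) < disagreement_rate
                flipped = np.where(truth_grass, 3, 7).astype(np.uint8)  # cropland / grassland
                base = np.where(flip, flipped, base)
            data[epoch] = base
        products.append(MockLCProduct(
            product_id=product_id, epochs=tuple(epochs), data=data,
        ))
    return products
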