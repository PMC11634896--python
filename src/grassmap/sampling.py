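"""Sample-design and reference-sample processing.

Two concerns live here. Feature Space Coverage Sampling (FSCS) picks
training-tile locations that cover the covariate space: covariate layers are
standardized, reduced by PCA, clustered by k-means, and each cluster
contributes the single pixel closest to its centre in component space.

The reference-sample chain turns visually-interpreted 1x1 km tiles (10 m
label grids) into point samples on a 60 m support (6x6 = 36 cells per
footprint), keeps only pure footprints (class proportion 1.0), replicates
same-class pairs from two sources across intermediate years when the dates
are less than 5 years apart, and removes points that a majority of external
land-cover products contradicts in at least two epochs.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import GeoTransform

#: Reference-tile geometry: 1x1 km tiles gridded at 10 m.
TILE_CELLS = 100
CELL_M = 10.0
#: Tile span in (30 m) landscape pixels.
TILE_SPAN_PX = int(np.ceil(TILE_CELLS * CELL_M / 30.0))

#: Label value for cells no analyst classified.
UNLABELED = -1


@dataclass
class CovariateStack:
    """Static covariate layers on a common grid, with an optional mask.

    ``mask`` is True where pixels may be sampled (the analog of restricting
    the design to a short-vegetation mask).
    """

    names: list[str]
    data: np.ndarray  # (layers, rows, cols)
    mask: np.ndarray | None = None
    transform: GeoTransform = field(default_factory=GeoTransform)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.names):
            raise ValueError("data must be (n_layers, rows, cols)")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[1:], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask must match the layer grid")

    @classmethod
    def from_landscape(cls, landscape, mask: np.ndarray | None = None) -> "CovariateStack":
        names = sorted(landscape.static_covariates)
        data = np.stack([landscape.static_covariates[n] for n in names])
        return cls(names=names, data=data, mask=mask, transform=landscape.transform)


@dataclass(frozen=True)
class SampleTile:
    tile_id: int
    center: tuple[int, int]  # (row, col) pixel indices
    cluster_id: int
    distance: float  # to the cluster centre, in principal-component units


@dataclass
class ReferenceTile:
    """A 1x1 km visually-interpreted tile: per source, a 10 m label grid.

    ``labels`` maps source name to ``(grid, reference_date)`` where grid is
    a 100x100 integer array of class codes (or -1 for unlabeled cells).
    ``origin`` is the tile's upper-left corner in landscape pixel indices.
    """

    tile_id: int
    origin: tuple[int, int]
    labels: dict[str, tuple[np.ndarray, dt.date]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for source, (grid, date) in self.labels.items():
            grid = np.asarray(grid)
            if grid.shape != (TILE_CELLS, TILE_CELLS):
                raise ValueError(
                    f"label grid for {source!r} must be {TILE_CELLS}x{TILE_CELLS}"
                )
            self.labels[source] = (grid, date)


@dataclass(frozen=True)
class PointSample:
    """One labeled location-year training record."""

    sample_id: str
    location: tuple[float, float]  # (row, col), landscape pixel coordinates
    year: int
    class_code: int
    class_proportion: float
    tile_id: int
    source: str = "observed"  # observed | augmented
    label_source: str = ""  # which reference source produced it
    parents: tuple[str, ...] = ()


def fscs_select_tiles(
    covariates: CovariateStack,
    k: int,
    variance_target: float = 0.75,
    n_components_cap: int = 10,
    seed: int = 0,
) -> list[SampleTile]:
    """Feature Space Coverage Sampling tile selection.

    Standardizes each layer, runs PCA keeping the leading components up to
    ``variance_target`` explained variance (at most ``n_components_cap``),
    clusters the unmasked pixels with seeded k-means, and returns per
    cluster the unmasked pixel with minimal Euclidean distance to the
    cluster centre in component space. Returned pixels are pairwise
    distinct; a pixel already claimed by an earlier cluster falls through to
    the next-nearest pixel.
    """
    rows, cols = np.nonzero(covariates.mask)
    n = rows.size
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} unmasked pixels")
    X = covariates.data[:, rows, cols].T  # (n, layers)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd

    n_comp_max = min(Z.shape[0], Z.shape[1])
    pca = PCA(n_components=n_comp_max, random_state=seed)
    scores = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_target) + 1)
    n_comp = min(n_comp, n_components_cap, n_comp_max)
    scores = scores[:, :n_comp]

    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    km.fit(scores)

    taken: set[int] = set()
    tiles: list[SampleTile] = []
    for cluster_id, centre in enumerate(km.cluster_centers_):
        d = np.linalg.norm(scores - centre, axis=1)
        order = np.argsort(d, kind="stable")
        idx = next(int(i) for i in order if int(i) not in taken)
        taken.add(idx)
        tiles.append(SampleTile(
            tile_id=cluster_id,
            center=(int(rows[idx]), int(cols[idx])),
            cluster_id=cluster_id,
            distance=float(d[idx]),
        ))
    return tiles


def tile_to_points(
    tile: ReferenceTile,
    support_m: float = 60.0,
    cell_m: float = CELL_M,
) -> tuple[list[PointSample], int]:
    """Convert a reference tile to candidate point samples on a 60 m support.

    The tile is paved with ``support_m`` footprints from its origin (partial
    edge footprints are dropped). Each footprint yields one candidate per
    source: its class is the modal class of the footprint's 10 m cells, its
    class proportion that class's cell share, and its year the source's
    reference date. Footprints containing unlabeled cells are skipped and
    counted. Purity filtering is a separate downstream step
    (:func:`purity_filter`).
    """
    f = int(round(support_m / cell_m))  # cells per footprint side (6)
    n_fp = TILE_CELLS // f
    skipped = 0
    points: list[PointSample] = []
    r0, c0 = tile.origin
    px_per_cell = cell_m / 30.0
    for source, (grid, date) in sorted(tile.labels.items()):
        for i in range(n_fp):
            for j in range(n_fp):
                cells = grid[i * f:(i + 1) * f, j * f:(j + 1) * f]
                if (cells == UNLABELED).any():
                    skipped += 1
                    continue
                counts = np.bincount(cells.ravel(), minlength=3)
                klass = int(counts.argmax())
                proportion = counts[klass] / cells.size
                row = r0 + (i * f + f / 2.0) * px_per_cell
                col = c0 + (j * f + f / 2.0) * px_per_cell
                points.append(PointSample(
                    sample_id=f"t{tile.tile_id}_{source}_{i}_{j}",
                    location=(row, col),
                    year=date.year,
                    class_code=klass,
                    class_proportion=float(proportion),
                    tile_id=tile.tile_id,
                    source="observed",
                    label_source=source,
                ))
    return points, skipped


def purity_filter(
    points: list[PointSample], min_proportion: float = 1.0
) -> list[PointSample]:
    """Keep only candidates whose class proportion reaches ``min_proportion``."""
    return [p for p in points if p.class_proportion >= min_proportion]


def augment_temporal(
    points: list[PointSample], max_gap_years: int = 5
) -> list[PointSample]:
    """Replicate same-class two-source pairs across intermediate years.

    For two observed samples at the same location with years ``y1 < y2``,
    equal class, and ``y2 - y1 < max_gap_years``, one augmented sample is
    emitted per year strictly between them. Pairs with different classes or
    a gap of ``max_gap_years`` or more contribute nothing.
    """
    by_loc: dict[tuple, list[PointSample]] = defaultdict(list)
    for p in points:
        if p.source == "observed":
            by_loc[(p.tile_id, round(p.location[0], 6), round(p.location[1], 6))].append(p)

    augmented: list[PointSample] = []
    for group in by_loc.values():
        group = sorted(group, key=lambda p: (p.year, p.label_source))
        for a_idx in range(len(group)):
            for b_idx in range(a_idx + 1, len(group)):
                a, b = group[a_idx], group[b_idx]
                if a.label_source == b.label_source:
                    continue
                if a.class_code != b.class_code:
                    continue
                if not 0 < b.year - a.year < max_gap_years:
                    continue
                for year in range(a.year + 1, b.year):
                    augmented.append(replace(
                        a,
                        sample_id=f"{a.sample_id}_aug{year}",
                        year=year,
                        source="augmented",
                        parents=(a.sample_id, b.sample_id),
                    ))
    # a location can appear in several pairs; keep one replicate per year
    seen: set[tuple] = set()
    out: list[PointSample] = []
    for p in augmented:
        key = (p.tile_id, p.location, p.year, p.class_code)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


#: Default crosswalk from the mock-product legend to filter roles.
DEFAULT_CROSSWALK: dict[str, str] = {
    "other": "neutral",
    "urban": "conflict",
    "forest": "conflict",
    "cropland": "conflict",
    "water": "conflict",
    "snow": "conflict",
    "wetland": "conflict",
    "grassland": "grass",
    "short_vegetation": "grass",
    "herbaceous": "grass",
}


def filter_by_lc_agreement(
    points: list[PointSample],
    products: list,
    crosswalk: dict[str, str] | None = None,
    min_products: int = 2,
    min_epochs: int = 2,
    count_product_epoch_pairs: bool = False,
    min_pairs: int = 2,
) -> tuple[list[PointSample], list[dict]]:
    """Remove points that external land-cover products consistently contradict.

    A grassland-class point (codes 1 or 2) is removed when at least
    ``min_products`` distinct products each disagree (show a class with
    crosswalk role ``conflict``) in at least ``min_epochs`` distinct epochs.
    An other-class point is removed symmetrically when products show a
    ``grass`` role class. With ``count_product_epoch_pairs`` the rule
    instead pools all (product, epoch) disagreement observations and
    removes at ``min_pairs`` of them — a laxer reading of the same
    majority idea, off by default.

    Returns the kept points and a removal log with the triggering evidence.
    """
    crosswalk = DEFAULT_CROSSWALK if crosswalk is None else crosswalk
    kept: list[PointSample] = []
    removed: list[dict] = []
    for p in points:
        against = "conflict" if p.class_code in (1, 2) else "grass"
        evidence: dict[str, list[int]] = {}
        for product in products:
            epochs = []
            for epoch in product.epochs:
                name = product.class_name_at(p.location, epoch)
                if name not in crosswalk:
                    raise ValueError(
                        f"crosswalk has no entry for product class {name!r}"
                    )
                if crosswalk[name] == against:
                    epochs.append(epoch)
            if epochs:
                evidence[product.product_id] = epochs
        if count_product_epoch_pairs:
            n_pairs = sum(len(v) for v in evidence.values())
            remove = n_pairs >= min_pairs
        else:
            strong = [pid for pid, ep in evidence.items() if len(ep) >= min_epochs]
            remove = len(strong) >= min_products
        if remove:
            removed.append({"point": p, "evidence": evidence})
        else:
            kept.append(p)
    return kept, removed


def points_to_table(points: list[PointSample], transform: GeoTransform):
    """Point samples as a pandas table with geographic coordinates."""
    import pandas as pd

    rows = []
    for p in points:
        lon, lat = transform.to_lonlat(*p.location)
        rows.append({
            "id": p.sample_id, "lon": lon, "lat": lat, "year": p.year,
            "class": p.class_code, "proportion": p.class_proportion,
            "tile_id": p.tile_id, "source": p.source,
            "label_source": p.label_source,
        })
    return pd.DataFrame(rows)
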