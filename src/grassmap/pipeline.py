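"""End-to-end orchestration of the desk-scale mapping pipeline.

Chains every stage over a synthetic world with known ground truth:
acquisitions -> bi-monthly composites with seasonal gap-filling -> spectral
indices -> reference tiles -> point samples (purity, temporal augmentation,
product-agreement filter) -> spacetime overlay -> tile-blocked models ->
probability cubes -> balanced thresholds -> 3-D smoothing -> dominant map,
and scores the recovered map against the known class map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model, postml, sampling, synthio
from .composite import build_composite_series
from .core import NODATA, DominantMap, ProbabilityCube
from .indices import build_index_cube
from .validation import accuracy_matrix


@dataclass
class PipelineResult:
    landscape: synthio.SyntheticLandscape
    dominant: DominantMap
    cubes: dict[str, ProbabilityCube]
    smoothed: dict[str, ProbabilityCube]
    thresholds: dict[str, postml.ThresholdResult]
    oof: dict = field(default_factory=dict)
    n_samples: int = 0
    gap_report: list = field(default_factory=list)

    def per_class_f1(self) -> dict[int, float]:
        """Pooled-over-years F1 of each class of the recovered map."""
        truth = np.broadcast_to(
            self.landscape.class_map, self.dominant.data.shape
        ).ravel()
        pred = self.dominant.data.ravel()
        ok = pred != NODATA
        matrix = accuracy_matrix(pred[ok], truth[ok])
        return {c: matrix.f1(c) for c in matrix.labels}


def run_end_to_end(
    seed: int = 1,
    shape: tuple[int, int] = (150, 150),
    years: tuple[int, ...] = (2016, 2017, 2018, 2019, 2020, 2021, 2022),
    cloud_prob: float = 0.1,
    n_tiles: int = 12,
    preset: str = "easy",
    max_points_per_tile: int = 60,
    disagreement_rate: float = 0.02,
    n_trees: int = 60,
) -> PipelineResult:
    """Run the full chain on a synthetic landscape and score the recovery.

    All randomness derives from ``seed``. Defaults are sized for a desk-run
    of a few minutes; the stages and their parameters match the production
    configuration (23 acquisitions/year, 6 composites/year, 84 seasonal
    features, 5 tile-blocked folds, balanced thresholds, 5^3 smoothing).
    """
    years = sorted(years)
    from .sampling import TILE_SPAN_PX

    slots = (shape[0] // TILE_SPAN_PX) * (shape[1] // TILE_SPAN_PX)
    if slots < 5:
        raise ValueError(
            f"landscape {shape} holds only {slots} 1x1 km tile slots; "
            f"at least 5 are needed for tile-blocked folds "
            f"(use a shape of {5 * TILE_SPAN_PX}x{TILE_SPAN_PX} or larger)"
        )
    n_tiles = min(n_tiles, slots)
    landscape = synthio.generate_landscape(seed, shape=shape)
    signatures = synthio.signature_preset(preset)
    acquisitions = synthio.generate_acquisitions(
        landscape, signatures, years, cloud_prob=cloud_prob, seed=seed + 1
    )
    composites, gap_report = build_composite_series(acquisitions, years)
    index_cube = build_index_cube(composites)

    mid = years[len(years) // 2]
    tiles = synthio.generate_reference_tiles(
        landscape, n_tiles,
        sources=[("src_early", (years[0], mid)), ("src_late", (mid, years[-1]))],
        seed=seed + 2,
    )
    points: list[sampling.PointSample] = []
    for tile in tiles:
        candidates, _skipped = sampling.tile_to_points(tile)
        points.extend(sampling.purity_filter(candidates))
    points.extend(sampling.augment_temporal(points))
    products = synthio.generate_mock_lc(
        landscape, disagreement_rate=disagreement_rate, seed=seed + 3
    )
    points, _removed = sampling.filter_by_lc_agreement(points, products)

    # cap per-tile sample counts to keep the fits desk-sized
    rng = np.random.default_rng(seed + 4)
    by_tile: dict[int, list[sampling.PointSample]] = {}
    for p in points:
        by_tile.setdefault(p.tile_id, []).append(p)
    capped: list[sampling.PointSample] = []
    for tile_id in sorted(by_tile):
        group = by_tile[tile_id]
        if len(group) > max_points_per_tile:
            take = rng.choice(len(group), max_points_per_tile, replace=False)
            group = [group[int(i)] for i in sorted(take)]
        capped.extend(group)

    static = sampling.CovariateStack.from_landscape(landscape)
    matrix, _excluded = model.spacetime_overlay(
        capped, composites, index_cube, static
    )
    folds = model.make_spatial_folds(matrix, k=5, seed=seed + 5)

    cubes: dict[str, ProbabilityCube] = {}
    smoothed: dict[str, ProbabilityCube] = {}
    thresholds: dict[str, postml.ThresholdResult] = {}
    oof_tables: dict[str, object] = {}
    for task in model.TASKS:
        spec = model.ModelSpec(
            task=task, learner="random_forest",
            hyperparameters={"n_estimators": n_trees}, seed=seed + 6,
        )
        oof = model.cross_val_predict_oof(matrix, folds, spec)
        curve = postml.pr_curve(
            oof["probability"].to_numpy(), oof["label"].to_numpy()
        )
        thresholds[task] = postml.balanced_threshold(curve, class_name=task)
        oof_tables[task] = oof
        cube = model.fit_predict_full(
            matrix, spec, composites, index_cube, static, years,
            transform=landscape.transform,
        )
        cubes[task] = cube
        smoothed[task] = postml.smooth_savgol3d(cube)

    dominant = postml.integrate_dominant(
        smoothed["cultivated"], smoothed["natural"],
        (thresholds["cultivated"], thresholds["natural"]),
    )
    return PipelineResult(
        landscape=landscape, dominant=dominant, cubes=cubes,
        smoothed=smoothed, thresholds=thresholds, oof=oof_tables,
        n_samples=len(matrix), gap_report=gap_report,
    )
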