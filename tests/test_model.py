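import numpy as np
import pandas as pd
import pytest

from grassmap import model
from grassmap.model import (
    ModelSpec,
    cross_val_predict_oof,
    feature_columns,
    make_spatial_folds,
    rfe_select,
    seasonal_feature_names,
    spacetime_overlay,
    split_calibration,
    successive_halving,
)


def synthetic_matrix(n_tiles=20, per_tile=10, n_noise=6, seed=0, separation=3.0):
    """Feature matrix with one informative feature separating class 2."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for tile in range(n_tiles):
        for _ in range(per_tile):
            klass = int(rng.integers(0, 3))
            row = {
                "sample_id": f"s{i}", "tile_id": tile, "year": 2020,
                "class_code": klass, "complete": True,
                "signal": separation * (klass == 2) + rng.normal(),
            }
            for j in range(n_noise):
                row[f"noise{j}"] = rng.normal()
            rows.append(row)
            i += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def overlay(landscape, one_year_composites):
    from grassmap.sampling import CovariateStack, PointSample

    composites, index_cube, _ = one_year_composites
    static = CovariateStack.from_landscape(landscape)
    points = [
        PointSample(
            sample_id=f"p{i}", location=(float(10 + i), 12.0), year=2020,
            class_code=int(landscape.class_map[10 + i, 12]),
            class_proportion=1.0, tile_id=i // 5,
        )
        for i in range(20)
    ]
    points.append(PointSample(
        sample_id="outside", location=(-3.0, 4.0), year=2020,
        class_code=0, class_proportion=1.0, tile_id=99,
    ))
    matrix, excluded = spacetime_overlay(points, composites, index_cube, static)
    return matrix, excluded, static


@pytest.fixture(scope="module")
def prediction_setup(landscape, one_year_composites):
    from grassmap.sampling import CovariateStack, PointSample

    composites, index_cube, _ = one_year_composites
    static = CovariateStack.from_landscape(landscape)
    rng = np.random.default_rng(0)
    points = []
    for i in range(60):
        r, c = int(rng.integers(0, 120)), int(rng.integers(0, 120))
        points.append(PointSample(
            sample_id=f"p{i}", location=(float(r), float(c)), year=2020,
            class_code=int(landscape.class_map[r, c]),
            class_proportion=1.0, tile_id=i % 8,
        ))
    matrix, _ = spacetime_overlay(points, composites, index_cube, static)
    return matrix, composites, index_cube, static


class TestSpacetimeOverlay:
    def test_84_seasonal_columns(self, overlay):
        matrix, _, _ = overlay
        seasonal = [c for c in seasonal_feature_names() if c in matrix.columns]
        assert len(seasonal) == 84

    def test_total_columns_84_plus_static(self, overlay):
        matrix, _, static = overlay
        assert len(feature_columns(matrix)) == 84 + len(static.names)

    def test_out_of_extent_point_excluded(self, overlay):
        matrix, excluded, _ = overlay
        assert excluded == ["outside"]
        assert "outside" not in set(matrix["sample_id"])

    def test_statics_identical_across_years_at_location(
        self, landscape, signatures
    ):
        from grassmap.composite import build_composite_series
        from grassmap.indices import build_index_cube
        from grassmap.sampling import CovariateStack, PointSample
        from grassmap.synthio import generate_acquisitions

        acq = generate_acquisitions(
            landscape, signatures, [2020, 2021], cloud_prob=0.0, seed=2
        )
        composites, _ = build_composite_series(acq, [2020, 2021])
        cube = build_index_cube(composites)
        static = CovariateStack.from_landscape(landscape)
        points = [
            PointSample(sample_id=f"y{y}", location=(30.0, 30.0), year=y,
                        class_code=0, class_proportion=1.0, tile_id=0)
            for y in (2020, 2021)
        ]
        matrix, _ = spacetime_overlay(points, composites, cube, static)
        static_cols = [c for c in matrix.columns if c.startswith("static_")]
        seasonal_cols = [c for c in seasonal_feature_names() if c in matrix]
        a, b = matrix.iloc[0], matrix.iloc[1]
        assert (a[static_cols] == b[static_cols]).all()
        assert (a[seasonal_cols] != b[seasonal_cols]).any()

    def test_missing_year_rejected(self, overlay, one_year_composites):
        from grassmap.sampling import PointSample

        composites, cube, _ = one_year_composites
        _, _, static = overlay
        bad = [PointSample(sample_id="x", location=(5.0, 5.0), year=1999,
                           class_code=0, class_proportion=1.0, tile_id=0)]
        with pytest.raises(ValueError, match="1999"):
            spacetime_overlay(bad, composites, cube, static)


class TestCalibrationSplit:
    def test_hundred_samples_gives_ten(self):
        matrix = synthetic_matrix(n_tiles=1, per_tile=100)
        train, cal = split_calibration(matrix, 0.10, seed=0)
        assert len(cal) == 10 and len(train) == 90

    def test_single_sample_tile_keeps_training(self):
        matrix = synthetic_matrix(n_tiles=3, per_tile=1)
        train, cal = split_calibration(matrix, 0.10, seed=0)
        assert len(cal) == 0 and len(train) == 3

    def test_split_is_partition(self):
        matrix = synthetic_matrix(n_tiles=7, per_tile=13)
        train, cal = split_calibration(matrix, 0.10, seed=1)
        ids = set(train["sample_id"]) | set(cal["sample_id"])
        assert len(ids) == len(matrix)
        assert set(train["sample_id"]).isdisjoint(cal["sample_id"])

    def test_deterministic_under_seed(self):
        matrix = synthetic_matrix()
        _, cal1 = split_calibration(matrix, 0.10, seed=5)
        _, cal2 = split_calibration(matrix, 0.10, seed=5)
        assert list(cal1["sample_id"]) == list(cal2["sample_id"])


class TestSpatialFolds:
    def test_samples_inherit_tile_fold(self):
        matrix = synthetic_matrix(n_tiles=10)
        folds = make_spatial_folds(matrix, k=5, seed=0)
        for _tile, group in matrix.groupby("tile_id"):
            fold_values = {folds.sample_fold[s] for s in group["sample_id"]}
            assert len(fold_values) == 1

    def test_partition_and_balance(self):
        matrix = synthetic_matrix(n_tiles=10)
        folds = make_spatial_folds(matrix, k=5, seed=1)
        per_fold = pd.Series(folds.tile_fold).value_counts()
        assert sorted(per_fold.index) == [1, 2, 3, 4, 5]
        assert (per_fold == 2).all()  # 10 tiles over 5 folds
        assert len(folds.sample_fold) == len(matrix)

    def test_too_few_tiles_rejected(self):
        matrix = synthetic_matrix(n_tiles=3)
        with pytest.raises(ValueError):
            make_spatial_folds(matrix, k=5, seed=0)


class TestRFE:
    def test_output_size_and_subset(self):
        matrix = synthetic_matrix(n_noise=20)
        features = feature_columns(matrix)
        selected = rfe_select(matrix, "natural", target=8, step=4,
                              spec=ModelSpec(task="natural",
                                             hyperparameters={"n_estimators": 25}))
        assert len(selected) == 8
        assert set(selected) <= set(features)

    def test_target_at_feature_count_is_identity(self):
        matrix = synthetic_matrix(n_noise=4)
        features = feature_columns(matrix)
        assert rfe_select(matrix, "natural", target=len(features)) == features

    def test_informative_features_survive(self):
        """With 4 informative + 40 noise features, elimination keeps the
        signal: over seeded runs most informative features survive."""
        retained = 0
        n_runs = 8
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            n = 240
            klass = rng.integers(0, 2, n)
            data = {"sample_id": [f"s{i}" for i in range(n)],
                    "tile_id": np.arange(n) % 12, "year": 2020,
                    "class_code": np.where(klass == 1, 2, 0), "complete": True}
            for j in range(4):
                data[f"info{j}"] = klass * 2.0 + rng.normal(0, 1, n)
            for j in range(40):
                data[f"noise{j}"] = rng.normal(0, 1, n)
            matrix = pd.DataFrame(data)
            spec = ModelSpec(task="natural",
                             hyperparameters={"n_estimators": 30}, seed=seed)
            selected = rfe_select(matrix, "natural", target=4, step=4, spec=spec)
            retained += sum(1 for f in selected if f.startswith("info"))
        assert retained / n_runs >= 3.2  # >=80% of informative slots


class TestSuccessiveHalving:
    def test_schedule_and_survivor(self, monkeypatch):
        calls = []

        def fake_logloss(matrix, task, spec, k, seed):
            calls.append((len(matrix), spec.hyperparameters["c"]))
            return spec.hyperparameters["c"]  # lower c is better

        monkeypatch.setattr(model, "_blocked_logloss", fake_logloss)
        matrix = synthetic_matrix(n_tiles=40, per_tile=50)  # 2000 rows
        candidates = [{"c": c} for c in range(8)]
        best = successive_halving(matrix, "natural", candidates,
                                  start_n=500, seed=0)
        assert best == {"c": 0}
        sizes = [n for n, _ in calls]
        # rounds: 8 candidates at 500, 4 at 1000, 2 at 2000
        assert sizes == [500] * 8 + [1000] * 4 + [2000] * 2

    def test_single_candidate_returned_without_rounds(self, monkeypatch):
        def boom(*a, **k):
            raise AssertionError("should not evaluate")

        monkeypatch.setattr(model, "_blocked_logloss", boom)
        best = successive_halving(synthetic_matrix(), "natural", [{"c": 1}])
        assert best == {"c": 1}

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            successive_halving(synthetic_matrix(), "natural", [])


class TestOOFPrediction:
    def test_every_sample_predicted_once_and_blocked(self):
        matrix = synthetic_matrix(n_tiles=10, per_tile=8, seed=3)
        folds = make_spatial_folds(matrix, k=5, seed=0)
        spec = ModelSpec(task="natural", hyperparameters={"n_estimators": 20})
        oof = cross_val_predict_oof(matrix, folds, spec)
        assert sorted(oof["sample_id"]) == sorted(matrix["sample_id"])
        assert oof["sample_id"].is_unique
        tile_of = dict(zip(matrix["sample_id"], matrix["tile_id"]))
        for sid, fold in zip(oof["sample_id"], oof["fold"]):
            assert folds.tile_fold[tile_of[sid]] == fold

    def test_separable_signal_gives_high_auc(self):
        from sklearn.metrics import roc_auc_score

        matrix = synthetic_matrix(n_tiles=20, per_tile=15, seed=1,
                                  separation=4.0)
        folds = make_spatial_folds(matrix, k=5, seed=0)
        spec = ModelSpec(task="natural", hyperparameters={"n_estimators": 40})
        oof = cross_val_predict_oof(matrix, folds, spec)
        assert roc_auc_score(oof["label"], oof["probability"]) > 0.95

    def test_blocking_no_tile_on_both_sides_200_tiles(self):
        """Exhaustive blocking check on a 200-tile synthetic set."""
        matrix = synthetic_matrix(n_tiles=200, per_tile=3, seed=2)
        folds = make_spatial_folds(matrix, k=5, seed=4)
        fold_of_tile = folds.tile_fold
        for fold in range(1, 6):
            test_tiles = {t for t, f in fold_of_tile.items() if f == fold}
            train_tiles = {t for t, f in fold_of_tile.items() if f != fold}
            assert test_tiles.isdisjoint(train_tiles)
            assert test_tiles | train_tiles == set(matrix["tile_id"].unique())

    def test_single_class_fold_raises(self):
        matrix = synthetic_matrix(n_tiles=5, per_tile=4, seed=0)
        matrix.loc[matrix["tile_id"] != 0, "class_code"] = 2
        matrix.loc[matrix["tile_id"] == 0, "class_code"] = 2
        folds = make_spatial_folds(matrix, k=5, seed=0)
        spec = ModelSpec(task="natural")
        with pytest.raises(ValueError, match="fold"):
            cross_val_predict_oof(matrix, folds, spec)


class TestFitPredictFull:
    def test_probability_encoding_and_exclusion(self, prediction_setup, landscape):
        matrix, composites, index_cube, static = prediction_setup
        exclusion = np.zeros(landscape.shape, bool)
        exclusion[:5] = True
        spec = ModelSpec(task="natural", hyperparameters={"n_estimators": 20})
        cube = model.fit_predict_full(
            matrix, spec, composites, index_cube, static, [2020],
            exclusion_mask=exclusion,
        )
        assert cube.data.dtype == np.uint8
        assert (cube.data[0, :5] == 255).all()
        valid = cube.data[0, 5:]
        assert valid.max() <= 100

    def test_deterministic_under_seed(self, prediction_setup):
        matrix, composites, index_cube, static = prediction_setup
        spec = ModelSpec(task="cultivated",
                         hyperparameters={"n_estimators": 15}, seed=3)
        a = model.fit_predict_full(matrix, spec, composites, index_cube,
                                   static, [2020])
        b = model.fit_predict_full(matrix, spec, composites, index_cube,
                                   static, [2020])
        assert np.array_equal(a.data, b.data)

    def test_missing_year_rejected(self, prediction_setup):
        matrix, composites, index_cube, static = prediction_setup
        spec = ModelSpec(task="natural")
        with pytest.raises(ValueError, match="2031"):
            model.fit_predict_full(matrix, spec, composites, index_cube,
                                   static, [2031])
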