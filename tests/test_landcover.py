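import numpy as np
import pandas as pd
import pytest

from peatwatch.grid import RasterGrid
from peatwatch.landcover import (
    BOG, CLASS_CODES, FOREST, GRASSLAND, NODATA, LandCoverMap, TrainingSet,
    TransitionMode, accuracy_report_from_confusion, assess_accuracy,
    class_areas, confusion_matrix, f1_from_errors, maximum_likelihood_classify,
    sample_balanced_training, shares_from_areas, split_train_validation,
    stable_pixel_mask, temporal_majority_filter, train_random_forest,
    transition_matrix, _ml_classify_stack,
)
from peatwatch.indices import PREDICTOR_NAMES

from conftest import make_composite


def lc(classes, year=2000):
    classes = np.asarray(classes, dtype=np.int16)
    return LandCoverMap(year, classes, RasterGrid.square(*classes.shape))


def make_training_frame(rng, n_per_class=60, separation=5.0):
    rows = []
    for code in CLASS_CODES:
        X = rng.normal(loc=code * separation, scale=1.0, size=(n_per_class, 10))
        df = pd.DataFrame(X, columns=list(PREDICTOR_NAMES))
        df.insert(0, "label", code)
        df.insert(0, "year", 2000)
        df.insert(0, "col", np.arange(n_per_class))
        df.insert(0, "row", np.arange(n_per_class))
        rows.append(df)
    return TrainingSet(pd.concat(rows, ignore_index=True))


class TestMaximumLikelihood:
    def _stats(self, means, cov=None):
        cov = np.eye(10) if cov is None else cov
        return {c: (np.asarray(m, dtype=float), cov.copy()) for c, m in means.items()}

    def test_pixel_at_class_mean(self):
        grid = RasterGrid.square(1, 1)
        stats = self._stats({1: np.zeros(10), 2: np.full(10, 1.0), 3: np.full(10, 2.0)})
        stack = np.full((10, 1, 1), 1.0)
        out = _ml_classify_stack(stack, grid, 2000, stats)
        assert out.classes[0, 0] == 2

    def test_tie_goes_to_lowest_code(self):
        grid = RasterGrid.square(1, 1)
        stats = self._stats({1: np.zeros(10), 2: np.zeros(10)})
        stack = np.full((10, 1, 1), 0.5)
        out = _ml_classify_stack(stack, grid, 2000, stats)
        assert out.classes[0, 0] == 1

    def test_density_oracle(self, rng):
        from scipy.stats import multivariate_normal
        grid = RasterGrid.square(20, 50)   # 1000 pixels
        means = {c: rng.normal(size=10) for c in CLASS_CODES}
        covs = {}
        for c in CLASS_CODES:
            A = rng.normal(size=(10, 10))
            covs[c] = A @ A.T / 10 + np.eye(10)
        stats = {c: (means[c], covs[c]) for c in CLASS_CODES}
        stack = rng.normal(size=(10, 20, 50))
        out = _ml_classify_stack(stack, grid, 2000, stats)
        ll = np.stack([
            multivariate_normal(means[c], covs[c]).logpdf(
                stack.reshape(10, -1).T)
            for c in CLASS_CODES])
        expected = np.asarray(CLASS_CODES)[np.argmax(ll, axis=0)].reshape(20, 50)
        np.testing.assert_array_equal(out.classes, expected)

    def test_singular_covariance_regularized(self):
        grid = RasterGrid.square(2, 2)
        stats = {1: (np.zeros(10), np.zeros((10, 10))),
                 2: (np.ones(10), np.eye(10))}
        stack = np.zeros((10, 2, 2))
        out = _ml_classify_stack(stack, grid, 2000, stats)
        assert set(np.unique(out.classes)) <= {1, 2}


class TestStablePixels:
    def test_identical_maps(self):
        m = lc([[1, 2], [3, 1]])
        masks = stable_pixel_mask([m, m, m])
        np.testing.assert_array_equal(masks[1], m.classes == 1)
        np.testing.assert_array_equal(masks[2], m.classes == 2)

    def test_changed_pixel_unstable(self):
        a = lc([[1, 1]])
        b = lc([[1, 2]])
        masks = stable_pixel_mask([a, b])
        assert masks[1][0, 0] and not masks[1][0, 1] and not masks[2][0, 1]

    def test_set_oracle(self, rng):
        maps = [lc(rng.integers(1, 4, size=(15, 15))) for _ in range(4)]
        masks = stable_pixel_mask(maps)
        for code in CLASS_CODES:
            expected = np.logical_and.reduce([m.classes == code for m in maps])
            np.testing.assert_array_equal(masks[code], expected)

    def test_single_map_rejected(self):
        with pytest.raises(ValueError):
            stable_pixel_mask([lc([[1]])])


class TestSampling:
    def _setup(self, rng, rows=20, cols=20):
        grid = RasterGrid.square(rows, cols)
        classes = rng.integers(1, 4, size=(rows, cols)).astype(np.int16)
        masks = {c: classes == c for c in CLASS_CODES}
        comps = {y: make_composite(grid, rng=rng, year=y) for y in (2000, 2005)}
        return masks, comps

    def test_balanced_pooled_counts(self, rng):
        masks, comps = self._setup(rng)
        ts = sample_balanced_training(masks, 10, [2000, 2005], comps, seed=1)
        counts = ts.class_counts
        assert all(counts[c] == 10 * 2 for c in CLASS_CODES)

    def test_exhaustive_sample(self, rng):
        masks, comps = self._setup(rng)
        n_min = min(int(m.sum()) for m in masks.values())
        ts = sample_balanced_training(masks, n_min, [2000], comps, seed=1)
        assert ts.class_counts == {c: n_min for c in CLASS_CODES}

    def test_insufficient_pixels_names_class(self, rng):
        masks, comps = self._setup(rng)
        masks[BOG] = np.zeros_like(masks[BOG])
        with pytest.raises(ValueError, match="Bog"):
            sample_balanced_training(masks, 5, [2000], comps, seed=1)

    def test_seed_reproducibility(self, rng):
        masks, comps = self._setup(rng)
        a = sample_balanced_training(masks, 10, [2000, 2005], comps, seed=42)
        b = sample_balanced_training(masks, 10, [2000, 2005], comps, seed=42)
        pd.testing.assert_frame_equal(a.points, b.points)


class TestSplit:
    def test_fraction_one_rejected(self, rng):
        ts = make_training_frame(rng)
        with pytest.raises(ValueError):
            split_train_validation(ts, 1.0)

    def test_partition(self, rng):
        ts = make_training_frame(rng)
        train, val = split_train_validation(ts, 0.75, seed=3)
        assert len(train) + len(val) == len(ts)
        merged = pd.concat([train.points, val.points]).sort_values(
            list(ts.points.columns)).reset_index(drop=True)
        orig = ts.points.sort_values(list(ts.points.columns)).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, orig)

    def test_split_size_distribution(self):
        # 1000 rows at 0.75 -> mean 750, sd ~13.7; check over seeds
        rng = np.random.default_rng(0)
        ts = make_training_frame(rng, n_per_class=334)  # ~1000 rows
        sizes = []
        for seed in range(30):
            train, _ = split_train_validation(ts, 0.75, seed=seed)
            sizes.append(len(train))
        n = len(ts)
        assert abs(np.mean(sizes) - 0.75 * n) < 3 * np.sqrt(n * 0.75 * 0.25 / 30)


class TestRandomForest:
    def test_separable_classes_high_oa(self, rng):
        ts = make_training_frame(rng, n_per_class=200, separation=5.0)
        train, val = split_train_validation(ts, 0.75, seed=1)
        clf = train_random_forest(train, n_trees=50, seed=1)
        report = assess_accuracy(clf, val, n_stratified_per_class=50, seed=1)
        assert report.overall_accuracy > 0.99

    def test_determinism(self, rng):
        ts = make_training_frame(rng, n_per_class=100)
        clf1 = train_random_forest(ts, n_trees=30, seed=9)
        clf2 = train_random_forest(ts, n_trees=30, seed=9)
        X = np.random.default_rng(1).normal(5, 3, size=(50, 10))
        np.testing.assert_array_equal(clf1.predict(X), clf2.predict(X))

    def test_single_class_rejected(self, rng):
        ts = make_training_frame(rng, n_per_class=20)
        single = TrainingSet(ts.points[ts.points.label == FOREST].reset_index(drop=True))
        with pytest.raises(ValueError):
            train_random_forest(single)


class TestAccuracy:
    def test_perfect_predictions(self):
        cm = np.diag([10, 20, 30])
        r = accuracy_report_from_confusion(cm)
        assert r.overall_accuracy == 1.0 and r.kappa == 1.0
        assert (r.per_class.f1 == 1.0).all()

    def test_hand_computed_kappa_2x2(self):
        r = accuracy_report_from_confusion(np.array([[2, 1], [0, 3]]), labels=(1, 2))
        assert r.overall_accuracy == pytest.approx(5 / 6)
        assert r.kappa == pytest.approx(2 / 3, abs=1e-3)

    def test_paper_f1_from_forest_errors(self):
        assert f1_from_errors(0.029, 0.153) == pytest.approx(0.905, abs=5e-4)

    def test_f1_identity_on_report(self, rng):
        cm = rng.integers(1, 50, size=(3, 3))
        r = accuracy_report_from_confusion(cm)
        for _, row in r.per_class.iterrows():
            ua, pa = row.ua, row.pa
            assert row.f1 == pytest.approx(2 * ua * pa / (ua + pa), abs=1e-12)

    def test_kappa_le_oa(self, rng):
        for _ in range(20):
            cm = rng.integers(0, 60, size=(3, 3))
            if cm.sum() == 0:
                continue
            r = accuracy_report_from_confusion(cm)
            assert r.kappa <= r.overall_accuracy + 1e-12

    def test_kappa_one_iff_diagonal(self, rng):
        r = accuracy_report_from_confusion(np.diag([5, 5, 5]))
        assert r.kappa == pytest.approx(1.0)
        cm = np.diag([5, 5, 5])
        cm[0, 1] = 1
        assert accuracy_report_from_confusion(cm).kappa < 1.0

    def test_confusion_matrix_orientation(self):
        # reference 1 predicted 2 -> row 0, col 1
        cm = confusion_matrix([1], [2])
        assert cm[0, 1] == 1 and cm.sum() == 1

    def test_empty_validation_class_rejected(self, rng):
        ts = make_training_frame(rng, n_per_class=30)
        clf = train_random_forest(ts, n_trees=10, seed=0)
        no_bog = TrainingSet(ts.points[ts.points.label != BOG].reset_index(drop=True))
        with pytest.raises(ValueError):
            assess_accuracy(clf, no_bog)


class TestMajorityFilter:
    def _series(self, labels):
        return [lc([[v]], year=2000 + i) for i, v in enumerate(labels)]

    def _filtered(self, labels, window=5):
        maps = temporal_majority_filter(self._series(labels), window)
        return [int(m.classes[0, 0]) for m in maps]

    def test_constant_series_unchanged(self):
        assert self._filtered([FOREST] * 6) == [FOREST] * 6

    def test_mode_wins(self):
        # F,B,F,F,B -> center year (index 2) mode F (3/5)
        out = self._filtered([FOREST, BOG, FOREST, FOREST, BOG])
        assert out[2] == FOREST

    def test_spike_removed(self):
        out = self._filtered([FOREST, FOREST, BOG, FOREST, FOREST])
        assert out[2] == FOREST

    def test_edge_tie_keeps_center(self):
        # year 0 window = {F, B} (truncated, window 3): tie -> center label kept
        out = self._filtered([FOREST, BOG], window=3)
        assert out[0] == FOREST and out[1] == BOG

    def test_nodata_conserved(self, rng):
        maps = [lc(rng.integers(0, 4, size=(8, 8)), year=2000 + i) for i in range(7)]
        filtered = temporal_majority_filter(maps, 5)
        for before, after in zip(maps, filtered):
            np.testing.assert_array_equal(before.classes == NODATA,
                                          after.classes == NODATA)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            temporal_majority_filter(self._series([1, 1]), 4)


class TestAreas:
    def test_known_counts_exact_ha(self):
        classes = np.full((10, 10), FOREST, dtype=np.int16)
        classes[:2] = BOG          # 20 pixels
        classes[9, :5] = GRASSLAND  # 5 pixels
        t = class_areas(lc(classes))   # 30 m pixels -> 0.09 ha each
        by = t.set_index("code")
        assert by.loc[BOG, "area_ha"] == pytest.approx(20 * 0.09)
        assert by.loc[FOREST, "area_ha"] == pytest.approx(75 * 0.09)
        assert t.percent.sum() == pytest.approx(100.0, abs=0.05)

    def test_single_class_map(self):
        t = class_areas(lc(np.full((5, 5), BOG, dtype=np.int16)))
        assert t.set_index("code").loc[BOG, "percent"] == pytest.approx(100.0)

    def test_printed_1984_shares(self):
        # printed class areas reproduce the printed forest share
        shares = shares_from_areas({"forest": 461.8, "bog": 327.9, "grassland": 91.8})
        assert round(shares["forest"], 2) == 52.39


class TestTransitions:
    def test_identity(self):
        m = lc([[1, 2], [3, 1]])
        tm = transition_matrix(m, m)
        np.testing.assert_allclose(tm.matrix, np.eye(3))

    def test_hand_counted_toy(self):
        first = lc([[BOG, BOG], [FOREST, GRASSLAND]])
        last = lc([[FOREST, BOG], [FOREST, FOREST]])
        tm = transition_matrix(first, last)
        assert tm.prob(BOG, FOREST) == pytest.approx(0.5)
        assert tm.prob(BOG, BOG) == pytest.approx(0.5)
        assert tm.prob(GRASSLAND, FOREST) == pytest.approx(1.0)
        assert tm.prob(FOREST, FOREST) == pytest.approx(1.0)

    def test_rows_sum_to_one(self, rng):
        a = lc(rng.integers(1, 4, size=(12, 12)))
        b = lc(rng.integers(1, 4, size=(12, 12)))
        tm = transition_matrix(a, b)
        np.testing.assert_allclose(tm.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_start_class_nan_row(self):
        first = lc([[FOREST, FOREST]])
        last = lc([[FOREST, BOG]])
        tm = transition_matrix(first, last)
        assert np.isnan(tm.matrix[1]).all()   # bog row undefined

    def test_pooled_annual_mode(self):
        maps = [lc([[BOG]]), lc([[FOREST]]), lc([[FOREST]])]
        tm = transition_matrix(annual_maps=maps, mode=TransitionMode.POOLED_ANNUAL)
        assert tm.prob(BOG, FOREST) == pytest.approx(1.0)
        assert tm.prob(FOREST, FOREST) == pytest.approx(1.0)
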