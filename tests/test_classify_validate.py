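"""Classifier stage: consensus labels, splitting, forest training, probabilities,
thresholding, metrics, overlap index and tuning."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from gdemapper import classify_validate as cv
from gdemapper import synthetic_scene as ss


def _flags(rows):
    return pd.DataFrame(rows, columns=["species", "region", "flag"])


class TestConsensusLabels:
    def test_two_phreatophyte_flags_win_despite_dissent(self):
        df = _flags([("salix", "AZ", "phreatophyte"), ("salix", "CA", "phreatophyte"),
                     ("salix", "NV", "not_phreatophyte"), ("salix", "OR", "not_phreatophyte")])
        out = cv.consensus_labels(df)
        assert out.loc[out.species == "salix", "label"].item() == "GDE"

    def test_three_negative_flags_label_nongde(self):
        df = _flags([("bromus", "AZ", "not_phreatophyte"),
                     ("bromus", "CA", "not_phreatophyte"),
                     ("bromus", "NV", "not_phreatophyte")])
        out = cv.consensus_labels(df)
        assert out.loc[out.species == "bromus", "label"].item() == "NONGDE"

    def test_insufficient_consensus_excluded(self):
        df = _flags([("larrea", "AZ", "phreatophyte"),
                     ("larrea", "CA", "not_phreatophyte"),
                     ("larrea", "NV", "not_phreatophyte")])
        assert cv.consensus_labels(df).empty

    def test_conflicting_duplicates_rejected(self):
        df = _flags([("acacia", "AZ", "phreatophyte"), ("acacia", "AZ", "not_phreatophyte")])
        with pytest.raises(cv.ValidationError, match="acacia"):
            cv.consensus_labels(df)


class TestSplit:
    def _points(self, n_gde=100, n_non=100):
        return pd.DataFrame({
            "lon": np.linspace(0, 1, n_gde + n_non),
            "lat": np.linspace(0, 1, n_gde + n_non),
            "label": ["GDE"] * n_gde + ["NONGDE"] * n_non,
            "source": "t", "region": "R",
        })

    def test_eighty_twenty_stratified(self):
        train, test = cv.split_train_test(self._points(), seed=1)
        assert (train["label"] == "GDE").sum() == 80
        assert (train["label"] == "NONGDE").sum() == 80
        assert (test["label"] == "GDE").sum() == 20
        assert (test["label"] == "NONGDE").sum() == 20

    def test_deterministic_and_disjoint_partition(self):
        pts = self._points(37, 53)
        t1 = cv.split_train_test(pts, seed=9)
        t2 = cv.split_train_test(pts, seed=9)
        assert t1[0].equals(t2[0]) and t1[1].equals(t2[1])
        key = lambda df: set(map(tuple, df[["lon", "lat"]].to_numpy()))
        assert key(t1[0]) & key(t1[1]) == set()
        assert key(t1[0]) | key(t1[1]) == key(pts)

    def test_tiny_class_rejected(self):
        pts = self._points(1, 50)
        with pytest.raises(cv.ValidationError):
            cv.split_train_test(pts)


class TestTrainPredict:
    def test_tree_count_matches_config(self, small_bundle, small_stack, small_points):
        train, _ = cv.split_train_test(small_points, seed=0)
        model = cv.train_rf(train, small_stack, cv.PAPER_RF_CONFIG)
        assert model.n_trees == 40
        assert sum(model.feature_importances.values()) == pytest.approx(1.0)

    def test_separable_clouds_low_oob(self, small_stack):
        # plant well-separated synthetic predictor vectors via direct fit
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (200, 11)), rng.normal(3, 0.3, (200, 11))])
        y = np.array(["GDE"] * 200 + ["NONGDE"] * 200)
        # nearest-centroid oracle achieves zero error on this geometry
        centroids = {lab: X[y == lab].mean(axis=0) for lab in ("GDE", "NONGDE")}
        nearest = np.array([
            min(centroids, key=lambda lab: np.linalg.norm(x - centroids[lab]))
            for x in X
        ])
        assert np.array_equal(nearest, y)
        from sklearn.ensemble import RandomForestClassifier
        import math
        cfg = cv.PAPER_RF_CONFIG
        forest = RandomForestClassifier(
            n_estimators=cfg.n_trees, max_features=cfg.vars_per_split,
            min_samples_leaf=cfg.min_leaf, max_leaf_nodes=math.ceil(cfg.max_nodes / 2),
            max_samples=cfg.bag_fraction, oob_score=True, random_state=0)
        forest.fit(X, y)
        assert 1.0 - forest.oob_score_ <= 0.05

    def test_vote_fraction_equals_per_tree_oracle(self, small_stack, small_points):
        train, test = cv.split_train_test(small_points, seed=2)
        model = cv.train_rf(train, small_stack,
                            cv.RFConfig(n_trees=7, vars_per_split=3, seed=5))
        X = small_stack.sample_at(test["lon"].to_numpy()[:5], test["lat"].to_numpy()[:5])
        assert not np.isnan(X).any()
        got = model.vote_fractions(X)
        gde_idx = list(model.forest.classes_).index("GDE")
        for i in range(5):
            votes = 0
            for tree in model.forest.estimators_:
                proba = tree.predict_proba(X[i:i + 1])[0]
                votes += int(np.argmax(proba) == gde_idx)
            assert got[i] == pytest.approx(votes / 7.0)

    def test_predict_masks_outside_extent(self, small_bundle, small_stack, small_points):
        train, _ = cv.split_train_test(small_points, seed=3)
        model = cv.train_rf(train, small_stack)
        extent = ss.scene_extent(small_bundle).extent
        prob = cv.predict_probability(model, small_stack, extent)
        outside = extent.values != 1.0
        assert np.all(prob.values[outside] == prob.nodata)
        inside_valid = prob.values[prob.values != prob.nodata]
        assert np.all((inside_valid >= 0) & (inside_valid <= 1))

    def test_one_class_training_rejected(self, small_stack, small_points):
        gde_only = small_points[small_points["label"] == "GDE"]
        with pytest.raises(cv.ValidationError):
            cv.train_rf(gde_only, small_stack)


class TestDynamicThreshold:
    def test_clean_separation_returns_smallest_perfect_threshold(self):
        val = pd.DataFrame({"label": ["GDE"] * 5 + ["NONGDE"] * 5,
                            "lon": 0.0, "lat": 0.0})
        scores = np.array([0.9] * 5 + [0.1] * 5)
        assert cv.dynamic_threshold(None, val, scores=scores) == pytest.approx(0.11)

    def test_single_class_rejected(self):
        val = pd.DataFrame({"label": ["GDE"] * 6, "lon": 0.0, "lat": 0.0})
        with pytest.raises(cv.ValidationError):
            cv.dynamic_threshold(None, val, scores=np.full(6, 0.5))

    def test_matches_bruteforce_accuracy_curve(self):
        # vote fractions quantised to 1/40, as a 40-tree ensemble produces
        rng = np.random.default_rng(11)
        scores = rng.integers(0, 41, size=80) / 40.0
        labels = np.where(rng.random(80) < 0.5, "GDE", "NONGDE")
        val = pd.DataFrame({"label": labels, "lon": 0.0, "lat": 0.0})
        t = cv.dynamic_threshold(None, val, scores=scores)
        acc_at = lambda thr: np.mean((scores >= thr) == (labels == "GDE"))
        best = max(acc_at(s) for s in np.unique(np.r_[scores, 0.0, 1.01]))
        assert acc_at(t) == pytest.approx(best)


class TestBinarize:
    def test_half_maps_to_gde(self):
        from .conftest import make_grid
        prob = make_grid([[0.5, 0.49], [1.0, -9999.0]])
        gmap = cv.binarize(prob)
        assert gmap.binary.values[0, 0] == 1.0   # boundary inclusive
        assert gmap.binary.values[0, 1] == 2.0
        assert gmap.binary.values[1, 1] == -9999.0
        assert gmap.threshold == 0.5

    def test_lowering_threshold_monotone(self):
        from .conftest import make_grid
        rng = np.random.default_rng(1)
        prob = make_grid(rng.random((6, 6)))
        hi = cv.binarize(prob, 0.7).binary.values == 1.0
        lo = cv.binarize(prob, 0.3).binary.values == 1.0
        assert np.all(hi <= lo)

    def test_threshold_out_of_range(self):
        from .conftest import make_grid
        with pytest.raises(cv.ValidationError):
            cv.binarize(make_grid(np.zeros((2, 2))), 1.5)


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        rep = cv.confusion_metrics(["GDE", "NONGDE"], ["GDE", "NONGDE"])
        assert (rep.accuracy, rep.precision, rep.recall) == (1.0, 1.0, 1.0)

    def test_hand_arithmetic_two_by_two(self):
        pred = ["GDE"] * 10 + ["NONGDE"] * 10
        truth = ["GDE"] * 8 + ["NONGDE"] * 2 + ["GDE"] * 1 + ["NONGDE"] * 9
        rep = cv.confusion_metrics(pred, truth)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (8, 2, 1, 9)
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.precision == pytest.approx(0.80)
        assert rep.recall == pytest.approx(8 / 9)

    def test_zero_denominator_reported_nan(self):
        rep = cv.confusion_metrics(["NONGDE", "NONGDE"], ["GDE", "NONGDE"])
        assert np.isnan(rep.precision)
        assert rep.recall == 0.0

    def test_length_mismatch(self):
        with pytest.raises(cv.ValidationError):
            cv.confusion_metrics(["GDE"], ["GDE", "NONGDE"])


class TestOverlapIndex:
    def test_sample_against_itself_is_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(500)
        assert cv.overlap_index(a, a) == 1.0

    def test_disjoint_supports_zero(self):
        rng = np.random.default_rng(1)
        assert cv.overlap_index(rng.uniform(0, 1, 100), rng.uniform(5, 6, 100)) == 0.0

    def test_two_sigma_normals_match_closed_form(self):
        rng = np.random.default_rng(2)
        est = cv.overlap_index(rng.normal(0, 1, 10000), rng.normal(2, 1, 10000))
        assert est == pytest.approx(2 * norm.cdf(-1), abs=0.02)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 300), rng.normal(1, 2, 400)
        assert cv.overlap_index(a, b) == pytest.approx(cv.overlap_index(b, a))

    def test_small_sample_rejected(self):
        with pytest.raises(cv.ValidationError):
            cv.overlap_index(np.zeros(5), np.zeros(100))

    def test_identical_constant_samples(self):
        assert cv.overlap_index(np.full(20, 3.0), np.full(30, 3.0)) == 1.0


class TestTuneHyperparameters:
    def test_singleton_grid(self, small_stack, small_points):
        only = cv.RFConfig(n_trees=15)
        assert cv.tune_hyperparameters(small_points, small_stack, [only], seed=1) == only

    def test_tie_breaks_to_fewer_trees(self, small_stack, small_points):
        # separable data: both configs hit accuracy 1, smaller forest wins
        grid = [cv.RFConfig(n_trees=40), cv.RFConfig(n_trees=10)]
        best = cv.tune_hyperparameters(small_points, small_stack, grid, seed=2)
        assert best.n_trees == 10

    def test_empty_grid_rejected(self, small_stack, small_points):
        with pytest.raises(cv.ValidationError):
            cv.tune_hyperparameters(small_points, small_stack, [], seed=0)


def test_groundwater_signatures_dominate_feature_importance():
    """ETaP and the LST spatial anomaly — the distinctive groundwater
    signals — rank in the top three predictors on default simulations."""
    from gdemapper import pipeline as pl
    hits = 0
    for s in range(5):
        res = pl.run_pipeline(ss.ScenarioConfig(seed=50 + s),
                              n_gde=500, n_nongde=500, n_barren=100,
                              threshold=0.5, seed=50 + s)
        ranked = sorted(res.model.feature_importances,
                        key=res.model.feature_importances.get, reverse=True)
        hits += {"etap", "lst_anom"} <= set(ranked[:3])
    assert hits >= 4


class TestRegionalCv:
    def test_report_covers_only_held_out_points(self, small_stack, small_points):
        region = small_points["region"].iloc[0]
        rep = cv.regional_cv(small_points, small_stack, region)
        n_held = (small_points["region"] == region).sum()
        assert rep.tp + rep.fp + rep.fn + rep.tn == n_held
        assert rep.context == f"holdout:{region}"

    def test_missing_region_rejected(self, small_stack, small_points):
        with pytest.raises(cv.ValidationError):
            cv.regional_cv(small_points, small_stack, "ATLANTIS")
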