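import numpy as np
import pytest

import dfncpm as d
from dfncpm import ValidationError
from dfncpm.classify import FeatureMatrix
from dfncpm.states import StateSequence


def _features(values, labels, names=None):
    values = np.asarray(values)
    names = tuple(names or [f"f{i}" for i in range(values.shape[1])])
    sids = tuple(f"s{i}" for i in range(values.shape[0]))
    return FeatureMatrix(values, names, sids, tuple(labels))


# small tuning grids keep unit tests quick; full grids are exercised in the
# end-to-end discrimination experiment
FAST = d.ClassificationProtocol(
    cv_repeats=5, cv_folds=5, seed=0,
    rf_grid={"n_estimators": [100], "min_samples_leaf": [1]},
)


class TestOneHotEncoding:
    def test_direct_containment_row(self):
        seqs = [StateSequence("s0", np.array([1, 2, 1]))]
        fm = d.one_hot_encode(seqs, [(1, 2), (2, 2)], compress=False)
        assert fm.values.tolist() == [[1, 0]]
        assert fm.feature_names == ("1-2", "2-2")

    def test_column_sums_meet_mining_support(self):
        rng = np.random.default_rng(0)
        seqs = [rng.integers(1, 4, size=15).tolist() for _ in range(12)]
        spec = d.MiningSpec(min_support=0.4, max_length=4, compress=False)
        ps = d.mine_patterns(seqs, spec)
        fm = d.one_hot_encode(
            [StateSequence(f"s{i}", np.array(s)) for i, s in enumerate(seqs)],
            ps, compress=False,
        )
        thresh = spec.absolute_support(len(seqs))
        assert fm.values.shape[1] == len(ps.patterns)
        assert (fm.values.sum(axis=0) >= thresh).all()

    def test_empty_pattern_set_yields_no_features_and_classifier_rejects(self):
        seqs = [StateSequence(f"s{i}", np.array([1, 2])) for i in range(8)]
        fm = d.one_hot_encode(seqs, [], groups={f"s{i}": "AB"[i % 2] for i in range(8)})
        assert fm.values.shape == (8, 0)
        with pytest.raises(ValidationError, match="no features"):
            d.evaluate_classifiers(fm, FAST)

    def test_alphabet_mismatch_rejected(self):
        seqs = [StateSequence("s0", np.array([1, 2, 1]))]
        with pytest.raises(ValidationError):
            d.one_hot_encode(seqs, [(1, 5)], n_states=3)

    def test_compression_convention_respected(self):
        seqs = [StateSequence("s0", np.array([1, 1, 2]))]
        raw = d.one_hot_encode(seqs, [(1, 1)], compress=False)
        comp = d.one_hot_encode(seqs, [(1, 1)], compress=True)
        assert raw.values.tolist() == [[1]]
        assert comp.values.tolist() == [[0]]


class TestEvaluateClassifiers:
    def test_perfectly_separating_feature_scores_one(self):
        # tiny within-class jitter keeps LDA's pooled covariance nonsingular
        # (with literally zero within-class variance its coefficients vanish)
        rng = np.random.default_rng(1)
        y = ["a"] * 10 + ["b"] * 10
        X = (np.array([[0.0]] * 10 + [[1.0]] * 10)
             + rng.normal(scale=0.01, size=(20, 1)))
        rep = d.evaluate_classifiers(_features(X, y), FAST)
        for model in ("rf", "lda"):
            assert rep.cv_metrics[model]["accuracy"][0] == pytest.approx(1.0)
            assert rep.cv_metrics[model]["auc"][0] == pytest.approx(1.0)

    def test_permuted_labels_score_near_chance(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, size=(24, 6))
        y = np.array(["a", "b"] * 12)
        rng.shuffle(y)
        rep = d.evaluate_classifiers(
            _features(X, y),
            d.ClassificationProtocol(cv_repeats=20, cv_folds=4, seed=2,
                                     rf_grid=FAST.rf_grid),
        )
        for model in ("rf", "lda"):
            mean, sd = rep.cv_metrics[model]["accuracy"]
            assert abs(mean - 0.5) <= max(3 * sd, 0.2)

    def test_protocol_defaults_match_study_constants(self):
        p = d.ClassificationProtocol()
        assert p.train_fraction == 0.8
        assert p.cv_repeats == 100
        assert p.cv_folds == 10

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValidationError):
            d.evaluate_classifiers(_features(X, ["a"] * 10), FAST)

    def test_column_order_invariance_of_metrics(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(20, 5)).astype(float)
        y = ["a"] * 10 + ["b"] * 10
        X[:, 0] = [0] * 10 + [1] * 10
        r1 = d.evaluate_classifiers(_features(X, y), FAST)
        r2 = d.evaluate_classifiers(_features(X[:, ::-1], y), FAST)
        for model in ("rf", "lda"):
            assert r1.cv_metrics[model]["accuracy"] == pytest.approx(
                r2.cv_metrics[model]["accuracy"]
            )

    def test_bit_for_bit_reproducible_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, size=(20, 4))
        y = ["a"] * 10 + ["b"] * 10
        r1 = d.evaluate_classifiers(_features(X, y), FAST)
        r2 = d.evaluate_classifiers(_features(X, y), FAST)
        assert r1.to_jsonable() == r2.to_jsonable()

    def test_small_class_reduces_folds_with_warning(self):
        X = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0], [1.0], [1.0]])
        y = ["a"] * 3 + ["b"] * 5
        with pytest.warns(UserWarning, match="reducing CV folds"):
            d.evaluate_classifiers(
                _features(X, y), d.ClassificationProtocol(cv_repeats=2, seed=0)
            )


class TestFeatureImportance:
    def test_planted_feature_ranks_first_for_both_models(self):
        rng = np.random.default_rng(5)
        n = 40
        y = np.array(["a"] * 20 + ["b"] * 20)
        X = rng.integers(0, 2, size=(n, 8)).astype(float)
        X[:, 3] = (y == "b").astype(float)  # the informative feature
        rep = d.evaluate_classifiers(_features(X, y), FAST)
        for model in ("rf", "lda"):
            assert rep.importances[model][0][0] == "f3"

    def test_identical_features_get_uniform_importance(self):
        rng = np.random.default_rng(6)
        col = rng.integers(0, 2, 30).astype(float)
        X = np.column_stack([col] * 4)
        y = np.where(col > 0, "b", "a")
        rep = d.evaluate_classifiers(_features(X, y), FAST)
        lda_scores = [s for _, s in rep.importances["lda"]]
        assert np.allclose(lda_scores, 0.25, atol=1e-6)
        rf_scores = [s for _, s in rep.importances["rf"]]
        assert np.allclose(rf_scores, 0.25, atol=0.15)

    def test_unfitted_model_rejected(self):
        from sklearn.ensemble import RandomForestClassifier

        with pytest.raises(ValidationError):
            d.rank_feature_importance({"rf": RandomForestClassifier()}, ["f0"])

    def test_ranking_is_capped_at_ten(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 2, size=(24, 15)).astype(float)
        y = ["a"] * 12 + ["b"] * 12
        X[:, 0] = [0] * 12 + [1] * 12
        rep = d.evaluate_classifiers(_features(X, y), FAST)
        assert len(rep.importances["rf"]) == 10
        assert len(rep.importances["lda"]) == 10
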