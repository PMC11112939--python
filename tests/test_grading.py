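import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nics.feature_extraction import extract_features
from nics.grading import (
    GradeResult,
    assign_grade,
    cohort_grade_summary,
    grade_embryos,
    load_model,
    predict_euploid_probability,
    rank_embryos,
    save_model,
    train_classifier,
)
from nics.synthetic_data import KaryotypeParams, simulate_karyotype, truth_to_callset


def _training_set(genome, n, seed, params=None, noise=0.05):
    params = params or KaryotypeParams()
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for i in range(n):
        truth = simulate_karyotype(rng, params, genome, f"e{i}")
        cs = truth_to_callset(truth, genome, fraction_noise_sd=noise, rng=rng)
        feats.append(extract_features(cs))
        labels.append(truth.label_euploid)
    return feats, labels


class TestAssignGrade:
    @pytest.mark.parametrize(
        "p,grade",
        [(0.95, "A"), (0.94, "A"), (0.9399, "B"), (0.80, "B"),
         (0.7001, "B"), (0.70, "C"), (0.30, "C"), (0.0, "C"), (1.0, "A")],
    )
    def test_thresholds(self, p, grade):
        assert assign_grade(p) == grade

    def test_out_of_range_rejected(self):
        for p in (-0.1, 1.1):
            with pytest.raises(ValueError):
                assign_grade(p)

    @given(p=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=200, deadline=None)
    def test_partition_property(self, p):
        g = assign_grade(p)
        assert g in ("A", "B", "C")
        if p >= 0.94:
            assert g == "A"
        elif p <= 0.70:
            assert g == "C"
        else:
            assert g == "B"


class TestTrainClassifier:
    def test_separable_data_high_accuracy(self, toy_genome):
        # euploid vs full multi-chromosome aneuploid: trivially separable
        params = KaryotypeParams(p_euploid=0.5, p_full=1.0, p_sex_chrom_event=0.0)
        feats, labels = _training_set(toy_genome, 400, seed=0, params=params, noise=0.0)
        test_f, test_y = _training_set(toy_genome, 200, seed=1, params=params, noise=0.0)
        model = train_classifier(feats, labels, n_trees=200, seed=0)
        pred = predict_euploid_probability(model, test_f) >= 0.5
        assert (pred == np.asarray(test_y)).mean() >= 0.99

    def test_shuffled_labels_near_prior(self, toy_genome):
        feats, labels = _training_set(toy_genome, 600, seed=2)
        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(labels))
        test_f, test_y = _training_set(toy_genome, 400, seed=3)
        # regularized, unweighted forest: fully-grown trees memorize tiny
        # leaves whose chance votes beat the prior on clustered features,
        # so the permutation null needs a minimum leaf size
        model = train_classifier(
            feats, shuffled, n_trees=200, seed=0, class_weight=None, min_samples_leaf=150
        )
        p = predict_euploid_probability(model, test_f)
        acc = ((p >= 0.5) == np.asarray(test_y)).mean()
        prior = max(np.mean(test_y), 1 - np.mean(test_y))
        # shuffled labels destroy signal: accuracy near the majority prior
        assert abs(acc - prior) < 0.07

    def test_single_class_rejected(self, toy_genome):
        feats, _ = _training_set(toy_genome, 20, seed=4)
        with pytest.raises(ValueError, match="single class"):
            train_classifier(feats, [True] * 20)

    def test_same_seed_identical_predictions(self, toy_genome):
        feats, labels = _training_set(toy_genome, 300, seed=5)
        test_f, _ = _training_set(toy_genome, 100, seed=6)
        p1 = predict_euploid_probability(train_classifier(feats, labels, seed=9, n_trees=100), test_f)
        p2 = predict_euploid_probability(train_classifier(feats, labels, seed=9, n_trees=100), test_f)
        np.testing.assert_array_equal(p1, p2)

    def test_probabilities_in_unit_interval(self, toy_genome):
        feats, labels = _training_set(toy_genome, 300, seed=7)
        model = train_classifier(feats, labels, n_trees=100, seed=0)
        p = predict_euploid_probability(model, feats)
        assert (p >= 0) .all() and (p <= 1).all()

    def test_model_roundtrip(self, toy_genome, tmp_path):
        feats, labels = _training_set(toy_genome, 200, seed=8)
        model = train_classifier(feats, labels, n_trees=50, seed=0)
        save_model(model, tmp_path / "m.joblib")
        loaded = load_model(tmp_path / "m.joblib")
        np.testing.assert_array_equal(
            predict_euploid_probability(model, feats),
            predict_euploid_probability(loaded, feats),
        )
        assert loaded.metadata["n_trees"] == 50


def _gr(embryo_id, p, morph=None):
    return GradeResult(embryo_id, p, assign_grade(p), morph)


class TestRankEmbryos:
    def test_a_before_b_c_excluded(self):
        ranked = rank_embryos([_gr("b", 0.85), _gr("a", 0.96), _gr("c", 0.30)])
        assert [r.embryo_id for r in ranked] == ["a", "b"]

    def test_empty(self):
        assert rank_embryos([]) == []

    def test_descending_probability_within_grade(self):
        ranked = rank_embryos([_gr("x", 0.95), _gr("y", 0.96)])
        assert [r.embryo_id for r in ranked] == ["y", "x"]

    def test_morphology_tiebreak(self):
        ranked = rank_embryos([_gr("low", 0.95, "4CB"), _gr("high", 0.95, "4AB")])
        assert [r.embryo_id for r in ranked] == ["high", "low"]

    def test_stable_under_full_tie(self):
        ranked = rank_embryos([_gr("first", 0.95, "4AA"), _gr("second", 0.95, "4AA")])
        assert [r.embryo_id for r in ranked] == ["first", "second"]


class TestCohortGradeSummary:
    def test_printed_cohort_counts(self):
        s = cohort_grade_summary({"A": 222, "B": 112, "C": 172})
        assert s["total"] == 506
        assert s["transferable"] == 334
        assert s["utilization_pct"] == 66.0

    def test_all_c(self):
        s = cohort_grade_summary({"A": 0, "B": 0, "C": 10})
        assert s["utilization_pct"] == 0.0

    def test_observational_cohort_share(self):
        s = cohort_grade_summary({"A": 161, "B": 58, "C": 59})
        assert s["total"] == 278
        assert s["utilization_pct"] == 78.8

    def test_from_results_list(self):
        results = [_gr("a", 0.96), _gr("b", 0.8), _gr("c", 0.5), _gr("d", 0.99)]
        s = cohort_grade_summary(results)
        assert s["counts"] == {"A": 2, "B": 1, "C": 1}
        assert s["utilization_pct"] == 75.0
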