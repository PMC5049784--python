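import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from refrma import (
    INTERMEDIATE,
    UNCLASSIFIED,
    ClassifierModel,
    ExpressionMatrix,
    ExpressionProfile,
    ProbeDataError,
    ReferenceArchive,
    TrainingConfig,
    call_dichotomous,
    call_multiclass,
    call_tertile,
    graham_combine,
    predict_probabilities,
    rescale_profile,
    train_elastic_net,
)


def _toy_expr(n_probesets=20, n_samples=40, effect=2.0, seed=0):
    """Two-class toy data: the first probe-set separates the classes."""
    rng = np.random.default_rng(seed)
    V = rng.normal(7, 1, size=(n_probesets, n_samples))
    labels = np.array(["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2))
    V[0, labels == "B"] += effect
    ids = [f"ps{k}" for k in range(n_probesets)]
    samples = [f"s{j}" for j in range(n_samples)]
    return ExpressionMatrix(ids, samples, V), labels


class TestTraining:
    def test_null_model_limit_at_max_shrinkage(self):
        """At the grid's lambda = e^2 all coefficients vanish and the
        intercept is the logit of the class prevalence."""
        expr, labels = _toy_expr(seed=1)
        labels = np.array(["A"] * 25 + ["B"] * 15)
        config = TrainingConfig(alpha_grid=[0.5], log_lambda_grid=[2.0],
                                n_folds=5, seed=0)
        model = train_elastic_net(expr, labels, config)
        assert len(model.coefficients) == 0
        prevalence = 15 / 40  # of the positive (second) class
        assert model.intercepts[0] == pytest.approx(logit(prevalence), abs=1e-2)

    def test_duplicated_feature_shares_weight_under_ridge_like_penalty(self):
        """The elastic net's grouping effect: at alpha = 0.1 two identical
        informative probe-sets receive near-equal coefficients."""
        expr, labels = _toy_expr(n_probesets=10, n_samples=60, effect=2.5, seed=2)
        V = np.vstack([expr.values, expr.values[0:1, :]])  # duplicate ps0
        dup = ExpressionMatrix(expr.probeset_ids + ["ps0_copy"],
                               expr.sample_ids, V)
        config = TrainingConfig(alpha_grid=[0.1], log_lambda_grid=[-2.0],
                                n_folds=5, seed=0)
        model = train_elastic_net(dup, labels, config)
        c0 = model.coefficients["ps0"][0]
        c1 = model.coefficients["ps0_copy"][0]
        assert c0 != 0
        assert abs(c0 - c1) <= 0.10 * abs(c0)

    def test_training_is_reproducible(self):
        expr, labels = _toy_expr(seed=3)
        config = TrainingConfig(alpha_grid=[0.2, 1.0], log_lambda_grid=[-3.0, -1.0],
                                n_folds=5, seed=42)
        m1 = train_elastic_net(expr, labels, config)
        m2 = train_elastic_net(expr, labels, config)
        assert (m1.alpha, m1.log_lambda) == (m2.alpha, m2.log_lambda)
        assert set(m1.coefficients) == set(m2.coefficients)
        for ps in m1.coefficients:
            assert m1.coefficients[ps] == pytest.approx(m2.coefficients[ps], abs=1e-8)

    def test_single_class_rejected(self):
        expr, _ = _toy_expr()
        with pytest.raises(ProbeDataError, match="single class"):
            train_elastic_net(expr, ["A"] * 40,
                              TrainingConfig(alpha_grid=[0.5],
                                             log_lambda_grid=[0.0], n_folds=5))

    def test_more_folds_than_minority_class_rejected(self):
        expr, _ = _toy_expr()
        labels = ["A"] * 37 + ["B"] * 3
        with pytest.raises(ProbeDataError, match="minority"):
            train_elastic_net(expr, labels,
                              TrainingConfig(alpha_grid=[0.5],
                                             log_lambda_grid=[0.0], n_folds=5))


def _model(coefs, intercept=0.0, kind="dichotomous", labels=("GCB", "ABC")):
    sds = pd.Series({ps: 1.0 for ps in coefs} or {"psx": 1.0})
    return ClassifierModel(
        model_kind=kind, class_labels=list(labels),
        intercepts=np.atleast_1d(intercept),
        coefficients={ps: np.atleast_1d(v) for ps, v in coefs.items()},
        training_sds=sds, alpha=0.5, log_lambda=0.0, cv_deviance=1.0,
        thresholds={"lower": 0.1, "upper": 0.9}, name="toy",
    )


def _profile(values: dict, **kw):
    kw.setdefault("centered", True)
    kw.setdefault("rescaled_for", "toy")
    return ExpressionProfile(list(values), np.asarray(list(values.values()), float), **kw)


def _archive_for(sds: dict, medians=None):
    ids = list(sds)
    n = len(ids) * 3
    return ReferenceArchive(
        chip_id="toy", n_reference=5,
        quantile_vector=np.sort(np.linspace(1, 100, n)),
        probe_effects=pd.Series(0.0, index=[f"p{i}" for i in range(n)]),
        probeset_medians=pd.Series(medians or {ps: 0.0 for ps in ids}),
        probeset_sds=pd.Series(sds),
    )


class TestRescaling:
    def test_equal_sds_leave_profile_unchanged(self):
        model = _model({"ps1": 1.0})
        model.training_sds = pd.Series({"ps1": 1.3})
        prof = _profile({"ps1": 2.0}, rescaled_for=None)
        out = rescale_profile(prof, model, _archive_for({"ps1": 1.3}))
        assert out.values[0] == pytest.approx(2.0)
        assert out.rescaled_for == "toy"

    def test_sd_ratio_arithmetic(self):
        model = _model({"ps1": 1.0})
        model.training_sds = pd.Series({"ps1": 1.5})
        prof = _profile({"ps1": 2.0}, rescaled_for=None)
        out = rescale_profile(prof, model, _archive_for({"ps1": 0.5}))
        assert out.values[0] == pytest.approx(6.0)

    def test_training_reference_bypasses_rescaling(self):
        model = _model({"ps1": 1.0})
        model.training_sds = pd.Series({"ps1": 9.0})
        prof = _profile({"ps1": 2.0}, rescaled_for=None)
        out = rescale_profile(prof, model, _archive_for({"ps1": 0.1}),
                              reference_is_training=True)
        assert out.values[0] == pytest.approx(2.0)

    def test_zero_reference_sd_lists_probesets(self):
        model = _model({"ps1": 1.0})
        prof = _profile({"ps1": 2.0}, rescaled_for=None)
        with pytest.raises(ProbeDataError, match="ps1"):
            rescale_profile(prof, model, _archive_for({"ps1": 0.0}))

    def test_uncentered_profile_rejected(self):
        model = _model({"ps1": 1.0})
        prof = _profile({"ps1": 2.0}, centered=False, rescaled_for=None)
        with pytest.raises(ProbeDataError, match="centered"):
            rescale_profile(prof, model, _archive_for({"ps1": 1.0}))


class TestPrediction:
    def test_null_model_gives_half(self):
        model = _model({}, intercept=0.0)
        p = predict_probabilities(model, _profile({"psx": 0.0}))
        assert p["ABC"] == pytest.approx(0.5)

    def test_hand_logistic_arithmetic(self):
        model = _model({"ps1": 1.0}, intercept=0.0)
        p = predict_probabilities(model, _profile({"ps1": float(np.log(3.0))}))
        assert p["ABC"] == pytest.approx(0.75)  # logistic(ln 3) = 3/4
        assert p["GCB"] == pytest.approx(0.25)

    def test_multinomial_probabilities_sum_to_one(self):
        rng = np.random.default_rng(4)
        labels = ["CB", "CC", "M", "N", "PB"]
        model = ClassifierModel(
            model_kind="multiclass", class_labels=labels,
            intercepts=rng.normal(size=5),
            coefficients={f"ps{k}": rng.normal(size=5) for k in range(6)},
            training_sds=pd.Series({f"ps{k}": 1.0 for k in range(6)}),
            alpha=0.5, log_lambda=0.0, cv_deviance=1.0,
            thresholds={"threshold": 0.5}, name="bags",
        )
        prof = _profile({f"ps{k}": rng.normal() for k in range(6)},
                        rescaled_for="bags")
        p = predict_probabilities(model, prof)
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)

    def test_unrescaled_profile_rejected(self):
        model = _model({"ps1": 1.0})
        with pytest.raises(ProbeDataError, match="rescaled"):
            predict_probabilities(model, _profile({"ps1": 0.0}, rescaled_for=None))


class TestCalling:
    @pytest.mark.parametrize("p,expected", [
        (0.95, "ABC"), (0.05, "GCB"),
        (0.9, UNCLASSIFIED), (0.1, UNCLASSIFIED), (0.5, UNCLASSIFIED),
    ])
    def test_dichotomous_thresholds(self, p, expected):
        assert call_dichotomous(p) == expected

    def test_dichotomous_rejects_invalid_probability(self):
        with pytest.raises(ProbeDataError):
            call_dichotomous(1.2)

    @pytest.mark.parametrize("probs,expected", [
        ({"N": 0.6, "CB": 0.1, "CC": 0.1, "M": 0.1, "PB": 0.1}, "N"),
        ({"N": 0.4, "CB": 0.3, "CC": 0.1, "M": 0.1, "PB": 0.1}, UNCLASSIFIED),
        ({"N": 0.2, "CB": 0.2, "CC": 0.2, "M": 0.2, "PB": 0.2}, UNCLASSIFIED),
    ])
    def test_multiclass_threshold(self, probs, expected):
        assert call_multiclass(probs) == expected

    def test_multiclass_rejects_unnormalized(self):
        with pytest.raises(ProbeDataError, match="sum"):
            call_multiclass({"A": 0.5, "B": 0.4})

    def test_tertile_split_on_uniform_grid(self):
        probs = np.arange(1, 101) / 100.0
        calls = call_tertile(probs)
        assert calls.count("sensitive") == 33
        assert calls.count(INTERMEDIATE) == 33
        assert calls.count("resistant") == 34

    def test_tertile_all_equal_is_all_intermediate(self):
        assert set(call_tertile(np.full(10, 0.4))) == {INTERMEDIATE}

    def test_tertile_is_rank_based(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.01, 0.99, 50)
        assert call_tertile(p) == call_tertile(p ** 3)  # monotone transform

    def test_tertile_needs_three_samples(self):
        with pytest.raises(ProbeDataError, match=">= 3"):
            call_tertile(np.array([0.2, 0.8]))


class TestGrahamFormula:
    def test_half_is_a_fixed_point(self):
        assert graham_combine(0.5, 0.5, 0.5) == pytest.approx(0.5)

    def test_certainty_propagates(self):
        assert graham_combine(1.0, 0.7, 0.6) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        assert graham_combine(0.8, 0.7, 0.6) == pytest.approx(0.336 / (0.336 + 0.024))

    def test_dropping_a_drug_uses_remaining_terms(self):
        assert graham_combine(0.8, 0.7) == pytest.approx(0.56 / (0.56 + 0.06))

    def test_contradictory_certainty_rejected(self):
        with pytest.raises(ProbeDataError, match="contradictory"):
            graham_combine(1.0, 0.0, 0.5)

    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(st.tuples(*[st.floats(0.01, 0.99) for _ in range(3)]))
    def test_symmetry_complement_and_monotonicity(self, triple):
        pc, ph, po = triple
        g = graham_combine(pc, ph, po)
        assert graham_combine(po, pc, ph) == pytest.approx(g, abs=1e-12)
        assert 1.0 - g == pytest.approx(
            graham_combine(1 - pc, 1 - ph, 1 - po), abs=1e-12)
        bumped = min(pc + 0.005, 0.995)
        if bumped > pc:
            assert graham_combine(bumped, ph, po) > g
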