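"""ALASSO selection, stay-criterion fitting, discrimination and the point
score."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ucipred import (
    ModelBuildConfig,
    PAPER_POINTS,
    PointScoreModel,
    PrognosticIndex,
    alasso_select,
    c_statistic,
    choose_threshold,
    classification_metrics,
    derive_point_score,
    fit_multivariable,
    os_point_score,
    prognostic_index,
    roc_auc,
    score_patient,
)
from ucipred.models import FittedModel, _round_half


def simulate_logistic(rng, n, beta, p_covariate=None):
    k = len(beta)
    if p_covariate is None:
        X = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])
    else:
        X = pd.DataFrame(
            (rng.random((n, k)) < p_covariate).astype(float),
            columns=[f"x{i}" for i in range(k)],
        )
    y = (rng.random(n) < expit(X.to_numpy() @ np.asarray(beta))).astype(int)
    return X, y


class TestAlasso:
    def test_selects_strong_drops_noise(self):
        rng = np.random.default_rng(0)
        X, y = simulate_logistic(rng, 1000, [1.2, -1.0, 1.5] + [0.0] * 7)
        selected = alasso_select(X, y, ModelBuildConfig(seed=0))
        assert {"x0", "x1", "x2"} <= set(selected)
        assert len(set(selected) - {"x0", "x1", "x2"}) <= 1

    def test_huge_lambda_empties_selection(self):
        rng = np.random.default_rng(1)
        X, y = simulate_logistic(rng, 200, [1.0, 0.0])
        config = ModelBuildConfig(lambda_grid=(1e6,), tuning="bic")
        assert alasso_select(X, y, config) == []

    def test_constant_outcome_rejected(self):
        X = pd.DataFrame({"x0": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError):
            alasso_select(X, [1, 1, 1], ModelBuildConfig())

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        X, y = simulate_logistic(rng, 300, [1.5])
        X["flat"] = 1.0
        with pytest.warns(RuntimeWarning, match="flat"):
            selected = alasso_select(X, y, ModelBuildConfig(seed=2))
        assert "flat" not in selected

    def test_cox_family_selects_strong_covariate(self):
        rng = np.random.default_rng(3)
        n = 400
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        lp = 1.2 * X["a"].to_numpy()
        times = rng.exponential(1.0 / (0.1 * np.exp(lp)))
        events = np.ones(n, int)
        config = ModelBuildConfig(family="cox", lambda_grid=tuple(np.logspace(-3, 0, 10)), seed=3)
        selected = alasso_select(X, config=config, times=times, events=events)
        assert "a" in selected


class TestFitMultivariable:
    def test_null_covariate_eliminated(self):
        rng = np.random.default_rng(4)
        X, y = simulate_logistic(rng, 1000, [1.3, -1.2, 0.0])
        model = fit_multivariable(X, y, family="logistic", stay_alpha=0.10)
        assert set(model.variables) == {"x0", "x1"}

    def test_all_significant_model_unchanged(self):
        rng = np.random.default_rng(5)
        X, y = simulate_logistic(rng, 1000, [1.3, -1.2])
        model = fit_multivariable(X, y, family="logistic", stay_alpha=0.10)
        assert set(model.variables) == {"x0", "x1"}
        assert all(p <= 0.10 for p in model.p_values)

    def test_effects_reported_as_exponentials(self):
        rng = np.random.default_rng(6)
        X, y = simulate_logistic(rng, 800, [1.0])
        model = fit_multivariable(X, y, family="logistic")
        est, lo, hi = model.effect_estimates["x0"]
        assert est == pytest.approx(math.exp(model.coefficients[0]), rel=1e-12)
        assert lo < est < hi

    def test_separation_triggers_firth_fallback(self):
        X = pd.DataFrame({"x0": np.r_[np.zeros(15), np.ones(15)]})
        y = np.r_[np.zeros(15), np.ones(15)].astype(int)
        model = fit_multivariable(X, y, family="logistic")
        assert "firth_fallback" in model.flags
        assert np.isfinite(model.coefficients[0])

    def test_cox_family_backward_elimination(self):
        rng = np.random.default_rng(7)
        n = 600
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        lp = 0.9 * X["a"].to_numpy() - 0.8 * X["b"].to_numpy()
        times = rng.exponential(1.0 / (0.1 * np.exp(lp)))
        model = fit_multivariable(
            X, times=times, events=np.ones(n, int), family="cox", stay_alpha=0.10
        )
        assert set(model.variables) == {"a", "b"}


class TestCStatistic:
    def test_boundary_conventions(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5
        # hand enumeration: pairs (s-: 0.2, 0.3), (s+: 0.1, 0.4) -> 2/4 concordant
        assert roc_auc([0.2, 0.1, 0.3, 0.4], [0, 1, 0, 1]) == 0.5

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            n = int(rng.integers(2, 13))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            scores = rng.choice([0.1, 0.2, 0.3, 0.4], size=n)  # ties likely
            num = denom = 0.0
            for i, j in itertools.product(range(n), range(n)):
                if y[i] == 1 and y[j] == 0:
                    denom += 1
                    num += 1.0 if scores[i] > scores[j] else (0.5 if scores[i] == scores[j] else 0.0)
            assert roc_auc(scores, y) == pytest.approx(num / denom)

    def test_bootstrap_ci_brackets_point(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=200) + np.r_[np.zeros(100), np.ones(100)]
        y = np.r_[np.zeros(100), np.ones(100)].astype(int)
        point, (lo, hi) = c_statistic(scores, y, n_boot=200, seed=1)
        assert lo <= point <= hi
        # same seed reproduces the interval
        assert c_statistic(scores, y, n_boot=200, seed=1)[1] == (lo, hi)

    def test_survival_concordance(self):
        times = [5.0, 4.0, 3.0, 2.0, 1.0]
        events = [1, 1, 1, 1, 1]
        scores = [1.0, 2.0, 3.0, 4.0, 5.0]  # higher score = shorter survival
        point, _ = c_statistic(scores, times=times, events=events, n_boot=50, seed=0)
        assert point == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


def paper_score_model() -> PointScoreModel:
    return PointScoreModel(
        intercept_points=PAPER_POINTS["intercept"],
        variable_points={k: v for k, v in PAPER_POINTS.items() if k != "intercept"},
        threshold=-1.0,
        rounding="explicit",
    )


class TestPointScore:
    def test_half_point_rounding(self):
        assert _round_half(3.21) == 3.0
        assert _round_half(-2.93) == -3.0
        assert _round_half(-2.11) == -2.0
        assert _round_half(0.0) == 0.0
        assert _round_half(1.25) == 1.5  # tie rounds away from zero
        assert _round_half(-1.25) == -1.5

    def test_published_points_enumeration(self):
        psm = paper_score_model()
        assert psm.enumerate_scores() == [-3.5, -1.5, -1.0, -0.5, 1.0, 1.5, 2.0, 4.0]
        assert psm.score_range == (-3.5, 4.0)

    def test_named_strata(self):
        psm = paper_score_model()
        worst = score_patient(psm, {"visceral_mets": True, "nlr_ge5": True, "snv_ge10": False})
        assert worst == (-3.5, "NCB")
        best = score_patient(psm, {"visceral_mets": False, "nlr_ge5": False, "snv_ge10": True})
        assert best == (4.0, "CB")
        baseline = score_patient(psm, {"visceral_mets": False, "nlr_ge5": False, "snv_ge10": False})
        assert baseline == (1.0, "CB")

    def test_ncb_iff_visceral_and_low_snv(self):
        """Under the published points and threshold -1, predicted NCB is
        exactly the visceral-metastasis-with-low-SNV stratum (scores -3.5
        and -1.5)."""
        psm = paper_score_model()
        for v, nl, s in itertools.product([False, True], repeat=3):
            score, pred = score_patient(
                psm, {"visceral_mets": v, "nlr_ge5": nl, "snv_ge10": s}
            )
            assert (pred == "NCB") == (v and not s)
            assert (pred == "NCB") == (score in (-3.5, -1.5))

    def test_monotone_in_favourable_flags(self):
        psm = paper_score_model()
        for v, nl, s in itertools.product([False, True], repeat=3):
            base, _ = score_patient(psm, {"visceral_mets": v, "nlr_ge5": nl, "snv_ge10": s})
            for flipped in (
                {"visceral_mets": False, "nlr_ge5": nl, "snv_ge10": s},
                {"visceral_mets": v, "nlr_ge5": False, "snv_ge10": s},
                {"visceral_mets": v, "nlr_ge5": nl, "snv_ge10": True},
            ):
                assert score_patient(psm, flipped)[0] >= base

    def test_missing_flag_directs_to_exclusion(self):
        with pytest.raises(ValueError, match="exclude"):
            score_patient(paper_score_model(), {"visceral_mets": None, "nlr_ge5": True, "snv_ge10": True})

    def test_derive_nearest_half_and_explicit(self):
        model = FittedModel(
            family="logistic",
            variables=("visceral_mets", "nlr_ge5", "snv_ge10"),
            coefficients=(-2.93, -2.11, 3.21),
            standard_errors=(1.06, 1.14, 0.97),
            p_values=(0.006, 0.066, 0.001),
            effect_estimates={},
            intercept=1.15,
            intercept_se=0.97,
        )
        rounded = derive_point_score(model, threshold=-1.0)
        assert rounded.intercept_points == 1.0
        assert rounded.variable_points == {
            "visceral_mets": -3.0, "nlr_ge5": -2.0, "snv_ge10": 3.0
        }
        pinned = derive_point_score(
            model, rounding="explicit", threshold=-1.0, explicit_points=PAPER_POINTS
        )
        assert pinned.score_range == (-3.5, 4.0)

    def test_threshold_must_be_achievable(self):
        with pytest.raises(ValueError):
            PointScoreModel(1.0, {"a": 1.0}, threshold=10.0)

    def test_choose_threshold_maximizes_youden(self):
        scores = np.array([-3.5, -1.5, 1.0, 4.0, 4.0, -3.5])
        outcomes = np.array([0, 0, 1, 1, 1, 0])
        assert choose_threshold(scores, outcomes) == 1.0


class TestClassificationMetrics:
    def test_published_sensitivity_rounding(self):
        predictions = ["CB"] * 22 + ["NCB"] * 2
        outcomes = ["CB"] * 24
        m = classification_metrics(predictions, outcomes)
        assert m["sensitivity"] == pytest.approx(22 / 24)
        assert m["sensitivity_pct"] == 92

    def test_perfect_and_inverted(self):
        m = classification_metrics(["CB", "NCB"], ["CB", "NCB"])
        assert (m["sensitivity_pct"], m["specificity_pct"]) == (100, 100)
        m = classification_metrics(["NCB", "CB"], ["CB", "NCB"])
        assert (m["sensitivity_pct"], m["specificity_pct"]) == (0, 0)

    def test_no_positives_flagged(self):
        m = classification_metrics(["NCB"], ["NCB"])
        assert m["sensitivity"] is None and "no_positives" in m["flags"]


class TestPrognosticIndex:
    @pytest.mark.parametrize(
        "index,expected", [(-0.5, "low"), (-0.29, "intermediate"), (1.0, "intermediate"), (1.54, "high")]
    )
    def test_left_closed_grouping(self, index, expected):
        pi = PrognosticIndex(coefficients={"x": 1.0})
        assert prognostic_index(pi, {"x": index}) == (index, expected)

    def test_missing_feature_rejected(self):
        pi = PrognosticIndex(coefficients={"x": 1.0, "y": 2.0})
        with pytest.raises(ValueError, match="y"):
            prognostic_index(pi, {"x": 1.0})

    def test_cutoffs_must_increase(self):
        with pytest.raises(ValueError):
            PrognosticIndex(coefficients={"x": 1.0}, cutoffs=(1.0, 0.5))


class TestOsPointScore:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ((True, True, True), (4, "4")),
            ((False, False, False), (0, "0-2")),
            ((True, False, False), (2, "0-2")),
            ((True, True, False), (3, "3")),
        ],
    )
    def test_weighting_and_grouping(self, flags, expected):
        assert os_point_score(*flags) == expected

    def test_missing_flag_rejected(self):
        with pytest.raises(ValueError, match="ecog"):
            os_point_score(True, True, None)
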