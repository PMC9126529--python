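"""Survival statistics against brute-force oracles, plus recovery simulations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cytoprs.survival import (
    PRSModel,
    SurvivalData,
    breslow_loglik,
    dichotomize,
    fit_cox,
    harrell_c,
    km_curve,
    km_logrank,
    lasso_cox_select,
    prs_score,
)

# ---------------------------------------------------------------- oracles


def harrell_bruteforce(scores, times, events):
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def logrank_bruteforce(times, events, groups):
    """Explicit 2x2 risk-table computation per distinct event time."""
    labels = np.unique(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o_minus_e**2 / var) if var > 0 else 0.0


# ---------------------------------------------------------------- KM / log-rank


class TestKM:
    def test_product_limit_by_hand(self):
        curve = km_curve(np.array([1.0, 2.0]), np.array([1, 0]))
        assert curve.at(0.5) == 1.0
        assert curve.at(1.0) == pytest.approx(0.5)
        assert curve.at(10.0) == pytest.approx(0.5)

    def test_km_equals_one_minus_ecdf_without_censoring(self, rng):
        times = rng.exponential(10, size=40)
        events = np.ones(40, dtype=int)
        curve = km_curve(times, events)
        for t in curve.times:
            ecdf = np.mean(times <= t)
            assert curve.at(t) == pytest.approx(1.0 - ecdf, abs=1e-12)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = np.array([3.0, 5.0, 7.0, 3.0, 5.0, 7.0])
        events = np.array([1, 0, 1, 1, 0, 1])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = km_logrank(times, events, groups)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two"):
            km_logrank(np.array([1.0, 2.0]), np.array([1, 1]), np.array(["a", "a"]))

    def test_no_events_warns_p_one(self):
        with pytest.warns(UserWarning, match="no events"):
            res = km_logrank(
                np.array([1.0, 2.0, 3.0, 4.0]),
                np.zeros(4, dtype=int),
                np.array(["a", "a", "b", "b"]),
            )
        assert res.p == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_risk_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 20))
        times = np.round(rng.exponential(10, n), 1) + 0.1
        events = rng.integers(0, 2, n)
        groups = np.where(rng.random(n) < 0.5, "a", "b")
        if len(np.unique(groups)) < 2:
            groups[0] = "a"
            groups[1] = "b"
        expected = logrank_bruteforce(times, events, groups)
        if events.sum() == 0:
            return
        res = km_logrank(times, events, groups)
        assert res.chi2 == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------- Harrell's C


class TestHarrellC:
    def test_hand_example(self):
        c = harrell_c(np.array([3.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        assert c == pytest.approx(2 / 3)

    def test_constant_scores(self):
        c = harrell_c(np.zeros(5), np.arange(1.0, 6.0), np.ones(5, dtype=int))
        assert c == pytest.approx(0.5)

    def test_negation_antisymmetry(self, rng):
        scores = rng.random(20)
        times = rng.exponential(5, 20)
        events = rng.integers(0, 2, 20)
        events[0] = 1
        c = harrell_c(scores, times, events)
        assert harrell_c(-scores, times, events) == pytest.approx(1.0 - c)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        scores = np.round(rng.random(n), 2)
        times = np.round(rng.exponential(5, n), 1) + 0.1
        events = rng.integers(0, 2, n)
        events[:2] = 1
        assert harrell_c(scores, times, events) == pytest.approx(
            harrell_bruteforce(scores, times, events)
        )

    def test_no_comparable_pairs(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_c(np.array([1.0, 2.0]), np.array([1.0, 2.0]), np.array([0, 1]))


# ---------------------------------------------------------------- Cox model


class TestFitCox:
    def test_two_group_hazard_ratio_recovery(self):
        rng = np.random.default_rng(3)
        n = 1000
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.01 * 2.0**x))
        cens = rng.uniform(0, 400, n)
        times = np.minimum(t, cens)
        events = (t <= cens).astype(int)
        fit = fit_cox(times, events, pd.DataFrame({"x": x.astype(float)}))
        assert 1.7 <= fit.hr.iloc[0] <= 2.3
        assert fit.ci95["lower"].iloc[0] < fit.hr.iloc[0] < fit.ci95["upper"].iloc[0]

    def test_null_covariate_calibration(self):
        rng = np.random.default_rng(4)
        n = 500
        t = rng.exponential(100, n)
        cens = rng.uniform(0, 300, n)
        times = np.minimum(t, cens)
        events = (t <= cens).astype(int)
        x = rng.standard_normal(n)  # independent of survival
        fit = fit_cox(times, events, pd.DataFrame({"x": x}))
        assert abs(fit.beta.iloc[0]) < 0.2
        assert fit.wald_p.iloc[0] > 0.001

    def test_null_p_uniformity(self):
        """Wald p under the null is ~U(0,1) over repeated simulations."""
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            n = 60
            t = rng.exponential(50, n)
            cens = rng.uniform(0, 150, n)
            times = np.minimum(t, cens)
            events = (t <= cens).astype(int)
            if events.sum() < 5:
                continue
            x = rng.standard_normal(n)
            ps.append(fit_cox(times, events, pd.DataFrame({"x": x})).wald_p.iloc[0])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_perfect_concordance(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.ones(4, dtype=int)
        x = np.array([4.0, 3.0, 2.0, 1.0])  # higher covariate -> earlier event
        fit = fit_cox(times, events, pd.DataFrame({"x": x}))
        assert fit.cindex == pytest.approx(1.0)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            fit_cox(np.array([1.0, 2.0]), np.array([0, 0]), pd.DataFrame({"x": [0.1, 0.2]}))


# ---------------------------------------------------------------- PRS plumbing


def _toy_model():
    return PRSModel(
        selected=("f1", "f2"),
        beta=np.array([1.0, -1.0]),
        lambda_=0.1,
        threshold=0.0,
        means=np.array([0.0, 0.0]),
        scales=np.array([1.0, 1.0]),
    )


class TestPRS:
    def test_dot_product(self):
        model = _toy_model()
        X = pd.DataFrame({"f1": [2.0], "f2": [0.5]})
        assert prs_score(model, X)[0] == pytest.approx(1.5)

    def test_patient_at_training_means_scores_zero(self):
        model = PRSModel(
            selected=("f1",),
            beta=np.array([2.0]),
            lambda_=0.1,
            threshold=0.0,
            means=np.array([5.0]),
            scales=np.array([2.0]),
        )
        assert prs_score(model, pd.DataFrame({"f1": [5.0]}))[0] == pytest.approx(0.0)

    def test_missing_column_raises(self):
        with pytest.raises(KeyError):
            prs_score(_toy_model(), pd.DataFrame({"f1": [1.0]}))

    def test_model_json_round_trip(self, tmp_path):
        model = _toy_model()
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = PRSModel.from_json(path)
        assert loaded.selected == model.selected
        np.testing.assert_allclose(loaded.beta, model.beta)
        assert loaded.lambda_ == model.lambda_

    def test_dichotomize_tie_goes_high(self):
        groups = dichotomize(np.array([-1.0, 0.0, 1.0]), 0.0)
        np.testing.assert_array_equal(groups, [False, True, True])

    def test_dichotomize_infinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            dichotomize(np.array([1.0]), np.inf)


# ---------------------------------------------------------------- LASSO-Cox


def _synthetic_survival_frame(rng, n=150, n_noise=30, beta=1.0):
    signal = rng.standard_normal(n)
    X = pd.DataFrame(
        {"signal": signal, **{f"noise_{k}": rng.standard_normal(n) for k in range(n_noise)}}
    )
    t = rng.exponential(1.0 / (0.01 * np.exp(beta * signal)))
    cens = rng.uniform(0, 300, n)
    times = np.maximum(np.minimum(t, cens), 1e-3)
    events = (t <= cens).astype(int)
    return SurvivalData(times, events, X)


class TestLassoCox:
    def test_recovers_signal_among_noise(self):
        data = _synthetic_survival_frame(np.random.default_rng(0))
        model = lasso_cox_select(data, n_folds=5, seed=0)
        assert "signal" in model.selected

    def test_threshold_is_training_mean(self):
        data = _synthetic_survival_frame(np.random.default_rng(1))
        model = lasso_cox_select(data, n_folds=5, seed=1)
        prs = prs_score(model, data.X)
        assert model.threshold == pytest.approx(prs.mean(), abs=1e-9)

    def test_constant_feature_dropped_with_warning(self):
        data = _synthetic_survival_frame(np.random.default_rng(2))
        data.X["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            model = lasso_cox_select(data, n_folds=5, seed=2)
        assert "flat" not in model.selected

    def test_duplicating_patients_leaves_selection_stable(self):
        data = _synthetic_survival_frame(np.random.default_rng(3), n=100, n_noise=10)
        model_a = lasso_cox_select(data, n_folds=5, seed=3)
        dup = SurvivalData(
            np.concatenate([data.times, data.times]),
            np.concatenate([data.events, data.events]),
            pd.concat([data.X, data.X], ignore_index=True),
        )
        model_b = lasso_cox_select(dup, n_folds=5, seed=3)
        assert "signal" in model_a.selected and "signal" in model_b.selected

    def test_no_events_rejected(self):
        rng = np.random.default_rng(4)
        data = SurvivalData(
            rng.uniform(1, 10, 20), np.zeros(20, dtype=int), pd.DataFrame({"x": rng.random(20)})
        )
        with pytest.raises(ValueError, match="event"):
            lasso_cox_select(data)


class TestBreslowLoglik:
    def test_zero_predictor_closed_form(self):
        # all lp = 0: ll = -sum over event times of d_k * log(n at risk)
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 0, 1])
        ll = breslow_loglik(times, events, np.zeros(4))
        expected = -(np.log(4) + np.log(3) + np.log(1))
        assert ll == pytest.approx(expected)
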