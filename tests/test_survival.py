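import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from daysgained import (
    cox_fit,
    dichotomize,
    hazard_reduction_percent,
    iterative_km_sweep,
    km_logrank,
    median_cutoff,
)
from daysgained.survival import (
    CutoffSource,
    CutoffSpec,
    DegenerateCovariateError,
    Endpoint,
)


# ---------------------------------------------------------------- oracles

def brute_force_km(times, events):
    """Product-limit estimate computed event time by event time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    surv = {}
    s = 1.0
    for t in np.unique(times):
        at_risk = np.sum(times >= t)
        deaths = np.sum((times == t) & events)
        if deaths:
            s *= 1.0 - deaths / at_risk
        surv[float(t)] = s
    return surv


def brute_force_logrank(times, events, group_mask):
    """Hypergeometric two-sample log-rank statistic over pooled risk sets."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group_mask = np.asarray(group_mask, dtype=bool)
    observed_minus_expected = 0.0
    variance = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group_mask).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & group_mask).sum()
        observed_minus_expected += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat = observed_minus_expected**2 / variance
    return stat, chi2.sf(stat, df=1)


def cox_partial_likelihood_mle(times, events, x):
    """Directly maximize the (no-ties) Cox partial log-likelihood."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    x = np.asarray(x, dtype=float)
    assert len(np.unique(times)) == len(times), "oracle assumes no ties"

    def negloglik(beta):
        ll = 0.0
        for i in np.flatnonzero(events):
            risk_set = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk_set])))
        return -ll

    res = minimize_scalar(negloglik, bounds=(-8, 8), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


# ---------------------------------------------------------------- tests

class TestDichotomize:
    def test_score_at_cutoff_is_high(self):
        labels = dichotomize([-10.0, 78.0, 200.0], 78.0)
        assert labels.tolist() == ["Low", "High", "High"]

    def test_cutoff_below_minimum_flags_not_evaluable(self):
        scores = np.array([10.0, 20.0, 30.0])
        labels = dichotomize(scores, 5.0)
        assert set(labels) == {"High"}
        result = km_logrank([5, 6, 7], [1, 1, 1], labels)
        assert not result.evaluable
        assert result.p_value is None

    def test_median_cutoff(self):
        spec = median_cutoff([10.0, 20.0, 30.0], Endpoint.OS)
        assert spec.value == 20.0
        assert dichotomize([10.0, 20.0, 30.0], spec.value).tolist() == [
            "Low", "High", "High",
        ]

    def test_prior_cutoff_values_are_pinned(self):
        with pytest.raises(ValueError):
            CutoffSpec(80.0, CutoffSource.PRIOR_OS_78, Endpoint.OS)
        with pytest.raises(ValueError):
            CutoffSpec(78.0, CutoffSource.PRIOR_PFS_93, Endpoint.PFS)


class TestKMLogrank:
    def test_identical_groups_give_null_statistic(self):
        times = [3.0, 5.0, 8.0, 3.0, 5.0, 8.0]
        events = [1, 0, 1, 1, 0, 1]
        labels = ["High"] * 3 + ["Low"] * 3
        result = km_logrank(times, events, labels)
        assert result.chi_square == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0, abs=1e-9)

    def test_eight_subject_table_matches_hand_oracle(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 20.0, 30.0, 40.0])
        events = np.ones(8, dtype=int)
        labels = np.array(["High"] * 4 + ["Low"] * 4)
        result = km_logrank(times, events, labels)
        stat, p = brute_force_logrank(times, events, labels == "High")
        assert result.chi_square == pytest.approx(stat, abs=1e-9)
        assert result.p_value == pytest.approx(p, abs=1e-9)

    def test_single_subject_per_group_matches_oracle(self):
        times = np.array([5.0, 9.0])
        events = np.array([1, 1])
        labels = np.array(["High", "Low"])
        result = km_logrank(times, events, labels)
        stat, p = brute_force_logrank(times, events, labels == "High")
        assert result.chi_square == pytest.approx(stat, abs=1e-9)
        assert result.p_value == pytest.approx(p, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_small_cohorts_match_oracles(self, seed):
        """KM product-limit and log-rank vs brute force, with ties/censoring."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 21))
        times = rng.integers(1, 10, n).astype(float)  # integer times force ties
        events = rng.random(n) < 0.7
        labels = np.where(rng.random(n) < 0.5, "High", "Low")
        if len(set(labels)) < 2:
            labels[0] = "High" if labels[0] == "Low" else "Low"
        result = km_logrank(times, events, labels)
        stat, p = brute_force_logrank(times, events, labels == "High")
        assert result.chi_square == pytest.approx(stat, abs=1e-9)
        assert result.p_value == pytest.approx(p, abs=1e-9)
        for lab in ("High", "Low"):
            mask = labels == lab
            oracle = brute_force_km(times[mask], events[mask])
            curve = result.curves[lab]
            for t, s in zip(curve["time"], curve["survival"]):
                if float(t) in oracle:
                    assert s == pytest.approx(oracle[float(t)], abs=1e-9)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(11)
        times = rng.exponential(100, 30)
        events = rng.random(30) < 0.8
        labels = np.where(rng.random(30) < 0.5, "High", "Low")
        swapped = np.where(labels == "High", "Low", "High")
        a = km_logrank(times, events, labels)
        b = km_logrank(times, events, swapped)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        assert a.chi_square == pytest.approx(b.chi_square, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_lifelines_logrank(self, seed):
        """Cross-check the in-package statistic against lifelines."""
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(seed)
        n = 80
        times = rng.exponential(200, n).round(0) + 1  # ties included
        events = rng.random(n) < 0.75
        labels = np.where(rng.random(n) < 0.5, "High", "Low")
        result = km_logrank(times, events, labels, compute_curves=False)
        mask = labels == "High"
        ref = logrank_test(times[mask], times[~mask], events[mask], events[~mask])
        assert result.chi_square == pytest.approx(float(ref.test_statistic), rel=1e-10)
        assert result.p_value == pytest.approx(float(ref.p_value), rel=1e-10)

    def test_group_with_zero_events_still_defined(self):
        times = [5.0, 6.0, 7.0, 8.0]
        events = [1, 1, 0, 0]
        labels = ["Low", "Low", "High", "High"]
        result = km_logrank(times, events, labels)
        assert result.evaluable
        assert np.isfinite(result.p_value)


class TestSweep:
    def _cohort(self, seed=5, n=60):
        rng = np.random.default_rng(seed)
        dg = rng.normal(100, 100, n)
        times = rng.exponential(300 * np.exp(0.005 * (dg - 100)), n)
        events = np.ones(n, dtype=int)
        return dg, times, events

    def test_single_cutoff_grid_equals_standalone_analysis(self):
        dg, times, events = self._cohort()
        sweep = iterative_km_sweep(dg, times, events, grid=[100.0])
        assert len(sweep.table) == 1
        km = km_logrank(times, events, dichotomize(dg, 100.0))
        assert sweep.table["p_value"].iloc[0] == pytest.approx(km.p_value, rel=1e-12)

    def test_sweep_at_median_reproduces_median_cutoff_analysis(self):
        dg, times, events = self._cohort()
        med = float(np.median(dg))
        sweep = iterative_km_sweep(dg, times, events, grid=[med])
        km = km_logrank(times, events, dichotomize(dg, med))
        assert sweep.table["p_value"].iloc[0] == km.p_value

    def test_small_arms_flagged_not_evaluable(self):
        dg, times, events = self._cohort(n=20)
        grid = [float(np.min(dg)) - 1.0, float(np.median(dg))]
        sweep = iterative_km_sweep(dg, times, events, grid=grid, min_group_size=3)
        assert not sweep.table["evaluable"].iloc[0]  # everyone High
        assert sweep.table["evaluable"].iloc[1]
        assert np.isnan(sweep.table["p_value"].iloc[0])

    def test_empty_grid_rejected(self):
        dg, times, events = self._cohort()
        with pytest.raises(ValueError):
            iterative_km_sweep(dg, times, events, grid=[])

    def test_grid_must_increase(self):
        dg, times, events = self._cohort()
        with pytest.raises(ValueError):
            iterative_km_sweep(dg, times, events, grid=[50.0, 50.0])


class TestCox:
    def test_six_subject_fit_matches_partial_likelihood_oracle(self):
        # hand-constructed, binary covariate, no censoring, no ties
        times = np.array([2.0, 4.0, 5.0, 7.0, 11.0, 13.0])
        events = np.ones(6, dtype=int)
        x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 0.0])
        beta_oracle = cox_partial_likelihood_mle(times, events, x)
        # feed x through the dg/25 interface: dg = 25*x makes dg_per25 = x
        result = cox_fit(25.0 * x, times, events, model_type="univariate")
        hr = result.table.loc["dg_per25", "hr"]
        assert np.log(hr) == pytest.approx(beta_oracle, abs=1e-4)

    def test_per25_scaling_exponentiates_per1_hr(self):
        rng = np.random.default_rng(3)
        n = 120
        dg = rng.normal(100, 100, n)
        times = rng.exponential(200 * np.exp(-0.004 * dg), n)
        events = np.ones(n, dtype=int)
        per25 = cox_fit(dg, times, events).table.loc["dg_per25", "hr"]
        per1 = cox_fit(dg * 25.0, times, events).table.loc["dg_per25", "hr"]
        assert per25 == pytest.approx(per1**25, rel=1e-6)

    def test_hr_invariant_to_affine_shift_of_other_covariate(self):
        rng = np.random.default_rng(4)
        n = 150
        dg = rng.normal(100, 100, n)
        age = rng.normal(57, 10, n)
        sex = (rng.random(n) < 0.6).astype(float)
        times = rng.exponential(200 * np.exp(-0.004 * dg + 0.01 * age), n)
        events = (rng.random(n) < 0.85).astype(int)
        a = cox_fit(dg, times, events, age=age, sex_male=sex, model_type="multivariate")
        b = cox_fit(dg, times, events, age=age - 57.0, sex_male=sex,
                    model_type="multivariate")
        assert a.table.loc["dg_per25", "hr"] == pytest.approx(
            b.table.loc["dg_per25", "hr"], rel=1e-6
        )

    def test_constant_covariate_flagged(self):
        with pytest.raises(DegenerateCovariateError):
            cox_fit([50.0] * 10, np.arange(1, 11, dtype=float), np.ones(10, dtype=int))

    def test_fewer_than_two_events_rejected(self):
        with pytest.raises(ValueError, match="2 observed events"):
            cox_fit([1.0, 2.0, 3.0], [5.0, 6.0, 7.0], [1, 0, 0])

    def test_ci_brackets_hr(self):
        rng = np.random.default_rng(9)
        n = 100
        dg = rng.normal(100, 100, n)
        times = rng.exponential(200 * np.exp(-0.004 * dg), n)
        result = cox_fit(dg, times, np.ones(n, dtype=int))
        row = result.table.loc["dg_per25"]
        assert row["ci_low"] <= row["hr"] <= row["ci_high"]
        assert row["hr"] > 0


class TestHazardReduction:
    @pytest.mark.parametrize(
        "hr, percent",
        [(0.875, 12.5), (1.0, 0.0), (0.956, 4.4), (0.877, 12.3), (1.25, -25.0)],
    )
    def test_percent_conversion(self, hr, percent):
        assert hazard_reduction_percent(hr) == percent

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            hazard_reduction_percent(0.0)
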