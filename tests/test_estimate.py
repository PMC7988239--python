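"""Anterograde/retrograde rate estimation, confidence intervals, half-lives."""

import math

import numpy as np
import pytest

from proturn import LogisticParams, TimeSeries, solve_anterograde
from proturn.estimate import (
    FitWindow,
    confidence_intervals,
    fit_anterograde,
    fit_retrograde,
    half_lives,
)
from proturn.logistic import convert_params, fit_logistic4
from proturn.synthetic import SyntheticSpec, consistent_pair, make_mrna, make_replicates


@pytest.fixture(scope="module")
def consistent_case(window):
    """Exactly model-consistent (mRNA, logistic protein) pair at known rates."""
    Sp, Dp = 0.5, 0.12
    params = LogisticParams(K=Sp / Dp, t_i=5.0, r=0.6)
    mrna, _ = consistent_pair(Sp, Dp, params, window)
    return mrna, params, Sp, Dp


class TestSelfConsistentRecovery:
    def test_both_modes_recover_exactly(self, consistent_case, window):
        mrna, params, Sp, Dp = consistent_case
        a = fit_anterograde(mrna, params, window)
        r = fit_retrograde(mrna, params, window)
        for est in (a, r):
            assert est.converged
            assert est.Sp == pytest.approx(Sp, rel=1e-3)
            assert est.Dp == pytest.approx(Dp, rel=1e-3)

    def test_modes_agree_within_one_percent(self, consistent_case, window):
        mrna, params, *_ = consistent_case
        a = fit_anterograde(mrna, params, window)
        r = fit_retrograde(mrna, params, window)
        assert abs(a.Sp - r.Sp) / a.Sp <= 0.01
        assert abs(a.Dp - r.Dp) / a.Dp <= 0.01

    def test_noiseless_ci_widths_negligible(self, consistent_case, window):
        mrna, params, Sp, Dp = consistent_case
        a = fit_anterograde(mrna, params, window)
        assert (a.Sp_ci_high - a.Sp_ci_low) <= 1e-4 * a.Sp
        assert (a.Dp_ci_high - a.Dp_ci_low) <= 1e-4 * a.Dp


class TestForwardRouteRecovery:
    def test_raw_trace_anterograde_recovers_truth(self, window):
        spec = SyntheticSpec(noise_cv=0.0, replicate_cv=0.0, n_replicates=1,
                             seed=5, window=window)
        traces, rates = make_replicates(spec)
        mrna = make_mrna(spec)
        est = fit_anterograde(mrna, traces[0], window, p0=0.0)
        assert est.Sp == pytest.approx(rates[0][0], rel=1e-6)
        assert est.Dp == pytest.approx(rates[0][1], rel=1e-6)

    def test_logistic_route_modes_agree(self, window):
        """Anterograde and retrograde agree within 5% on clean data that
        satisfies the model assumptions (the internal-consistency property)."""
        spec = SyntheticSpec(noise_cv=0.0, replicate_cv=0.0, n_replicates=1,
                             seed=5, window=window)
        traces, _ = make_replicates(spec)
        mrna = make_mrna(spec)
        params = convert_params(fit_logistic4(traces[0]))
        a = fit_anterograde(mrna, params, window)
        r = fit_retrograde(mrna, params, window)
        assert abs(a.Sp - r.Sp) / a.Sp <= 0.05
        assert abs(a.Dp - r.Dp) / a.Dp <= 0.05


class TestScaleEquivariance:
    def test_mrna_rescaling(self, consistent_case, window):
        """Scaling M by c leaves Dp unchanged and scales Sp by 1/c."""
        mrna, params, *_ = consistent_case
        c = 3.7
        scaled = TimeSeries(mrna.times, mrna.values * c)
        base = fit_anterograde(mrna, params, window)
        scl = fit_anterograde(scaled, params, window)
        assert scl.Dp == pytest.approx(base.Dp, rel=1e-9)
        assert scl.Sp == pytest.approx(base.Sp / c, rel=1e-9)

    def test_protein_rescaling(self, consistent_case, window):
        """Scaling the protein (K) by c scales Sp by c; Dp is invariant."""
        mrna, params, *_ = consistent_case
        c = 2.5
        scaled_params = LogisticParams(K=params.K * c, t_i=params.t_i, r=params.r)
        base = fit_anterograde(mrna, params, window)
        scl = fit_anterograde(mrna, scaled_params, window)
        assert scl.Dp == pytest.approx(base.Dp, rel=1e-6)
        assert scl.Sp == pytest.approx(base.Sp * c, rel=1e-6)


class TestObjective:
    def test_final_cost_not_above_initial(self, window):
        spec = SyntheticSpec(noise_cv=0.05, replicate_cv=0.0, n_replicates=1,
                             seed=9, window=window)
        traces, _ = make_replicates(spec)
        mrna = make_mrna(spec)
        params = convert_params(fit_logistic4(traces[0]))
        # deliberately poor initialization
        bad_init = (5.0, 1.5)
        est = fit_anterograde(mrna, params, window, init=bad_init)
        from proturn.core import logistic_eval

        grid_t = window.times()
        target = np.asarray(logistic_eval(params, grid_t)) - params.bottom
        mrna_w = TimeSeries(grid_t, np.interp(grid_t, mrna.times, mrna.values))
        init_resid = (
            solve_anterograde(mrna_w, *bad_init, p0=target[0]).values - target
        )
        assert est.residual_ss <= float(init_resid @ init_resid)

    def test_window_outside_mrna_range_rejected(self, consistent_case):
        mrna, params, *_ = consistent_case
        with pytest.raises(ValueError):
            fit_anterograde(mrna, params, FitWindow(0.0, 30.0, 2.0))


class TestConfidenceIntervals:
    def test_estimate_inside_interval(self, consistent_case, window):
        mrna, params, *_ = consistent_case
        for est in (fit_anterograde(mrna, params, window),
                    fit_retrograde(mrna, params, window)):
            assert est.Sp_ci_low <= est.Sp <= est.Sp_ci_high
            assert est.Dp_ci_low <= est.Dp <= est.Dp_ci_high

    def test_singular_jacobian_gives_unbounded(self):
        J = np.zeros((10, 2))
        lo, hi = confidence_intervals(J, np.ones(10), dof=8,
                                      estimates=np.array([1.0, 2.0]))
        assert np.all(np.isinf(lo)) and np.all(np.isinf(hi))

    def test_known_linear_case(self):
        """For a linear model the asymptotic CI equals the exact OLS CI."""
        rng = np.random.default_rng(0)
        x = np.linspace(0, 1, 50)
        J = x[:, None]
        resid = rng.normal(0, 0.1, size=50)
        lo, hi = confidence_intervals(J, resid, dof=49, estimates=np.array([2.0]))
        s2 = resid @ resid / 49
        se = math.sqrt(s2 / (x @ x))
        from scipy import stats

        t = stats.t.ppf(0.975, 49)
        assert hi[0] - lo[0] == pytest.approx(2 * t * se, rel=1e-12)

    def test_coverage_under_additive_noise(self, window):
        """True rates fall inside the 95% CI in about 95% of noisy repeats."""
        spec = SyntheticSpec(window=window)
        mrna = make_mrna(spec)
        Sp, Dp = 0.5, 0.12
        clean = solve_anterograde(mrna, Sp, Dp, 0.0).values
        sd = 0.05 * Sp * 1.0 / Dp
        rng = np.random.default_rng(1234)
        n_rep, cov_sp, cov_dp = 60, 0, 0
        for _ in range(n_rep):
            noisy = clean + sd * rng.normal(size=clean.size)
            est = fit_anterograde(
                mrna, TimeSeries(mrna.times, noisy, raw=True), window, p0=0.0
            )
            cov_sp += est.Sp_ci_low <= Sp <= est.Sp_ci_high
            cov_dp += est.Dp_ci_low <= Dp <= est.Dp_ci_high
        # loose binomial band for a quick check; the acceptance suite runs 200
        assert 0.85 <= cov_sp / n_rep <= 1.0
        assert 0.85 <= cov_dp / n_rep <= 1.0


class TestHalfLives:
    def make_est(self, dp, converged=True, rid=""):
        from proturn.core import TurnoverEstimate

        return TurnoverEstimate(
            Sp=0.5, Dp=dp, Sp_ci_low=0.4, Sp_ci_high=0.6,
            Dp_ci_low=dp - 0.01, Dp_ci_high=dp + 0.01,
            mode="anterograde", replicate_id=rid, converged=converged,
        )

    def test_mean_of_identical_rates(self):
        summary = half_lives([self.make_est(0.12), self.make_est(0.12)])
        assert summary.mean_h == pytest.approx(math.log(2) / 0.12, rel=1e-12)
        assert summary.mean_h == pytest.approx(5.78, abs=0.01)

    def test_single_ln2_rate(self):
        summary = half_lives([self.make_est(math.log(2))])
        assert summary.half_lives_h[0] == pytest.approx(1.0, rel=1e-12)

    def test_unconverged_excluded_with_flag(self):
        summary = half_lives([self.make_est(0.12), self.make_est(0.2, converged=False)])
        assert summary.n_excluded == 1
        assert summary.half_lives_h[1] is None
        assert summary.mean_h == pytest.approx(math.log(2) / 0.12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            half_lives([])
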