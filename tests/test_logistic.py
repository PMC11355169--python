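"""Tests for the logistic-map plaque model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaquedyn import logistic as lm
from plaquedyn.exceptions import (
    ClassificationError,
    DomainError,
    EvaluationError,
    SimulationError,
)


class TestLogisticStep:
    @pytest.mark.parametrize(
        "P, r, expected",
        [
            (0.0, 3.8, 0.0),  # zero burden is absorbing
            (0.5, 2.0, 0.5),  # fixed point (r-1)/r = 0.5
            (0.1, 1.8, 0.162),  # direct arithmetic 1.8*0.1*0.9
        ],
    )
    def test_values(self, P, r, expected):
        assert lm.logistic_step(P, r) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "P, r, offender",
        [(1.2, 2.0, "P"), (-0.1, 2.0, "P"), (0.5, 4.5, "r"), (0.5, -1.0, "r")],
    )
    def test_domain_errors_name_offender(self, P, r, offender):
        with pytest.raises(DomainError, match=offender):
            lm.logistic_step(P, r)

    @given(
        P=st.floats(0.0, 1.0, allow_nan=False),
        r=st.floats(0.0, 4.0, allow_nan=False),
    )
    @settings(deadline=None, derandomize=True)
    def test_range_preservation(self, P, r):
        assert 0.0 <= lm.logistic_step(P, r) <= 1.0


class TestFixedPoint:
    @pytest.mark.parametrize(
        "r, expected", [(0.5, 0.0), (1.0, 0.0), (2.0, 0.5), (1.8, (1.8 - 1) / 1.8)]
    )
    def test_values(self, r, expected):
        assert lm.fixed_point(r) == pytest.approx(expected, abs=1e-15)

    def test_rejects_nonpositive_r(self):
        with pytest.raises(DomainError):
            lm.fixed_point(0.0)

    @given(r=st.floats(1.001, 2.999))
    @settings(deadline=None, derandomize=True)
    def test_residual(self, r):
        fp = lm.fixed_point(r)
        assert abs(lm.logistic_step(fp, r) - fp) < 1e-12


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "r, regime",
        [
            (0.5, lm.Regime.EXTINCTION),
            (1.0, lm.Regime.EXTINCTION),  # boundary belongs to lower regime
            (1.8, lm.Regime.MONOTONE_CONVERGENCE),
            (2.0, lm.Regime.MONOTONE_CONVERGENCE),
            (2.8, lm.Regime.TRANSIENT_FLUCTUATION),
            (3.0, lm.Regime.TRANSIENT_FLUCTUATION),
            (3.2, lm.Regime.PERIODIC),
            (3.8, lm.Regime.CHAOTIC),
        ],
    )
    def test_taxonomy(self, r, regime):
        assert lm.classify_regime(r).label is regime

    def test_fixed_point_attached_where_defined(self):
        assert lm.classify_regime(1.8).fixed_point == pytest.approx((1.8 - 1) / 1.8)
        assert lm.classify_regime(3.8).fixed_point is None

    def test_invalid_chaos_onset(self):
        with pytest.raises(DomainError):
            lm.classify_regime(2.0, chaos_onset_value=2.5)


class TestGrowthAggregate:
    def test_reduces_to_baseline(self):
        g = lm.GrowthAggregate(alpha=1.5, r_lower_bound=None)
        assert lm.aggregate_growth_rate(0.3, g) == pytest.approx(1.5)

    def test_single_factor(self):
        g = lm.GrowthAggregate(
            alpha=1.0,
            betas=(0.5, 0.0, 0.0, 0.0),
            factors=(lm.factor_constant(1.0),) * 4,
            r_lower_bound=None,
        )
        assert lm.aggregate_growth_rate(0.3, g) == pytest.approx(1.5)

    def test_lower_bound_clamp(self):
        g = lm.GrowthAggregate(alpha=0.8, r_lower_bound=1.0)
        assert lm.aggregate_growth_rate(0.3, g) == pytest.approx(1.0)

    def test_negative_clamped_at_zero(self):
        g = lm.GrowthAggregate(
            alpha=1.0, betas=(-5.0, 0, 0, 0), r_lower_bound=None
        )
        assert lm.aggregate_growth_rate(0.3, g) == 0.0

    def test_nonfinite_factor_names_index(self):
        bad = lambda P: float("nan")
        g = lm.GrowthAggregate(
            alpha=1.0,
            betas=(0, 1.0, 0, 0),
            factors=(lm.factor_constant(), bad, lm.factor_constant(), lm.factor_constant()),
            r_lower_bound=None,
        )
        with pytest.raises(EvaluationError, match="f2"):
            lm.aggregate_growth_rate(0.3, g)

    def test_factor_library(self):
        assert lm.factor_linear(2.0)(0.25) == pytest.approx(0.5)
        assert lm.factor_saturating(0.5)(0.5) == pytest.approx(0.5)


class TestLumen:
    def test_fixed_point_at_amax(self):
        lum = lm.RemodelingLumen(A0=10, Amax=14, rate=0.5)
        assert lm.update_lumen(14.0, lum) == pytest.approx(14.0)

    def test_geometric_step(self):
        lum = lm.RemodelingLumen(A0=10, Amax=14, rate=0.5)
        assert lm.update_lumen(10.0, lum) == pytest.approx(12.0)

    def test_iterates_converge_to_amax(self):
        lum = lm.RemodelingLumen(A0=10, Amax=14, rate=0.3)
        A = 10.0
        previous = A
        for _ in range(200):
            A = lm.update_lumen(A, lum)
            assert A >= previous
            previous = A
        assert A == pytest.approx(14.0, abs=1e-6)

    def test_domain_error_outside_band(self):
        lum = lm.RemodelingLumen(A0=10, Amax=14, rate=0.5)
        with pytest.raises(DomainError):
            lm.update_lumen(9.0, lum)


class TestSimulateTrajectory:
    def test_extinction(self):
        traj = lm.simulate_trajectory(0.1, 500, r_schedule=0.8)
        assert traj.P_series[-1] < 1e-6
        # monotone regression is not an oscillatory (erosion/rupture) course
        assert traj.oscillation_onset is None

    def test_convergence_to_fixed_point(self):
        traj = lm.simulate_trajectory(0.1, 500, r_schedule=1.8)
        assert traj.P_series[-1] == pytest.approx((1.8 - 1) / 1.8, abs=1e-9)
        assert traj.oscillation_onset is None

    def test_series_share_length_and_record_rates(self):
        traj = lm.simulate_trajectory(0.1, 20, r_schedule=1.8)
        assert len(traj.P_series) == len(traj.r_series) == len(traj.A_series) == 21
        assert np.isnan(traj.r_series[0])
        assert np.all(traj.r_series[1:] == 1.8)

    def test_oscillation_onset_requires_r_above_two(self):
        # unstable-plaque scenario: above r = 2 the approach to the fixed
        # point fluctuates, so a grown plaque erodes (first decrease)
        traj = lm.simulate_trajectory(0.1, 30, r_schedule=2.8)
        onset = traj.oscillation_onset
        assert onset is not None
        assert traj.r_series[onset] > 2.0
        assert traj.P_series[onset] < traj.P_series[onset - 1]
        # the plaque grew before eroding
        assert traj.P_series[: onset].max() > traj.P_series[0]
        # below r = 2 the same start converges monotonically: no onset
        assert lm.simulate_trajectory(0.1, 30, r_schedule=1.8).oscillation_onset is None

    def test_slow_ramp_tracks_fixed_point_without_oscillating(self):
        # with a gentle additive drift of r the burden chases the rising
        # fixed point from below quasi-statically and never overshoots
        g = lm.GrowthAggregate(alpha=1.0, r_update_increment=0.08)
        traj = lm.simulate_trajectory(0.1, 30, growth=g)
        assert traj.oscillation_onset is None
        fp = (traj.r_series[-1] - 1.0) / traj.r_series[-1]
        assert traj.P_series[-1] == pytest.approx(fp, abs=0.05)

    def test_remodeling_lowers_effective_stenosis(self):
        lum = lm.RemodelingLumen(A0=10, Amax=14, rate=0.2)
        traj = lm.simulate_trajectory(0.1, 30, r_schedule=1.8, lumen=lum)
        assert traj.A_series[-1] == pytest.approx(14.0, abs=1e-2)
        # derived stenosis series scales P by the lumen growth
        assert traj.stenosis_vs_baseline[-1] == pytest.approx(
            traj.P_series[-1] * traj.A_series[-1] / 10.0
        )

    def test_exactly_one_mode(self):
        with pytest.raises(DomainError):
            lm.simulate_trajectory(0.1, 5)
        with pytest.raises(DomainError):
            lm.simulate_trajectory(
                0.1, 5, growth=lm.GrowthAggregate(), r_schedule=1.8
            )

    def test_escape_reports_visit(self):
        with pytest.raises(SimulationError) as exc_info:
            lm.simulate_trajectory(0.1, 10, r_schedule=[1.8, 5.0] + [1.8] * 8)
        assert exc_info.value.visit == 2

    def test_schedule_length_checked(self):
        with pytest.raises(DomainError):
            lm.simulate_trajectory(0.1, 10, r_schedule=[1.8] * 3)


class TestInstabilityProportion:
    @staticmethod
    def brute_force(P, r_max, n=100_000):
        """Independent grid oracle: fraction of uniformly spaced r values in
        [0, r_max] whose next iterate decreases P."""
        r = np.linspace(0.0, r_max, n)
        return np.mean(r * P * (1.0 - P) < P)

    @pytest.mark.parametrize("P", [0.001, 0.3, 0.5, 0.7, 0.72, 0.9])
    def test_matches_brute_force(self, P):
        closed = lm.instability_proportion(P, 3.5)
        assert closed == pytest.approx(self.brute_force(P, 3.5), abs=2e-5)

    def test_saturates_at_072(self):
        assert lm.instability_proportion(0.72, 3.5) == 1.0

    def test_small_P_limit(self):
        assert lm.instability_proportion(1e-9, 3.5) == pytest.approx(1 / 3.5, rel=1e-6)

    @pytest.mark.parametrize("P", [0.0, 1.0])
    def test_degenerate_boundaries_rejected(self, P):
        with pytest.raises(DomainError):
            lm.instability_proportion(P)

    def test_curve_matches_scalar(self):
        P = np.array([0.2, 0.5, 0.8])
        curve = lm.instability_curve(P, 3.5)
        for p, v in zip(P, curve):
            assert v == lm.instability_proportion(p, 3.5)


class TestChaosDiagnostics:
    def test_lyapunov_negative_at_stable_fixed_point(self):
        assert lm.lyapunov_exponent(1.8, n_iter=10_000) < 0

    def test_lyapunov_fully_chaotic_closed_form(self):
        # at r = 4 the map conjugates to the tent map with exponent ln 2
        assert lm.lyapunov_exponent(4.0) == pytest.approx(math.log(2), abs=5e-3)

    def test_lyapunov_positive_in_chaos(self):
        assert lm.lyapunov_exponent(3.8) > 0

    def test_attractor_periods(self):
        assert lm.attractor_period(2.9, burn_in=10_000) == 1
        assert lm.attractor_period(3.2, burn_in=10_000) == 2
        assert lm.attractor_period(3.5, burn_in=10_000) == 4

    def test_regimes_straddle_chaos_onset(self):
        onset = lm.chaos_onset(tolerance=1e-4, n_iter=20_000)
        assert lm.classify_regime(onset - 0.01, onset).label is lm.Regime.PERIODIC
        assert lm.classify_regime(onset + 0.01, onset).label is lm.Regime.CHAOTIC


class TestEstimateR:
    def test_fixed_point_pair(self):
        est = lm.estimate_r_series([0.5, 0.5])
        assert est.r_hat[0] == pytest.approx(2.0)

    def test_inverts_logistic_step(self):
        est = lm.estimate_r_series([0.1, 0.162])
        assert est.r_hat[0] == pytest.approx(1.8)

    def test_noiseless_roundtrip_exact(self):
        traj = lm.simulate_trajectory(0.17, 30, r_schedule=1.7)
        est = lm.estimate_r_series(traj.P_series)
        np.testing.assert_allclose(est.r_hat, 1.7, rtol=1e-12)

    def test_degenerate_start_flagged_not_dropped(self):
        est = lm.estimate_r_series([0.5, 0.0, 0.0])
        assert len(est) == 2
        assert not est.undefined[0] and est.r_hat[0] == 0.0
        assert est.undefined[1] and np.isnan(est.r_hat[1])

    def test_rejects_out_of_range(self):
        with pytest.raises(DomainError):
            lm.estimate_r_series([0.5, 1.2])


class TestRiskClassification:
    @pytest.mark.parametrize(
        "estimates, expected",
        [
            ([1.4, 1.6, 1.9], "STABLE"),
            ([1.8, 2.1], "UNSTABLE"),
            ([2.0], "STABLE"),  # instability requires strictly r > 2
        ],
    )
    def test_latest_rule(self, estimates, expected):
        assert lm.classify_plaque_risk(estimates) == expected

    def test_trailing_mean_rule(self):
        assert (
            lm.classify_plaque_risk([3.0, 1.0, 1.0, 1.0], summary="trailing_mean")
            == "STABLE"
        )
        assert (
            lm.classify_plaque_risk([2.5, 2.5, 2.5], summary="trailing_mean")
            == "UNSTABLE"
        )

    def test_all_undefined_is_an_error(self):
        est = lm.estimate_r_series([0.0, 0.0])
        with pytest.raises(ClassificationError):
            lm.classify_plaque_risk(est)
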