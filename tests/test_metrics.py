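import numpy as np
import pandas as pd
import pytest

import vmrkit as v
from vmrkit import metrics as m
from vmrkit.schedule import Phase
from vmrkit.simulator import SessionData

from conftest import make_trajectory


class TestExtractMovementAngle:
    def test_straight_reach_is_zero(self):
        traj = make_trajectory(0.0)
        assert m.extract_movement_angle(traj, (0, 0), (1, 0)) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [-60.0, -15.0, 1.0, 15.0, 89.0])
    @pytest.mark.parametrize("target_dir", [0.0, 90.0, 180.0, 270.0])
    def test_rotated_reach_recovers_angle_exactly(self, angle, target_dir):
        """Agrees with plane geometry to < 1e-6 deg for any target direction."""
        traj = make_trajectory(angle, target_dir_deg=target_dir)
        start, tvec = (0.0, 0.0), np.radians(target_dir)
        target = (np.cos(tvec), np.sin(tvec))
        got = m.extract_movement_angle(traj, start, target)
        assert got == pytest.approx(angle, abs=1e-6)

    def test_interpolates_between_bracketing_samples(self):
        # two samples straddle the 95% radius at 0.94 and 0.97 on a 15 deg ray
        theta = np.radians(15.0)
        traj = [
            (0.0, 0.0, 0.0),
            (10.0, 0.94 * np.cos(theta), 0.94 * np.sin(theta)),
            (20.0, 0.97 * np.cos(theta), 0.97 * np.sin(theta)),
        ]
        got = m.extract_movement_angle(traj, (0, 0), (1.0, 0.0), radial_disp=1.0)
        assert got == pytest.approx(15.0, abs=1e-9)

    def test_never_crossing_raises(self):
        traj = [(t, 0.1 * t, 0.0) for t in np.linspace(0, 1, 5)]  # stops at r=0.1
        with pytest.raises(ValueError):
            m.extract_movement_angle(traj, (0, 0), (10.0, 0.0))

    def test_movement_initiation_index(self):
        traj = make_trajectory(0.0, n=100)
        idx = m.movement_initiation_index(traj, (0, 0), radial_disp=1.0)
        radii = [np.hypot(x, y) for _, x, y in traj]
        assert radii[idx] >= 0.05 and radii[idx - 1] < 0.05


def _session_from_angles(angles, phases, valid=None, epoch_size=4):
    n = len(angles)
    df = pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "movement_angle_deg": angles,
            "phase": phases,
            "reaction_time_ms": 300.0,
            "valid": valid if valid is not None else [True] * n,
        }
    )
    return SessionData(trials=df, paradigm_name="synthetic", epoch_size=epoch_size)


class TestEpochAverage:
    def test_plain_mean(self):
        sess = _session_from_angles([1, 2, 3, 4], ["baseline"] * 4)
        assert m.epoch_average(sess).values.tolist() == [2.5]

    def test_invalid_trials_excluded(self):
        sess = _session_from_angles([1, 2, 3, 99], ["baseline"] * 4, valid=[1, 1, 1, 0])
        assert m.epoch_average(sess).values.tolist() == [2.0]

    def test_all_invalid_epoch_propagates_nan(self):
        sess = _session_from_angles([1, 2, 3, 4], ["baseline"] * 4, valid=[0, 0, 0, 0])
        assert np.isnan(m.epoch_average(sess).values[0])

    def test_360_trials_give_90_epochs(self, noiseless_session):
        assert len(m.epoch_average(noiseless_session)) == 90

    def test_indivisible_count_errors(self):
        sess = _session_from_angles([1, 2, 3], ["baseline"] * 3)
        with pytest.raises(ValueError):
            m.epoch_average(sess)


class TestBaselineSubtract:
    def _series(self, values, phases=None):
        return m.EpochSeries(
            values=np.asarray(values, dtype=float),
            phases=phases or [Phase.BASELINE] * len(values),
        )

    def test_constant_series_zeros(self):
        out = m.baseline_subtract(self._series([2.0] * 10), rotation_start_epoch=5)
        assert np.allclose(out.values, 0.0)

    def test_subtracts_pre_mean(self):
        s = self._series([0, 0, 2, 2, 2, 12.0])
        out = m.baseline_subtract(s, rotation_start_epoch=5)
        assert out.values[-1] == pytest.approx(10.0)

    def test_sign_flip_for_opposite_rotation(self):
        s = self._series([0, 0, -2, -2, -2, -12.0])
        out = m.baseline_subtract(s, rotation_start_epoch=5, sign_flip=True)
        assert out.values[-1] == pytest.approx(10.0)

    def test_insufficient_pre_epochs(self):
        with pytest.raises(ValueError):
            m.baseline_subtract(self._series([1.0, 2.0]), rotation_start_epoch=1)


class TestDeltaAngle:
    def _series(self, pre, post):
        vals = list(pre) + list(post)
        return m.EpochSeries(values=np.array(vals, float), phases=[Phase.BASELINE] * len(vals))

    def test_identical_series_zero(self):
        s = self._series([0, 0, 0], [5, 6, 7])
        assert m.delta_angle(s, s, 3, 3) == 0.0

    def test_arithmetic(self):
        s1 = self._series([0, 0, 0], [5, 5, 5])
        s2 = self._series([0, 0, 0], [9, 9, 9])
        assert m.delta_angle(s1, s2, 3, 3) == pytest.approx(4.0)

    def test_antisymmetric_under_swap(self):
        s1 = self._series([0, 0, 0], [5, 5, 5])
        s2 = self._series([0, 0, 0], [9, 9, 9])
        assert m.delta_angle(s1, s2, 3, 3) == -m.delta_angle(s2, s1, 3, 3)

    def test_too_few_epochs(self):
        s = self._series([0], [5])
        with pytest.raises(ValueError):
            m.delta_angle(s, s, 1, 1)


class TestFitExponential:
    @pytest.mark.parametrize("rho", [0.05, 0.15, 0.4, 1.0])
    @pytest.mark.parametrize("A", [5.0, 25.0, 30.0])
    def test_recovery_on_noiseless_curves(self, rho, A):
        t = np.arange(1, 31)
        y = A + (0.0 - A) * np.exp(-rho * t)
        rho_hat, a_hat, _ = m.fit_exponential(y, y_pre=0.0)
        assert rho_hat == pytest.approx(rho, rel=0.01)
        assert a_hat == pytest.approx(A, rel=0.01)

    def test_flat_series_slowest_rate_tiebreak(self):
        rho_hat, a_hat, _ = m.fit_exponential([3.0] * 10, y_pre=3.0)
        assert rho_hat == 0.0 and a_hat == 3.0

    def test_fitted_curve_matches_parameters(self):
        t = np.arange(1, 20)
        y = 20 + (2.0 - 20) * np.exp(-0.3 * t)
        rho_hat, a_hat, curve = m.fit_exponential(y, y_pre=2.0)
        np.testing.assert_allclose(curve, y, atol=1e-6)

    def test_too_short_series_errors(self):
        with pytest.raises(ValueError):
            m.fit_exponential([1.0, 2.0, 3.0], y_pre=0.0)


class TestDecompose:
    def _series(self, rot, nofb):
        vals = np.concatenate([rot, nofb])
        phases = [Phase.ROTATION1] * len(rot) + [Phase.NO_FEEDBACK] * len(nofb)
        return m.EpochSeries(values=vals, phases=phases)

    def test_subtraction_identity(self):
        s = self._series(np.full(10, 20.0), np.full(10, 12.0))
        res = m.decompose(s)
        assert res.total_adaptation_deg == 20.0
        assert res.implicit_early_deg == 12.0
        assert res.explicit_deg == pytest.approx(8.0)
        # identity holds exactly by construction
        assert res.explicit_deg + res.implicit_early_deg == res.total_adaptation_deg

    def test_variants_use_stated_epochs(self):
        nofb = np.array([10, 11, 12, 13, 14, 5, 5, 5, 5, 5], float)
        s = self._series(np.full(10, 20.0), nofb)
        res = m.decompose(s)
        assert res.implicit_early_deg == pytest.approx(12.0)
        assert res.implicit_late_deg == pytest.approx(5.0)
        assert res.implicit_full_deg == pytest.approx(nofb.mean())

    def test_all_zero(self):
        res = m.decompose(self._series(np.zeros(10), np.zeros(10)))
        assert res.total_adaptation_deg == res.explicit_deg == 0.0

    def test_missing_phase_errors(self):
        s = m.EpochSeries(values=np.zeros(5), phases=[Phase.ROTATION1] * 5)
        with pytest.raises(ValueError):
            m.decompose(s)

    def test_noiseless_simulated_implicit_matches_latent_state(self, noiseless_session):
        series = m.epoch_average(noiseless_session)
        res = m.decompose(series)
        nofb = noiseless_session.trials[
            noiseless_session.trials["phase"] == Phase.NO_FEEDBACK.value
        ]
        assert res.implicit_early_deg == pytest.approx(nofb["x_i"].iloc[:20].mean(), abs=1e-9)


class TestDecorrelatedMeasures:
    def test_uniform_epochs(self):
        imp, exp = m.decorrelated_measures([10.0] * 6, total=20.0)
        assert (imp, exp) == (10.0, 10.0)

    def test_alternating_epochs(self):
        imp, exp = m.decorrelated_measures([12, 10, 12, 10, 12, 10], total=20.0)
        assert imp == pytest.approx(10.0)
        assert exp == pytest.approx(8.0)

    def test_no_shared_noise_on_white_noise(self):
        """Disjoint epoch sets leave the two measures uncorrelated."""
        rng = np.random.default_rng(5)
        imps, exps = [], []
        for _ in range(2000):
            epochs = rng.normal(10.0, 3.0, 6)
            i, e = m.decorrelated_measures(epochs, total=20.0)
            imps.append(i)
            exps.append(e)
        assert abs(np.corrcoef(imps, exps)[0, 1]) < 0.05

    def test_too_few_epochs(self):
        with pytest.raises(ValueError):
            m.decorrelated_measures([1.0] * 5, total=10.0)


class TestSpontaneousRecoveryPeriods:
    def test_constant_series(self):
        s = m.EpochSeries(values=np.full(100, 7.0), phases=[Phase.BASELINE] * 100)
        out = m.spontaneous_recovery_periods(s)
        assert set(out.values()) == {7.0}

    def test_period_lengths(self):
        vals = np.arange(100, dtype=float)
        s = m.EpochSeries(values=vals, phases=[Phase.BASELINE] * 100)
        out = m.spontaneous_recovery_periods(s)
        assert out["baseline"] == np.mean(vals[0:10])
        assert out["counter_rotation_end"] == np.mean(vals[78:80])
        assert out["no_feedback"] == np.mean(vals[80:100])

    def test_short_series_errors(self):
        s = m.EpochSeries(values=np.zeros(99), phases=[Phase.BASELINE] * 99)
        with pytest.raises(ValueError):
            m.spontaneous_recovery_periods(s)


class TestPreparationTime:
    def test_median_robust_to_outliers(self):
        df = pd.DataFrame(
            {
                "trial": [1, 2, 3, 4, 5, 6, 7, 8],
                "movement_angle_deg": 0.0,
                "phase": ["baseline"] * 4 + ["rotation1"] * 4,
                "reaction_time_ms": [300, 300, 300, 10_000, 360, 360, 360, 10_000],
                "valid": True,
            }
        )
        sess = SessionData(trials=df, paradigm_name="x")
        b, r, change = m.preparation_time_summary(sess)
        assert b == 300.0 and r == 360.0 and change == 60.0

    def test_screen_delay_adjustment_shifts_medians_not_change(self, noiseless_session):
        b0, r0, c0 = m.preparation_time_summary(noiseless_session)
        b1, r1, c1 = m.preparation_time_summary(noiseless_session, adjust_screen_delay=True)
        assert b1 == pytest.approx(b0 - 154.0)
        assert c1 == pytest.approx(c0)

    def test_simulated_strategy_user_has_positive_rt_change(self, standard_schedule):
        sess = v.simulate_session(standard_schedule, v.ParticipantParams(seed=2))
        _, _, change = m.preparation_time_summary(sess)
        assert change > 0


class TestTwoExposureMetrics:
    def test_savings_cohort_positive_metrics(self, savings_schedule):
        cohort = v.simulate_cohort(
            10,
            savings_schedule,
            modifiers=v.simulator.modifiers_for_paradigm("savings"),
            seed=31,
        )
        tab = m.cohort_metrics(cohort)
        assert tab.delta_angle_deg.mean() > 0
        assert tab.delta_rate.mean() > 0

    def test_interference_cohort_negative_metrics(self):
        sched = v.build_paradigm_schedule(v.ParadigmParams(paradigm="interference"), seed=3)
        cohort = v.simulate_cohort(
            10, sched, modifiers=v.simulator.modifiers_for_paradigm("interference"), seed=32
        )
        tab = m.cohort_metrics(cohort)
        assert tab.delta_angle_deg.mean() < 0
        assert tab.delta_rate.mean() < 0

    def test_requires_second_exposure(self, noiseless_session):
        with pytest.raises(ValueError):
            m.two_exposure_metrics(noiseless_session)
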