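"""Cumulative-curve timing on synchronized time courses."""

import numpy as np
import pytest

from cohesion.errors import DataError
from cohesion.synchrony import (
    CumulativeCurve,
    TimecourseSample,
    cell_cycle_periods,
    cohesion_period,
    crossing_time,
    cumulative_curve,
)
from cohesion.synthetic import SimulationConfig, simulate_synchronized_timecourse


def samples_from(times, copies, foci=None, n=1000):
    foci = foci if foci is not None else copies
    return [
        TimecourseSample(t, c, f, n) for t, c, f in zip(times, copies, foci)
    ]


def curve_pair(config, times, n=1000):
    samples, _ = simulate_synchronized_timecourse(config, times, n)
    return (
        cumulative_curve(samples, "copies"),
        cumulative_curve(samples, "foci"),
    )


class TestCumulativeCurve:
    def test_step_input(self):
        times = np.arange(0, 90, 10.0)
        copies = np.where(times < 40, 1.0, 1.8)
        curve = cumulative_curve(samples_from(times, copies), "copies")
        assert curve.cumulative_percent[times < 40].max() == 0.0
        assert curve.cumulative_percent[times >= 40].min() == 100.0

    def test_linear_ramp_t50_at_midpoint(self):
        times = np.arange(0, 90, 10.0)
        copies = np.interp(times, [20, 60], [1.0, 2.0])
        curve = cumulative_curve(samples_from(times, copies), "copies")
        assert crossing_time(curve) == pytest.approx(40.0)
        assert crossing_time(curve, method="linear") == pytest.approx(40.0)

    def test_monotone_normalized_zero_to_hundred(self, wt_config):
        rep, seg = curve_pair(wt_config, np.arange(0, 121, 10.0))
        for curve in (rep, seg):
            assert curve.cumulative_percent[0] == 0.0
            assert curve.cumulative_percent[-1] == 100.0
            assert np.all(np.diff(curve.cumulative_percent) >= 0)

    def test_tracks_generator_truth_cdf(self, wt_config):
        """The normalized curve stays within 5 percentage points of the
        true synchronous-fraction event CDF."""
        from scipy.stats import norm

        times = np.arange(0, 121, 10.0)
        samples, truth = simulate_synchronized_timecourse(wt_config, times, 2000)
        curve = cumulative_curve(samples, "copies")
        a_r, sd = truth["replication_age"], truth["event_sd_minutes"]
        alpha = norm.cdf(-a_r / sd)
        true_cdf = 100 * (norm.cdf((times - a_r) / sd) - alpha) / (1 - alpha)
        assert np.max(np.abs(curve.cumulative_percent - np.clip(true_cdf, 0, 100))) < 5.0

    def test_flat_signal_rejected(self):
        times = np.arange(0, 60, 10.0)
        with pytest.raises(DataError, match="baseline"):
            cumulative_curve(samples_from(times, np.full_like(times, 1.5)), "copies")

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            cumulative_curve(samples_from([0, 10, 20], [1, 1.5, 2]), "copies")


class TestCrossingTime:
    @staticmethod
    def curve(times, percents):
        return CumulativeCurve(
            times=np.asarray(times, float),
            cumulative_percent=np.asarray(percents, float),
            baseline=1.0,
            plateau=2.0,
            synchrony_fraction=1.0,
        )

    def test_interpolation_midpoint(self):
        c = self.curve([0, 30, 40, 80], [0, 40, 60, 100])
        assert crossing_time(c, 50.0) == pytest.approx(35.0)
        assert crossing_time(c, 50.0, method="linear") == pytest.approx(35.0)

    def test_exact_hit_returns_first_occurrence(self):
        c = self.curve([0, 30, 40, 80], [0, 50, 50, 100])
        assert crossing_time(c, 50.0) == 30.0

    def test_level_never_reached(self):
        c = self.curve([0, 10], [0, 40])
        with pytest.raises(DataError, match="never"):
            crossing_time(c, 50.0)

    def test_recovery_bias_below_half_sampling_interval(self):
        errors = []
        for seed in range(50):
            cfg = SimulationConfig(seed=seed)
            times = np.arange(0, 121, 10.0)
            samples, truth = simulate_synchronized_timecourse(cfg, times, 1000)
            curve = cumulative_curve(samples, "copies")
            # the synchronous fraction's median event time is the target
            errors.append(crossing_time(curve) - truth["replication_age"])
        assert abs(np.mean(errors)) < 5.0  # half the 10-min sampling interval


class TestCohesionPeriod:
    def test_identical_curves_give_zero(self, wt_config):
        rep, _ = curve_pair(wt_config, np.arange(0, 121, 10.0))
        result = cohesion_period(rep, rep)
        assert result.cohesion_period == 0.0
        assert not result.negative_cohesion_flag

    def test_wild_type_conditions_recover_printed_period(self):
        recovered = []
        for seed in (1, 2, 3):
            cfg = SimulationConfig(seed=seed, generation_time=119.0, cohesion_minutes=31.0)
            rep, seg = curve_pair(cfg, np.arange(0, 121, 10.0))
            recovered.append(cohesion_period(rep, seg).cohesion_period)
        assert np.mean(recovered) == pytest.approx(31.0, abs=2.0)

    def test_seqa_null_conditions_recover_printed_period(self):
        recovered = []
        for seed in (1, 2, 3):
            cfg = SimulationConfig(seed=seed, generation_time=134.0, cohesion_minutes=12.0)
            rep, seg = curve_pair(cfg, np.arange(0, 121, 10.0))
            recovered.append(cohesion_period(rep, seg).cohesion_period)
        assert np.mean(recovered) == pytest.approx(12.0, abs=2.0)

    def test_perfect_synchrony_recovers_exactly(self):
        cfg = SimulationConfig(
            seed=0, synchrony_fraction=1.0, event_sd_minutes=0.0,
            measurement_noise_sd=0.0, cohesion_minutes=30.0,
        )
        rep, seg = curve_pair(cfg, np.arange(0, 121, 10.0))
        result = cohesion_period(rep, seg)
        assert result.cohesion_period == pytest.approx(30.0, abs=1e-9)

    def test_shift_equivariance(self, wt_config):
        rep, seg = curve_pair(wt_config, np.arange(0, 121, 10.0))
        shift = 17.0
        rep2 = CumulativeCurve(rep.times + shift, rep.cumulative_percent,
                               rep.baseline, rep.plateau, rep.synchrony_fraction)
        seg2 = CumulativeCurve(seg.times + shift, seg.cumulative_percent,
                               seg.baseline, seg.plateau, seg.synchrony_fraction)
        r1, r2 = cohesion_period(rep, seg), cohesion_period(rep2, seg2)
        assert r2.t50_replication == pytest.approx(r1.t50_replication + shift)
        assert r2.cohesion_period == pytest.approx(r1.cohesion_period)

    def test_parameter_recovery_grid(self):
        """Bias <= 2 min and SD <= 3 min over cohesion durations and
        synchrony fractions, at 1000 cells/point and 10-min sampling."""
        for delta in (5.0, 20.0, 60.0):
            for phi in (0.75, 0.85):
                recovered = []
                for seed in (1, 2, 3):
                    cfg = SimulationConfig(
                        seed=seed, cohesion_minutes=delta, synchrony_fraction=phi
                    )
                    rep, seg = curve_pair(cfg, np.arange(0, 121, 10.0))
                    recovered.append(cohesion_period(rep, seg).cohesion_period)
                assert abs(np.mean(recovered) - delta) <= 2.0
                assert np.std(recovered) <= 3.0


class TestCellCyclePeriods:
    @staticmethod
    def curve_at(t50, times=np.arange(0, 121, 10.0)):
        # sigmoid sampled on the grid with its 50% crossing exactly at t50
        percent = 100.0 / (1.0 + np.exp(-(times - t50) / 2.0))
        percent = (percent - percent[0]) / (percent[-1] - percent[0]) * 100.0
        return CumulativeCurve(times, percent, 1.0, 2.0, 1.0)

    def test_definition_arithmetic(self):
        b, c, d = cell_cycle_periods(self.curve_at(10.0), self.curve_at(70.0), 119.0)
        assert (b, c, d) == pytest.approx((10.0, 60.0, 49.0), abs=0.5)
        assert b + c + d == pytest.approx(119.0)

    def test_termination_at_division_boundary(self):
        b, c, d = cell_cycle_periods(self.curve_at(10.0), self.curve_at(60.0), 60.0)
        assert d == pytest.approx(0.0, abs=0.5)

    def test_ter_before_oric_rejected(self):
        with pytest.raises(DataError):
            cell_cycle_periods(self.curve_at(70.0), self.curve_at(10.0), 119.0)

    def test_recovery_from_synthetic_curves(self):
        """B/C/D from simulated oriC and ter time courses, each within
        +/-2 min of the injected truth."""
        tau, b_true, c_true = 119.0, 12.0, 65.0
        ter_age = b_true + c_true
        recovered = []
        for seed in (1, 2, 3):
            ori_cfg = SimulationConfig(
                seed=seed, generation_time=tau, locus_replication_age=b_true,
                cohesion_minutes=0.0,
            )
            ter_cfg = SimulationConfig(
                seed=seed + 100, generation_time=tau, locus_replication_age=ter_age,
                cohesion_minutes=0.0,
            )
            times = np.arange(0, 121, 10.0)
            ori_s, _ = simulate_synchronized_timecourse(ori_cfg, times, 1000)
            ter_s, _ = simulate_synchronized_timecourse(ter_cfg, times, 1000)
            recovered.append(
                cell_cycle_periods(
                    cumulative_curve(ori_s, "copies"),
                    cumulative_curve(ter_s, "copies"),
                    tau,
                )
            )
        mean = np.mean(recovered, axis=0)
        assert mean == pytest.approx((b_true, c_true, tau - ter_age), abs=2.0)
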