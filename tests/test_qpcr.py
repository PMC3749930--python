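"""qPCR ratios, runoff reconstruction, standard curves and ΔΔCt."""

import math

import numpy as np
import pytest

from cohesion.errors import DataError
from cohesion.qpcr import (
    ChipSample,
    QpcrRecord,
    RunoffHistogram,
    chip_fold_enrichment,
    copies_per_cell_from_runoff,
    relative_ratio,
    roadblock_ratio,
    standard_curve_quantification,
)
from cohesion.synthetic import SimulationConfig, simulate_qpcr, simulate_runoff_histogram


def rec(ct, target="x", sample="s", reps=3, efficiency=1.0):
    return QpcrRecord(sample, target, tuple([ct] * reps), efficiency)


class TestRelativeRatio:
    def test_equal_cts_give_unity(self):
        assert relative_ratio(rec(20.0), rec(20.0, "ref")) == 1.0

    def test_one_cycle_is_one_doubling(self):
        assert relative_ratio(rec(19.0), rec(20.0, "ref")) == pytest.approx(2.0)

    def test_gln_to_oric_printed_ratio(self):
        # the Ct gap that encodes the wild-type 0.98 gln:oriC frequency
        gap = -math.log2(0.98)
        assert relative_ratio(rec(20.0 + gap), rec(20.0, "ref")) == pytest.approx(0.98)

    def test_brute_force_oracle(self, rng):
        for _ in range(20):
            e = rng.uniform(0.7, 1.0)
            ct_t, ct_r = rng.uniform(15, 30, 2)
            expected = (1 + e) ** (-(ct_t - ct_r))
            got = relative_ratio(rec(ct_t, efficiency=e), rec(ct_r, "ref", efficiency=e))
            assert got == pytest.approx(expected)

    def test_multiplicative_chaining(self):
        a, b, c = rec(19.0, "a"), rec(20.0, "b"), rec(21.5, "c")
        assert relative_ratio(a, c) == pytest.approx(
            relative_ratio(a, b) * relative_ratio(b, c)
        )

    def test_replicate_spread_warns(self):
        noisy = QpcrRecord("s", "x", (20.0, 20.9, 20.1))
        with pytest.warns(UserWarning, match="spread"):
            relative_ratio(noisy, rec(20.0, "ref"))

    def test_generator_round_trip_noise_free(self):
        cfg = SimulationConfig(seed=1, ct_noise_sd=0.0)
        records, _ = simulate_qpcr(cfg, {"gln": 2.0, "oriC": 1.0})
        by = {r.target_locus: r for r in records}
        assert by["gln"].mean_ct - by["oriC"].mean_ct == pytest.approx(-1.0)
        assert relative_ratio(by["gln"], by["oriC"]) == pytest.approx(2.0)

    def test_generator_recovery_with_noise(self):
        # mean over repeated samples converges on the injected 0.98
        ratios = []
        for seed in range(30):
            cfg = SimulationConfig(seed=seed, ct_noise_sd=0.1)
            records, _ = simulate_qpcr(cfg, {"gln": 0.98, "oriC": 1.0})
            by = {r.target_locus: r for r in records}
            ratios.append(relative_ratio(by["gln"], by["oriC"]))
        se = np.std(ratios, ddof=1) / math.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 0.98) < 3 * se + 1e-3


class TestRunoff:
    def test_single_peak_two_origins(self):
        # a lone peak needs the one-chromosome calibration to be labelled
        cfg = SimulationConfig(seed=0, runoff_peak_cv=0.05)
        hist, _ = simulate_runoff_histogram(cfg, {2: 1.0}, n_cells=5000)
        q = copies_per_cell_from_runoff(hist, 1.0, unit_fluorescence=100.0)
        assert q.origins_per_cell == pytest.approx(2.0, abs=0.02)
        # uncalibrated, the parsimony convention reads the same peak as
        # one origin at twice the unit fluorescence
        q2 = copies_per_cell_from_runoff(hist, 1.0)
        assert q2.origins_per_cell == pytest.approx(1.0, abs=0.01)
        assert q2.mu1 == pytest.approx(2 * q.mu1, rel=0.02)

    def test_weighted_mean_worked_example(self):
        # 94% of mass at two origins, 6% at one, times the 0.98 ratio
        cfg = SimulationConfig(seed=4, runoff_peak_cv=0.06)
        hist, _ = simulate_runoff_histogram(cfg, {1: 0.06, 2: 0.94}, n_cells=50000)
        q = copies_per_cell_from_runoff(hist, 0.98)
        assert q.peak_masses[1] == pytest.approx(0.06, abs=0.01)
        assert q.peak_masses[2] == pytest.approx(0.94, abs=0.01)
        assert q.copies_per_cell == pytest.approx((2 * 0.94 + 1 * 0.06) * 0.98, abs=0.02)

    def test_seeded_recovery(self):
        cfg = SimulationConfig(seed=9, runoff_peak_cv=0.08)
        hist, truth = simulate_runoff_histogram(cfg, {1: 0.06, 2: 0.94}, n_cells=10000)
        q = copies_per_cell_from_runoff(hist, 1.0)
        assert q.origins_per_cell == pytest.approx(truth["true_origins_per_cell"], abs=0.03)

    def test_mass_conservation(self):
        cfg = SimulationConfig(seed=1)
        hist, _ = simulate_runoff_histogram(cfg, {1: 0.2, 2: 0.8}, n_cells=4000)
        assert hist.counts.sum() == 4000
        q = copies_per_cell_from_runoff(hist, 1.0)
        assert sum(q.peak_masses.values()) == pytest.approx(1.0)
        assert 0.0 <= q.unassigned_fraction <= 1.0

    def test_histogram_validation(self):
        with pytest.raises(DataError):
            RunoffHistogram(bin_centers=[1.0, 1.0, 2.0], counts=[1, 1, 1])
        with pytest.raises(DataError):
            RunoffHistogram(bin_centers=[1.0, 2.0], counts=[0, 0])


class TestStandardCurve:
    def test_perfect_doubling_slope_implies_full_efficiency(self):
        slope = -1.0 / math.log10(2.0)
        points = [(q, 30.0 + slope * q) for q in (-1.0, 0.0, 1.0, 2.0)]
        result = standard_curve_quantification(points, sample_ct=30.0 + slope * 0.5)
        assert result.implied_efficiency == pytest.approx(1.0)
        assert result.quantity == pytest.approx(10**0.5)
        assert result.r_squared == pytest.approx(1.0)

    def test_noisy_curve_recovers_quantity(self, rng):
        e = 0.95
        slope = -1.0 / math.log10(1 + e)
        points = [(q, 30.0 + slope * q + rng.normal(0, 0.05)) for q in np.linspace(-1, 2, 8)]
        true_q = 3.0
        sample_ct = 30.0 + slope * math.log10(true_q)
        result = standard_curve_quantification(points, sample_ct)
        assert result.quantity == pytest.approx(true_q, rel=0.05)

    def test_extrapolation_warns(self):
        slope = -3.3219
        points = [(q, 30.0 + slope * q) for q in (0.0, 1.0, 2.0)]
        with pytest.warns(UserWarning, match="extrapolat"):
            standard_curve_quantification(points, sample_ct=40.0)

    def test_agreement_with_runoff_route(self):
        """Absolute quantification agrees with the runoff-based copy
        number within the assay's stated +/-0.08 copies."""
        cfg = SimulationConfig(seed=6)
        hist, _ = simulate_runoff_histogram(cfg, {1: 0.06, 2: 0.94}, n_cells=20000)
        runoff_copies = copies_per_cell_from_runoff(hist, 0.98).copies_per_cell
        # calibrator standard curve measuring the same true quantity
        true_copies = (2 * 0.94 + 1 * 0.06) * 0.98
        slope = -1.0 / math.log10(2.0)
        points = [(q, 25.0 + slope * q) for q in np.linspace(-1, 1, 5)]
        sample_ct = 25.0 + slope * math.log10(true_copies)
        absolute = standard_curve_quantification(points, sample_ct).quantity
        assert abs(absolute - runoff_copies) <= 0.08


class TestRoadblock:
    def test_free_fork_passage(self):
        result = roadblock_ratio(rec(20.0, "up"), rec(20.0, "down"))
        assert result.ratio == 1.0 and not result.flagged

    def test_threefold_block_flagged(self):
        up = rec(20.0 - math.log2(3.0), "up")
        result = roadblock_ratio(up, rec(20.0, "down"))
        assert result.ratio == pytest.approx(3.0)
        assert result.flagged

    def test_twofold_synthetic_block(self):
        cfg = SimulationConfig(seed=2, ct_noise_sd=0.05)
        records, _ = simulate_qpcr(cfg, {"up": 2.0, "down": 1.0})
        by = {r.target_locus: r for r in records}
        result = roadblock_ratio(by["up"], by["down"])
        assert result.ratio == pytest.approx(2.0, abs=0.2)
        assert result.flagged


class TestChipEnrichment:
    def test_reference_self_normalizes_to_exactly_one(self):
        samples = [
            ChipSample("dnaB", 28.0, 20.0),
            ChipSample("gln", 28.0 - math.log2(10.0), 20.0),
            ChipSample("oriC", 28.0 - math.log2(25.0), 20.0),
        ]
        table = chip_fold_enrichment(samples, "dnaB").set_index("locus")
        assert table.loc["dnaB", "fold"] == 1.0
        assert table.loc["gln", "fold"] == pytest.approx(10.0)
        assert table.loc["oriC", "fold"] == pytest.approx(25.0)

    def test_global_ct_shift_cancels(self):
        base = [
            ChipSample("dnaB", 28.0, 20.0),
            ChipSample("gln", 24.3, 19.5),
            ChipSample("ter", 27.8, 20.2),
        ]
        shifted = [ChipSample(s.locus, s.ct_ip + 3.7, s.ct_input + 3.7) for s in base]
        t1 = chip_fold_enrichment(base, "dnaB")
        t2 = chip_fold_enrichment(shifted, "dnaB")
        assert np.allclose(t1["fold"], t2["fold"])

    def test_replicates_averaged_before_differencing(self):
        samples = [ChipSample("dnaB", 28.0 + d, 20.0) for d in (-0.3, 0.0, 0.3)]
        samples += [ChipSample("gln", 25.0 + d, 20.0) for d in (-0.1, 0.0, 0.1)]
        table = chip_fold_enrichment(samples, "dnaB").set_index("locus")
        assert table.loc["gln", "fold"] == pytest.approx(2.0**3.0)

    def test_missing_reference_rejected(self):
        with pytest.raises(DataError, match="reference"):
            chip_fold_enrichment([ChipSample("gln", 25.0, 20.0)], "dnaB")
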