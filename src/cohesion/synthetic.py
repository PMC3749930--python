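"""Seeded generators for every input the analysis stages consume.

Each generator is a pure function of its configuration and seed:
identical seeds give identical outputs.  Alongside the simulated data,
every generator returns a machine-readable truth record carrying the
injected ground-truth values, so recovery can be scored without
re-deriving it.

Defaults reproduce the study conditions of the slow-growth wild-type
experiments: 119-min doubling time (minimal alanine, 30°C), a locus
replicated early enough to give 1.9 copies per cell, a 31-min cohesion
period, 80% synchrony from the baby machine (the method yields 75–85%),
a 1.4% whole-cell detection-failure probability, 5% non-expressing
cells (normal range 2–8%), 0.1-cycle Ct noise, 8% runoff-peak CV, and
two-phase focus separation (0.4 µm/min fast phase, then 0.02 µm/min
cell elongation) censored at the 0.23 µm resolution limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from cohesion.errors import DataError, DomainError
from cohesion.foci_qc import CellObservation
from cohesion.genomics import GenomeTrack, LocusAnnotation, motif_positions, moving_average, window_density
from cohesion.population_model import CellCycleParams, sample_ages
from cohesion.qpcr import ChipSample, QpcrRecord, RunoffHistogram
from cohesion.synchrony import TimecourseSample
from cohesion.timelapse import RESOLUTION_LIMIT_UM, Trajectory

__all__ = [
    "SimulationConfig",
    "simulate_async_population",
    "simulate_synchronized_timecourse",
    "simulate_qpcr",
    "simulate_chip",
    "simulate_runoff_histogram",
    "simulate_genome",
    "simulate_timelapse",
    "simulate_stationary_cells",
    "simulate_distance_snapshot",
]

#: Default replication age fraction a_r/tau, chosen so the closed-form
#: copies/cell equals the wild-type 1.9: a_r/tau = 1 - log2(1.9).
WT_REPLICATION_AGE_FRACTION = 1.0 - math.log2(1.9)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and noise model for all generators."""

    seed: int = 0
    # cell cycle
    generation_time: float = 119.0
    locus_name: str = "gln"
    locus_replication_age: float | None = None  # default: WT fraction of tau
    cohesion_minutes: float = 31.0
    # baby-machine synchrony
    synchrony_fraction: float = 0.80
    event_sd_minutes: float = 5.0
    measurement_noise_sd: float = 0.02
    # detection
    whole_cell_miss: float = 0.014
    per_focus_miss: float = 0.0
    non_expressing_fraction: float = 0.05
    # fluorescence model (arbitrary units; log-separable modes)
    expressing_fluorescence: float = 100.0
    expressing_fluorescence_cv: float = 0.10
    non_expressing_fluorescence: float = 10.0
    non_expressing_fluorescence_cv: float = 0.15
    # qPCR
    qpcr_efficiency: float = 1.0
    ct_noise_sd: float = 0.1
    ct_intercept: float = 25.0
    # runoff flow cytometry
    runoff_peak_cv: float = 0.08
    runoff_unit_fluorescence: float = 100.0
    # time lapse
    fast_velocity: float = 0.4
    fast_duration: float = 2.5
    elongation_rate: float = 0.02
    frame_interval: float = 10.0
    position_noise_sd: float = 0.03
    resolution_limit: float = RESOLUTION_LIMIT_UM
    # genome
    genome_length: int = 1_000_000
    snap_gatc_multiplier: float = 3.0

    def __post_init__(self) -> None:
        for name in ("whole_cell_miss", "per_focus_miss", "non_expressing_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DomainError(f"{name} must be a probability, got {v}")
        if not 0 < self.synchrony_fraction <= 1:
            raise DomainError("synchrony_fraction must be in (0, 1]")
        if self.generation_time <= 0:
            raise DomainError("generation_time must be positive")

    @property
    def replication_age(self) -> float:
        if self.locus_replication_age is not None:
            return self.locus_replication_age
        return WT_REPLICATION_AGE_FRACTION * self.generation_time

    def cell_cycle_params(self) -> CellCycleParams:
        return CellCycleParams(
            generation_time=self.generation_time,
            locus_replication_age=self.replication_age,
            cohesion_duration=self.cohesion_minutes,
        )


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    # salt decorrelates generators sharing one config seed
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def _fluorescence(rng, mean: float, cv: float, n: int) -> np.ndarray:
    sigma = math.sqrt(math.log(1 + cv**2))
    mu = math.log(mean) - sigma**2 / 2
    return rng.lognormal(mu, sigma, size=n)


def simulate_async_population(
    config: SimulationConfig,
    n_cells: int,
) -> tuple[list[CellObservation], dict]:
    """Asynchronous exponential-phase population for the batch assay.

    Cell ages follow the steady-state exponential age distribution; a
    cell older than the replication age carries 2 locus copies, and
    shows 2 foci once cohesion has resolved.  Whole-cell detection
    failures zero the focus count, per-focus thinning (off by default)
    drops foci independently, and a configured fraction of
    non-expressing cells (zero foci, low background fluorescence) is
    mixed in.  The truth record carries the exact pre-thinning means.
    """
    rng = _rng(config, 1)
    tau = config.generation_time
    a_r = config.replication_age
    split_age = a_r + config.cohesion_minutes
    wraparound = split_age > tau

    ages = sample_ages(n_cells, tau, rng)
    copies = 1 + (ages >= a_r).astype(int)
    foci_true = 1 + (ages >= split_age).astype(int)  # all 1 when wraparound

    # detection layer
    observed = foci_true.copy()
    miss = rng.random(n_cells) < config.whole_cell_miss
    observed[miss] = 0
    if config.per_focus_miss > 0:
        kept = rng.binomial(observed, 1.0 - config.per_focus_miss)
        observed = kept
    fluor = _fluorescence(
        rng, config.expressing_fluorescence, config.expressing_fluorescence_cv, n_cells
    )

    cells = [
        CellObservation(cell_id=f"cell{i:06d}", background_fluorescence=float(fluor[i]),
                        focus_count=int(observed[i]))
        for i in range(n_cells)
    ]
    n_nonexpr = int(round(config.non_expressing_fraction * n_cells))
    if n_nonexpr:
        dark = _fluorescence(
            rng, config.non_expressing_fluorescence, config.non_expressing_fluorescence_cv,
            n_nonexpr,
        )
        cells += [
            CellObservation(cell_id=f"dark{i:06d}", background_fluorescence=float(dark[i]),
                            focus_count=0)
            for i in range(n_nonexpr)
        ]
        perm = rng.permutation(len(cells))
        cells = [cells[j] for j in perm]

    truth = {
        "seed": config.seed,
        "generation_time": tau,
        "replication_age": a_r,
        "cohesion_minutes": config.cohesion_minutes,
        "wraparound": wraparound,
        "true_mean_copies": float(copies.mean()),
        "true_mean_foci": float(foci_true.mean()),
        "true_copies_per_focus": float(copies.mean() / foci_true.mean()),
        "whole_cell_miss": config.whole_cell_miss,
        "non_expressing_fraction": config.non_expressing_fraction,
        "n_expressing": n_cells,
    }
    return cells, truth


def simulate_stationary_cells(
    config: SimulationConfig,
    n_cells: int,
    chromosomes_per_cell: int = 2,
) -> tuple[list[CellObservation], dict]:
    """Cohesion-free stationary-phase cells for validating the
    detection correction: every cell has ``chromosomes_per_cell`` fully
    segregated foci, thinned only by whole-cell detection failure."""
    rng = _rng(config, 2)
    miss = rng.random(n_cells) < config.whole_cell_miss
    fluor = _fluorescence(
        rng, config.expressing_fluorescence, config.expressing_fluorescence_cv, n_cells
    )
    cells = [
        CellObservation(
            cell_id=f"stat{i:06d}",
            background_fluorescence=float(fluor[i]),
            focus_count=0 if miss[i] else chromosomes_per_cell,
        )
        for i in range(n_cells)
    ]
    truth = {
        "seed": config.seed,
        "chromosomes_per_cell": chromosomes_per_cell,
        "whole_cell_miss": config.whole_cell_miss,
    }
    return cells, truth


def simulate_synchronized_timecourse(
    config: SimulationConfig,
    sample_times: np.ndarray,
    n_cells_per_sample: int = 1000,
) -> tuple[list[TimecourseSample], dict]:
    """Baby-machine time course of mean copies and foci per cell.

    The synchronous fraction replicates the locus at a Gaussian event
    time centered on the replication age (SD ``event_sd_minutes``,
    negative draws resampled) and segregates it one cohesion period
    later.  The asynchronous contaminant fraction is stationary: those
    cells keep cycling with steady-state exponential-law ages advancing
    modulo the generation time, so their event times are uniform over
    one generation and their ensemble mean contributes a constant
    offset to both curves rather than a trend.  Sampled means carry the
    per-cell binomial noise plus an additive measurement noise.
    """
    rng = _rng(config, 3)
    tau = config.generation_time
    a_r = config.replication_age
    delta = config.cohesion_minutes
    phi = config.synchrony_fraction
    split_age = a_r + delta
    times = np.asarray(sample_times, dtype=float)

    samples = []
    for t in times:
        n = n_cells_per_sample
        sync = rng.random(n) < phi
        # synchronous newborns: one replication event, then one split
        events = _truncated_normal(rng, a_r, config.event_sd_minutes, n)
        copies = 1 + (t >= events).astype(int)
        foci = 1 + (t >= events + delta).astype(int)
        # stationary contaminants: age advances mod tau
        bg_age = (sample_ages(n, tau, rng) + t) % tau
        copies = np.where(sync, copies, 1 + (bg_age >= a_r).astype(int))
        foci = np.where(sync, foci, 1 + (bg_age >= split_age).astype(int))
        mean_copies = copies.mean() + rng.normal(0.0, config.measurement_noise_sd)
        mean_foci = foci.mean() + rng.normal(0.0, config.measurement_noise_sd)
        samples.append(
            TimecourseSample(
                time_after_birth=float(t),
                mean_copy_number=float(mean_copies),
                mean_foci=float(mean_foci),
                n_cells=n_cells_per_sample,
            )
        )
    truth = {
        "seed": config.seed,
        "generation_time": tau,
        "replication_age": a_r,
        "cohesion_minutes": delta,
        "synchrony_fraction": phi,
        "event_sd_minutes": config.event_sd_minutes,
    }
    return samples, truth


def _truncated_normal(rng, mean: float, sd: float, n: int) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, n)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def simulate_qpcr(
    config: SimulationConfig,
    true_quantities: dict[str, float],
    sample_id: str = "sample",
    replicates: int = 3,
) -> tuple[list[QpcrRecord], dict]:
    """Ct tables from true template quantities.

    Ct = intercept - log_{1+E}(quantity) + Gaussian noise, in
    ``replicates`` technical replicates per target.
    """
    rng = _rng(config, 4)
    base = 1.0 + config.qpcr_efficiency
    records = []
    for target, q in true_quantities.items():
        if not q > 0:
            raise DataError(f"{target}: quantity must be positive")
        true_ct = config.ct_intercept - math.log(q, base)
        cts = true_ct + rng.normal(0.0, config.ct_noise_sd, replicates)
        records.append(
            QpcrRecord(
                sample_id=sample_id,
                target_locus=target,
                replicate_cts=tuple(float(c) for c in cts),
                amplification_efficiency=config.qpcr_efficiency,
            )
        )
    truth = {"seed": config.seed, "true_quantities": dict(true_quantities)}
    return records, truth


def simulate_chip(
    config: SimulationConfig,
    fold_enrichments: dict[str, float],
    reference_locus: str = "dnaB",
    replicates: int = 3,
) -> tuple[list[ChipSample], dict]:
    """IP/input Ct pairs with injected fold enrichments over a reference.

    The reference locus has fold 1 by construction; an enriched locus
    crosses threshold log2(fold) cycles earlier in the IP channel.
    """
    if reference_locus not in fold_enrichments:
        raise DataError(f"reference locus {reference_locus!r} missing from folds")
    rng = _rng(config, 5)
    base_delta = 8.0  # IP is dilute relative to input
    samples = []
    for locus, fold in fold_enrichments.items():
        if not fold > 0:
            raise DataError(f"{locus}: fold must be positive")
        for _ in range(replicates):
            ct_input = config.ct_intercept + rng.normal(0.0, config.ct_noise_sd)
            ct_ip = (
                ct_input
                + base_delta
                - math.log2(fold / fold_enrichments[reference_locus])
                + rng.normal(0.0, config.ct_noise_sd)
            )
            samples.append(ChipSample(locus=locus, ct_ip=float(ct_ip), ct_input=float(ct_input)))
    truth = {"seed": config.seed, "fold_enrichments": dict(fold_enrichments)}
    return samples, truth


def simulate_runoff_histogram(
    config: SimulationConfig,
    origins_distribution: dict[int, float],
    n_cells: int = 10000,
    n_bins: int = 256,
) -> tuple[RunoffHistogram, dict]:
    """Runoff DNA-content histogram with Gaussian 2^n peaks.

    Each cell's fluorescence is Gaussian around n * unit fluorescence
    with a shared coefficient of variation; peak masses follow the
    supplied origin-count distribution (support {1, 2, 4, 8}).
    """
    if not origins_distribution:
        raise DataError("empty origins distribution")
    ns = np.array(sorted(origins_distribution), dtype=int)
    if not set(ns.tolist()) <= {1, 2, 4, 8}:
        raise DataError("origin counts must be in {1, 2, 4, 8}")
    probs = np.array([origins_distribution[int(n)] for n in ns], dtype=float)
    probs = probs / probs.sum()
    rng = _rng(config, 6)
    origins = rng.choice(ns, size=n_cells, p=probs)
    mu = origins * config.runoff_unit_fluorescence
    fl = rng.normal(mu, config.runoff_peak_cv * mu)
    lo = 0.0
    hi = float((ns.max() + 1) * config.runoff_unit_fluorescence)
    counts, edges = np.histogram(fl, bins=n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    keep = np.ones_like(counts, dtype=bool)  # keep empty bins; centers stay increasing
    hist = RunoffHistogram(bin_centers=centers[keep], counts=counts[keep])
    truth = {
        "seed": config.seed,
        "true_origins_per_cell": float(np.dot(ns, probs)),
        "distribution": {int(n): float(p) for n, p in zip(ns, probs)},
        "cv": config.runoff_peak_cv,
    }
    return hist, truth


def simulate_genome(
    config: SimulationConfig,
    snap_windows: list[tuple[int, int]] | None = None,
    n_loci: int = 8,
    locus_window_bp: int = 5000,
) -> tuple[str, list[LocusAnnotation], GenomeTrack, dict]:
    """Random circular genome with GATC-enriched snap regions.

    The background sequence is uniform-random (spontaneous GATC density
    ~length/4^4 sites per bp).  When ``snap_windows`` is given, extra
    GATC sites are planted inside those windows so the local density is
    approximately ``snap_gatc_multiplier`` times background (broad
    snap-domain geometry).  Independently, ``n_loci`` characterized
    loci are planted at well-separated positions, each centered in its
    own ``locus_window_bp`` window carrying a *graded* enrichment
    between 1x and the snap multiplier, with the cohesion duration a
    monotone function of that local enrichment — long-cohesion snap
    loci sit in locally GATC-dense DNA.  Because the planted signal
    lives at the locus-window scale, smoothing at that scale preserves
    the cohesion-vs-binding ranking better than a much wider window.

    The returned binding track is the 5-kb smoothed GATC density plus
    proportional noise.
    """
    L = config.genome_length
    if L < 10_000:
        raise DataError("genome length must be >= 10 kb")
    rng = _rng(config, 7)
    seq = rng.choice(np.array(list("ACGT")), size=L)

    background_rate = 1.0 / 256.0  # expected spontaneous GATC per bp

    if snap_windows:
        extra_rate = (config.snap_gatc_multiplier - 1.0) * background_rate
        if extra_rate > 0:
            for start, end in snap_windows:
                n_extra = rng.poisson(extra_rate * (end - start))
                sites = rng.integers(start, end - 4, size=n_extra)
                for s in sites:
                    seq[s : s + 4] = list("GATC")

    # graded per-locus enrichment: multipliers spaced between 1 (typical
    # non-snap DNA) and the snap multiplier; cohesion maps monotonically
    # from the 7-10 min non-snap band to the 19-30 min snap band
    multipliers = np.linspace(1.0, max(config.snap_gatc_multiplier, 1.0), n_loci)
    spacing = L // n_loci
    loci = []
    for i, mult in enumerate(multipliers):
        center = int(spacing * i + spacing // 2)
        start = max(center - locus_window_bp // 2, 0)
        end = min(center + locus_window_bp // 2, L - 4)
        n_extra = rng.poisson((mult - 1.0) * background_rate * (end - start))
        for s in rng.integers(start, end - 4, size=n_extra):
            seq[s : s + 4] = list("GATC")
        frac = (mult - 1.0) / max(config.snap_gatc_multiplier - 1.0, 1e-9)
        cohesion = 7.0 + frac * (30.0 - 7.0)
        loci.append(
            LocusAnnotation(
                name=f"locus{i:02d}",
                position=center,
                cohesion_minutes=float(cohesion),
                locus_class="snap" if cohesion >= 19.0 else "non-snap",
            )
        )
    sequence = "".join(seq.tolist())

    scan = motif_positions(sequence, "GATC", circular=True)
    density = window_density(scan.positions, L, window_bp=1000)
    smooth = moving_average(density, window_bp=5000)
    noisy = GenomeTrack(
        genome_length=L,
        positions=smooth.positions,
        values=smooth.values + rng.normal(0.0, 0.05 * max(smooth.values.std(), 1e-9),
                                          size=len(smooth.values)),
        window_bp=5000,
        circular=True,
    )

    truth = {
        "seed": config.seed,
        "snap_windows": [list(w) for w in snap_windows] if snap_windows else [],
        "snap_gatc_multiplier": config.snap_gatc_multiplier,
        "locus_window_bp": locus_window_bp,
        "locus_multipliers": [float(m) for m in multipliers],
        "total_gatc": int(len(scan.positions)),
    }
    return sequence, loci, noisy, truth


def simulate_timelapse(
    config: SimulationConfig,
    n_cells: int = 10,
    n_frames: int = 13,
) -> tuple[list[Trajectory], dict]:
    """Two-phase focus-separation trajectories.

    Per cell, a split time is drawn uniformly within the first third of
    the movie; the true inter-sister distance then grows at the fast
    velocity for the fast duration and at the elongation rate
    afterwards.  Focus positions get isotropic Gaussian noise, and any
    frame where the (noisy) pair is closer than the resolution limit is
    emitted as a single merged focus.
    """
    rng = _rng(config, 8)
    dt = config.frame_interval
    times = np.arange(n_frames) * dt
    movie_len = times[-1]
    trajs = []
    split_times = rng.uniform(0.2 * movie_len, 0.35 * movie_len, n_cells)
    for i in range(n_cells):
        t_split = float(split_times[i])
        frames: list[list[tuple[float, float]]] = []
        y0 = 0.5
        for t in times:
            if t < t_split:
                frames.append([(0.0 + rng.normal(0, config.position_noise_sd), y0)])
                continue
            dt_post = t - t_split
            d_true = config.fast_velocity * min(dt_post, config.fast_duration)
            if dt_post > config.fast_duration:
                d_true += config.elongation_rate * (dt_post - config.fast_duration)
            p1 = np.array([-d_true / 2.0, y0]) + rng.normal(0, config.position_noise_sd, 2)
            p2 = np.array([+d_true / 2.0, y0]) + rng.normal(0, config.position_noise_sd, 2)
            if float(np.hypot(*(p2 - p1))) < config.resolution_limit:
                mid = (p1 + p2) / 2.0
                frames.append([(float(mid[0]), float(mid[1]))])
            else:
                frames.append([(float(p1[0]), float(p1[1])), (float(p2[0]), float(p2[1]))])
        trajs.append(
            Trajectory(
                cell_id=f"tl{i:04d}",
                frame_times=times.copy(),
                foci_per_frame=frames,
                resolution_limit=config.resolution_limit,
            )
        )
    truth = {
        "seed": config.seed,
        "split_times": [float(t) for t in split_times],
        "fast_velocity": config.fast_velocity,
        "fast_duration": config.fast_duration,
        "elongation_rate": config.elongation_rate,
        "frame_interval": dt,
    }
    return trajs, truth


def simulate_distance_snapshot(
    config: SimulationConfig,
    n_cells: int = 500,
    component_means: tuple[float, ...] = (0.6, 1.9),
    component_weights: tuple[float, ...] | None = None,
    component_sd: float = 0.15,
) -> tuple[list[CellObservation], dict]:
    """Snapshot of two-focus cells with mixture-distributed inter-focus
    distances, for distance-distribution summaries.

    The default two components mirror the two-step separation pattern
    of non-snap loci (a first separation to ~0.6 µm and a later one to
    ~1.9 µm); a single component gives a unimodal population.
    """
    rng = _rng(config, 9)
    k = len(component_means)
    w = np.full(k, 1.0 / k) if component_weights is None else np.asarray(component_weights, float)
    w = w / w.sum()
    comp = rng.choice(k, size=n_cells, p=w)
    d = rng.normal(np.asarray(component_means)[comp], component_sd)
    d = np.clip(d, config.resolution_limit, None)
    cells = [
        CellObservation(
            cell_id=f"snap{i:05d}",
            background_fluorescence=config.expressing_fluorescence,
            focus_count=2,
            focus_positions=((0.0, 0.5), (float(d[i]), 0.5)),
        )
        for i in range(n_cells)
    ]
    truth = {
        "seed": config.seed,
        "component_means": [float(m) for m in component_means],
        "component_weights": [float(x) for x in w],
        "component_sd": component_sd,
    }
    return cells, truth
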