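# Methods

This note documents the models, estimators and numerical choices behind
the `cohesion` package, and what its synthetic-data generators do and do
not emulate.

## The cohesion observable

In *E. coli*, a chromosomal locus tagged with a fluorescent
repressor–operator system (FROS) appears as one focus until its two
newly replicated sister copies separate beyond the ~230 nm resolution
limit of light microscopy. The interval between locus replication and
focus splitting is the **cohesion period** Δ (minutes). Two independent
measurement routes are implemented:

1. **Batch (asynchronous) route** — compare the population-mean locus
   copy number against the corrected mean number of resolvable foci.
2. **Synchronized route** — follow newborn cells from a baby machine
   and read the time interval between the copy-number and focus-count
   cumulative curves.

## Exponential-age population model

In steady-state exponential growth the cell-age density is
f(a) = (2 ln2/τ)·2^(−a/τ) on [0, τ], with τ the doubling time: newborns
outnumber dividing cells two to one. For a locus replicated at cell age
a_r whose sisters split at age a_r + Δ,

- copies/cell  N = 2^(1 − a_r/τ)
- foci/cell    F = 2^(1 − (a_r + Δ)/τ)
- copies/focus N/F = 2^(Δ/τ), inverted as Δ = τ·log₂(N/F).

The a_r term cancels in the ratio, which is why the batch statistic
needs no cell-cycle mapping. The closed forms assume a single
replication round per cycle and Δ resolved before division
(a_r + Δ ≤ τ); parameters outside that regime raise a typed error
rather than being approximated, and are handled only by the numeric
simulator (flagged `wraparound` in its truth record). Ratios below 1
after focus correction are *flagged*, never clamped, so over-correction
stays visible.

Sanity anchors under the wild-type slow-growth conditions (τ = 119 min,
minimal alanine, 30 °C): a_r = τ(1 − log₂1.9) ≈ 8.8 min reproduces the
observed 1.9 copies/cell, and Δ ≈ 34 min reproduces 1.22 copies/focus.
The batch inversion (≈34 min) and the synchronized estimate (31 min)
differ slightly; the package treats this as measurement discrepancy
between two assays and does not reconcile them.

## Focus-count quality control

Two detection artifacts contaminate raw focus counts:

- **Non-expressing cells** (typically 2–8% of a field) lack the
  fluorescent repressor entirely. They are excluded by an exact
  two-cluster least-squares split (1-D k-means, solved exhaustively,
  hence deterministic) on log background fluorescence. If the two
  clusters are not separated by more than twice the combined
  within-cluster spread, the distribution is treated as unimodal, a
  warning is issued, and no cell is excluded.
- **Whole-cell detection failures**: since every cell carries the
  locus, an expressing cell with zero foci can only be a detection
  failure. The inefficiency i is the zero-focus fraction among
  expressing cells, and the population mean focus count is corrected by
  dividing by e = 1 − i. Division (rather than adding i·raw) is used
  because a whole-cell failure removes the cell's entire focus
  contribution; it reproduces the expected ≤ +0.10 foci/cell correction
  at 94% efficiency. The detection-failure model is whole-cell rather
  than per-focus because the estimator reads the zero-focus fraction;
  per-focus thinning exists in the generator to probe robustness.

The correction is validated on cohesion-free stationary-phase cells,
where corrected foci/cell must match chromosomes/cell from flow
cytometry (default tolerance 0.05).

## qPCR and runoff copy-number reconstruction

Ct values follow the exponential amplification model with efficiency
E ∈ (0, 1] (E = 1 is perfect doubling; default, since no efficiency
corrections are applied upstream). Replicate Cts are averaged
arithmetically *before* exponentiation. Relative abundance is
(1+E)^(−ΔCt); ChIP fold enrichment is 2^(−ΔΔCt) with
ΔΔCt = (Ct_IP − Ct_input)_site − (Ct_IP − Ct_input)_reference, so the
reference locus is exactly 1 and any global Ct shift cancels.

Rifampicin-runoff histograms (DNA content after ongoing rounds finish)
are fitted with a constrained Gaussian mixture: peak means at n·μ₁ for
n ∈ {1, 2, 4, 8} (synchronous initiation gives 2ⁿ origins), a shared
coefficient of variation, nonnegative weights, solved by bounded least
squares with initialization from assigning the tallest bin to each
candidate n. Peaks whose means fall outside the histogram are pinned to
zero weight (they are unidentifiable). Without an absolute DNA-content
calibration, a spectrum whose mass sits entirely on even origin counts
is exactly degenerate with the half-labelled spectrum at 2μ₁; the fit
resolves this deterministically toward the fewest origins, unless the
caller anchors μ₁ via `unit_fluorescence` (a reference-standard
calibration). Origins/cell is the mass-weighted mean origin count, and
locus copies/cell multiplies it by the locus:oriC qPCR ratio.

## Synchronized cumulative-curve timing

The mean signal (copies or foci per cell) of a baby-machine cohort
rises sigmoidally from a baseline near 1 to a plateau near 2. The
estimator: (1) fit a monotone non-decreasing curve to the raw means by
isotonic regression weighted by cell counts; (2) normalize so the
fitted value at the first sample is 0% and at the last is 100%; (3)
read event times at the 50% crossing. Replication time is the 50%
crossing of the copy-number curve, segregation time that of the foci
curve, and the cohesion period is their difference. B/C/D periods
follow from the oriC and ter crossings: B = t50(oriC),
C = t50(ter) − t50(oriC), D = τ − t50(ter), summing to τ by
construction.

Two numerical choices matter at 10-minute sampling:

- **Crossing interpolation.** The 50% crossing is interpolated between
  the two bracketing samples on the **probit scale** (classic
  50%-point practice in dose–response analysis). Plain linear
  interpolation of a sigmoid sampled every 10 min carries a chord bias
  of up to ±0.6 min per crossing depending on where the rise sits on
  the grid; probit interpolation is exact when the event-time spread is
  Gaussian and reduces the worst-case bias of the recovered period from
  ≈2 min to under 1 min. Both methods agree on symmetric brackets, and
  `method="linear"` is available.
- **First crossing wins** on ties/flat segments.

Recovered periods carry a small residual negative bias (≤ ~1 min over
the tested grid) from noise interacting with the isotonic fit; the
acceptance checks average two replicate simulated experiments per
condition, mirroring how the bench time courses are averaged.

## Genome scans

Coordinates are 1-based, fully closed; genomes are circular by default.
GATC is its own reverse complement, so motif scans report forward-
strand start positions only (counting each site once) and include
matches spanning the origin junction. Windows containing ambiguous
bases that would otherwise match are skipped and tallied. Density
tracks tile the genome into non-overlapping windows (the last absorbs
any remainder) so window counts conserve the total. Moving averages are
unweighted means of probe values inside a centered bp window with
circular wraparound — probe weighting or gap interpolation is *not*
applied. Cohesion-vs-binding association uses Spearman rank correlation
of locus cohesion durations against the smoothed signal at the nearest
probe. On disk, tracks are bedGraph (0-based half-open); the converter
maps disk [start, end) to internal [start+1, end] exactly.

## Time-lapse separation kinetics

A trajectory's split time is the first frame showing two resolvable
foci; transient re-merging afterwards does not reset it. Because
separation is much faster than the frame interval, the initial speed is
reported two ways: a **lower bound** (first post-split distance minus
the resolution limit, over one frame interval) and an **early slope**
(least-squares over the first 20 min post-split); the late slope over
the remaining frames estimates the cell elongation rate. Distances are
planar Euclidean; no 3-D correction. Distance distributions use 0.2 µm
bins, the mode is the fullest bin's center with ties toward smaller
distances, and bimodality (the two-step separation pattern of non-snap
loci) is called by BIC comparison of one- vs two-component Gaussian
mixtures, requiring both components to hold >10% of mass and to be
separated by >2 bins.

## Synthetic-data generators

Every generator is a pure function of (config, seed) — identical seeds
give identical outputs — and emits a truth sidecar with the injected
parameters. Defaults encode the slow-growth study conditions:
τ = 119 min, Δ = 31 min, a_r from the 1.9 copies/cell anchor, 80%
synchrony (range 75–85%), 1.4% whole-cell miss probability, 5%
non-expressing cells, 0.1-cycle Ct noise, 8% runoff peak CV,
0.4 µm/min fast separation for 2.5 min then 0.02 µm/min elongation,
0.23 µm resolution censoring, and a 700 nt/s fork speed for
map-position conversions.

Choices where the design was open:

- **Synchronized event spread**: Gaussian with σ = 5 min truncated at
  zero (resampled), matching the observed steepness of replication
  rises; exposed in config.
- **Asynchronous contaminants** in baby-machine output are modeled as a
  *stationary* population: steady-state exponential-law ages advancing
  modulo τ, so their event times are uniform over the cycle and their
  ensemble mean adds a constant offset to both curves. Modeling them
  instead as cells that freeze after a single event adds an artificial
  background ramp that biases the recovered period downward by ~2 min
  at long Δ; the stationary model is the correct steady-state picture.
- **Genome generator**: uniform-random background sequence (spontaneous
  GATC ≈ 1/256 per bp ≈ 3.9/kb), optional broad snap windows at a
  multiplied GATC rate, plus per-locus 5-kb windows with *graded*
  enrichment whose cohesion duration is a monotone map from the
  non-snap band (7–10 min) to the snap band (19–30 min). Because that
  signal lives at 5-kb scale, 5-kb smoothing preserves the
  cohesion-binding ranking better than 40-kb smoothing.

What the generators do **not** emulate: pixel-level images and spot
detection (detection is simulated at the focus-count level), raw
amplification curves (Cts are primitive), flow-cytometer artifacts
beyond Gaussian peak broadening, cell-to-cell growth-rate variation,
replication fork stalling, and overlapping replication rounds in the
analytic regime (the simulator flags them; closed forms refuse them).
Passing tests therefore demonstrate estimator correctness under the
stated statistical model, not robustness to every artifact of real
microscopy or qPCR data.

## Problem sizes

Simulation sizes used by the test suite and the acceptance script —
1000 cells per time point, two replicate time courses per condition,
10⁴–10⁵ cells for population means, 10-kb–1-Mb synthetic genomes,
50–100 trajectories — match the scale of the emulated experiments
(~1000 cells analyzed per sample; n = 500 distance snapshots) and keep
every check fast on a single CPU.

## Known limitations

- The batch inversion assumes the single-round, pre-division-resolution
  regime; fast growth with overlapping rounds needs the numeric path.
- The ~65-min condition sits near the edge of the sampled window
  (150 min); its recovered period is the least precise of the three.
- The uncalibrated runoff labelling convention (fewest origins) is
  wrong for populations whose true origin counts are all even; supply
  `unit_fluorescence` when a calibration exists.
- Spearman correlation with few loci (n < ~8) is highly variable; the
  5-kb-vs-40-kb ordering holds in distribution, not for every seed.
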