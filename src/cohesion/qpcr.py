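"""qPCR copy-number reconstruction and ChIP enrichment.

Quantities here follow the exponential amplification model: a template
that is ``r``-fold more abundant crosses the detection threshold
``log_{1+E}(r)`` cycles earlier, where ``E`` in (0, 1] is the fraction
of templates duplicated per cycle (E = 1 is perfect doubling).  All
replicate Ct values are averaged arithmetically before any
exponentiation.

Locus copy number per cell is reconstructed by combining two
measurements: origins per cell from rifampicin-runoff flow cytometry
(DNA-content peaks at integer origin counts), and the locus:oriC
abundance ratio from qPCR.  ChIP enrichment uses the standard double
difference, fold = 2^-ΔΔCt with ΔΔCt = (Ct_IP - Ct_input)_site -
(Ct_IP - Ct_input)_reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from cohesion.errors import DataError, DomainError

__all__ = [
    "QpcrRecord",
    "RunoffHistogram",
    "RunoffQuantification",
    "ChipSample",
    "StandardCurveResult",
    "RoadblockResult",
    "relative_ratio",
    "copies_per_cell_from_runoff",
    "standard_curve_quantification",
    "roadblock_ratio",
    "chip_fold_enrichment",
]

#: Runoff histograms are fitted with peaks at these origin counts
#: (synchronous initiation yields 2^n origins per cell).
RUNOFF_ORIGIN_COUNTS = (1, 2, 4, 8)


@dataclass(frozen=True)
class QpcrRecord:
    """Averaged-replicate qPCR measurement for one sample/target."""

    sample_id: str
    target_locus: str
    replicate_cts: tuple[float, ...]
    amplification_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if not self.replicate_cts:
            raise DataError(f"{self.sample_id}/{self.target_locus}: no replicates")
        cts = np.asarray(self.replicate_cts, dtype=float)
        if not np.all(np.isfinite(cts)) or np.any(cts <= 0):
            raise DataError(f"{self.sample_id}/{self.target_locus}: Cts must be finite and > 0")
        if not 0 < self.amplification_efficiency <= 1:
            raise DomainError("amplification_efficiency must be in (0, 1]")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.replicate_cts))

    @property
    def ct_spread(self) -> float:
        return float(np.max(self.replicate_cts) - np.min(self.replicate_cts))


@dataclass
class RunoffHistogram:
    """DNA-content histogram after replication runoff.

    ``bin_centers`` are fluorescence units proportional to chromosome
    equivalents; peaks sit at integer multiples of the one-chromosome
    position.
    """

    bin_centers: np.ndarray
    counts: np.ndarray
    peak_assignments: dict[int, float] | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_centers.shape != self.counts.shape:
            raise DataError("bin_centers and counts must have equal length")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise DataError("bin_centers must be strictly increasing")
        if np.any(self.counts < 0) or self.counts.sum() <= 0:
            raise DataError("counts must be nonnegative with positive total")


@dataclass(frozen=True)
class ChipSample:
    """One locus's IP and input Ct values (replicates pre-averaged)."""

    locus: str
    ct_ip: float
    ct_input: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_ip) and math.isfinite(self.ct_input)):
            raise DataError(f"{self.locus}: non-finite Ct")


def relative_ratio(
    target: QpcrRecord,
    reference: QpcrRecord,
    *,
    spread_warn_cycles: float = 0.5,
) -> float:
    """Relative abundance of target vs reference, (1+E)^-(ΔCt).

    ΔCt is the difference of replicate-averaged Cts.  When both records
    specify efficiencies they must agree (per-reaction efficiency
    differences are not modeled); a replicate spread above
    ``spread_warn_cycles`` raises a warning.
    """
    for rec in (target, reference):
        if rec.ct_spread > spread_warn_cycles:
            warnings.warn(
                f"{rec.sample_id}/{rec.target_locus}: replicate Ct spread "
                f"{rec.ct_spread:.2f} cycles exceeds {spread_warn_cycles}",
                stacklevel=2,
            )
    if not math.isclose(
        target.amplification_efficiency, reference.amplification_efficiency, rel_tol=1e-9
    ):
        raise DataError("target and reference amplification efficiencies differ")
    base = 1.0 + target.amplification_efficiency
    delta_ct = target.mean_ct - reference.mean_ct
    return float(base ** (-delta_ct))


@dataclass
class RunoffQuantification:
    origins_per_cell: float
    copies_per_cell: float
    peak_masses: dict[int, float]
    unassigned_fraction: float
    mu1: float
    cv: float


def _runoff_model(bin_centers: np.ndarray, mu1: float, cv: float, weights: np.ndarray) -> np.ndarray:
    out = np.zeros_like(bin_centers)
    for w, n in zip(weights, RUNOFF_ORIGIN_COUNTS):
        mu = n * mu1
        sigma = max(cv * mu, 1e-9)
        out += w * np.exp(-0.5 * ((bin_centers - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    return out


def copies_per_cell_from_runoff(
    hist: RunoffHistogram,
    locus_to_oric_ratio: float,
    *,
    unit_fluorescence: float | None = None,
    unassigned_warn: float = 0.10,
) -> RunoffQuantification:
    """Reconstruct locus copies per cell from a runoff histogram.

    A constrained Gaussian mixture with peak means at n*mu1 for
    n in {1, 2, 4, 8} and a shared coefficient of variation is fitted to
    the histogram by least squares.  Origins per cell is the
    mass-weighted mean origin count; multiplying by the locus:oriC
    qPCR ratio gives locus copies per cell.

    Without an absolute DNA-content calibration a lone peak is
    ambiguous (n origins at unit mu1 is indistinguishable from n/2 at
    2*mu1), so uncalibrated fits adopt the parsimonious labelling with
    the fewest origins.  Pass ``unit_fluorescence`` (the one-chromosome
    peak position, e.g. from a reference standard) to anchor mu1
    instead.
    """
    if not locus_to_oric_ratio > 0:
        raise DomainError("locus_to_oric_ratio must be positive")
    x = hist.bin_centers
    y = hist.counts.astype(float)
    total = y.sum()
    bin_width = float(np.median(np.diff(x)))

    # Initialize mu1 by assigning the tallest bin to each candidate origin
    # count and keeping the assignment with the lowest residual.
    x_peak = float(x[np.argmax(y)])
    candidates = []
    if unit_fluorescence is not None:
        mu1_starts = [float(unit_fluorescence)]
    else:
        mu1_starts = [x_peak / n for n in RUNOFF_ORIGIN_COUNTS]
    for mu1_0 in mu1_starts:
        if mu1_0 <= 0 or RUNOFF_ORIGIN_COUNTS[-1] * mu1_0 > 4 * x[-1]:
            continue
        # peaks whose mean falls outside the histogram are unidentifiable:
        # pin their weights to zero instead of letting the fit float them
        in_range = np.array(
            [x[0] - 2 * 0.08 * n * mu1_0 <= n * mu1_0 <= x[-1] + 2 * 0.08 * n * mu1_0
             for n in RUNOFF_ORIGIN_COUNTS]
        )
        if not in_range.any():
            continue
        w0 = np.where(in_range, total / in_range.sum(), 0.0)
        p0 = np.concatenate([[mu1_0, 0.08], w0])

        def resid(p):
            mu1, cv = p[0], p[1]
            w = p[2:]
            return _runoff_model(x, mu1, cv, w) - y / bin_width

        lb = np.concatenate([[x[0] * 0.25, 0.005], np.zeros(len(RUNOFF_ORIGIN_COUNTS))])
        ub = np.concatenate(
            [[x[-1] * 2.0, 0.5], np.where(in_range, np.inf, 1e-12)]
        )
        try:
            sol = optimize.least_squares(resid, p0, bounds=(lb, ub), max_nfev=2000)
        except ValueError:
            continue
        candidates.append(sol)
    if not candidates:
        raise DataError("no resolvable peaks: runoff mixture fit failed")
    # n -> 2n relabelling with mu1 -> mu1/2 is observationally equivalent;
    # among near-tied fits keep the largest unit-chromosome fluorescence
    # (fewest origins), the parsimonious calibration.
    min_cost = min(s.cost for s in candidates)
    best = max(
        (s for s in candidates if s.cost <= min_cost * 1.10 + 1e-12),
        key=lambda s: s.x[0],
    )

    mu1, cv = float(best.x[0]), float(best.x[1])
    weights = best.x[2:]
    fitted_mass = float(weights.sum())
    if fitted_mass <= 0:
        raise DataError("no resolvable peaks: fitted mass is zero")
    w_frac = weights / fitted_mass
    masses = {n: float(wf) for n, wf in zip(RUNOFF_ORIGIN_COUNTS, w_frac)}
    # exact relabelling degeneracy: masses on {2,4,8} at mu1 are identical
    # to masses on {1,2,4} at 2*mu1; adopt the parsimonious (fewest
    # origins, largest unit fluorescence) labelling deterministically,
    # unless mu1 was anchored by an explicit calibration
    tol = 0.01
    while unit_fluorescence is None and masses.get(1, 0.0) <= tol and sum(
        m for n, m in masses.items() if n % 2 == 0
    ) > tol:
        masses = {n // 2: masses.get(n, 0.0) for n in RUNOFF_ORIGIN_COUNTS if n % 2 == 0}
        masses[8] = 0.0
        mu1 *= 2.0
    unassigned = max(0.0, 1.0 - fitted_mass / total)
    if unassigned > unassigned_warn:
        warnings.warn(
            f"{unassigned:.1%} of histogram mass not assigned to 2^n peaks",
            stacklevel=2,
        )
    origins = float(sum(n * wf for n, wf in masses.items()))
    return RunoffQuantification(
        origins_per_cell=origins,
        copies_per_cell=origins * locus_to_oric_ratio,
        peak_masses=masses,
        unassigned_fraction=unassigned,
        mu1=mu1,
        cv=cv,
    )


@dataclass
class StandardCurveResult:
    quantity: float
    slope: float
    intercept: float
    r_squared: float
    implied_efficiency: float
    extrapolated: bool


def standard_curve_quantification(
    curve_points: list[tuple[float, float]],
    sample_ct: float,
    *,
    r2_warn: float = 0.98,
) -> StandardCurveResult:
    """Absolute quantification against a calibrator standard curve.

    ``curve_points`` are (log10 input quantity, Ct) pairs from a dilution
    series of a calibrator of known copies per cell.  A least-squares
    line Ct = m*log10(q) + b is fitted; the sample quantity is
    10^((Ct - b)/m) and the implied amplification efficiency is
    (1+E) = 10^(-1/m).
    """
    if len(curve_points) < 3:
        raise DataError("need at least 3 standard-curve points")
    logq = np.array([p[0] for p in curve_points], dtype=float)
    cts = np.array([p[1] for p in curve_points], dtype=float)
    fit = stats.linregress(logq, cts)
    if fit.slope >= 0:
        raise DataError("standard curve slope must be negative (more template, lower Ct)")
    r2 = float(fit.rvalue**2)
    if r2 < r2_warn:
        warnings.warn(f"standard curve R^2 = {r2:.3f} < {r2_warn}", stacklevel=2)
    extrapolated = not (cts.min() <= sample_ct <= cts.max())
    if extrapolated:
        warnings.warn("sample Ct outside standard-curve range; extrapolating", stacklevel=2)
    quantity = float(10.0 ** ((sample_ct - fit.intercept) / fit.slope))
    implied = float(10.0 ** (-1.0 / fit.slope) - 1.0)
    return StandardCurveResult(
        quantity=quantity,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        implied_efficiency=implied,
        extrapolated=extrapolated,
    )


@dataclass
class RoadblockResult:
    ratio: float
    flagged: bool
    threshold: float


def roadblock_ratio(
    upstream: QpcrRecord,
    downstream: QpcrRecord,
    *,
    flag_threshold: float = 1.5,
) -> RoadblockResult:
    """Upstream:downstream abundance ratio around an array insertion.

    Replication pausing at a repressor-bound operator array piles up DNA
    upstream of the insertion; a ratio near 1 indicates free fork
    passage, while strong blocks show several-fold upstream excess.
    """
    ratio = relative_ratio(upstream, downstream)
    return RoadblockResult(ratio=ratio, flagged=ratio > flag_threshold, threshold=flag_threshold)


def chip_fold_enrichment(
    samples: list[ChipSample],
    reference_locus: str,
) -> pd.DataFrame:
    """ΔΔCt fold enrichment of IP vs input, relative to a reference locus.

    Repeated rows per locus (replicates) are averaged (IP and input Cts
    separately) before differencing.  Returns a DataFrame with columns
    ``locus``, ``delta_ct``, ``delta_delta_ct``, ``fold``; the reference
    locus has fold exactly 1.
    """
    if not samples:
        raise DataError("no ChIP samples supplied")
    df = pd.DataFrame(
        {
            "locus": [s.locus for s in samples],
            "ct_ip": [s.ct_ip for s in samples],
            "ct_input": [s.ct_input for s in samples],
        }
    )
    grouped = df.groupby("locus", sort=False).mean()
    if reference_locus not in grouped.index:
        raise DataError(f"reference locus {reference_locus!r} not present")
    delta_ct = grouped["ct_ip"] - grouped["ct_input"]
    ddct = delta_ct - delta_ct.loc[reference_locus]
    out = pd.DataFrame(
        {
            "locus": grouped.index,
            "delta_ct": delta_ct.values,
            "delta_delta_ct": ddct.values,
            "fold": np.exp2(-ddct.values),
        }
    ).reset_index(drop=True)
    return out
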