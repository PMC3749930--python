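"""Steady-state exponential-age population model for locus cohesion.

In a steady-state exponential culture the distribution of cell ages is
not uniform: young cells outnumber old cells two to one because every
division creates two newborns.  The age density is

    f(a) = (2 ln2 / tau) * 2**(-a / tau),   0 <= a <= tau,

where ``tau`` is the generation (doubling) time.  A locus replicated at
cell age ``a_r`` is present in 2 copies in cells older than ``a_r`` and
1 copy otherwise, giving a population mean of

    copies/cell = 2**(1 - a_r / tau).

If the two sister copies stay within the optical resolution limit for a
cohesion period ``Delta`` after replication, a cell shows 2 foci only
once it is older than ``a_r + Delta``, so

    foci/cell   = 2**(1 - (a_r + Delta) / tau)
    copies/focus = 2**(Delta / tau),

with the replication-age term cancelling in the ratio.  Inverting the
ratio statistic yields the cohesion duration

    Delta = tau * log2(copies/focus).

These closed forms hold in the single-replication-round regime with
cohesion resolved before division (``a_r + Delta <= tau``); anything
else must be simulated numerically (see :mod:`cohesion.synthetic`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from cohesion.errors import DomainError, UnsupportedRegimeError

__all__ = [
    "CellCycleParams",
    "CohesionEstimate",
    "age_density",
    "age_cdf",
    "sample_ages",
    "expected_copies_per_cell",
    "expected_foci_per_cell",
    "expected_copies_per_focus",
    "cohesion_duration_from_ratio",
    "batch_cohesion_statistic",
    "relative_cohesion_timecourse",
]

LN2 = math.log(2.0)

#: Replication fork speed in nucleotides per second used to convert map
#: distance from oriC into replication-age offsets.
DEFAULT_FORK_SPEED_NT_PER_S = 700.0


@dataclass(frozen=True)
class CellCycleParams:
    """Ground-truth cell-cycle parameters for one locus.

    Parameters
    ----------
    generation_time
        Doubling time tau in minutes.
    locus_replication_age
        Cell age a_r (minutes) at which the locus is duplicated.
    cohesion_duration
        Delta (minutes): interval between locus duplication and focus
        splitting.
    b_period, c_period, d_period
        Optional cell-cycle phases (minutes); when all are given they
        must sum to the generation time.
    fork_speed
        Replication fork speed in nt/s (used for map-position
        conversions; default 700).
    """

    generation_time: float
    locus_replication_age: float
    cohesion_duration: float
    b_period: float | None = None
    c_period: float | None = None
    d_period: float | None = None
    fork_speed: float = DEFAULT_FORK_SPEED_NT_PER_S

    def __post_init__(self) -> None:
        tau = self.generation_time
        if not tau > 0:
            raise DomainError(f"generation_time must be positive, got {tau}")
        if not 0 <= self.locus_replication_age <= tau:
            raise DomainError(
                f"locus_replication_age {self.locus_replication_age} outside [0, {tau}]"
            )
        if self.cohesion_duration < 0:
            raise DomainError(f"cohesion_duration must be >= 0, got {self.cohesion_duration}")
        periods = (self.b_period, self.c_period, self.d_period)
        if all(p is not None for p in periods):
            total = sum(periods)  # type: ignore[arg-type]
            if not math.isclose(total, tau, rel_tol=0.0, abs_tol=1e-6 * max(1.0, tau)):
                raise DomainError(
                    f"B + C + D = {total} does not equal generation_time {tau}"
                )


@dataclass
class CohesionEstimate:
    """One locus's measured cohesion, batch-culture style.

    ``copies_per_focus`` is the cohesion statistic: mean locus copy
    number per cell divided by the detection-corrected mean number of
    resolvable foci per cell.  A value of 1.0 means no cohesion; values
    below 1 indicate over-correction of the focus counts and are
    flagged (``sub_unity``) rather than clamped.
    """

    copies_per_cell: float
    foci_per_cell_corrected: float
    copies_per_focus: float
    foci_per_cell_raw: float | None = None
    cohesion_minutes: float | None = None
    sub_unity: bool = field(default=False)


def _validate_age(age: np.ndarray, generation_time: float) -> None:
    if np.any(age < 0) or np.any(age > generation_time):
        raise DomainError(f"age outside [0, {generation_time}] minutes")


def age_density(age, generation_time: float):
    """Steady-state cell-age probability density (per minute).

    f(a) = (2 ln2 / tau) 2^(-a/tau) on [0, tau]; vectorized over `age`.
    """
    if not generation_time > 0:
        raise DomainError("generation_time must be positive")
    a = np.asarray(age, dtype=float)
    _validate_age(a, generation_time)
    out = (2.0 * LN2 / generation_time) * np.exp2(-a / generation_time)
    return out if out.ndim else float(out)


def age_cdf(age, generation_time: float):
    """Cumulative age distribution F(a) = 2 (1 - 2^(-a/tau))."""
    if not generation_time > 0:
        raise DomainError("generation_time must be positive")
    a = np.asarray(age, dtype=float)
    _validate_age(a, generation_time)
    out = 2.0 * (1.0 - np.exp2(-a / generation_time))
    return out if out.ndim else float(out)


def sample_ages(n: int, generation_time: float, rng: np.random.Generator) -> np.ndarray:
    """Draw cell ages by inverse-CDF: a = -tau * log2(1 - u/2)."""
    u = rng.random(n)
    return -generation_time * np.log2(1.0 - u / 2.0)


def _check_single_round(params: CellCycleParams) -> None:
    # a_r within [0, tau] is enforced by the dataclass; overlapping
    # rounds would need a_r outside the cycle, which that check rejects.
    pass


def expected_copies_per_cell(params: CellCycleParams) -> float:
    """Population-mean locus copies per cell, N = 2^(1 - a_r/tau)."""
    _check_single_round(params)
    return float(2.0 ** (1.0 - params.locus_replication_age / params.generation_time))


def expected_foci_per_cell(params: CellCycleParams) -> float:
    """Population-mean resolvable foci per cell, 2^(1 - (a_r+Delta)/tau).

    Valid only when cohesion resolves before division.
    """
    tau = params.generation_time
    split_age = params.locus_replication_age + params.cohesion_duration
    if split_age > tau:
        raise UnsupportedRegimeError(
            f"cohesion spans division (a_r + Delta = {split_age} > tau = {tau}); "
            "use the numeric simulator for this regime"
        )
    return float(2.0 ** (1.0 - split_age / tau))


def expected_copies_per_focus(params: CellCycleParams) -> float:
    """Predicted cohesion statistic, copies/focus = 2^(Delta/tau).

    The replication-age term cancels between the copies and foci means,
    so the statistic depends only on the cohesion duration relative to
    the generation time.
    """
    tau = params.generation_time
    if params.locus_replication_age + params.cohesion_duration > tau:
        raise UnsupportedRegimeError(
            "cohesion spans division; closed form invalid (a_r + Delta > tau)"
        )
    return float(2.0 ** (params.cohesion_duration / tau))


def cohesion_duration_from_ratio(copies_per_focus: float, generation_time: float) -> float:
    """Invert the ratio statistic: Delta = tau * log2(copies/focus)."""
    if not generation_time > 0:
        raise DomainError("generation_time must be positive")
    if copies_per_focus < 1.0:
        raise DomainError(
            f"copies_per_focus = {copies_per_focus} < 1 suggests over-corrected "
            "focus counts; cannot invert to a cohesion duration"
        )
    return float(generation_time * math.log2(copies_per_focus))


def batch_cohesion_statistic(
    copies_per_cell: float,
    foci_per_cell_corrected: float,
    *,
    generation_time: float | None = None,
    foci_per_cell_raw: float | None = None,
) -> CohesionEstimate:
    """Form the copies-per-focus cohesion statistic from the two
    independently measured population means.

    When ``generation_time`` is supplied and the ratio is >= 1, the
    model inversion to a cohesion duration (minutes) is included.
    Ratios below 1 are flagged via ``sub_unity`` (over-correction made
    visible, never clamped).
    """
    if not copies_per_cell > 0:
        raise DomainError(f"copies_per_cell must be positive, got {copies_per_cell}")
    if not foci_per_cell_corrected > 0:
        raise DomainError(
            f"foci_per_cell_corrected must be positive, got {foci_per_cell_corrected}"
        )
    ratio = copies_per_cell / foci_per_cell_corrected
    sub_unity = ratio < 1.0
    cohesion_minutes = None
    if generation_time is not None and not sub_unity:
        cohesion_minutes = cohesion_duration_from_ratio(ratio, generation_time)
    return CohesionEstimate(
        copies_per_cell=copies_per_cell,
        foci_per_cell_corrected=foci_per_cell_corrected,
        foci_per_cell_raw=foci_per_cell_raw,
        copies_per_focus=ratio,
        cohesion_minutes=cohesion_minutes,
        sub_unity=sub_unity,
    )


def relative_cohesion_timecourse(
    series_mutant: Sequence[CohesionEstimate],
    series_control: Sequence[CohesionEstimate],
) -> np.ndarray:
    """Mutant-vs-control cohesion difference normalized to time zero.

    For matched time courses, returns (mutant - control) copies/focus at
    each time point divided by the difference at the first point, so the
    series starts at exactly 1.0.  Used for temperature-shift
    experiments where absolute cohesion differs between loci but the
    relative rate of change is compared.
    """
    if len(series_mutant) != len(series_control):
        raise DomainError("mutant and control series must have matched time points")
    if not series_mutant:
        raise DomainError("empty series")
    diffs = np.array(
        [m.copies_per_focus - c.copies_per_focus for m, c in zip(series_mutant, series_control)]
    )
    baseline = diffs[0]
    if baseline == 0.0:
        raise DomainError(
            "cohesion difference at t=0 is zero; relative normalization undefined "
            "(mutant and control are indistinguishable at baseline)"
        )
    return diffs / baseline
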