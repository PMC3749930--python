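"""Synchronized-culture cumulative-curve timing.

Newborn cells collected from a baby machine are 75–85% synchronous, so
the mean locus copy number (and focus count) rises sigmoidally from a
baseline near 1 toward a plateau near 2 as the synchronous fraction
replicates (or segregates) the locus.  The raw mean signal is smoothed
with a monotone non-decreasing fit (isotonic regression) and rescaled
so the first sample maps to 0% and the last to 100%; the rescaled curve
is the cumulative fraction of the synchronous population that has
passed the event.  Event times are read off at the 50% crossing by
linear interpolation:

* locus replication time  = 50% crossing of the copy-number curve,
* locus segregation time  = 50% crossing of the foci curve,
* cohesion period         = segregation time - replication time,
* B = t50(oriC), C = t50(ter) - t50(oriC), D = tau - t50(ter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression

from cohesion.errors import DataError, DomainError

__all__ = [
    "TimecourseSample",
    "TimingResult",
    "CumulativeCurve",
    "cumulative_curve",
    "crossing_time",
    "cohesion_period",
    "cell_cycle_periods",
]

#: Minimum baseline-to-plateau rise, relative to the baseline, below
#: which a cumulative curve is considered noise.
MIN_RELATIVE_RISE = 0.05


@dataclass(frozen=True)
class TimecourseSample:
    """One sample of a synchronized time course."""

    time_after_birth: float
    mean_copy_number: float
    mean_foci: float
    n_cells: int


@dataclass
class TimingResult:
    """Timing readouts from one or more cumulative curves."""

    t50_replication: float | None = None
    t50_segregation: float | None = None
    cohesion_period: float | None = None
    negative_cohesion_flag: bool = False
    b_period: float | None = None
    c_period: float | None = None
    d_period: float | None = None
    synchrony_fraction: float | None = None


@dataclass
class CumulativeCurve:
    """Normalized cumulative event curve (percent of synchronous cells)."""

    times: np.ndarray
    cumulative_percent: np.ndarray
    baseline: float
    plateau: float
    synchrony_fraction: float


def _extract_signal(samples: list[TimecourseSample], channel: str) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([s.time_after_birth for s in samples], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise DataError("sample times must be strictly increasing")
    if channel == "copies":
        signal = np.array([s.mean_copy_number for s in samples], dtype=float)
    elif channel == "foci":
        signal = np.array([s.mean_foci for s in samples], dtype=float)
    else:
        raise DomainError(f"unknown channel {channel!r}; expected 'copies' or 'foci'")
    return times, signal


def cumulative_curve(samples: list[TimecourseSample], channel: str = "copies") -> CumulativeCurve:
    """Build the cumulative event curve for one channel.

    The raw means are fitted with isotonic regression (weighted by cell
    count), then normalized: the fitted value at the first sample is 0%
    and at the last sample is 100%.  The plateau-to-baseline rise also
    yields the synchrony-fraction estimate (rise relative to the ideal
    doubling of the baseline), reported for QC only.
    """
    if len(samples) < 5:
        raise DataError(f"need at least 5 time points, got {len(samples)}")
    times, signal = _extract_signal(samples, channel)
    weights = np.array([max(s.n_cells, 1) for s in samples], dtype=float)
    fit = isotonic_regression(signal, weights=weights, increasing=True)
    smooth = np.asarray(fit.x)
    baseline, plateau = float(smooth[0]), float(smooth[-1])
    rise = plateau - baseline
    if rise <= MIN_RELATIVE_RISE * max(baseline, 1e-12):
        raise DataError(
            f"plateau ({plateau:.3f}) indistinguishable from baseline ({baseline:.3f}); "
            "no replication/segregation signal in this channel"
        )
    cumulative = ((smooth - baseline) / rise) * 100.0  # endpoints exactly 0 and 100
    synchrony = rise / baseline  # ideal doubling of the synchronous fraction
    return CumulativeCurve(
        times=times,
        cumulative_percent=cumulative,
        baseline=baseline,
        plateau=plateau,
        synchrony_fraction=float(synchrony),
    )


def crossing_time(curve: CumulativeCurve, level: float = 50.0, method: str = "probit") -> float:
    """Time at which the cumulative curve first reaches ``level`` percent.

    Interpolates between the two bracketing samples; on a flat segment
    exactly at the level, the first crossing wins.  The default
    ``probit`` method interpolates on the probit (inverse-normal) scale,
    which is exact when the underlying event-time distribution is
    Gaussian and substantially reduces the chord bias of coarse
    (e.g. 10-min) sampling; ``linear`` interpolates the percentages
    directly.  Both are symmetric, so the midpoint examples coincide.
    """
    c = curve.cumulative_percent
    t = curve.times
    if level < c[0] or level > c[-1]:
        raise DataError(f"cumulative curve never reaches {level}%")
    idx = int(np.searchsorted(c, level, side="left"))
    if c[idx] == level:
        return float(t[idx])
    lo, hi = idx - 1, idx
    if c[hi] == c[lo]:
        return float(t[lo])
    if method == "probit":
        from scipy.stats import norm

        eps = 1e-6
        z = norm.ppf(np.clip(np.array([c[lo], level, c[hi]]) / 100.0, eps, 1 - eps))
        z_lo, z_level, z_hi = z
        if np.isfinite(z_lo) and np.isfinite(z_hi) and z_hi > z_lo:
            frac = (z_level - z_lo) / (z_hi - z_lo)
            return float(t[lo] + frac * (t[hi] - t[lo]))
        # degenerate probit bracket: fall through to linear
    elif method != "linear":
        raise DomainError(f"unknown interpolation method {method!r}")
    frac = (level - c[lo]) / (c[hi] - c[lo])
    return float(t[lo] + frac * (t[hi] - t[lo]))


def cohesion_period(
    replication_curve: CumulativeCurve,
    segregation_curve: CumulativeCurve,
    *,
    level: float = 50.0,
) -> TimingResult:
    """Cohesion period: interval between the replication and segregation
    cumulative curves at the 50% crossing.

    Negative values (segregation apparently preceding replication) are
    flagged, not clipped — they indicate a data problem upstream.
    """
    t_rep = crossing_time(replication_curve, level)
    t_seg = crossing_time(segregation_curve, level)
    period = t_seg - t_rep
    return TimingResult(
        t50_replication=t_rep,
        t50_segregation=t_seg,
        cohesion_period=period,
        negative_cohesion_flag=period < 0,
        synchrony_fraction=replication_curve.synchrony_fraction,
    )


def cell_cycle_periods(
    oric_curve: CumulativeCurve,
    ter_curve: CumulativeCurve,
    generation_time: float,
) -> tuple[float, float, float]:
    """B/C/D cell-cycle periods from oriC and ter replication curves.

    B is birth to initiation, C is the replication period, D is
    termination to division; B + C + D = generation time by
    construction.
    """
    if not generation_time > 0:
        raise DomainError("generation_time must be positive")
    t_ori = crossing_time(oric_curve)
    t_ter = crossing_time(ter_curve)
    if t_ter < t_ori:
        raise DataError(
            f"ter 50% crossing ({t_ter:.1f} min) precedes oriC crossing ({t_ori:.1f} min)"
        )
    b = t_ori
    c = t_ter - t_ori
    d = generation_time - t_ter
    return b, c, d
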