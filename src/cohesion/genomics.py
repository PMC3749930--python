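"""Circular-genome motif scans and binding-track smoothing.

GATC sites are the substrate of Dam methylation and, while
hemimethylated behind the replication fork, of SeqA binding; their
local density therefore predicts SeqA occupancy.  This module scans a
(circular) genome for motif occurrences, tiles motif counts into a
per-kb density track, smooths binding tracks with centered circular
moving averages, and correlates locus cohesion durations with smoothed
binding signal.

Coordinates are 1-based, fully closed, on the forward strand; GATC is
its own reverse complement so each site is counted once.  Circular
wraparound is on by default (the E. coli chromosome is circular).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cohesion.errors import DataError, DomainError

__all__ = [
    "GenomeTrack",
    "LocusAnnotation",
    "MotifScan",
    "motif_positions",
    "window_density",
    "moving_average",
    "cohesion_binding_correlation",
]

_IUPAC_AMBIGUOUS = set("NRYSWKMBDHV")


@dataclass
class GenomeTrack:
    """Positioned signal values on a (circular) genome.

    ``positions`` are 1-based bp coordinates, sorted; ``values`` are the
    signal (e.g. motif counts per kb, or log2 IP/input ratios).
    """

    genome_length: int
    positions: np.ndarray
    values: np.ndarray
    window_bp: int | None = None
    circular: bool = True

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise DataError("positions and values must have equal length")
        if len(self.positions) and (
            self.positions.min() < 1 or self.positions.max() > self.genome_length
        ):
            raise DataError("positions must lie in [1, genome_length]")
        if np.any(np.diff(self.positions) < 0):
            raise DataError("positions must be sorted")
        if not np.all(np.isfinite(self.values)):
            raise DataError("track values must be finite")


@dataclass(frozen=True)
class LocusAnnotation:
    """A cohesion-characterized chromosomal locus."""

    name: str
    position: int
    cohesion_minutes: float
    locus_class: str = "non-snap"  # snap | non-snap | oriC

    def __post_init__(self) -> None:
        if self.cohesion_minutes < 0:
            raise DomainError(f"{self.name}: cohesion must be >= 0")


@dataclass
class MotifScan:
    positions: np.ndarray
    ambiguous_skipped: int


def motif_positions(sequence: str, motif: str = "GATC", circular: bool = True) -> MotifScan:
    """All start positions (1-based, forward strand) of ``motif``.

    On a circular sequence, matches spanning the origin junction are
    included (reported by their start coordinate near the sequence end).
    Candidate windows that would match except for ambiguous bases (N and
    other IUPAC codes) are skipped and tallied in ``ambiguous_skipped``.
    """
    if not motif:
        raise DomainError("motif must be non-empty")
    seq = sequence.upper()
    mot = motif.upper()
    n, m = len(seq), len(mot)
    if n < m:
        return MotifScan(positions=np.array([], dtype=np.int64), ambiguous_skipped=0)
    search = seq + (seq[: m - 1] if circular else "")
    limit = n if circular else n - m + 1

    positions: list[int] = []
    start = search.find(mot)
    while 0 <= start < limit:
        positions.append(start + 1)
        start = search.find(mot, start + 1)

    # tally candidate windows lost to ambiguous bases: windows containing
    # an ambiguity whose unambiguous bases are still consistent with the motif
    ambiguous = 0
    amb_idx = [i for i, b in enumerate(search) if b in _IUPAC_AMBIGUOUS]
    candidate_starts: set[int] = set()
    for i in amb_idx:
        for s in range(max(0, i - m + 1), min(i, limit - 1) + 1):
            candidate_starts.add(s)
    for s in candidate_starts:
        window = search[s : s + m]
        if len(window) == m and all(
            b in _IUPAC_AMBIGUOUS or b == q for b, q in zip(window, mot)
        ) and any(b in _IUPAC_AMBIGUOUS for b in window):
            ambiguous += 1
    return MotifScan(positions=np.array(positions, dtype=np.int64), ambiguous_skipped=ambiguous)


def window_density(
    positions: np.ndarray,
    genome_length: int,
    window_bp: int = 1000,
) -> GenomeTrack:
    """Tile the genome into non-overlapping windows and count motifs.

    Returns a track of counts per kb at window midpoints.  The circular
    tiling covers every base exactly once (the final window absorbs any
    remainder), so window counts sum to the total motif count.
    """
    if window_bp > genome_length:
        raise DomainError("window_bp larger than genome")
    if window_bp < 1:
        raise DomainError("window_bp must be >= 1")
    pos = np.asarray(positions, dtype=np.int64)
    n_windows = genome_length // window_bp
    edges = np.arange(n_windows + 1, dtype=np.int64) * window_bp  # 0-based window starts
    edges[-1] = genome_length  # last window absorbs the remainder
    counts, _ = np.histogram(pos - 1, bins=edges)
    widths = np.diff(edges)
    centers = (edges[:-1] + (widths + 1) // 2).astype(np.int64)
    centers = np.clip(centers, 1, genome_length)
    values = counts / (widths / 1000.0)
    return GenomeTrack(
        genome_length=genome_length,
        positions=centers,
        values=values,
        window_bp=window_bp,
        circular=True,
    )


def moving_average(track: GenomeTrack, window_bp: int) -> GenomeTrack:
    """Centered moving average of a track over a bp window.

    For each probe position p, averages the values of all probes within
    [p - window_bp/2, p + window_bp/2], wrapping around the origin when
    the track is circular.  Probes are equally weighted (no length
    weighting), matching common ChIP-chip smoothing practice.
    """
    n = len(track.positions)
    if n == 0:
        raise DataError("empty track")
    if window_bp < 1:
        raise DomainError("window_bp must be >= 1")
    half = window_bp / 2.0
    pos = track.positions.astype(float)
    val = track.values
    L = float(track.genome_length)

    if track.circular:
        # unwrap: replicate probes shifted by +/- L so a plain sorted
        # two-sided window search handles the junction
        ext_pos = np.concatenate([pos - L, pos, pos + L])
        ext_val = np.concatenate([val, val, val])
    else:
        ext_pos, ext_val = pos, val
    order = np.argsort(ext_pos, kind="stable")
    ext_pos, ext_val = ext_pos[order], ext_val[order]
    csum = np.concatenate([[0.0], np.cumsum(ext_val)])

    lo = np.searchsorted(ext_pos, pos - half, side="left")
    hi = np.searchsorted(ext_pos, pos + half, side="right")
    counts = hi - lo
    if np.all(counts < 2):
        raise DataError(f"fewer than 2 probes in every {window_bp}-bp window")
    sums = csum[hi] - csum[lo]
    smoothed = sums / counts
    return GenomeTrack(
        genome_length=track.genome_length,
        positions=track.positions.copy(),
        values=smoothed,
        window_bp=window_bp,
        circular=track.circular,
    )


def cohesion_binding_correlation(
    loci: list[LocusAnnotation],
    smoothed: GenomeTrack,
) -> tuple[float, pd.DataFrame]:
    """Spearman rank correlation of locus cohesion vs smoothed binding.

    Each locus is looked up at its nearest probe on the smoothed track
    (circular nearest when the track is circular).  Returns the rank
    correlation and a per-locus table of the values entering it.
    """
    if len(loci) < 4:
        raise DataError(f"need at least 4 loci, got {len(loci)}")
    values = []
    for locus in loci:
        d = np.abs(smoothed.positions - locus.position)
        if smoothed.circular:
            d = np.minimum(d, smoothed.genome_length - d)
        values.append(float(smoothed.values[int(np.argmin(d))]))
    cohesion = [l.cohesion_minutes for l in loci]
    if len(set(cohesion)) == 1 or len(set(values)) == 1:
        raise DataError("all ranks tied; rank correlation undefined")
    rho = float(stats.spearmanr(cohesion, values).statistic)
    table = pd.DataFrame(
        {
            "locus": [l.name for l in loci],
            "position": [l.position for l in loci],
            "class": [l.locus_class for l in loci],
            "cohesion_minutes": cohesion,
            "binding_value": values,
        }
    )
    return rho, table
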