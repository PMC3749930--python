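"""Per-cell focus-count quality control.

Two artifacts contaminate raw focus counts from repressor-operator
(FROS) imaging: cells that never expressed the fluorescent repressor
(no foci, low background fluorescence), and expressing cells whose foci
were missed by detection.  Non-expressing cells are excluded by a
deterministic two-cluster split on log background fluorescence; the
detection inefficiency ``i`` is then the zero-focus fraction among the
remaining expressing cells — every cell carries the locus, so a genuine
zero-focus expressing cell can only be a detection failure.  The
population mean focus count is corrected by dividing by the efficiency
``e = 1 - i``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from cohesion.errors import DataError, DomainError

__all__ = [
    "CellObservation",
    "DetectionModel",
    "QcReport",
    "StationaryValidation",
    "classify_expressing_cells",
    "estimate_detection_efficiency",
    "correct_foci_per_cell",
    "stationary_phase_validation",
]


@dataclass(frozen=True)
class CellObservation:
    """One cell's record from a focus-counting experiment."""

    cell_id: str
    background_fluorescence: float
    focus_count: int
    focus_positions: tuple[tuple[float, float], ...] | None = None
    cell_length: float | None = None

    def __post_init__(self) -> None:
        if self.background_fluorescence < 0:
            raise DataError(f"{self.cell_id}: negative background fluorescence")
        if self.focus_count < 0:
            raise DataError(f"{self.cell_id}: negative focus count")
        if self.focus_positions is not None and len(self.focus_positions) != self.focus_count:
            raise DataError(
                f"{self.cell_id}: focus_count {self.focus_count} does not match "
                f"{len(self.focus_positions)} recorded positions"
            )


@dataclass
class DetectionModel:
    """Focus detection efficiency for one experiment.

    ``inefficiency`` is the whole-cell miss probability i; efficiency is
    e = 1 - i.  ``correction_applied`` records the additive foci/cell
    delta from the most recent correction.
    """

    expressing_fraction: float
    inefficiency: float
    efficiency: float = field(init=False)
    correction_applied: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.expressing_fraction <= 1:
            raise DomainError("expressing_fraction must be in (0, 1]")
        if not 0 <= self.inefficiency < 1:
            raise DomainError("inefficiency must be in [0, 1)")
        self.efficiency = 1.0 - self.inefficiency


@dataclass
class QcReport:
    """Partition of a field of cells into expressing / non-expressing."""

    expressing: list[CellObservation]
    non_expressing: list[CellObservation]
    threshold: float | None
    excluded_fraction: float
    separable: bool


def _two_cluster_split(values: np.ndarray) -> tuple[int, float]:
    """Exact 1-D two-cluster least-squares split of sorted values.

    Returns (split index k, total within-cluster SSE) where the low
    cluster is values[:k].  Equivalent to k-means with k=2 in one
    dimension, solved exhaustively (deterministic).
    """
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    csq = np.concatenate([[0.0], np.cumsum(values**2)])

    def sse(lo: int, hi: int) -> float:  # [lo, hi)
        m = hi - lo
        s = csum[hi] - csum[lo]
        q = csq[hi] - csq[lo]
        return q - s * s / m

    best_k, best = 1, math.inf
    for k in range(1, n):
        total = sse(0, k) + sse(k, n)
        if total < best:
            best, best_k = total, k
    return best_k, best


def classify_expressing_cells(
    cells: list[CellObservation],
    *,
    min_cells: int = 20,
    separation_factor: float = 2.0,
) -> QcReport:
    """Partition cells into expressing / non-expressing by background
    fluorescence.

    Non-expressing cells (typically a few percent of a field) form a
    distinct low mode in the background-fluorescence histogram.  The
    split is the exact two-cluster least-squares partition of the log
    fluorescence values; it is accepted only if the two cluster means
    are separated by more than ``separation_factor`` times the combined
    within-cluster spread.  Otherwise the distribution is treated as
    unimodal: a warning is raised and every cell is classified as
    expressing.
    """
    if len(cells) < min_cells:
        raise DataError(f"need at least {min_cells} cells, got {len(cells)}")
    fluor = np.array([c.background_fluorescence for c in cells], dtype=float)
    if not np.all(np.isfinite(fluor)):
        raise DataError("non-finite background fluorescence values")

    logf = np.log(np.maximum(fluor, np.finfo(float).tiny))
    order = np.argsort(logf, kind="stable")
    sorted_log = logf[order]

    k, _ = _two_cluster_split(sorted_log)
    low, high = sorted_log[:k], sorted_log[k:]
    mu_low, mu_high = float(low.mean()), float(high.mean())
    sd_low = float(low.std()) if len(low) > 1 else 0.0
    sd_high = float(high.std()) if len(high) > 1 else 0.0
    gap = mu_high - mu_low
    spread = math.hypot(sd_low, sd_high)

    separable = gap > separation_factor * spread and spread > 0 or (spread == 0 and gap > 0)
    if not separable:
        warnings.warn(
            "background fluorescence looks unimodal (no separable low mode); "
            "classifying all cells as expressing",
            stacklevel=2,
        )
        return QcReport(
            expressing=list(cells),
            non_expressing=[],
            threshold=None,
            excluded_fraction=0.0,
            separable=False,
        )

    threshold_log = 0.5 * (sorted_log[k - 1] + sorted_log[k])
    threshold = float(math.exp(threshold_log))
    non_idx = set(order[:k].tolist())
    expressing = [c for j, c in enumerate(cells) if j not in non_idx]
    non_expressing = [c for j, c in enumerate(cells) if j in non_idx]
    return QcReport(
        expressing=expressing,
        non_expressing=non_expressing,
        threshold=threshold,
        excluded_fraction=len(non_expressing) / len(cells),
        separable=True,
    )


def estimate_detection_efficiency(
    expressing_cells: list[CellObservation],
) -> DetectionModel:
    """Estimate detection inefficiency from the zero-focus fraction.

    Assumes all input cells express the fluorescent repressor, so a cell
    with zero foci reflects a whole-cell detection failure (every cell
    carries at least one copy of the locus).
    """
    if not expressing_cells:
        raise DataError("no expressing cells supplied")
    n_zero = sum(1 for c in expressing_cells if c.focus_count == 0)
    n = len(expressing_cells)
    if n_zero == n:
        raise DataError("all cells have zero foci: no detectable signal")
    return DetectionModel(expressing_fraction=1.0, inefficiency=n_zero / n)


def correct_foci_per_cell(raw_mean: float, model: DetectionModel) -> float:
    """Correct a raw mean focus count for detection inefficiency.

    corrected = raw / e.  The correction delta is recorded on the model.
    """
    if raw_mean < 0:
        raise DomainError(f"raw_mean must be >= 0, got {raw_mean}")
    if not model.efficiency > 0:
        raise DomainError("efficiency must be positive")
    corrected = raw_mean / model.efficiency
    model.correction_applied = corrected - raw_mean
    return corrected


@dataclass
class StationaryValidation:
    corrected_foci_per_cell: float
    chromosomes_per_cell: float
    absolute_error: float
    tolerance: float
    passed: bool


def stationary_phase_validation(
    cells: list[CellObservation],
    chromosomes_per_cell: float,
    *,
    detection: DetectionModel | None = None,
    tolerance: float = 0.05,
) -> StationaryValidation:
    """Validate the detection correction on cohesion-free cells.

    Stationary-phase cells have fully replicated, fully segregated
    chromosomes, so the corrected foci/cell should equal the
    chromosomes/cell measured independently by flow cytometry.
    """
    if detection is None:
        detection = estimate_detection_efficiency(cells)
    raw_mean = float(np.mean([c.focus_count for c in cells]))
    corrected = correct_foci_per_cell(raw_mean, detection)
    err = abs(corrected - chromosomes_per_cell)
    return StationaryValidation(
        corrected_foci_per_cell=corrected,
        chromosomes_per_cell=chromosomes_per_cell,
        absolute_error=err,
        tolerance=tolerance,
        passed=err <= tolerance,
    )
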