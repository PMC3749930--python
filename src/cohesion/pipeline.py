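"""End-to-end cohesion-assay driver.

Chains the batch-culture assay exactly as performed at the bench: locus
copy number from rifampicin-runoff origins per cell times the
locus:oriC qPCR ratio; foci per cell from the imaging table after
non-expressing-cell exclusion and detection-inefficiency correction;
then the copies-per-focus statistic and its model inversion to a
cohesion duration.  Every intermediate value is recorded in a
provenance log keyed by stage, together with the seed and a hash of the
configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from cohesion import foci_qc, population_model, qpcr
from cohesion.errors import CohesionError, DataError
from cohesion.foci_qc import CellObservation
from cohesion.qpcr import QpcrRecord, RunoffHistogram

__all__ = ["PipelineConfig", "AssayBundle", "run_cohesion_assay", "run_cohesion_assay_files"]


@dataclass
class PipelineConfig:
    """Thresholds and conventions for one pipeline run."""

    generation_time: float
    seed: int = 0
    replicate_spread_warn: float = 0.5
    roadblock_threshold: float = 1.5
    stationary_tolerance: float = 0.05
    output_dir: str | None = None

    def config_hash(self) -> str:
        fields = asdict(self)
        fields.pop("output_dir", None)  # where results land is not what they are
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class AssayBundle:
    """All inputs for one locus's batch cohesion measurement."""

    locus: str
    cells: list[CellObservation]
    locus_qpcr: QpcrRecord
    oric_qpcr: QpcrRecord
    runoff: RunoffHistogram
    roadblock_upstream: QpcrRecord | None = None
    roadblock_downstream: QpcrRecord | None = None


def run_cohesion_assay(
    bundles: list[AssayBundle],
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict]:
    """Run the full batch cohesion assay for each locus bundle.

    Returns a per-locus result table (copies/cell, raw and corrected
    foci/cell, copies/focus, cohesion minutes, QC flags) and the
    provenance log.  A stage failure aborts with the stage and locus
    named in the exception.
    """
    provenance: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "loci": {},
    }
    rows = []
    for bundle in bundles:
        locus = bundle.locus
        log: dict = {}
        try:
            # --- roadblock QC (optional, aborts on planted fork block)
            if bundle.roadblock_upstream is not None and bundle.roadblock_downstream is not None:
                rb = qpcr.roadblock_ratio(
                    bundle.roadblock_upstream,
                    bundle.roadblock_downstream,
                    flag_threshold=config.roadblock_threshold,
                )
                log["roadblock_ratio"] = rb.ratio
                if rb.flagged:
                    raise DataError(
                        f"replication roadblock at {locus}: upstream:downstream "
                        f"ratio {rb.ratio:.2f} > {rb.threshold}"
                    )

            # --- copy number: runoff origins/cell x locus:oriC ratio
            ratio = qpcr.relative_ratio(
                bundle.locus_qpcr, bundle.oric_qpcr,
                spread_warn_cycles=config.replicate_spread_warn,
            )
            log["locus_to_oric_ratio"] = ratio
            runoff = qpcr.copies_per_cell_from_runoff(bundle.runoff, ratio)
            log["origins_per_cell"] = runoff.origins_per_cell
            log["copies_per_cell"] = runoff.copies_per_cell

            # --- foci per cell: classify, estimate, correct
            report = foci_qc.classify_expressing_cells(bundle.cells)
            log["excluded_fraction"] = report.excluded_fraction
            detection = foci_qc.estimate_detection_efficiency(report.expressing)
            log["detection_inefficiency"] = detection.inefficiency
            raw_mean = float(np.mean([c.focus_count for c in report.expressing]))
            corrected = foci_qc.correct_foci_per_cell(raw_mean, detection)
            log["foci_raw"] = raw_mean
            log["foci_corrected"] = corrected
            log["correction_applied"] = detection.correction_applied

            # --- cohesion statistic and model inversion
            estimate = population_model.batch_cohesion_statistic(
                runoff.copies_per_cell,
                corrected,
                generation_time=config.generation_time,
                foci_per_cell_raw=raw_mean,
            )
            log["copies_per_focus"] = estimate.copies_per_focus
            log["cohesion_minutes"] = estimate.cohesion_minutes
            log["sub_unity_flag"] = estimate.sub_unity
        except CohesionError as exc:
            raise type(exc)(f"[locus {locus}] {exc}") from exc
        provenance["loci"][locus] = log
        rows.append(
            {
                "locus": locus,
                "copies_per_cell": runoff.copies_per_cell,
                "foci_raw": raw_mean,
                "efficiency": detection.efficiency,
                "foci_corrected": corrected,
                "copies_per_focus": estimate.copies_per_focus,
                "cohesion_min": estimate.cohesion_minutes,
                "sub_unity": estimate.sub_unity,
                "config_hash": provenance["config_hash"],
                "seed": config.seed,
            }
        )
    table = pd.DataFrame(rows)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohesion_batch.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return table, provenance


def run_cohesion_assay_files(
    locus: str,
    cells_csv,
    qpcr_csv,
    runoff_csv,
    config: PipelineConfig,
    oric_name: str = "oriC",
) -> tuple[pd.DataFrame, dict]:
    """File-based wrapper around :func:`run_cohesion_assay` for one locus."""
    from cohesion import io as cio

    cells = cio.read_cells_csv(cells_csv)
    records = cio.read_qpcr_csv(qpcr_csv)
    by_target = {r.target_locus: r for r in records}
    if locus not in by_target or oric_name not in by_target:
        raise DataError(f"qPCR table must contain targets {locus!r} and {oric_name!r}")
    bundle = AssayBundle(
        locus=locus,
        cells=cells,
        locus_qpcr=by_target[locus],
        oric_qpcr=by_target[oric_name],
        runoff=cio.read_runoff_csv(runoff_csv),
    )
    return run_cohesion_assay([bundle], config)
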