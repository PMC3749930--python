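"""Readers and writers for the plain-text formats the pipeline speaks.

CSV dialects are one-table-per-file with a header row.  Genomes are
FASTA (read through Biopython).  Binding tracks are bedGraph:
**on disk** intervals are 0-based half-open ``[start, end)`` per the
UCSC convention; **internally** coordinates are 1-based fully closed,
so disk ``[0, 1000)`` is internal ``[1, 1000]`` (``start+1 .. end``).
Point probes on a track are placed at interval midpoints.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from cohesion.errors import DataError
from cohesion.foci_qc import CellObservation
from cohesion.genomics import GenomeTrack, LocusAnnotation
from cohesion.qpcr import ChipSample, QpcrRecord, RunoffHistogram
from cohesion.synchrony import TimecourseSample
from cohesion.timelapse import Trajectory

__all__ = [
    "read_cells_csv",
    "write_cells_csv",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_qpcr_csv",
    "write_qpcr_csv",
    "read_runoff_csv",
    "write_runoff_csv",
    "read_chip_csv",
    "write_chip_csv",
    "read_locus_csv",
    "write_locus_csv",
    "read_trajectories_csv",
    "write_trajectories_csv",
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "bedgraph_to_track",
    "track_to_bedgraph",
    "write_json",
]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------- cells

def read_cells_csv(path) -> list[CellObservation]:
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "background_fluorescence", "focus_count"], path)
    cells = []
    has_pos = "focus_positions" in df.columns
    for _, row in df.iterrows():
        positions = None
        if has_pos and isinstance(row["focus_positions"], str) and row["focus_positions"]:
            positions = tuple(
                tuple(float(v) for v in pair.split(":")) for pair in row["focus_positions"].split(";")
            )
        cells.append(
            CellObservation(
                cell_id=str(row["cell_id"]),
                background_fluorescence=float(row["background_fluorescence"]),
                focus_count=int(row["focus_count"]),
                focus_positions=positions,  # type: ignore[arg-type]
                cell_length=float(row["cell_length"]) if "cell_length" in df.columns and pd.notna(row.get("cell_length")) else None,
            )
        )
    return cells


def write_cells_csv(cells: list[CellObservation], path) -> None:
    rows = []
    for c in cells:
        pos = ""
        if c.focus_positions:
            pos = ";".join(f"{x:g}:{y:g}" for x, y in c.focus_positions)
        rows.append(
            {
                "cell_id": c.cell_id,
                "background_fluorescence": c.background_fluorescence,
                "focus_count": c.focus_count,
                "focus_positions": pos,
                "cell_length": c.cell_length if c.cell_length is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ----------------------------------------------------------- timecourse

def read_timecourse_csv(path) -> list[TimecourseSample]:
    df = pd.read_csv(path)
    _require_columns(df, ["time_min", "copies_per_cell", "foci_per_cell", "n_cells"], path)
    return [
        TimecourseSample(
            time_after_birth=float(r["time_min"]),
            mean_copy_number=float(r["copies_per_cell"]),
            mean_foci=float(r["foci_per_cell"]),
            n_cells=int(r["n_cells"]),
        )
        for _, r in df.iterrows()
    ]


def write_timecourse_csv(samples: list[TimecourseSample], path, locus: str = "gln") -> None:
    pd.DataFrame(
        {
            "time_min": [s.time_after_birth for s in samples],
            "copies_per_cell": [s.mean_copy_number for s in samples],
            "foci_per_cell": [s.mean_foci for s in samples],
            "n_cells": [s.n_cells for s in samples],
            "locus": locus,
        }
    ).to_csv(path, index=False)


# ----------------------------------------------------------------- qPCR

def read_qpcr_csv(path) -> list[QpcrRecord]:
    """Long-format Ct table: sample, target, replicate, ct [, efficiency]."""
    df = pd.read_csv(path)
    _require_columns(df, ["sample", "target", "ct"], path)
    records = []
    for (sample, target), grp in df.groupby(["sample", "target"], sort=False):
        eff = float(grp["efficiency"].iloc[0]) if "efficiency" in df.columns else 1.0
        records.append(
            QpcrRecord(
                sample_id=str(sample),
                target_locus=str(target),
                replicate_cts=tuple(float(c) for c in grp["ct"]),
                amplification_efficiency=eff,
            )
        )
    return records


def write_qpcr_csv(records: list[QpcrRecord], path) -> None:
    rows = []
    for rec in records:
        for i, ct in enumerate(rec.replicate_cts, start=1):
            rows.append(
                {
                    "sample": rec.sample_id,
                    "target": rec.target_locus,
                    "replicate": i,
                    "ct": ct,
                    "efficiency": rec.amplification_efficiency,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------- runoff

def read_runoff_csv(path) -> RunoffHistogram:
    df = pd.read_csv(path)
    _require_columns(df, ["fluorescence", "count"], path)
    return RunoffHistogram(
        bin_centers=df["fluorescence"].to_numpy(float),
        counts=df["count"].to_numpy(float),
    )


def write_runoff_csv(hist: RunoffHistogram, path) -> None:
    pd.DataFrame({"fluorescence": hist.bin_centers, "count": hist.counts}).to_csv(
        path, index=False
    )


# ----------------------------------------------------------------- ChIP

def read_chip_csv(path) -> list[ChipSample]:
    df = pd.read_csv(path)
    _require_columns(df, ["locus", "ct_ip", "ct_input"], path)
    return [
        ChipSample(locus=str(r["locus"]), ct_ip=float(r["ct_ip"]), ct_input=float(r["ct_input"]))
        for _, r in df.iterrows()
    ]


def write_chip_csv(samples: list[ChipSample], path) -> None:
    pd.DataFrame(
        {
            "locus": [s.locus for s in samples],
            "ct_ip": [s.ct_ip for s in samples],
            "ct_input": [s.ct_input for s in samples],
        }
    ).to_csv(path, index=False)


# ------------------------------------------------------------- loci CSV

def read_locus_csv(path) -> list[LocusAnnotation]:
    df = pd.read_csv(path)
    _require_columns(df, ["name", "position", "cohesion_minutes"], path)
    return [
        LocusAnnotation(
            name=str(r["name"]),
            position=int(r["position"]),
            cohesion_minutes=float(r["cohesion_minutes"]),
            locus_class=str(r["class"]) if "class" in df.columns else "non-snap",
        )
        for _, r in df.iterrows()
    ]


def write_locus_csv(loci: list[LocusAnnotation], path) -> None:
    pd.DataFrame(
        {
            "name": [l.name for l in loci],
            "position": [l.position for l in loci],
            "cohesion_minutes": [l.cohesion_minutes for l in loci],
            "class": [l.locus_class for l in loci],
        }
    ).to_csv(path, index=False)


# ----------------------------------------------------------- timelapse

def read_trajectories_csv(path) -> list[Trajectory]:
    """Long format: cell_id, time_min, focus_index, x_um, y_um."""
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "time_min", "focus_index", "x_um", "y_um"], path)
    trajs = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        times = sorted(grp["time_min"].unique())
        frames = []
        for t in times:
            sub = grp[grp["time_min"] == t].sort_values("focus_index")
            frames.append([(float(r["x_um"]), float(r["y_um"])) for _, r in sub.iterrows()])
        trajs.append(
            Trajectory(cell_id=str(cell_id), frame_times=np.array(times, float), foci_per_frame=frames)
        )
    return trajs


def write_trajectories_csv(trajs: list[Trajectory], path) -> None:
    rows = []
    for tr in trajs:
        for t, foci in zip(tr.frame_times, tr.foci_per_frame):
            for j, (x, y) in enumerate(foci):
                rows.append(
                    {"cell_id": tr.cell_id, "time_min": t, "focus_index": j, "x_um": x, "y_um": y}
                )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """All records; soft-wrapped lines are concatenated by the parser."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ------------------------------------------------------------- bedGraph

def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph into (chrom, start, end, value); disk coordinates
    (0-based half-open) are preserved in the frame."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise DataError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t{r['value']:g}\n")


def bedgraph_to_track(df: pd.DataFrame, genome_length: int, circular: bool = True) -> GenomeTrack:
    """Convert disk intervals to an internal point track.

    Disk ``[start, end)`` 0-based maps to internal closed
    ``[start+1, end]`` 1-based; each interval becomes one probe at its
    (internal) midpoint carrying the interval's value.
    """
    start1 = df["start"].to_numpy(np.int64) + 1
    end1 = df["end"].to_numpy(np.int64)
    mid = (start1 + end1) // 2
    order = np.argsort(mid, kind="stable")
    return GenomeTrack(
        genome_length=genome_length,
        positions=mid[order],
        values=df["value"].to_numpy(float)[order],
        circular=circular,
    )


def track_to_bedgraph(track: GenomeTrack, chrom: str = "chr", span: int = 1) -> pd.DataFrame:
    """Each probe at internal 1-based position p becomes the disk
    interval [p-1, p-1+span)."""
    start = track.positions.astype(np.int64) - 1
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": np.minimum(start + span, track.genome_length),
            "value": track.values,
        }
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
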