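"""Polycistronic transcription-unit delineation from coverage continuity.

Plastid genes are transcribed in polycistronic primary mRNAs; contiguous
read coverage across gene boundaries is the evidence for co-transcription.
Units are maximal runs of positions at or above a depth threshold, with
circular wrap-around merged; member genes are assigned sense/antisense
orientation relative to the unit's presumed strand (the majority strand of
its protein-coding members), which is how an antisense tRNA inside a
protein-coding operon is recognized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .plastome import AnnotatedPlastome, GeneFeature, Interval


@dataclass
class TranscriptionUnit:
    interval: Interval  # may span the origin
    presumed_strand: str  # '+', '-' or 'mixed'
    members: list[tuple[GeneFeature, str]]  # (feature, 'sense'|'antisense')
    mean_depth: float

    def member_names(self) -> list[str]:
        return [f.name for f, _ in self.members]


def _covered_runs(covered: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Maximal 0-based [start, end] runs of True, gaps <= max_gap merged,
    circular wrap-around merged."""
    n = len(covered)
    if not covered.any():
        return []
    if covered.all():
        return [(0, n - 1)]
    edges = np.flatnonzero(np.diff(covered.astype(np.int8)))
    starts = list((edges[covered[edges + 1]] + 1))
    ends = list(edges[~covered[edges + 1]])
    if covered[0]:
        starts.insert(0, 0)
    if covered[-1]:
        ends.append(n - 1)
    runs = list(zip(starts, ends))
    # merge internal gaps <= max_gap
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe - 1 <= max_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    # circular wrap: merge last into first when the origin gap is small enough
    if len(merged) > 1:
        fs, fe = merged[0]
        ls, le = merged[-1]
        if (n - le - 1) + fs <= max_gap:
            merged[0] = (ls, fe)  # start > end marks origin-spanning
            merged.pop()
    return [(int(s), int(e)) for s, e in merged]


def delineate_units(
    depth: np.ndarray,
    genome: AnnotatedPlastome,
    d_min: int = 1,
    max_gap: int = 0,
) -> list[TranscriptionUnit]:
    """Segment the depth track into transcription units.

    A unit is a maximal run of positions with depth >= ``d_min``; runs
    separated by <= ``max_gap`` uncovered positions are merged, including
    across the origin.  The presumed strand is the majority strand of the
    protein-coding members ('mixed' on a tie or with none).
    """
    depth = np.asarray(depth)
    if len(depth) != genome.length:
        raise ValueError("depth length != genome length")
    n = genome.length
    units = []
    for s0, e0 in _covered_runs(depth >= d_min, max_gap):
        iv = Interval(s0 + 1, e0 + 1)
        members = [f for f in genome.features if _overlaps(f, iv, n)]
        coding_strands = [f.strand for f in members if f.is_coding]
        plus = coding_strands.count("+")
        minus = coding_strands.count("-")
        if plus > minus:
            strand = "+"
        elif minus > plus:
            strand = "-"
        else:
            strand = "mixed"
        # sense iff the member's strand equals the unit's presumed strand
        # (so every member of a 'mixed' unit reports antisense-ambiguous)
        oriented = [
            (f, "sense" if f.strand == strand else "antisense") for f in members
        ]
        if s0 <= e0:
            d = depth[s0 : e0 + 1]
        else:
            d = np.concatenate([depth[s0:], depth[: e0 + 1]])
        units.append(
            TranscriptionUnit(
                interval=iv,
                presumed_strand=strand,
                members=oriented,
                mean_depth=float(d.mean()),
            )
        )
    return units


def _overlaps(f: GeneFeature, iv: Interval, n: int) -> bool:
    if iv.start <= iv.end:
        return not (f.end < iv.start or f.start > iv.end)
    return f.end >= iv.start or f.start <= iv.end


def unit_report(
    units: list[TranscriptionUnit], genome: AnnotatedPlastome
) -> pd.DataFrame:
    """One row per (unit, member gene), with orientation and pseudogene flag."""
    rows = []
    for i, u in enumerate(units, start=1):
        for f, orientation in u.members:
            rows.append(
                {
                    "unit": i,
                    "unit_start": u.interval.start,
                    "unit_end": u.interval.end,
                    "unit_strand": u.presumed_strand,
                    "gene": f.name,
                    "copy": f.copy_index,
                    "gene_strand": f.strand,
                    "orientation": orientation,
                    "pseudogene": f.kind == "pseudogene",
                    "mean_depth": round(u.mean_depth, 2),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "unit", "unit_start", "unit_end", "unit_strand", "gene", "copy",
            "gene_strand", "orientation", "pseudogene", "mean_depth",
        ],
    )


def write_units_gff3(
    units: list[TranscriptionUnit], genome: AnnotatedPlastome, path
) -> None:
    from pathlib import Path

    lines = ["##gff-version 3"]
    for i, u in enumerate(units, start=1):
        strand = u.presumed_strand if u.presumed_strand in "+-" else "."
        lines.append(
            "\t".join(
                [
                    genome.identifier, "plastoscope", "transcribed_region",
                    str(u.interval.start), str(u.interval.end), ".", strand, ".",
                    f"ID=unit{i};members={','.join(u.member_names())}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
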