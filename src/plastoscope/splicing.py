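"""Intron-splicing detection from gapped read alignments.

A spliced read aligns with an N (reference-skip) CIGAR operation across the
excised intron; the skip's flanking aligned bases define a splice junction.
Annotated introns are then scored spliced / unspliced / no_data by matching
junctions to their boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .ingest import AlignedRead, parse_cigar
from .plastome import AnnotatedPlastome, GeneFeature


@dataclass
class SpliceJunction:
    """A donor/acceptor pair: the exon-adjacent aligned bases flanking a skip."""

    donor: int  # last aligned reference base before the gap (1-based)
    acceptor: int  # first aligned reference base after the gap
    supporting_reads: int
    matched_intron: Optional[tuple[GeneFeature, int]] = None

    @property
    def intron_interval(self) -> tuple[int, int]:
        return self.donor + 1, self.acceptor - 1


def extract_junctions(reads: Iterable[AlignedRead]) -> list[SpliceJunction]:
    """One junction per distinct (donor, acceptor) with summed support.

    Multi-gap reads contribute one junction per N operation.  Junctions are
    returned sorted by (donor, acceptor).
    """
    support: dict[tuple[int, int], int] = {}
    for read in reads:
        rpos = read.start  # 1-based position of next reference base
        for op, length in parse_cigar(read.cigar):
            if op in "M=X":
                rpos += length
            elif op == "D":
                rpos += length
            elif op == "N":
                key = (rpos - 1, rpos + length)
                support[key] = support.get(key, 0) + 1
                rpos += length
    return [
        SpliceJunction(donor=d, acceptor=a, supporting_reads=c)
        for (d, a), c in sorted(support.items())
    ]


def score_introns(
    junctions: list[SpliceJunction],
    genome: AnnotatedPlastome,
    tolerance: int = 0,
    depth: np.ndarray | None = None,
) -> pd.DataFrame:
    """Score every annotated intron as spliced / unspliced / no_data.

    An intron is spliced when some junction matches both boundaries within
    ``tolerance`` bp.  With a ``depth`` array, introns whose span carries no
    reads at all are reported ``no_data`` instead of ``unspliced``.
    """
    rows = []
    for f in genome.features:
        for i, (istart, iend) in enumerate(f.introns()):
            match = None
            for j in junctions:
                js, je = j.intron_interval
                if abs(js - istart) <= tolerance and abs(je - iend) <= tolerance:
                    match = j
                    j.matched_intron = (f, i)
                    break
            if match is not None:
                status = "spliced"
                sup = match.supporting_reads
            else:
                sup = 0
                if depth is not None and not depth[istart - 1 : iend].any():
                    status = "no_data"
                else:
                    status = "unspliced"
            rows.append(
                {
                    "gene": f.name,
                    "copy": f.copy_index,
                    "intron": i + 1,
                    "start": istart,
                    "end": iend,
                    "status": status,
                    "junction_support": sup,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "copy", "intron", "start", "end", "status", "junction_support"],
    )


def write_junctions_bed(
    junctions: list[SpliceJunction], genome: AnnotatedPlastome, path: str | Path
) -> None:
    """BED6 export of junction intron spans (0-based half-open)."""
    lines = []
    for i, j in enumerate(junctions, start=1):
        s, e = j.intron_interval
        lines.append(
            f"{genome.identifier}\t{s - 1}\t{e}\tjunction{i}\t{j.supporting_reads}\t."
        )
    Path(path).write_text("\n".join(lines) + "\n")
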