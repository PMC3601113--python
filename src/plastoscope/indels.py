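"""Comparative indel cataloguing from aligned plastome sequences.

Takes a precomputed gapped alignment (aligned multi-FASTA); each maximal gap
run in a pairwise comparison against the chosen reference is one indel,
positioned at the reference base immediately before the gap and classified
by genomic region (CDS / intron / IGS / tRNA / rRNA) using the reference
annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import AlignIO

from .plastome import AnnotatedPlastome, RegionClass, classify_position


@dataclass
class IndelRecord:
    reference_position: int  # reference base before the gap (1-based)
    length: int
    kind: str  # 'insertion' | 'deletion' relative to the reference
    other: str  # name of the compared sequence
    region: Optional[RegionClass] = None

    @property
    def region_label(self) -> str:
        if self.region is None:
            return ""
        return self.region.label


def read_alignment_fasta(path: str | Path) -> list[tuple[str, str]]:
    aln = AlignIO.read(str(path), "fasta")
    return [(rec.id, str(rec.seq).upper()) for rec in aln]


def catalog_indels(
    alignment: list[tuple[str, str]],
    reference_index: int = 0,
    genome: AnnotatedPlastome | None = None,
) -> list[IndelRecord]:
    """Catalog indels of every non-reference sequence against the reference.

    A gap run in the other sequence is a deletion; a gap run in the
    reference is an insertion.  Adjacent gap runs separated by at least one
    match column are separate indels.  Columns gapped in both sequences of a
    pair are skipped.
    """
    if not alignment:
        raise ValueError("empty alignment")
    ncol = len(alignment[0][1])
    if any(len(s) != ncol for _, s in alignment):
        raise ValueError("alignment sequences differ in length")
    for col in range(ncol):
        if all(s[col] == "-" for _, s in alignment):
            raise ValueError(f"alignment column {col + 1} is all-gap")
    ref_name, ref = alignment[reference_index]
    records: list[IndelRecord] = []
    for idx, (name, other) in enumerate(alignment):
        if idx == reference_index:
            continue
        refpos = 0  # ungapped reference coordinate consumed so far
        run: Optional[list] = None  # [kind, flank_position, length]

        def flush(run):
            if run is not None:
                records.append(IndelRecord(run[1], run[2], run[0], name))

        for rc, oc in zip(ref, other):
            if rc == "-" and oc == "-":
                continue
            if rc == "-":  # gap in reference: insertion between refpos, refpos+1
                if run is not None and run[0] == "insertion":
                    run[2] += 1
                else:
                    flush(run)
                    run = ["insertion", refpos, 1]
            elif oc == "-":  # gap in other: deletion of reference bases
                refpos += 1
                if run is not None and run[0] == "deletion":
                    run[2] += 1
                else:
                    flush(run)
                    run = ["deletion", refpos - 1, 1]
            else:  # match column ends any run
                refpos += 1
                flush(run)
                run = None
        flush(run)
    for r in records:
        r.reference_position = max(r.reference_position, 1)
        if genome is not None:
            r.region = classify_position(genome, r.reference_position)
    records.sort(key=lambda r: (r.reference_position, r.other))
    return records


def indel_summary(records: list[IndelRecord]) -> dict:
    """Arithmetic over indel lengths plus per-region counts.

    The mean is reported both to one decimal and integer-rounded, since
    published catalogs differ in their rounding convention.
    """
    if not records:
        return {
            "count": 0, "min": 0, "max": 0, "mean": 0.0, "mean_rounded": 0,
            "total": 0, "per_region": {},
        }
    lengths = [r.length for r in records]
    per_region: dict[str, int] = {}
    for r in records:
        label = r.region_label or "unclassified"
        per_region[label] = per_region.get(label, 0) + 1
    mean = sum(lengths) / len(lengths)
    return {
        "count": len(records),
        "min": min(lengths),
        "max": max(lengths),
        "mean": round(mean, 1),
        "mean_rounded": round(mean),
        "total": sum(lengths),
        "per_region": per_region,
    }


def indels_to_dataframe(records: list[IndelRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": r.reference_position,
                "length": r.length,
                "kind": r.kind,
                "sequence": r.other,
                "region": r.region.display if r.region else "",
                "region_label": r.region_label,
            }
            for r in records
        ],
        columns=["position", "length", "kind", "sequence", "region", "region_label"],
    )
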