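"""C-to-U RNA-editing site calling from pileup columns.

Plastid RNA editing converts selected cytidines to uridines in mRNAs.  On an
unstranded library a C-to-U edit in a plus-strand transcript shows up as U
reads over a reference C, while an edit in a minus-strand transcript shows up
over a reference G — as A reads under the strict plus-strand complement
convention, or occasionally reported as U by upstream tools; ``lenient``
orientation accepts whichever of the two is better supported for
minus-strand sites.

A column is accepted when depth >= min_depth, depth <= max_depth,
edited-base support >= min_support and support/depth >= min_frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio.Seq import Seq

from .ingest import PileupColumn
from .plastome import AnnotatedPlastome, RegionClass, classify_position, codon_context

__all__ = [
    "EditingCallParams",
    "EditCall",
    "edited_support",
    "call_editing_sites",
    "annotate_codon_change",
    "summarize_calls",
    "calls_to_dataframe",
    "write_calls_tsv",
    "write_calls_vcf",
]


@dataclass
class EditingCallParams:
    min_depth: int = 10
    min_support: int = 5
    min_frequency: float = 0.5
    min_base_quality: int = 20
    max_depth: int = 2000
    orientation_mode: str = "lenient"  # or "strict"

    def __post_init__(self) -> None:
        if not 0 < self.min_frequency <= 1:
            raise ValueError("min_frequency must be in (0, 1]")
        if self.min_support > self.min_depth:
            raise ValueError("min_support must not exceed min_depth")
        if self.orientation_mode not in ("strict", "lenient"):
            raise ValueError(f"unknown orientation_mode {self.orientation_mode!r}")


@dataclass
class EditCall:
    """One accepted C-to-U editing site."""

    position: int
    strand: str
    ref_base_plus: str
    counts: tuple[int, int, int, int]  # (A, C, G, U), plus-strand oriented
    support: int
    depth: int
    frequency: float
    region: Optional[RegionClass] = None
    codon_change: Optional[str] = None  # "XYZ -> XYZ", transcript orientation
    aa_change: Optional[str] = None  # "X -> Y"

    @property
    def completeness(self) -> str:
        return "complete" if self.support == self.depth else "partial"

    @property
    def region_label(self) -> str:
        return self.region.display if self.region else ""

    @property
    def is_coding(self) -> bool:
        return self.region is not None and self.region.label == "CDS"


def edited_support(
    column: PileupColumn, feature_strand: str, mode: str = "lenient"
) -> tuple[int, str]:
    """Edited-base support for a candidate column, and the plus-strand base
    that carries it.

    For a '+' transcript the edited C reads as U on the plus strand; for a
    '−' transcript the edited C sits under a plus-strand G and its U reads as
    A when complemented onto the plus strand (strict mode).  Lenient mode
    takes the better-supported of A and U for '−' sites, accommodating
    unstranded libraries whose upstream tools report either.
    """
    ref = column.ref_base.upper()
    if feature_strand == "+":
        if ref != "C":
            return 0, "U"
        return column.count_u, "U"
    if ref != "G":
        return 0, "A"
    if mode == "strict":
        return column.count_a, "A"
    if column.count_u > column.count_a:
        return column.count_u, "U"
    return column.count_a, "A"


def _candidate_strand(
    column: PileupColumn, region: Optional[RegionClass]
) -> Optional[str]:
    """Transcript strand to test at a column: the owning feature's strand
    where there is one, else whichever orientation reads the reference base
    as a C (plus-strand C -> '+', plus-strand G -> '−')."""
    if region is not None and region.feature is not None:
        return region.feature.strand
    ref = column.ref_base.upper()
    if ref == "C":
        return "+"
    if ref == "G":
        return "-"
    return None


def call_editing_sites(
    pileup: Iterable[PileupColumn],
    genome: AnnotatedPlastome,
    params: EditingCallParams | None = None,
    annotate: bool = True,
) -> list[EditCall]:
    """Call C-to-U editing sites from pileup columns.

    Only C-to-U (and its plus-strand mirror G-to-A) is considered.  Calls are
    sorted by position and, when ``annotate`` is set, carry region labels and
    codon/amino-acid changes for coding sites.
    """
    params = params or EditingCallParams()
    calls: list[EditCall] = []
    for col in pileup:
        depth = col.depth
        if depth < params.min_depth or depth > params.max_depth:
            continue
        region = classify_position(genome, col.position) if annotate else None
        strand = _candidate_strand(col, region)
        if strand is None:
            continue
        support, _ = edited_support(col, strand, params.orientation_mode)
        if support < params.min_support or support / depth < params.min_frequency:
            continue
        call = EditCall(
            position=col.position,
            strand=strand,
            ref_base_plus=col.ref_base.upper(),
            counts=col.counts,
            support=support,
            depth=depth,
            frequency=support / depth,
            region=region,
        )
        if annotate:
            call = annotate_codon_change(call, genome)
        calls.append(call)
    calls.sort(key=lambda c: c.position)
    return calls


def annotate_codon_change(call: EditCall, genome: AnnotatedPlastome) -> EditCall:
    """Fill codon_change / aa_change for calls in coding exons.

    The codon is reported in transcript orientation, before and after
    replacing the edited base with U (written T); the amino-acid change uses
    the standard genetic code.  Pseudogenes and non-coding regions keep the
    call with codon fields absent.
    """
    region = call.region
    if region is None or region.label != "CDS" or region.feature is None:
        return call
    codon, offset = codon_context(genome, region.feature, call.position)
    if codon[offset - 1] != "C":  # transcript base must be an editable C
        return call
    edited = codon[: offset - 1] + "T" + codon[offset:]
    call.codon_change = f"{codon} -> {edited}"
    call.aa_change = f"{Seq(codon).translate()} -> {Seq(edited).translate()}"
    return call


def summarize_calls(
    calls: list[EditCall], genome: AnnotatedPlastome | None = None
) -> dict:
    """Totals: overall, coding/noncoding split and per-region-label counts."""
    per_region: dict[str, int] = {}
    coding = 0
    nonsynonymous = 0
    for c in calls:
        label = c.region.label if c.region else "unclassified"
        per_region[label] = per_region.get(label, 0) + 1
        if c.is_coding:
            coding += 1
            if c.aa_change:
                before, after = [s.strip() for s in c.aa_change.split("->")]
                if before != after:
                    nonsynonymous += 1
    return {
        "total": len(calls),
        "coding": coding,
        "noncoding": len(calls) - coding,
        "nonsynonymous": nonsynonymous,
        "per_region": per_region,
    }


def calls_to_dataframe(calls: list[EditCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        a, cc, g, u = c.counts
        rows.append(
            {
                "gene": c.region_label,
                "strand": c.strand,
                "position": c.position,
                "base": c.ref_base_plus,
                "A": a,
                "C": cc,
                "G": g,
                "U": u,
                "support": c.support,
                "depth": c.depth,
                "frequency": round(c.frequency, 4),
                "completeness": c.completeness,
                "codon_change": c.codon_change or "-",
                "aa_change": c.aa_change or "-",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "strand", "position", "base", "A", "C", "G", "U",
            "support", "depth", "frequency", "completeness",
            "codon_change", "aa_change",
        ],
    )


def write_calls_tsv(calls: list[EditCall], path: str | Path) -> None:
    calls_to_dataframe(calls).to_csv(path, sep="\t", index=False)


def write_calls_vcf(
    calls: list[EditCall], genome: AnnotatedPlastome, path: str | Path
) -> None:
    """VCF-like export: one record per call, INFO carries support/frequency."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={genome.identifier},length={genome.length}>",
        '##INFO=<ID=SUP,Number=1,Type=Integer,Description="Edited-base support">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Editing frequency">',
        '##INFO=<ID=STRAND,Number=1,Type=String,Description="Transcript strand">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in calls:
        alt = "T" if c.ref_base_plus == "C" else "A"
        lines.append(
            f"{genome.identifier}\t{c.position}\t.\t{c.ref_base_plus}\t{alt}\t.\tPASS\t"
            f"SUP={c.support};DP={c.depth};AF={c.frequency:.4f};STRAND={c.strand}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
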