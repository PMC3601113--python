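"""Alignment ingestion: quality/length filtering, strand-oriented pileups.

Reads come either from SAM/BAM files (via pysam) or from the simulator's
placement records.  Filtering follows the conventions of short-read plastid
transcriptome studies: uniquely mapped reads of at least 30 bp are kept, and
individual bases below the Phred threshold are excluded at pileup time.
Read T is recorded as U in pileup columns (RNA convention).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .plastome import AnnotatedPlastome

log = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
BASES = "ACGU"


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if not ops or "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"unparseable CIGAR {cigar!r}")
    return ops


def cigar_reference_length(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in "MDN=X")


@dataclass
class AlignedRead:
    """One aligned read, reference coordinates 1-based."""

    query_name: str
    start: int
    cigar: str
    strand: str
    sequence: str
    qualities: list[int]
    mapping_quality: int = 60
    nm: Optional[int] = None  # edit distance when the aligner reported one

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"{self.query_name}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        """Last reference base consumed (1-based inclusive, unwrapped)."""
        return self.start + cigar_reference_length(self.cigar) - 1

    def identity(self) -> Optional[float]:
        """Percent identity from CIGAR+NM; None when NM is absent."""
        if self.nm is None:
            return None
        aln = sum(n for op, n in parse_cigar(self.cigar) if op in "MIDX=")
        if aln == 0:
            return None
        return 100.0 * (aln - self.nm) / aln


@dataclass
class IngestParams:
    min_base_quality: int = 20
    min_read_length: int = 30
    min_identity: float = 90.0
    unique_only: bool = True

    def __post_init__(self) -> None:
        if min(self.min_base_quality, self.min_read_length, self.min_identity) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class PileupColumn:
    """Per-position plus-strand-oriented base counts."""

    position: int
    ref_base: str
    count_a: int = 0
    count_c: int = 0
    count_g: int = 0
    count_u: int = 0
    mean_quality: float = 0.0

    @property
    def depth(self) -> int:
        return self.count_a + self.count_c + self.count_g + self.count_u

    def count(self, base: str) -> int:
        return (self.count_a, self.count_c, self.count_g, self.count_u)[
            _BASE_CODE[base.upper()]
        ]

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.count_a, self.count_c, self.count_g, self.count_u)


def read_sam(path: str | Path) -> Iterator[AlignedRead]:
    """Stream mapped reads from a SAM/BAM file."""
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            quals = (
                list(seg.query_qualities)
                if seg.query_qualities is not None
                else [40] * len(seg.query_sequence)
            )
            yield AlignedRead(
                query_name=seg.query_name,
                start=seg.reference_start + 1,
                cigar=seg.cigarstring or f"{len(seg.query_sequence)}M",
                strand="-" if seg.is_reverse else "+",
                sequence=seg.query_sequence.upper(),
                qualities=quals,
                mapping_quality=seg.mapping_quality,
                nm=seg.get_tag("NM") if seg.has_tag("NM") else None,
            )


def filter_reads(
    reads: Iterable[AlignedRead],
    params: IngestParams | None = None,
    stats: dict | None = None,
) -> Iterator[AlignedRead]:
    """Apply read-level filters: length, uniqueness and percent identity.

    Per-base quality filtering is deferred to :func:`build_pileup`.  Reads
    with an unparseable CIGAR are skipped and counted in ``stats``.
    """
    params = params or IngestParams()
    counters = stats if stats is not None else {}
    counters.setdefault("kept", 0)
    counters.setdefault("dropped", 0)
    counters.setdefault("bad_cigar", 0)
    warned_nm = False
    for read in reads:
        try:
            parse_cigar(read.cigar)
        except ValueError:
            counters["bad_cigar"] += 1
            log.warning("skipping %s: bad CIGAR %r", read.query_name, read.cigar)
            continue
        if read.length < params.min_read_length:
            counters["dropped"] += 1
            continue
        if params.unique_only and read.mapping_quality <= 0:
            counters["dropped"] += 1
            continue
        ident = read.identity()
        if ident is None:
            if not warned_nm:
                log.warning("reads without NM tags: identity filter skipped")
                warned_nm = True
        elif ident < params.min_identity:
            counters["dropped"] += 1
            continue
        counters["kept"] += 1
        yield read


def build_pileup(
    reads: Iterable[AlignedRead],
    genome: AnnotatedPlastome,
    params: IngestParams | None = None,
) -> list[PileupColumn]:
    """Build plus-strand-oriented pileup columns over a circular genome.

    Bases below ``min_base_quality`` are excluded from counts; deletions and
    reference skips contribute nothing; insertions and soft clips are
    consumed from the read without counting.  Reads running past the genome
    end wrap around the origin.
    """
    params = params or IngestParams()
    n = genome.length
    counts = np.zeros((4, n), dtype=np.int64)
    qual_sum = np.zeros(n, dtype=np.float64)
    for read in reads:
        seq = np.frombuffer(read.sequence.encode(), dtype=np.uint8)
        quals = np.asarray(read.qualities)
        rpos = read.start - 1  # 0-based reference cursor
        qpos = 0
        for op, length in parse_cigar(read.cigar):
            if op in "M=X":
                idx = np.arange(rpos, rpos + length) % n
                bases = seq[qpos : qpos + length]
                q = quals[qpos : qpos + length]
                code = np.full(length, -1, dtype=np.int64)
                code[bases == ord("A")] = 0
                code[bases == ord("C")] = 1
                code[bases == ord("G")] = 2
                code[(bases == ord("T")) | (bases == ord("U"))] = 3
                keep = (q >= params.min_base_quality) & (code >= 0)
                np.add.at(counts, (code[keep], idx[keep]), 1)
                np.add.at(qual_sum, idx[keep], q[keep])
                rpos += length
                qpos += length
            elif op in "DN":
                rpos += length
            elif op in "IS":
                qpos += length
            # H, P consume nothing
    depth = counts.sum(axis=0)
    columns = []
    for pos0 in np.flatnonzero(depth):
        d = int(depth[pos0])
        columns.append(
            PileupColumn(
                position=int(pos0) + 1,
                ref_base=genome.sequence[pos0],
                count_a=int(counts[0, pos0]),
                count_c=int(counts[1, pos0]),
                count_g=int(counts[2, pos0]),
                count_u=int(counts[3, pos0]),
                mean_quality=float(qual_sum[pos0] / d),
            )
        )
    return columns


def depth_vector(pileup: Iterable[PileupColumn], genome_length: int) -> np.ndarray:
    """Per-base depth array of length ``genome_length``; uncovered = 0."""
    depth = np.zeros(genome_length, dtype=np.int64)
    for col in pileup:
        depth[col.position - 1] = col.depth
    return depth


def pileup_to_dataframe(pileup: Iterable[PileupColumn]) -> pd.DataFrame:
    rows = [
        (c.position, c.ref_base, c.count_a, c.count_c, c.count_g, c.count_u, c.depth)
        for c in pileup
    ]
    return pd.DataFrame(rows, columns=["position", "ref", "A", "C", "G", "U", "depth"])


def write_pileup_tsv(pileup: Iterable[PileupColumn], path: str | Path) -> None:
    pileup_to_dataframe(pileup).to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path: str | Path) -> list[PileupColumn]:
    df = pd.read_csv(path, sep="\t")
    return [
        PileupColumn(
            position=int(r.position),
            ref_base=str(r.ref),
            count_a=int(r.A),
            count_c=int(r.C),
            count_g=int(r.G),
            count_u=int(r.U),
        )
        for r in df.itertuples()
    ]
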