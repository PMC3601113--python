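"""Plastome data model: circular genome, annotation, quadripartite structure.

Coordinates are 1-based inclusive on the plus strand everywhere user-facing,
matching the convention of published chloroplast editing-site tables.
Positions may be given modulo the genome length (the molecule is circular).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "pseudogene", "intron-containing-CDS")

#: classification priority at positions covered by overlapping features
_KIND_PRIORITY = {
    "CDS": 0,
    "intron-containing-CDS": 0,
    "tRNA": 1,
    "rRNA": 2,
    "pseudogene": 3,
}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval; ``start > end`` means it spans the origin."""

    start: int
    end: int

    def length(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end

    def contains(self, pos: int, genome_length: int) -> bool:
        pos = normalize_position(pos, genome_length)
        if self.start <= self.end:
            return self.start <= pos <= self.end
        return pos >= self.start or pos <= self.end


def normalize_position(pos: int, genome_length: int) -> int:
    return (pos - 1) % genome_length + 1


@dataclass
class GeneFeature:
    """A gene with its exon structure on the plus-strand coordinate system.

    ``exons`` are 1-based inclusive intervals, ordered along the plus strand;
    for minus-strand genes the transcript reads the exons right-to-left,
    reverse-complemented.  ``phase`` is the codon offset of the first
    transcript base (0, 1 or 2).
    """

    name: str
    kind: str
    strand: str
    exons: list[tuple[int, int]]
    phase: int = 0
    copy_index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.name}: overlapping exons {(s1, e1)} {(s2, e2)}")

    @property
    def is_coding(self) -> bool:
        return self.kind in ("CDS", "intron-containing-CDS")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exon_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Intervals between consecutive exons (plus-strand order)."""
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def contains_exonic(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def intron_index_at(self, pos: int) -> Optional[int]:
        for i, (s, e) in enumerate(self.introns()):
            if s <= pos <= e:
                return i
        return None


@dataclass
class QuadripartiteStructure:
    """The four canonical plastome regions: LSC, IRb, SSC, IRa."""

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval

    def regions(self) -> dict[str, Interval]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def ir_length(self, genome_length: int) -> int:
        return self.irb.length(genome_length)


@dataclass
class RegionClass:
    """Classification of one genomic position.

    ``label`` is one of CDS, intron, IGS, tRNA, rRNA or pseudogene; CDS, tRNA,
    rRNA and pseudogene hits carry the owning feature, intron hits the feature
    whose exons flank the position, IGS hits the names of the nearest flanking
    genes as ``"geneA - geneB"``.
    """

    label: str
    feature: Optional[GeneFeature] = None
    igs_label: Optional[str] = None
    intron_index: Optional[int] = None

    @property
    def display(self) -> str:
        if self.label == "IGS":
            return self.igs_label or "IGS"
        if self.label == "intron":
            return f"{self.feature.name} intron" if self.feature else "intron"
        return self.feature.name if self.feature else self.label


@dataclass
class AnnotatedPlastome:
    identifier: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    structure: Optional[QuadripartiteStructure] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-DNA characters {sorted(bad)}")
        self.validate()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = self.length
        seen = set()
        for f in self.features:
            if not (1 <= f.start and f.end <= n):
                raise ValueError(
                    f"feature {f.name} interval [{f.start},{f.end}] exceeds "
                    f"sequence length {n}"
                )
            key = (f.name, f.copy_index)
            if key in seen:
                raise ValueError(f"duplicate feature {key}")
            seen.add(key)

    def base(self, pos: int) -> str:
        return self.sequence[normalize_position(pos, self.length) - 1]

    def subseq(self, start: int, end: int) -> str:
        """Inclusive 1-based slice; wraps around the origin when start > end."""
        start = normalize_position(start, self.length)
        end = normalize_position(end, self.length)
        if start <= end:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]

    def interval_seq(self, iv: Interval) -> str:
        return self.subseq(iv.start, iv.end)

    def spliced_transcript(self, feature: GeneFeature) -> str:
        """Mature transcript sequence (exons joined, oriented 5'->3')."""
        joined = "".join(self.subseq(s, e) for s, e in feature.exons)
        return revcomp(joined) if feature.strand == "-" else joined


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _features_from_genbank(record) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    counts: dict[str, int] = {}
    for f in record.features:
        if f.type not in ("CDS", "tRNA", "rRNA"):
            continue
        quals = f.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
        parts = sorted(f.location.parts, key=lambda p: int(p.start))
        exons = [(int(p.start) + 1, int(p.end)) for p in parts]
        strand = "-" if f.location.strand == -1 else "+"
        if "pseudo" in quals or "pseudogene" in quals:
            kind = "pseudogene"
        elif f.type == "CDS":
            kind = "intron-containing-CDS" if len(exons) > 1 else "CDS"
        else:
            kind = f.type
        phase = int(quals.get("codon_start", ["1"])[0]) - 1
        idx = counts.get(name, 0)
        counts[name] = idx + 1
        feats.append(GeneFeature(name, kind, strand, exons, phase, copy_index=idx))
    return feats


def _features_from_gff3(gff3_path: str | Path) -> list[GeneFeature]:
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    feats: list[GeneFeature] = []
    counts: dict[str, int] = {}
    for g in db.features_of_type("gene", order_by="start"):
        name = g.attributes.get("Name", [g.id])[0]
        kind = g.attributes.get("kind", ["CDS"])[0]
        exons = []
        phase = 0
        for ex in db.children(g, featuretype="exon", order_by="start"):
            exons.append((ex.start, ex.end))
            if ex.frame and ex.frame.isdigit():
                phase = int(ex.frame)
        if not exons:
            exons = [(g.start, g.end)]
        idx = counts.get(name, 0)
        counts[name] = idx + 1
        feats.append(GeneFeature(name, kind, g.strand, exons, phase, copy_index=idx))
    return feats


def read_plastome(
    path: str | Path,
    format: str = "genbank",
    gff3: str | Path | None = None,
) -> AnnotatedPlastome:
    """Read a plastome from a GenBank flat file or a FASTA + GFF3 pair.

    Coordinates are normalized to 1-based inclusive plus-strand intervals;
    join/complement locations are decomposed into exon lists with strand.
    """
    path = Path(path)
    if format == "genbank":
        record = SeqIO.read(str(path), "genbank")
        return AnnotatedPlastome(record.id, str(record.seq), _features_from_genbank(record))
    if format == "fasta+gff3":
        if gff3 is None:
            raise ValueError("fasta+gff3 format requires a gff3 path")
        record = SeqIO.read(str(path), "fasta")
        return AnnotatedPlastome(record.id, str(record.seq), _features_from_gff3(gff3))
    raise ValueError(f"unknown format {format!r}")


def write_fasta(genome: AnnotatedPlastome, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.identifier, description="")
    SeqIO.write([rec], str(path), "fasta")


def write_gff3(genome: AnnotatedPlastome, path: str | Path) -> None:
    lines = ["##gff-version 3", f"##sequence-region {genome.identifier} 1 {genome.length}"]
    for f in sorted(genome.features, key=lambda f: f.start):
        fid = f"gene-{f.name}-{f.copy_index}"
        lines.append(
            "\t".join(
                [
                    genome.identifier, "plastoscope", "gene",
                    str(f.start), str(f.end), ".", f.strand, ".",
                    f"ID={fid};Name={f.name};kind={f.kind}",
                ]
            )
        )
        for i, (s, e) in enumerate(f.exons):
            frame = str(f.phase) if (f.is_coding and i == 0) else "."
            lines.append(
                "\t".join(
                    [
                        genome.identifier, "plastoscope", "exon",
                        str(s), str(e), ".", f.strand, frame,
                        f"ID={fid}-exon{i + 1};Parent={fid}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# quadripartite structure
# ---------------------------------------------------------------------------

def _maximal_inverted_repeats(seq: str, min_len: int, seed: int = 20):
    """Maximal exact inverted-repeat pairs via seed-and-extend.

    Matches the sequence against its own reverse complement: a run of seed
    hits on one diagonal is one maximal exact match.  Yields
    ``(iv_a, iv_b, L)`` with disjoint 1-based intervals, iv_a leftmost.
    """
    n = len(seq)
    k = min(seed, min_len)
    if n < 2 * k:
        return []
    rc = revcomp(seq)
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    # diagonal -> sorted seed start positions in rc
    diags: dict[int, list[int]] = {}
    for p in range(n - k + 1):
        for a in index.get(rc[p : p + k], ()):
            diags.setdefault(a - p, []).append(p)
    out = []
    seen = set()
    for d, ps in diags.items():
        ps.sort()
        run_start = ps[0]
        prev = ps[0]
        runs = []
        for p in ps[1:]:
            if p == prev + 1:
                prev = p
            else:
                runs.append((run_start, prev))
                run_start = prev = p
        runs.append((run_start, prev))
        for p0, p1 in runs:
            L = p1 - p0 + k
            if L < min_len:
                continue
            a = p0 + d
            b = n - (p0 + L)  # rc[p0:p0+L] == revcomp(seq[b:b+L])
            iv1, iv2 = sorted([(a + 1, a + L), (b + 1, b + L)])
            if iv1[1] >= iv2[0]:  # overlapping (palindrome) — not an IR pair
                continue
            key = (iv1, iv2)
            if key not in seen:
                seen.add(key)
                out.append((Interval(*iv1), Interval(*iv2), L))
    return out


def detect_quadripartite(
    genome: AnnotatedPlastome, min_ir_len: int = 1000
) -> Optional[QuadripartiteStructure]:
    """Detect the LSC/IRb/SSC/IRa partition from exact inverted repeats.

    Returns the maximal-length pair of disjoint exact inverted repeats of at
    least ``min_ir_len`` bp and the two single-copy regions they bound, the
    larger one labeled LSC.  Ties broken by leftmost start.  Returns ``None``
    when no qualifying repeat exists.
    """
    n = genome.length
    cands = _maximal_inverted_repeats(genome.sequence, min_ir_len)
    if not cands:
        return None
    cands.sort(key=lambda c: (-c[2], c[0].start))
    first, second, _ = cands[0]
    # regions between the repeats, walking the circle
    inner_len = second.start - first.end - 1
    outer_len = n - (second.end - first.start + 1) - inner_len
    if inner_len <= 0 or outer_len <= 0:
        return None  # degenerate: repeats adjacent, no single-copy regions
    inner = Interval(first.end + 1, second.start - 1)
    outer = Interval(
        normalize_position(second.end + 1, n), normalize_position(first.start - 1, n)
    )  # wraps the origin
    if inner_len >= outer_len:
        lsc, ssc = inner, outer
        irb, ira = second, first  # order around circle: LSC(inner), second, SSC, first
    else:
        lsc, ssc = outer, inner
        irb, ira = first, second
    return QuadripartiteStructure(lsc=lsc, irb=irb, ssc=ssc, ira=ira)


# ---------------------------------------------------------------------------
# position classification and codon context
# ---------------------------------------------------------------------------

def classify_position(genome: AnnotatedPlastome, position: int) -> RegionClass:
    """Classify one genomic position as CDS/tRNA/rRNA/pseudogene exon, intron
    or intergenic spacer (IGS).

    Overlapping features resolve by the fixed priority
    CDS > tRNA > rRNA > pseudogene; ambiguity is logged.
    """
    pos = normalize_position(position, genome.length)
    exon_hits = [f for f in genome.features if f.contains_exonic(pos)]
    if exon_hits:
        exon_hits.sort(key=lambda f: (_KIND_PRIORITY[f.kind], f.start))
        if len(exon_hits) > 1:
            log.debug(
                "position %d in %d overlapping features; keeping %s",
                pos, len(exon_hits), exon_hits[0].name,
            )
        f = exon_hits[0]
        label = "CDS" if f.is_coding else f.kind
        return RegionClass(label=label, feature=f)
    for f in genome.features:
        idx = f.intron_index_at(pos)
        if idx is not None:
            return RegionClass(label="intron", feature=f, intron_index=idx)
    return RegionClass(label="IGS", igs_label=_igs_label(genome, pos))


def _igs_label(genome: AnnotatedPlastome, pos: int) -> str:
    n = genome.length
    if not genome.features:
        return "IGS"

    def circ_dist(a: int, b: int) -> int:  # from a forward to b
        return (b - a) % n

    left = min(genome.features, key=lambda f: circ_dist(f.end, pos))
    right = min(genome.features, key=lambda f: circ_dist(pos, f.start))
    return f"{left.name} - {right.name}"


def codon_context(
    genome: AnnotatedPlastome, feature: GeneFeature, position: int
) -> tuple[str, int]:
    """Return (codon, offset) for a position inside a coding exon.

    The codon is read in transcript orientation (reverse-complemented for
    minus-strand genes and spliced across exon junctions); ``offset`` in
    {1, 2, 3} is the queried base's place within that codon.
    """
    if not feature.is_coding:
        raise ValueError(f"no codon frame for {feature.kind} feature {feature.name}")
    pos = normalize_position(position, genome.length)
    plus_idx = 0
    found = False
    for s, e in feature.exons:
        if s <= pos <= e:
            plus_idx += pos - s
            found = True
            break
        plus_idx += e - s + 1
    if not found:
        raise ValueError(f"position {pos} not exonic in {feature.name}")
    transcript = genome.spliced_transcript(feature)
    idx = plus_idx if feature.strand == "+" else len(transcript) - 1 - plus_idx
    cidx = idx - feature.phase
    if cidx < 0:
        raise ValueError(f"position {pos} upstream of codon frame in {feature.name}")
    start = feature.phase + (cidx // 3) * 3
    codon = transcript[start : start + 3]
    if len(codon) < 3:
        raise ValueError(f"position {pos} in trailing partial codon of {feature.name}")
    return codon, cidx % 3 + 1
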