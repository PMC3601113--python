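"""Synthetic plastome and transcriptome generation with machine-readable truth.

Emulates the inputs of a chloroplast transcriptome study: a circular genome
with two exact inverted repeats separating a large and a small single-copy
region; protein-coding, tRNA and rRNA genes on both strands, including
intron-containing genes and pseudogenes (with internal stop codons);
polycistronic transcription units tiling most of the circle; C-to-U edits
planted at chosen sites with chosen editing fractions; partially spliced
introns; and roughly uniform read sampling with base errors.

Every sampling step draws from one seeded generator, so truth-vs-call tests
are exact regression tests.  Genes are planted in the single-copy regions
only, which keeps the inverted repeats byte-exact mirrors of each other.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .ingest import AlignedRead
from .plastome import (
    AnnotatedPlastome,
    GeneFeature,
    Interval,
    QuadripartiteStructure,
    normalize_position,
    revcomp,
    write_fasta,
    write_gff3,
)

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


@dataclass
class SimulationConfig:
    """Study-scale defaults: a 157 kb circle with 26 kb inverted repeats,
    133 genes, 100 bp reads at ~400x depth over ~97% of the genome."""

    seed: int = 0
    genome_length: int = 157_162
    ir_length: int = 26_134
    n_genes: int = 133
    trna_genes: int = 30
    rrna_genes: int = 4
    intron_genes: int = 17
    two_intron_genes: int = 2
    pseudogenes: int = 4
    untranscribed_genes: int = 3
    transcribed_fraction: float = 0.971
    n_edit_sites: int = 31
    edit_sites: Optional[list[tuple[int, float]]] = None
    splice_fraction: float = 0.8
    unspliced_intron_genes: int = 2
    splice_fractions: Optional[dict[tuple[str, int], float]] = None
    operons: Optional[list[tuple[tuple[int, int], str, float]]] = None
    read_length: int = 100
    target_depth: float = 399.0
    base_error_rate: float = 0.001

    def __post_init__(self) -> None:
        for name in ("transcribed_fraction", "splice_fraction", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ir_length < 0:
            raise ValueError("ir_length must be >= 0")
        if self.genome_length < 2 * self.ir_length + 200:
            raise ValueError("genome_length cannot accommodate the inverted repeats")


@dataclass
class PlantedEdit:
    position: int
    fraction: float
    strand: str  # transcript strand
    region_label: str  # CDS / intron / IGS


@dataclass
class PlantedJunction:
    gene: str
    copy_index: int
    intron_index: int
    donor: int  # last base of the upstream exon
    acceptor: int  # first base of the downstream exon
    fraction: float


@dataclass
class PlantedUnit:
    interval: Interval
    strand: str
    expression: float


@dataclass
class ReadRecord:
    name: str
    unit_index: int
    segments: list[tuple[int, int]]  # aligned (start, end) reference intervals
    strand: str
    n_errors: int
    identity: float


@dataclass
class SyntheticTruth:
    structure: Optional[QuadripartiteStructure]
    features: list[GeneFeature]
    units: list[PlantedUnit]
    edits: list[PlantedEdit]
    junctions: list[PlantedJunction]
    untranscribed: list[str]
    transcribed_mask: np.ndarray
    reads: list[ReadRecord] = field(default_factory=list)

    @property
    def transcribed_fraction(self) -> float:
        return float(self.transcribed_mask.mean())

    def expected_depth(self, genome_length: int) -> np.ndarray:
        """Per-base depth implied by the recorded read placements."""
        depth = np.zeros(genome_length, dtype=np.int64)
        for rec in self.reads:
            for s, e in rec.segments:
                idx = np.arange(s - 1, e) % genome_length
                depth[idx] += 1
        return depth


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _random_cds(rng, n_codons: int, pseudo: bool = False) -> str:
    body = ["ATG"] + [_CODONS[i] for i in rng.integers(0, len(_CODONS), n_codons - 2)]
    if pseudo and n_codons > 4:
        body[int(rng.integers(2, n_codons - 2))] = _STOPS[int(rng.integers(0, 3))]
    body.append(_STOPS[int(rng.integers(0, 3))])
    return "".join(body)


def _plan_region_genes(rng, cfg: SimulationConfig, region_len: int, specs: list[dict]):
    """Assign lengths to the genes planned for one single-copy region."""
    if not specs:
        return 0
    budget = int(0.60 * region_len)
    n_cds = sum(1 for s in specs if s["kind"] != "tRNA" and s["kind"] != "rRNA")
    fixed = sum(78 for s in specs if s["kind"] == "tRNA")
    rrna_len = min(1500, max(300, budget // max(1, len(specs))))
    rrna_len -= rrna_len % 3
    fixed += sum(rrna_len for s in specs if s["kind"] == "rRNA")
    # introns drawn first; CDS lengths shrink to whatever budget remains
    intron_total = 0
    for s in specs:
        s["intron_lengths"] = [
            int(rng.integers(150, 601)) for _ in range(s.get("n_introns", 0))
        ]
        intron_total += sum(s["intron_lengths"])
    cds_budget = max(0, budget - fixed - intron_total)
    per_cds = max(63, (cds_budget // max(1, n_cds)) // 3 * 3)
    total = fixed + intron_total
    for s in specs:
        if s["kind"] == "tRNA":
            s["length"] = 78
        elif s["kind"] == "rRNA":
            s["length"] = rrna_len
        else:
            jitter = int(rng.integers(-per_cds // 6, per_cds // 6 + 1)) * 3
            s["length"] = max(63, per_cds + jitter)
            total += s["length"]
    min_gap = 2
    needed = total + min_gap * (len(specs) + 1)
    if needed > region_len:
        raise ValueError(
            f"infeasible packing: {len(specs)} genes need {needed} bp "
            f"but the region is {region_len} bp"
        )
    return total


def _layout_region(rng, specs: list[dict], rstart: int, rend: int) -> None:
    """Place genes sequentially with random intergenic gaps; sets coords."""
    region_len = rend - rstart + 1
    span = sum(s["length"] + sum(s["intron_lengths"]) for s in specs)
    slack = region_len - span
    # split slack into len(specs)+1 gaps of at least 2 bp
    n_gaps = len(specs) + 1
    cuts = np.sort(rng.integers(0, slack - 2 * n_gaps + 1, n_gaps - 1))
    parts = np.diff(np.concatenate([[0], cuts, [slack - 2 * n_gaps]])) + 2
    pos = rstart
    for s, gap in zip(specs, parts[:-1]):
        pos += int(gap)
        exons = []
        remaining = s["length"]
        n_int = len(s["intron_lengths"])
        if n_int:
            exon_lens = [remaining // (n_int + 1) // 3 * 3] * n_int
            exon_lens.append(remaining - sum(exon_lens))
        else:
            exon_lens = [remaining]
        p = pos
        for i, el in enumerate(exon_lens):
            exons.append((p, p + el - 1))
            p += el
            if i < n_int:
                p += s["intron_lengths"][i]
        s["exons"] = exons
        pos = p


def generate_plastome(
    config: SimulationConfig,
) -> tuple[AnnotatedPlastome, SyntheticTruth]:
    """Generate an annotated circular plastome with planted truth.

    Deterministic under a fixed seed.  The planted inverted-repeat pair is
    exact; genes lie on both strands in the single-copy regions; pseudogenes
    contain at least one internal stop codon.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.genome_length
    ir = cfg.ir_length
    sc_total = n - 2 * ir
    if ir > 0:
        ssc_len = max(100, int(round(sc_total * 0.1743)))
        lsc_len = sc_total - ssc_len
        lsc = Interval(1, lsc_len)
        irb = Interval(lsc_len + 1, lsc_len + ir)
        ssc = Interval(lsc_len + ir + 1, lsc_len + ir + ssc_len)
        ira = Interval(lsc_len + ir + ssc_len + 1, n)
        structure = QuadripartiteStructure(lsc=lsc, irb=irb, ssc=ssc, ira=ira)
        regions = [(1, lsc_len), (ssc.start, ssc.end)]
    else:
        structure = None
        lsc_len, ssc_len = n, 0
        regions = [(1, n)]

    # --- plan gene composition -------------------------------------------
    n_other = cfg.trna_genes + cfg.rrna_genes + cfg.pseudogenes
    n_cds = cfg.n_genes - n_other
    if n_cds < cfg.intron_genes:
        raise ValueError("infeasible packing: more intron genes than CDS genes")
    if n_cds < 1:
        raise ValueError("infeasible packing: n_genes too small for gene mix")
    specs: list[dict] = []
    for i in range(n_cds):
        n_introns = 0
        if i < cfg.two_intron_genes and cfg.intron_genes:
            n_introns = 2
        elif i < cfg.intron_genes:
            n_introns = 1
        specs.append(
            {"name": f"cds{i + 1}", "kind": "CDS", "n_introns": n_introns}
        )
    specs += [
        {"name": f"trn{i + 1}", "kind": "tRNA", "n_introns": 0}
        for i in range(cfg.trna_genes)
    ]
    specs += [
        {"name": f"rrn{i + 1}", "kind": "rRNA", "n_introns": 0}
        for i in range(cfg.rrna_genes)
    ]
    specs += [
        {"name": f"psi{i + 1}", "kind": "pseudogene", "n_introns": 0}
        for i in range(cfg.pseudogenes)
    ]
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]
    for s in specs:
        s["strand"] = "+" if rng.random() < 0.5 else "-"

    # split genes across the single-copy regions by length share
    if len(regions) == 2 and ssc_len > 0:
        k_ssc = max(1, int(round(len(specs) * ssc_len / sc_total)))
    else:
        k_ssc = 0
    region_specs = [specs[: len(specs) - k_ssc], specs[len(specs) - k_ssc :]]
    for (rstart, rend), sp in zip(regions, region_specs):
        _plan_region_genes(rng, cfg, rend - rstart + 1, sp)
        _layout_region(rng, sp, rstart, rend)

    # --- write sequence ---------------------------------------------------
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n)
    features: list[GeneFeature] = []
    for s in specs:
        total_exonic = sum(e - st + 1 for st, e in s["exons"])
        if s["kind"] in ("CDS", "pseudogene"):
            transcript = _random_cds(rng, total_exonic // 3, s["kind"] == "pseudogene")
        else:
            letters = np.frombuffer(b"ACGT", dtype=np.uint8)
            transcript = rng.choice(letters, size=total_exonic).tobytes().decode()
        genomic = transcript if s["strand"] == "+" else revcomp(transcript)
        # genomic string laid across the exons in plus-strand order
        off = 0
        for st, e in s["exons"]:
            piece = genomic[off : off + e - st + 1]
            seq[st - 1 : e] = np.frombuffer(piece.encode(), dtype=np.uint8)
            off += e - st + 1
        kind = s["kind"]
        if kind == "CDS" and len(s["exons"]) > 1:
            kind = "intron-containing-CDS"
        features.append(
            GeneFeature(s["name"], kind, s["strand"], s["exons"], phase=0)
        )

    # --- transcription units ---------------------------------------------
    features_sorted = sorted(features, key=lambda f: f.start)
    untranscribed: list[str] = []
    mask = np.ones(n, dtype=bool)
    if cfg.operons is not None:
        mask[:] = False
        units = []
        for (us, ue), strand, expr in cfg.operons:
            iv = Interval(us, ue)
            if us <= ue:
                mask[us - 1 : ue] = True
            else:
                mask[us - 1 :] = True
                mask[:ue] = True
            units.append(PlantedUnit(iv, strand, expr))
    else:
        # leave a few whole genes and a handful of intergenic windows dark
        simple = [
            f for f in features_sorted
            if f.kind in ("tRNA", "CDS") and f.name not in untranscribed
        ]
        picks = rng.permutation(len(simple))[: cfg.untranscribed_genes]
        for i in sorted(picks):
            f = simple[i]
            untranscribed.append(f.name)
            mask[f.start - 1 : f.end] = False
        budget = int(round((1.0 - cfg.transcribed_fraction) * n)) - int(
            (~mask).sum()
        )
        # intergenic pool (1 bp margin so flanking genes stay covered)
        gaps = []
        prev_end = 0
        for f in features_sorted:
            if f.start - 1 - prev_end >= 3:
                gaps.append((prev_end + 2, f.start - 2))
            prev_end = max(prev_end, f.end)
        if n - prev_end >= 3:
            gaps.append((prev_end + 2, n - 1))
        # first window anchored at the origin so no unit wraps position 1
        if budget > 0 and gaps:
            first = gaps[0]
            w = max(1, min(budget // 4 + 1, first[1]))
            mask[:w] = False
            budget -= w
        gaps = gaps[1:]
        order = rng.permutation(len(gaps))
        gi = 0
        while budget > 0 and gi < len(order):
            gs, ge = gaps[order[gi]]
            w = min(budget, ge - gs + 1)
            mid = (gs + ge) // 2
            ws = max(gs, min(mid - w // 2, ge - w + 1))
            mask[ws - 1 : ws - 1 + w] = False
            budget -= w
            gi += 1
        # drop transcribed slivers shorter than a read: they cannot be
        # sampled meaningfully and would appear as degenerate units
        run_start = None
        for i in range(n + 1):
            on = i < n and mask[i]
            if on and run_start is None:
                run_start = i
            elif not on and run_start is not None:
                if i - run_start < cfg.read_length:
                    mask[run_start:i] = False
                run_start = None
        units = []
        edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
        starts = [0] if mask[0] else []
        starts += list(edges[~mask[edges]] + 1)
        ends = list(edges[mask[edges]])
        if mask[-1]:
            ends.append(n - 1)
        for s0, e0 in zip(starts, ends):
            members = [
                f for f in features_sorted if not (f.end < s0 + 1 or f.start > e0 + 1)
            ]
            strands = [f.strand for f in members if f.is_coding]
            strand = (
                "+" if strands.count("+") > strands.count("-")
                else "-" if strands.count("-") > strands.count("+")
                else "mixed"
            )
            expr = float(np.exp(rng.normal(0.0, 0.3)))
            if any(f.kind == "rRNA" for f in members):
                expr *= 3.0  # rRNA operons dominate plastid transcriptomes
            units.append(PlantedUnit(Interval(int(s0) + 1, int(e0) + 1), strand, expr))

    # --- edits ------------------------------------------------------------
    # edits are restricted to the single-copy regions so the inverted
    # repeats remain byte-exact mirrors after base forcing
    def in_single_copy(pos: int) -> bool:
        if structure is None:
            return True
        return structure.lsc.contains(pos, n) or structure.ssc.contains(pos, n)

    # auto-planted sites are placed away from unit starts (where uniform
    # read sampling tapers off) and outside introns (where splicing removes
    # most of the depth), so the planted editing fraction is actually
    # observable at the site
    # ... and only in units at or above ~average expression, so the
    # configured target depth is the depth scale that applies at the sites
    w_typical = float(np.median([u.expression for u in units])) if units else 1.0
    well_covered = np.zeros(n, dtype=bool)
    for u in units:
        if u.expression < 0.6 * w_typical:
            continue
        us, ue = u.interval.start, u.interval.end
        if us <= ue and us + cfg.read_length <= ue:
            well_covered[us + cfg.read_length - 1 : ue] = True

    edits: list[PlantedEdit] = []
    occupied: set[int] = set()
    if structure is not None:
        # reserve the repeat flanks: they are adjusted below to keep the
        # planted repeat maximal, so no edit may be forced onto them
        occupied.update(
            {structure.irb.end + 1, structure.irb.start - 1, structure.ira.start - 1, 1}
        )
    if cfg.edit_sites is not None:
        for pos, frac in cfg.edit_sites:
            pos = normalize_position(pos, n)
            strand = _force_editable_base(seq, features_sorted, pos)
            label = _planted_region_label(features_sorted, pos)
            edits.append(PlantedEdit(pos, float(frac), strand, label))
    elif cfg.n_edit_sites > 0:
        n_coding = min(int(round(cfg.n_edit_sites * 26 / 31)), cfg.n_edit_sites)
        coding_pool = [
            f for f in features_sorted
            if f.kind in ("CDS", "intron-containing-CDS")
            and f.name not in untranscribed and mask[f.start - 1]
        ]
        tries = 0
        while coding_pool and len(edits) < n_coding and tries < 50 * cfg.n_edit_sites:
            tries += 1
            f = coding_pool[int(rng.integers(0, len(coding_pool)))]
            codon_i = int(rng.integers(1, f.exon_length // 3 - 1))
            offset = int(rng.integers(1, 3))  # codon offset 1 or 2
            tpos = codon_i * 3 + (offset - 1)  # transcript index, phase 0
            pos = _transcript_to_genome(f, tpos)
            if pos in occupied or not well_covered[pos - 1]:
                continue
            occupied.add(pos)
            _set_transcript_base(seq, pos, f.strand, "C")
            frac = 1.0 if rng.random() < 0.3 else float(rng.uniform(0.6, 0.95))
            edits.append(PlantedEdit(pos, frac, f.strand, "CDS"))
        # non-coding sites: intergenic positions inside transcribed blocks
        while len(edits) < cfg.n_edit_sites and tries < 100 * cfg.n_edit_sites:
            tries += 1
            pos = int(rng.integers(1, n + 1))
            if pos in occupied or not well_covered[pos - 1] or not in_single_copy(pos):
                continue
            label = _planted_region_label(features_sorted, pos)
            if label in ("CDS", "intron"):
                continue
            strand = _owning_strand(features_sorted, pos) or "+"
            _set_transcript_base(seq, pos, strand, "C")
            occupied.add(pos)
            frac = 1.0 if rng.random() < 0.3 else float(rng.uniform(0.6, 0.95))
            edits.append(PlantedEdit(pos, frac, strand, label))
    edits.sort(key=lambda e: e.position)

    # --- splice truth ------------------------------------------------------
    junctions: list[PlantedJunction] = []
    intron_feats = [f for f in features_sorted if len(f.exons) > 1]
    unspliced_names = {
        f.name for f in intron_feats[len(intron_feats) - cfg.unspliced_intron_genes :]
    } if cfg.unspliced_intron_genes else set()
    for f in intron_feats:
        for i in range(len(f.exons) - 1):
            frac = cfg.splice_fraction if f.name not in unspliced_names else 0.0
            if cfg.splice_fractions is not None:
                frac = cfg.splice_fractions.get((f.name, i), frac)
            junctions.append(
                PlantedJunction(
                    gene=f.name,
                    copy_index=f.copy_index,
                    intron_index=i,
                    donor=f.exons[i][1],
                    acceptor=f.exons[i + 1][0],
                    fraction=float(frac),
                )
            )

    # --- mirror the inverted repeat ----------------------------------------
    if ir > 0:
        irb_seq = seq[structure.irb.start - 1 : structure.irb.end].tobytes().decode()
        seq[structure.ira.start - 1 : structure.ira.end] = np.frombuffer(
            revcomp(irb_seq).encode(), dtype=np.uint8
        )
        # make the planted repeat maximal: the flanking bases must not
        # extend the complementarity by chance
        comp = {65: 84, 84: 65, 67: 71, 71: 67}

        def break_extension(i: int, j: int) -> None:
            if seq[i] == comp[seq[j]]:
                for b in b"ACGT":
                    if b != comp[seq[j]]:
                        seq[i] = b
                        break

        break_extension(structure.irb.end, structure.ira.start - 2)
        if structure.irb.start >= 2:
            break_extension(structure.irb.start - 2, 0)  # circular neighbor

    genome = AnnotatedPlastome(
        identifier=f"synthetic_plastome_seed{cfg.seed}",
        sequence=seq.tobytes().decode(),
        features=features_sorted,
        structure=structure,
    )
    truth = SyntheticTruth(
        structure=structure,
        features=features_sorted,
        units=units,
        edits=edits,
        junctions=junctions,
        untranscribed=sorted(untranscribed),
        transcribed_mask=mask,
    )
    return genome, truth


def _transcript_to_genome(f: GeneFeature, tpos: int) -> int:
    """Map a 0-based transcript index to a genomic position."""
    if f.strand == "-":
        tpos = f.exon_length - 1 - tpos
    for s, e in f.exons:
        span = e - s + 1
        if tpos < span:
            return s + tpos
        tpos -= span
    raise IndexError("transcript index out of range")


def _set_transcript_base(seq: np.ndarray, pos: int, strand: str, base: str) -> None:
    genomic = base if strand == "+" else revcomp(base)
    seq[pos - 1] = ord(genomic)


def _force_editable_base(seq, features, pos: int) -> str:
    strand = _owning_strand(features, pos)
    if strand is None:
        strand = "+" if chr(seq[pos - 1]) != "G" else "-"
    _set_transcript_base(seq, pos, strand, "C")
    return strand


def _owning_strand(features, pos: int) -> Optional[str]:
    for f in features:
        if f.start <= pos <= f.end:
            return f.strand
    return None


def _planted_region_label(features, pos: int) -> str:
    for f in features:
        if f.contains_exonic(pos):
            return "CDS" if f.is_coding else f.kind
        if f.intron_index_at(pos) is not None:
            return "intron"
    return "IGS"


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: AnnotatedPlastome,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> list[AlignedRead]:
    """Sample reads from the planted transcription units.

    Reads are drawn uniformly within each unit, in numbers proportional to
    unit length x expression so the overall mean depth over transcribed
    sequence matches ``target_depth``.  At edited positions a read carries
    the edited base with the site's editing fraction; molecules spanning a
    spliced intron yield N-gapped alignments; each fragment is reported on a
    random strand (unstranded library).  Placements are ground truth, also
    recorded in ``truth.reads``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    n = genome.length
    seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8).copy()
    reads: list[AlignedRead] = []
    truth.reads = []
    if cfg.target_depth <= 0 or not truth.units:
        return reads
    lens = np.array([u.interval.length(n) for u in truth.units], dtype=float)
    w = np.array([u.expression for u in truth.units], dtype=float)
    # normalize by the typical (median) unit so target_depth is the depth
    # a typical unit actually receives; boosted rRNA units sit above it
    wbar = float(np.median(w))
    edit_positions = np.array([e.position for e in truth.edits], dtype=np.int64)
    edit_order = np.argsort(edit_positions)
    edit_positions = edit_positions[edit_order]
    edit_list = [truth.edits[i] for i in edit_order]
    for ui, unit in enumerate(truth.units):
        L = int(lens[ui])
        depth_i = cfg.target_depth * unit.expression / wbar
        n_reads = int(round(depth_i * L / cfg.read_length))
        introns = [
            j for j in truth.junctions
            if unit.interval.contains(j.donor, n)
            and unit.interval.contains(j.acceptor, n)
        ]
        for ri in range(n_reads):
            spliced = [j for j in introns if rng.random() < j.fraction]
            segments = _retained_segments(unit.interval, spliced, n)
            total = sum(e - s + 1 for s, e in segments)
            start_off = int(rng.integers(0, total))
            read_segs = _take(segments, start_off, cfg.read_length)
            # a SAM record cannot wrap the origin: truncate at the wrap
            for si in range(1, len(read_segs)):
                if read_segs[si][0] <= read_segs[si - 1][1]:
                    read_segs = read_segs[:si]
                    break
            bases = []
            for s, e in read_segs:
                frag = seq[s - 1 : e].copy()
                lo, hi = np.searchsorted(edit_positions, [s, e + 1])
                for k in range(lo, hi):
                    edit = edit_list[k]
                    if rng.random() < edit.fraction:
                        frag[edit.position - s] = (
                            ord("T") if edit.strand == "+" else ord("A")
                        )
                bases.append(frag)
            read = np.concatenate(bases)
            errs = np.flatnonzero(rng.random(len(read)) < cfg.base_error_rate)
            for k in errs:
                ref_b = read[k]
                alts = [b for b in b"ACGT" if b != ref_b]
                read[k] = alts[int(rng.integers(0, 3))]
            # true edit distance: compare against the reference segments
            ref = np.concatenate([seq[s - 1 : e] for s, e in read_segs])
            nm = int((read != ref).sum())
            cigar = _segments_to_cigar(read_segs)
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"sim_u{ui}_r{ri}"
            rec = AlignedRead(
                query_name=name,
                start=read_segs[0][0],
                cigar=cigar,
                strand=strand,
                sequence=read.tobytes().decode(),
                qualities=[40] * len(read),
                mapping_quality=42,
                nm=nm,
            )
            reads.append(rec)
            truth.reads.append(
                ReadRecord(
                    name=name,
                    unit_index=ui,
                    segments=read_segs,
                    strand=strand,
                    n_errors=len(errs),
                    identity=100.0 * (len(read) - nm) / len(read),
                )
            )
    return reads


def _retained_segments(
    iv: Interval, spliced: list[PlantedJunction], n: int
) -> list[tuple[int, int]]:
    """The unit's interval minus its spliced introns (no origin wrap)."""
    start, end = iv.start, iv.end
    if start > end:  # origin-spanning unit: treat as linear tail + head
        segs = [(start, n), (1, end)]
    else:
        segs = [(start, end)]
    for j in sorted(spliced, key=lambda j: j.donor):
        out = []
        for s, e in segs:
            if j.donor + 1 > e or j.acceptor - 1 < s:
                out.append((s, e))
                continue
            if s <= j.donor:
                out.append((s, j.donor))
            if j.acceptor <= e:
                out.append((j.acceptor, e))
        segs = out
    return segs


def _take(
    segments: list[tuple[int, int]], offset: int, length: int
) -> list[tuple[int, int]]:
    """Take up to ``length`` bases starting ``offset`` bases into segments."""
    out = []
    need = length
    for s, e in segments:
        span = e - s + 1
        if offset >= span:
            offset -= span
            continue
        take = min(need, span - offset)
        out.append((s + offset, s + offset + take - 1))
        need -= take
        offset = 0
        if need == 0:
            break
    return out


def _segments_to_cigar(segments: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(segments):
        if i:
            gap = s - segments[i - 1][1] - 1
            parts.append(f"{gap}N")
        parts.append(f"{e - s + 1}M")
    return "".join(parts)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_sam(
    reads: list[AlignedRead], genome: AnnotatedPlastome, path: str | Path
) -> None:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": genome.identifier, "LN": genome.length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.query_name
            seg.reference_id = 0
            seg.reference_start = r.start - 1
            seg.flag = 16 if r.strand == "-" else 0
            seg.mapping_quality = r.mapping_quality
            seg.cigarstring = r.cigar
            seg.query_sequence = r.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.qualities)
            )
            if r.nm is not None:
                seg.set_tag("NM", r.nm)
            out.write(seg)


def write_fastq(reads: list[AlignedRead], path: str | Path) -> None:
    """FASTQ of the reads as sequenced (minus-strand fragments revcomped)."""
    lines = []
    for r in reads:
        seq, quals = r.sequence, r.qualities
        if r.strand == "-":
            seq = revcomp(seq)
            quals = quals[::-1]
        lines.append(f"@{r.query_name}")
        lines.append(seq)
        lines.append("+")
        lines.append("".join(chr(q + 33) for q in quals))
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    def iv(i: Interval):
        return [i.start, i.end]

    payload = {
        "structure": None
        if truth.structure is None
        else {k: iv(v) for k, v in truth.structure.regions().items()},
        "features": [
            {
                "name": f.name,
                "kind": f.kind,
                "strand": f.strand,
                "exons": [list(e) for e in f.exons],
                "phase": f.phase,
                "copy_index": f.copy_index,
            }
            for f in truth.features
        ],
        "units": [
            {"interval": iv(u.interval), "strand": u.strand, "expression": u.expression}
            for u in truth.units
        ],
        "edits": [dataclasses.asdict(e) for e in truth.edits],
        "junctions": [dataclasses.asdict(j) for j in truth.junctions],
        "untranscribed": truth.untranscribed,
        "reads": [
            {
                "name": r.name,
                "unit": r.unit_index,
                "segments": [list(s) for s in r.segments],
                "strand": r.strand,
                "n_errors": r.n_errors,
                "identity": r.identity,
            }
            for r in truth.reads
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def simulate_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a genome, reads and truth and write the full file bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, truth = generate_plastome(config)
    reads = simulate_reads(genome, truth, config)
    paths = {
        "fasta": out / "genome.fasta",
        "gff3": out / "genome.gff3",
        "sam": out / "reads.sam",
        "fastq": out / "reads.fastq",
        "truth": out / "truth.json",
    }
    write_fasta(genome, paths["fasta"])
    write_gff3(genome, paths["gff3"])
    write_sam(reads, genome, paths["sam"])
    write_fastq(reads, paths["fastq"])
    write_truth_json(truth, paths["truth"])
    return paths
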