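"""Published reference data: the C. sinensis var. assamica chloroplast
editing-site table.

The 31 rows give, for each RNA-editing site detected in the Camellia
sinensis var. assamica chloroplast transcriptome (genome accession
JQ975030), the transcript strand, 1-based plus-strand position, plus-strand
reference base, the A/C/G/U read counts observed at the position, and — for
sites in protein-coding exons — the affected codon (transcript orientation)
with the edited base's offset within it.

:func:`reference_editing_pileup` exposes the counts as pileup columns.
:func:`reference_scaffold_genome` builds a synthetic scaffold genome
(random filler sequence) that places each site's gene, strand, codon and
reading frame at its published coordinate, so region classification and
codon-change annotation can be exercised against the published table
without downloading the accession.
"""

from __future__ import annotations

import numpy as np

from .ingest import PileupColumn
from .plastome import AnnotatedPlastome, GeneFeature, revcomp

GENOME_LENGTH = 157_162  # JQ975030
IR_LENGTH = 26_134
PERCENT_CODING = 51.3
CONSENSUS_COVERED_LENGTH = 152_566
GENE_COUNT = 133

#: (gene label, strand, position, plus-strand base, A, C, G, U,
#:  codon before editing or None, edited-base offset in codon or None,
#:  region kind: CDS / intron / IGS / tRNA)
EDITING_SITE_ROWS: list[tuple] = [
    ("matK", "-", 2314, "G", 21, 0, 1, 0, "CAT", 1, "CDS"),
    ("matK", "-", 2847, "G", 11, 0, 4, 0, "TCT", 2, "CDS"),
    ("matK", "-", 3103, "G", 11, 0, 0, 0, "CAC", 1, "CDS"),
    ("rps16", "-", 5699, "G", 14, 0, 0, 0, None, None, "intron"),
    ("psbK - psbI", "+", 8518, "C", 0, 28, 0, 29, None, None, "IGS"),
    ("atpA", "-", 11607, "G", 100, 0, 3, 0, "TCA", 2, "CDS"),
    ("atpA", "-", 11730, "G", 196, 0, 4, 0, "CCA", 2, "CDS"),
    ("atpF", "-", 13759, "G", 89, 0, 27, 0, "CCA", 2, "CDS"),
    ("rps2", "-", 16993, "G", 231, 0, 2, 0, "TCA", 2, "CDS"),
    ("rps2", "-", 17107, "G", 65, 0, 39, 0, "ACA", 2, "CDS"),
    ("rpoC2", "-", 17896, "G", 178, 0, 24, 0, "TCA", 2, "CDS"),
    ("rpoC2", "-", 18775, "G", 14, 0, 3, 0, "TCT", 2, "CDS"),
    ("rpoC1", "-", 23350, "G", 9, 0, 5, 0, "TCA", 2, "CDS"),
    ("rpoC1", "-", 24541, "G", 13, 0, 10, 0, "TCA", 2, "CDS"),
    ("rpoB", "-", 25821, "G", 13, 0, 2, 0, "TCT", 2, "CDS"),
    ("psbZ", "+", 37874, "C", 0, 45, 0, 138, "TCA", 2, "CDS"),
    ("rps14", "-", 38898, "G", 346, 0, 50, 0, "CCA", 2, "CDS"),
    ("rps14", "-", 38967, "G", 326, 1, 26, 0, "TCA", 2, "CDS"),
    ("ycf3", "-", 45008, "G", 46, 0, 9, 0, None, None, "intron"),
    ("trnL-UAA", "-", 49664, "G", 0, 0, 16, 60, None, None, "intron"),
    ("ndhK", "-", 52696, "G", 8, 0, 4, 0, "TCA", 2, "CDS"),
    ("accD", "+", 60548, "C", 0, 9, 0, 30, "CCT", 2, "CDS"),
    ("psaI", "+", 61442, "C", 0, 1, 0, 12, "TCT", 2, "CDS"),
    ("psaI", "+", 61447, "C", 0, 3, 0, 7, "CAT", 1, "CDS"),
    ("psbF", "-", 66717, "G", 88, 0, 15, 21, "TCT", 2, "CDS"),
    ("psbE", "-", 66841, "G", 137, 0, 10, 0, "CCT", 2, "CDS"),
    ("trnW-CCA", "-", 68908, "G", 16, 0, 0, 0, None, None, "tRNA"),
    ("rps18", "+", 70757, "C", 0, 9, 0, 29, "TCG", 2, "CDS"),
    ("petB", "+", 78772, "C", 0, 18, 0, 133, "CCA", 2, "CDS"),
    ("ndhF", "-", 114757, "G", 12, 0, 4, 0, "TCA", 2, "CDS"),
    ("ndhH", "-", 125218, "G", 75, 0, 8, 0, "TCA", 2, "CDS"),
]


def reference_editing_pileup() -> list[PileupColumn]:
    """The published per-site base counts as pileup columns."""
    return [
        PileupColumn(
            position=pos,
            ref_base=base,
            count_a=a,
            count_c=c,
            count_g=g,
            count_u=u,
            mean_quality=40.0,
        )
        for (_, _, pos, base, a, c, g, u, _, _, _) in EDITING_SITE_ROWS
    ]


def expected_codon_changes() -> dict[int, tuple[str, str]]:
    """position -> (codon before, codon after) for the coding sites."""
    out = {}
    for (_, _, pos, _, _, _, _, _, codon, off, kind) in EDITING_SITE_ROWS:
        if kind == "CDS":
            out[pos] = (codon, codon[: off - 1] + "T" + codon[off:])
    return out


def _plant_cds(seq: np.ndarray, name: str, strand: str, sites: list[tuple]) -> GeneFeature:
    """One single-exon CDS holding every published (pos, codon, offset) site
    of the gene, with the reading frame the offsets imply."""
    if strand == "+":
        starts = [p - (off - 1) for p, _, off in sites]
        ends = [p + (3 - off) for p, _, off in sites]
    else:
        starts = [p - (3 - off) for p, _, off in sites]
        ends = [p + (off - 1) for p, _, off in sites]
    s0, e0 = min(starts) - 9, max(ends) + 9  # 3 filler codons each side
    length = e0 - s0 + 1
    assert length % 3 == 0, f"{name}: published offsets are frame-inconsistent"
    transcript = "GCA" * (length // 3)
    for p, codon, off in sites:
        if strand == "+":
            t0 = p - (off - 1) - s0
        else:
            t0 = e0 - p - (off - 1)
        transcript = transcript[:t0] + codon + transcript[t0 + 3 :]
    genomic = transcript if strand == "+" else revcomp(transcript)
    seq[s0 - 1 : e0] = np.frombuffer(genomic.encode(), dtype=np.uint8)
    return GeneFeature(name, "CDS", strand, [(s0, e0)], phase=0)


def reference_scaffold_genome(seed: int = 0) -> AnnotatedPlastome:
    """Synthetic scaffold genome realizing the published editing-site table.

    Random filler sequence of the published genome length, with each
    site's gene planted so that strand, region class (CDS exon, intron,
    intergenic spacer, tRNA) and codon context at the published coordinate
    match the table.  This is a synthetic stand-in for the deposited
    genome, sufficient to exercise calling and annotation; it is not the
    accession's sequence.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=GENOME_LENGTH)
    features: list[GeneFeature] = []

    cds_sites: dict[str, tuple[str, list[tuple]]] = {}
    for (gene, strand, pos, _, _, _, _, _, codon, off, kind) in EDITING_SITE_ROWS:
        if kind == "CDS":
            cds_sites.setdefault(gene, (strand, []))[1].append((pos, codon, off))
    for gene, (strand, sites) in cds_sites.items():
        features.append(_plant_cds(seq, gene, strand, sites))

    for (gene, strand, pos, _, _, _, _, _, _, _, kind) in EDITING_SITE_ROWS:
        if kind == "intron":
            host_kind = "tRNA" if gene.startswith("trn") else "intron-containing-CDS"
            exons = [(pos - 60, pos - 10), (pos + 10, pos + 60)]  # 51+51 bp
            features.append(GeneFeature(gene, host_kind, strand, exons, phase=0))
        elif kind == "tRNA":
            features.append(
                GeneFeature(gene, "tRNA", strand, [(pos - 35, pos + 36)], phase=0)
            )

    # the intergenic site sits between two planted flanking genes
    features.append(GeneFeature("psbK", "CDS", "+", [(8400, 8501)], phase=0))
    features.append(GeneFeature("psbI", "CDS", "+", [(8530, 8631)], phase=0))

    # force the published plus-strand reference base at every site
    for (_, _, pos, base, *_rest) in EDITING_SITE_ROWS:
        seq[pos - 1] = ord(base.replace("U", "T"))

    return AnnotatedPlastome(
        identifier="synthetic_editing_scaffold",
        sequence=seq.tobytes().decode(),
        features=sorted(features, key=lambda f: f.start),
    )
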