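"""Genome model: file I/O round trips, IR detection, classification, codons."""

import difflib

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from plastoscope.plastome import (
    AnnotatedPlastome,
    GeneFeature,
    classify_position,
    codon_context,
    detect_quadripartite,
    read_plastome,
    revcomp,
    write_fasta,
    write_gff3,
)


class TestReadPlastome:
    def test_genbank_single_cds_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        seq = seq[:10] + "ATG" + "GCT" * 28 + "TAA" + seq[100:]
        rec = SeqRecord(Seq(seq), id="mini", annotations={"molecule_type": "DNA"})
        rec.features.append(
            SeqFeature(
                SimpleLocation(10, 100, strand=1),
                type="CDS",
                qualifiers={"gene": ["psbA"], "codon_start": ["1"]},
            )
        )
        path = tmp_path / "mini.gb"
        SeqIO.write([rec], str(path), "genbank")
        genome = read_plastome(path, format="genbank")
        assert genome.length == 200
        assert len(genome.features) == 1
        f = genome.features[0]
        assert (f.name, f.kind, f.strand, f.exons) == ("psbA", "CDS", "+", [(11, 100)])

    def test_fasta_gff3_round_trip_matches_simulator_truth(self, sim_bundle, tmp_path):
        _, genome, truth, _ = sim_bundle
        write_fasta(genome, tmp_path / "g.fasta")
        write_gff3(genome, tmp_path / "g.gff3")
        back = read_plastome(
            tmp_path / "g.fasta", format="fasta+gff3", gff3=tmp_path / "g.gff3"
        )
        assert back.sequence == genome.sequence
        want = {
            (f.name, f.kind, f.strand, tuple(f.exons), f.phase, f.copy_index)
            for f in truth.features
        }
        got = {
            (f.name, f.kind, f.strand, tuple(f.exons), f.phase, f.copy_index)
            for f in back.features
        }
        assert got == want

    def test_feature_exceeding_length_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            AnnotatedPlastome("x", "ACGT" * 10, [GeneFeature("g", "CDS", "+", [(30, 45)])])


class TestQuadripartite:
    def test_planted_repeat_found_exactly(self):
        rng = np.random.default_rng(5)
        u1 = "".join(rng.choice(list("ACGT"), size=2500))
        repeat = "".join(rng.choice(list("ACGT"), size=800))
        u2 = "".join(rng.choice(list("ACGT"), size=600))
        seq = u1 + repeat + u2 + revcomp(repeat)
        genome = AnnotatedPlastome("planted", seq)
        s = detect_quadripartite(genome, min_ir_len=500)
        assert s is not None
        assert (s.irb.start, s.irb.end) == (2501, 3300)
        assert (s.ira.start, s.ira.end) == (3901, 4700)
        assert s.ir_length(genome.length) == 800
        # mirror invariant, byte-exact
        assert genome.interval_seq(s.irb) == revcomp(genome.interval_seq(s.ira))
        # independent longest-common-substring oracle: the longest exact
        # match between the sequence and its reverse complement is the
        # planted repeat itself
        m = difflib.SequenceMatcher(
            None, seq, revcomp(seq), autojunk=False
        ).find_longest_match(0, len(seq), 0, len(seq))
        assert m.size == 800

    def test_random_sequence_without_repeat(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        assert detect_quadripartite(AnnotatedPlastome("r", seq), min_ir_len=1000) is None

    def test_tiling_and_lsc_ordering(self, sim_bundle):
        _, genome, truth, _ = sim_bundle
        s = detect_quadripartite(genome, min_ir_len=1000)
        n = genome.length
        assert sum(iv.length(n) for iv in s.regions().values()) == n
        assert s.lsc.length(n) >= s.ssc.length(n)
        assert s == truth.structure


class TestClassifyPosition:
    def test_cds_exon_hit(self, toy_genome):
        rc = classify_position(toy_genome, 50)
        assert rc.label == "CDS" and rc.feature.name == "psbA"

    def test_intron_between_exons(self, toy_genome):
        rc = classify_position(toy_genome, 280)
        assert rc.label == "intron" and rc.feature.name == "rps16"
        assert rc.display == "rps16 intron"

    def test_igs_labeled_with_flanking_genes(self, toy_genome):
        rc = classify_position(toy_genome, 150)
        assert rc.label == "IGS"
        assert rc.display == "psbA - rps16"

    def test_partition_of_whole_genome(self, toy_genome):
        labels = {"CDS", "intron", "IGS", "tRNA", "rRNA", "pseudogene"}
        for pos in range(1, toy_genome.length + 1):
            rc = classify_position(toy_genome, pos)
            assert rc.label in labels

    def test_igs_site_between_planted_flanks(self, scaffold_genome):
        rc = classify_position(scaffold_genome, 8518)
        assert rc.display == "psbK - psbI"


class TestCodonContext:
    def test_plus_strand_first_codon(self, toy_genome):
        codon, offset = codon_context(toy_genome, toy_genome.features[0], 11)
        assert (codon, offset) == ("ATG", 1)

    def test_minus_strand_codon_read_on_transcript(self, scaffold_genome):
        matK = next(f for f in scaffold_genome.features if f.name == "matK")
        assert scaffold_genome.base(2314) == "G"
        assert codon_context(scaffold_genome, matK, 2314) == ("CAT", 1)

    def test_codon_across_exon_junction(self, toy_genome):
        # oracle: rebuild the whole mRNA naively and index into it
        f = toy_genome.features[1]  # minus-strand two-exon CDS
        mrna = revcomp(
            toy_genome.sequence[200:260] + toy_genome.sequence[300:360]
        )
        for pos in (260, 301, 302, 240, 330):
            codon, offset = codon_context(toy_genome, f, pos)
            # transcript index of a minus-strand genomic position
            plus_idx = (pos - 201) if pos <= 260 else 60 + (pos - 301)
            idx = len(mrna) - 1 - plus_idx
            assert codon == mrna[(idx // 3) * 3 : (idx // 3) * 3 + 3]
            assert offset == idx % 3 + 1

    def test_agrees_with_naive_mrna_rebuild_on_simulated_genome(self, sim_bundle):
        _, genome, _, _ = sim_bundle
        rng = np.random.default_rng(0)
        coding = [f for f in genome.features if f.is_coding]
        checked = 0
        while checked < 1000:
            f = coding[int(rng.integers(0, len(coding)))]
            s, e = f.exons[int(rng.integers(0, len(f.exons)))]
            pos = int(rng.integers(s, e + 1))
            codon, offset = codon_context(genome, f, pos)
            mrna = genome.spliced_transcript(f)
            plus_idx = 0
            for es, ee in f.exons:
                if es <= pos <= ee:
                    plus_idx += pos - es
                    break
                plus_idx += ee - es + 1
            idx = plus_idx if f.strand == "+" else len(mrna) - 1 - plus_idx
            assert codon == mrna[(idx // 3) * 3 : (idx // 3) * 3 + 3]
            assert offset == idx % 3 + 1
            checked += 1

    def test_pseudogene_has_no_frame(self, toy_genome):
        with pytest.raises(ValueError, match="no codon frame"):
            codon_context(toy_genome, toy_genome.features[3], 520)
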