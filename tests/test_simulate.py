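"""Simulator: determinism, structural truth, edit/splice statistics, file I/O."""

import filecmp

import numpy as np
import pytest
from scipy import stats

from plastoscope.ingest import build_pileup, depth_vector, filter_reads, read_sam
from plastoscope.plastome import detect_quadripartite, revcomp
from plastoscope.simulate import (
    SimulationConfig,
    generate_plastome,
    simulate_bundle,
    simulate_reads,
    write_sam,
)

TINY = dict(
    genome_length=10_000,
    ir_length=1_000,
    n_genes=10,
    trna_genes=3,
    rrna_genes=1,
    intron_genes=2,
    two_intron_genes=1,
    pseudogenes=1,
    untranscribed_genes=1,
    n_edit_sites=5,
    transcribed_fraction=0.9,
    target_depth=25.0,
)


class TestDeterminism:
    def test_bundle_byte_identical_under_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(seed=5, **TINY)
        p1 = simulate_bundle(cfg, tmp_path / "a")
        p2 = simulate_bundle(cfg, tmp_path / "b")
        for key in ("fasta", "gff3", "sam", "fastq", "truth"):
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_different_seed_changes_sequence(self):
        g1, _ = generate_plastome(SimulationConfig(seed=1, **TINY))
        g2, _ = generate_plastome(SimulationConfig(seed=2, **TINY))
        assert g1.sequence != g2.sequence


class TestGenomeGeneration:
    def test_zero_ir_yields_no_structure(self):
        cfg = SimulationConfig(seed=3, **{**TINY, "ir_length": 0})
        genome, truth = generate_plastome(cfg)
        assert truth.structure is None
        assert detect_quadripartite(genome, min_ir_len=1000) is None

    def test_infeasible_packing_rejected_with_named_constraint(self):
        cfg = SimulationConfig(
            seed=0, genome_length=3_000, ir_length=1_000, n_genes=30,
            trna_genes=5, rrna_genes=2, intron_genes=10, pseudogenes=2,
        )
        with pytest.raises(ValueError, match="infeasible packing"):
            generate_plastome(cfg)

    def test_pseudogenes_contain_internal_stop(self, sim_bundle):
        _, genome, _, _ = sim_bundle
        stops = {"TAA", "TAG", "TGA"}
        for f in genome.features:
            if f.kind != "pseudogene":
                continue
            mrna = genome.spliced_transcript(f)
            internal = {
                mrna[i : i + 3] for i in range(3, len(mrna) - 3, 3)
            }
            assert internal & stops, f.name

    def test_detection_matches_truth_over_random_configs(self):
        """Planted IR coordinates recovered exactly on 25 random genomes."""
        rng = np.random.default_rng(99)
        for trial in range(25):
            cfg = SimulationConfig(
                seed=1000 + trial,
                genome_length=int(rng.integers(8_000, 12_001)),
                ir_length=int(rng.integers(600, 1_201)),
                n_genes=8,
                trna_genes=2,
                rrna_genes=1,
                intron_genes=2,
                two_intron_genes=0,
                pseudogenes=1,
                untranscribed_genes=0,
                n_edit_sites=0,
                target_depth=0.0,
            )
            genome, truth = generate_plastome(cfg)
            s = detect_quadripartite(genome, min_ir_len=500)
            assert s == truth.structure, f"trial {trial}"
            assert genome.interval_seq(s.irb) == revcomp(genome.interval_seq(s.ira))
            assert sum(
                iv.length(genome.length) for iv in s.regions().values()
            ) == genome.length


class TestReadSimulation:
    def test_zero_depth_empty(self):
        cfg = SimulationConfig(seed=4, **{**TINY, "target_depth": 0.0})
        genome, truth = generate_plastome(cfg)
        assert simulate_reads(genome, truth, cfg) == []

    def test_error_free_unedited_reads_match_reference(self):
        cfg = SimulationConfig(
            seed=6, **{**TINY, "n_edit_sites": 0, "base_error_rate": 0.0,
                       "untranscribed_genes": 0}
        )
        genome, truth = generate_plastome(cfg)
        reads = simulate_reads(genome, truth, cfg)
        assert reads
        for col in build_pileup(reads, genome):
            ref = col.ref_base.replace("T", "U")
            assert col.depth == col.count(ref)

    def test_complete_editing_gives_full_support(self):
        cfg = SimulationConfig(
            seed=7, **{**TINY, "base_error_rate": 0.0, "n_edit_sites": 0,
                       "untranscribed_genes": 0},
        )
        genome, truth = generate_plastome(cfg)
        # plant one complete edit mid-genome inside a transcribed block
        pos = next(
            p for p in range(2_000, genome.length)
            if truth.transcribed_mask[p - 1]
        )
        cfg2 = SimulationConfig(
            seed=7, **{**TINY, "base_error_rate": 0.0,
                       "untranscribed_genes": 0,
                       "edit_sites": [(pos, 1.0)], "n_edit_sites": 1},
        )
        genome2, truth2 = generate_plastome(cfg2)
        reads = simulate_reads(genome2, truth2, cfg2)
        col = next(
            c for c in build_pileup(reads, genome2) if c.position == pos
        )
        edited = "U" if truth2.edits[0].strand == "+" else "A"
        assert col.depth > 0
        assert col.count(edited) == col.depth

    def test_partial_editing_fraction_within_binomial_interval(self):
        """Planted fraction 0.6 at deep coverage: observed support/depth
        inside the binomial 99.9% interval around 0.6."""
        cfg = SimulationConfig(
            seed=8, **{**TINY, "base_error_rate": 0.0, "target_depth": 200.0,
                       "untranscribed_genes": 0, "edit_sites": [(3_000, 0.6)]},
        )
        genome, truth = generate_plastome(cfg)
        assert truth.transcribed_mask[2_999], "site must be transcribed"
        reads = simulate_reads(genome, truth, cfg)
        col = next(c for c in build_pileup(reads, genome) if c.position == 3_000)
        edited = "U" if truth.edits[0].strand == "+" else "A"
        lo, hi = stats.binom.ppf([0.0005, 0.9995], col.depth, 0.6)
        assert lo <= col.count(edited) <= hi
        assert 0.5 <= col.count(edited) / col.depth <= 0.7

    def test_unstranded_library_emits_both_strands(self, sim_bundle):
        _, _, truth, reads = sim_bundle
        strands = {r.strand for r in reads}
        assert strands == {"+", "-"}
        frac_plus = np.mean([r.strand == "+" for r in reads])
        assert 0.45 < frac_plus < 0.55

    def test_sam_round_trip_preserves_alignments(self, sim_bundle, tmp_path):
        _, genome, _, reads = sim_bundle
        path = tmp_path / "reads.sam"
        write_sam(reads[:200], genome, path)
        back = list(read_sam(path))
        assert len(back) == 200
        for orig, rt in zip(reads[:200], back):
            assert (orig.query_name, orig.start, orig.cigar, orig.sequence) == (
                rt.query_name, rt.start, rt.cigar, rt.sequence
            )
            assert rt.nm == orig.nm

    def test_truth_read_records_consistent_with_reads(self, sim_bundle):
        _, genome, truth, reads = sim_bundle
        assert len(truth.reads) == len(reads)
        rec = truth.reads[0]
        read = reads[0]
        assert rec.name == read.query_name
        assert rec.segments[0][0] == read.start
        assert rec.identity == pytest.approx(read.identity())
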