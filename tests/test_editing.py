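"""Editing caller: support orientation, thresholds, annotation, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastoscope.datasets import (
    EDITING_SITE_ROWS,
    expected_codon_changes,
    reference_editing_pileup,
)
from plastoscope.editing import (
    EditingCallParams,
    annotate_codon_change,
    call_editing_sites,
    edited_support,
    summarize_calls,
)
from plastoscope.ingest import PileupColumn, build_pileup
from plastoscope.plastome import AnnotatedPlastome, GeneFeature
from plastoscope.simulate import SimulationConfig, generate_plastome, simulate_reads


def col(pos, ref, a, c, g, u):
    return PileupColumn(pos, ref, a, c, g, u, mean_quality=40.0)


class TestEditedSupport:
    def test_minus_strand_support_read_as_a(self):
        # published matK site: ref G on plus strand, U reads complement to A
        assert edited_support(col(2314, "G", 21, 0, 1, 0), "-")[0] == 21

    def test_plus_strand_support_read_as_u(self):
        assert edited_support(col(8518, "C", 0, 28, 0, 29), "+")[0] == 29

    def test_all_zero_counts(self):
        assert edited_support(col(1, "C", 0, 0, 0, 0), "+")[0] == 0

    def test_wrong_reference_base_no_candidate(self):
        assert edited_support(col(1, "A", 9, 0, 0, 9), "+")[0] == 0
        assert edited_support(col(1, "C", 9, 0, 0, 9), "-")[0] == 0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        counts=st.tuples(*[st.integers(0, 500)] * 4),
        strand=st.sampled_from("+-"),
        ref=st.sampled_from("ACGT"),
    )
    def test_strict_support_never_exceeds_lenient(self, counts, strand, ref):
        column = col(1, ref, *counts)
        strict, _ = edited_support(column, strand, "strict")
        lenient, _ = edited_support(column, strand, "lenient")
        assert 0 <= strict <= lenient <= column.depth

    def test_lenient_takes_better_supported_orientation(self):
        # minus-strand site reported with U rather than A reads
        assert edited_support(col(49664, "G", 0, 0, 16, 60), "-", "lenient")[0] == 60
        assert edited_support(col(49664, "G", 0, 0, 16, 60), "-", "strict")[0] == 0


class TestThresholds:
    def genome(self):
        return AnnotatedPlastome("g", "C" * 100)

    def test_depth_below_minimum_rejected(self):
        calls = call_editing_sites([col(5, "C", 0, 0, 0, 9)], self.genome())
        assert calls == []

    def test_boundary_exactly_accepted(self):
        calls = call_editing_sites([col(5, "C", 0, 5, 0, 5)], self.genome())
        assert len(calls) == 1
        assert calls[0].completeness == "partial"

    def test_max_depth_prunes(self):
        params = EditingCallParams(max_depth=100)
        calls = call_editing_sites([col(5, "C", 0, 0, 0, 150)], self.genome(), params)
        assert calls == []

    def test_complete_when_support_equals_depth(self):
        calls = call_editing_sites([col(5, "C", 0, 0, 0, 12)], self.genome())
        assert calls[0].completeness == "complete"

    def test_every_call_satisfies_all_predicates(self, scaffold_genome, table_pileup):
        params = EditingCallParams()
        for c in call_editing_sites(table_pileup, scaffold_genome, params):
            assert c.depth >= params.min_depth
            assert c.depth <= params.max_depth
            assert c.support >= params.min_support
            assert c.support / c.depth >= params.min_frequency
            assert c.frequency == pytest.approx(c.support / c.depth)


class TestMonotonicityAndModes:
    def n_calls(self, scaffold, pileup, **kw):
        return len(call_editing_sites(pileup, scaffold, EditingCallParams(**kw)))

    def test_raising_any_threshold_never_adds_calls(self, scaffold_genome, table_pileup):
        base = self.n_calls(scaffold_genome, table_pileup)
        for depth in (10, 12, 20, 50, 200):
            assert self.n_calls(scaffold_genome, table_pileup, min_depth=depth) <= base
        prev = base
        for support in (5, 8, 10, 30, 100):
            n = self.n_calls(
                scaffold_genome, table_pileup, min_depth=max(10, support),
                min_support=support,
            )
            assert n <= prev
            prev = n
        prev = base
        for freq in (0.5, 0.6, 0.8, 0.95, 1.0):
            n = self.n_calls(scaffold_genome, table_pileup, min_frequency=freq)
            assert n <= prev
            prev = n
        prev = None
        for max_depth in (2000, 300, 100, 20):
            n = self.n_calls(scaffold_genome, table_pileup, max_depth=max_depth)
            if prev is not None:
                assert n <= prev
            prev = n

    def test_strict_calls_subset_of_lenient(self, scaffold_genome, table_pileup):
        strict = {
            c.position
            for c in call_editing_sites(
                table_pileup, scaffold_genome,
                EditingCallParams(orientation_mode="strict"),
            )
        }
        lenient = {
            c.position
            for c in call_editing_sites(table_pileup, scaffold_genome)
        }
        assert strict <= lenient


class TestAnnotation:
    def test_published_codon_changes_reproduced(self, scaffold_genome, table_pileup):
        calls = call_editing_sites(table_pileup, scaffold_genome)
        expected = expected_codon_changes()
        for c in calls:
            if c.position in expected:
                pre, post = expected[c.position]
                assert c.codon_change == f"{pre} -> {post}"

    def test_synonymous_edit_at_offset_three(self):
        seq = "T" * 10 + "ATG" + "TCC" + "GCA" * 5 + "TAA" + "T" * 10
        genome = AnnotatedPlastome(
            "g", seq, [GeneFeature("x", "CDS", "+", [(11, 34)])]
        )
        # edit at the third base of the TCC codon (position 16)
        calls = call_editing_sites([col(16, "C", 0, 2, 0, 18)], genome)
        assert calls[0].codon_change == "TCC -> TCT"
        assert calls[0].aa_change == "S -> S"

    def test_noncoding_calls_keep_empty_codon_fields(self, scaffold_genome, table_pileup):
        calls = call_editing_sites(table_pileup, scaffold_genome)
        noncoding = [c for c in calls if not c.is_coding]
        assert len(noncoding) == 5
        assert all(c.codon_change is None and c.aa_change is None for c in noncoding)


class TestSummary:
    def test_empty(self):
        s = summarize_calls([])
        assert (s["total"], s["coding"], s["noncoding"]) == (0, 0, 0)

    def test_simulated_truth_split(self):
        cfg = SimulationConfig(
            seed=21, genome_length=20_000, ir_length=1_500, n_genes=18,
            trna_genes=4, rrna_genes=1, intron_genes=4, two_intron_genes=1,
            pseudogenes=1, untranscribed_genes=0, n_edit_sites=15,
            transcribed_fraction=0.97, target_depth=40.0,
        )
        genome, truth = generate_plastome(cfg)
        reads = simulate_reads(genome, truth, cfg)
        calls = call_editing_sites(build_pileup(reads, genome), genome)
        s = summarize_calls(calls)
        want_coding = sum(1 for e in truth.edits if e.region_label == "CDS")
        assert s["total"] == len(truth.edits)
        assert s["coding"] == want_coding
        assert s["noncoding"] == len(truth.edits) - want_coding


class TestParameterRecovery:
    def test_full_recovery_of_planted_sites(self):
        """20 planted sites at depth >= 30 and fraction >= 0.6: sensitivity
        1.0 and zero false calls at default parameters."""
        cfg = SimulationConfig(
            seed=42, genome_length=24_000, ir_length=2_000, n_genes=20,
            trna_genes=5, rrna_genes=1, intron_genes=4, two_intron_genes=1,
            pseudogenes=1, untranscribed_genes=0, n_edit_sites=20,
            transcribed_fraction=0.97, target_depth=40.0, base_error_rate=0.003,
        )
        genome, truth = generate_plastome(cfg)
        assert len(truth.edits) == 20
        assert all(e.fraction >= 0.6 for e in truth.edits)
        reads = simulate_reads(genome, truth, cfg)
        calls = call_editing_sites(build_pileup(reads, genome), genome)
        assert {c.position for c in calls} == {e.position for e in truth.edits}
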