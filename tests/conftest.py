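"""Shared fixtures: simulated bundles and the published-table scaffold.

Simulation sizes are kept at the tens-of-kilobase scale so the whole suite
runs in well under a minute while still exercising every code path
(quadripartite structure, introns, pseudogenes, partial editing,
untranscribed genes).
"""

from __future__ import annotations

import numpy as np
import pytest

from plastoscope.datasets import reference_editing_pileup, reference_scaffold_genome
from plastoscope.plastome import AnnotatedPlastome, GeneFeature
from plastoscope.simulate import SimulationConfig, generate_plastome, simulate_reads

SMALL_SIM = dict(
    seed=11,
    genome_length=24_000,
    ir_length=2_000,
    n_genes=24,
    trna_genes=6,
    rrna_genes=1,
    intron_genes=5,
    two_intron_genes=1,
    pseudogenes=2,
    untranscribed_genes=2,
    n_edit_sites=15,
    transcribed_fraction=0.95,
    target_depth=80.0,  # deep enough that no unit has chance coverage holes
)


@pytest.fixture(scope="session")
def sim_bundle():
    """(config, genome, truth, reads) for a deeply covered small plastome."""
    cfg = SimulationConfig(**SMALL_SIM)
    genome, truth = generate_plastome(cfg)
    reads = simulate_reads(genome, truth, cfg)
    return cfg, genome, truth, reads


@pytest.fixture(scope="session")
def scaffold_genome():
    """Synthetic scaffold realizing the published editing-site table."""
    return reference_scaffold_genome(seed=0)


@pytest.fixture()
def table_pileup():
    return reference_editing_pileup()


def make_toy_genome() -> AnnotatedPlastome:
    """1 kb circle: one '+' CDS, one two-exon '-' CDS, a tRNA, a pseudogene."""
    rng = np.random.default_rng(7)
    seq = list(rng.choice(list("ACGT"), size=1000))
    # plus-strand CDS [11,100]: ATG + 28 GCT codons + TAA
    cds = "ATG" + "GCT" * 28 + "TAA"
    seq[10:100] = list(cds)
    # minus-strand two-exon CDS [201,260]+[301,360]: transcript is revcomp
    from plastoscope.plastome import revcomp

    transcript = "ATG" + "GAA" * 38 + "TAA"  # 120 bp
    genomic = revcomp(transcript)
    seq[200:260] = list(genomic[:60])
    seq[300:360] = list(genomic[60:])
    features = [
        GeneFeature("psbA", "CDS", "+", [(11, 100)]),
        GeneFeature("rps16", "intron-containing-CDS", "-", [(201, 260), (301, 360)]),
        GeneFeature("trnW", "tRNA", "+", [(401, 475)]),
        GeneFeature("psiX", "pseudogene", "-", [(501, 560)]),
    ]
    return AnnotatedPlastome("toy", "".join(seq), features)


@pytest.fixture()
def toy_genome():
    return make_toy_genome()
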