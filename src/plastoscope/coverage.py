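"""Genome-wide transcription coverage profiling.

Computes the consensus covered fraction (positions with depth at or above a
threshold), per-feature depth statistics, undetected (untranscribed) genes,
and the percent of the genome occupied by coding sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .plastome import AnnotatedPlastome, GeneFeature


@dataclass
class FeatureCoverage:
    mean_depth: float
    covered_fraction: float
    read_bases: int  # total depth summed over the feature's exons


@dataclass
class CoverageProfile:
    depth: np.ndarray
    cover_min: int
    covered_length: int
    covered_fraction: float
    mean_depth: float  # over covered positions
    per_feature: dict[tuple[str, int], FeatureCoverage] = field(default_factory=dict)

    @property
    def covered_percent(self) -> float:
        """Covered fraction as a percent rounded to 0.1."""
        return round(100.0 * self.covered_fraction, 1)


def profile_coverage(
    depth: np.ndarray, genome: AnnotatedPlastome, cover_min: int = 1
) -> CoverageProfile:
    """Profile per-base depth against the genome and its annotation.

    A position counts as covered when its depth is at least ``cover_min``
    (default 1: the union of any mapped read, as used for consensus-sequence
    coverage claims).
    """
    depth = np.asarray(depth)
    if len(depth) != genome.length:
        raise ValueError(
            f"depth array length {len(depth)} != genome length {genome.length}"
        )
    covered = depth >= cover_min
    covered_length = int(covered.sum())
    per_feature = {}
    for f in genome.features:
        idx = np.concatenate(
            [np.arange(s - 1, e) for s, e in f.exons]
        )
        d = depth[idx]
        per_feature[(f.name, f.copy_index)] = FeatureCoverage(
            mean_depth=float(d.mean()),
            covered_fraction=float((d >= cover_min).mean()),
            read_bases=int(d.sum()),
        )
    return CoverageProfile(
        depth=depth,
        cover_min=cover_min,
        covered_length=covered_length,
        covered_fraction=covered_length / genome.length,
        mean_depth=float(depth[covered].mean()) if covered_length else 0.0,
        per_feature=per_feature,
    )


def covered_percent(covered_length: int, genome_length: int) -> float:
    """Consensus covered fraction as a percent, reported to 0.1."""
    return round(100.0 * covered_length / genome_length, 1)


def untranscribed_features(
    profile: CoverageProfile,
    genome: AnnotatedPlastome,
    min_feature_fraction: float = 0.05,
) -> list[GeneFeature]:
    """Features with essentially no transcript evidence: covered over less
    than ``min_feature_fraction`` of their exonic length.  Sorted by name."""
    out = [
        f
        for f in genome.features
        if profile.per_feature[(f.name, f.copy_index)].covered_fraction
        < min_feature_fraction
    ]
    return sorted(out, key=lambda f: (f.name, f.copy_index))


def percent_coding(
    genome: AnnotatedPlastome,
    include: str = "all_genes",
    count_ir_copies: bool = True,
) -> float:
    """Percent of the genome covered by the union of gene exons.

    ``include`` selects protein-coding genes only (``protein_only``) or all
    annotated functional genes incl. tRNA/rRNA (``all_genes``; pseudogenes
    are never counted).  ``count_ir_copies=False`` drops duplicate gene
    copies (copy_index > 0), i.e. counts each inverted-repeat gene once.
    """
    if include not in ("protein_only", "all_genes"):
        raise ValueError(f"unknown include mode {include!r}")
    mask = np.zeros(genome.length, dtype=bool)
    for f in genome.features:
        if f.kind == "pseudogene":
            continue
        if include == "protein_only" and not f.is_coding:
            continue
        if not count_ir_copies and f.copy_index > 0:
            continue
        for s, e in f.exons:
            mask[s - 1 : e] = True
    return round(100.0 * mask.sum() / genome.length, 1)


def feature_report(profile: CoverageProfile, genome: AnnotatedPlastome) -> pd.DataFrame:
    rows = []
    for f in genome.features:
        fc = profile.per_feature[(f.name, f.copy_index)]
        rows.append(
            {
                "gene": f.name,
                "copy": f.copy_index,
                "kind": f.kind,
                "strand": f.strand,
                "start": f.start,
                "end": f.end,
                "mean_depth": round(fc.mean_depth, 2),
                "covered_fraction": round(fc.covered_fraction, 4),
                "read_bases": fc.read_bases,
            }
        )
    return pd.DataFrame(rows)


def write_bedgraph(
    depth: np.ndarray, genome: AnnotatedPlastome, path: str | Path
) -> None:
    """BedGraph export of the depth track (0-based half-open runs)."""
    lines = [f"track type=bedGraph name={genome.identifier}_depth"]
    depth = np.asarray(depth)
    boundaries = np.flatnonzero(np.diff(depth)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(depth)]])
    for s, e in zip(starts, ends):
        lines.append(f"{genome.identifier}\t{s}\t{e}\t{int(depth[s])}")
    Path(path).write_text("\n".join(lines) + "\n")
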