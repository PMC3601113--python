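# Methods

## Scope and model

plastoscope analyses a circular plastome and bulk RNA-seq alignments to
it. The stages mirror how organellar transcriptomes are actually read
out of short-read data:

1. **Structure.** The quadripartite LSC/IRb/SSC/IRa partition is found as
   the maximal-length pair of disjoint *exact* inverted repeats, by
   seed-and-extend: every k-mer (k = 20 by default, clamped to the
   minimum repeat length) of the sequence is indexed, k-mer hits against
   the reverse complement are grouped by diagonal, and each maximal run
   of consecutive hits on one diagonal is one maximal exact match. Ties
   are broken by leftmost start; the larger single-copy region is
   labelled LSC. Exactness is deliberate: real plastid IRs are near
   identical, and an exact contract is testable (the reported IRb must be
   the byte-exact reverse complement of IRa, and the four regions must
   tile the circle).

2. **Ingest.** Reads are filtered at the read level (length ≥ 30 bp,
   mapping uniqueness, percent identity ≥ 90 from CIGAR+NM when the tag
   is present) and at the base level (Phred ≥ 20, applied at pileup
   time). Pileup columns hold plus-strand-oriented A/C/G/U counts, with
   read T recorded as U (RNA convention). Reads may wrap the circular
   origin; deletions and reference skips contribute nothing; insertions
   are consumed without counting.

3. **Editing.** A column with plus-strand reference C (or G, for a
   minus-strand transcript) is accepted as a C-to-U site when depth ≥ 10,
   depth ≤ 2000, edited-base support ≥ 5 and support/depth ≥ 0.5. Depth
   counts all four bases after quality filtering. Only C-to-U (and its
   plus-strand mirror G-to-A) is considered; U-to-C calling is out of
   scope. Sites with support equal to depth are *complete*, otherwise
   *partial*.

4. **Coverage / units.** The consensus covered fraction is the share of
   positions with depth ≥ 1 (configurable), reported to 0.1%.
   Transcription units are maximal runs of positions at or above a depth
   threshold, with runs separated by at most `max_gap` uncovered bases
   merged, including across the origin. The unit's presumed strand is the
   majority strand of its protein-coding members; a member is *sense*
   exactly when its annotated strand equals the unit strand, which is how
   an antisense tRNA inside a protein-coding operon is recognised.

5. **Splicing.** Junctions are the (donor, acceptor) base pairs flanking
   N (reference-skip) CIGAR operations, aggregated over reads;
   multi-gap reads contribute one junction per gap. An annotated intron
   is *spliced* when a junction matches both boundaries within a
   tolerance (default 0 bp), *no_data* when a depth track shows no reads
   over its span, else *unspliced*. Trans-spliced genes whose halves sit
   apart on the genome are not representable as a single skip and report
   no_data.

6. **Indels.** Input is a precomputed gapped alignment (aligned FASTA);
   whole-genome alignment itself is out of scope. Each maximal gap run in
   a pairwise comparison against the chosen reference is one indel — a
   deletion when the gap is in the other sequence, an insertion when it
   is in the reference — positioned at the reference base before the gap
   and classified by region. Gap runs separated by at least one match
   column are separate indels; columns gapped in both sequences of a pair
   are skipped.

## Key decisions where the design was open

- **Orientation mode.** On an unstranded library, a minus-strand edit
  appears as plus-strand A reads over a reference G; published per-site
  tables, however, sometimes report the support of a minus-strand site in
  the U column instead. The default `lenient` mode therefore takes
  max(A, U) for minus-strand sites; `strict` mode (A only) is provided
  for stranded data. Strict-mode calls are provably a subset of
  lenient-mode calls.
- **Strand of non-genic sites.** Sites inside annotated features take the
  feature's strand; intergenic sites take the orientation under which the
  reference base reads as C (plus-strand C → '+', plus-strand G → '−').
- **Region labels.** Positions are classified CDS / intron / IGS / tRNA /
  rRNA, with a fixed priority CDS > tRNA > rRNA > pseudogene where
  features overlap. A `pseudogene` label was added beyond the canonical
  five so that exonic hits in pseudogenes are neither mislabelled coding
  (they have no reading frame) nor intergenic; the editing caller keeps
  such calls but leaves codon fields absent.
- **Percent coding.** Published "percent coding" figures rarely state
  whether tRNA/rRNA exons and duplicated IR gene copies are counted. The
  computation exposes both choices as flags (`include=all_genes|
  protein_only`, `count_ir_copies`), counts exon unions (introns
  excluded), and never counts pseudogenes.
- **Unit segmentation.** Coverage-run segmentation with `d_min=1`,
  `max_gap=0` is the most conservative reading of "contiguous
  transcription"; both knobs are exposed.
- **Indel mean.** The summary reports the mean length both to one decimal
  and integer-rounded, since published catalogs differ in rounding
  convention.

## The synthetic data generator

`simulate.generate_plastome` plants, deterministically under one seeded
generator: an exact IR pair separating two single-copy regions (larger
labelled LSC, SSC sized at ~17% of the single-copy total, matching real
plastome proportions); protein-coding, tRNA and rRNA genes on both
strands, packed into the single-copy regions with codon-structured CDS
sequences (ATG start, no internal stops, stop codon); intron-containing
genes (introns 150–600 bp); pseudogenes with at least one forced internal
stop; polycistronic transcription units tiling the configured fraction of
the circle (default 97.1%), built by darkening a few whole genes and a
handful of intergenic windows; C-to-U edit sites with per-site editing
fractions; and per-intron splice fractions (default 0.8, with the introns
of a configurable number of genes left entirely unspliced).

`simulate.simulate_reads` samples reads uniformly within each unit, in
numbers proportional to unit length × expression. Unit expression is
log-normal (σ = 0.3) with a 3× boost for rRNA-containing units (rRNA
dominates real plastid transcriptomes); depths are normalised by the
*median* unit expression, so `target_depth` is the depth a typical unit
receives. Each read carries the edited base at planted sites with the
site's fraction, N-gapped CIGARs across spliced introns (per-molecule
Bernoulli splicing), substitution errors at `base_error_rate`, constant
Phred-40 qualities, a random reporting strand (unstranded library), and a
ground-truth placement with an exact NM tag — no aligner is run.

Defaults are study-scale: a 157,162 bp circle, 26,134 bp IRs, 133 genes
(30 tRNA, 4 rRNA, 17 intron-containing of which 2 with two introns, 4
pseudogenes), 100 bp reads at 399× typical depth, 97.1% transcribed
fraction, 31 edit sites (26 coding). Tests use the same machinery at
10–30 kb and 25–80× so the whole suite runs in seconds.

Deliberate simplifications, hence what passing tests do *not* show about
real data: genes are planted only in the single-copy regions (keeping the
IRs byte-exact mirrors), so IR-resident genes and their duplicated copies
are not exercised; reads are single-end (real libraries are usually
paired); qualities are constant rather than position-dependent; edits are
independent per read (no haplotype structure); auto-planted edit sites
are restricted to well-covered, non-intron positions in units at or above
~average expression, so the configured editing fraction is actually
observable at the site — detection power at poorly covered sites is a
separate question the recovery tests do not address; IR flip isomers,
heteroplasmy and nuclear plastid-like insertions are not simulated. Two
technical conventions: the repeat flanks are adjusted so the planted IR
is exactly maximal (random flanking bases would otherwise extend it by
chance in ~1 of 4 genomes), and one untranscribed window is anchored at
the origin so no auto-generated unit wraps position 1 (wrapped units are
supported when specified explicitly; reads sampled across the origin are
truncated at the genome end, since a single SAM record cannot wrap).

## Numerical and degenerate-input conventions

- Coordinates are 1-based inclusive plus-strand everywhere user-facing;
  positions normalise modulo the genome length.
- Frequency is support/depth exactly; threshold comparisons are ≥ (a
  depth-10, support-5, frequency-0.5 column is accepted).
- An empty pileup, an empty call list, a genome without introns, and an
  empty indel list all yield empty-but-well-formed results, not errors.
- Detection of the quadripartite structure returns "absent" (None) rather
  than failing when no repeat reaches `min_ir_len`; repeats whose
  single-copy gap would be empty are rejected as degenerate.
- IR detection scans the linear sequence; an IR pair spanning the origin
  would need a rotation first. Origin-spanning *features* and *units* are
  supported.
- The identity filter is skipped (with one warning) for reads lacking NM
  tags, since SAM dialects vary; unparseable CIGARs skip the read and
  increment a counter.

## Known limitations

- Exact-match IR detection will under-report organisms whose repeats
  have diverged internally; a single mismatch truncates the detected
  repeat at that point.
- Junction matching is annotation-driven; novel splice sites are
  extracted but never matched to introns, and trans-splicing is out of
  scope.
- "Uniquely mapped" is interpreted as mapping quality > 0, which tracks
  but does not exactly reproduce any particular aligner's uniqueness
  notion.
- The per-gene expression report gives both mean depth and summed read
  bases; neither is normalised for transcript length or library size
  (no TPM/FPKM).
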