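# Methods

This note documents the models, parameters and design choices behind
gvdiversity: what each stage computes, what the synthetic data does and
does not emulate, and where genuinely open decisions were settled.

## Coordinate model

The reference is a single circular nucleotide sequence over {A,C,G,T,N}.
All internal coordinates are 0-based, half-open, on the forward strand;
emitted VCF and GFF3 are 1-based per their standards. Origin-spanning
features (ORFs, homopolymer runs) are represented with `end > length` and
resolved modulo the length, which keeps overlap arithmetic free of special
cases. Annotated ORF intervals include the stop codon (GenBank CDS
convention), so coding lengths are multiples of 3 and the 150 bp minimum
ORF size counts the stop. N bases are legal in the reference; any codon
containing N yields an `undetermined` effect downstream.

`orf_scan` reports maximal ATG→stop frames (first ATG after the previous
in-frame stop) on both strands of the doubled sequence, de-duplicated
modulo the length; its independent oracle in the test suite is a
regex-based scanner with an explicit maximality filter.

## Read mapping

The mapper is a seed-and-extend aligner sized for near-identical viral
reads, not a general-purpose tool:

* exact 15-mer seeds against an index of the doubled reference (positions
  reduced modulo length, so reads crossing the origin map without being
  split);
* candidate start diagonals collected by voting; the top diagonals are
  extended by unit-cost (edit-distance) alignment in a window padded by
  `band` = 16 bp, computed with edlib;
* the single best-scoring location wins; a tie between distinct loci
  discards the read (random placement would bias variant frequencies);
* alignment identity = matching columns / alignment columns; reads under
  `min_identity` = 0.90 are discarded. The threshold deliberately
  tolerates the 0.5–2% true divergence between field isolates plus
  sequencing error; the much stricter 97% figure that appears in de novo
  assembly contexts governs read–read overlaps, a different problem.

Externally produced alignments can be ingested from plain SAM
(M/I/D/S/=/X; hard clips rejected) and bypass the mapper entirely.

Pileups count bases and deletions per column; an insertion is recorded at
the column preceding the inserted sequence. The consensus caller is
majority-rule with ties broken toward the reference, positions under
`min_depth` = 5 retained as reference, and a deletion removing a position
only when it outnumbers every base.

## Homopolymer error correction

Pyrosequencing misreads homopolymer lengths; the dominant artifact is a
±1 bp indel confined to single-base runs. Correction operates on pileup
columns inside runs ≥ 3 bp: deletion observations with frequency < 1% or
support < 3 reads are folded back into the reference base count (depth is
conserved), and insertion observations failing either rule are dropped.
Because insertions live on the column to the left of the run, the
insertion rule extends one column left of each run. Substitutions are
never touched.

Residual artifacts: at 100× coverage a 2% per-traversal indel error gives
each run a deletion-allele support distributed ~Poisson(1), so a few runs
per 10 kb will exceed both the correction thresholds and the 5-read
calling rule by chance. Indel calls inside homopolymer runs are therefore
flagged `homopolymer_artifact` rather than PASS — the automated
counterpart of the manual curation such studies apply to surviving
homopolymer signals. The flag is a calling-time decision; the underlying
counts remain in the pileup and the flagged calls in the VCF, so genuine
homopolymer-length polymorphisms remain auditable even though they are
never counted in summary statistics. This conservatism is a documented
limitation: a true, well-supported indel inside a homopolymer will not be
PASS.

## Variant calling and filters

Every non-reference allele at every covered column becomes a call
(multi-allelic columns yield one call per allele). Filters:

| rule | per isolate | pooled |
|---|---|---|
| minimum supporting reads | 5 | 3 |
| minimum frequency | 1% | 1% |

The frequency denominator is the post-correction column depth (bases +
deletions); the source study does not define the denominator, and this
choice keeps `support ≤ depth` exact under correction. Positions inside
tandem direct repeats are flagged `in_tandem_repeat` for substitutions and
indels alike — repeat-length changes are copy-number variation handled by
the repeats module, not allele-level variants. Failing calls are written
with their flag(s) rather than dropped, so audits and threshold
sensitivity analyses stay possible; all statistics count PASS calls only.

Pooling maps the union of all isolates' reads against a majority consensus
built from the same pooled reads, then applies the same correction and the
relaxed 3-read rule. Two regimes follow arithmetically and are fixed as
tests: alleles shared at sub-threshold support across isolates accumulate
to a PASS pooled call, and isolate-private alleles are diluted below the
1% pooled frequency.

## Effect classification

Effects are per (variant, ORF) pair: for each ORF containing the position,
the codon is rebuilt on that ORF's coding strand ('−' ORFs on the reverse
complement), the alternative base substituted, and both codons translated
with the standard genetic code (baculoviruses use the standard nuclear
code). Stop gain/loss is non-synonymous. The independent oracle —
translate the whole ORF before and after the substitution and compare
protein strings — is used for test parity over thousands of random draws,
including draws inside the overlapping-ORF pair where the two frames can
disagree.

For genome-wide per-SNP tallies each SNP counts once with precedence
non-synonymous > synonymous > non-coding; the precedence rule at overlap
sites is a package decision (the source presentation does not state one)
and is noted in output metadata. Per-gene counts are *not* collapsed: each
gene counts its own view of an overlap site.

## Diversity statistics

Per-gene diversity is NSS/bp ×10⁻³ — non-synonymous substitution count
over gene length. Genes with zero NSS are always listed (invariable genes
are findings). Category and core/non-core summaries are unweighted
arithmetic means over genes, matching the one-dot-per-gene presentation
typical of these studies; a length-weighted mean (total NSS / total bp) is
available behind `weight_by_length`. Whether to weight was genuinely open;
unweighted is the default because the per-gene statistic already
normalizes by length. Genes above 15 ×10⁻³ NSS/bp carry a configurable
`highly_diverse` flag. Pearson correlations (SNPs vs coverage, NSS/bp vs
gene length) raise on degenerate input rather than returning 0.

The tabulated value is computed as `nss_count * 1e3 / length` — one
correctly-rounded float division — so it equals the exact rational value
bit-for-bit, and tests assert that.

## Direct repeats and large indels

`find_direct_repeats` detects maximal *perfect* tandem arrays: for each
unit length u ∈ [6, 64], stretches where `s[i] == s[i+u]`; arrays need
≥ 2.0 copies and ≥ 18 bp span; overlapping reports merge to the longest
span; units are canonicalized to their lexicographically minimal rotation.
`min_unit` = 6 excludes homopolymers (the error-correction stage owns
those). Degenerate/imperfect repeats are out of scope — the biological
signal of interest is whole-unit copy-number change, which perfect arrays
capture.

`locate_indels` compares two near-identical genomes: shared unique 21-mers
are chained colinearly (patience LIS); consecutive chain anchors are
forced non-overlapping, because junction k-mers reaching into a repeat can
sit closer than k on shifted diagonals and would otherwise swallow the
length difference; inter-anchor gaps are aligned globally with affine gap
penalties (match 1, mismatch −2, open −4, extend −0.5, Biopython
PairwiseAligner); gaps ≥ 10 bp are emitted, left-aligned (VCF convention,
so any placement within a repeat array canonicalizes to the array start),
and annotated with the containing direct repeat. Anchors covering < 50% of
either genome raise a divergence error.

## Synthetic data: what it emulates, and what it does not

The generator builds a circular toy genome (default 10 kb) carrying:
planted ORFs of 300–600 bp (8 by default, including one same-strand
overlapping pair sharing 134 bp in different frames); perfect direct-repeat
arrays with unit lengths 6/9/23/8 bp whose copy-number differences between
isolates produce 12–88 bp indels; and homopolymer runs. Intergenic spacers
are random sequence laced every ≤ 88 bp with `CTAG`×3 "stop islands",
which read as a stop within 12 bp in all six frames and contain no ATG —
this guarantees that a six-frame scan finds exactly the planted ORFs, which
purely random spacers cannot (a random 10 kb sequence carries ~20 chance
ORFs ≥ 150 bp). Chance upstream in-frame ATGs that would extend a planted
ORF are repaired by writing a stop into the spacer extension. The
homopolymer truth table is the scan of the final sequence, so background
runs are included.

Isolates are weighted haplotype mixtures: planted variants segregate
independently, weights are exact rationals (products of fᵢ and 1−fᵢ), so
the marginal allele frequency at each site is exact by construction, and
direct-repeat copy differences apply to whole haplotypes. Reads are
single-ended, uniform on the circle, lengths ~N(400, 80) truncated to
[100, 1000] bp (a plausible GS FLX Titanium profile; the source reports no
read-length statistics), with per-run-traversal homopolymer ±1 errors
(default rate 0.02) and a small uniform substitution error (5×10⁻⁴).
Constant Q30 placeholder qualities. Not emulated: realistic quality
models, chimeric reads, paired ends, strand bias, GC bias, and imperfect
repeats. Passing tests therefore demonstrate algorithmic correctness under
this error model, not performance on real 454 data.

All randomness descends from one integer seed via `SeedSequence`
splitting with fixed stage tags, so genome construction, haplotype
building and read simulation are independently reproducible.

## Self-check experiments and their problem sizes

The `validation` module (shared by the test suite and
`scripts/acceptance.py`) runs at desk scale, chosen to finish in minutes on
one CPU:

* effect parity: 1000 random (ORF, offset, alt) draws on one toy genome,
  100 of them inside the overlapping pair;
* threshold battery: support {4,5,6} × frequency {0.9%, 1.0%, 1.1%} under
  both rule sets;
* recovery: 20 simulations at 10 kb / 100× / 2% homopolymer error, eight
  planted SNPs per simulation at frequencies {2, 5, 10, 50}%; recall is
  reported over variants whose expected support (f × coverage) reaches the
  5-read rule, alongside per-frequency recall, false PASS counts, and the
  fraction of estimated frequencies within 3·√(f(1−f)/depth) of truth.
  Note the statistical ceiling: at 100× the 5% class has expected support
  exactly 5, and P(Binom(100, 0.05) ≥ 5) = 0.56, so per-variant recall at
  that frequency cannot exceed ~56% whatever the implementation does; the
  10% class caps near 97.6%. The recovery test asserts the 99% design
  target regardless and is expected to fail on exactly that bound under
  these conditions, with the other recovery properties (no false PASS
  calls, frequency accuracy) holding.
* diversity ratio: 20 simulations of a 12 kb toy genome carrying 16
  non-overlapping genes (half core), planting non-synonymous SNPs at 12 vs
  24 ×10⁻³ per bp (binomial counts per gene, alleles chosen non-synonymous
  via the translation oracle). The rates are higher than typical
  field-isolate diversity by design: with these sizes the binomial
  sampling error of the recovered ratio is ~4–5%, so the 2:1 recovery is
  tested with a ≥ 3σ margin against its 15% tolerance rather than at the
  edge of its own sampling noise.

## Known limitations

* Mapper and caller assume near-identical reads; no base-quality model.
* Indel consequences (frameshifts) are not annotated; `classify_variant`
  rejects indels by design.
* Homopolymer-run indels are never PASS (see above).
* When the pooled consensus changes length relative to the reference
  (majority deletions), ORF annotations are kept on the reference frame
  and a warning is logged; with the default simulation conditions the
  consensus is length-preserving.
* Perfect-repeat detection only; diverged repeat units below ~99% identity
  are invisible to `find_direct_repeats`.
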