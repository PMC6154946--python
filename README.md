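# gvdiversity

Genome-wide diversity analysis for granulovirus (betabaculovirus) field
isolates — a tested, reusable pipeline for the kind of study where several
field populations of a ~100 kb circular dsDNA virus are deep-sequenced on a
pyrosequencing platform and compared for intra- and inter-isolate variation.

It is written for virologists and bioinformaticians who need to:

* call **low-frequency SNPs** from per-isolate read sets under explicit
  support/frequency thresholds (≥ 5 reads and ≥ 1% frequency per isolate),
  with tandem-repeat positions masked;
* correct **pyrosequencing homopolymer indel noise** before calling
  (indel observations in single-base runs ≥ 3 bp are removed when below 1%
  frequency or 3 supporting reads);
* classify each SNP's coding consequence **codon-aware across overlapping
  ORFs** — in these compact genomes a single substitution can be silent in
  one gene and amino-acid-changing in the gene it overlaps out of frame;
* summarize per-gene diversity as **NSS/bp**: the number of non-synonymous
  substitutions (NSS) in a gene divided by its length, reported ×10⁻³
  (raw counts, deliberately not dN/dS), with functional-category and
  core/non-core gene means;
* pool all isolates into a **metapopulation**: reads combined and mapped
  against a majority-rule consensus, called at relaxed pooled thresholds
  (≥ 3 reads, ≥ 1%), which gains shared rare alleles and dilutes
  isolate-private ones;
* detect **tandem direct repeats (drs)** and localize the large indels
  (tens of bp) that arise between isolates from repeat-unit copy-number
  changes, left-aligned to reproducible coordinates.

Because raw reads of the motivating study were never deposited, the package
ships a first-class synthetic-data module: toy circular genomes with
planted ORFs (including a same-strand overlapping pair in different
frames), direct-repeat arrays, homopolymer runs, exact-frequency haplotype
mixtures, and 454-like reads (~N(400, 80) bp, homopolymer ±1 indel errors).
Every pipeline stage is validated against these known truths.

## Worked example

Simulate two isolates from one 10 kb toy genome and analyse them. The
simulation config plants four SNPs with known frequencies and effects:

```yaml
# sim.yaml
genome_length: 10000
n_orfs: 8
depth: 60.0
isolates: [SC86, AC]
planted:
  - {position: 1863, alt: A, frequencies: {SC86: 0.25, AC: 0.25}}  # granulin, amino-acid change
  - {position: 2964, alt: C, frequencies: {SC86: 0.10}}            # lef-2, silent
  - {position: 5150, alt: A, frequencies: {AC: 0.40}}              # pif-3, stop gain
  - {frequencies: {AC: 0.02}}                                      # rare allele, below the 5-read rule
```

```bash
gvdiversity simulate --config sim.yaml --seed 11 --out demo
gvdiversity run-isolate --config pipeline.yaml --isolate SC86
gvdiversity run-isolate --config pipeline.yaml --isolate AC
gvdiversity pool --config pipeline.yaml
```

(`pipeline.yaml` points at `demo/reference.fasta`, `demo/annotations.tsv`
and the two FASTQ files; see `gvdiversity run-isolate --help`.)

With seed 11 this prints, per isolate (abridged):

```
SC86:  total_snps: 2   pct_synonymous: 50.0  pct_non_synonymous: 50.0   mean_coverage: 60.0
AC:    total_snps: 2   pct_synonymous: 0.0   pct_non_synonymous: 100.0  mean_coverage: 60.0
pool:  total_snps: 3   consensus_length: 10000
```

and the pooled VCF contains exactly the three detectable planted alleles:

```
toy11_consensus  1864  C  A  PASS  DP=117;AF=0.256410;...;ANN=g01|non_synonymous|CCA>CAA|3
toy11_consensus  2965  T  C  PASS  DP=123;AF=0.048780;...;ANN=g03|synonymous|TGT>TGC|3
toy11_consensus  5151  G  A  PASS  DP=118;AF=0.245763;...;ANN=g05|non_synonymous|TGG>TAG|3
```

Reading these numbers: the shared 25% *granulin* substitution passes in
both isolates (observed AF 0.27 and 0.24 at ~60× — binomial sampling
around the planted truth) and in the pool at AF 0.26. The isolate-private
alleles are halved by pooling: AC's 40% stop-gain in *pif-3* (TGG→TAG,
classified non-synonymous) drops to 0.25, and SC86's 10% silent allele in
*lef-2* to 0.049 — still above the pooled 3-read/1% rules here, but the
same arithmetic is what makes genuinely rare shared alleles appear only in
the pool and low-frequency private ones vanish from it. The 2% allele is
never detectable at this depth (expected support ≈ 1 read). The pooled
per-gene table then reports, e.g., `granulin  489 bp  1 NSS
2.04 ×10⁻³ NSS/bp`.

All randomness flows from the one seed; re-running any command reproduces
byte-identical outputs.

## Layout

```
src/gvdiversity/
  genome_model.py   circular reference + ORF annotations, six-frame scan
  synth.py          toy genomes, haplotype mixtures, 454-like reads
  mapping.py        seed-and-extend mapper, pileups, consensus, SAM I/O
  variants.py       homopolymer correction, thresholded calling, VCF
  effects.py        codon-aware effect classification, translation oracle
  diversity.py      NSS/bp, category/core summaries, correlations
  repeats.py        tandem direct repeats, motif copies, indel localization
  pipeline.py       per-isolate and metapopulation orchestration
  validation.py     seeded self-check experiments (used by tests and
                    scripts/acceptance.py)
  cli.py            `gvdiversity` command-line interface
```

See `docs/methods.md` for the model, parameter and design documentation.
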