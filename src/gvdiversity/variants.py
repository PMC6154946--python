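"""Homopolymer error correction and thresholded variant calling.

The calling rules mirror the study design for 454 pyrosequencing data:

* homopolymer correction: at pileup columns inside single-base runs of
  length >= 3, indel observations below 1% frequency or supported by fewer
  than 3 reads are treated as sequencing noise and folded back into the
  reference state; substitutions are never touched at this stage;
* per-isolate calls: a non-reference allele is PASS when supported by at
  least 5 reads and at least 1% frequency, and substitutions inside tandem
  repeats are masked;
* metapopulation calls: reads of all isolates pooled and mapped against a
  consensus; PASS needs at least 3 reads and 1% of the pooled depth.

Alleles failing a rule are retained with explanatory filter flags so audits
remain possible, but every downstream statistic counts PASS calls only.
The frequency denominator is the post-correction column depth (bases plus
deletions).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genome_model import OrfAnnotation, ReferenceGenome, find_homopolymer_runs
from .mapping import MappingStats, Pileup, build_pileup, map_reads

FILTER_PASS = "PASS"
FILTER_LOW_SUPPORT = "low_support"
FILTER_LOW_FREQUENCY = "low_frequency"
FILTER_IN_TANDEM_REPEAT = "in_tandem_repeat"
FILTER_HOMOPOLYMER = "homopolymer_artifact"


@dataclass
class VariantCall:
    """An observed non-reference allele at a reference position.

    ``kind`` is SNP / insertion / deletion; ``filters`` is {PASS} for calls
    passing every rule, otherwise the set of failed rules. ``scope`` is
    ``isolate:<id>`` or ``metapopulation``. ``region`` is filled by
    :func:`classify_region`.
    """
    position: int
    ref_allele: str
    alt_allele: str
    kind: str
    support: int
    depth: int
    scope: str
    filters: set[str] = field(default_factory=set)
    region: str | None = None

    @property
    def frequency(self) -> float:
        return self.support / self.depth if self.depth else 0.0

    @property
    def is_pass(self) -> bool:
        return self.filters == {FILTER_PASS}

    @property
    def key(self) -> tuple[int, str, str, str]:
        return (self.position, self.ref_allele, self.alt_allele, self.kind)


def load_mask_bed(path: str | Path) -> list[tuple[int, int]]:
    """Mask intervals from a BED file (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append((int(fields[1]), int(fields[2])))
    return sorted(out)


def write_mask_bed(mask: Sequence[tuple[int, int]], chrom: str,
                   path: str | Path) -> None:
    with open(path, "w") as fh:
        for start, end in mask:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def in_intervals(position: int, intervals: Sequence[tuple[int, int]],
                 genome_length: int | None = None) -> bool:
    for start, end in intervals:
        if start <= position < end:
            return True
        if genome_length and end > genome_length and position + genome_length < end:
            return True
    return False


def correct_homopolymers(
    pileup: Pileup,
    runs: Sequence[tuple[int, int, str]] | None = None,
    min_freq: float = 0.01,
    min_reads: int = 3,
) -> Pileup:
    """Remove low-level indel noise inside homopolymer runs.

    ``runs`` are (start, end, base) intervals of single-base runs >= 3 bp
    (scanned from the reference when omitted). At columns inside a run,
    deletion observations with frequency < ``min_freq`` or support <
    ``min_reads`` are folded into the reference base count; insertion
    observations failing either rule are dropped. Because insertions are
    recorded at the column preceding the inserted bases, the run interval is
    extended one column to the left for the insertion rule. Substitutions
    are untouched. Returns a corrected copy; the input pileup is unchanged.
    """
    if runs is None:
        runs = find_homopolymer_runs(pileup.genome, min_len=3)
    n = len(pileup.genome)
    in_run: set[int] = set()
    in_run_ins: set[int] = set()
    for start, end, _base in runs:
        for p in range(start, end):
            in_run.add(p % n)
            in_run_ins.add(p % n)
        in_run_ins.add((start - 1) % n)

    corrected = Pileup(pileup.genome)
    corrected.columns = {p: copy.deepcopy(c) for p, c in pileup.columns.items()}
    for pos, col in corrected.columns.items():
        depth = col.depth
        if pos in in_run and col.del_count:
            if col.del_count < min_reads or col.del_count / depth < min_freq:
                col.base_counts[col.ref_base] += col.del_count
                col.del_count = 0
        if pos in in_run_ins and col.insertions:
            kept = {}
            for ins, count in col.insertions.items():
                if count >= min_reads and count / depth >= min_freq:
                    kept[ins] = count
            col.insertions = kept
    return corrected


def call_variants_from_pileup(
    pileup: Pileup,
    min_support: int,
    min_freq: float,
    mask: Sequence[tuple[int, int]] = (),
    scope: str = "isolate:unknown",
    homopolymer_runs: Sequence[tuple[int, int, str]] = (),
) -> list[VariantCall]:
    """Emit one :class:`VariantCall` per non-reference allele per column.

    PASS requires support >= ``min_support`` AND frequency >= ``min_freq``
    AND the position outside every mask interval; failing alleles carry the
    corresponding filter flags. Multi-allelic columns yield one call per alt
    allele. The mask applies to substitutions and indels alike (tandem
    repeat length changes are treated as copy-number variation elsewhere).

    When ``homopolymer_runs`` is given, indel calls inside those runs are
    flagged ``homopolymer_artifact`` instead of PASS: pyrosequencing indel
    noise in homopolymers routinely exceeds the correction thresholds at
    high coverage, and the study design treated surviving cases as
    artifacts to curate, not variants. Substitutions are unaffected.
    """
    n = len(pileup.genome)
    hp_del: set[int] = set()
    hp_ins: set[int] = set()
    for start, end, _base in homopolymer_runs:
        hp_del.update(p % n for p in range(start, end))
        hp_ins.update(p % n for p in range(start - 1, end))
    calls: list[VariantCall] = []
    for col in pileup:
        depth = col.depth
        if depth == 0:
            continue
        candidates: list[tuple[str, str, str, int]] = []
        for base in "ACGT":
            count = col.base_counts.get(base, 0)
            if base != col.ref_base and count > 0:
                candidates.append(("SNP", col.ref_base, base, count))
        if col.del_count > 0:
            candidates.append(("deletion", col.ref_base, "", col.del_count))
        for ins, count in sorted(col.insertions.items()):
            candidates.append(("insertion", "", ins, count))
        for kind, ref, alt, support in candidates:
            filters: set[str] = set()
            if support < min_support:
                filters.add(FILTER_LOW_SUPPORT)
            if support / depth < min_freq:
                filters.add(FILTER_LOW_FREQUENCY)
            if in_intervals(col.position, mask, n):
                filters.add(FILTER_IN_TANDEM_REPEAT)
            if (kind == "deletion" and col.position in hp_del) or \
                    (kind == "insertion" and col.position in hp_ins):
                filters.add(FILTER_HOMOPOLYMER)
            if not filters:
                filters = {FILTER_PASS}
            calls.append(VariantCall(
                position=col.position, ref_allele=ref, alt_allele=alt,
                kind=kind, support=support, depth=depth, scope=scope,
                filters=filters))
    return calls


def call_isolate_variants(
    pileup: Pileup,
    min_support: int = 5,
    min_freq: float = 0.01,
    mask: Sequence[tuple[int, int]] = (),
    isolate_id: str = "unknown",
    homopolymer_runs: Sequence[tuple[int, int, str]] = (),
) -> list[VariantCall]:
    """Per-isolate calling at the 5-read / 1% thresholds (expects a
    homopolymer-corrected pileup)."""
    return call_variants_from_pileup(pileup, min_support, min_freq, mask,
                                     scope=f"isolate:{isolate_id}",
                                     homopolymer_runs=homopolymer_runs)


def call_pooled_variants(
    read_sets: Mapping[str, Sequence],
    consensus: ReferenceGenome,
    min_support: int = 3,
    min_freq: float = 0.01,
    mask: Sequence[tuple[int, int]] = (),
    hp_min_reads: int = 3,
    hp_min_freq: float = 0.01,
    mapper_kwargs: Mapping | None = None,
    stats: MappingStats | None = None,
) -> tuple[list[VariantCall], Pileup]:
    """Metapopulation calling: pool every isolate's reads, map them jointly
    against the consensus genome, homopolymer-correct, and call at the
    pooled 3-read / 1% thresholds. Returns (calls, corrected pileup)."""
    pooled = [r for reads in read_sets.values() for r in reads]
    alignments = map_reads(pooled, consensus,
                           **(dict(mapper_kwargs) if mapper_kwargs else {}),
                           stats=stats)
    pileup = build_pileup(alignments, consensus)
    runs = find_homopolymer_runs(consensus, min_len=3)
    corrected = correct_homopolymers(pileup, runs, min_reads=hp_min_reads,
                                     min_freq=hp_min_freq)
    calls = call_variants_from_pileup(corrected, min_support, min_freq, mask,
                                      scope="metapopulation",
                                      homopolymer_runs=runs)
    return calls, corrected


def classify_region(variants: Iterable[VariantCall],
                    annotations: Sequence[OrfAnnotation],
                    genome_length: int) -> None:
    """Label each call coding / non-coding: coding iff the position lies in
    at least one annotated ORF interval (overlaps included)."""
    for v in variants:
        coding = any(a.contains(v.position, genome_length) for a in annotations)
        v.region = "coding" if coding else "non-coding"


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_VCF_FILTERS = {
    FILTER_LOW_SUPPORT: "allele supported by fewer reads than the threshold",
    FILTER_LOW_FREQUENCY: "allele frequency below the threshold",
    FILTER_IN_TANDEM_REPEAT: "position inside a tandem direct repeat",
    FILTER_HOMOPOLYMER: "indel inside a homopolymer run failing correction",
}


def write_vcf(variants: Sequence[VariantCall], genome: ReferenceGenome,
              path: str | Path,
              info_extra: Mapping[tuple, str] | None = None) -> None:
    """Write calls as VCF v4.2 (1-based positions). Indels are anchored on
    the preceding reference base per VCF convention."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={genome.id},length={len(genome)}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Post-correction column depth">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency (support/depth)">',
        '##INFO=<ID=SCOPE,Number=1,Type=String,Description="isolate:<id> or metapopulation">',
        '##INFO=<ID=ANN,Number=.,Type=String,Description="gene_id|effect|ref_codon>alt_codon|codon_index">',
        '##INFO=<ID=REGION,Number=1,Type=String,Description="coding or non-coding">',
    ]
    for name, desc in _VCF_FILTERS.items():
        lines.append(f'##FILTER=<ID={name},Description="{desc}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    n = len(genome)
    for v in sorted(variants, key=lambda v: (v.position, v.alt_allele)):
        if v.kind == "SNP":
            pos1, ref, alt = v.position + 1, v.ref_allele, v.alt_allele
        elif v.kind == "deletion":
            anchor = genome.sequence[(v.position - 1) % n]
            pos1, ref, alt = ((v.position - 1) % n) + 1, anchor + v.ref_allele, anchor
        else:  # insertion (recorded at the column preceding the insertion)
            anchor = genome.sequence[v.position % n]
            pos1, ref, alt = (v.position % n) + 1, anchor, anchor + v.alt_allele
        filt = "PASS" if v.is_pass else ";".join(sorted(v.filters))
        info = f"DP={v.depth};AF={v.frequency:.6f};SCOPE={v.scope}"
        if v.region:
            info += f";REGION={v.region}"
        if info_extra and v.key in info_extra:
            info += f";{info_extra[v.key]}"
        lines.append(f"{genome.id}\t{pos1}\t.\t{ref}\t{alt}\t.\t{filt}\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")
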