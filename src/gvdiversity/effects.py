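"""Codon-aware effect classification of SNPs, overlapping-ORF safe.

Baculovirus genomes are compact enough that coding sequences overlap, on
the same or opposite strands, in different reading frames (the classic case
being lef-10 sharing a third of its coding region with vp1054). A single
substitution therefore gets one effect record *per ORF containing it*:
codons are rebuilt on each ORF's coding strand, translated with the
standard genetic code, and compared. Stop gains and losses count as
non-synonymous; codons containing N are undetermined.

For genome-wide tallies each SNP is counted once, with precedence
non-synonymous > synonymous > non-coding (the per-gene counts in the
diversity module are not collapsed this way — each gene counts its own).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .errors import DataError, UnsupportedVariantError
from .genome_model import OrfAnnotation, ReferenceGenome
from .variants import VariantCall

EFFECT_SYNONYMOUS = "synonymous"
EFFECT_NON_SYNONYMOUS = "non_synonymous"
EFFECT_UNDETERMINED = "undetermined"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class EffectRecord:
    """Consequence of one SNP in one reading frame."""
    variant_key: tuple
    gene_id: str
    codon_index: int
    position_in_codon: int
    ref_codon: str
    alt_codon: str
    ref_aa: str | None
    alt_aa: str | None
    effect: str


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())  # '*' for stop


def classify_variant(variant: VariantCall,
                     annotations: Sequence[OrfAnnotation],
                     genome: ReferenceGenome) -> list[EffectRecord]:
    """One :class:`EffectRecord` per ORF whose interval contains the SNP.

    Codons are read on the coding strand ('-' strand ORFs on the reverse
    complement); the list is empty iff the position is non-coding. Indels
    are rejected (frameshift annotation is out of scope).
    """
    if variant.kind != "SNP":
        raise UnsupportedVariantError(
            f"effect classification supports SNPs only, got {variant.kind}")
    n = len(genome)
    records: list[EffectRecord] = []
    for ann in annotations:
        if not ann.contains(variant.position, n):
            continue
        offset_fwd = ann.offset_of(variant.position, n)
        if ann.strand == "+":
            coding_offset = offset_fwd
            alt_coding = variant.alt_allele
        else:
            coding_offset = ann.length - 1 - offset_fwd
            alt_coding = variant.alt_allele.translate(_COMPLEMENT)
        ci, pic = divmod(coding_offset, 3)
        cds = ann.coding_sequence(genome)
        ref_codon = cds[3 * ci: 3 * ci + 3]
        alt_codon = ref_codon[:pic] + alt_coding + ref_codon[pic + 1:]
        if ref_codon == alt_codon:
            raise DataError(
                f"variant at {variant.position}: alt equals reference codon")
        if "N" in ref_codon or "N" in alt_codon:
            records.append(EffectRecord(variant.key, ann.gene_id, ci, pic,
                                        ref_codon, alt_codon, None, None,
                                        EFFECT_UNDETERMINED))
            continue
        ref_aa = _translate(ref_codon)
        alt_aa = _translate(alt_codon)
        effect = EFFECT_SYNONYMOUS if ref_aa == alt_aa else EFFECT_NON_SYNONYMOUS
        records.append(EffectRecord(variant.key, ann.gene_id, ci, pic,
                                    ref_codon, alt_codon, ref_aa, alt_aa, effect))
    return records


def effect_oracle(orf_sequence: str, offset: int, alt_base: str) -> str:
    """Brute-force ground truth: translate the whole ORF before and after
    the substitution and compare the protein strings."""
    if not 0 <= offset < len(orf_sequence):
        raise DataError(f"offset {offset} outside ORF of {len(orf_sequence)} bp")
    if orf_sequence[offset] == alt_base:
        raise DataError("alt base equals the reference base")
    mutated = orf_sequence[:offset] + alt_base + orf_sequence[offset + 1:]
    before = str(Seq(orf_sequence).translate())
    after = str(Seq(mutated).translate())
    return EFFECT_SYNONYMOUS if before == after else EFFECT_NON_SYNONYMOUS


@dataclass(frozen=True)
class SnpLevelSummary:
    """Genome-wide per-SNP proportions; percentages sum to 100 exactly in
    rational arithmetic (floats shown rounded)."""
    n_snps: int
    n_synonymous: int
    n_non_synonymous: int
    n_non_coding: int

    @property
    def empty(self) -> bool:
        return self.n_snps == 0

    def percentages(self) -> tuple[float, float, float]:
        if self.empty:
            return (0.0, 0.0, 0.0)
        f = lambda c: float(Fraction(100 * c, self.n_snps))
        return (f(self.n_synonymous), f(self.n_non_synonymous),
                f(self.n_non_coding))


def snp_level_summary(effects_by_variant: dict[tuple, list[EffectRecord]],
                      variants: Iterable[VariantCall]) -> SnpLevelSummary:
    """Count each PASS SNP exactly once: non-synonymous if any of its
    effect records is non-synonymous; else synonymous if any is synonymous;
    else non-coding (which includes fully undetermined calls)."""
    n = syn = nonsyn = noncoding = 0
    for v in variants:
        if v.kind != "SNP" or not v.is_pass:
            continue
        n += 1
        recs = effects_by_variant.get(v.key, [])
        labels = {r.effect for r in recs}
        if EFFECT_NON_SYNONYMOUS in labels:
            nonsyn += 1
        elif EFFECT_SYNONYMOUS in labels:
            syn += 1
        else:
            noncoding += 1
    return SnpLevelSummary(n, syn, nonsyn, noncoding)


def classify_all(variants: Iterable[VariantCall],
                 annotations: Sequence[OrfAnnotation],
                 genome: ReferenceGenome) -> dict[tuple, list[EffectRecord]]:
    """Effect records for every PASS SNP, keyed by the variant key."""
    out: dict[tuple, list[EffectRecord]] = {}
    for v in variants:
        if v.kind != "SNP" or not v.is_pass:
            continue
        out[v.key] = classify_variant(v, annotations, genome)
    return out


def effects_to_tsv(effects_by_variant: dict[tuple, list[EffectRecord]],
                   path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tref\talt\tgene_id\tcodon_index\tposition_in_codon\t"
                 "ref_codon\talt_codon\tref_aa\talt_aa\teffect\n")
        for key in sorted(effects_by_variant):
            pos, ref, alt, _kind = key
            for r in effects_by_variant[key]:
                fh.write(f"{pos}\t{ref}\t{alt}\t{r.gene_id}\t{r.codon_index}\t"
                         f"{r.position_in_codon}\t{r.ref_codon}\t{r.alt_codon}\t"
                         f"{r.ref_aa or '.'}\t{r.alt_aa or '.'}\t{r.effect}\n")


def ann_info_strings(effects_by_variant: dict[tuple, list[EffectRecord]]
                     ) -> dict[tuple, str]:
    """VCF INFO ANN= strings (gene_id|effect|ref>alt|codon_index)."""
    out = {}
    for key, recs in effects_by_variant.items():
        if recs:
            out[key] = "ANN=" + ",".join(
                f"{r.gene_id}|{r.effect}|{r.ref_codon}>{r.alt_codon}|{r.codon_index}"
                for r in recs)
    return out
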