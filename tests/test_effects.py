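"""Codon-aware effect classification, translation oracle, SNP summaries."""

import pytest

from gvdiversity.effects import (EFFECT_NON_SYNONYMOUS, EFFECT_SYNONYMOUS,
                                 EFFECT_UNDETERMINED, classify_all,
                                 classify_variant, effect_oracle,
                                 snp_level_summary)
from gvdiversity.errors import DataError, UnsupportedVariantError
from gvdiversity.genome_model import OrfAnnotation, ReferenceGenome, revcomp
from gvdiversity.variants import VariantCall


def _snp(pos, ref, alt, **kw):
    return VariantCall(position=pos, ref_allele=ref, alt_allele=alt,
                       kind="SNP", support=kw.get("support", 10),
                       depth=kw.get("depth", 100), scope="isolate:t",
                       filters={"PASS"})


def _orf_genome(codons, pad="CTAGCTAGCTAG"):
    """Genome with one '+' ORF at [12, 12+len)."""
    seq = pad + codons + pad
    g = ReferenceGenome(id="t", sequence=seq, circular=False)
    ann = OrfAnnotation("g1", "g1", 12, 12 + len(codons), "+", "UNK", False)
    return g, ann


class TestEffectOracle:
    def test_synonymous_third_position(self):
        assert effect_oracle("ATGAAATAA", 5, "G") == EFFECT_SYNONYMOUS  # AAA->AAG

    def test_non_synonymous_first_position(self):
        assert effect_oracle("ATGAAATAA", 3, "C") == EFFECT_NON_SYNONYMOUS  # K->Q

    def test_alt_equal_ref_rejected(self):
        with pytest.raises(DataError):
            effect_oracle("ATGAAATAA", 3, "A")


class TestClassifyVariant:
    def test_ctg_to_cta_synonymous(self):
        # leucine CTG -> CTA, the canonical silent change
        codons = "ATG" + "CTG" + "AAA" * 48 + "TAA"
        g, ann = _orf_genome(codons)
        (rec,) = classify_variant(_snp(12 + 5, "G", "A"), [ann], g)
        assert (rec.ref_codon, rec.alt_codon) == ("CTG", "CTA")
        assert rec.effect == EFFECT_SYNONYMOUS
        assert (rec.codon_index, rec.position_in_codon) == (1, 2)

    def test_stop_gain_is_non_synonymous(self):
        codons = "ATG" + "TAC" + "AAA" * 48 + "TAA"  # TAC -> TAA
        g, ann = _orf_genome(codons)
        (rec,) = classify_variant(_snp(12 + 5, "C", "A"), [ann], g)
        assert rec.alt_aa == "*"
        assert rec.effect == EFFECT_NON_SYNONYMOUS

    def test_minus_strand_codon_on_reverse_complement(self):
        codons = "ATG" + "CTG" + "AAA" * 48 + "TAA"
        pad = "CTAGCTAGCTAG"
        seq = pad + revcomp(codons) + pad
        g = ReferenceGenome(id="t", sequence=seq, circular=False)
        ann = OrfAnnotation("g1", "g1", 12, 12 + len(codons), "-", "UNK", False)
        # codon offset 5 on the coding strand = forward position end-1-5
        pos = ann.end - 1 - 5
        fwd_ref = g.sequence[pos]
        fwd_alt = revcomp("A")  # A on coding strand
        (rec,) = classify_variant(_snp(pos, fwd_ref, fwd_alt), [ann], g)
        assert rec.ref_codon == "CTG" and rec.alt_codon == "CTA"
        assert rec.effect == EFFECT_SYNONYMOUS

    def test_codon_with_n_undetermined(self):
        codons = "ATG" + "CNG" + "AAA" * 48 + "TAA"
        g, ann = _orf_genome(codons)
        (rec,) = classify_variant(_snp(12 + 3, "C", "T"), [ann], g)
        assert rec.effect == EFFECT_UNDETERMINED
        assert rec.ref_aa is None

    def test_intergenic_position_empty(self):
        codons = "ATG" + "AAA" * 49 + "TAA"
        g, ann = _orf_genome(codons)
        assert classify_variant(_snp(0, g.sequence[0], "A" if g.sequence[0] != "A" else "T"),
                                [ann], g) == []

    def test_indel_rejected(self):
        codons = "ATG" + "AAA" * 49 + "TAA"
        g, ann = _orf_genome(codons)
        indel = VariantCall(position=20, ref_allele="A", alt_allele="",
                            kind="deletion", support=10, depth=100,
                            scope="isolate:t", filters={"PASS"})
        with pytest.raises(UnsupportedVariantError):
            classify_variant(indel, [ann], g)

    def test_overlapping_orfs_one_record_each(self, toy):
        anns = {a.gene_id: a for a in toy.annotations}
        ga, gb = toy.overlap_gene_ids
        a, b = anns[ga], anns[gb]
        pos = b.start + 40
        ref = toy.genome.sequence[pos]
        alt = "A" if ref != "A" else "G"
        recs = classify_variant(_snp(pos, ref, alt), toy.annotations, toy.genome)
        assert sorted(r.gene_id for r in recs) == sorted([ga, gb])
        for rec in recs:
            ann = anns[rec.gene_id]
            assert rec.effect == effect_oracle(
                ann.coding_sequence(toy.genome), pos - ann.start, alt)

    def test_overlap_can_split_effects(self, toy):
        """Somewhere in the overlap one allele is silent in one gene and
        amino-acid-changing in the other (different frames)."""
        anns = {a.gene_id: a for a in toy.annotations}
        ga, gb = toy.overlap_gene_ids
        b, a_end = anns[gb].start, anns[ga].end
        split = 0
        for pos in range(b, a_end):
            ref = toy.genome.sequence[pos]
            for alt in "ACGT":
                if alt == ref:
                    continue
                recs = classify_variant(_snp(pos, ref, alt),
                                        toy.annotations, toy.genome)
                effects = {r.gene_id: r.effect for r in recs}
                if len(set(effects.values())) == 2:
                    split += 1
        assert split > 0

    def test_strand_symmetry(self, toy):
        """Reverse-complementing the genome and flipping every annotation
        leaves each effect label unchanged."""
        g = toy.genome
        n = len(g)
        rc = ReferenceGenome(id="rc", sequence=revcomp(g.sequence),
                             circular=True)
        flipped = [OrfAnnotation(a.gene_id, a.name, n - a.end, n - a.start,
                                 "-" if a.strand == "+" else "+",
                                 a.category, a.is_core)
                   for a in toy.annotations if a.end <= n]
        fwd_anns = [a for a in toy.annotations if a.end <= n]
        for ann in fwd_anns[:3]:
            for pos in range(ann.start + 3, ann.start + 24):
                ref = g.sequence[pos]
                alt = "A" if ref != "A" else "C"
                fwd = classify_variant(_snp(pos, ref, alt), fwd_anns, g)
                mirror_pos = n - 1 - pos
                rc_recs = classify_variant(
                    _snp(mirror_pos, revcomp(ref), revcomp(alt)), flipped, rc)
                assert {(r.gene_id, r.effect) for r in fwd} == \
                    {(r.gene_id, r.effect) for r in rc_recs}


class TestSnpLevelSummary:
    def _variants(self, n):
        return [_snp(i, "A", "G") for i in range(n)]

    def test_plain_arithmetic(self):
        codons = "ATG" + "AAA" * 49 + "TAA"
        g, ann = _orf_genome(codons)
        variants, effects = [], {}
        # 5 synonymous (third codon positions AAA->AAG), 4 non-syn, 1 non-coding
        for i in range(5):
            pos = 12 + 3 * (i + 1) + 2
            v = _snp(pos, "A", "G")
            variants.append(v)
            effects[v.key] = classify_variant(v, [ann], g)
        for i in range(4):
            pos = 12 + 3 * (i + 20)
            v = _snp(pos, "A", "C")
            variants.append(v)
            effects[v.key] = classify_variant(v, [ann], g)
        v = _snp(0, g.sequence[0], "A" if g.sequence[0] != "A" else "T")
        variants.append(v)
        effects[v.key] = []
        summary = snp_level_summary(effects, variants)
        assert summary.percentages() == (50.0, 40.0, 10.0)

    def test_overlap_precedence_non_synonymous_wins(self):
        v = _snp(5, "A", "G")
        effects = {v.key: []}
        from gvdiversity.effects import EffectRecord
        effects[v.key] = [
            EffectRecord(v.key, "a", 0, 0, "AAA", "GAA", "K", "E",
                         EFFECT_NON_SYNONYMOUS),
            EffectRecord(v.key, "b", 3, 2, "CTG", "CTA", "L", "L",
                         EFFECT_SYNONYMOUS)]
        summary = snp_level_summary(effects, [v])
        assert summary.n_non_synonymous == 1
        assert summary.n_synonymous == 0

    def test_empty_input_marked(self):
        summary = snp_level_summary({}, [])
        assert summary.empty
        assert summary.percentages() == (0.0, 0.0, 0.0)

    def test_partition_sums_to_100_exactly(self, toy):
        import numpy as np
        rng = np.random.default_rng(3)
        variants = []
        for _ in range(37):
            pos = int(rng.integers(0, len(toy.genome)))
            ref = toy.genome.sequence[pos]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                continue
            variants.append(_snp(pos, ref, alt))
        effects = classify_all(variants, toy.annotations, toy.genome)
        s = snp_level_summary(effects, variants)
        assert s.n_synonymous + s.n_non_synonymous + s.n_non_coding == s.n_snps
        assert sum(s.percentages()) == pytest.approx(100.0, abs=1e-9)
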