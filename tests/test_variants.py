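"""Homopolymer correction, threshold semantics, pooling, masks, VCF."""

import numpy as np
import pysam
import pytest

from gvdiversity.genome_model import (OrfAnnotation, ReferenceGenome,
                                      find_homopolymer_runs)
from gvdiversity.mapping import Pileup
from gvdiversity.variants import (FILTER_HOMOPOLYMER, FILTER_IN_TANDEM_REPEAT,
                                  FILTER_LOW_FREQUENCY, FILTER_LOW_SUPPORT,
                                  call_isolate_variants,
                                  call_variants_from_pileup, classify_region,
                                  correct_homopolymers, load_mask_bed,
                                  write_mask_bed, write_vcf)


def _genome(seq="ACGT" * 100):
    return ReferenceGenome(id="g", sequence=seq, circular=False)


def _col(pile, pos, ref_count, alt=None, alt_count=0, dels=0, ins=None):
    col = pile.column(pos)
    col.base_counts[col.ref_base] = ref_count
    if alt:
        col.base_counts[alt] = alt_count
    col.del_count = dels
    if ins:
        col.insertions.update(ins)
    return col


class TestCorrectHomopolymers:
    def _run_pileup(self, dels, depth=300):
        g = _genome("CGTCG" + "AAAA" + "CGTCG" * 20)
        runs = find_homopolymer_runs(g, min_len=3)
        pile = Pileup(g)
        _col(pile, 6, depth - dels, dels=dels)
        return g, runs, pile

    def test_low_frequency_noise_removed(self):
        g, runs, pile = self._run_pileup(dels=2)  # 0.67% < 1%
        out = correct_homopolymers(pile, runs)
        col = out.get(6)
        assert col.del_count == 0
        assert col.depth == 300  # folded into the reference base

    def test_sufficient_signal_retained(self):
        g, runs, pile = self._run_pileup(dels=9)  # 3%, 9 reads
        out = correct_homopolymers(pile, runs)
        assert out.get(6).del_count == 9

    def test_three_reads_below_frequency_removed(self):
        g, runs, pile = self._run_pileup(dels=2, depth=150)
        # 2 reads: fails the 3-read rule even at 1.3%
        out = correct_homopolymers(pile, runs)
        assert out.get(6).del_count == 0

    def test_signal_outside_runs_untouched(self):
        g = _genome("CGTCG" + "AAAA" + "CGTCG" * 20)
        runs = find_homopolymer_runs(g, min_len=3)
        pile = Pileup(g)
        _col(pile, 20, 298, dels=2)
        out = correct_homopolymers(pile, runs)
        assert out.get(20).del_count == 2

    def test_input_pileup_unchanged(self):
        g, runs, pile = self._run_pileup(dels=2)
        correct_homopolymers(pile, runs)
        assert pile.get(6).del_count == 2

    def test_insertion_noise_removed_at_preceding_column(self):
        g = _genome("CGTCG" + "AAAA" + "CGTCG" * 20)
        runs = find_homopolymer_runs(g, min_len=3)
        pile = Pileup(g)
        col = _col(pile, 4, 300, ins={"A": 2})  # column before the run
        out = correct_homopolymers(pile, runs)
        assert out.get(4).insertions == {}


class TestThresholds:
    @pytest.mark.parametrize("support,depth,expected_flags", [
        (4, 200, {FILTER_LOW_SUPPORT}),          # 2% but only 4 reads
        (6, 800, {FILTER_LOW_FREQUENCY}),        # 6 reads but 0.75%
        (4, 800, {FILTER_LOW_SUPPORT, FILTER_LOW_FREQUENCY}),
        (10, 500, {"PASS"}),                     # 2%, 10 reads
        (5, 500, {"PASS"}),                      # exactly at both thresholds
    ])
    def test_isolate_rules(self, support, depth, expected_flags):
        g = _genome()
        pile = Pileup(g)
        _col(pile, 10, depth - support, alt="A" if g.sequence[10] != "A" else "G",
             alt_count=support)
        (call,) = call_isolate_variants(pile)
        assert call.filters == expected_flags
        assert call.support == support and call.depth == depth

    def test_mask_flags_tandem_repeat(self):
        g = _genome()
        pile = Pileup(g)
        _col(pile, 10, 490, alt="A" if g.sequence[10] != "A" else "G",
             alt_count=10)
        (call,) = call_isolate_variants(pile, mask=[(5, 15)])
        assert FILTER_IN_TANDEM_REPEAT in call.filters
        assert not call.is_pass

    def test_multiallelic_site_one_call_per_allele(self):
        g = _genome("GGGG" * 100)
        pile = Pileup(g)
        col = pile.column(10)
        col.base_counts.update({"G": 480, "A": 12, "C": 8})
        calls = call_isolate_variants(pile)
        assert {(c.alt_allele, c.support) for c in calls} == {("A", 12), ("C", 8)}
        assert all(c.is_pass for c in calls)

    def test_homopolymer_indels_flagged_not_pass(self):
        g = _genome("CGTCG" + "AAAA" + "CGTCG" * 20)
        runs = find_homopolymer_runs(g, min_len=3)
        pile = Pileup(g)
        _col(pile, 6, 280, dels=20)  # strong signal, but inside a run
        (call,) = call_isolate_variants(pile, homopolymer_runs=runs)
        assert call.filters == {FILTER_HOMOPOLYMER}

    def test_monotonicity_in_thresholds(self):
        """Raising min_support or min_freq never adds a PASS variant."""
        rng = np.random.default_rng(42)
        g = _genome("ACGT" * 250)
        pile = Pileup(g)
        for pos in range(0, 1000, 7):
            depth = int(rng.integers(50, 900))
            support = int(rng.integers(0, 15))
            if support == 0:
                continue
            alt = "A" if g.sequence[pos] != "A" else "G"
            _col(pile, pos, depth - support, alt=alt, alt_count=support)
        base = {c.key for c in call_variants_from_pileup(pile, 5, 0.01)
                if c.is_pass}
        for s, f in [(6, 0.01), (5, 0.02), (8, 0.03)]:
            tighter = {c.key for c in call_variants_from_pileup(pile, s, f)
                       if c.is_pass}
            assert tighter <= base

    def test_pass_set_matches_brute_force_rescan(self):
        rng = np.random.default_rng(7)
        g = _genome("ACGT" * 250)
        mask = [(100, 150), (700, 720)]
        pile = Pileup(g)
        truth = {}
        for pos in range(0, 1000, 11):
            depth = int(rng.integers(30, 600))
            support = int(rng.integers(1, 12))
            alt = "C" if g.sequence[pos] != "C" else "T"
            _col(pile, pos, depth - support, alt=alt, alt_count=support)
            truth[pos] = (support, depth)
        calls = call_variants_from_pileup(pile, 5, 0.01, mask=mask)
        got_pass = {c.position for c in calls if c.is_pass}
        expected = {p for p, (s, d) in truth.items()
                    if s >= 5 and s / d >= 0.01
                    and not any(a <= p < b for a, b in mask)}
        assert got_pass == expected


class TestPooling:
    def test_cumulative_gain_metapopulation_only(self):
        """4/300 in each of two isolates fails per isolate (5-read rule)
        but passes pooled: 8/600 = 1.33% with the 3-read rule."""
        g = _genome()
        alt = "A" if g.sequence[50] != "A" else "G"
        per_isolate = []
        for _ in range(2):
            pile = Pileup(g)
            _col(pile, 50, 296, alt=alt, alt_count=4)
            per_isolate.append(call_isolate_variants(pile))
        assert all(c.filters == {FILTER_LOW_SUPPORT}
                   for calls in per_isolate for c in calls)
        pooled = Pileup(g)
        _col(pooled, 50, 592, alt=alt, alt_count=8)
        (call,) = call_variants_from_pileup(pooled, 3, 0.01,
                                            scope="metapopulation")
        assert call.is_pass
        assert call.frequency == pytest.approx(8 / 600)

    def test_isolate_specific_allele_diluted_in_pool(self):
        """6% in one isolate passes there; pooled over depth 2000 the same
        six reads fall to 0.3% and fail the frequency rule."""
        g = _genome()
        alt = "A" if g.sequence[50] != "A" else "G"
        iso = Pileup(g)
        _col(iso, 50, 94, alt=alt, alt_count=6)
        (iso_call,) = call_isolate_variants(iso)
        assert iso_call.is_pass
        pooled = Pileup(g)
        _col(pooled, 50, 1994, alt=alt, alt_count=6)
        (pool_call,) = call_variants_from_pileup(pooled, 3, 0.01,
                                                 scope="metapopulation")
        assert pool_call.filters == {FILTER_LOW_FREQUENCY}

    def test_pooled_support_is_sum_of_isolates(self):
        g = _genome()
        alt = "A" if g.sequence[50] != "A" else "G"
        supports = [4, 7, 2]
        pooled = Pileup(g)
        _col(pooled, 50, 900 - sum(supports), alt=alt, alt_count=sum(supports))
        (call,) = call_variants_from_pileup(pooled, 3, 0.01)
        assert call.support == sum(supports)


class TestClassifyRegion:
    def test_coding_noncoding_and_overlap(self):
        g = _genome("A" * 1000)
        anns = [OrfAnnotation("a", "a", 100, 400, "+", "UNK", False),
                OrfAnnotation("b", "b", 300, 600, "+", "UNK", False)]
        pile = Pileup(g)
        for pos in (150, 350, 800):
            _col(pile, pos, 90, alt="G", alt_count=10)
        calls = call_variants_from_pileup(pile, 5, 0.01)
        classify_region(calls, anns, len(g))
        regions = {c.position: c.region for c in calls}
        assert regions == {150: "coding", 350: "coding", 800: "non-coding"}


class TestVcfOutput:
    def test_vcf_parses_with_pysam(self, tmp_path):
        g = _genome("ACGTACGTAC" * 10)
        pile = Pileup(g)
        _col(pile, 20, 180, alt="A" if g.sequence[20] != "A" else "C",
             alt_count=20)
        _col(pile, 40, 190, dels=10)
        _col(pile, 60, 195, ins={"TT": 5})
        calls = call_variants_from_pileup(pile, 5, 0.01)
        path = tmp_path / "out.vcf"
        write_vcf(calls, g, path)
        recs = list(pysam.VariantFile(str(path)))
        by_pos = {r.pos: r for r in recs}
        snp = by_pos[21]
        assert snp.ref == g.sequence[20]
        assert snp.info["DP"] == 200
        deletion = by_pos[40]  # anchored one base left
        assert len(deletion.ref) == 2 and len(deletion.alts[0]) == 1
        insertion = by_pos[61]
        assert len(insertion.alts[0]) == 3

    def test_mask_bed_round_trip(self, tmp_path):
        mask = [(10, 50), (200, 260)]
        path = tmp_path / "mask.bed"
        write_mask_bed(mask, "chr", path)
        assert load_mask_bed(path) == mask
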