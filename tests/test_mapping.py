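"""Seed-and-extend mapping, pileups, consensus, SAM round trip."""

from dataclasses import dataclass

import pytest

from gvdiversity.errors import DataError
from gvdiversity.genome_model import ReferenceGenome, revcomp
from gvdiversity.mapping import (AlignedRead, MappingStats, build_pileup,
                                 consensus_from_pileup, ingest_sam, map_reads,
                                 write_sam)
from gvdiversity.synth import (build_isolate_haplotypes, simulate_reads,
                               stage_rng)


@dataclass
class FakeRead:
    read_id: str
    sequence: str


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestMapReads:
    def test_exact_substring(self, toy):
        g = toy.genome
        read = FakeRead("r1", g.sequence[100:500])
        (aln,) = map_reads([read], g)
        assert aln.ref_start == 100
        assert aln.cigar == [("M", 400)]
        assert aln.identity == 1.0
        assert aln.strand == "+"

    def test_reverse_complement_orientation(self, toy):
        g = toy.genome
        read = FakeRead("r1", revcomp(g.sequence[100:500]))
        (aln,) = map_reads([read], g)
        assert aln.ref_start == 100
        assert aln.strand == "-"
        assert aln.query == g.sequence[100:500]

    def test_origin_spanning_read_not_split(self, toy):
        g = toy.genome
        n = len(g)
        read = FakeRead("r1", g.fetch(n - 100, n + 200))
        (aln,) = map_reads([read], g)
        assert aln.ref_start == n - 100
        assert aln.cigar == [("M", 300)]

    def test_unrelated_read_unmapped(self, toy):
        rng = stage_rng(0, 55)
        stats = MappingStats()
        read = FakeRead("junk", _random_seq(rng, 300))
        assert map_reads([read], toy.genome, stats=stats) == []
        assert stats.unmapped == 1

    def test_low_identity_discarded(self, toy):
        g = toy.genome
        seq = list(g.sequence[200:500])
        # heavy divergence confined to the first half (identity ~0.88),
        # clean second half still provides exact seeds
        for i in range(0, 140, 4):
            seq[i] = "A" if seq[i] != "A" else "C"
        stats = MappingStats()
        out = map_reads([FakeRead("r", "".join(seq))], g, stats=stats)
        assert out == [] and stats.low_identity == 1

    def test_read_with_deletion(self, toy):
        g = toy.genome
        read = FakeRead("r", g.sequence[100:250] + g.sequence[255:400])
        (aln,) = map_reads([read], g)
        assert aln.ref_start == 100
        # unit costs allow equally optimal gap splits; total gap must be 5
        assert sum(n for op, n in aln.cigar if op == "D") == 5
        assert aln.ref_span == 300

    def test_idempotent_remapping(self, small_toy, small_config):
        haps = build_isolate_haplotypes(small_toy.genome, [], isolates=["i"])
        reads = simulate_reads(haps, small_config)["i"]
        first = map_reads(reads, small_toy.genome)
        again = map_reads([FakeRead(a.read_id, a.query) for a in first],
                          small_toy.genome)
        assert [(a.read_id, a.ref_start, a.cigar) for a in first] == \
            [(a.read_id, a.ref_start, a.cigar) for a in again]


class TestPileup:
    def test_uniform_coverage(self, toy):
        g = toy.genome
        alns = [AlignedRead(f"r{i}", 0, "+", [("M", 100)], g.sequence[:100], 1.0)
                for i in range(10)]
        pile = build_pileup(alns, g)
        for pos in range(100):
            col = pile.get(pos)
            assert col.depth == 10
            assert col.base_counts[g.sequence[pos]] == 10

    def test_deletion_column(self, toy):
        g = toy.genome
        alns = [AlignedRead(f"m{i}", 0, "+", [("M", 100)], g.sequence[:100], 1.0)
                for i in range(9)]
        q = g.sequence[0:50] + g.sequence[51:100]
        alns.append(AlignedRead("del", 0, "+",
                                [("M", 50), ("D", 1), ("M", 49)], q, 0.99))
        pile = build_pileup(alns, g)
        col = pile.get(50)
        assert col.del_count == 1
        assert col.depth == 10

    def test_insertion_recorded_at_preceding_column(self, toy):
        g = toy.genome
        q = g.sequence[0:50] + "ACGT" + g.sequence[50:100]
        aln = AlignedRead("ins", 0, "+", [("M", 50), ("I", 4), ("M", 50)], q, 0.96)
        pile = build_pileup([aln], g)
        assert pile.get(49).insertions == {"ACGT": 1}

    def test_overlap_additivity(self, toy):
        g = toy.genome
        alns = [AlignedRead("a", 0, "+", [("M", 60)], g.sequence[:60], 1.0),
                AlignedRead("b", 40, "+", [("M", 60)], g.sequence[40:100], 1.0)]
        pile = build_pileup(alns, g)
        assert all(pile.get(p).depth == 2 for p in range(40, 60))
        assert pile.get(10).depth == 1 and pile.get(80).depth == 1

    def test_mass_conservation(self, small_toy, small_config):
        haps = build_isolate_haplotypes(small_toy.genome, [], isolates=["i"])
        reads = simulate_reads(haps, small_config)["i"]
        alns = map_reads(reads, small_toy.genome)
        pile = build_pileup(alns, small_toy.genome)
        md = sum(n for a in alns for op, n in a.cigar if op in "MD")
        assert pile.total_mass() == md

    def test_inconsistent_cigar_rejected(self):
        with pytest.raises(DataError, match="cigar"):
            AlignedRead("bad", 0, "+", [("M", 10)], "ACGT", 1.0)


class TestConsensus:
    def _one_col_pileup(self, g, pos, counts, dels=0):
        from gvdiversity.mapping import Pileup
        pile = Pileup(g)
        # keep every position at depth >= 5 so min_depth never interferes
        for p in range(len(g)):
            pile.column(p).base_counts[g.sequence[p]] = 10
        col = pile.column(pos)
        col.base_counts = dict.fromkeys("ACGTN", 0)
        col.base_counts.update(counts)
        col.del_count = dels
        return pile

    def test_majority_wins(self):
        g = ReferenceGenome(id="g", sequence="G" * 20, circular=False)
        pile = self._one_col_pileup(g, 5, {"A": 9, "G": 1})
        assert consensus_from_pileup(pile, g).sequence[5] == "A"

    def test_tie_keeps_reference(self):
        g = ReferenceGenome(id="g", sequence="G" * 20, circular=False)
        pile = self._one_col_pileup(g, 5, {"A": 5, "G": 5})
        assert consensus_from_pileup(pile, g).sequence[5] == "G"

    def test_low_depth_keeps_reference(self):
        g = ReferenceGenome(id="g", sequence="G" * 20, circular=False)
        pile = self._one_col_pileup(g, 5, {"A": 3})
        assert consensus_from_pileup(pile, g, min_depth=5).sequence[5] == "G"

    def test_deletion_outvoting_bases_drops_position(self):
        g = ReferenceGenome(id="g", sequence="G" * 20, circular=False)
        pile = self._one_col_pileup(g, 5, {"G": 4}, dels=6)
        cons = consensus_from_pileup(pile, g)
        assert len(cons) == 19

    def test_fixed_variant_reaches_consensus(self, small_toy, small_config):
        """An allele fixed in the population (frequency 1.0) becomes the
        consensus base at its site."""
        from fractions import Fraction
        from gvdiversity.synth import PlantedVariant
        g = small_toy.genome
        pos = small_toy.annotations[0].start + 10
        ref = g.sequence[pos]
        alt = "A" if ref != "A" else "C"
        haps = build_isolate_haplotypes(
            g, [PlantedVariant(pos, ref, alt, {"i": Fraction(1)})])
        reads = simulate_reads(haps, small_config)["i"]
        alns = map_reads(reads, g)
        cons = consensus_from_pileup(build_pileup(alns, g), g)
        assert cons.sequence[pos] == alt
        assert len(cons) == len(g)


class TestSamIO:
    def test_round_trip(self, toy, tmp_path):
        g = toy.genome
        alns = [AlignedRead("r1", 100, "+", [("M", 200)],
                            g.sequence[100:300], 1.0),
                AlignedRead("r2", 400, "-", [("M", 50), ("D", 2), ("M", 50)],
                            g.sequence[400:450] + g.sequence[452:502], 0.98,
                            edit_distance=2)]
        path = tmp_path / "out.sam"
        write_sam(alns, g, path)
        back = ingest_sam(path, g)
        assert [(a.read_id, a.ref_start, a.strand, a.cigar, a.query)
                for a in back] == \
               [(a.read_id, a.ref_start, a.strand, a.cigar, a.query)
                for a in alns]

    def test_hard_clips_rejected(self, toy, tmp_path):
        sam = tmp_path / "hard.sam"
        sam.write_text(
            f"@HD\tVN:1.6\n@SQ\tSN:{toy.genome.id}\tLN:{len(toy.genome)}\n"
            f"r1\t0\t{toy.genome.id}\t1\t60\t5H100M\t*\t0\t0\t"
            f"{toy.genome.sequence[:100]}\t*\n")
        with pytest.raises(DataError, match="hard clip"):
            ingest_sam(sam, toy.genome)
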