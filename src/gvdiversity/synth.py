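"""Synthetic genomes, isolate populations and pyrosequencing-like reads.

Raw reads for the study system (seven field isolates of a ~103 kb circular
granulovirus genome, sequenced on a 454 GS FLX Titanium) are not publicly
available, so every downstream stage is exercised on synthetic data that
emulates the relevant structure:

* a circular toy genome carrying planted ORFs (including, optionally, one
  same-strand overlapping ORF pair in different frames, mirroring the
  lef-10/vp1054 arrangement), perfect tandem direct-repeat arrays, and
  homopolymer runs;
* isolate populations represented as weighted haplotype mixtures whose
  marginal allele frequency at each planted site is exact (rational
  weights), with direct-repeat copy-number differences realized as whole
  repeat-unit insertions/deletions;
* single-end reads with 454-like properties: lengths ~N(400, 80) truncated
  to [100, 1000] bp, positions uniform on the circle, homopolymer ±1 indel
  errors confined to runs of length >= 3, and a small uniform substitution
  error rate.

All randomness flows from one integer seed through numpy ``SeedSequence``
spawning, so each stage is independently reproducible.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .genome_model import (
    OrfAnnotation,
    ReferenceGenome,
    CATEGORIES,
    STOP_CODONS,
    find_homopolymer_runs,
    orf_scan,
    revcomp,
)

_BASES = "ACGT"
_NONSTOP_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES
                   if a + b + c not in STOP_CODONS]

# stage tags for seed splitting
_TAG_GENOME = 1
_TAG_READS = 2
_TAG_HAPLO = 3


def _stable_int(text: str) -> int:
    return zlib.crc32(text.encode())


def stage_rng(seed: int, tag: int, *extra: int) -> np.random.Generator:
    """Derive an independent generator for one pipeline stage from the master
    seed (counter-based splitting via SeedSequence)."""
    return np.random.default_rng(np.random.SeedSequence([seed, tag, *extra]))


@dataclass(frozen=True)
class DrSpec:
    """One planted tandem direct-repeat array: ``unit_len`` bp repeated
    ``copies`` times on the reference; the unit sequence is drawn randomly
    unless given."""
    unit_len: int
    copies: int
    unit: str | None = None


@dataclass(frozen=True)
class PlantedVariant:
    """A known substitution planted at given per-isolate frequencies."""
    position: int
    ref_allele: str
    alt_allele: str
    frequency_per_isolate: Mapping[str, Fraction | float]

    def frequency(self, isolate: str) -> Fraction:
        f = self.frequency_per_isolate.get(isolate, 0)
        fr = f if isinstance(f, Fraction) else Fraction(f).limit_denominator(10**6)
        if not 0 <= fr <= 1:
            raise ConfigError(f"variant at {self.position}: frequency {f} outside [0,1]")
        return fr


@dataclass(frozen=True)
class SimulationConfig:
    """Free parameters of the toy-genome and read simulation.

    Defaults emulate the study's sequencing design at desk scale: a 10 kb
    circular genome, mean coverage 100x, 454-like read lengths (mean 400,
    sd 80), a 2% homopolymer indel error rate per run traversal and a small
    (5e-4) per-base substitution error rate.
    """
    seed: int
    genome_length: int = 10_000
    n_orfs: int = 8
    overlap_pair: bool = True
    overlap_len: int = 134
    dr_specs: tuple[DrSpec, ...] = (
        DrSpec(6, 5), DrSpec(9, 5), DrSpec(23, 4), DrSpec(8, 13),
    )
    homopolymer_runs: tuple[tuple[str, int], ...] = (("A", 6), ("T", 7), ("C", 5))
    orf_len_range: tuple[int, int] = (300, 600)
    core_fraction: float = 0.38
    read_length_mean: float = 400.0
    read_length_sd: float = 80.0
    read_length_bounds: tuple[int, int] = (100, 1000)
    depth: float = 100.0
    hp_indel_rate: float = 0.02
    sub_error_rate: float = 5e-4
    circular: bool = True

    def validate(self) -> None:
        for name in ("hp_indel_rate", "sub_error_rate", "core_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.overlap_pair and self.n_orfs < 2:
            raise ConfigError("overlap_pair requires n_orfs >= 2")


@dataclass(frozen=True)
class DirectRepeatTruth:
    dr_id: str
    start: int
    end: int
    unit: str
    copies: int


@dataclass
class ToyGenome:
    """A generated genome plus exact truth tables for its planted features."""
    genome: ReferenceGenome
    annotations: list[OrfAnnotation]
    dr_truth: list[DirectRepeatTruth]
    hp_truth: list[tuple[int, int, str]]
    overlap_gene_ids: tuple[str, str] | None


# ---------------------------------------------------------------------------
# toy genome construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


# "CTAG" x3 reads as a stop within 12 bp in all six frames (CTAG is its own
# reverse complement up to rotation) and contains no ATG, so intergenic
# spacers laced with these islands cannot host or transmit reading frames
# >= 150 bp; the unit (4 bp) and span (12 bp) stay below direct-repeat
# detection thresholds.
_STOP_ISLAND = "CTAGCTAGCTAG"


def _spacer(rng: np.random.Generator, n: int) -> str:
    """Intergenic filler: random sequence interrupted by stop islands every
    <= 88 bp, with an island guaranteed near the downstream end."""
    if n < 15:
        return _random_seq(rng, n)
    s = ""
    while len(s) < n - 15:
        s += _STOP_ISLAND + _random_seq(rng, 88)
    return s[: n - 15] + _STOP_ISLAND + _random_seq(rng, 3)


def _screen_block(seq: str, expected_orfs: set[tuple[int, int, str]]) -> bool:
    """Screen a feature block in its genomic context: flanked by stop
    islands, as the assembled spacers provide. This catches frames that
    carry an ATG but no stop inside the block and would otherwise complete
    a few bases into the neighboring spacer, where no whole mutable codon
    remains for suppression. The 135 bp screen margin covers the few extra
    bases such a frame can gain before the first in-spacer stop."""
    flanked = _STOP_ISLAND + seq + _STOP_ISLAND
    off = len(_STOP_ISLAND)
    shifted = {(a + off, b + off, s) for a, b, s in expected_orfs}
    toy = ReferenceGenome(id="block", sequence=flanked, circular=False)
    return set(orf_scan(toy, min_len=135)) == shifted


def _random_orf_block(rng: np.random.Generator, length: int) -> str:
    """An ORF of ``length`` bp (ATG + non-stop codons + stop) whose block
    hosts no other reading frame, even one completing in the flanks."""
    n_codons = length // 3
    for _ in range(500):
        body = [_NONSTOP_CODONS[i] for i in
                rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)]
        stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
        seq = "ATG" + "".join(body) + stop
        if _screen_block(seq, {(0, length, "+")}):
            return seq
    raise ConfigError(f"could not build a clean {length} bp ORF block")


def _overlap_locus(rng: np.random.Generator, len_a: int, len_b: int,
                   overlap: int) -> tuple[str, int]:
    """A locus hosting two same-strand ORFs in different frames: gene A at
    [0, len_a), gene B at [len_a - overlap, len_a - overlap + len_b).

    Returns (sequence, b_start). Frame difference is guaranteed by the
    caller's choice of lengths ((len_a - overlap) % 3 != 0).
    """
    b_start = len_a - overlap
    total = b_start + len_b
    if (len_a % 3) or (len_b % 3) or (b_start % 3 == 0):
        raise ConfigError("overlap locus lengths must put B out of frame with A")
    expected = {(0, len_a, "+"), (b_start, total, "+")}
    for _ in range(2000):
        seq: list[str] = [""] * total
        # B written in its own frame: ATG + non-stop codons + stop
        b_codons = (["ATG"]
                    + [_NONSTOP_CODONS[i] for i in
                       rng.integers(0, len(_NONSTOP_CODONS), size=len_b // 3 - 2)]
                    + [("TAA", "TAG", "TGA")[rng.integers(0, 3)]])
        seq[b_start:total] = "".join(b_codons)
        # force A's stop inside B; the straddling B codons (x,y,T)/(A,A,z) or
        # (x,T,A)/(A,y,z) can never become stops themselves
        seq[len_a - 3:len_a] = "TAA"
        # A's own codons up to B's start
        n_full = b_start // 3
        a_codons = ["ATG"] + [_NONSTOP_CODONS[i] for i in
                              rng.integers(0, len(_NONSTOP_CODONS), size=n_full - 1)]
        seq[0:3 * n_full] = "".join(a_codons)
        # A codon straddling b_start: pick free bases keeping it non-stop
        free = b_start - 3 * n_full
        if free:
            fixed = "".join(seq[b_start:3 * n_full + 3])
            choices = [p for p in itertools.product(_BASES, repeat=free)
                       if "".join(p) + fixed not in STOP_CODONS]
            pick = choices[rng.integers(0, len(choices))]
            seq[3 * n_full:b_start] = pick
        candidate = "".join(seq)
        if _screen_block(candidate, expected):
            return candidate, b_start
    raise ConfigError("could not construct the overlapping ORF locus")


def _random_unit(rng: np.random.Generator, unit_len: int) -> str:
    """A primitive repeat unit (no smaller internal period)."""
    for _ in range(100):
        u = _random_seq(rng, unit_len)
        if len(set(u)) < 2:
            continue
        if (u + u).find(u, 1) == unit_len:  # smallest period == full length
            return u
    raise ConfigError(f"could not draw a primitive unit of {unit_len} bp")


_GENE_NAMES = ["granulin", "lef-1", "lef-2", "p10", "pif-3", "desmoplakin",
               "fgf-1", "pep-1", "dnapol", "alk-exo", "odv-e18", "vlf-1",
               "helicase", "me53", "p6.9", "odv-e27"]


def generate_toy_genome(config: SimulationConfig) -> ToyGenome:
    """Build a circular toy genome realizing the configured features.

    Deterministic given ``config.seed``. Guarantees: every planted ORF (and
    only those) is found by a six-frame ORF scan at 150 bp; each direct
    repeat is a perfect, maximal tandem array at the truth coordinates; the
    homopolymer truth table lists every single-base run of length >= 3 in
    the final sequence (planted long runs plus background runs).
    """
    config.validate()
    last_err = "unknown"
    for attempt in range(40):
        rng = stage_rng(config.seed, _TAG_GENOME, attempt)
        try:
            toy = _assemble(rng, config)
        except _RetryLayout as exc:
            last_err = str(exc)
            continue
        return toy
    raise ConfigError(f"toy genome generation failed: {last_err}")


class _RetryLayout(Exception):
    pass


def _assemble(rng: np.random.Generator, config: SimulationConfig) -> ToyGenome:
    lo, hi = config.orf_len_range
    n_plain = config.n_orfs - (2 if config.overlap_pair else 0)

    blocks: list[tuple[str, str, object]] = []  # (kind, sequence, payload)
    for i in range(n_plain):
        length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        blocks.append(("orf", _random_orf_block(rng, length), length))
    if config.overlap_pair:
        if config.overlap_len % 3 == 0:
            # B would land in A's frame; a frame offset needs overlap != 0 mod 3
            raise ConfigError("overlap_len must not be a multiple of 3")
        len_a = 3 * int(rng.integers(max(lo, config.overlap_len + 60) // 3, hi // 3 + 1))
        len_b = 3 * int(rng.integers(max(lo, config.overlap_len + 60) // 3, hi // 3 + 1))
        seq, b_start = _overlap_locus(rng, len_a, len_b, config.overlap_len)
        blocks.append(("overlap", seq, (len_a, len_b, b_start)))
    for spec in config.dr_specs:
        unit = spec.unit or _random_unit(rng, spec.unit_len)
        if spec.copies < 2:
            raise ConfigError("dr_specs require at least 2 copies")
        array = unit * spec.copies
        g1 = _BASES[(_BASES.index(array[-1]) + 1) % 4]
        g2 = _BASES[(_BASES.index(array[0]) + 1) % 4]
        blocks.append(("dr", g1 + array + g2, (unit, spec.copies)))
    for base, run in config.homopolymer_runs:
        g = _BASES[(_BASES.index(base) + 1) % 4]
        blocks.append(("hp", g + base * run + g, (base, run)))

    order = list(rng.permutation(len(blocks)))
    blocks = [blocks[i] for i in order]

    total_block = sum(len(b[1]) for b in blocks)
    n_gaps = len(blocks) + 1
    slack = config.genome_length - total_block - 20 * n_gaps
    if slack < 0:
        raise ConfigError(
            f"genome_length={config.genome_length} too short for the requested "
            f"features ({total_block} bp of features + minimal spacers)"
        )
    gap_extra = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps))
    gaps = [20 + int(g) for g in gap_extra]

    seq_parts: list[str] = []
    pos = 0
    placed: list[tuple[str, int, int, object]] = []
    for i, (kind, bseq, payload) in enumerate(blocks):
        spacer = _spacer(rng, gaps[i])
        seq_parts.append(spacer)
        pos += len(spacer)
        placed.append((kind, pos, pos + len(bseq), payload))
        seq_parts.append(bseq)
        pos += len(bseq)
    seq_parts.append(_spacer(rng, gaps[-1]))
    sequence = "".join(seq_parts)
    assert len(sequence) == config.genome_length

    # build annotations and truth tables from placement
    annotations: list[OrfAnnotation] = []
    dr_truth: list[DirectRepeatTruth] = []
    overlap_ids: tuple[str, str] | None = None
    protected = np.zeros(config.genome_length, dtype=bool)
    planted_orfs: set[tuple[int, int, str]] = set()
    gene_no = 0
    dr_no = 0
    names = list(_GENE_NAMES)

    def next_gene(start: int, end: int) -> OrfAnnotation:
        nonlocal gene_no
        gene_no += 1
        gid = f"g{gene_no:02d}"
        name = names.pop(0) if names else gid
        return OrfAnnotation(
            gene_id=gid, name=name, start=start, end=end, strand="+",
            category=CATEGORIES[rng.integers(0, len(CATEGORIES))],
            is_core=bool(rng.random() < config.core_fraction),
        )

    for kind, start, end, payload in placed:
        if kind == "orf":
            ann = next_gene(start, end)
            annotations.append(ann)
            planted_orfs.add((start, end, "+"))
            protected[start:end] = True
        elif kind == "overlap":
            len_a, len_b, b_start = payload
            ann_a = next_gene(start, start + len_a)
            ann_b = next_gene(start + b_start, start + b_start + len_b)
            annotations.extend([ann_a, ann_b])
            overlap_ids = (ann_a.gene_id, ann_b.gene_id)
            planted_orfs.add((ann_a.start, ann_a.end, "+"))
            planted_orfs.add((ann_b.start, ann_b.end, "+"))
            protected[start:end] = True
        elif kind == "dr":
            unit, copies = payload
            dr_no += 1
            dr_truth.append(DirectRepeatTruth(
                dr_id=f"dr{dr_no:02d}", start=start + 1, end=end - 1,
                unit=unit, copies=copies))
            protected[start:end] = True
        elif kind == "hp":
            protected[start:end] = True

    sequence = _suppress_spurious_orfs(
        sequence, planted_orfs, protected, rng, config)

    genome = ReferenceGenome(id=f"toy{config.seed}", sequence=sequence,
                             circular=config.circular)
    _check_dr_arrays(genome, dr_truth)
    hp_truth = find_homopolymer_runs(genome, min_len=3)
    return ToyGenome(genome=genome, annotations=annotations,
                     dr_truth=dr_truth, hp_truth=hp_truth,
                     overlap_gene_ids=overlap_ids)


def _suppress_spurious_orfs(sequence: str, planted: set[tuple[int, int, str]],
                            protected: np.ndarray, rng: np.random.Generator,
                            config: SimulationConfig) -> str:
    """Mutate spacer positions until a six-frame scan finds exactly the
    planted ORFs. Chance reading frames >= 150 bp arising in random spacer
    sequence (or straddling feature boundaries) get an in-frame stop codon
    written into a fully unprotected codon."""
    n = len(sequence)
    seq = list(sequence)
    for _round in range(40):
        genome = ReferenceGenome(id="draft", sequence="".join(seq),
                                 circular=config.circular)
        scanned = set(orf_scan(genome, min_len=150))
        spurious = scanned - planted
        if not spurious and planted <= scanned:
            return "".join(seq)
        # A spurious interval may be a planted ORF extended upstream by a
        # chance in-frame spacer ATG (same stop codon, longer interval); the
        # fix must then land in the upstream extension, not inside the gene.
        restrict: dict[tuple[int, int, str], tuple[int, int]] = {}
        explained: set[tuple[int, int, str]] = set()
        for sp in spurious:
            a, b, strand = sp
            for pa, pb, ps in planted:
                if ps != strand:
                    continue
                if strand == "+" and b == pb and a < pa and (pa - a) % 3 == 0:
                    restrict[sp] = (a, pa)
                    explained.add((pa, pb, ps))
                    break
                if strand == "-" and a == pa and b > pb and (b - pb) % 3 == 0:
                    restrict[sp] = (pb, b)
                    explained.add((pa, pb, ps))
                    break
        if planted - scanned - explained:
            raise _RetryLayout("a planted ORF was destroyed during suppression")
        for a, b, strand in spurious:
            # default window spares only the ORF's own stop codon, so a
            # start codon sitting at a feature edge can itself be erased
            default = (a, b - 3) if strand == "+" else (a + 3, b)
            lo, hi = restrict.get((a, b, strand), default)
            for start in range(lo, hi - 2, 3):
                pos = [(start + j) % n for j in range(3)]
                if any(protected[p] for p in pos):
                    continue
                stop = "TAA" if strand == "+" else "TTA"  # TAA read on minus
                for p, ch in zip(pos, stop):
                    seq[p] = ch
                break
            else:
                raise _RetryLayout(
                    f"spurious ORF at [{a},{b}){strand} has no mutable codon")
    raise _RetryLayout("spurious ORF suppression did not converge")


def _check_dr_arrays(genome: ReferenceGenome, dr_truth: list[DirectRepeatTruth]) -> None:
    for dr in dr_truth:
        span = genome.fetch(dr.start, dr.end)
        if span != dr.unit * dr.copies:
            raise _RetryLayout(f"{dr.dr_id}: planted array corrupted")
        if genome.fetch(dr.start - len(dr.unit), dr.start) == dr.unit or \
           genome.fetch(dr.end, dr.end + len(dr.unit)) == dr.unit:
            raise _RetryLayout(f"{dr.dr_id}: array extends beyond truth interval")


# ---------------------------------------------------------------------------
# haplotype mixtures
# ---------------------------------------------------------------------------

def build_isolate_haplotypes(
    genome: ReferenceGenome,
    planted: Sequence[PlantedVariant],
    dr_truth: Sequence[DirectRepeatTruth] = (),
    dr_copies: Mapping[str, Mapping[str, int]] | None = None,
    isolates: Sequence[str] | None = None,
) -> dict[str, list[tuple[str, Fraction]]]:
    """Weighted haplotype mixtures per isolate.

    Planted variants segregate independently, so an isolate with k variants
    at frequencies f_i is a mixture of up to 2^k haplotypes whose weights
    are exact rational products of f_i and (1 - f_i); the marginal allele
    frequency at each site equals the requested frequency exactly.
    ``dr_copies[isolate][dr_id]`` overrides the reference copy number of a
    direct repeat, realized as insertion/deletion of whole units (applied to
    every haplotype of that isolate).
    """
    dr_copies = dr_copies or {}
    ids = list(isolates) if isolates is not None else sorted(
        {i for v in planted for i in v.frequency_per_isolate} | set(dr_copies))
    if not ids:
        raise ConfigError("no isolates defined")
    for v in planted:
        ref = genome.fetch(v.position, v.position + len(v.ref_allele))
        if ref != v.ref_allele:
            raise ConfigError(
                f"variant at {v.position}: ref_allele {v.ref_allele!r} does not "
                f"match reference {ref!r}")

    out: dict[str, list[tuple[str, Fraction]]] = {}
    for iso in ids:
        fixed: list[PlantedVariant] = []
        stochastic: list[tuple[PlantedVariant, Fraction]] = []
        seen_pos: dict[int, PlantedVariant] = {}
        for v in planted:
            f = v.frequency(iso)
            if f == 0:
                continue
            if v.position in seen_pos:
                raise ConfigError(
                    f"isolate {iso}: incompatible variants at position {v.position}")
            seen_pos[v.position] = v
            if f == 1:
                fixed.append(v)
            else:
                stochastic.append((v, f))
        if len(stochastic) > 14:
            raise ConfigError(
                f"isolate {iso}: {len(stochastic)} segregating variants would "
                f"need {2 ** len(stochastic)} haplotypes")
        haps: list[tuple[str, Fraction]] = []
        for mask in itertools.product((False, True), repeat=len(stochastic)):
            weight = Fraction(1)
            chosen = list(fixed)
            for present, (v, f) in zip(mask, stochastic):
                weight *= f if present else (1 - f)
                if present:
                    chosen.append(v)
            if weight == 0:
                continue
            haps.append((_apply_variants(genome, chosen, dr_truth,
                                         dr_copies.get(iso, {})), weight))
        out[iso] = haps
    return out


def _apply_variants(genome: ReferenceGenome, snps: Sequence[PlantedVariant],
                    dr_truth: Sequence[DirectRepeatTruth],
                    copies_override: Mapping[str, int]) -> str:
    seq = list(genome.sequence)
    for v in snps:
        if len(v.ref_allele) != 1 or len(v.alt_allele) != 1:
            raise ConfigError("planted variants must be single-base substitutions")
        seq[v.position % len(seq)] = v.alt_allele
    # apply dr copy-number overrides right-to-left so coordinates stay valid
    for dr in sorted(dr_truth, key=lambda d: -d.start):
        new = copies_override.get(dr.dr_id)
        if new is None or new == dr.copies:
            continue
        if new < 0:
            raise ConfigError(f"{dr.dr_id}: negative copy number")
        seq[dr.start:dr.end] = list(dr.unit * new)
    return "".join(seq)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    quality: str
    isolate: str
    hap_index: int
    start: int
    strand: str
    template_length: int


def simulate_reads(
    haplotypes: Mapping[str, list[tuple[str, Fraction]]],
    config: SimulationConfig,
) -> dict[str, list[SimulatedRead]]:
    """Draw reads per isolate until mean coverage reaches ``config.depth``.

    Reads are sampled from haplotypes proportionally to their weights, start
    uniformly on the circle, and may span the origin (emitted as plain linear
    strings). Homopolymer ±1 indel errors occur with probability
    ``hp_indel_rate`` per traversed run of length >= 3; substitution errors
    with ``sub_error_rate`` per base. Qualities are a constant Q30
    placeholder. Fully reproducible from ``config.seed``.
    """
    config.validate()
    lo, hi = config.read_length_bounds
    out: dict[str, list[SimulatedRead]] = {}
    for iso, haps in haplotypes.items():
        rng = stage_rng(config.seed, _TAG_READS, _stable_int(iso))
        weights = np.array([float(w) for _, w in haps])
        weights = weights / weights.sum()
        length = len(haps[0][0])
        target = config.depth * length
        reads: list[SimulatedRead] = []
        total = 0
        i = 0
        while total < target:
            h = int(rng.choice(len(haps), p=weights))
            hap = haps[h][0]
            start = int(rng.integers(0, len(hap)))
            rl = 0
            while not lo <= rl <= hi:
                rl = int(round(rng.normal(config.read_length_mean,
                                          config.read_length_sd)))
            end = start + rl
            if end <= len(hap):
                seq = hap[start:end]
            else:
                seq = hap[start:] + hap[:end - len(hap)]
            seq = _apply_hp_errors(seq, rng, config.hp_indel_rate)
            seq = _apply_sub_errors(seq, rng, config.sub_error_rate)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = revcomp(seq)
            reads.append(SimulatedRead(
                read_id=f"{iso}_r{i:06d}", sequence=seq, quality="?" * len(seq),
                isolate=iso, hap_index=h, start=start, strand=strand,
                template_length=rl))
            total += rl
            i += 1
        out[iso] = reads
    return out


def _apply_hp_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    edits: list[tuple[int, int, int]] = []  # (run_start, run_end, delta)
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= 3 and rng.random() < rate:
            delta = 1 if rng.random() < 0.5 else -1
            edits.append((i, j, delta))
        i = j
    for a, b, delta in reversed(edits):
        run = seq[a:b]
        seq = seq[:a] + run[0] * (len(run) + delta) + seq[b:]
    return seq


def _apply_sub_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for p in positions:
        alts = [b for b in _BASES if b != chars[p]]
        chars[p] = alts[rng.integers(0, 3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_fastq(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def write_read_truth(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tisolate\thap_index\tstart\tstrand\ttemplate_length\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.isolate}\t{r.hap_index}\t{r.start}\t"
                     f"{r.strand}\t{r.template_length}\n")


def write_dr_truth(dr_truth: Sequence[DirectRepeatTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("dr_id\tstart\tend\tunit\tcopies\n")
        for d in dr_truth:
            fh.write(f"{d.dr_id}\t{d.start}\t{d.end}\t{d.unit}\t{d.copies}\n")


def choose_clean_sites(toy: ToyGenome, n_sites: int,
                       rng: np.random.Generator, min_gap: int = 10) -> list[int]:
    """Positions suitable for planting SNPs: outside direct-repeat arrays
    (masked at calling time) and clear of homopolymer runs (where the 454
    error model is indel-dominated), pairwise at least ``min_gap`` apart."""
    genome = toy.genome
    n = len(genome)
    excluded: set[int] = set()
    for d in toy.dr_truth:
        excluded.update(range(d.start, d.end))
    for a, b, _base in toy.hp_truth:
        excluded.update(p % n for p in range(a - 1, b + 1))
    sites: list[int] = []
    attempts = 0
    while len(sites) < n_sites:
        attempts += 1
        if attempts > 10000:
            raise ConfigError(f"could not place {n_sites} clean SNP sites")
        pos = int(rng.integers(0, n))
        if pos in excluded or any(abs(pos - s) < min_gap for s in sites):
            continue
        sites.append(pos)
    return sites
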