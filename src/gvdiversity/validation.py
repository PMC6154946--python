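"""Seeded self-check experiments on synthetic data.

Because the original read sets of the study system were never deposited,
the pipeline's correctness is demonstrated property-style: every experiment
here builds synthetic inputs with known truth, runs the ordinary pipeline
code paths, and measures agreement. The same functions back the test suite
and the ``scripts/acceptance.py`` report.

All experiments are deterministic given their seed.
"""

from __future__ import annotations

import math
from fractions import Fraction
import numpy as np

from .effects import (EFFECT_NON_SYNONYMOUS, classify_all, classify_variant,
                      effect_oracle)
from .diversity import category_summary, gene_diversity
from .genome_model import ReferenceGenome, find_homopolymer_runs
from .mapping import Pileup, build_pileup, map_reads
from .repeats import find_direct_repeats, locate_indels
from .synth import (PlantedVariant, SimulationConfig, build_isolate_haplotypes,
                    generate_toy_genome, simulate_reads, stage_rng)
from .variants import (FILTER_PASS, VariantCall, call_isolate_variants,
                       call_variants_from_pileup, correct_homopolymers)

_TAG_VALIDATION = 77


def _pass_snp(position: int, ref: str, alt: str) -> VariantCall:
    return VariantCall(position=position, ref_allele=ref, alt_allele=alt,
                       kind="SNP", support=10, depth=100, scope="isolate:v",
                       filters={FILTER_PASS})


# ---------------------------------------------------------------------------
# effect-annotation parity against the translation oracle
# ---------------------------------------------------------------------------

def oracle_parity_experiment(seed: int, n_draws: int = 1000,
                             overlap_draws: int = 100) -> dict:
    """Random (ORF, offset, alt) draws on a toy genome: the codon-level
    classifier must agree with the whole-ORF translation oracle in every
    determinate case. ``overlap_draws`` of the draws are forced inside the
    overlapping-ORF pair, where codons differ per gene."""
    toy = generate_toy_genome(SimulationConfig(seed=seed))
    genome = toy.genome
    anns = {a.gene_id: a for a in toy.annotations}
    ga, gb = toy.overlap_gene_ids
    ov_lo, ov_hi = anns[gb].start, anns[ga].end
    rng = stage_rng(seed, _TAG_VALIDATION, 1)

    n_records = n_agree = n_overlap = 0
    for i in range(n_draws):
        if i < overlap_draws:
            pos = int(rng.integers(ov_lo, ov_hi))
            n_overlap += 1
        else:
            ann = toy.annotations[int(rng.integers(0, len(toy.annotations)))]
            pos = int(rng.integers(ann.start, ann.end))
        ref = genome.sequence[pos]
        alt = "ACGT"[int(rng.integers(0, 4))]
        while alt == ref:
            alt = "ACGT"[int(rng.integers(0, 4))]
        records = classify_variant(_pass_snp(pos, ref, alt),
                                   toy.annotations, genome)
        for rec in records:
            ann = anns[rec.gene_id]
            offset = ann.offset_of(pos, len(genome))
            if ann.strand == "-":
                offset = ann.length - 1 - offset
            expected = effect_oracle(ann.coding_sequence(genome), offset,
                                     alt if ann.strand == "+" else
                                     alt.translate(str.maketrans("ACGT", "TGCA")))
            n_records += 1
            n_agree += (rec.effect == expected)
    return {
        "n_draws": n_draws,
        "n_overlap_draws": n_overlap,
        "n_determinate_records": n_records,
        "n_agree": n_agree,
        "parity_pct": 100.0 * n_agree / n_records if n_records else 0.0,
    }


# ---------------------------------------------------------------------------
# threshold semantics battery
# ---------------------------------------------------------------------------

def threshold_battery() -> dict:
    """A support x frequency grid around the calling thresholds: PASS must
    equal (support >= 5 and freq >= 1%) per isolate and (support >= 3 and
    freq >= 1%) pooled, exactly."""
    genome = ReferenceGenome(id="battery", sequence="A" * 64, circular=False)
    cells = []
    pile = Pileup(genome)
    pos = 0
    for support in (4, 5, 6):
        for f_target in (0.009, 0.010, 0.011):
            depth = round(support / f_target)
            col = pile.column(pos)
            col.base_counts["G"] = support
            col.base_counts["A"] = depth - support
            cells.append((pos, support, depth))
            pos += 1
    results = {"n_cells": 0, "n_agree_isolate": 0, "n_agree_pooled": 0}
    iso = {c.position: c for c in call_variants_from_pileup(pile, 5, 0.01)}
    pooled = {c.position: c for c in call_variants_from_pileup(pile, 3, 0.01)}
    for pos, support, depth in cells:
        freq = support / depth
        results["n_cells"] += 1
        expect_iso = support >= 5 and freq >= 0.01
        expect_pool = support >= 3 and freq >= 0.01
        results["n_agree_isolate"] += (iso[pos].is_pass == expect_iso)
        results["n_agree_pooled"] += (pooled[pos].is_pass == expect_pool)
    results["agreement_pct"] = 100.0 * (
        results["n_agree_isolate"] + results["n_agree_pooled"]
    ) / (2 * results["n_cells"])
    return results


# ---------------------------------------------------------------------------
# metapopulation pooling behavior
# ---------------------------------------------------------------------------

def _single_site_pileup(genome: ReferenceGenome, pos: int, alt: str,
                        support: int, depth: int) -> Pileup:
    pile = Pileup(genome)
    col = pile.column(pos)
    col.base_counts[alt] = support
    col.base_counts[col.ref_base] = depth - support
    return pile


def pooling_fixture() -> dict:
    """The two canonical pooling outcomes.

    Cumulative gain: an allele at 4/300 in each of two isolates fails the
    5-read rule per isolate but passes pooled (8/600 = 1.33%, >= 3 reads).
    Dilution: an allele at 6/100 in one isolate passes there but, pooled
    over 2000 reads of depth, drops to 0.3% and fails the frequency rule.
    """
    genome = ReferenceGenome(id="pool", sequence="ACGT" * 100, circular=False)
    pos = 50
    ref = genome.sequence[pos]
    alt = "A" if ref != "A" else "G"

    iso_a = _single_site_pileup(genome, pos, alt, 4, 300)
    iso_b = _single_site_pileup(genome, pos, alt, 4, 300)
    pooled = _single_site_pileup(genome, pos, alt, 8, 600)
    a_calls = call_isolate_variants(iso_a, isolate_id="A")
    b_calls = call_isolate_variants(iso_b, isolate_id="B")
    pooled_calls = call_variants_from_pileup(pooled, 3, 0.01,
                                             scope="metapopulation")
    gain = {
        "isolate_pass": any(c.is_pass for c in a_calls + b_calls),
        "isolate_flag": sorted(a_calls[0].filters),
        "pooled_pass": any(c.is_pass for c in pooled_calls),
        "pooled_frequency_pct": 100.0 * pooled_calls[0].frequency,
    }

    iso_c = _single_site_pileup(genome, pos, alt, 6, 100)
    diluted = _single_site_pileup(genome, pos, alt, 6, 2000)
    c_calls = call_isolate_variants(iso_c, isolate_id="C")
    dil_calls = call_variants_from_pileup(diluted, 3, 0.01,
                                          scope="metapopulation")
    dilution = {
        "isolate_pass": any(c.is_pass for c in c_calls),
        "pooled_pass": any(c.is_pass for c in dil_calls),
        "pooled_flag": sorted(dil_calls[0].filters),
        "pooled_frequency_pct": 100.0 * dil_calls[0].frequency,
    }
    return {"cumulative_gain": gain, "dilution": dilution}


# ---------------------------------------------------------------------------
# planted-variant recovery through the full read pipeline
# ---------------------------------------------------------------------------

PLANTED_FREQUENCIES = (Fraction(1, 50), Fraction(1, 20),
                       Fraction(1, 10), Fraction(1, 2))


def _choose_sites(toy, mask, rng, per_freq: int = 2) -> list[PlantedVariant]:
    """Planted SNP sites: outside the tandem-repeat mask and clear of
    homopolymer runs (the local error model there is indel-dominated), at
    least 10 bp apart."""
    genome = toy.genome
    n = len(genome)
    excluded = set()
    for a, b in mask:
        excluded.update(p % n for p in range(a, b))
    for a, b, _base in find_homopolymer_runs(genome, min_len=3):
        excluded.update(p % n for p in range(a - 1, b + 1))
    sites: list[int] = []
    variants: list[PlantedVariant] = []
    freqs = [f for f in PLANTED_FREQUENCIES for _ in range(per_freq)]
    while len(variants) < len(freqs):
        pos = int(rng.integers(0, n))
        if pos in excluded or any(abs(pos - s) < 10 for s in sites):
            continue
        ref = genome.sequence[pos]
        alt = "ACGT"[int(rng.integers(0, 4))]
        while alt == ref:
            alt = "ACGT"[int(rng.integers(0, 4))]
        sites.append(pos)
        variants.append(PlantedVariant(pos, ref, alt,
                                       {"iso1": freqs[len(variants)]}))
    return variants


def recovery_experiment(seed: int, n_sims: int = 20) -> dict:
    """Full-pipeline recovery of planted SNPs at 2/5/10/50% frequency under
    the default simulation conditions (10 kb genome, 100x coverage, 2%
    homopolymer indel rate).

    Recall is measured over variants whose expected support (frequency x
    nominal coverage) reaches the 5-read calling threshold. False PASS SNPs
    are counted at unplanted sites; indel artifacts surviving homopolymer
    correction are tallied separately. Frequency accuracy uses the binomial
    sampling band 3*sqrt(f(1-f)/depth).
    """
    eligible = recalled = 0
    per_freq_counts: dict[str, list[int]] = {}
    false_snps = false_indels = 0
    freq_checked = freq_within = 0
    for sim in range(n_sims):
        cfg = SimulationConfig(seed=int(stage_rng(seed, _TAG_VALIDATION, 2, sim)
                                        .integers(0, 2**31 - 1)))
        toy = generate_toy_genome(cfg)
        genome = toy.genome
        mask = [(d.start, d.end) for d in find_direct_repeats(genome)]
        rng = stage_rng(cfg.seed, _TAG_VALIDATION, 3)
        planted = _choose_sites(toy, mask, rng)
        haps = build_isolate_haplotypes(genome, planted)
        reads = simulate_reads(haps, cfg)["iso1"]
        alignments = map_reads(reads, genome)
        pileup = build_pileup(alignments, genome)
        runs = find_homopolymer_runs(genome)
        corrected = correct_homopolymers(pileup, runs)
        calls = call_isolate_variants(corrected, mask=mask, isolate_id="iso1",
                                      homopolymer_runs=runs)
        pass_snps = {(c.position, c.alt_allele): c
                     for c in calls if c.kind == "SNP" and c.is_pass}
        planted_keys = {(v.position, v.alt_allele): v for v in planted}
        for (pos, alt), v in planted_keys.items():
            f = float(v.frequency("iso1"))
            label = f"{f:.2f}"
            hit = (pos, alt) in pass_snps
            per_freq_counts.setdefault(label, [0, 0])
            per_freq_counts[label][1] += 1
            per_freq_counts[label][0] += hit
            if f * cfg.depth >= 5:
                eligible += 1
                recalled += hit
            if hit:
                call = pass_snps[(pos, alt)]
                bound = 3 * math.sqrt(f * (1 - f) / call.depth)
                freq_checked += 1
                freq_within += (abs(call.frequency - f) <= bound)
        for key, c in pass_snps.items():
            if key not in planted_keys:
                false_snps += 1
        false_indels += sum(1 for c in calls
                            if c.kind != "SNP" and c.is_pass)
    return {
        "n_sims": n_sims,
        "n_eligible": eligible,
        "recall_pct": 100.0 * recalled / eligible if eligible else 0.0,
        "per_frequency_recall": {
            k: {"recalled": v[0], "planted": v[1]}
            for k, v in sorted(per_freq_counts.items())},
        "false_pass_snps": false_snps,
        "false_pass_indels": false_indels,
        "freq_within_bound_pct":
            100.0 * freq_within / freq_checked if freq_checked else 0.0,
        "n_freq_checked": freq_checked,
    }


# ---------------------------------------------------------------------------
# homopolymer correction fixture
# ---------------------------------------------------------------------------

def homopolymer_correction_fixture() -> dict:
    """Noise at 0.7% inside a run >= 3 must vanish; a genuine 3% indel in
    the same run must survive correction and reach a PASS call; an
    identical low signal outside any run must stay untouched."""
    seq = ("ACGTCG" * 10) + "AAAA" + ("CGTGCA" * 10) + "AAAA" + ("GTACGT" * 10)
    genome = ReferenceGenome(id="hp", sequence=seq, circular=False)
    runs = find_homopolymer_runs(genome, min_len=3)
    run1, run2 = runs[0], runs[1]
    outside_pos = 5
    pile = Pileup(genome)
    for pos, dels in ((run1[0] + 1, 2), (run2[0] + 1, 9), (outside_pos, 2)):
        col = pile.column(pos)
        col.base_counts[col.ref_base] = 300 - dels
        col.del_count = dels
    corrected = correct_homopolymers(pile, runs)
    noise_col = corrected.get(run1[0] + 1)
    real_col = corrected.get(run2[0] + 1)
    out_col = corrected.get(outside_pos)
    calls = call_variants_from_pileup(corrected, 5, 0.01)
    surviving = [c for c in calls if c.kind == "deletion" and c.is_pass]
    return {
        "noise_removed": noise_col.del_count == 0,
        "noise_depth_conserved": noise_col.depth == 300,
        "real_retained": real_col.del_count == 9,
        "outside_untouched": out_col.del_count == 2,
        "real_called_pass": any(c.position == run2[0] + 1 for c in surviving),
    }


# ---------------------------------------------------------------------------
# direct-repeat indel recovery
# ---------------------------------------------------------------------------

DR_INDEL_SIZES = (12, 18, 46, 88)


def dr_indel_experiment(seed: int) -> dict:
    """Copy-number changes engineered to produce 12-, 18-, 46- and 88-bp
    deletions, each expected at the exact left-aligned array start with the
    containing dr annotated."""
    toy = generate_toy_genome(SimulationConfig(seed=seed))
    genome = toy.genome
    by_unit = {len(d.unit): d for d in toy.dr_truth}
    plan = {  # unit length -> units removed
        6: 2,    # 12 bp
        9: 2,    # 18 bp
        23: 2,   # 46 bp
        8: 11,   # 88 bp
    }
    copies = {by_unit[u].dr_id: by_unit[u].copies - k for u, k in plan.items()}
    haps = build_isolate_haplotypes(genome, [], toy.dr_truth,
                                    {"isoB": copies}, isolates=["isoB"])
    other = ReferenceGenome(id="isoB", sequence=haps["isoB"][0][0])
    drs = find_direct_repeats(genome)
    events = locate_indels(genome, other, drs)
    deletions = {e.length: e for e in events if e.kind == "deletion"}
    expected = {u * k: by_unit[u] for u, k in plan.items()}
    n_exact = 0
    details = {}
    for size, truth in expected.items():
        e = deletions.get(size)
        ok = (e is not None and e.ref_start == truth.start
              and e.in_dr is not None)
        n_exact += ok
        details[str(size)] = {
            "found": e is not None,
            "left_aligned_start": e.ref_start if e else None,
            "expected_start": truth.start,
            "in_dr": e.in_dr if e else None,
        }
    return {"n_sizes": len(expected), "n_recovered_exact": n_exact,
            "recovery_pct": 100.0 * n_exact / len(expected),
            "details": details}


# ---------------------------------------------------------------------------
# per-gene diversity ratio recovery
# ---------------------------------------------------------------------------

# Planted per-bp NSS rates. The ratio (2:1) is the quantity under test; the
# absolute rates are set high enough that, over 20 simulations of 16 genes,
# the binomial sampling error of the recovered ratio (~5%) sits well inside
# the 15% acceptance band (a >= 3 sigma margin by design).
CORE_NSS_RATE = 0.012       # NSS per bp planted in core genes
NONCORE_NSS_RATE = 0.024    # non-core genes get twice the core rate


def diversity_ratio_experiment(seed: int, n_sims: int = 20) -> dict:
    """Plant non-synonymous SNPs at a 2:1 non-core:core per-bp rate and
    check that unweighted category means recover the ratio.

    Counts are binomial per gene; positions and alleles are random, with
    the allele chosen non-synonymous via the translation oracle. Per-gene
    NSS/bp x10^3 is also checked against exact rational recomputation.
    """
    core_means = []
    noncore_means = []
    arithmetic_exact = True
    for sim in range(n_sims):
        sub = int(stage_rng(seed, _TAG_VALIDATION, 4, sim).integers(0, 2**31 - 1))
        cfg = SimulationConfig(seed=sub, genome_length=12_000, n_orfs=16,
                               overlap_pair=False, core_fraction=0.5)
        toy = generate_toy_genome(cfg)
        genome = toy.genome
        rng = stage_rng(sub, _TAG_VALIDATION, 5)
        if not any(a.is_core for a in toy.annotations) or \
           all(a.is_core for a in toy.annotations):
            continue  # degenerate draw; extremely rare with 12 genes
        variants = []
        for ann in toy.annotations:
            rate = CORE_NSS_RATE if ann.is_core else NONCORE_NSS_RATE
            n_nss = int(rng.binomial(ann.length, rate))
            chosen: set[int] = set()
            cds = ann.coding_sequence(genome)
            while len(chosen) < n_nss:
                off = int(rng.integers(0, ann.length))
                if off in chosen:
                    continue
                ref = cds[off]
                alts = [b for b in "ACGT" if b != ref]
                rng.shuffle(alts)
                pick = next((b for b in alts
                             if effect_oracle(cds, off, b) ==
                             EFFECT_NON_SYNONYMOUS), None)
                if pick is None:
                    continue  # fourfold-degenerate site; draw another
                chosen.add(off)
                pos = ann.start + off  # toy ORFs are all '+' strand
                variants.append(_pass_snp(pos, genome.sequence[pos], pick))
        effects = classify_all(variants, toy.annotations, genome)
        genes = gene_diversity(effects, toy.annotations)
        for s in genes:
            if s.nss_per_bp_e3 != float(Fraction(s.nss_count * 1000, s.length)):
                arithmetic_exact = False
        summary = category_summary(genes)
        core_means.append(summary["core"]["mean_nss_per_bp_e3"])
        noncore_means.append(summary["non_core"]["mean_nss_per_bp_e3"])
    core = float(np.mean(core_means))
    noncore = float(np.mean(noncore_means))
    return {
        "n_sims": len(core_means),
        "core_mean_nss_per_bp_e3": core,
        "noncore_mean_nss_per_bp_e3": noncore,
        "ratio": noncore / core,
        "planted_ratio": NONCORE_NSS_RATE / CORE_NSS_RATE,
        "arithmetic_exact": arithmetic_exact,
    }
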