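"""End-to-end orchestration: per-isolate and metapopulation analyses.

A :class:`PipelineConfig` names the reference, the ORF annotations, and the
per-isolate read sets (FASTQ or externally aligned SAM), plus every numeric
threshold of the analysis. :func:`run_isolate` reproduces the per-isolate
workflow — map, pile up, homopolymer-correct, call at 5 reads / 1%, mask
tandem repeats, classify effects, per-gene NSS/bp — and
:func:`run_metapopulation` the pooled workflow: build a majority consensus
from the pooled reads, remap everything against it, and call at the pooled
3 reads / 1% thresholds. All intermediates are plain standard formats
(SAM, VCF, BED, TSV, FASTA) so any stage can be re-run or swapped out.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from . import __version__
from .errors import ConfigError
from .diversity import (category_summary, gene_diversity, pearson,
                        summaries_to_frame, write_gene_table)
from .effects import ann_info_strings, classify_all, effects_to_tsv, snp_level_summary
from .genome_model import (ReferenceGenome, find_homopolymer_runs,
                           load_annotations, load_reference, write_reference)
from .mapping import (MappingStats, build_pileup, consensus_from_pileup,
                      ingest_sam, map_reads, write_sam)
from .repeats import find_direct_repeats
from .variants import (call_isolate_variants, call_pooled_variants,
                       classify_region, correct_homopolymers, load_mask_bed,
                       write_mask_bed, write_vcf)

logger = logging.getLogger("gvdiversity")


@dataclass
class IsolateInput:
    isolate_id: str
    fastq: str | None = None
    sam: str | None = None


@dataclass
class Thresholds:
    isolate_min_support: int = 5
    isolate_min_freq: float = 0.01
    pooled_min_support: int = 3
    pooled_min_freq: float = 0.01
    hp_min_reads: int = 3
    hp_min_freq: float = 0.01
    consensus_min_depth: int = 5
    indel_min_report: int = 10
    orf_min_len: int = 150
    min_identity: float = 0.90

    def validate(self) -> None:
        for name, v in self.__dict__.items():
            if v is None or (isinstance(v, (int, float)) and v <= 0):
                raise ConfigError(f"threshold {name} must be positive, got {v}")


@dataclass
class PipelineConfig:
    reference: str
    annotations: str
    isolates: list[IsolateInput]
    thresholds: Thresholds = field(default_factory=Thresholds)
    mask_bed: str | None = None
    seed: int = 0
    outdir: str = "gvdiversity_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            isolates = [IsolateInput(isolate_id=i["id"], fastq=i.get("fastq"),
                                     sam=i.get("sam"))
                        for i in raw["isolates"]]
            cfg = cls(reference=raw["reference"], annotations=raw["annotations"],
                      isolates=isolates,
                      thresholds=Thresholds(**raw.get("thresholds", {})),
                      mask_bed=raw.get("mask_bed"),
                      seed=int(raw.get("seed", 0)),
                      outdir=raw.get("outdir", "gvdiversity_out"))
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.thresholds.validate()
        ids = [i.isolate_id for i in self.isolates]
        if len(ids) != len(set(ids)):
            raise ConfigError("isolate ids must be unique")
        for i in self.isolates:
            if not (i.fastq or i.sam):
                raise ConfigError(f"isolate {i.isolate_id}: needs fastq or sam")
        for p in [self.reference, self.annotations,
                  *(i.fastq or i.sam for i in self.isolates)]:
            if not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")


def _load_shared(config: PipelineConfig):
    genome = load_reference(config.reference)
    annotations = load_annotations(config.annotations, genome,
                                   min_len=config.thresholds.orf_min_len)
    if config.mask_bed:
        mask = load_mask_bed(config.mask_bed)
    else:
        mask = [(d.start, d.end) for d in find_direct_repeats(genome)]
    return genome, annotations, mask


def _alignments_for(iso: IsolateInput, genome: ReferenceGenome,
                    thresholds: Thresholds, stats: MappingStats):
    if iso.sam:
        return ingest_sam(iso.sam, genome)
    reads = list(SeqIO.parse(iso.fastq, "fastq"))
    return map_reads(reads, genome, min_identity=thresholds.min_identity,
                     stats=stats)


def run_isolate(config: PipelineConfig, isolate_id: str) -> dict:
    """Per-isolate report: VCF + effects TSV + per-gene diversity TSV +
    SNP tallies. Returns the report dictionary (also written as JSON)."""
    matches = [i for i in config.isolates if i.isolate_id == isolate_id]
    if not matches:
        raise ConfigError(f"isolate {isolate_id!r} not in config")
    iso = matches[0]
    genome, annotations, mask = _load_shared(config)
    outdir = Path(config.outdir) / isolate_id
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds

    stats = MappingStats()
    alignments = _alignments_for(iso, genome, th, stats)
    logger.info("%s: %d alignments (%d unmapped, %d ambiguous)", isolate_id,
                len(alignments), stats.unmapped, stats.ambiguous)
    write_sam(alignments, genome, outdir / "alignments.sam")

    pileup = build_pileup(alignments, genome)
    runs = find_homopolymer_runs(genome)
    corrected = correct_homopolymers(pileup, runs, min_freq=th.hp_min_freq,
                                     min_reads=th.hp_min_reads)
    calls = call_isolate_variants(corrected, min_support=th.isolate_min_support,
                                  min_freq=th.isolate_min_freq, mask=mask,
                                  isolate_id=isolate_id,
                                  homopolymer_runs=runs)
    classify_region(calls, annotations, len(genome))
    effects = classify_all(calls, annotations, genome)
    summary = snp_level_summary(effects, calls)
    genes = gene_diversity(effects, annotations, scope=f"isolate:{isolate_id}")

    write_vcf(calls, genome, outdir / "variants.vcf",
              info_extra=ann_info_strings(effects))
    effects_to_tsv(effects, outdir / "effects.tsv")
    write_gene_table(genes, outdir / "gene_diversity.tsv")
    write_mask_bed(mask, genome.id, outdir / "mask.bed")
    corrected.write_tsv(outdir / "pileup.tsv")

    pct_syn, pct_nonsyn, pct_noncoding = summary.percentages()
    n_pass_snps = sum(1 for c in calls if c.kind == "SNP" and c.is_pass)
    n_pass_indels = sum(1 for c in calls if c.kind != "SNP" and c.is_pass)
    mean_cov = (sum(len(a.query) for a in alignments) / len(genome)
                if alignments else 0.0)
    report = {
        "isolate": isolate_id,
        "version": __version__,
        "seed": config.seed,
        "n_reads_mapped": len(alignments),
        "n_reads_unmapped": stats.unmapped,
        "mean_coverage": round(mean_cov, 3),
        "total_snps": n_pass_snps,
        "total_indels": n_pass_indels,
        "pct_synonymous": round(pct_syn, 2),
        "pct_non_synonymous": round(pct_nonsyn, 2),
        "pct_non_coding": round(pct_noncoding, 2),
        "thresholds": th.__dict__,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   sort_keys=True) + "\n")
    return report


def run_metapopulation(config: PipelineConfig) -> dict:
    """Pooled analysis: consensus FASTA + pooled VCF + combined per-gene
    diversity + correlation diagnostics."""
    if len(config.isolates) < 2:
        raise ConfigError(
            "metapopulation pooling needs at least 2 isolates; a single "
            "isolate is just the per-isolate analysis")
    genome, annotations, mask = _load_shared(config)
    outdir = Path(config.outdir) / "metapopulation"
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds

    # first pass: map everything to the reference and build the consensus
    read_sets: dict[str, list] = {}
    per_isolate_counts: dict[str, dict] = {}
    all_alignments = []
    for iso in config.isolates:
        stats = MappingStats()
        alignments = _alignments_for(iso, genome, th, stats)
        all_alignments.extend(alignments)
        if iso.sam:
            reads = [_AlignedAsRead(a) for a in alignments]
        else:
            reads = list(SeqIO.parse(iso.fastq, "fastq"))
        read_sets[iso.isolate_id] = reads
        per_isolate_counts[iso.isolate_id] = {
            "coverage": sum(len(a.query) for a in alignments) / len(genome)}
    pooled_pileup = build_pileup(all_alignments, genome)
    consensus = consensus_from_pileup(pooled_pileup, genome,
                                      min_depth=th.consensus_min_depth)
    write_reference(consensus, outdir / "consensus.fasta")

    # second pass: remap pooled reads against the consensus and call
    stats = MappingStats()
    calls, corrected = call_pooled_variants(
        read_sets, consensus, min_support=th.pooled_min_support,
        min_freq=th.pooled_min_freq, mask=mask, hp_min_reads=th.hp_min_reads,
        hp_min_freq=th.hp_min_freq,
        mapper_kwargs={"min_identity": th.min_identity}, stats=stats)
    if len(consensus) == len(genome):
        ann_for_effects = annotations
    else:
        logger.warning("consensus length %d differs from reference %d; "
                       "annotation coordinates kept on the reference frame",
                       len(consensus), len(genome))
        ann_for_effects = annotations
    classify_region(calls, ann_for_effects, len(consensus))
    effects = classify_all(calls, ann_for_effects, consensus)
    summary = snp_level_summary(effects, calls)
    genes = gene_diversity(effects, ann_for_effects, scope="metapopulation")

    write_vcf(calls, consensus, outdir / "pooled.vcf",
              info_extra=ann_info_strings(effects))
    write_gene_table(genes, outdir / "gene_diversity.tsv")
    effects_to_tsv(effects, outdir / "effects.tsv")

    # per-isolate SNP counts for the coverage correlation
    for iso in config.isolates:
        rep = run_isolate(config, iso.isolate_id)
        per_isolate_counts[iso.isolate_id]["snps"] = rep["total_snps"]

    correlations = {}
    iso_ids = sorted(per_isolate_counts)
    snps = [per_isolate_counts[i]["snps"] for i in iso_ids]
    cov = [per_isolate_counts[i]["coverage"] for i in iso_ids]
    correlations["snps_vs_coverage"] = _corr_or_none(
        cov, snps, "mean_coverage", "n_snps")
    df = summaries_to_frame(genes)
    correlations["nss_per_bp_vs_length"] = _corr_or_none(
        df["length"].tolist(), df["nss_per_bp_e3"].tolist(),
        "orf_length_bp", "nss_per_bp_e3")

    pct_syn, pct_nonsyn, pct_noncoding = summary.percentages()
    n_pass_snps = sum(1 for c in calls if c.kind == "SNP" and c.is_pass)
    report = {
        "version": __version__,
        "seed": config.seed,
        "n_isolates": len(config.isolates),
        "consensus_length": len(consensus),
        "total_snps": n_pass_snps,
        "total_substitutions_all_regions": n_pass_snps,
        "pct_synonymous": round(pct_syn, 2),
        "pct_non_synonymous": round(pct_nonsyn, 2),
        "pct_non_coding": round(pct_noncoding, 2),
        "category_summary": category_summary(genes),
        "correlations": correlations,
        "per_isolate": per_isolate_counts,
        "thresholds": th.__dict__,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   sort_keys=True) + "\n")
    return report


def _corr_or_none(x, y, xl, yl):
    from .errors import UndefinedCorrelationError
    try:
        rep = pearson(x, y, xl, yl)
        return {"x": xl, "y": yl, "n": rep.n, "r": round(rep.r, 4)}
    except UndefinedCorrelationError as exc:
        return {"x": xl, "y": yl, "n": len(x), "r": None, "note": str(exc)}


class _AlignedAsRead:
    """Adapter: re-map reads extracted from external alignments."""

    def __init__(self, aln):
        self.read_id = aln.read_id
        self.sequence = aln.query
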