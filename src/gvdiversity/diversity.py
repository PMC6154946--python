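"""Per-gene diversity statistics: NSS/bp, category and core/non-core means.

The diversity statistic is deliberately simple: the number of
non-synonymous substitutions (NSS) observed in a gene divided by the gene's
length, reported x10^-3 per bp. It is not dN/dS — no site-opportunity
normalization is applied — which matches how compact dsDNA virus isolate
studies usually report per-gene variability. Genes with zero NSS are kept
in every table: invariable genes are findings, not missing data.

Category summaries are unweighted arithmetic means over genes (each gene
one dot, regardless of length); a length-weighted alternative is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedCorrelationError
from .effects import EFFECT_NON_SYNONYMOUS, EffectRecord
from .genome_model import OrfAnnotation

HIGH_DIVERSITY_THRESHOLD_E3 = 15.0  # "highly diverse" flag, x10^-3 NSS/bp


@dataclass(frozen=True)
class GeneDiversitySummary:
    gene_id: str
    name: str
    length: int
    nss_count: int
    category: str
    is_core: bool

    @property
    def nss_per_bp_e3(self) -> float:
        # single division of exact integers: correctly-rounded, so the value
        # matches rational recomputation bit-for-bit
        return self.nss_count * 1e3 / self.length

    @property
    def highly_diverse(self) -> bool:
        return self.nss_per_bp_e3 > HIGH_DIVERSITY_THRESHOLD_E3


@dataclass(frozen=True)
class CorrelationReport:
    x_label: str
    y_label: str
    n: int
    r: float


def gene_diversity(effects_by_variant: Mapping[tuple, list[EffectRecord]],
                   annotations: Sequence[OrfAnnotation],
                   scope: str = "") -> list[GeneDiversitySummary]:
    """Per-gene NSS counts over one scope (an isolate or the metapopulation).

    A SNP contributes 1 to each gene in which one of its effect records is
    non-synonymous — each gene counts its own view of an overlap site, so
    the per-gene total may exceed the number of distinct non-synonymous
    SNPs. Every annotated gene appears, zeros included.
    """
    per_gene: dict[str, set] = {a.gene_id: set() for a in annotations}
    for key, records in effects_by_variant.items():
        for rec in records:
            if rec.effect == EFFECT_NON_SYNONYMOUS and rec.gene_id in per_gene:
                per_gene[rec.gene_id].add(key)
    return [GeneDiversitySummary(
        gene_id=a.gene_id, name=a.name, length=a.length,
        nss_count=len(per_gene[a.gene_id]), category=a.category,
        is_core=a.is_core) for a in annotations]


def summaries_to_frame(summaries: Sequence[GeneDiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": [s.gene_id for s in summaries],
        "name": [s.name for s in summaries],
        "length": [s.length for s in summaries],
        "nss_count": [s.nss_count for s in summaries],
        "nss_per_bp_e3": [s.nss_per_bp_e3 for s in summaries],
        "category": [s.category for s in summaries],
        "is_core": [s.is_core for s in summaries],
        "highly_diverse": [s.highly_diverse for s in summaries],
    })


def write_gene_table(summaries: Sequence[GeneDiversitySummary], path) -> None:
    df = summaries_to_frame(summaries).copy()
    df["nss_per_bp_e3"] = df["nss_per_bp_e3"].round(2)
    df.to_csv(path, sep="\t", index=False)


def category_summary(summaries: Sequence[GeneDiversitySummary],
                     weight_by_length: bool = False) -> dict:
    """Mean NSS/bp x10^-3 per functional category plus core vs non-core.

    Unweighted arithmetic mean over genes by default; with
    ``weight_by_length`` the mean is total NSS over total length. Empty
    groups are omitted. Group sizes are reported alongside the means.
    """
    df = summaries_to_frame(summaries)

    def group_mean(sub: pd.DataFrame) -> float:
        if weight_by_length:
            return float(sub["nss_count"].sum() / sub["length"].sum() * 1e3)
        return float(sub["nss_per_bp_e3"].mean())

    categories = {}
    for cat, sub in df.groupby("category"):
        categories[cat] = {"mean_nss_per_bp_e3": group_mean(sub), "n_genes": len(sub)}
    core = df[df["is_core"]]
    noncore = df[~df["is_core"]]
    out = {"categories": categories, "weighted_by_length": weight_by_length}
    if len(core):
        out["core"] = {"mean_nss_per_bp_e3": group_mean(core), "n_genes": len(core)}
    if len(noncore):
        out["non_core"] = {"mean_nss_per_bp_e3": group_mean(noncore),
                           "n_genes": len(noncore)}
    return out


def pearson(x: Sequence[float], y: Sequence[float],
            x_label: str = "x", y_label: str = "y") -> CorrelationReport:
    """Product-moment correlation; degenerate input (n < 2 or zero
    variance) raises instead of silently returning 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise UndefinedCorrelationError("x and y have different lengths")
    if len(x) < 2:
        raise UndefinedCorrelationError(f"need n >= 2 points, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the variables")
    r, _p = sps.pearsonr(x, y)
    return CorrelationReport(x_label=x_label, y_label=y_label, n=len(x),
                             r=float(r))
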