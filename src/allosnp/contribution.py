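"""Per-gene aggregation: category counts and subgenome expression contribution.

At each homoeoSNP the tetraploid's reads split between the two
homoeoalleles, so the read fraction carrying the G2 allele estimates the G2
subgenome's share of that transcript.  Averaging over a gene's homoeoSNPs
gives the gene-level homoeolog expression bias.  The default average is the
unweighted mean of per-site ratios, which keeps one ultra-deep site from
dominating; a pooled-depth mean (total G2 reads over total reads) is
available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd

from .classifier import ClassifiedSnp, SnpCategory
from .io import GeneModel
from .regions import RegionSet, restrict, total_positions

RatioMode = Literal["unweighted", "pooled"]

INTERGENIC = "(intergenic)"

CATEGORY_ORDER = [
    SnpCategory.P1,
    SnpCategory.P2,
    SnpCategory.P3,
    SnpCategory.P4,
    SnpCategory.P3OR4,
    SnpCategory.P5,
    SnpCategory.OTHER,
]


@dataclass
class GeneSummary:
    gene_id: str
    counts: dict[SnpCategory, int] = field(default_factory=dict)
    mean_ratio_g2: Optional[float] = None
    n_p5_with_depth: int = 0
    covered_positions: int = 0
    snp_per_covered_kb: Optional[float] = None

    def n_classified(self) -> int:
        return sum(self.counts.values())


def site_ratio(snp: ClassifiedSnp) -> Optional[float]:
    """G2 fraction of tetraploid reads at a homoeoSNP; None elsewhere.

    Defined only for category-5 sites carrying both homoeoallele depths.
    """
    if snp.category != SnpCategory.P5:
        return None
    if snp.depth_g1 is None or snp.depth_g2 is None:
        return None
    total = snp.depth_g1 + snp.depth_g2
    if total == 0:
        warnings.warn(f"{snp.contig}:{snp.pos}: homoeoSNP with zero depth on both alleles")
        return None
    return snp.depth_g2 / total


def _assign_genes(
    snps: Iterable[ClassifiedSnp], genes: list[GeneModel]
) -> dict[str, list[ClassifiedSnp]]:
    """Map each SNP to the first gene (by coordinate) containing it."""
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for models in by_contig.values():
        models.sort(key=lambda m: (m.start, m.end, m.gene_id))
        for prev, nxt in zip(models, models[1:]):
            if nxt.start <= prev.end:
                warnings.warn(
                    f"overlapping gene models {prev.gene_id} and {nxt.gene_id} on "
                    f"{prev.contig}; first by coordinate wins"
                )

    assigned: dict[str, list[ClassifiedSnp]] = {}
    for snp in snps:
        hit = INTERGENIC
        for g in by_contig.get(snp.contig, []):
            if g.start <= snp.pos <= g.end:
                hit = g.gene_id
                break
            if g.start > snp.pos:
                break
        assigned.setdefault(hit, []).append(snp)
    return assigned


def _summarize_one(
    gene_id: str,
    snps: list[ClassifiedSnp],
    covered: int,
    ratio_mode: RatioMode,
) -> GeneSummary:
    counts = {c: 0 for c in CATEGORY_ORDER}
    ratios: list[float] = []
    pooled_g2 = pooled_total = 0
    for snp in snps:
        counts[snp.category] = counts.get(snp.category, 0) + 1
        r = site_ratio(snp)
        if r is not None:
            ratios.append(r)
            pooled_g2 += snp.depth_g2  # type: ignore[operator]
            pooled_total += snp.depth_g1 + snp.depth_g2  # type: ignore[operator]
    mean_ratio: Optional[float] = None
    if ratios:
        if ratio_mode == "pooled":
            mean_ratio = pooled_g2 / pooled_total
        else:
            mean_ratio = sum(ratios) / len(ratios)
    per_kb = 1000 * len(snps) / covered if covered > 0 else None
    return GeneSummary(
        gene_id=gene_id,
        counts=counts,
        mean_ratio_g2=mean_ratio,
        n_p5_with_depth=len(ratios),
        covered_positions=covered,
        snp_per_covered_kb=per_kb,
    )


def summarize_genes(
    snps: list[ClassifiedSnp],
    common: RegionSet,
    genes: Optional[list[GeneModel]] = None,
    ratio_mode: RatioMode = "unweighted",
) -> list[GeneSummary]:
    """Aggregate classified SNPs per gene.

    With ``genes=None`` (transcriptome mode) each reference sequence is one
    gene; with gene models (genome mode) SNPs outside every model fall into
    an ``(intergenic)`` bin.  ``covered_positions`` is the number of
    analyzable positions (common coverage) inside each gene, and
    ``snp_per_covered_kb`` normalizes the SNP count by it.
    """
    summaries: list[GeneSummary] = []
    if genes is None:
        by_contig: dict[str, list[ClassifiedSnp]] = {}
        for snp in snps:
            by_contig.setdefault(snp.contig, []).append(snp)
        all_ids = sorted(set(by_contig) | set(common.intervals))
        for contig in all_ids:
            covered = total_positions(RegionSet({contig: common.intervals.get(contig, [])}))
            summaries.append(
                _summarize_one(contig, by_contig.get(contig, []), covered, ratio_mode)
            )
    else:
        assigned = _assign_genes(snps, genes)
        for g in sorted(genes, key=lambda m: m.gene_id):
            covered = total_positions(restrict(common, g.contig, g.start, g.end))
            summaries.append(
                _summarize_one(g.gene_id, assigned.get(g.gene_id, []), covered, ratio_mode)
            )
        if INTERGENIC in assigned:
            summaries.append(
                _summarize_one(INTERGENIC, assigned[INTERGENIC], 0, ratio_mode)
            )
    summaries.sort(key=lambda s: s.gene_id)
    return summaries


GENE_SUMMARY_COLUMNS = [
    "gene_id",
    "n_1",
    "n_2",
    "n_3",
    "n_4",
    "n_3or4",
    "n_5",
    "n_other",
    "n_p5_with_depth",
    "mean_ratio_g2",
    "covered_positions",
    "snp_per_covered_kb",
]


def write_gene_summaries(summaries: list[GeneSummary], path: str | Path) -> None:
    """Write the per-gene summary TSV (sorted by gene_id, fixed column order)."""
    rows = []
    for s in sorted(summaries, key=lambda x: x.gene_id):
        row: dict[str, object] = {"gene_id": s.gene_id}
        for cat in CATEGORY_ORDER:
            row[f"n_{cat.value}"] = s.counts.get(cat, 0)
        row["n_p5_with_depth"] = s.n_p5_with_depth
        row["mean_ratio_g2"] = "NA" if s.mean_ratio_g2 is None else f"{s.mean_ratio_g2:.6g}"
        row["covered_positions"] = s.covered_positions
        row["snp_per_covered_kb"] = (
            "NA" if s.snp_per_covered_kb is None else f"{s.snp_per_covered_kb:.6g}"
        )
        rows.append(row)
    pd.DataFrame(rows, columns=GENE_SUMMARY_COLUMNS).to_csv(path, sep="\t", index=False)
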