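"""Polyploid-versus-polyploid mode: shared and sample-specific SNPs.

Two samples called against the same reference are compared position by
position inside their common coverage.  "Shared" is split into
same-alleles and same-position-different-alleles; their sum is the shared
count in the coarse sense.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .classifier import ClassifyParams, _merge_by_position
from .genotyping import GenotypingError, absent_site_genotype, effective_genotype
from .io import SiteRecord
from .regions import RegionSet, contains, total_positions


@dataclass
class CompareCounts:
    shared_same_alleles: int = 0
    shared_position_different_alleles: int = 0
    specific_to_sample1: int = 0
    specific_to_sample2: int = 0

    def total_variant_positions(self) -> int:
        return (
            self.shared_same_alleles
            + self.shared_position_different_alleles
            + self.specific_to_sample1
            + self.specific_to_sample2
        )


@dataclass
class ComparisonReport:
    totals: CompareCounts = field(default_factory=CompareCounts)
    per_contig: dict[str, CompareCounts] = field(default_factory=dict)
    positions_compared: int = 0
    n_mono: int = 0  # union positions whose both genotypes collapse to reference


def compare_samples(
    sites1: Iterable[SiteRecord],
    sites2: Iterable[SiteRecord],
    common: RegionSet,
    params: Optional[ClassifyParams] = None,
) -> ComparisonReport:
    """Count shared and specific SNPs between two samples in common coverage.

    A sample "has" a variant at a position when its MAF-filtered allele set
    differs from homozygous-reference; a position carried by only one VCF is
    homozygous-reference in the other sample.  ``positions_compared`` is the
    total number of analyzable positions, for frequency normalization.
    """
    params = params or ClassifyParams()
    report = ComparisonReport(positions_compared=total_positions(common))

    for contig, pos, s1, s2 in _merge_by_position(sites1, sites2):
        if not contains(common, contig, pos):
            continue
        ref = (s1 or s2).ref_allele
        if s1 is not None and s2 is not None and s1.ref_allele != s2.ref_allele:
            raise ValueError(
                f"{contig}:{pos}: reference allele mismatch between samples "
                f"({s1.ref_allele} vs {s2.ref_allele}); were both samples "
                "called against the same reference?"
            )
        try:
            g1 = (
                effective_genotype(s1, params.maf_diploid)
                if s1 is not None
                else absent_site_genotype(ref)
            )
            g2 = (
                effective_genotype(s2, params.maf_tetraploid)
                if s2 is not None
                else absent_site_genotype(ref)
            )
        except GenotypingError:
            continue
        ref_only = frozenset({ref})
        v1, v2 = g1.alleles != ref_only, g2.alleles != ref_only
        counts = report.per_contig.setdefault(contig, CompareCounts())
        if v1 and v2:
            if g1.alleles == g2.alleles:
                counts.shared_same_alleles += 1
                report.totals.shared_same_alleles += 1
            else:
                counts.shared_position_different_alleles += 1
                report.totals.shared_position_different_alleles += 1
        elif v1:
            counts.specific_to_sample1 += 1
            report.totals.specific_to_sample1 += 1
        elif v2:
            counts.specific_to_sample2 += 1
            report.totals.specific_to_sample2 += 1
        else:
            report.n_mono += 1
    return report


COMPARISON_COLUMNS = [
    "contig",
    "shared_same_alleles",
    "shared_position_different_alleles",
    "specific_to_sample1",
    "specific_to_sample2",
    "positions_compared",
]


def write_comparison(report: ComparisonReport, path: str | Path) -> None:
    """Per-contig rows plus a global ``(all)`` row."""
    rows = []
    for contig in sorted(report.per_contig):
        c = report.per_contig[contig]
        rows.append(
            {
                "contig": contig,
                "shared_same_alleles": c.shared_same_alleles,
                "shared_position_different_alleles": c.shared_position_different_alleles,
                "specific_to_sample1": c.specific_to_sample1,
                "specific_to_sample2": c.specific_to_sample2,
                "positions_compared": "NA",
            }
        )
    t = report.totals
    rows.append(
        {
            "contig": "(all)",
            "shared_same_alleles": t.shared_same_alleles,
            "shared_position_different_alleles": t.shared_position_different_alleles,
            "specific_to_sample1": t.specific_to_sample1,
            "specific_to_sample2": t.specific_to_sample2,
            "positions_compared": report.positions_compared,
        }
    )
    pd.DataFrame(rows, columns=COMPARISON_COLUMNS).to_csv(path, sep="\t", index=False)
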