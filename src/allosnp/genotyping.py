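"""Turn raw VCF site records into effective allele observations.

A site's "effective genotype" is the set of alleles that survive the minor
allele frequency (MAF) filter applied to the allelic read depths.  Alleles
supported by a read fraction below ``maf_min`` are treated as sequencing
noise: they are dropped and their reads discarded, and if a single allele
remains the site is treated as homozygous for it.  When the VCF carries no
AD field the genotype call is trusted as-is (with empty depths, so the site
can be classified but contributes no depth ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .io import SiteRecord


class GenotypingError(RuntimeError):
    """Raised when no allele survives filtering (cannot happen for maf <= 0.5)."""


@dataclass(frozen=True)
class EffectiveGenotype:
    """Observed allele set at one site after noise filtering.

    ``depths`` maps each retained allele to its read count; it is empty when
    the source record carried no allelic depths.
    """

    alleles: frozenset[str]
    depths: Mapping[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.alleles)

    def total_depth(self) -> int:
        return sum(self.depths.values())


def effective_genotype(site: SiteRecord, maf_min: float) -> EffectiveGenotype:
    """Apply the MAF filter to one site's allelic depths.

    Alleles with zero reads are never retained (an unobserved allele cannot
    be called), so with ``maf_min == 0`` the result is exactly the alleles
    present in AD — or, when AD is absent, the alleles named by GT.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5], got {maf_min}")

    alleles_all = site.alleles()
    if site.allelic_depths is None or sum(site.allelic_depths) == 0:
        if site.gt is None:
            raise GenotypingError(
                f"{site.contig}:{site.pos}: no genotype call and no allelic depths"
            )
        called = frozenset(alleles_all[i] for i in site.gt)
        return EffectiveGenotype(called, {})

    depths = {a: int(d) for a, d in zip(alleles_all, site.allelic_depths) if d > 0}
    total = sum(depths.values())
    kept = {a: d for a, d in depths.items() if d / total >= maf_min}
    if not kept:
        raise GenotypingError(
            f"{site.contig}:{site.pos}: every allele is below maf_min={maf_min}"
        )
    return EffectiveGenotype(frozenset(kept), kept)


def absent_site_genotype(ref_allele: str) -> EffectiveGenotype:
    """Genotype for a covered position absent from a sample's VCF.

    Inside the common coverage region, a position with no VCF record for a
    sample means that sample is homozygous for the reference allele there
    (callers only emit non-reference calls).  Callers of this function must
    guarantee the coverage precondition.
    """
    return EffectiveGenotype(frozenset({ref_allele}), {})
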