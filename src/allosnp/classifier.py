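"""Assign evolutionary categories to variant positions in an allopolyploid.

The comparison involves three allele observations per position: the
sequenced diploid progenitor (its genome is called G1), the mapping
reference (which stands for the second parental genome, G2), and the
allotetraploid sample that combines both subgenomes.

Categories
----------
``1``      tetraploid fixed for the G1 allele at a site where the parents
           differ (interspecific SNP; the G2 copy was lost or replaced).
``2``      tetraploid fixed for the G2/reference allele at a site where the
           parents differ (interspecific SNP).
``5``      tetraploid shows both parental alleles where the parents differ:
           a homoeoSNP, the apparent heterozygosity of co-assembled
           homoeologs.  The non-reference allele resides on the G1
           subgenome, the reference allele on G2.
``3or4``   tetraploid carries a novel allele at a site where the parents
           agree: a mutation that arose in one subgenome after
           polyploidization.  Which subgenome is unknown until phasing
           links the site to a homoeoSNP (category ``3`` = on G1,
           ``4`` = on G2).
``mono``   no variation anywhere; counted but not listed.
``other``  configurations outside the model: diploid-heterozygous sites
           (intra-genome allelic variation), tetraploid alleles absent from
           both parents while the parents differ, or >2 observed alleles.

The numbering convention (1 = fixed for the G1 allele, 3 = post-polyploidy
mutation on G1) can be swapped with ``swap_labels`` for users who number the
parents the other way around; the ``origin`` field is unambiguous either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

from .genotyping import (
    EffectiveGenotype,
    GenotypingError,
    absent_site_genotype,
    effective_genotype,
)
from .io import SiteRecord
from .regions import RegionSet, contains

ORIGIN_G1 = "G1"
ORIGIN_G2 = "G2"
ORIGIN_UNKNOWN = "unknown"
ORIGIN_NA = "n/a"


class SnpCategory(str, Enum):
    P1 = "1"
    P2 = "2"
    P3 = "3"
    P4 = "4"
    P3OR4 = "3or4"
    P5 = "5"
    OTHER = "other"
    MONO = "mono"


class SortOrderError(ValueError):
    """An input stream was not sorted by (contig, pos)."""


class ClassificationContractError(ValueError):
    """An effective genotype with 0 or >2 alleles reached classify_site."""


@dataclass
class ClassifiedSnp:
    """One classified variant position.

    ``allele_g1``/``allele_g2`` name the two homoeoalleles at a homoeoSNP;
    ``novel_allele`` is the post-polyploidization mutation at 3/4/"3 or 4"
    sites.  ``depth_g1``/``depth_g2`` are tetraploid read counts for the two
    homoeoalleles (homoeoSNPs only) and ``ratio_g2`` is the G2 share of
    them — the per-site estimate of the G2 subgenome's contribution to the
    transcript pool.
    """

    contig: str
    pos: int
    ref_allele: str
    diploid: EffectiveGenotype
    tetraploid: EffectiveGenotype
    category: SnpCategory
    origin: str
    allele_g1: Optional[str] = None
    allele_g2: Optional[str] = None
    novel_allele: Optional[str] = None
    depth_g1: Optional[int] = None
    depth_g2: Optional[int] = None
    ratio_g2: Optional[float] = None
    phase_conflict: bool = False


@dataclass
class ClassifyParams:
    """Per-sample MAF thresholds applied before classification."""

    maf_diploid: float = 0.05
    maf_tetraploid: float = 0.05


@dataclass
class ClassificationResult:
    snps: list[ClassifiedSnp]
    n_mono: int = 0
    n_union_in_common: int = 0
    n_outside_common: int = 0
    n_unusable: int = 0  # sites with neither GT nor AD

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c.value: 0 for c in SnpCategory}
        counts[SnpCategory.MONO.value] = self.n_mono
        for snp in self.snps:
            counts[snp.category.value] += 1
        return counts


def _swap(category: SnpCategory, origin: str) -> tuple[SnpCategory, str]:
    cat_map = {SnpCategory.P1: SnpCategory.P2, SnpCategory.P2: SnpCategory.P1,
               SnpCategory.P3: SnpCategory.P4, SnpCategory.P4: SnpCategory.P3}
    org_map = {ORIGIN_G1: ORIGIN_G2, ORIGIN_G2: ORIGIN_G1}
    return cat_map.get(category, category), org_map.get(origin, origin)


def classify_site(
    diploid: EffectiveGenotype,
    tetraploid: EffectiveGenotype,
    ref_allele: str,
    swap_labels: bool = False,
) -> tuple[SnpCategory, str]:
    """Classify one position from the two effective genotypes and the reference base.

    Returns the category together with the subgenome origin of the variant
    allele (G1/G2 for categories 3, 4 and 5 — for homoeoSNPs the origin
    named is that of the non-reference homoeoallele, always G1 under this
    convention; "unknown" for unresolved "3 or 4"; "n/a" otherwise).
    """
    D, T = diploid.alleles, tetraploid.alleles
    if not (1 <= len(D) <= 2) or not (1 <= len(T) <= 2):
        raise ClassificationContractError(
            f"allele sets must have size 1 or 2 (got |D|={len(D)}, |T|={len(T)})"
        )
    R = ref_allele

    if len(D) == 2:
        # allelic variation within the diploid progenitor itself: outside the model
        result = SnpCategory.OTHER, ORIGIN_NA
    else:
        (x,) = D
        if x != R:  # parents differ at this site
            if T == {x}:
                result = SnpCategory.P1, ORIGIN_NA
            elif T == {R}:
                result = SnpCategory.P2, ORIGIN_NA
            elif T == {x, R}:
                result = SnpCategory.P5, ORIGIN_G1
            else:
                result = SnpCategory.OTHER, ORIGIN_NA
        else:  # parents agree: any tetraploid variation arose post-polyploidization
            if T == {R}:
                result = SnpCategory.MONO, ORIGIN_NA
            elif len(T) == 2 and R in T:
                result = SnpCategory.P3OR4, ORIGIN_UNKNOWN
            else:
                result = SnpCategory.OTHER, ORIGIN_NA
    return _swap(*result) if swap_labels else result


def _checked_stream(
    sites: Iterable[SiteRecord], label: str
) -> Iterator[SiteRecord]:
    last: Optional[tuple[str, int]] = None
    seen_contigs: set[str] = set()
    current: Optional[str] = None
    for site in sites:
        if current != site.contig:
            if site.contig in seen_contigs:
                raise SortOrderError(
                    f"{label}: contig {site.contig} revisited at {site.contig}:{site.pos}"
                )
            seen_contigs.add(site.contig)
            current = site.contig
            last = None
        if last is not None and site.pos <= last[1]:
            raise SortOrderError(
                f"{label}: unsorted input at {site.contig}:{site.pos} (after {last[1]})"
            )
        last = (site.contig, site.pos)
        yield site


def _merge_by_position(
    a: Iterable[SiteRecord], b: Iterable[SiteRecord]
) -> Iterator[tuple[str, int, Optional[SiteRecord], Optional[SiteRecord]]]:
    """Merge two (contig, pos)-sorted streams into per-position pairs.

    Contigs are compared lexicographically, matching the sort order of
    VCFs produced against the same reference index.
    """
    ia = iter(_checked_stream(a, "sample1"))
    ib = iter(_checked_stream(b, "sample2"))
    sa = next(ia, None)
    sb = next(ib, None)
    while sa is not None or sb is not None:
        if sb is None or (sa is not None and (sa.contig, sa.pos) < (sb.contig, sb.pos)):
            yield sa.contig, sa.pos, sa, None
            sa = next(ia, None)
        elif sa is None or (sb.contig, sb.pos) < (sa.contig, sa.pos):
            yield sb.contig, sb.pos, None, sb
            sb = next(ib, None)
        else:
            yield sa.contig, sa.pos, sa, sb
            sa = next(ia, None)
            sb = next(ib, None)


def _make_snp(
    contig: str,
    pos: int,
    ref: str,
    dip: EffectiveGenotype,
    tet: EffectiveGenotype,
    category: SnpCategory,
    origin: str,
) -> ClassifiedSnp:
    snp = ClassifiedSnp(contig, pos, ref, dip, tet, category, origin)
    if category == SnpCategory.P5:
        (x,) = dip.alleles
        snp.allele_g1, snp.allele_g2 = x, ref
        if tet.depths:
            snp.depth_g1 = tet.depths.get(x, 0)
            snp.depth_g2 = tet.depths.get(ref, 0)
            total = snp.depth_g1 + snp.depth_g2
            if total > 0:
                snp.ratio_g2 = snp.depth_g2 / total
    elif category in (SnpCategory.P3OR4, SnpCategory.P3, SnpCategory.P4):
        novel = tet.alleles - {ref}
        if len(novel) == 1:
            (snp.novel_allele,) = novel
    return snp


def classify_all(
    diploid_sites: Iterable[SiteRecord],
    tetra_sites: Iterable[SiteRecord],
    common: RegionSet,
    params: Optional[ClassifyParams] = None,
) -> ClassificationResult:
    """Classify the union of variant positions of both samples inside the common regions.

    A position carried by only one VCF uses the homozygous-reference
    genotype for the other sample (legitimate because both samples are
    adequately covered everywhere inside ``common``).  Monomorphic
    positions are counted but not listed.  Positions whose effective
    genotype has more than two alleles even after filtering are reported as
    ``other``.
    """
    params = params or ClassifyParams()
    result = ClassificationResult(snps=[])

    for contig, pos, dsite, tsite in _merge_by_position(diploid_sites, tetra_sites):
        if not contains(common, contig, pos):
            result.n_outside_common += 1
            continue
        ref = (dsite or tsite).ref_allele
        if dsite is not None and tsite is not None and dsite.ref_allele != tsite.ref_allele:
            raise ValueError(
                f"{contig}:{pos}: reference allele mismatch between samples "
                f"({dsite.ref_allele} vs {tsite.ref_allele}); were both samples "
                "called against the same reference?"
            )
        result.n_union_in_common += 1
        try:
            dip = (
                effective_genotype(dsite, params.maf_diploid)
                if dsite is not None
                else absent_site_genotype(ref)
            )
            tet = (
                effective_genotype(tsite, params.maf_tetraploid)
                if tsite is not None
                else absent_site_genotype(ref)
            )
        except GenotypingError:
            result.n_unusable += 1
            continue

        if len(dip) > 2 or len(tet) > 2:
            category, origin = SnpCategory.OTHER, ORIGIN_NA
        else:
            category, origin = classify_site(dip, tet, ref)

        if category == SnpCategory.MONO:
            result.n_mono += 1
            continue
        result.snps.append(_make_snp(contig, pos, ref, dip, tet, category, origin))

    return result
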