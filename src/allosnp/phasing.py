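"""Resolve "3 or 4" sites into 3 or 4 using haplotype blocks.

A post-polyploidization mutation produces an apparent heterozygous site in
the tetraploid whose subgenome of origin cannot be told from the site
alone.  But read-backed phasing links neighbouring heterozygous sites into
haplotype blocks, and any homoeoSNP in the same block is an anchor whose
two alleles have known subgenome origins.  Following the haplotype that
carries the novel allele to the anchors identifies the mutated subgenome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .classifier import (
    ORIGIN_G1,
    ORIGIN_G2,
    ClassifiedSnp,
    SnpCategory,
)
from .io import SiteRecord

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeBlock:
    """A run of consecutively phased heterozygous sites on one contig.

    ``haplotypes`` maps position -> (hap1 base, hap2 base); the pair order
    is haplotype-consistent across the whole block.
    """

    contig: str
    haplotypes: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def positions(self) -> list[int]:
        return list(self.haplotypes)


def build_blocks(tetra_sites: Iterable[SiteRecord]) -> list[HaplotypeBlock]:
    """Group consecutive phased heterozygous sites into haplotype blocks.

    An *unphased* heterozygous site terminates the current block (the
    phasing chain is broken there); homozygous or uncalled sites carry no
    phase information and are simply skipped.  Blocks with fewer than two
    sites are useless for linkage and are discarded.
    """
    blocks: list[HaplotypeBlock] = []
    current: Optional[HaplotypeBlock] = None
    current_contig: Optional[str] = None

    def close() -> None:
        nonlocal current
        if current is not None and len(current) >= 2:
            blocks.append(current)
        current = None

    for site in tetra_sites:
        if site.contig != current_contig:
            close()
            current_contig = site.contig
        if not site.is_het():
            continue
        if not site.phased:
            close()
            continue
        alleles = site.alleles()
        a, b = site.gt  # type: ignore[misc]
        if current is None:
            current = HaplotypeBlock(site.contig)
        current.haplotypes[site.pos] = (alleles[a], alleles[b])
    close()
    return blocks


@dataclass
class PhasingStats:
    n_resolved_p3: int = 0
    n_resolved_p4: int = 0
    n_conflicts: int = 0
    n_unphased: int = 0  # "3 or 4" sites with no usable anchor


def _hap1_is_g1(block: HaplotypeBlock, anchor: ClassifiedSnp) -> Optional[bool]:
    """Which haplotype of the block corresponds to the G1 subgenome, per one anchor."""
    haps = block.haplotypes.get(anchor.pos)
    if haps is None or anchor.allele_g1 is None or anchor.allele_g2 is None:
        return None
    if haps == (anchor.allele_g1, anchor.allele_g2):
        return True
    if haps == (anchor.allele_g2, anchor.allele_g1):
        return False
    warnings.warn(
        f"{anchor.contig}:{anchor.pos}: phased alleles {haps} are inconsistent "
        f"with homoeoSNP alleles ({anchor.allele_g1}, {anchor.allele_g2}); anchor skipped"
    )
    return None


def resolve_p3or4(
    snps: list[ClassifiedSnp],
    blocks: list[HaplotypeBlock],
    stats: Optional[PhasingStats] = None,
) -> list[ClassifiedSnp]:
    """Resolve "3 or 4" sites that share a haplotype block with a homoeoSNP anchor.

    Every homoeoSNP in the block votes on which haplotype is the G1
    subgenome; if the votes disagree the site stays "3 or 4" with its
    conflict flag set (conservative policy).  Sites in no block, or in
    blocks without anchors, are returned unchanged.  No category other
    than "3 or 4" is ever modified, so the operation is idempotent.
    """
    stats = stats if stats is not None else PhasingStats()
    by_block: dict[int, list[ClassifiedSnp]] = {}
    block_index: dict[tuple[str, int], int] = {
        (b.contig, pos): i for i, b in enumerate(blocks) for pos in b.haplotypes
    }
    for snp in snps:
        i = block_index.get((snp.contig, snp.pos))
        if i is not None:
            by_block.setdefault(i, []).append(snp)

    for i, members in by_block.items():
        block = blocks[i]
        votes = {
            v
            for anchor in members
            if anchor.category == SnpCategory.P5
            and (v := _hap1_is_g1(block, anchor)) is not None
        }
        targets = [s for s in members if s.category == SnpCategory.P3OR4]
        if not targets:
            continue
        if not votes:
            stats.n_unphased += len(targets)
            continue
        if len(votes) > 1:
            for snp in targets:
                snp.phase_conflict = True
            stats.n_conflicts += len(targets)
            continue
        (hap1_g1,) = votes
        for snp in targets:
            haps = block.haplotypes.get(snp.pos)
            if haps is None or snp.novel_allele is None:
                stats.n_unphased += 1
                continue
            if haps == (snp.novel_allele, snp.ref_allele):
                mutant_on_hap1 = True
            elif haps == (snp.ref_allele, snp.novel_allele):
                mutant_on_hap1 = False
            else:
                logger.warning(
                    "%s:%d: phased alleles %s do not match ref/novel pair; left unresolved",
                    snp.contig, snp.pos, haps,
                )
                stats.n_unphased += 1
                continue
            on_g1 = mutant_on_hap1 == hap1_g1
            snp.category = SnpCategory.P3 if on_g1 else SnpCategory.P4
            snp.origin = ORIGIN_G1 if on_g1 else ORIGIN_G2
            if on_g1:
                stats.n_resolved_p3 += 1
            else:
                stats.n_resolved_p4 += 1

    n_in_block = {id(s) for members in by_block.values() for s in members}
    stats.n_unphased += sum(
        1
        for s in snps
        if s.category == SnpCategory.P3OR4
        and not s.phase_conflict
        and id(s) not in n_in_block
    )
    return snps
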