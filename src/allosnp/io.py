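"""Readers and writers for the external formats the tool touches.

Variant sites arrive one VCF per sample (each sample is aligned and called
against the same diploid reference independently), coverage arrives as a
GATK DepthOfCoverage-style table (``contig:pos<TAB>total_depth``), and gene
models come from GFF3.  All coordinates are 1-based inclusive, following the
VCF and GFF conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

NUCLEOTIDES = frozenset("ACGT")

#: Sites with more than this many alternate alleles are skipped: with four
#: nucleotides a true SNP can show at most three alternates, so anything
#: beyond that is a representation we do not model.
MAX_ALTS = 3


class VcfFormatError(ValueError):
    """The VCF file could not be parsed."""


class DepthTableFormatError(ValueError):
    """A row of the per-position depth table is malformed."""


class GffFormatError(ValueError):
    """A GFF3 line is structurally invalid."""


@dataclass(frozen=True)
class SiteRecord:
    """One single-nucleotide VCF position for one sample.

    ``gt`` holds the pair of allele indices (0 = reference, k = k-th
    alternate) or ``None`` when the genotype is missing.  ``phased`` is True
    iff the genotype separator was the phased form (``|``).
    ``allelic_depths`` is aligned to ``[ref] + alts`` and is ``None`` when
    the AD field is absent.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    gt: Optional[tuple[int, int]]
    phased: bool
    allelic_depths: Optional[tuple[int, ...]]
    total_depth: int

    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele,) + self.alt_alleles

    def gt_alleles(self) -> Optional[tuple[str, str]]:
        if self.gt is None:
            return None
        alls = self.alleles()
        return (alls[self.gt[0]], alls[self.gt[1]])

    def is_het(self) -> bool:
        return self.gt is not None and self.gt[0] != self.gt[1]


@dataclass
class VcfReadStats:
    """Counters accumulated while streaming a VCF."""

    n_sites: int = 0
    n_skipped_non_snp: int = 0
    n_skipped_many_alts: int = 0


@dataclass
class DepthTrack:
    """Per-position total read depth on one reference sequence.

    Positions absent from the table have depth 0, so ``depth(pos)`` is total
    over all positive positions.
    """

    contig: str
    positions: np.ndarray  # sorted, 1-based
    depths: np.ndarray  # same length, >= 0

    def depth(self, pos: int) -> int:
        i = np.searchsorted(self.positions, pos)
        if i < len(self.positions) and self.positions[i] == pos:
            return int(self.depths[i])
        return 0

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


def read_vcf(
    path: str | Path,
    sample_name: Optional[str] = None,
    stats: Optional[VcfReadStats] = None,
) -> Iterator[SiteRecord]:
    """Stream single-nucleotide records from a single-sample VCF.

    Multi-nucleotide REF/ALT records (indels, MNPs) and sites with more than
    ``MAX_ALTS`` alternates are skipped and counted in ``stats``.  If
    ``sample_name`` is None the first sample column is used.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib reports parse failures as generic errors
        raise VcfFormatError(f"{path}: cannot parse VCF header ({exc})") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError(f"{path}: VCF has no sample column")
    if sample_name is None:
        idx = 0
    else:
        if sample_name not in samples:
            raise KeyError(f"{path}: sample {sample_name!r} not in header (has {samples})")
        idx = samples.index(sample_name)

    for v in vcf:
        ref = v.REF.upper()
        alts = tuple(a.upper() for a in v.ALT)
        if (
            len(ref) != 1
            or ref not in NUCLEOTIDES
            or any(len(a) != 1 or a not in NUCLEOTIDES for a in alts)
        ):
            if stats is not None:
                stats.n_skipped_non_snp += 1
            continue
        if len(alts) > MAX_ALTS:
            if stats is not None:
                stats.n_skipped_many_alts += 1
            continue

        g = v.genotypes[idx]
        phased = bool(g[-1])
        calls = [int(a) for a in g[:-1]]
        if len(calls) == 1:  # haploid call: duplicate
            calls = calls * 2
        gt: Optional[tuple[int, int]]
        if len(calls) != 2 or any(a < 0 for a in calls):
            gt = None
        else:
            gt = (calls[0], calls[1])

        ad_raw = v.format("AD")
        depths: Optional[tuple[int, ...]] = None
        if ad_raw is not None:
            row = ad_raw[idx]
            if not np.any(row < 0):
                depths = tuple(int(d) for d in row)

        dp_raw = v.format("DP")
        total = 0
        if dp_raw is not None and int(dp_raw[idx][0]) >= 0:
            total = int(dp_raw[idx][0])
        if depths is not None:
            total = max(total, sum(depths))

        if stats is not None:
            stats.n_sites += 1
        yield SiteRecord(
            contig=v.CHROM,
            pos=v.POS,
            ref_allele=ref,
            alt_alleles=alts,
            gt=gt,
            phased=phased,
            allelic_depths=depths,
            total_depth=total,
        )


def read_depth_table(path: str | Path) -> dict[str, DepthTrack]:
    """Parse a ``contig:pos<TAB>depth`` coverage table into per-contig tracks.

    A header row (locus token without ``:pos``) is tolerated in the first
    line only.  Extra columns beyond the second are ignored.  Duplicate loci
    keep the last value, with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, usecols=[0, 1], names=["locus", "depth"])
    if df.empty:
        return {}
    parts = df["locus"].str.rsplit(":", n=1, expand=True)
    if 1 not in parts.columns:  # no row contains ":" at all
        parts[1] = None
    bad = parts[1].isna() | ~parts[1].str.fullmatch(r"\d+", na=False)
    if bad.any():
        first_bad = int(np.flatnonzero(bad.to_numpy())[0])
        if first_bad == 0:
            # header row
            df = df.iloc[1:]
            parts = parts.iloc[1:]
            bad = bad.iloc[1:]
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
                raise DepthTableFormatError(f"{path}: row {row}: locus token lacks ':pos'")
        else:
            raise DepthTableFormatError(f"{path}: row {first_bad + 1}: locus token lacks ':pos'")
    if df.empty:
        return {}

    positions = parts[1].astype(np.int64).to_numpy()
    depths = pd.to_numeric(df["depth"], errors="raise").astype(np.int64).to_numpy()
    if (depths < 0).any():
        raise DepthTableFormatError(f"{path}: negative depth value")

    # single lexsort instead of per-contig masking: tables can run to
    # millions of rows over thousands of contigs
    codes, uniques = pd.factorize(parts[0])
    order = np.lexsort((positions, codes))
    codes, positions, depths = codes[order], positions[order], depths[order]
    dup = np.concatenate(
        [(codes[1:] == codes[:-1]) & (positions[1:] == positions[:-1]), [False]]
    )
    if dup.any():
        warnings.warn(f"{path}: duplicate loci; last value wins")
        keep = ~dup
        codes, positions, depths = codes[keep], positions[keep], depths[keep]

    tracks: dict[str, DepthTrack] = {}
    bounds = np.searchsorted(codes, np.arange(len(uniques) + 1))
    for i, contig in enumerate(uniques):
        lo, hi = bounds[i], bounds[i + 1]
        tracks[str(contig)] = DepthTrack(str(contig), positions[lo:hi], depths[lo:hi])
    return tracks


def read_gff(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Load gene models of one feature type from a GFF3 file.

    IDs are taken from the ``ID=`` attribute, falling back to ``Name=`` and
    then to a synthesized ordinal.  Output is sorted by (contig, start).
    """
    import gffutils

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            if len(stripped.split("\t")) < 9:
                raise GffFormatError(f"{path}: line {lineno}: expected 9 tab-separated columns")

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for n, feat in enumerate(db.features_of_type(feature_type), 1):
        ids = feat.attributes.get("ID") or feat.attributes.get("Name")
        gene_id = ids[0] if ids else f"{feature_type}_{n}"
        strand = feat.strand if feat.strand in {"+", "-"} else "."
        models.append(GeneModel(gene_id, feat.seqid, feat.start, feat.end, strand))
    models.sort(key=lambda m: (m.contig, m.start, m.end, m.gene_id))
    return models


CLASSIFIED_SNP_COLUMNS = [
    "contig",
    "pos",
    "ref",
    "diploid_gt",
    "tetraploid_gt",
    "category",
    "subgenome_origin",
    "depth_g1",
    "depth_g2",
    "ratio_g2",
]


def _fmt_genotype(alleles: frozenset[str]) -> str:
    ordered = sorted(alleles)
    if len(ordered) == 1:
        ordered = ordered * 2
    return "/".join(ordered)


def write_classified_snps(records: list, path: str | Path) -> None:
    """Write classified sites as TSV, sorted by (contig, pos).

    Undefined depths/ratios are emitted as ``NA`` (never 0).
    """
    rows = []
    for snp in sorted(records, key=lambda s: (s.contig, s.pos)):
        rows.append(
            {
                "contig": snp.contig,
                "pos": snp.pos,
                "ref": snp.ref_allele,
                "diploid_gt": _fmt_genotype(snp.diploid.alleles),
                "tetraploid_gt": _fmt_genotype(snp.tetraploid.alleles),
                "category": snp.category.value,
                "subgenome_origin": snp.origin,
                "depth_g1": "NA" if snp.depth_g1 is None else snp.depth_g1,
                "depth_g2": "NA" if snp.depth_g2 is None else snp.depth_g2,
                "ratio_g2": "NA" if snp.ratio_g2 is None else f"{snp.ratio_g2:.6g}",
            }
        )
    df = pd.DataFrame(rows, columns=CLASSIFIED_SNP_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_classified_snps(path: str | Path) -> list:
    """Read back a classified-SNP TSV into ``ClassifiedSnp`` records.

    Genotype depth mappings are not stored in the TSV, so the returned
    records carry depth-free effective genotypes plus the g1/g2 depths.
    """
    from .classifier import ClassifiedSnp, SnpCategory
    from .genotyping import EffectiveGenotype

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        dip = frozenset(row.diploid_gt.split("/"))
        tet = frozenset(row.tetraploid_gt.split("/"))
        category = SnpCategory(row.category)
        depth_g1 = None if row.depth_g1 == "NA" else int(row.depth_g1)
        depth_g2 = None if row.depth_g2 == "NA" else int(row.depth_g2)
        ratio = None if row.ratio_g2 == "NA" else float(row.ratio_g2)
        out.append(
            ClassifiedSnp(
                contig=row.contig,
                pos=int(row.pos),
                ref_allele=row.ref,
                diploid=EffectiveGenotype(dip, {}),
                tetraploid=EffectiveGenotype(tet, {}),
                category=category,
                origin=row.subgenome_origin,
                depth_g1=depth_g1,
                depth_g2=depth_g2,
                ratio_g2=ratio,
            )
        )
    return out
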