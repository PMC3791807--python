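"""Synthetic allopolyploid RNA-seq variant data with a known truth table.

The generative model mirrors the evolutionary setting the classifier
assumes.  A reference transcriptome (one contig per gene) plays the role of
the second parental genome G2.  The sequenced diploid progenitor's genome
G1 differs from it at a per-base divergence rate; at each divergent site
the tetraploid either retains both homoeoalleles (a homoeoSNP, category 5)
or is fixed for one parent's allele (categories 1/2).  After
polyploidization each subgenome accumulates additional mutations at its own
rate (categories 3/4).  Transcript reads at each tetraploid site are drawn
from the two subgenomes with a per-gene G2 bias, so homoeoSNP allelic
depths are binomial around that bias; sequencing noise redirects a fraction
of reads to random wrong bases.

What this emulates — and what it does not: allelic depths, homoeolog
expression bias, per-site Poisson depth variation, phasing, and base-call
noise are modelled; read mapping, mapping bias toward the reference parent,
paralogy, and intra-genome allelic variation in the progenitors are not.

Output files are standard formats (FASTA, VCF v4.2, GFF3, depth TSV) and
byte-identical for identical seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

_RATE_FIELDS = [
    "divergence_rate",
    "p5_fraction",
    "post_poly_rate_g1",
    "post_poly_rate_g2",
    "noise_rate",
    "phased_fraction",
]


@dataclass
class SimulationParams:
    """Knobs of the generative model.

    Defaults describe a recent allotetraploid sequenced at transcriptome
    depth: ~2% divergence between the parental genomes (closely related
    congeneric diploids), most divergent sites retained as homoeoSNPs,
    rare post-polyploidization mutations, 100x mean depth, and per-gene
    homoeolog expression bias anywhere in (0.1, 0.9).
    """

    n_genes: int = 50
    gene_length: int = 1000
    divergence_rate: float = 0.02
    #: fraction of divergent sites where the tetraploid keeps both
    #: homoeoalleles; the remainder is fixed for one parent (half each).
    p5_fraction: float = 0.8
    post_poly_rate_g1: float = 0.002
    post_poly_rate_g2: float = 0.002
    bias_low: float = 0.1
    bias_high: float = 0.9
    #: optional override: callable (rng, n_genes) -> per-gene G2 bias array
    bias_sampler: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None
    mean_depth: float = 100.0
    noise_rate: float = 0.005
    phased_fraction: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ValueError(f"mean_depth must be > 0, got {self.mean_depth}")
        if self.n_genes < 1 or self.gene_length < 1:
            raise ValueError("n_genes and gene_length must be >= 1")
        if not 0.0 < self.bias_low <= self.bias_high < 1.0:
            raise ValueError("bias bounds must satisfy 0 < low <= high < 1")


@dataclass
class SimulatedBundle:
    """Paths of one simulated dataset plus its truth table."""

    outdir: Path
    reference_fasta: Path
    diploid_vcf: Path
    diploid_depth: Path
    tetraploid_vcf: Path
    tetraploid_depth: Path
    gff: Path
    truth_tsv: Path
    truth: pd.DataFrame
    params: SimulationParams


def _other_base_indices(rng: np.random.Generator, base_idx: np.ndarray) -> np.ndarray:
    """Uniformly pick a base different from each entry of ``base_idx``."""
    return (base_idx + rng.integers(1, 4, size=base_idx.shape)) % 4


def _vcf_header(sample: str, contigs: list[tuple[str, int]]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=allosnp-simulate"]
    lines += [f"##contig=<ID={name},length={length}>" for name, length in contigs]
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    return "\n".join(lines) + "\n"


def _noisy_counts(
    rng: np.random.Generator, true_counts: dict[int, int], noise_rate: float
) -> np.ndarray:
    """Redistribute a fraction of reads to random wrong bases.

    ``true_counts`` maps base index -> reads truly carrying that base; the
    returned length-4 vector is the observed base-call counts.
    """
    observed = np.zeros(4, dtype=np.int64)
    for base in sorted(true_counts):
        c = true_counts[base]
        if c == 0:
            continue
        if noise_rate == 0.0:
            observed[base] += c
            continue
        errs = rng.binomial(c, noise_rate)
        observed[base] += c - errs
        if errs:
            others = [b for b in range(4) if b != base]
            observed[others] += rng.multinomial(errs, [1 / 3] * 3)
    return observed


def _format_record(
    contig: str,
    pos: int,
    ref_idx: int,
    true_alts: list[int],
    counts: np.ndarray,
    gt: str,
) -> Optional[str]:
    """One VCF data line; error alleles observed in the counts are appended
    to ALT after the true alternates.  Returns None if no alternate remains."""
    alts = list(true_alts)
    for b in range(4):
        if b != ref_idx and b not in alts and counts[b] > 0:
            alts.append(b)
    if not alts:
        return None
    ad = [int(counts[ref_idx])] + [int(counts[b]) for b in alts]
    dp = int(counts.sum())
    alt_str = ",".join(BASES[b] for b in alts)
    ad_str = ",".join(str(d) for d in ad)
    return (
        f"{contig}\t{pos}\t.\t{BASES[ref_idx]}\t{alt_str}\t.\t.\t.\t"
        f"GT:AD:DP\t{gt}:{ad_str}:{dp}\n"
    )


def simulate_dataset(params: SimulationParams, outdir: str | Path) -> SimulatedBundle:
    """Generate reference, per-sample VCFs and depth tables, GFF3 and truth table.

    The diploid sample is the G1 progenitor (homozygous for the G1 base
    everywhere); the tetraploid combines both subgenomes with per-gene
    expression bias.  VCFs list only non-reference calls, so positions
    monomorphic across all three genomes produce no records and no truth
    rows.  Heterozygous tetraploid sites are emitted phased (``a|b``, with
    haplotype 1 = G1 subgenome throughout) with probability
    ``phased_fraction``, else unphased ``0/1``.
    """
    params.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    L = params.gene_length

    width = max(5, len(str(params.n_genes)))
    contig_names = [f"gene{i + 1:0{width}d}" for i in range(params.n_genes)]
    contigs = [(name, L) for name in contig_names]

    if params.bias_sampler is not None:
        biases = np.asarray(params.bias_sampler(rng, params.n_genes), dtype=float)
    else:
        biases = rng.uniform(params.bias_low, params.bias_high, params.n_genes)
    if biases.shape != (params.n_genes,) or (biases <= 0).any() or (biases >= 1).any():
        raise ValueError("bias_sampler must return n_genes values strictly inside (0, 1)")

    paths = SimulatedBundle(
        outdir=outdir,
        reference_fasta=outdir / "reference.fasta",
        diploid_vcf=outdir / "diploid.vcf",
        diploid_depth=outdir / "diploid.depth.tsv",
        tetraploid_vcf=outdir / "tetraploid.vcf",
        tetraploid_depth=outdir / "tetraploid.depth.tsv",
        gff=outdir / "annotation.gff3",
        truth_tsv=outdir / "truth.tsv",
        truth=pd.DataFrame(),
        params=params,
    )

    truth_rows: list[tuple[str, int, str, str, float]] = []
    dip_depth_frames: list[pd.DataFrame] = []
    tet_depth_frames: list[pd.DataFrame] = []

    with open(paths.reference_fasta, "w") as fasta, open(
        paths.diploid_vcf, "w"
    ) as dvcf, open(paths.tetraploid_vcf, "w") as tvcf, open(paths.gff, "w") as gff:
        dvcf.write(_vcf_header("diploid", contigs))
        tvcf.write(_vcf_header("tetraploid", contigs))
        gff.write("##gff-version 3\n")

        for gi, contig in enumerate(contig_names):
            bias = float(biases[gi])
            ref_idx = rng.integers(0, 4, L)

            seq = "".join(BASES[ref_idx])
            fasta.write(f">{contig}\n")
            for start in range(0, L, 60):
                fasta.write(seq[start : start + 60] + "\n")
            gff.write(f"{contig}\t.\tgene\t1\t{L}\t.\t+\t.\tID={contig}\n")

            divergent = rng.random(L) < params.divergence_rate
            fate = rng.random(L)  # among divergent: homoeoSNP vs fixed-for-a-parent
            fixed_side = rng.random(L)
            post = rng.random(L)
            is_p5 = divergent & (fate < params.p5_fraction)
            is_p1 = divergent & ~is_p5 & (fixed_side < 0.5)
            is_p2 = divergent & ~is_p5 & (fixed_side >= 0.5)
            r1, r2 = params.post_poly_rate_g1, params.post_poly_rate_g2
            is_p3 = ~divergent & (post < r1)
            is_p4 = ~divergent & (post >= r1) & (post < r1 + r2)

            g1_idx = np.where(divergent, _other_base_indices(rng, ref_idx), ref_idx)
            novel_idx = np.where(is_p3 | is_p4, _other_base_indices(rng, ref_idx), -1)

            n_dip = rng.poisson(params.mean_depth, L)
            n_tet = rng.poisson(params.mean_depth, L)
            # reads sampled from the G2 subgenome at each tetraploid position
            k_g2 = rng.binomial(n_tet, bias)

            positions = np.arange(1, L + 1)
            dip_depth_frames.append(
                pd.DataFrame({"locus": [f"{contig}:{p}" for p in positions], "depth": n_dip})
            )
            tet_depth_frames.append(
                pd.DataFrame({"locus": [f"{contig}:{p}" for p in positions], "depth": n_tet})
            )

            variant_pos = np.flatnonzero(divergent | is_p3 | is_p4)
            phased_draw = rng.random(L) < params.phased_fraction

            for p in variant_pos:
                pos = int(p) + 1
                R = int(ref_idx[p])
                x = int(g1_idx[p])
                nd, nt, k = int(n_dip[p]), int(n_tet[p]), int(k_g2[p])

                if divergent[p]:
                    # the diploid progenitor is homozygous for its own base
                    dcounts = _noisy_counts(rng, {x: nd}, params.noise_rate)
                    line = _format_record(contig, pos, R, [x], dcounts, "1/1")
                    if line:
                        dvcf.write(line)

                if is_p1[p]:
                    tcounts = _noisy_counts(rng, {x: nt}, params.noise_rate)
                    line = _format_record(contig, pos, R, [x], tcounts, "1/1")
                    if line:
                        tvcf.write(line)
                    truth_rows.append((contig, pos, "1", "n/a", bias))
                elif is_p2[p]:
                    # tetraploid fixed for the reference parent's base: no record
                    truth_rows.append((contig, pos, "2", "n/a", bias))
                elif is_p5[p]:
                    # G2-subgenome reads carry the reference base, G1 reads carry x
                    tcounts = _noisy_counts(rng, {R: k, x: nt - k}, params.noise_rate)
                    gt = "1|0" if phased_draw[p] else "0/1"
                    line = _format_record(contig, pos, R, [x], tcounts, gt)
                    if line:
                        tvcf.write(line)
                    truth_rows.append((contig, pos, "5", "G1", bias))
                elif is_p3[p]:
                    y = int(novel_idx[p])
                    tcounts = _noisy_counts(rng, {R: k, y: nt - k}, params.noise_rate)
                    gt = "1|0" if phased_draw[p] else "0/1"
                    line = _format_record(contig, pos, R, [y], tcounts, gt)
                    if line:
                        tvcf.write(line)
                    truth_rows.append((contig, pos, "3", "G1", bias))
                elif is_p4[p]:
                    y = int(novel_idx[p])
                    tcounts = _noisy_counts(rng, {R: nt - k, y: k}, params.noise_rate)
                    gt = "0|1" if phased_draw[p] else "0/1"
                    line = _format_record(contig, pos, R, [y], tcounts, gt)
                    if line:
                        tvcf.write(line)
                    truth_rows.append((contig, pos, "4", "G2", bias))

    header = pd.DataFrame({"locus": ["Locus"], "depth": ["Total_Depth"]})
    for frames, path in (
        (dip_depth_frames, paths.diploid_depth),
        (tet_depth_frames, paths.tetraploid_depth),
    ):
        pd.concat([header] + frames, ignore_index=True).to_csv(
            path, sep="\t", index=False, header=False
        )

    truth = pd.DataFrame(
        truth_rows, columns=["contig", "pos", "category", "origin", "gene_bias"]
    )
    truth.to_csv(paths.truth_tsv, sep="\t", index=False)
    paths.truth = truth
    return paths
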