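import textwrap
from pathlib import Path

import pytest


def vcf_text(rows, sample="sample1", contigs=(("c1", 100000),)):
    """Build a minimal single-sample VCF from data-line strings or tuples.

    Tuple rows are (contig, pos, ref, alts, gt, ad, dp) with alts a list,
    ad a list or None, gt a string like ``0/1`` or ``1|0``.
    """
    header = ["##fileformat=VCFv4.2"]
    header += [f"##contig=<ID={c},length={ln}>" for c, ln in contigs]
    header += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    lines = []
    for row in rows:
        if isinstance(row, str):
            lines.append(row)
            continue
        contig, pos, ref, alts, gt, ad, dp = row
        fmt, vals = ["GT"], [gt]
        if ad is not None:
            fmt.append("AD")
            vals.append(",".join(str(d) for d in ad))
        if dp is not None:
            fmt.append("DP")
            vals.append(str(dp))
        alt_str = ",".join(alts) if alts else "."
        lines.append(
            f"{contig}\t{pos}\t.\t{ref}\t{alt_str}\t.\t.\t.\t"
            f"{':'.join(fmt)}\t{':'.join(vals)}"
        )
    return "\n".join(header + lines) + "\n"


def write_vcf(path: Path, rows, sample="sample1", contigs=(("c1", 100000),)):
    path.write_text(vcf_text(rows, sample=sample, contigs=contigs))
    return path


def write_depth(path: Path, depths_by_contig, header=True):
    """depths_by_contig: {contig: {pos: depth}} -> GATK-style locus table."""
    lines = ["Locus\tTotal_Depth"] if header else []
    for contig, depths in depths_by_contig.items():
        for pos in sorted(depths):
            lines.append(f"{contig}:{pos}\t{depths[pos]}")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def tiny_bundle(tmp_path):
    """Small deterministic simulated dataset shared by pipeline-level tests."""
    from allosnp.fixtures import SimulationParams, simulate_dataset

    params = SimulationParams(
        n_genes=5, gene_length=500, noise_rate=0.0, phased_fraction=1.0, seed=11
    )
    return simulate_dataset(params, tmp_path / "bundle")
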