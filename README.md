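# allosnp

SNP interpretation for allopolyploids from RNA-seq variant calls.

Allopolyploid species (coffee, wheat, cotton, peanut, ...) carry two
divergent parental subgenomes whose gene copies — homoeologs — co-assemble
when reads are mapped against a single diploid reference transcriptome.
Fixed differences between subgenomes then masquerade as heterozygous SNPs,
and standard diploid-oriented SNP pipelines cannot tell them from true
allelic variation. `allosnp` interprets the variants called in an
allotetraploid by comparing them with variants called in one of its
modern-day diploid progenitors, both mapped against the same reference
(which stands for the second parental genome). It is aimed at plant
genomicists analyzing homoeolog expression and polyploid genome evolution
from GATK-style VCF + depth-of-coverage outputs.

## The classification model

Write G1 for the sequenced diploid progenitor's genome and G2 for the
parental genome represented by the mapping reference. At each position
covered adequately in **both** samples, three observations meet: the
diploid's allele(s) *D*, the reference base *R*, and the tetraploid's
allele(s) *T* (allele sets are taken from allelic depths after a minor
allele frequency filter). The assigned category hypothesizes the
evolutionary path:

| D vs R | T | category | meaning |
|---|---|---|---|
| D = {x}, x ≠ R | {x} | 1 | interspecific SNP, tetraploid fixed for the G1 allele |
| D = {x}, x ≠ R | {R} | 2 | interspecific SNP, tetraploid fixed for the G2 allele |
| D = {x}, x ≠ R | {x, R} | 5 | homoeoSNP: both subgenome alleles co-assembled; x resides on G1, R on G2 |
| D = {R} | {R, y} | 3 or 4 | post-polyploidization mutation on an unknown subgenome |
| D = {R} | {R} | mono | no variation (counted, not listed) |
| anything else | — | other | outside the model (e.g. diploid-heterozygous site) |

Two downstream quantities follow:

* **Subgenome contribution.** At a homoeoSNP the tetraploid's reads split
  between the two homoeoalleles, so
  `ratio_g2 = AD(G2 allele) / (AD(G1 allele) + AD(G2 allele))`
  estimates the G2 subgenome's share of that transcript; the per-gene mean
  over homoeoSNPs estimates the gene's homoeolog expression bias.
* **3-vs-4 resolution.** When the tetraploid VCF carries phasing
  (`0|1`-style genotypes), each "3 or 4" site sharing a haplotype block
  with a homoeoSNP anchor is followed along its haplotype: if the novel
  allele rides the haplotype carrying G1 homoeoalleles the category is 3
  (mutation on G1), otherwise 4.

A second mode compares two polyploid samples directly and counts shared
and sample-specific SNPs inside their common coverage.

## Worked example

Simulate a small dataset (2 genes of 300 bp, no sequencing noise, fully
phased) and classify it:

```sh
allosnp simulate --out example --seed 7 --n-genes 2 --gene-length 300 \
    --noise-rate 0 --phased-fraction 1
allosnp classify \
    --vcf1 example/diploid.vcf    --depth1 example/diploid.depth.tsv \
    --vcf2 example/tetraploid.vcf --depth2 example/tetraploid.depth.tsv \
    --maf1 0 --maf2 0 --out example/out
```

`example/out/gene_summary.tsv` then reads:

```
gene_id	n_1	n_2	n_3	n_4	n_3or4	n_5	n_other	n_p5_with_depth	mean_ratio_g2	covered_positions	snp_per_covered_kb
gene00001	0	0	1	0	0	1	0	1	0.601942	300	6.66667
gene00002	0	1	0	1	0	3	0	3	0.766444	300	16.6667
```

gene00001 has one homoeoSNP and one post-polyploidization mutation that
phasing resolved to the G1 subgenome (`n_3 = 1`); about 60% of its
homoeoSNP reads carry the reference (G2) allele. gene00002 has three
homoeoSNPs averaging a 0.77 G2 share — a gene expressed mostly from its
G2 subgenome copy — plus one interspecific SNP fixed for the reference
allele and one mutation on G2. Per-site detail (alleles, depths, origins)
is in `classified_snps.tsv`, and `run_stats.json` holds the global
counters. With an annotation, `allosnp map-export` aggregates the same
numbers per gene and per genomic window for chromosome-scale overviews.

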