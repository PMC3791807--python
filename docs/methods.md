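# Methods

## Inputs and coordinate conventions

Each sample arrives as a single-sample VCF v4.x (genotype `GT`, allelic
depths `AD`, depth `DP`, optional phasing via the `|` separator) plus a
per-position coverage table of `contig:pos<TAB>total_depth` rows, the
layout produced by GATK DepthOfCoverage. Coordinates are 1-based inclusive
everywhere externally (VCF/GFF convention); BED export converts to 0-based
half-open. Contig names are matched by exact string equality across all
inputs — `chr1` and `1` are different sequences, and both samples must be
called against the same reference (a reference-base mismatch at a shared
position aborts the run rather than silently producing asymmetric counts).

Only single-nucleotide records are interpreted: indels and MNPs are
skipped and counted. Records with more than three alternates are likewise
skipped — with four nucleotides a true SNP admits at most three — which
keeps the classifier's case enumeration closed.

## Step 1: common coverage regions

For each sample, maximal runs of positions with depth ≥ `min_depth`
(per-sample threshold, CLI default 10×) become a set of disjoint,
non-adjacent intervals; the analysis is restricted to the intersection of
the two samples' sets. A variant well covered in only one sample is
therefore never interpreted: its state in the other sample would be a
guess. Interval sets are plain sorted tuples with bisect lookup and a
two-pointer intersection; depth tracks hold parallel position/depth
arrays, grouped per contig with one factorize + lexsort pass so
million-row tables over thousands of contigs parse in seconds.

## Step 2: effective genotypes

Allele frequencies at a site are computed from `AD`. Alleles below the
minor-allele-frequency floor `maf_min` (default 0.05) are treated as
sequencing noise: dropped, with their reads discarded; if one allele
remains the site is effectively homozygous. Zero-read alleles are never
retained, so `maf_min = 0` reproduces exactly the alleles with read
support. When `AD` is missing the `GT` call is trusted verbatim (the site
can be classified but yields no contribution ratio). A position inside the
common region but absent from a sample's VCF is homozygous-reference for
that sample, since callers emit only non-reference calls — this is what
makes the "tetraploid fixed for the reference parent's allele" category
observable at diploid-only variants.

## Step 3: classification

The decision table in the README is implemented directly and verified in
the tests against an independently written brute-force enumerator over all
400 (diploid set, tetraploid set, reference base) combinations. Two bins
absorb everything outside the evolutionary model rather than dropping it,
so position counts are conserved: `mono` (no variation; counted, not
listed) and `other` (diploid-heterozygous sites, tetraploid alleles absent
from both parents, >2 surviving alleles). Numbering is a convention —
category 1 is "fixed for the sequenced diploid's allele" and 3 is
"mutation on the diploid-side subgenome G1"; an analysis that numbers the
parents the other way can pass `swap_labels`, and the `origin` field
(G1/G2) is unambiguous regardless. At a homoeoSNP the reported origin is
that of the non-reference homoeoallele, which under this convention always
resides on G1.

## Phasing-based 3-vs-4 resolution

Haplotype blocks are runs of consecutively phased heterozygous sites on a
contig; an *unphased heterozygous* site breaks the chain. Homozygous or
uncalled sites carry no phase information and are skipped without closing
the block — read-backed phasers chain heterozygous sites across intervening
homozygous ones, and treating a fixed interspecific site as a block
boundary would needlessly orphan mutations from their anchors. Blocks of
one site are discarded.

Within a block, every homoeoSNP acts as an anchor voting on which
haplotype is the G1 subgenome (the haplotype carrying its G1 allele). All
anchors in the block are consulted; if they disagree the block's "3 or 4"
sites stay unresolved with a conflict flag (conservative: disagreement
means the phasing or the anchors are wrong, and a coin-flip assignment
would contaminate both the 3 and 4 bins). An anchor whose phased alleles
do not match its recorded homoeoallele pair is skipped with a warning.
Resolution only ever maps "3 or 4" to 3, 4, or itself; it is idempotent
and never touches other categories.

## Subgenome contribution

`ratio_g2` at a homoeoSNP is the G2-allele share of the two homoeoallele
depths, in [0, 1]; it is undefined (emitted as `NA`, never 0) when depths
are missing. The per-gene average is the unweighted mean of per-site
ratios: sites are noisy replicates of the same underlying transcript
mixture, and an unweighted mean keeps a single ultra-deep site from
dominating. A pooled-depth alternative (total G2 reads / total reads,
effectively depth-weighted) is available via `ratio_mode="pooled"`.
Per-gene output also reports category counts, the number of analyzable
positions in the gene (`covered_positions`), and SNPs per covered kb. In
transcriptome mode each reference sequence is a gene; in genome mode GFF
gene models partition positions, overlapping models resolve
first-by-coordinate with a warning, and unassigned SNPs fall into an
`(intergenic)` bin so the per-gene counts still sum to the global ones.

## Polyploid-versus-polyploid comparison

Within the common coverage of two samples, each union variant position is
counted as shared-with-identical-alleles, shared-position-with-different-
alleles, or specific to one sample (the other being effectively
homozygous-reference after MAF filtering). The two shared bins sum to
"shared" in the coarse sense; splitting them is strictly more informative.
`positions_compared` (the size of the common region) is reported for
frequency normalization.

## Synthetic data generator

The simulator emulates the assumed data-generating process, one contig per
gene: the reference **is** the G2 parent (no reference error); the G1
genome differs at rate `divergence_rate` per base; each divergent site is
a retained homoeoSNP with probability `p5_fraction`, else the tetraploid
is fixed for one parent (half each); each non-divergent site mutates
post-polyploidization on G1 or G2 at `post_poly_rate_g1/g2`. Per-site
depths are Poisson(`mean_depth`); tetraploid reads come from the G2
subgenome with per-gene probability drawn from Uniform(`bias_low`,
`bias_high`); each read miscalls to a uniformly random wrong base with
probability `noise_rate`; heterozygous tetraploid sites are phased
(haplotype 1 = G1 throughout) with probability `phased_fraction`.

Defaults — 50 genes × 1 kb, 2% divergence, 80% homoeoSNP retention, 0.2%
post-polyploidization rates per subgenome, 100× depth, 0.5% noise, 90%
phased — describe a recent allotetraploid of two closely related congeners
sequenced at transcriptome depth. Identical seeds give byte-identical
files.

Not emulated: read mapping and its bias toward the reference-side
subgenome (a mapping phenomenon upstream of this tool), paralogy,
allelic variation within the progenitors, and depth variation driven by
expression level beyond Poisson noise. Passing tests on simulated data
therefore validate the interpretation logic, not robustness to mapping
artifacts.

## Numerical and policy choices

* Zero-depth alleles are dropped before MAF filtering; an unobserved
  allele is never called.
* A site with neither `GT` nor `AD` is unusable and skipped with a
  counter.
* Undefined ratios and densities are `NA` in every TSV, never 0.
* `mono` positions are counted (they enter position totals) but not
  listed, so `len(snps) + n_mono` equals the union position count.
* Input streams must be position-sorted per contig; violations raise
  immediately, naming the first offending position.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; reruns are byte-identical.

## Problem sizes in the test suite

The truth-recovery check uses 50 genes × 1 kb (noise-free, fully phased —
with no sequencing noise the MAF filter is run at 0); bias recovery uses
200 genes at 100× with per-gene bias uniform on (0.1, 0.9), asserting ≥99%
of genes with ≥5 depth-bearing homoeoSNPs within 3 binomial standard
errors and a calibration slope in [0.95, 1.05]; the scale check simulates
~600k variant positions (2000 genes × 1.2 kb at 25% divergence) and
reports wall-clock without asserting it. Brute-force oracles (per-position
coverage filters, bitmask intersection, set-comparison SNP counting)
verify the interval and comparison machinery on randomized instances.

## Known limitations

Tetraploid genotypes are represented by their observed allele set, not a
four-copy dosage call: 2:2 versus 3:1 configurations are not
distinguished, matching the presence/absence logic of the categories.
Triallelic tetraploid sites and diploid-heterozygous sites are parked in
`other` rather than modelled. No statistical test accompanies the per-gene
bias estimate, and no cross-sample normalization is attempted. The tool
consumes phasing; it does not perform read-backed phasing itself.
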