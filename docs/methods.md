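# Methods

## The mapping model

The package analyses a pseudo-F2 mapping population for nontarget-site
herbicide resistance. The working model is a single dominant resistance
locus whose R haplotype also carries a cis-regulatory variant driving
overexpression of a physically linked block of genes. Two consequences are
exploited jointly:

* between plants, genes of the block are differentially expressed between
  resistant (R) and sensitive (S) cohorts, and those DEGs cluster
  physically on one scaffold;
* within a heterozygous plant, the R copy of each block gene is expressed
  more than the S copy, visible as allelic imbalance in RNA-seq read depths
  at SNPs inside the genes.

If the R haplotype multiplies a gene's per-copy expression by *f*, the
expected allelic ratio in a heterozygote is ρ = f/(1+f); the generator and
the tests treat this identity as an invariant, so the expression and ASE
stages must recover mutually consistent effects.

## Synthetic data generator

`synthetic_data.SimConfig` defaults define the simulated study:

| parameter | default | meaning |
|---|---|---|
| `n_scaffolds`, `scaffold_length_bp` | 16 × 20 Mb | genome anchoring the gene models |
| `genes_per_scaffold` | 400 | evenly spaced 2-kb genes (6,400 total) |
| `n_f2` | 100 | phenotyped F2 plants |
| `n_selected_per_category` | 4 | plants sequenced per joint R/S category (16 total, 8 R vs 8 S per herbicide) |
| `fold_change_f` | 3 | per-haplotype cis fold change ⇒ ρ = 0.75 |
| `n_cis_genes`, `cluster_span_bp` | 12, 3 Mb | cis-regulated block around the causal locus |
| `recomb_rate_cM_per_Mb` | 4 | Haldane map, r = ½(1 − e^(−2d)) |
| `nb_dispersion` | 0.02 | residual negative-binomial dispersion |
| `baseline_log_mean/sd` | log 300, 1.0 | log-normal baseline expression |
| `mean_depth` | 60 | mean allelic read depth at SNPs |
| `rating_noise_sd` | 1.0 | noise on the 1–10 damage rating |
| `seq_error_rate` | 0.002 | stray reads on the uncarried allele in homozygotes |

F1 parents are modelled as fully heterozygous along every scaffold; each F2
receives two independent gametes simulated as Markov walks over the gene
grid with Haldane recombination fractions. Resistance is dominant: carriers
rate ~9, non-carriers ~1 (10 = undamaged), with Gaussian noise, and the R/S
cutoff is ratings > 3 (a rating of exactly 3 is S; configurable). A second,
unlinked dominant locus drives the second herbicide trait so that
segregation independence is testable. Sample selection mirrors the
extreme-phenotype sequencing design: the four most extreme plants per joint
category; when a rare joint category (expected frequency 1/16) has fewer
than four plants, the shortfall is filled from plants matching the primary
herbicide label so the 8 R vs 8 S contrast is preserved.

Residual dispersion 0.02 (count CV ≈ 14% on top of Poisson noise) reflects
clonally propagated plants raised in a controlled greenhouse whose dominant
*genetic* expression variance is modelled explicitly through the haplotypes;
the baseline of ~300 median counts per gene corresponds to a typical
20–40 M-read library over ~6,000 expressed genes. Every SNP's alt allele
rides the R-parent haplotype; heterozygote depths are Poisson totals split
binomially at ρ for cis genes and ½ elsewhere.

What the generator does **not** emulate: mapping bias toward the reference
allele, overdispersed (beta-binomial) allelic counts, expression-dependent
SNP coverage heterogeneity beyond the genotype effect, multi-locus or
epistatic resistance, population structure, and isoform-level variation.
Passing tests therefore demonstrate correctness of the statistical chain
under a clean cis-regulation model, not robustness to those artefacts.

## Stage-specific choices

**Differential expression.** The default engine is deliberately simple —
Welch's t-test per gene on log2(CPM+1) — because the cluster/SNP/ASE chain,
not the DE engine, is the package's contribution; a per-gene p-value table
from any external engine (e.g. a bootstrap-based transcript-level model)
can be injected via `method="external"`. Effect sign is positive when
expression is higher in R. Genes with zero variance in both groups get
p = 1. DEGs are q ≤ 0.1 (boundary inclusive).

**Cluster detection.** Windows bin the raw 1-based gene start coordinate
tiling from 0 (a gene at bp 500,000 falls in the second 500-kb window).
N and K are genome-wide totals; BH is applied across all tested windows;
significant overlapping-or-adjacent windows merge, and reported cluster
bounds are the first/last member DEG coordinates, never window-grid
multiples. The hypergeometric tail is computed once here and reused by the
TFBS stage.

**SNP association.** Hard filters remove a record when any *present*
annotation violates its threshold; absent annotations never fail (variant
callers omit annotations for some sites). The clustered-SNP rule removes
every SNP in any run of ≥ 3 SNPs spanning ≤ 35 bp. The association
statistic is the two-sided Fisher exact p on allele counts (each genotyped
sample contributes two alleles); the permutation test permutes R/S labels
with group sizes fixed and reports emp_p = (b+1)/(T+1). Adaptive pruning
stops a SNP at checkpoints {50, 100, 200, 500} when the 95% Clopper–Pearson
interval for its empirical p excludes α. Because "corrected p" is ambiguous
across association toolchains, a SNP is called condition-specific only when
*both* the BH-adjusted exact p and the empirical p are ≤ α — a conservative,
reproducible conjunction, recorded in the run report.

**ASE.** "Shows expression of each allele" is operationalised as both
allele depths ≥ 2 (`min_allele_depth`). The R allele is assigned only when
homozygous R and homozygous S plants are unanimous and opposite; ambiguous
SNPs are reported as unclassified rather than dropped. The default test is
a paired two-sided t-test on raw (R, S) depth pairs — pairing uses the
natural within-individual coupling; a log-ratio variant is available
(`log_ratio=True`). SNPs with < 3 heterozygotes are excluded.

**TFBS.** PFMs become log2-odds matrices with pseudocount 0.8 split by a
uniform background; "90% score" means relative score ≥ 0.9 on the
(min, max)-normalised scale. Over-representation uses per-gene presence
(≥ 1 hit) of a motif in the promoter, the testable reading of
"matched and counted" at gene-set level.

**Relatedness.** IBS distance d(i,j) = mean |g_i − g_j|/2 over shared typed
loci substitutes for package-specific dissimilarities: the scientific claim
(plants sharing the R haplotype at a locus co-cluster) depends only on
genotype similarity there. UPGMA is implemented directly so ties break
deterministically on the lexicographically smallest member label; a
permutation-based group-significance step is replaced by cutting the tree
at a fixed fraction of its height (default 0.5). Because heterozygotes
carry both parental haplotypes, the recovery property asserted in tests is
that no cut group mixes an R-homozygote with an S-homozygote.

**Pipeline.** Overlap between the expression and variant evidence is
defined as a non-empty intersection of the FDR-significant hypergeometric
DEG windows with the 500-kb windows containing ≥ 1 condition-specific SNP;
both live on the same 500-kb-aligned grid, so overlap is plain interval
intersection (merged cluster calls, trimmed to DEG coordinates, are
reported separately). Reports are JSON with sorted keys; reruns with the
same seed are byte-identical.

## Numerical notes

* BH adjustment is a vectorised step-up (`q_(i) = min_{j≥i} min(1, m p_(j)/j)`),
  cross-checked against statsmodels in tests.
* The two-sided Fisher p is computed by hypergeometric point-probability
  summation with a 1 + 1e−7 relative tolerance on the "as extreme" rule
  (the same tail definition as the classical two-sided test) and cached on
  the table margins — the permutation stage reuses cached entries, which is
  what makes 1,000 permutations × hundreds of SNPs cheap. Values ≥ 1 − 1e−12
  are clamped to 1.
* Monomorphic or zero-margin tables get p = 1 by definition.
* UPGMA heights are exact pairwise averages; Newick branch lengths are
  parent-minus-child heights and must be non-negative (average linkage is
  monotone).

## Problem sizes in the test suite

Simulation-backed checks use: 200 replicates for planted-cluster recovery,
for relatedness separation, and for the full end-to-end pipeline; 2,000
null SNPs / 2,000 null genes for calibration; and pooled significant SNPs
from 10 datasets for the ASE ratio. The acceptance script uses 100/30/8
replicates for the same quantities.

## Known limitations

* At the default conditions (f = 3, dominant locus, 12 cis genes among
  6,400, 8 vs 8 samples), end-to-end cluster recovery has a measured
  ceiling near 90–95%: occasionally a single R-cohort plant recombines
  between the causal locus and the cis block, inflating the R-group
  variance of every block gene at once and collapsing the BH step-up
  cascade. This is a property of the genetics, not of the noise model — it
  persists as dispersion → 0.
* The Welch-t DE engine ignores count-level uncertainty; at very low
  counts a dedicated count model is more powerful.
* The ASE t-test on raw depths assumes roughly comparable total depth
  across heterozygotes; the log-ratio option is preferable when depths vary
  by orders of magnitude.
* PWM scanning assumes i.i.d. background; promoters with strong
  compositional bias will inflate hit rates for matching motifs.
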