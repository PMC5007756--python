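# Methods

This note documents the statistical models and procedures the package
implements, the defaults and why they were chosen, and what the synthetic
data can and cannot establish.

## Variant filter cascade

Inputs are per-site (ref, alt) read-count pairs for 8 pooled samples (two
morphs × four timepoints), carried separately for candidates from uniquely
(UNI) and multiply (REP) mapped reads. The cascade is order-fixed; each
site is flagged by the first stage it fails, so the funnel counts are
nested.

**Interspecific filter.** Remove a site iff the alternate-allele frequency
is ≥ `interspecific_min_freq` (default 0.90, tie included) in every sample
with coverage. A single intermediate-frequency sample rescues the site:
within-species polymorphism in any pool is evidence against a fixed
cross-species difference. Samples with zero coverage are skipped here —
they carry no frequency information — but they do count as low coverage in
the next stage.

**Coverage filter.** Remove iff, within either morph, at least
`low_cov_min_samples_per_morph` (default 3) of its samples have total
reads ≤ `low_cov_reads` (default 5). "Either morph" is the default reading
(a switch accepts "both"): a site unusable in one morph cannot support a
morph contrast.

**Homogeneity screen (paralog artifacts).** True SNPs sampled through
pools of ~6 individuals fluctuate between pools; a fixed difference
between co-mapping paralogs sits at the paralogs' expression share in
every sample. Default test: the minimum two-sided Fisher exact p over all
C(8,2) = 28 pairwise 2×2 (ref, alt) tables of covered samples, compared
to `homogeneity_alpha` (0.05) **without** multiple-testing correction;
sites *not* significant (min p ≥ α) are removed. Pairwise exact tests were
chosen because a 2×8 exact test is intractable in general; a single 2×k
chi-square mode is available via `homogeneity_mode="chisq"`. The min-p
screen is deliberately anti-conservative: with 28 correlated tests its
measured null retention is ≈ 0.43 (binomial read noise only, coverage
100), which errs toward keeping artifacts out of the *removed* class —
appropriate because removal here is permanent. Its discriminating power is
what matters: simulated artifacts are retained at ≈ 0.03–0.05 through the
full cascade versus ≈ 1.0 for truly differentiated SNPs.

**Morph comparison.** Reads are summed over each morph's four samples;
the pooled 2×2 table must give a two-sided Fisher p < `morph_alpha`
(0.05). Survivors are binned by delta = |f_morph1 − f_morph2| into tiers
with strict inequality (> 0.5, > 0.75, > 0.95). The derived allele is the
one differing from the outgroup (Atlantic salmon) base; when the outgroup
base matches neither allele the site stays unpolarized and is excluded
from the per-morph tier rows (not from the stage rows).

The Fisher exact p itself is computed by exact integer hypergeometric
enumeration: table probabilities are compared as integer weights
C(r1, x)·C(r2, c1−x), so ties at the observed probability need no
floating-point tolerance; the final division is exact big-integer
division. An all-zero table returns p = 1 with a warning.

## Effect prediction

Regions follow the explicit 1-based inclusive CDS interval: 5'UTR strictly
before `cds_start`, coding inside, 3'UTR strictly after. Coding changes
substitute the alternate base into its codon and translate both codons
with the standard genetic code (vertebrate nuclear sequences); equal amino
acids give "synonymous", otherwise "X to Y" in single-letter code, with
"X to *" for gained stops and "unknown" when the codon contains N. Sites
lacking a CDS annotation are tallied separately, never rescued by ORF
guessing — EST contigs with uncertain frames would make such guesses
unreliable. The UNI/REP category distributions are compared with an
uncorrected Pearson chi-square (3 df over the four categories 5'UTR /
synonymous / non-synonymous / 3'UTR).

## Paralog-group expression

Contigs sharing an annotation are summed into paralog groups (ohnologs
from the salmonid whole-genome duplication frequently co-annotate); groups
with fewer than 800 reads across the whole dataset are dropped (boundary:
exactly 800 is kept).

Differential expression uses a negative binomial GLM with log link,
counts ~ morph + time, both factors categorical. With one pooled library
per morph × time cell the additive model is the finest estimable design;
no interaction term exists. The morph effect is tested by a
likelihood-ratio chi-square (1 df) against the time-only model, the time
effect (3 df) against the morph-only model; both p families are BH
adjusted separately. Fold changes are reported in base 2.

Dispersion (Var = μ + αμ²) is a single common α shared by all groups:
groups are first fitted as Poisson, then α is solved so the pooled Pearson
chi-square equals its pooled residual degrees of freedom (3 per group) — a
method-of-moments estimate in the pseudo-likelihood style. Sharing α
across thousands of groups makes it effectively known, which keeps the
1-df LRT close to nominal: measured type-I error at α = 0.05 on null NB
counts (2000 groups, dispersion 0.1, mean 500) is ≈ 0.05–0.06, and a
planted log2 fold change of 2 is recovered to within ~0.01 on average.
Per-group tagwise shrinkage (as in empirical-Bayes RNA-seq packages) is
deliberately not reproduced; with n = 8 and no replication it would add
machinery without improving the additive-model tests evaluated here.

Log-CPM uses prior count 0.25 before log2 to keep zeros finite.
Clustering z-scores each group's log-CPM profile (zero-variance profiles
are excluded with a warning) and cuts a complete-linkage euclidean tree
into k groups (default k = 4). Set enrichment is an upper-tail
hypergeometric test per category with BH across categories; gene length is
not modeled, since pooled paralog groups have no single length.

## qPCR quantification

ΔCt = Ct_target − mean(reference Cts); the arithmetic mean of reference
Cts is algebraically identical to geometric-mean normalization of the
2^−Ct abundances under the perfect-doubling model. ΔΔCt subtracts the
calibrator group's mean ΔCt, rq = 2^−ΔΔCt, and the SE-propagated bounds
are 2^−(ΔΔCt+SE) (minimum fold) and 2^−(ΔΔCt−SE) (maximum fold), SE being
the standard error of the ΔCt replicates within the group. The calibrator
group has rq = 1 identically. Efficiency 2 is assumed throughout; measured
efficiencies travel as metadata and values below 1.9 trigger a warning
(fold estimates from such assays are weak). Technical duplicates are
averaged within (gene, morph, time, replicate) before ΔCt.

Group tests run on ΔCt values: a fixed-effects two-way ANOVA with
interaction and sequential (type I) sums of squares — balanced designs
make the SS-type choice moot and the decomposition exact — plus Tukey's
HSD for pairwise factor-level comparisons. Cells without replication drop
the interaction with a warning; an all-constant response returns the
F = 0, p = 1 convention; pairs involving single-observation groups are NA.

## Verification statistics

Genotype tables treat mitochondrial markers as haploid (one sequence per
individual). The k-population comparison is an uncorrected Pearson
chi-square on the 2×k variant/non-variant table, df = k − 1; no Yates
correction, which is what reproduces the printed 9.3333 for carrier counts
(0, 1, 5) of 8 per population. Jointly monomorphic tables return χ² = 0,
p = 1. Column conservation is the fraction of non-gap species in an
alignment column sharing the reference base.

## Synthetic data: what it emulates, and what it does not

Defaults encode the study conditions: 8 pools (2 morphs × 4 timepoints) of
6 diploid individuals, NB coverage with mean 100 and size 5, sequencing
error 0.005, and a site-class mix of 40% true SNPs / 40% paralog artifacts
/ 20% interspecific sites with 40% of candidates from the REP stratum —
the mix and REP share are round figures of the same order as real
candidate lists, chosen once for the simulations. True SNPs draw each
pool's allele count Binomial(12, q_morph); planted morph differentiation
sets q = (1±δ)/2 for δ ∈ {0, 0.5, 0.75, 0.95} (δ = 0 sites share a
uniform q). A family mode first draws the spawners' alleles, inflating
between-pool variance as sib-group pools do. Artifacts use a constant
expression share r ~ U(0.15, 0.85); interspecific sites are fixed for the
alternate base up to sequencing error. Expression counts are NB with
log-linear morph/time effects; qPCR Cts follow Ct = baseline −
log2(relative expression) + N(0, σ); genotype tables have a deterministic
rounding mode so small worked examples come out exactly.

Not emulated: mapping and alignment error structure, reference bias,
indels near variant sites, expression-ratio drift of paralogs across
development (artifacts here are perfectly steady — real ones are harder),
linkage between sites, and family structure beyond the simple spawner
model. Passing the classification checks therefore shows the cascade
separates the *generative signatures* it targets at realistic depth and
pool size, not that real candidate lists reach the same purity.

## Problem sizes and numerical choices

Simulated checks use 3000 sites for cascade classification, 2000/500
groups for NB-GLM calibration/recovery, 1000 sites for the homogeneity
null level, and exhaustive 2×2 tables with margins ≤ 30 (~164k tables)
for the Fisher enumeration — sizes at which the Monte-Carlo bands quoted
above are stable to a few thousandths while the whole suite stays fast.
Dispersion solving uses Brent's method on [0, 10^4] with xtol 1e-8;
NB-GLM non-convergence yields NA statistics for that group rather than an
error. Delta tiers use strict inequality, the interspecific threshold
includes the tie (≥ 0.90), and the 800-read expression filter keeps the
boundary value, matching the published rule wordings ("or higher",
"fewer than").

## Known limitations

* The homogeneity screen's min-pairwise-p form is one of several readings
  of "Fisher exact tests between samples"; the 2×k chi-square alternative
  is provided, and the two agree on clear-cut cases but not near the
  threshold.
* The morph-comparison significance is applied as p < α (retention);
  documentation of the original procedure is ambiguous on the inequality's
  direction, and the conservative reading was chosen.
* Common dispersion under-serves genes with atypical variability; with one
  library per cell there is no way to estimate per-group dispersion
  reliably, so such groups' p-values should be read with care.
* The published chi-square values for two of the three mitochondrial
  variants (8.6 and 19.76) do not reproduce from their printed frequencies
  with n = 8 per morph (the uncorrected statistic gives 12.5042 and 16.0);
  only the third (9.3333) reconciles exactly, and only that one is used as
  a numerical anchor.
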