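# Methods

## Overview

`apoeld` screens for SNPs whose linkage disequilibrium (LD) with an *APOE*
ε-defining anchor SNP differs between Alzheimer's-affected (AD) and
unaffected (NAD) subjects, and quantifies how such SNPs modulate the anchor
allele's effect on age at AD onset through compound-genotype proportional-
hazards models with cross-dataset meta-analysis.  This note records the
models, the defaults and why, the numerical choices, and what the synthetic
data do and do not establish.

## Data model and quality control

Genotypes are hard calls 0/1/2 counting a declared effect allele, with -1
for missing; imputed posterior dosages must be hard-called upstream (we
recommend calling the max-probability genotype when that probability is at
least 0.9 and setting the call missing otherwise).  QC drops, in order:
imputed variants with imputation r² < 0.7; variants then samples with
missing rate > 5%; variants with MAF < 5%; variants failing Hardy–Weinberg
at p < 10⁻⁶ (1-df χ² goodness of fit by default; a conditional exact mid-p
test is available via `method="exact"`).  The order is part of the contract
because missingness interacts with MAF; QC is idempotent.  All thresholds
are strict inequalities on the "bad" side, so a variant at exactly MAF 5%
or r² 0.7 is retained.  Filters are applied per dataset, before pooling.
The two anchor SNPs are exempt from variant-level filters: within an
ε-negative stratum the other anchor is necessarily monomorphic, which is a
design feature, not a QC failure.

Pedigree-transmission (Mendel-error) checks are out of scope; the synthetic
data contain no Mendel errors and the analysis never uses transmission
information.

## APOE strata

ε alleles are defined by rs429358 (minor C → ε4) and rs7412 (minor T → ε2);
with the vanishingly rare ε1 allele excluded, the dosage pair determines
the diplotype uniquely, and (1,1) is called ε2ε4.  The rs7412 analysis runs
in the ε4-negative stratum (ε2ε2, ε2ε3, ε3ε3) and the rs429358 analysis in
the ε2-negative stratum (ε4ε4, ε3ε4, ε3ε3); ε2ε4 subjects belong to
neither.  Directly reported APOE genotypes, when present in the phenotype
table, override derived calls and disagreements are logged.  Each stratum
splits into AD and NAD groups by case status.

## Two-locus haplotype EM and LD

For one SNP pair, unphased genotypes give a 3×3 table of dosage pairs.
Every cell except the double heterozygote has a determined haplotype
decomposition; the double heterozygote mixes the cis configuration
(minor,minor)+(major,major) and the trans configuration with probabilities
proportional to 2·p₁₁·p₀₀ and 2·p₁₀·p₀₁.  The E-step splits that cell
accordingly; the M-step re-estimates the four haplotype frequencies from
expected haplotype counts.  This maximizes the genotype multinomial
likelihood under random union of haplotypes.

Numerical choices:

* convergence at max|Δp| < 10⁻¹⁰ or 1000 iterations, with a `converged`
  flag on the result;
* three starts — linkage equilibrium plus two points at 98% of the maximal
  positive and negative D compatible with the allele-frequency margins —
  best final log-likelihood wins.  The extra starts exist because data
  dominated by double heterozygotes put a saddle at equilibrium between
  the cis- and trans-dominated maxima;
* all estimation runs through a single vectorized batch implementation
  (`em_hapfreqs_batch` on (B, 9) count arrays); the scalar API wraps it.

LD statistics: D = p₁₁ − p_A·p_B and r = D/√(p_A(1−p_A)p_B(1−p_B)),
computed between the minor (effect) alleles of both SNPs with the anchor's
effect allele fixed (T for rs7412, C for rs429358) so signs are comparable
across datasets and groups.  Significance uses χ² = r²·n with *n* the
number of subjects rather than 2n gametes — deliberately conservative,
because haplotypes are inferred, not observed — with a 1-df upper-tail
p-value.  The identity χ² = r²·n holds exactly by construction.

var(r) is a delta-method variance: the observed Fisher information of the
three free haplotype frequencies (negative Hessian of the multinomial
log-likelihood at the EM estimate, central finite differences with step
10⁻⁵) propagated through the numerical gradient of r.  When the estimate
sits on the simplex boundary or the information is singular, a seeded
nonparametric bootstrap over subjects (200 multinomial resamples of the
9-cell table) replaces it.  var(r) feeds confidence intervals only — never
the screening test.  At independence with balanced frequencies it
reproduces the classical (1−r²)²/n ≈ 1/n limit within 10% at n = 1000.

## Stage 1 screen

For each anchor and group, LD is computed per dataset and on the pooled
subjects; pooling subjects is exactly summing per-dataset 9-cell tables, so
variants absent from a dataset simply contribute nothing there.  Selection:

* **replication set** — p < 5×10⁻⁶ in some dataset (discovery; the
  genome-wide band p < 5×10⁻⁸ is handled identically, as one band) and
  p < 0.0125 (= 0.05/4, Bonferroni over four potential replication
  datasets) in at least one other dataset, evaluated over all ordered
  dataset pairs, recorded once;
* **pooled set** — pooled p < 5×10⁻⁶, excluding replication-set members.

A SNP qualifying in both AD and NAD scans is recorded once with group
"both".

## Stage 2: Δr permutation test

For each stage-1 SNP, Δr = r_AD − r_NAD from group-wise EM estimates on the
pooled stratum.  The null reshuffles AD/NAD labels within each dataset,
preserving per-dataset group sizes and hence dataset composition (a global
permutation is available via `within_dataset=False`).  Since a label
permutation only redistributes subjects between the two groups' genotype
tables, each replicate is drawn directly as a multivariate hypergeometric
split of the per-dataset cell counts — equivalent to permuting labels and
much faster — followed by batch EM on both groups.  The two-sided p-value
is (1 + #{|Δr*| ≥ |Δr_obs|})/(B + 1); the +1 keeps p > 0.  Replicates in
which a permuted group goes monomorphic are redrawn and counted.

B_max defaults to 10⁶ with adaptive early stopping: permutation proceeds in
blocks of 2000 and stops once a 99.99% Clopper–Pearson interval for the
exceedance probability excludes the decision threshold α/m, where m is the
number of stage-1 SNPs for that anchor (Bonferroni thresholds near 6×10⁻⁵
need ~10⁵ permutations to resolve, hence the large default).  With a fixed
B and seed, results are bit-exact reproducible; the B actually used is
recorded on the result.  Selection uses strict inequality p < α/m.

## Compound-genotype survival analysis

The compound genotype crosses anchor dosage (0 vs 1–2) with partner-SNP
dosage (0 vs 1–2) into CompG1 (reference), CompG2, CompG3, CompG4.  AD
subjects enter with (age at onset, event = 1), NAD subjects with (age last
seen, event = 0) — censoring at age last seen is our choice; no left
truncation is modeled because entry ages are not part of the data model.
The Cox partial likelihood uses Efron tie handling (ages in integer years
tie heavily), CompG2/3/4 indicators, sex, the top five principal
components, and cohort dummies when a dataset has more than one cohort.

Family clustering is absorbed through a cluster-robust (sandwich) variance
with family id as cluster whenever families with more than one member
exist.  A penalized shared log-normal frailty would refine the variance
decomposition but no maintained Python implementation exists; the robust
variance is the package's documented approach, flagged per fit via
`cluster_robust`, and its point estimates coincide with the independence
fit — exactly so when the true frailty variance is zero.  Monotone partial
likelihoods (complete separation) raise with a message suggesting a
Firth-style penalized fit, which is not implemented.

Per-dataset coefficients are combined by inverse-variance fixed-effect
meta-analysis: weights 1/se², pooled se = 1/√Σw.  Cochran's Q and I² are
reported but never gate results.  Direction strings record per-dataset
effect signs in a fixed configured order ('?' for a missing or unfit
dataset); a CompG level absent in a dataset contributes '?' and is excluded
from that level's meta-analysis.  The CompG3-vs-CompG4 contrast
χ² = (b₃ − b₄)²/(se₃² + se₄²), 1 df, is applied to the meta-analyzed
coefficients (a per-dataset contrast is available through the same
function), alongside |β|-difference |b₄| − |b₃|.  CompG results are
classified against the Bonferroni level 0.05/m₂ with m₂ the number of
group-specific SNPs for the anchor.

## Synthetic data

Two deliberately complementary generators:

* **LD mode** simulates genotype given status: each group draws anchor
  alleles at its configured frequency and partner alleles conditional on
  the anchor haplotype, so each group's r is an analytic property of its
  haplotype pool.  All partner SNPs must share the anchor's per-group
  margin (validated before sampling).  Null SNPs are binomial draws
  independent of the anchor, identical in both groups.  Ages are decorative
  here (onset ~ N(75, 7²) clipped to [60, 95], censoring ~ U(60, 95),
  rounded to years): survival coefficients estimated from LD-mode data
  reflect the induced genotype–status association, not a planted hazard.

* **Survival mode** simulates status given genotype: one haplotype pool
  with configured margins and r, onset from a Weibull proportional-hazards
  model — baseline shape 4 and scale 85 years, chosen to mimic late-onset
  AD incidence rising steeply after age 70 — log hazard ratios per CompG
  level (defaults 0, −0.73, −0.18 for CompG2/3/4, an ε2-like attenuation
  pattern), independent censoring U(60, 95) years, optional families of
  fixed size sharing a normal log-frailty.  Status is endogenous:
  event-before-censoring defines AD.

Default LD-mode frequencies are ε2-like: anchor minor allele 4% in AD and
8% in NAD (the protective allele is depleted among cases), AD groups
smaller than NAD.  Each dataset uses its own stream seeded as
(master seed, dataset index), so output is bit-identical given
(scenario, seed).

What the synthetic data do **not** emulate: genome-wide LD structure among
the scanned SNPs (nulls are mutually independent), population
stratification (PCs are pure noise with zero effect), genotyping/imputation
error, Mendel errors, informative censoring, and secular cohort effects.
Passing tests therefore establish correctness of the estimators and error
control under the stated model, not robustness to those real-data
complications.

## Problem sizes and verification

The test suite verifies, among others: EM against a coarse-to-fine grid
maximization of the same likelihood (resolution ≤ 10⁻³) on random tables of
up to 200 subjects; per-iteration monotonicity of the EM log-likelihood;
permutation type-I calibration under a common-pool null (500 subjects per
group, B = 999, 500 replicates — the empirical size must fall inside the
exact binomial 95% band around 0.05 and the p-value distribution must pass
a Kolmogorov–Smirnov uniformity check at α = 0.01); Cox recovery of a
planted CompG3 log hazard ratio of −0.7 (4000 subjects, 200 replicates,
mean bias under 0.05 and model SE within 20% of the empirical SE); and an
end-to-end run with one planted group-specific SNP among 999 nulls in two
cohorts of 2000 (the planted SNP must be selected, at most one null may
survive, and a rerun under the same seed must write byte-identical tables).
These sizes are the package's chosen desk-scale study conditions.

## Known limitations

* The asymptotic variance of r is a delta-method construction from the
  observed information; other published variance formulas for EM-based r
  may differ in finite samples.  It never affects selection.
* No genotype imputation, phasing, multi-allelic handling, or PLINK binary
  input; split multi-allelics and hard-call dosages upstream.
* Fixed-effect meta-analysis only; heterogeneity is reported, not modeled.
* Family correlation is handled by robust variances, not an explicit
  frailty likelihood; with substantial frailty variance the coefficients
  retain their marginal (population-averaged) interpretation.
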