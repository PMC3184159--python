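# Methods

This note documents the statistical models implemented in `pathsnp`, the
defaults and why they were chosen, what the bundled cohort simulator does
and does not emulate, and the numerical decisions that affect results.

## Data model

Genotypes are biallelic, coded as the variant-allele count 0/1/2 (WW / WV /
VV) with NaN for missing.  The variant allele is structural — the VCF ALT
allele or the table dialect's V allele — not the minor allele, so coding is
stable across samples; minor-allele frequency is a derived report field.
Missing genotypes are handled complete-case per SNP (per block for
haplotype analysis, per gene for gene tests); no imputation is performed.
Subjects carry case/control status plus the adjustment covariates age
(continuous) and ethnicity (indicator contrasts, largest stratum as
reference).

A count-table dialect stores per-SNP genotype class counts split
case/control (the form association studies print).  It expands
deterministically to pseudo-subjects — cases before controls, WW then WV
then VV within status — so printed tables can be loaded and their
arithmetic reproduced exactly.  Expansion destroys between-SNP correlation
by construction; anything beyond single-SNP arithmetic needs subject-level
data.

## Single-SNP association

Three genetic codings (dominant, recessive, additive) are fitted by
unconditional maximum-likelihood logistic regression (Newton/IRLS via
statsmodels).  Odds ratios are exp of the exposure coefficient; intervals
are Wald, exp(β ± 1.96·SE), and P values are Wald z tests — matching the
"OR (95% CI)" convention of epidemiological reports rather than
profile-likelihood intervals.  The best model is the candidate with the
smallest P; when the VV class is below 5% *of* cases or controls the
candidate set collapses to the dominant model (the recessive and additive
contrasts are then driven by a handful of subjects).  The threshold is read
as a fraction; an absolute-count rule is available
(`threshold_rule="count"`).  Exact P ties break deterministically by
DOM > REC > ADD.  Perfect separation or non-convergence yields a flagged
failure record, never an exception that kills a panel scan.

Internal validation draws B = 100 bootstrap resamples of subjects,
stratified within case and control to preserve the matched design (plain
resampling by option), refits the chosen model with covariates, and counts
resamples with P < 0.05; the pass rule is ≥ 80 of 100.  The chosen model is
held fixed across resamples by default; re-selecting the best model inside
each resample is available (`reselect_model=True`) but makes the pass count
answer a different question (stability of selection, not of the effect).

## Cumulative unfavorable-genotype score

For each validated SNP the unfavorable genotype set is the risk-raising
side of its best model: the exposed set when OR > 1, the complement when
OR < 1; additive-model SNPs use the dominant grouping of the risk-raising
allele (variant carriers when OR > 1, wild-type carriers when OR < 1).
Published tables sometimes label variant-carrier groups "unfavorable" even
for protective SNPs; when the complement rule fires a warning says so
rather than silently matching either convention.  A subject's score counts
unfavorable genotypes across rule SNPs; missing genotypes contribute zero
and a per-subject completeness count is reported alongside.

Scores are binned into ordered categories (default: quartile-based upper
edges collapsed to unique integer breaks, always user-overridable, e.g.
`breaks=[4, 7, 10]` for the 2–4 / 5–7 / 8–10 / 11–13 style).  One logistic
model with k−1 category indicators plus covariates gives each category's
OR against the lowest-score reference; the trend P comes from a separate
fit on the ordinal category index — the standard epidemiological trend
test.  Percentile bootstrap CIs over stratified subject resamples are
optional (B configurable; reports that mirror published tables used
B = 10,000 there, which is overkill for the simulated cohorts in the test
suite).

## Gene-level likelihood-ratio test

All of a gene's SNPs enter one logistic model under a dominant or additive
coding; the LRT statistic 2·(ll_full − ll_null) is referred to χ² with df
equal to the number of SNP terms retained.  Perfectly dependent exposure
columns (duplicate tags) are pruned greedily using a singular-value
criterion (smallest singular value ≤ 1e-8 × largest marks dependence), and
df shrinks accordingly; constant columns carry no term.  The full model is
fitted by BFGS, which is more robust than Newton when many correlated SNP
terms enter jointly.  Both codings are reported side by side; a gene is
flagged when either P < 0.05.

## Haplotype EM, LD, and blocks

Within a block of k ≤ 8 SNPs (2^k haplotype space; the cap is configurable
but exponential), population haplotype frequencies are estimated by EM over
unobserved phase: the E-step weights each subject's compatible ordered
phase pairs by the product of current frequencies; the M-step re-estimates
frequencies from expected haplotype counts.  Iteration stops when the
largest frequency change is below 1e-8 or after 1,000 iterations.  The
log-likelihood is non-decreasing across iterations and frequencies sum to
one at every step (both asserted in tests).  Because symmetric genotype
configurations are EM saddle points, estimation is multi-start: a
counting-based start (compatible pairs weighted uniformly) plus 5 random
Dirichlet starts by default, best final likelihood wins.  Tiny samples
(≈ 12 subjects) have rugged likelihoods; the oracle-equivalence checks in
the test suite use 16 restarts, where EM matches an independent brute-force
likelihood maximization within 1e-4 on every random instance tried.

Pairwise LD is summarized by D = p₁₁ − p_A·p_B, D′ = D/D_max (standard
sign-dependent D_max), and r².  The one-sided 95% CI on |D′| comes from
the normalized likelihood profile over a |D′| grid (step 0.001) with allele
frequencies fixed at their sample estimates — the construction used for
block calling: the 5th and 95th percentiles of the cumulative normalized
likelihood.  Blocks follow the published CI rules: a pair is strong LD when
the CI is [≥ 0.70, ≥ 0.98], strong recombination when the upper bound is
< 0.90, and an interval of ordered SNPs is a candidate block when ≥ 95% of
its informative pairs are strong LD.  Maximal non-overlapping candidates
are chosen greedily from the longest spans (leftmost on ties).  All four
thresholds are exposed in `GabrielParams`.

Haplotype association uses each subject's *expected dosage* (0–2 copies
from the EM posterior) rather than best-guess phase, propagating phase
uncertainty into the logistic fit; haplotypes rarer than 3% pool into
"other".  Each non-reference haplotype is tested one at a time against the
most common haplotype (highest pooled frequency; lexicographic tie-break
with a warning) with covariate adjustment; expected case/control copy
counts and row percentages accompany each OR.

## Interaction tree

At each node every candidate SNP and every bipartition of its observed
genotype codes ({0} vs {1,2}, {0,1} vs {2}, {0} vs {1}, …) is scored by the
Pearson chi-square P (df 1, no continuity correction) of the induced 2×2
status table; smallest P wins, ties break by SNP order then partition
order, so trees are deterministic and subject-order invariant.  Splitting
stops at purity, below twice the minimum leaf size (default 20), at depth 4,
or when the best P ≥ 0.05 — pre-pruning in place of cost-complexity
pruning, since the reported object is a single grown tree.  A Gini-impurity
criterion is available as an alternative.  Subjects missing the split
genotype follow the larger side.  Terminal nodes are numbered by ascending
case fraction; node ORs come from one logistic fit on leaf indicators plus
covariates against the lowest-risk node, with an ordinal trend P and
optional percentile bootstrap CIs (subjects resampled, tree held fixed).

## Synthetic cohorts

The simulator emulates the target study design: ~417 cases and ~417
controls, age drawn from a normal (mean 60.5, SD 10.5, truncated to
[18, 95]) matching the reported cohort means, ethnicity from a discrete
distribution with an 82% majority stratum, genotypes from haplotype blocks
(independent draws per chromosome copy within a block; blocks independent),
and disease status from a logistic model whose linear predictor is a
baseline log-odds (default −1.0, giving an efficient case yield) plus one
term per planted effect SNP under its stated genetic model with odds ratios
in the 0.45–1.6 range of the reported panel.  Controls are
frequency-matched to the realized case distribution over 5-year age strata
× ethnicity (largest-remainder allocation) — the matching that
unconditional logistic regression with covariate adjustment supports; 1:1
pair matching (and conditional logistic analysis) is deliberately not
simulated.  Case-control sampling of a logistic disease model shifts only
the intercept, so planted ORs are the estimands downstream stages should
recover.

The default design plants the 13 validated panel variants (their models,
odds ratios, and control-group variant frequencies) as independent
single-SNP blocks and adds five strong-LD "ladder" blocks (haplotype j
carries the variant at the first j SNPs, so every within-block pair has
|D′| = 1) for the haplotype stages; `ld_panel_design` provides a 29-SNP
five-block null layout for block-partition recovery.  What the simulator
does **not** emulate: realistic genome-wide LD decay, partial-LD blocks,
population stratification beyond discrete ethnicity labels, genotyping
error, or missingness.  Passing tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to those real-data
features.

All randomness flows from a single root seed; the pipeline derives
per-stage generators with a fixed stream order (assoc = 1, cumulative = 2,
haplotype = 3, cart = 4), so a run is a pure function of inputs, config,
and seed.

## Problem sizes in the checks

The test suite and `scripts/acceptance.py` use: 1,000 random 2×2 tables
for the logistic/cross-product equivalence (agreement to 6 significant
figures); 50 random 3-SNP/12-subject instances for EM vs brute force
(within 1e-4); 50 random ≤3-SNP/≤60-subject instances for tree-split
enumeration; 1,000 simulated 417+417 cohorts for Wald-CI coverage of a
planted dominant OR 1.6 at variant frequency 0.09 (coverage expected in
93–97%; 1,000 replicates hold the Monte-Carlo SE of the estimated rate
near 0.7 points so the band is meaningful); 200 cohorts for the null-SNP
bootstrap pass rate (< 5%); and 100 cohorts with all 13 planted effects
for the dose-response properties.

## Known limitations

- Wald intervals misbehave near separation (rare exposures, small
  categories); affected records are flagged rather than patched.
- The EM block cap (8 SNPs) is exact but exponential; long blocks need
  windowing, which is out of scope.
- The |D′| CI profiles the likelihood with allele frequencies fixed at
  their estimates; a full joint profile would be slightly wider.
- Category breaks "based on the distribution of ORs", as published reports
  phrase it, are not algorithmically reproducible; the quartile default is
  transparent and any break set can be supplied.
- Multiple-testing correction across the panel is intentionally absent:
  the design relies on bootstrap internal validation, as the analysis it
  implements did.
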