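# Methods

## The analysis

`ifnstab` implements a screening pipeline for composite interferon (IFN)
scores in rheumatoid arthritis (RA) cohorts. A panel of interferon
response genes (IRGs) is quantified in peripheral blood by qPCR, each
patient receives an IFN score — the arithmetic mean of the panel's log2
relative expression — and the score is screened against a list of
clinical variables. Two layers of inference are reported side by side:

1. **Complete-group screen.** For every variable, a rank-based test
   against the IFN score on all pairwise-complete cases: Spearman
   correlation for continuous variables, Mann-Whitney U for dichotomous
   ones, with Benjamini-Hochberg (BH) multiple-testing adjustment across
   the whole variable list.
2. **Split-half stability screen.** The cohort is randomly bipartitioned
   into two equally sized halves `n_iter` times (default 1000). Each
   iteration shares one bipartition across all variables; each variable's
   test runs on each half, and we count iterations in which p < alpha in
   both halves, exactly one, or neither, plus per-set median p values. An
   association that rarely replicates in disjoint halves is fragile even
   if the complete-group p looks convincing: because the halves are
   disjoint, under an iid null they are independent samples, and the
   both-halves rate calibrates to roughly alpha^2 (0.0025 at alpha =
   0.05). This calibration is verified by simulation in the test suite.

## Quantification model

The standard-curve method maps a gene's Ct to a relative template
quantity through an ordinary-least-squares line Ct = intercept +
slope*log10(quantity) fitted to a dilution series. Slope must be negative;
the implied per-cycle amplification efficiency 10^(-1/slope) is checked
against (1.0, 2.5] (2.0 is perfect doubling) and flagged otherwise.
Quantities are divided by the same sample's reference-gene quantity
(GAPDH by convention) and log2-transformed. Because quantification is
relative, upstream preamplification cancels and is not modelled.

Missing Ct values (non-amplifying wells) propagate as missing expression;
a sample is dropped only when its reference gene itself is missing, since
nothing can be normalized without it. Zero or negative quantities are set
missing with a warning rather than producing infinities. Analyses that
start from pre-computed log2 relative expression can bypass this module
entirely; that is the mode all downstream defaults assume.

## Score and panel QC

The IFN score is the unweighted mean of the panel genes' log2 values; by
default a sample needs every panel gene measured (`min_fraction = 1.0`),
because missing-gene handling changes the score's scale and no principled
reweighting is obviously right. Averaging is justified by panel
coherence, which `correlation_qc` quantifies as the fraction of gene
pairs with pairwise-complete Pearson r >= 0.7 at two-sided p <= 0.002 (t
approximation, n-2 df). Pearson on log2 values is the default flavor —
the threshold convention follows log transformation — with Spearman as a
switch. The QC is advisory: a panel below 90% coherent pairs triggers a
warning, never a filter, since dropping genes post hoc would change the
estimand. The panel itself is always a configuration input; the package
hard-codes no gene list.

## Tests and the BH dialects

* **Spearman**: average ranks over ties; two-sided p from
  t = rho*sqrt((n-2)/(1-rho^2)) with n-2 df; p = 0 at |rho| = 1; flagged
  not-computable below n = 4 or at zero variance. An exact mode
  enumerates all permutations of the ranks (n <= 9) and is the reference
  for small samples.
* **Mann-Whitney U**: normal approximation with tie and continuity
  corrections (U reported for the first group); an exact mode enumerates
  all C(n_a+n_b, n_a) rank assignments (tie-aware) for n_a + n_b <= 12.
  Which convention the original desktop statistics packages applied is
  generally unknowable, so the enumeration modes serve as ground truth:
  the asymptotic p tracks the exact p within ~0.02 at the sizes where
  both run.
* **BH adjustment** comes in two dialects. `monotone` is the standard
  step-up estimate q_(i) = min(1, min_{j>=i} p_(j)*m/j) and is the
  library default. `plain` computes q = min(1, p*m/rank) without
  enforcing monotonicity, ties sharing the smaller rank; some widely used
  statistics packages print this variant, and it is the replication
  default (`--replicate-published-bh`) for reproducing published screens of
  this design, where it reproduces the published adjusted column exactly
  at printed precision with family size m = 25 (24 reported p values plus
  one test whose p went unreported — `m` may exceed the length of the p
  list for exactly this reason). Both dialects agree whenever the raw p
  values are strictly increasing in rank.

All tests are two-sided; alpha defaults to 0.05. Missing data are handled
pairwise-complete per test, with no imputation. Not-computable tests stay
in the BH family size but receive no q.

## Stability screen details

* One bipartition per iteration is shared across all variables (the
  randomization is of patients, not of variable-specific subsets); sizes
  are floor(n/2) and ceil(n/2), and cohorts below n = 8 are refused.
* The RNG policy is one `numpy.random.default_rng(seed)` stream; the
  i-th iteration's bipartition is the i-th permutation drawn from it.
  This is documented precisely so an independent reimplementation can
  reproduce results bit-for-bit, which a test does.
* A half in which a test is not computable (e.g. an empty treatment group
  after splitting) counts as not-significant for that half and is
  excluded from the median p.
* The median statistic reported for continuous variables pools the
  Spearman rho values of both halves across iterations; set labels are
  arbitrary under exchangeability, so pooling only halves the noise.

## Synthetic cohort generator

No patient-level data ship with the package; the generator produces
cohorts with the structure the analysis assumes.

* **Expression**: the equicorrelated one-factor model
  x_gj = mu + sigma*(sqrt(rho)*f_j + sqrt(1-rho)*e_gj) with rho = 0.8
  across 19 genes, mu and sigma calibrated so the panel-mean score has
  mean 0.26 and SD 1.01 (the reported cohort-level IFN-score moments
  this generator emulates). At rho = 0.8 and n = 182 essentially all 171
  gene pairs clear r >= 0.7, comfortably reproducing the >= 90% coherence
  regime the score presumes.
* **Treatment suppression**: each suppressing agent (prednisone, HCQ,
  SSZ) a patient takes subtracts delta*score_sd from every gene, delta in
  score-SD units per agent, additive across agents — encoding the
  observation that co-treatment suppresses more. Defaults are delta = 0
  (null cohorts); ground truth is returned alongside the data.
* **Clinical marginals** default to an established-RA profile: age
  N(54.2, 11.8); 75% female; DAS28 ~ N(5.1, 1.2) truncated to [0, 9.4];
  ESR ~ positive-truncated N(24.5, 18.0); RF titer log-normal matched to
  mean 124.7, SD 279; ACPA titer log-normal matched to mean 1563, SD
  2680; erosions 72%, nodules 24%; MTX 84% (dose N(21.0, 6.3) among
  users), prednisone 29% (dose N(7.2, 3.5)), HCQ 19%, SSZ 15%. Truncated
  normals are moment-matched: the underlying parameters are solved so the
  *truncated* distribution has the stated mean and SD. Disease duration
  (9.7, 10.3) and CRP (17.8, 22.1) have SD > mean, which no left-truncated
  normal can produce (its coefficient of variation is below 1), so both
  use moment-matched log-normals — also the realistic right-skewed shape
  for those variables. DAS28 components are screened in cohorts of this
  design but their marginals are rarely reported, so the defaults are
  chosen as realistic for active established RA: TJC28 ~ N(8, 6) and
  SJC28 ~ N(6, 4) truncated to [0, 28] and rounded to counts, VAS ~
  N(50, 22) truncated to [0, 100].
* **Derived columns** (ESR > 20, CRP >= 10, ACPA >= 3x cutoff, RF&ACPA
  combinations, any-suppressor) are always recomputed from parents. The
  ACPA assay cutoff defaults to 500 AU/ml, chosen so roughly 40% of
  ACPA-positive patients exceed the 3x-cutoff "high positivity" line
  under the titer marginal.
* **Missingness** mimics availability footnotes: nodules 6/182, RF 21/182
  (titer and positivity blanked together), ACPA 7/182.
* Clinical variables are mutually independent by default, and only the
  treatment flags feed into expression — so every non-treatment signal a
  screen finds in synthetic data is a false positive by construction,
  which is exactly what the calibration tests rely on. Treatment flags
  are also mutually independent; the untreated (no prednisone/HCQ/SSZ)
  subgroup therefore averages 182 x 0.71 x 0.81 x 0.85 ≈ 89 patients.
  Real treatment assignments co-occur more than independence predicts;
  the overlap is configurable but deliberately left independent by
  default to keep the null clean.

### What passing tests do and do not show

The generator emulates marginals, panel coherence, and an additive
treatment effect. It does not emulate confounding between clinical
variables (e.g. ESR-CRP-DAS28 coupling), longitudinal structure, batch or
plate effects, or treatment-by-severity selection (confounding by
indication). Calibration and power results on synthetic cohorts therefore
validate the machinery — not any claim about what a real cohort would
show.

## Numerical choices

* Ties: average ranks everywhere; plain-BH ties share the smaller rank.
* Exact-test two-sided p values count permutations whose statistic is at
  least as extreme as observed, with a 1e-9 (MWU) / 1e-12 (Spearman)
  slack against float rank noise.
* Score/report storage is full double precision; the rendered TSV rounds
  to 3 significant figures and writes "." for not-computable cells.
* All pipeline randomness flows from a single seed through one
  `default_rng` stream; reports are byte-identical across reruns with the
  same config and seed.

## Problem sizes used in validation

The shipped validation uses cohorts of n = 182 with 19 genes; the null
calibration averages 200 fresh cohorts at 200 iterations each, power
checks use 200 iterations per suppression level, and the end-to-end
determinism check runs the full 25-variable spec at 1000 iterations.
Large-sample marginal-fidelity checks use n = 10,000. These sizes give
Monte-Carlo standard errors small enough for 3-sigma assertions while
keeping the suite quick to run.

## Known limitations

* The screen is univariable by design; no confounder adjustment is
  offered, so treatment-linked findings in real data may reflect
  indication rather than pharmacology.
* The plain BH dialect is not monotone in p and can rank-invert adjusted
  values; it exists for replication, not as a recommended default.
* Exact test modes are enumeration-bound (n <= 9 Spearman, n <= 12 MWU).
* The IFN score weights genes equally; no attempt is made to reweight by
  assay reliability or factor loadings.
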