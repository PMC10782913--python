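# Methods

## Pair encoding and its invariance

The core representation is the within-sample ordering indicator of a
regulator–target pair: `I = +1` when the regulator's expression is greater
than or equal to the target's in that sample, `-1` otherwise. Ties take the
`+1` branch, so the encoding is total and deterministic. Any strictly
increasing transform applied per sample (log scaling, affine rescaling,
rank transforms) preserves all within-sample orderings and therefore the
entire indicator matrix; this is checked by property tests over random
transform families. Consequently no cross-cohort normalization is
performed anywhere in the pipeline — expression matrices are used exactly
as supplied, and only need to be *within-sample comparable* (one monotone
transform per sample, e.g. `log2(x+1)` of TPM).

The Pearson correlation step that builds the pair catalog is **not**
transform-invariant; correlations are computed on the matrix as supplied,
and a log-like scale is recommended because it tempers the leverage of
extreme values. Thresholds are applied as strict inequalities,
`|r| > 0.5` and `p < 0.01`, with the p-value from the exact
t-transformation `t = r·sqrt((n-2)/(1-r²))` on `n-2` degrees of freedom.
No multiple-testing correction is applied at this stage: the catalog is a
screen, not an inference, and the downstream Fisher cutoff is far more
stringent. Duplicate gene rows in input files are collapsed by arithmetic
mean (deterministic and order-independent); day-scale survival times can be
converted to months with the fixed factor 30.44 at ingest.

## The reversal test in log space

For each pair, samples are cross-tabulated as indicator (+1/−1) × group
(LGG/GBM) into counts `a, b, c, d`. Two quantities are computed:

* the **hypergeometric point probability** of the observed table given its
  margins, `(a+b)!(c+d)!(a+c)!(b+d)! / (a!b!c!d!n!)`;
* the **two-sided Fisher exact p**: the sum of point probabilities, over
  all tables with the same margins, that do not exceed the observed one
  (the standard "as or more extreme" convention).

Selection uses the two-sided p, at `log10 p < -70`. Both values are
computed entirely in log10 space through `gammaln`, with `logsumexp` for
the two-sided sum; with cohorts of several hundred samples per group the
relevant probabilities reach below 1e-140, where any linear-space
intermediate would underflow. The "≤ observed" comparison carries a
relative slack of 1e-7 on the log scale, guarding against spurious
exclusion of tables whose exact probabilities tie with the observed one but
differ in the last float bits. Correctness is pinned by a rational-
arithmetic enumeration oracle (exact `Fraction` factorials): point and
two-sided values agree to 12 significant digits on every 2×2 table with
n ≤ 20, and in the deep tail (250 vs 250, perfectly reversed) the log-space
value matches the exact rational computation to 10 significant digits.

## Signature construction

Candidate pairs passing the reversal screen enter an L1-penalized Cox
regression (coordinate-descent elastic net with `l1_ratio = 1`). The
penalty path is generated from the data (50 alphas, `alpha_min_ratio`
0.01) and the penalty is chosen as the minimizer of 10-fold
cross-validated partial-likelihood deviance, computed as −2× the held-out
Breslow partial log-likelihood. The fold split is seeded and the whole
selection is bit-reproducible given the seed. Indicator features are
deliberately **not** standardized: they are already symmetric ±1 variables
on a common scale, and rescaling by column SDs would only distort the
interpretation of the coefficients.

Selected pairs are refit by unpenalized multivariate Cox regression
(Newton–Raphson, Breslow ties) to obtain coefficients, hazard ratios with
95% Wald intervals, per-pair Wald p-values and the global likelihood-ratio
p. Exactly collinear feature columns are rejected with an error naming the
offending pairs rather than silently dropped.

The risk score is the coefficient-weighted sum of pair indicators. Cohorts
are stratified at the median score; samples exactly at the median are
assigned to the low-risk (reference) group, which keeps the rule
deterministic. With few distinct score levels this tie rule can make the
split asymmetric by design — the imbalance is bounded by 2·(ties at the
median) − 1, and with a five-pair signature (up to 32 score levels) median
ties are rare.

The published five-pair signature is stored with its coefficients to three
decimals exactly as printed, provenance-tagged `published`, and is never
refit. Scoring a cohort that lacks any of its eight genes is a hard error:
a fixed linear score is only defined with all of its terms.

Clinical covariates (age in years; radiotherapy and gender encoded 1/0)
can be added to the pair indicators in a combined Cox model that returns a
per-patient prognostic index. The default covariate set is {age,
radiotherapy}, with gender optional. A single-gene baseline signature
(classical LASSO Cox on per-gene standardized expressions, by default
steered to about 20 genes by choosing the path penalty with selection size
closest to the target) is provided for comparison against the pair model.

## Evaluation suite

All metrics adopt the orientation *higher score = higher risk = shorter
survival*.

* **Kaplan–Meier / log-rank**: product-limit estimates and the k-group
  log-rank chi-square test.
* **Time-dependent ROC**: the cumulative-case / dynamic-control estimator
  with inverse-probability-of-censoring weights. Cases at horizon `t` are
  samples with an observed event at or before `t`, weighted `1/G(T⁻)`;
  controls are samples observed beyond `t`, weighted `1/G(t)`; `G` is the
  Kaplan–Meier estimate of the censoring survival function. Horizons
  default to 12/36/60 months. With no censoring all weights are 1 and the
  estimator reduces exactly to the empirical AUC of cases vs controls
  (verified against a brute-force rank statistic). A horizon with no cases
  or no controls is reported as undefined (`NaN`), not an exception.
* **C-index**: Harrell's estimator. Usable pairs are those where the
  shorter observed time carries an event; pairs tied on time are excluded;
  score ties count 0.5. (Uno's IPCW variant is not implemented; Harrell's
  is the default and only estimator.)
* **Calibration**: the signature's linear predictor is combined with a
  Breslow baseline cumulative hazard estimated on the evaluation cohort,
  giving `S_i(t) = exp(-H0(t)·exp(lp_i))`; samples are binned by predicted
  survival quantiles (default 3 bins) and mean predicted survival is
  compared with the within-bin KM estimate at the horizon. Bins whose
  follow-up ends before the horizon are flagged undefined.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with ground
truth for recovery tests:

* **Expression**: each regulator and its targets are jointly Gaussian
  through a shared block factor, giving pairwise correlation `rho`
  (default 0.7). Gene symbols for regulators come from the packaged
  regulator list, so generated cohorts work with the default catalog
  builder.
* **Group structure**: two diagnosis groups (LGG-like and GBM-like,
  defaults 520/170 mirroring the LGG-heavy imbalance of real glioma
  cohorts), optionally a normal-brain-like group. Every gene of a block
  shifts up by `group_shift` (default 1.0 SD) in the GBM-like group —
  coordinated grade-driven dysregulation. This shift cancels inside the
  within-sample difference but keeps the pooled regulator–target
  correlation of reversed pairs above the catalog threshold despite their
  group-dependent means.
* **Planted reversals**: a chosen number of pairs (default 10,
  round-robin across regulators) whose target additionally shifts by
  `-delta` in the LGG-like group, `+delta` in the GBM-like group and
  `-2*delta` in normal tissue, so the +1 indicator has probability
  `Phi(delta/tau)` per group with `tau = sqrt(2(1-rho))`, and the
  proportion of +1 falls monotonically across normal → LGG → GBM. The
  default `delta = 3` makes the ordering near-deterministic, matching the
  deep-tail `p < 1e-70` regime of real cohort sizes; recovery experiments
  use `delta = 1.5`, which still clears the cutoff comfortably
  (log10 p ≈ −120 at 250/250) while leaving enough within-group indicator
  variation for the Cox coefficients to be well identified.
* **Survival**: event times follow a proportional-hazards model whose
  linear predictor is built from the *true* indicators of the planted
  prognostic pairs (default hazards 0.8 and −0.5), with an exponential
  baseline (rate 0.02/month, median ≈ 3 years at null predictor; a Weibull
  shape is exposed as an option). Generating survival from indicators
  rather than raw expression makes the fitted model exactly well-specified,
  so parameter recovery is a fair test of the fitting code. Censoring is
  independent Uniform(0, c_max) with c_max solved numerically on the
  realized event times to hit the requested censoring fraction (default
  0.3; realized rate within ±5 points of target for n ≥ 500).

What passing tests on these cohorts do **not** show: robustness to
realistic marginal distributions (counts, zero inflation), library-size or
platform noise, non-proportional hazards, or informative censoring — the
generator deliberately models none of these.

## Problem sizes and numerical choices

The shipped experiments use cohorts of 500 tumor samples, 5 regulators × 8
targets, and 30–50 replicates for the recovery studies; these sizes put
every statistic comfortably in its asymptotic regime while keeping the full
test suite and the acceptance script fast. Other conventions: regulator
symbols are matched case-insensitively by upper-casing; median-tied samples
go to the low-risk group; Fisher two-sided comparisons use the 1e-7
relative log-slack above; LASSO penalties below 1e-8 are floored to keep
the coordinate-descent solver well-posed; censoring-distribution weights
are floored at 1e-12.

## Known limitations

* The regulator list ships the 25 regulators that are individually named
  in the source material for the signature; the remaining members of the
  full 30-regulator panel can be appended from a user TSV.
* The reversal screen assumes exactly two phenotype groups; multi-group
  designs are only supported descriptively through reversal proportions.
* `hypergeometric_overlap` is a generic enrichment utility; curated
  CLIP-verified pair sets must be supplied by the user.
* Calibration estimates the baseline hazard on the evaluation cohort
  itself, which is the usual practice for fixed linear scores but means
  calibration intercepts are not externally validated.
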