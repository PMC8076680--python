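# Methods

## The rank-pair risk model

Let `x_g(i)` be the expression of gene `g` in sample `i` (any non-negative
scale).  For an oriented immune-gene pair `(A, B)` the feature is the
indicator `z_AB(i) = 1{x_A(i) > x_B(i)}`; ties score 0 (the rule is stated
for a strict comparison, and "not higher" maps to 0).  The risk index is
the linear combination `IRGPI(i) = Σ_k β_k z_k(i)` and a sample is called
high-risk iff its index strictly exceeds a fixed cutoff (a tie at the
cutoff is low-risk; the convention is arbitrary but fixed).

The point of the construction is invariance: any strictly increasing
per-sample transform of expression — affine rescaling, log transforms,
rank replacement, quantile shifts applied within one sample — leaves every
indicator, hence every index, bit-identical.  Cross-platform transfer then
needs no normalisation at all.  The test suite asserts this invariance
exactly, not approximately.

### Signature fitting

1. **Variable-gene filter.** Genes with scaled median absolute deviation
   ≤ 0.5 are discarded.  MAD is `median(|x − median(x)|) × 1.4826`; the
   1.4826 consistency constant is the default of the common statistical
   environments, and the threshold applies to that scaled value.
2. **Pair construction.** All unordered pairs of immune genes present in
   the expression matrix, one orientation per pair (lexicographically
   smaller symbol first; a published signature keeps its stored
   orientations verbatim).  Pairs whose minority indicator frequency is
   below `min_minor_freq` (default 0.2) are dropped: a nearly constant
   indicator cannot carry prognostic information, and the pruning
   threshold is configurable because no canonical value exists.
3. **Univariate screen.** A pair survives when both its single-covariate
   Cox Wald p-value and the two-group log-rank p-value are below `alpha`
   (default 0.05, configurable).  The two tests are asymptotically
   equivalent for a binary covariate, so the joint rule behaves like a
   single test at `alpha`; the screen's null retention rate is measured by
   the calibration experiment (~5%).
4. **Lasso-Cox selection.** L1-penalised Cox partial likelihood maximised
   by coordinate descent (scikit-survival's Coxnet) over a log-spaced
   penalty grid whose largest value zeroes all coefficients.  K-fold
   (default 10) cross-validated deviance uses the Verweij–Van Houwelingen
   leave-fold-out construction, `dev_k = −2[pl_full(β_k) − pl_train(β_k)]`
   with Breslow ties; folds are seeded and stratified by event status,
   which noticeably stabilises the deviance curve in simulations.  The
   selected penalty minimises mean CV deviance (`lambda.min`), with
   `lambda.1se` available by configuration.  Features are left
   unstandardised: the indicators live on a common binary scale.
5. **Cutoff.** One-year (365-day) time-dependent ROC of the fitted index,
   cumulative-case / dynamic-control definition with Kaplan–Meier
   conditional survival inside score strata:
   `sens(c) = P(X>c)(1−S(t|X>c))/(1−S(t))`,
   `spec(c) = P(X≤c)S(t|X≤c)/S(t)`.  Cutpoints are midpoints between
   consecutive unique scores plus open ends; AUC is the trapezoidal area
   after sorting the (1−spec, sens) points and anchoring (0,0) and (1,1);
   the cutoff maximises the Youden index `J = sens + spec − 1`, the
   standard optimal-cutpoint rule when none is otherwise specified.
   Coordinates are snapped at 12 decimals before integration so that
   censoring-free staircases integrate exactly (the no-censoring AUC then
   equals case/control concordance to machine precision).

### Survival statistics

`cox_fit` maximises the partial likelihood by Newton–Raphson with
step-halving, Efron tie correction by default (Breslow by option),
convergence at max |score| < 1e−8 or 50 iterations; a monotone likelihood
(perfect separation) warns and stops at the cap.  Constant or collinear
covariates are rejected rather than silently dropped.  Hazard ratios carry
normal-approximation 95% intervals (`exp(β ± 1.96·se)`).  Untied data take
a fully vectorised prefix-sum path — the univariate screen fits thousands
of single-covariate models per simulated cohort, so per-fit overhead
matters.  The two-group log-rank uses the observed-minus-expected sum over
event times with hypergeometric variance and a 1-df chi-square; the
Kaplan–Meier estimator carries Greenwood variance bands.  Age is modelled
continuous in the Cox tables; gender is coded male = 1.

### Enrichment

**ssGSEA.** Per sample, genes are ranked by expression (average ranks on
ties, rank N for the highest).  Walking the ranking top-down, the in-set
cumulative weight uses rank^tau (tau = 0.25, the cited implementation's
default) and the out-of-set cumulative count is uniform; the enrichment
score is the sum of their differences over all positions (the integrated,
not maximal, deviation).  Scores are normalised by the global max−min of
the score matrix.  Only within-sample ranks enter, so ssGSEA inherits the
platform invariance of the pair features.

**Preranked GSEA.** Genes ranked by
`log2((mean_high + ε)/(mean_low + ε))` with pseudocount ε = 0.01 (guards
zero means; configurable), ties broken by gene symbol for determinism.
The running sum increments hits by `|score|^p / Σ_hits |score|^p` (p = 1)
and decrements misses by `1/(N − |S|)`; ES is the signed maximal
deviation, ties towards the positive extreme.  The null permutes gene
labels (seeded, vectorised); NES divides ES by the mean |null ES| of
matching sign, and the nominal p is `(1 + #{same-sign nulls ≥ |ES|}) /
(#same-sign nulls + 1)` — the same-sign denominator is what keeps the null
rejection rate at the nominal level (measured 0.04–0.06 at α = 0.05), and
matches the convention of the standard enrichment libraries.
Benjamini–Hochberg adjusts across sets.

**Comparisons.** Mann–Whitney U is exact for group sizes ≤ 8 without ties
(making toy examples reproducible) and tie-corrected normal otherwise;
stars follow NS / * / ** / *** / **** at 0.05 / 0.01 / 0.001 / 0.0001.
Spearman correlations use average ranks and the t approximation with n − 2
df; perfect correlations report the smallest representable positive p.  No
multiplicity correction is applied across the correlation matrix — the
flags deliberately mirror raw-threshold reporting.  PD-L1 is addressed by
its gene symbol CD274 via a small alias map.

## The synthetic cohort generator

The generator emulates the two-cohort design the pipeline targets:
discovery n = 149 and validation n = 374 by default, matching the cohort
sizes of the glioblastoma setting.

* **Expression.** Per-gene log-normal: `log x_g ~ N(μ_g, 0.5)` with
  `μ_g ~ U[1, 4]`.  The family is arbitrary by design — every downstream
  statistic is rank-based — but it gives realistic positive, right-skewed
  values.
* **Planted pairs.** For each planted pair the two genes' values are
  swapped within a sample where needed so the indicator is an exact
  Bernoulli(0.5) coin; default coefficients (±0.29–0.56, mixed sign)
  mirror the magnitude range of published pair signatures.
* **Survival.** `T_i ~ Exponential(h₀ · exp(η_i))` with
  `η_i = Σ β_k z_k(i)` and `h₀ = ln 2 / 400` per day (≈ 400-day baseline
  median, a realistic glioblastoma scale).  Censoring is independent
  `U(0, c)` with `c` solved numerically so the expected censoring fraction
  hits `censor_rate` (default 0.3).
* **Platform distortion.** A strictly increasing per-sample transform:
  affine, log-affine (power-law), or full rank-preserving random
  replacement.  Validation cohorts default to log-affine to emulate
  cross-platform transfer.
* **Immune signal.** Member genes of a planted immune set are shifted by
  ±1.0 on the log scale in samples with above-median η.  The effect size
  makes ssGSEA group differences reliably detectable at n ≈ 150, which is
  what the infiltration-comparison tests need to exercise their logic.
* Clinical covariates (age, gender, radiotherapy, chemotherapy) are drawn
  independently of survival, so multivariate Cox tables should show risk,
  and only risk, as prognostic.

What the generator does **not** emulate: gene–gene correlation structure,
batch effects beyond monotone distortion, competing risks, non-proportional
hazards, or informative censoring.  Passing tests therefore demonstrate
the pipeline's statistical machinery under its own model assumptions, not
performance on real tumour data.

## Replicated experiments and problem sizes

`irgpi.experiments` packages the operating-characteristic studies used by
the test suite and the reproduction script:

* **Recovery** (25 replicates): discovery n = 300, five planted pairs with
  |β| ∈ {0.35, 0.4, 0.45, 0.5, 0.55} among 200 noise pairs built from
  genes disjoint from the planted ones (pairs sharing a planted gene are
  correlated proxies, not noise).  Recovery is measured on the
  cross-validated lasso selection over the candidate features — the
  operation whose parameter-recovery behaviour is being characterised —
  and transfer as the log-rank p of the fitted signature and ROC cutoff on
  an independently log-affine-distorted validation cohort (n = 374).
  Note the full chain with the univariate screen ahead of the lasso
  recovers less often: at these effect sizes the screen's marginal power
  is ~0.6–0.7 for the weakest pairs (omitted covariates attenuate the
  marginal hazard), which is worth knowing when applying the pipeline at
  similar scales.
* **Null calibration** (50 replicates): same design with all planted
  coefficients zero; measures the screen's retention fraction (~5% at
  α = 0.05) and the rate at which a fitted (spurious) signature separates
  the validation cohort (≤ 10%; finding no signature counts as a correct
  non-rejection).
* **GSEA null** (100 lists × 10 random sets, 200 permutations): fraction
  of nominal p < 0.05 under i.i.d. normal scores.

These sizes keep each study to a few minutes on one CPU while leaving the
binomial error on the measured rates well inside the margins asserted.

## Known limitations

* The time-dependent ROC uses the simple Kaplan–Meier plug-in, which can
  produce locally non-monotone curves under heavy censoring (the
  nearest-neighbour smoothed variant is not implemented).
* Lasso selection at `lambda.min` is liberal: fitted signatures often
  include noise pairs alongside true ones, and at discovery n = 149 the
  cross-validated deviance curve can be flat enough that no signature is
  selected or transfer fails for some simulation seeds.
* The packaged immune gene list and 30-cell-type marker panel are
  synthetic stand-ins (structure, counts and the nine signature genes'
  categories are faithful; the broader memberships are illustrative).
* No proportional-hazards diagnostics, time-varying covariates, competing
  risks, or >2-group log-rank.
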