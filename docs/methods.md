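# Methods

## Data model

A study records, per subject, a binary index test result T, a
verification indicator V, and gold-standard disease status D observed
only where V = 1. Every estimator in the package is a function of the
six-cell sufficient statistic: the verified 2×2 table
(s₁₁, s₁₀, s₀₁, s₀₀) of (T, D) counts plus the unverified counts
(u₁, u₀) by test result. Subject-level inputs are therefore reduced to
counts internally; unverified subjects carry an explicit missing marker
(NaN), never a sentinel value, so no estimator can silently use them.

## Missingness model and synthetic data

The generator draws complete data multinomially over the four (T, D)
cells with probabilities

    π₁ = Sn·p,  π₂ = (1−Sn)·p,  π₃ = (1−Sp)(1−p),  π₄ = Sp(1−p),

then verifies each subject Bernoulli with probability pv₁ = P(V=1|T=1)
or pv₀ = P(V=1|T=0) and masks D where unverified. Defaults are
pv₁ = 0.8, pv₀ = 0.4 — the classic clinical work-up pattern in which a
positive test doubles the chance of gold-standard referral. The
implied overall verification fraction is
P(V=1) = pv₁·P(T=1) + pv₀·P(T=0); for the standard scenario grid this
is 0.59/0.52/0.64 (p = 0.4) and 0.57/0.46/0.58 (p = 0.1) across the
(Sn, Sp) pairs (0.6, 0.6), (0.6, 0.9), (0.9, 0.6).

Verification here depends on T only. The generator does not emulate
verification driven by covariates or by unrecorded clinical suspicion
(which would be MNAR), correlated tests, or multi-category results; a
passing simulation says nothing about those settings.

The Monte-Carlo engine uses a count-level equivalent of the
subject-level generator: one multinomial draw over the four complete
cells followed by binomial thinning of each cell with its verification
probability. The two paths are identical in distribution (checked by
test); the count path is what makes 500-replicate studies run in
seconds.

## Estimators

With p̂ₜ = P̂(D=1 | T=t, V=1), k_t the verified count in stratum t, and
P̂(T=1) taken over all N subjects:

* **FDA** — Sn = s₁₁/(s₁₁+s₀₁) on fully verified data; Wald intervals.
* **CCA** — the same formulas on the verified subset. Under MAR its
  large-sample limits are Sn·pv₁/(Sn·pv₁+(1−Sn)·pv₀) and the mirror
  expression for Sp — exposed as `cca_asymptotic_sn_sp`, the oracle for
  simulation checks.
* **BG** — Bayes-theorem reassembly from P̂(T) and predictive values.
  The interval is a delta-method normal interval for logit(Sn) with
  variance 1/(N·P̂(T=1)P̂(T=0)) + (1−p̂₁)/(k₁p̂₁) + (1−p̂₀)/(k₀p̂₀) (the
  Sp analogue swaps p̂ₜ for 1−p̂ₜ), back-transformed, which keeps
  endpoints inside (0, 1). A bootstrap interval is available through
  the IPWE machinery; the two agree closely at large N (tested). The
  exact historical variance formula for this estimator is not uniquely
  settled, which is why both routes exist.
* **IPWE** — Horvitz–Thompson weighting of verified subjects by the
  inverse fitted propensity. With the saturated propensity fit it
  coincides with BG to machine precision (asserted at 1e−12 on random
  tables). Intervals: nonparametric BCa over resamples of all N
  subjects with the propensity refitted per resample; the jackknife
  uses the six distinct leave-one-out values expanded by multiplicity.
* **MI** — proper multiple imputation from logit P(D=1|T) = β₀ + β₁T.
  The model is saturated, so the asymptotic posterior of (β₀, β₁) is
  equivalent to independent normal posteriors of the two stratum
  log-odds; each imputation draws the log-odds, fills missing D
  binomially, and computes the full-data estimates; pooling follows
  Rubin's rules with the classic (m−1)(1 + W/((1+1/m)B))² degrees of
  freedom (no small-sample adjustment). Default m: 100 in simulation,
  the percentage of incomplete cases for data analysis.
* **IPB** — the verification propensity PS = P(V=1|T) is fitted by
  logistic regression of V on T (saturated, so the stratum verified
  fractions exactly; a known PS may be supplied instead for oracle
  experiments). Normalized inverse-propensity weights
  wᵢ = (1/PSᵢ)/Σⱼ(1/PSⱼ) over the n complete cases define a weighted
  resample of size n — the debiased synthetic dataset. The default
  (`variant="debias_once"`) draws that synthetic dataset once and then
  b ordinary bootstrap resamples of it; the point estimate is the mean
  of the per-resample Sn/Sp, the SE their SD, the interval the normal
  bootstrap interval clipped to [0, 1]. This matches IPB's purpose —
  produce debiased data usable by any downstream full-data analysis —
  and carries the corresponding extra resampling variance, which is why
  IPB is systematically less precise than BG/IPWE/MI in the simulation
  study (most visibly at N = 200 and low prevalence, where the diseased
  group in the n verified subjects is small). `variant="weighted"`
  instead averages b direct weighted resamples, a smoothed estimator
  whose replicate SD matches the plug-in IPWE; `point="plugin"` reports
  the direct weighted estimate.

  Because verified subjects fall into four exchangeable (T, D) types,
  weighted resampling is a four-cell multinomial; the count-level
  resampler is distributionally identical to literal subject-level
  resampling (KS-tested) and is the default path.

## Numerical conventions and degenerate inputs

* Bootstrap resamples with no diseased (or no non-diseased) subjects
  leave Sn (or Sp) undefined; the affected quantity is excluded from the
  mean/SD and counted, with a warning above 1% incidence. Imputing an
  arbitrary value instead would bias the estimate toward it.
* A verified test stratum with a single observed disease outcome makes
  the MI logistic likelihood degenerate (perfect separation). The
  default is an error advising a larger verified sample or a different
  method; `on_separation="augment"` adds half a pseudo-success and half
  a pseudo-failure to each degenerate stratum before fitting, the
  standard data-augmentation repair.
* A test stratum with zero verified subjects makes the inverse
  weighting undefined; propensity fitting fails loudly rather than
  returning a zero.
* BCa intervals use the conventional probit-scale interpolation between
  bootstrap order statistics; equal replicates degenerate to a point
  interval with a warning. All probability-scale intervals are clipped
  to [0, 1] after construction, with unclipped endpoints retained for
  diagnostics.

## Monte-Carlo engine

`run_cell` runs B replicates of one scenario. Per replicate, all
requested methods see the same masked dataset (common random numbers,
so method contrasts carry less noise) and FDA sees the pre-masking
data. Replicate streams derive from (master seed, replicate index),
making each replicate independently reproducible. Bias is the mean
estimate minus the truth; SE is the SD over replicates with the B−1
denominator.

A replicate on which any requested method is inestimable is dropped for
**all** methods, keeping the comparison paired: every summary row of a
cell refers to the identical replicate set. The reported metrics are
therefore conditional on joint estimability. This matters in exactly
one region of the default grid — low prevalence with high sensitivity
at N = 200, where roughly half the replicates contain no verified
false negative, the MI model is separated, and the conditioning pulls
every method's mean Sn down by a few points (CCA's conditional mean
lands near the truth there only as an artifact of this selection, not
because the complete-case analysis has become valid). The dropped
count is logged and reported; a cell aborts if more than 75% of
replicates are dropped. Study defaults: B = 500 replicates, b = 1000
bootstrap samples, m = 100 imputations, full grid
{0.4, 0.1} × {(0.6, 0.6), (0.6, 0.9), (0.9, 0.6)} × {200, 1000}.

These defaults complete in seconds thanks to the count-level fast
paths; the acceptance script runs every reported quantity at the full
B = 500.

## Known limitations

* Verification may depend only on the binary test result; no covariate
  propensities, no MNAR sensitivity analysis.
* Coverage of the confidence intervals is not evaluated by the
  simulation engine (bias and SE only).
* The BG analytic interval uses a first-order delta method; at very
  small strata prefer the bootstrap route.
* IPB's SE reflects the single-synthetic-sample design above; users
  wanting the smoothed estimator should select `variant="weighted"`
  explicitly.
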