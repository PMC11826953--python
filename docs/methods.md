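# Methods

## The problem and the model

Macronutrients compete for a fixed energy budget: eating relatively more
protein necessarily means relatively less of something else.  Analysing
each nutrient's association with sleep in isolation therefore answers an
ill-posed question.  `dietsleep` treats the macronutrient profile as a
composition — the 5-part vector of energy shares

x = (protein, carbohydrate, saturated fat, monounsaturated fat,
polyunsaturated fat),  x_i > 0,  Σ x_i = 1,

obtained by weighting gram intakes with 4 kcal/g (protein, carbohydrate)
and 9 kcal/g (each fat class) and closing the result.  Statistics are done
in Aitchison geometry: a composition is mapped to D−1 = 4 unconstrained
balance coordinates by an isometric log-ratio (ilr) transform, z = B ln x,
with B an orthonormal sequential-binary-partition basis.  Pivot bases put
one nutrient into the first balance,

z1 = sqrt((D−1)/D) · ln( x_focal / g(rest) ),

where g(·) is the geometric mean; positive z1 means the focal nutrient
sits above the geometric mean of the others.  Distances in ilr coordinates
do not depend on the basis, so model predictions are basis-invariant and a
single default-basis fit per outcome serves every focal nutrient.

Each sleep outcome y (total sleep time in hours, sleep-onset latency in
minutes, %WASO — wakefulness after sleep onset as a percentage of the
sleep period) is modelled by OLS:

y = β0 + β'z + γ1·age + γ2·female + γ3·BMI + ε.

Two estimand families are derived from a fitted model, both evaluated at
the cohort's compositional mean x̄ (the closed vector of componentwise
geometric means):

* **Proportional reallocation** — displace a fixed share δ of energy into
  (or out of) one nutrient, scaling the remaining shares proportionally;
  the estimand is the difference in model predictions between ilr(x̄') and
  ilr(x̄).
* **Isotemporal (one-to-one) substitution** — move δ from one nutrient to
  another, all other shares untouched.

Confidence intervals use the exact linear-model algebra: for design rows
x1, x0 and d = x1 − x0, the interval is d'β̂ ± t_{df,(1+level)/2} · s ·
sqrt(d'(X'X)⁻¹d), where s is the residual standard error.  Covariate
columns identical in both rows cancel, so the estimands do not depend on
where the covariates are held (verified bit-exactly in the tests).

The third analysis is conventional: each exposure (total energy,
energy-adjusted macronutrient percentages, sodium, potassium, fiber, the
sodium-to-potassium mass ratio) is cut at its 25th/50th/75th sample
percentiles (linear-interpolation convention, right-closed intervals) and
each outcome regressed on quartile dummies (lowest quartile as reference)
plus age, sex and BMI, all forced into the model.

## Key parameters

| parameter | default | meaning |
| --- | --- | --- |
| δ (delta) | 0.06 | displaced energy share; capped by the share being drained, and at the reference mean composition the binding cap is the smallest share (polyunsaturated fat ≈ 6.5 %), which is why 6 % is the default |
| level | 0.95 | two-sided CI level; t critical values, never a normal approximation |
| min_days | 7 | minimum retained days in *each* record stream |
| z_cut | 3.0 | total-sleep-time outlier bound in sample-SD multiples |

## The exclusion cascade

`apply_exclusions` removes, in order: (1) rows with a missing sleep
summary (missingness in any other analysis variable also removes the row,
with a logged reason — tallied in the same ledger stage); (2) rows whose
total sleep time lies outside mean ± z_cut·SD, with mean and sample
(n−1) SD computed once on the post-stage-1 cohort; (3) rows with fewer
than `min_days` days in either stream.  The ledger reconciles by
construction.  Note that the 3-SD rule on a normal sample is not
idempotent: re-applying the cascade to its own output recomputes a tighter
SD and can trim a further ~0.3 % of rows.  The fixed-point property holds
only for cohorts whose sleep times are strictly inside the recomputed
band, and the test suite asserts it on exactly such a fixture.

Upstream of the cascade, `filter_complete_meal_days` keeps only days with
all three meals logged (a missing meal is indistinguishable from a skipped
recording), and `restrict_overlap_and_average` averages each participant's
days inside the overlap of the two record streams.

## The synthetic cohort

No participant-level data are deposited, so the pipeline is validated
against a seeded simulator whose defaults are the reference cohort's
published marginal structure: n = 4825, 81.6 % female, age 36.7 (10.4) y,
BMI 24.8 (4.8) kg/m², TST 6.7 (1.1) h, SL 21.5 (12.1) min, %WASO 9.9
(7.2), energy 1662.6 (330.3) kcal/d, fiber 11.7 (3.5) g/d, potassium
2295.3 (602.1) mg/d, Na/K ratio 1.6 (0.4), and mean composition
(0.182, 0.538, 0.097, 0.118, 0.065).  The reported per-nutrient %kcal
means are mutually inconsistent with closure (they sum to 101.7, plausibly
because their denominators include non-macronutrient energy); the
generator targets the closed composition, not those rows.

Design choices:

* **Compositions** are logistic-normal: balances drawn from a normal
  centred at ilr of the mean composition with diagonal SD 0.12 per
  coordinate and back-transformed — the simplest family guaranteeing
  positivity and closure when only marginal summaries are available.
* **Planted effects.**  The default scenario plants three reallocation
  effects (add-6 %-protein → TST +0.27 h; add-6 %-monounsaturated → SL
  +4.64 min; add-6 %-polyunsaturated → SL −4.72 min), each as a
  coefficient on its focal pivot balance.  Because a reallocation aimed at
  one nutrient also moves the other focal balances, coefficients sharing
  an outcome are solved jointly from a small linear system so every
  model-implied difference equals its target exactly (verified to 1e-9 in
  the tests).  The systematic part is centred empirically, preserving the
  marginal means.
* **Noise.**  TST noise is normal, truncated to (0, 14] h; SL and %WASO
  noise is gamma, moment-matched so the total variance meets the marginal
  SD — normal noise would produce negative times.  The noise variance is
  the marginal variance minus the realised variance of the systematic
  part (floored at (0.05·SD)²).
* **Covariate slopes** are not published; the sex contrasts mirror the
  cohort's male/female gaps (TST +0.2 h, SL −2.4 min, %WASO −3.9 for
  women) and small fixed age/BMI slopes (−0.005 h/y, −0.01 h per kg/m²
  for TST, 0.05/0.1 for the other outcomes) make the adjustment
  non-trivial.  Age is truncated to [18, 80] y and BMI to [14, 60] kg/m²
  as plausibility bounds.
* **Sodium is derived** as (lognormal Na/K ratio) × (lognormal potassium),
  so the mean ratio is controlled directly in expectation rather than
  emerging from two marginals.
* **Exclusion planting.**  A roster can carry missing-sleep rows (NaN
  sleep summary), TST outliers planted symmetrically at mean ± 6 SD —
  far enough outside the stage-1 band (which the outliers themselves
  inflate to roughly ±5.9 clean SDs) that the cascade separates them from
  clean rows — and short-usage rows with 1–6 days per stream.
* **Daily logs** multiply participant-level values by mean-one lognormal
  noise (CV 0.15 by default) over 28 days with completeness probability
  0.8, so averages over retained days reproduce the participant values in
  expectation.

What passing tests do *not* show about real data: the simulator has no
day-of-week or seasonal structure, no correlation between diet and
app-usage propensity, no measurement error model for the accelerometer or
the food database, and its diet–sleep effects are linear in the balances
by construction.  Recovery of the planted effects validates the
estimation machinery, not the substantive findings.

## Numerical conventions

* Sample (n−1) SDs throughout; a single-row group reports SD 0.
* Quartile cutpoints via linear interpolation; intervals closed on the
  right (a value equal to a cutpoint falls in the lower quartile) —
  labels shift under other percentile conventions, hence the choice is
  documented and tested.
* OLS via explicit normal equations with a rank pre-check; rank-deficient
  designs raise an error naming the collinear columns (identified by
  pivoted QR).  Fits agree with an independent solver to 1e-8 on random
  problems.
* alr/ilr round-trips hold to 1e-10; every operation returning a
  composition is closed to 1e-9 and strictly positive.
* Reallocation feasibility: the displacement may not exceed the share
  actually being drained (focal share in take mode, the complement of the
  focal share in add mode, the donor share in a pairwise swap) minus 1e-6.
  Add and take with the same δ are exact mutual inverses.
* Compositions require strict positivity; zero gram intakes upstream
  should be replaced by a small positive mass (0.1 g) before closure.
* No multiple-testing correction is applied anywhere; significance flags
  mean the 95 % CI excludes zero.
* Determinism: one `numpy` Generator seeded from the config drives each
  generated table; identical configs give byte-identical CSV output.  The
  pipeline's tabular artifacts are byte-stable across reruns; only the run
  log contains timestamps.

## Problem sizes used in validation

Generator-marginal and recovery checks run at the study scale
(n = 4825); the recovery suite uses 20 replicate seeds and requires ≥80 %
CI coverage of each planted value.  The CI-coverage property uses 1000
simulated null datasets of n = 50–60; transform round-trips use 1000
random compositions; the OLS oracle uses 100 random small problems.  The
acceptance script averages each recovered reallocation estimate over 16
replicate cohorts, which reduces its Monte-Carlo standard error to about
0.013 h (TST cell) and 0.19–0.24 min (SL cells) while leaving the
estimator unchanged.

## Known limitations

* The balance-linear outcome model is the estimation model; real
  diet–sleep relations need not be linear in log-ratio space.
* Estimands are evaluated at the compositional mean only; effects at
  other points of the simplex differ whenever the model is nonlinear in
  the original shares (it always is, through the log).
* The exclusion cascade computes outlier bounds once; iterated trimming
  would remove slightly more rows.
* Cross-sectional by design: nothing here supports causal claims about
  changing diet to change sleep.
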