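# Methods

## 1. Item scoring

A menu item's Fast-Food Health Score (FFHS) is the number of satisfied
criteria among seven, each expressed relative to the item's energy content.
Gram quantities are converted to energy shares with the Atwater factors
(9 kcal/g fat, 4 kcal/g carbohydrate and protein); sodium is compared per
calorie and fiber per 100 calories.  Defaults (`ScoringCriteria`):

| component | rule | default |
|---|---|---|
| fat | share in window | [0.20, 0.35] |
| saturated fat | share below | 0.10 |
| sodium | mg/kcal below | 1.15 |
| carbohydrate | share in window | [0.45, 0.65] |
| fiber | g per 100 kcal at least | 1.4 |
| sugars | share below | 0.10 |
| protein | share in window | [0.10, 0.30] |

Conventions, all explicit and configurable:

* **Boundaries.** "Between a and b" is read as the closed interval
  (`boundary_policy="closed_windows"`, default); an open-window variant is
  provided.  One-sided rules keep their literal reading under either
  policy: "less than" is strict, "or more" inclusive.
* **Zero-calorie items.** Energy shares do not exist at 0 kcal.  Under the
  default `undefined_share` policy every share-based and per-calorie
  criterion is unsatisfied while the fiber floor (≥ 1.4 g per 100 kcal →
  ≥ 0 g) is trivially met, so water and diet drinks score 1.  The stricter
  `no_points` policy scores them 0.  Published item examples do not pin
  down which convention the original analysis used (a zero-score energy
  drink is consistent with neither literal reading), so both are shipped
  and the choice is surfaced rather than hidden.
* **Missing nutrients.** Scoring refuses incomplete profiles by default
  (`missing_policy="error"`), naming the item and field; opt-in zero
  imputation logs a warning.  Silent zeros would corrupt scores when
  nutrition data are assembled from heterogeneous sources.
* **No rounding.** Awards compare exact floating-point shares against the
  thresholds; shares are never rounded first.  Scale invariance
  (score(k·profile) = score(profile)) holds because every criterion is a
  ratio to calories.

## 2. Aggregation

Each ledger row is one purchased item; baskets appear as multiple rows, and
item modifications ("no lettuce") never alter the scored base profile.  A
configurable calendar maps timestamps to semesters (default: fall =
Aug 1–Dec 31, spring = Jan 1–May 31, summer rejected as out of term;
rejections are counted, never silently dropped).  The Student Average FFHS
for a (student, semester) cell is the transaction-weighted mean — each
purchase counts once, so buying the same item ten times weights it ten
times.  `n_items`, `total_spend` and rejection counts are carried for
weighting and conservation checks (spend in = spend aggregated + spend
rejected).  A student active in several semesters contributes one
independent record per semester.

## 3. Regression

Weighted least squares with weight = `n_items`, the literal encoding of
"variance inversely proportional to the number of items purchased".  This
is exactly correct under the generator below: records are means of i.i.d.
per-transaction scores, so Var(avg | x, n) = σ²/n.  Weights are not
normalised (coefficients are invariant to weight scale).  Sexes are fitted
as fully separate regressions with separate residual variances, not as
interaction terms.  Covariate scaling follows the reporting convention:
spend in hundreds of dollars, recreation visits per 10; race/ethnicity
dummy-coded against White; GPA enters the regression continuously (0–4)
while the descriptive table also bands it (0.01–2.0 / 2.01–3.0 / 3.01–4.0).
Classical WLS standard errors are the default with HC1 robust errors behind
`RegressionSpec(robust=True)`; p-values are raw, starred at 0.05/0.01, with
no multiplicity adjustment.  Repeated student-semesters are treated as
independent observations (no clustering), matching the estimand of the
stratified per-semester design; a cluster-robust option was considered and
deliberately left out of scope.

Degenerate inputs: rank-deficient designs raise an error naming the
collinear columns (pivoted-QR diagnosis); zero-weight records are excluded
with a logged count; a stratum needs at least two distinct outcome values.
The sex comparison reports weighted and unweighted stratum means and a
Welch two-sample test, skipped with an explanation when a stratum has fewer
than two records.

## 4. Synthetic data-generating process

The generator fabricates the three input tables with known ground truth.
All randomness derives from one seed (stage-local `numpy` generators are
spawned deterministically from it), and identical (seed, config) pairs give
byte-identical CSVs.

**Catalog.**  Each item draws a target score from
`target_score_distribution` (default `(0.03, 0.12, 0.27, 0.30, 0.15, 0.08,
0.04, 0.01)` over scores 0–7: mode 3, mean m₀ = 2.87, matching the reported
shape of the real menu where most items score 2–3).  The passing subset of
criteria is uniform among the C(7, k) possibilities, and each nutrient is
drawn uniformly from an interval strictly inside (or outside) its
threshold, so the realized score equals the target exactly — verified
internally on every generation — and boundary logic is exercised without
ever sitting on a boundary.  Calories are uniform on [50, 800].  Profiles
are score-exact but not constrained to be compositionally consistent
(saturated fat may exceed total fat when the drawn pattern demands it);
menu realism is a non-goal.

**Cohort.**  Covariate marginals default to the studied population: 44.4%
female, race 22/5/7/59/7% (African American / Asian-Pacific Islander /
Hispanic / White / Other), 2% international, 33.1% low income, age discrete
with median 19 and IQR 2, GPA bands 13/33/54% with uniform fill, dining
visits ≈ NB(mean 44.9, SD 27.9), recreation visits ≈ NB(mean 17.7,
SD 30.7).  These are documented defaults, not claims about any real
population.  Demographics are fixed within a student; behavioural
covariates are redrawn each semester.

**Ledger.**  Per record: transaction count 1 + NB(mean 44, dispersion 2.3)
and i.i.d. Gamma prices (mean $6.75, CV 0.25), reproducing semester spend
≈ $303 (SD ≈ $208).  Price paid is drawn from the spend model rather than
copied from the chosen item, which keeps spend exogenous so a spend effect
can be planted directly.  Item choice is a tilted discrete choice over
score strata: with linear predictor

&nbsp;&nbsp;η = offset_sex + β_sex′(x − x̄_sex) + ε,&nbsp;&nbsp;ε ~ N(0, noise_scale²) i.i.d. per transaction,

the transaction's score is forced to 7 with probability η/(7−m₀) when η ≥ 0
(to 0 with probability −η/m₀ when η < 0) and otherwise drawn from the base
catalog distribution; the item is then uniform within its score stratum.
This mixture construction makes **E[score | x] = m₀ + η̄ exactly** — affine
in the covariates over the whole feasible range |η̄| ≤ min(m₀, 7−m₀) — so
the WLS estimand is literally correct and parameter recovery is a fair
test.  (A log-linear tilt was rejected because its mean response is only
approximately affine.)  Default planted effects β_sex are the published
stratified coefficients per sex, on the same covariate scale the regression
uses; sex offsets (0 / −0.05) land the female and male means near 2.87 and
2.82 and the overall mean near 2.85.  Per-sex centering of covariates makes
the within-sex expected mean equal m₀ + offset exactly.

Because per-transaction scores are i.i.d. given the record, the null
(all-zero effects) simulation yields an exactly-specified WLS model, which
is what makes the 5%-level rejection-rate calibration check meaningful.

## 5. Problem sizes and tolerances

Tests and the acceptance script choose sizes where Monte-Carlo error is
well separated from the tolerance: oracle equivalence on 10,000 random
profiles (exact match required); aggregation versus brute force on a
≥10,000-row ledger (exact counts, 1e-9 on sums); WLS vs OLS at equal
weights to 1e-10; parameter recovery over 20 seeds × 5,000
student-semesters with planted effects ≥ 0.02 score units (3-SE coverage
and sign recovery ≥ 95%); null calibration over 200 simulations of 400
students (3-SD binomial band around 5%; the small-design international
share is raised to 10% purely to keep the dummy column full rank at that
cohort size).  Marginal checks use 3-SD binomial bands.  The acceptance
script runs the full default scale (3,781 items; 35,448 records; ≈1.6M
transactions) in seconds because generation and aggregation are fully
vectorised.

## 6. Known limitations

* The generator has no behavioural realism: no menus, outlet popularity,
  meal timing, price–item coupling or refunds; passing tests demonstrate
  statistical correctness of the pipeline, not fidelity to any real campus.
* Dining-hall (buffet) consumption is unobservable in this design and out
  of scope; the spend covariate is declining-balance spend only.
* The affine-mean choice model implies some per-record variance
  heterogeneity beyond 1/n when effects are large; WLS point estimates
  remain unbiased and the effect on SEs at the default effect sizes is
  negligible, but the null-calibration guarantee is stated for the
  zero-effect configuration.
* Item-level component prevalences are a consequence of the
  uniform-subset construction (every component ≈ mean/7), not matched to
  any published per-component table.
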