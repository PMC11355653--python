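# Methods

## Data model

A cohort is a participants × variables table over a fixed measurement grid:
8 pelvic-floor parameters × 3 manoeuvres (rest, contraction, Valsalva) × up
to 4 pessary conditions (none, ring, ring with support, Falk). The
sacrococcygeal straight length and the pubococcygeal–sacral angle are
assessed only without a pessary, so the grid has 6·3·4 + 2·3 = 78 variables.
Lengths are in cm, the levator hiatal area in cm², angles in degrees; the
levator hiatal area is measured in the coronal plane but is kept in the same
flat grid (the imaging plane is metadata, not structure). On disk a cohort
is a flat CSV with columns `parameter__manoeuvre__pessary` (double
underscores, so multi-word parameter names parse unambiguously), plus
participant id, outcome and baseline characteristics; missing measurements
are empty cells, never sentinel numbers.

## Preprocessing

Variables are z-scored column-wise with mean and sample SD (n−1 denominator)
computed over observed entries only — missing cells are excluded from the
statistics and are replaced *after* normalization by 1×10⁻⁶, a value close
enough to the column mean (0 on the normalized scale) to leave the fitted
directions essentially untouched. The outcome is coded +1 (fitting) / −1
(non-fitting). A column that is constant within the data at hand maps to
all-zero z-scores with a logged warning rather than an error, because
resampling folds of a 15-participant cohort can easily produce constant
columns and the pipeline must not crash there.

## PLS1 and VIP

The regression is univariate-response PLS (PLS1) via NIPALS deflation. With
a single response the weight vector has the closed form
w_a = X_aᵀy_a / ‖X_aᵀy_a‖, so the algorithm is deterministic, and for one
response NIPALS and SIMPLS span the same score space and give identical
predictions. X and y are centred inside the fit (the design matrix is
already z-scored, but imputation and fold subsetting leave small residual
means), and the model carries an explicit intercept, so a row of zeros — the
normalized mean point — predicts the intercept. At the full component count
min(n−1, p) on complete full-rank data, PLS1 coefficients coincide with
ordinary least squares; this identity is used as an oracle in the tests,
with scikit-learn's PLSRegression as an independent cross-implementation
check (it is never used in the implementation itself).

The per-component explained variances are computed from the deflation
residuals; because scores are mutually orthogonal, the cumulative fractions
are non-decreasing and bounded by 1. If the deflated residual becomes
orthogonal to the response before the requested number of components, the
fit truncates with a warning rather than producing numerically meaningless
components.

VIP uses Wold's formula, VIP_j = √(p · Σ_a SSY_a w_ja² / Σ_a SSY_a) with
SSY_a = q_a² t_aᵀt_a and unit-norm weights, which enforces mean(VIP²) = 1.
Ranking ties are broken by the canonical grid order so reports are
deterministic.

**Component count.** No principled universal choice exists at n = 15; the
default is the smallest A whose cumulative explained response variance
reaches 0.9, capped at min(n−1, p), and every entry point accepts an
explicit component count instead.

## Variable selection and cross-validation

The default (two-stage) mode ranks variables by VIP once on the full cohort
and then cross-validates the top-k model for k = 1…10 — this mirrors the
two-stage initial-analysis / validation-study design, but it lets the
held-out participant influence selection, so reported accuracies carry
selection bias. A `nested` mode that re-selects the top-k inside every
training fold is provided for unbiased estimates; it is not the default
because the two-stage procedure is the reference workflow.

Normalization is likewise configurable: `global` (default) z-scores and
imputes the full matrix once and then folds — matching the stated order of
operations (normalize, impute, model) — while `fold` recomputes the
statistics within each training fold and projects the held-out rows onto
them.

Leave-one-out makes n predictions; leave-two-out iterates over all unordered
pairs {i, j}, fitting on the remaining n−2 and predicting both, which yields
n(n−1) predictions (14 per participant at n = 15, 210 in total) and fills an
n × n heatmap whose cell (i, j) is the call for participant i when {i, j}
was held out. The trichotomous rule maps ŷ > 0.1 to fitting, ŷ < −0.1 to
non-fitting and the closed middle band to unknown; boundary values go to
unknown because the middle zone is the conservative call. Unknown
predictions count toward the total but not toward accuracy, so
n_correct + n_incorrect + n_unknown = n_total always holds. The validation
model's component count defaults to min(k, n_train−1, A*) with A* the
automatic choice above. Percentages in reports are rounded to one decimal.

A training fold can be unfittable — a single outcome class (unavoidable
under leave-two-out when one class has only two members) or predictors with
no usable variation. The `degenerate_folds` policy either raises (default)
or records such folds' predictions as unknown calls, which keeps the
exhaustive-resampling count identities intact for degenerate inputs.

## Baseline statistics

Continuous characteristics use the pooled-variance independent-samples
t-test (Welch is an option); the implementation also accepts (n, mean, SD)
summaries, because published tables often provide only those — summaries
rounded to one decimal bound, but cannot pin, the p-value of the underlying
raw data. The whole-sample column is reconstructed from group summaries by
size-weighting the means and rebuilding the total sum of squares
(within-group + between-group) for the SD.

Ordinal variables use a Mann–Whitney U test with midranks; for combined
n ≤ 20 the two-sided p-value is exact by full enumeration of all
C(n, n₁) rank assignments (the permutation null conditions on the observed
value multiset, so ties are exact too); above that a tie-corrected normal
approximation is used.

Nominal variables use the exact conditional test with both margins fixed.
The two-sided rule sums the probabilities of all tables whose point
probability is at most the observed one (with a 1+1e−7 relative slack, the
convention shared by the major statistical packages); 2 × 2 tables use the
hypergeometric distribution directly and larger tables (needed for the
three-level avulsion row) are fully enumerated, capped at a total count of
30. The generic enumerator and the hypergeometric specialization agree to
1e−12 on 2 × 2 tables.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not the biology:

- **Group sizes** default to 9 fitting / 6 non-fitting.
- **Correlation** is per-parameter exchangeable: all conditions of one
  parameter share a participant-level component,
  x = μ + σ(√ρ·z_participant + √(1−ρ)·z_condition), giving correlation ρ
  exactly and a positive-definite block for ρ ∈ [0, 1). Repeated
  measurements of the same structure under different manoeuvres and
  pessaries are the physical source of collinearity, so correlation is
  modelled within parameters rather than via a global 78 × 78 matrix.
  Default ρ = 0.5 — the true magnitudes are unknown (raw clinical data are
  unavailable), and this value is an exposed, documented guess.
- **Effects**: six designated informative variables (three TVL conditions,
  CL at rest with ring-with-support, the sacrococcygeal angle on Valsalva
  with ring-with-support, the pubococcygeal angle at rest with ring) get a
  group-mean shift of 1.5 SD by default, positive in the fitting group.
- **Base means/SDs** are realistic per-parameter values (TVL 7.3 ± 1.2 cm on
  dynamic MRI at rest, levator hiatal area 25 ± 6 cm², angles far from the
  0°/360° bounds, so linear-scale generation without wrap-around is
  adequate).
- **Missingness** is MCAR at 2% by default (no missingness mechanism is
  known for the real data).
- **Baseline characteristics** (age ~ Normal(70, 8.5) years, group-specific
  BMI means 27.8/23.9 kg/m², parity, POP-Q stage, avulsion grade, …) are
  generated for the statistics module but never consumed by the PLS
  pipeline.

What passing tests on these cohorts show: the pipeline recovers designated
signal (all six informative keys in the VIP top 10 in ≥ 95% of seeds at
n = 100/100, effect 1.5 SD), behaves at chance on null cohorts (mean
leave-one-out accuracy within [0.3, 0.7] at n = 9/6 with a pre-specified
variable set — selection is deliberately excluded there, since re-selecting
on the full data would add selection bias to the null), and keeps every
bookkeeping identity. What they do not show: anything about real anatomy —
real effect sizes, non-Gaussian measurement error, informative missingness
and inter-parameter correlations are all outside the generator.

## Problem sizes and numerical choices

Simulation-backed tests use 10–50 seeds at n = 15 (9/6) and 20 seeds at
n = 200 (100/100); the whole suite and the acceptance script each run in
well under a minute on one CPU. Exact-test enumeration bounds are n ≤ 20
(Mann–Whitney) and total ≤ 30 (r × c tables). Numerical tolerances: score
orthogonality and VIP normalization at 1e−8, PLS-vs-OLS and
cross-implementation agreement at 1e−6, exact-test agreement at 1e−12.
Degenerate inputs (constant columns, unfittable folds, single-class
responses) have explicit, documented behaviour rather than incidental
crashes.

## Known limitations

- The two-stage default reports optimistically biased accuracies by design;
  use `selection="nested"` for honest small-sample estimates.
- VIP magnitudes depend on the component count, which the automatic rule
  fixes only by convention; rankings are more stable than magnitudes.
- The exact r × c test is limited to small tables (total ≤ 30) by
  enumeration cost.
- The generator's correlation structure is block-exchangeable; real
  inter-parameter dependence (e.g. TVL with CL) is not modelled.
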