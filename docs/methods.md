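# Methods

This note documents the statistical machinery in `hingeselect`: the model
and its assumptions, the defaults and why they are what they are, what the
synthetic generator does and does not emulate, and the numerical choices a
maintainer would need to know.

## 1. The classification model

Subjects are rows of a feature matrix; the outcome is binary with the
convention **+1 = the adverse class** (steroid-resistant, SRNS) and −1 the
favorable class (SSNS). The base classifier is a linear SVM on an
engineered design: `score(x) = β₀ + Σ features(x)·β`, class = sign(score),
with score 0 mapped to +1.

The hinge loss `L_H(β) = n⁻¹ Σ (1 − yᵢxᵢᵀβ)₊` is replaced during
optimization by the modified-logistic (softplus) surrogate

    L_γ(β) = (nγ)⁻¹ Σ log(1 + exp(γ(1 − yᵢxᵢᵀβ)))

which satisfies `0 ≤ L_γ − L_H ≤ log 2 / γ` termwise and converges to the
hinge as γ → ∞. Evaluation uses `log1p`/`logaddexp` identities and never
overflows.

**γ default = 50**, reached through a warm-started continuation schedule
γ ∈ {5, 10, 25, 50}: the surrogate at γ = 50 is nearly kinked and
ill-conditioned from a cold start, while each continuation stage is an easy
smooth problem whose solution seeds the next. Warm-started refits (e.g.
cross-validation folds) skip the schedule and solve at the final γ only.

## 2. Penalties and the selection stage

Supported penalties on non-intercept coefficients (intercept never
penalized):

| kind  | form | role |
|-------|------|------|
| ridge | λβ² | final-model regularization (no selection) |
| lasso | λ·abs(β) | convex selection baseline |
| SCAD  | three-branch, plateau `(a+1)λ²/2`, a = 3.7 | comparator |
| MCP   | `λ·abs(β) − β²/(2a)` then `aλ²/2`, a = 3.0 | comparator |
| TLP   | `λ·min(abs(β)/τ, 1)`, τ = 10⁻⁴ | the primary selector |

Two printed-formula ambiguities were resolved in favor of continuity: the
SCAD constant branch must be `(a+1)λ²/2` (the value its middle branch
attains at `aλ`), and the undefined symbol in the MCP first branch is read
as the coefficient magnitude, which makes its constant branch continuous.

**Optimizer.** Convex cases: damped Newton (ridge/unpenalized) or FISTA
(lasso). Nonconvex cases: an outer difference-of-convex (DC) loop —
equivalently local linear approximation — that replaces the penalty by the
weight `P′(|β_current|)·|β|` and solves each weighted-ℓ₁ subproblem with
FISTA at the fixed step `1/L`, `L = γ·σ_max(X)²/(4n)` (the exact global
Lipschitz bound of ∇L_γ; a fixed valid step was preferred to backtracking
for determinism). The true penalized objective is tracked across outer
iterations and is nonincreasing by construction (the inner solver returns
its best iterate). Tolerances: 10⁻⁶ relative objective change (outer),
10⁻⁹ (inner), 500 outer / 2000 inner iterations, plus a hard budget of
10×2000 inner iterations per fit: in the quasi-unpenalized regime
(λ → 0 on separable data) the minimizer runs to infinity and FISTA would
crawl forever; the budget stops the crawl and flags `converged=False`
without raising.

**How TLP selects here.** With τ = 10⁻⁴ far below the noise level of a
standardized coefficient, the DC iteration started at β = 0 is effectively
one weighted-lasso step (weight λ/τ) that fixes the support, followed by
an unpenalized refit of the survivors (coefficients past τ sit on the
penalty plateau and receive weight 0). TLP at this τ therefore behaves
like a continuous best-subset penalty with a debiased refit — which is why
it selects far fewer variables than SCAD/MCP on the same data.

**λ selection** uses the stated grid `(2⁰ … 2⁻¹⁰)×10⁻³` and maximizes
cross-validated accuracy, leave-one-out by default, ties broken toward the
larger λ (sparser model). Accuracy is nearly flat in λ on strong-signal
data, so CV tends to admit small λ and with it occasional decoys; exact
support recovery is a property of the fit at a fixed λ near the lasso
universal weight `sqrt(2 ln p / n)` (on the λ/τ weight scale), and the
recovery tests pin λ there a priori. Fold fits warm-start from the
full-data fit along the λ path. Standardization is not recomputed inside
these selection folds (glmnet-style); the *validation* LOO-CV does
re-standardize per fold.

## 3. Nonparametric screening

The screening stage plays the role of a model-free marginal/joint
association filter. The exact statistic of the original analysis lives in
an uncited companion method, so the module fixes a documented default
behind a pluggable interface (`statistic=` hook):

* **marginal**: R² of regressing the 0/1 class indicator on an order-4,
  no-interior-knot B-spline basis of the variable (4 df, spans all cubics
  on the observed range);
* **joint**: R² of the order-3 × order-3 tensor-product surface minus the
  larger single-axis R², floored at 0;
* significance by label permutation within the variable's
  pairwise-complete rows: `p = (#{stat_perm ≥ stat_obs} + 1)/(n_perm + 1)`,
  default n_perm = 199, selection gate raw p < 0.05 (a Benjamini–Hochberg
  switch exists, off by default, mirroring the original raw gate).

Joint pairs are classified T1 (neither member marginally selected) or T2
(exactly one); pairs with both members already selected are excluded, and
joint results are reported but never fed into the final model — again
mirroring the motivating analysis. Variables with fewer than 20 complete
pairs are skipped with a warning; constant variables get statistic 0, p 1.

## 4. Feature encoding and the stepwise build

Variables chosen by the penalized stage enter the final model linearly
(linear wins if a variable is also screened); screen-only variables enter
as order-s B-spline blocks with **no interior knots** — the knot vector
repeats the observed [min, max] s times, so an order-s block contributes
exactly s basis columns (this matches the published coefficient-vector
lengths, which force zero interior knots). Out-of-domain values at
prediction time are clamped to the boundary rather than extrapolated.

The spline order s ∈ {2, 3, 4} is picked per variable by LOO-CV accuracy
of the single-variable model **subject to** passing the overfitting test
at level α; ties resolve to the smaller order, and a variable with no
passing order is dropped.

The final model is grown greedily: start from the best single-variable
ridge smooth-hinge SVM (ridge λ = 10⁻³ by default; the original analysis
does not state its value) and add the candidate that most improves LOO-CV
accuracy, stopping at `max_vars` or when no addition strictly improves.
Ties break toward the earlier candidate in the (deterministic) candidate
order. Complete cases are taken per evaluated model, exactly as the
complete-case rule prescribes.

## 5. Validation and the overfitting test

LOO-CV refits the model n times; standardization parameters **and spline
domains** are re-estimated inside each fold from the n−1 training subjects
(no leakage). A fold whose training set degenerates to one class predicts
the majority class with a warning. Metrics follow the standard confusion-
matrix formulas; MCC is 0 when any marginal factor is 0. AUC uses the
rank (Mann–Whitney) formulation with ties counting ½.

The overfitting test asks whether the model's accuracy could be produced
by fitting noise: for b = 1…B (default 200), permute the labels (without
replacement, preserving class balance), refit and re-cross-validate, and
report

    p = (#{T_b > T₀} + 1)/(B + 1)

with the **strict inequality exactly as published**. T_b uses the same
LOO-CV estimator as T₀ — using training accuracy instead would break the
comparison. Replicate seeds are pre-drawn from the master seed, so
replicates are independent and parallelizable with identical results.
Because the features are untouched by permutation, the per-fold designs
are prepared once and reused across all B replicates.

**Known limitation (deliberate).** LOO-CV accuracy is discrete
(granularity 1/n), so permuted accuracies tie with T₀ with non-negligible
probability, and the strict-`>` count treats ties as non-exceedances:
under a true null every quantile of p inflates by roughly the tie mass
(measured: P(p ≤ 0.05) ≈ 0.085 instead of 0.05 in a balanced 5-variable
null at n = 80, tie rate ≈ 0.07; far worse under class imbalance, where
intercept-dominated null fits make nearly all permutations tie and p
collapses toward 1/(B+1)). The tie-inclusive count (≥) is calibrated — a
companion test demonstrates this — but the package reports the formula as
published. Consequence: a small p on a *null-like* model is weaker
evidence than its nominal level; on models with real signal the test is
unaffected (T₀ sits far above every T_b).

## 6. The synthetic-cohort generator

Features are block-equicorrelated standard normals (equicorrelation ρ
within blocks). The latent score is

    Σ βⱼxⱼ + Σ aₖ·fₖ(xₖ) + logistic noise (scale 1),

with fₖ one of three unit-variance smooth shapes — quadratic `(x²−1)/√2`,
sigmoid `tanh(2x)/0.726`, cubic `x³/√15` — and the intercept calibrated on
an internal 4000-draw sample so the +1 fraction matches the target balance
(34/91 by default) in expectation. Missingness is MCAR per variable;
labels can be flipped at a stated noise rate. Identical (spec, seed) give
byte-identical tables.

Presets (each a fully stated world, fixed once):

* **null** — no signal; calibration input.
* **linear5** — n = 91, p = 20, five blocks of four at ρ = 0.3; latent
  coefficients (−2.0, −2.5, −1.5, +1.8, +1.5) on variables echoing the
  lymphocyte %, neutrophil %, albumin (protective) and C4, vinculin-
  autoantibody (risk) roles. The sizes were chosen once so the weakest
  effect clears the lasso universal threshold at n = 300 ("effects strong
  enough that an oracle fit recovers them"); at the cohort-sized n = 91
  the same world is hard, which is the realistic operating point of the
  overfitting-test demonstrations.
* **mixed8** — two linear + six nonlinear effects echoing the reduced
  clinical model's composition. n = 300 and cubic amplitude 3.0 (others
  2.0) came from a design-stage power analysis: six mutually competing
  nonlinear signals cap each variable's marginal R² near 1/7 of the latent
  variance regardless of amplitude, so cohort-sized n cannot give the
  per-variable power (~0.97) that "flag all six" requires, and the
  tail-concentrated cubic shape needs a larger amplitude for marginal
  detectability comparable to the bounded shapes.
* **cohort_shaped** — 91 × 87 with 9 variables at 60% missingness (the
  >50% filter leaves 78), balance 34:57, five linear + six nonlinear
  signals.

What the generator does **not** emulate: realistic clinical ranges/units,
missingness that depends on disease severity (MNAR), ordinal lab grades,
heavy-tailed lab distributions. A green recovery test therefore
establishes that the algorithms work under stated Gaussian worlds, not
that they would select the same variables in a real cohort.

## 7. Published-model fixtures

The two printed coefficient sets (5-variable linear; reduced 8-variable
with six order-4 spline blocks) ship as frozen formula objects. The
original standardization constants and spline domains are unpublished, so
the fixtures take standardized inputs and caller-supplied basis values
(defaulting to zero) and exist for formula-evaluation tests and sign/
structure inspection only.

## 8. Numerical conventions

* Standardization divides by the population (ddof = 0) standard deviation.
* Zero-variance columns are left unscaled (warning), correlation with a
  constant column is reported as 0, and a constant screening variable gets
  p = 1.
* Support threshold: a coefficient is "selected" when its magnitude
  exceeds τ (the TLP plateau edge); for non-TLP penalties a 10⁻⁶
  numerical-zero threshold applies.
* Missing cells are NaN throughout; "NA" or empty in the CSV dialect.
* All randomness flows through `numpy.random.SeedSequence` spawning, so
  every stage is reproducible from one integer seed.
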