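# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `cultivopt`. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` compute.

## Data model

The unit of analysis is a *treatment*: a light recipe (blue, red, white,
far-red irradiance, each in [0, 100] μmol/m²/s) plus a sucrose level
(1–6 % w/v). The packaged dataset holds 66 treatments (22 spectra × 3
sucrose levels), each with five trait means and standard errors over 4
replicate plantlets (264 plantlets in total). Traits: shoot length (mm),
root length (mm), node number, shoot number, canopy surface area (mm²).

Modelling operates on the 66 treatment means by default — they are the only
fully published data. Replicate-level analysis is supported through
`pseudo_replicates`, which reconstructs plantlet rows from the means and
SEs (a mean and an SE over n replicates are sufficient statistics under the
normal model used here).

## Preprocessing

* **Targets** are Box-Cox normalized, λ fit by profile maximum likelihood.
  Trait columns containing exact zeros (root length, where some treatments
  produced no roots) are shifted by half the smallest positive value before
  the transform — a scale-aware constant that keeps the transform defined
  without distorting the bulk of the data. Inverse transformation is exact
  on the image of the fit domain; model predictions are winsorized to the
  transformed training range ± 10 % of its span before inversion, because a
  power transform with λ < 0 diverges outside its image and an
  extrapolating network would otherwise produce astronomically large
  back-transformed values.
* **Inputs** are min–max scaled to [0, 1]. They are designed factor levels,
  not skewed observations, so no power transform is applied to them.
* **Outlier screen**: rows are flagged when their PCA score distance
  (leading components covering ≥ 95 % variance, scores standardized by
  component SD) exceeds the mean distance by more than 3 SD. On the
  packaged design matrix no rows are flagged.
* **Cross-validation**: shuffled 5-fold splits with 10 repetitions
  (`sklearn.model_selection.RepeatedKFold` behind the `FoldPlan` surface).
  All transforms are fit on the training partition of each fold only.

## Surrogate families

**GRNN.** Kernel regression with a Gaussian kernel of width σ on scaled
inputs. σ is selected by minimizing mean CV test RMSE over 20
logarithmically spaced candidates in [0.02, 2] (scaled-distance units);
ties prefer the smaller σ. Numerics: kernel weights are computed via a
log-sum-exp shift so the σ → 0 limit degrades gracefully to
nearest-neighbour prediction instead of 0/0.

**MLP.** One hidden tanh layer, linear output, targets standardized
internally. Training is full-batch Levenberg–Marquardt: solve
(JᵀJ + μI)δ = −Jᵀr with μ ×10 on a rejected step and ÷10 on an accepted
one, starting at μ = 1e−3; stop on 200 iterations, an ∞-norm gradient
below 1e−9, or relative loss improvement below 1e−12. Initialization is
seeded Gaussian, so fits are bit-reproducible. Hidden size is chosen by CV
test R² over a small candidate set (default 2, 4, 8, 12 out of the
supported range [1, 20]).

**ANFIS.** Grid partition with 3–5 Gaussian memberships per input, member-
ship μ(x) = exp[−((x−c)/a)²] (a `conventional_mf` flag switches to the
exp[−(x−c)²/2a²] form). With 5 inputs and 3 memberships the rule base has
243 first-order Takagi–Sugeno rules — 1458 consequent coefficients against
66 training rows. A hard cap (default 256 rules) rejects larger grids with
advice to reduce memberships. Hybrid learning runs 10 epochs of (i) ridge
least squares for the consequents and (ii) one normalized gradient step on
the premise centers and widths. Targets are standardized during training
and the mean/scale folded back into the consequents. The consequent ridge
penalty is dimensionless — it multiplies the mean squared design-row norm —
with default 1e−7: a numerical stabilizer for the (heavily
underdetermined) least-squares solve, small enough that exactly
representable targets (e.g. linear functions) are recovered to
near-machine precision. The solve uses the dual (kernel) form when
parameters outnumber samples, reducing an n_param × n_param system to
n × n. Note the regularization does not make the 243-rule architecture
genuinely identifiable at n = 66; its out-of-sample weakness relative to
GRNN is an expected property of this architecture at this sample size.

Every fitted model is wrapped in `SurrogateModel`, which owns the input
scaler and target transform and predicts in original trait units. Models
serialize to a versioned JSON container.

## Performance indices

R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² (coefficient of determination), RMSE =
√(Σ(y−ŷ)²/n), MBE = mean(ŷ − y) with positive values meaning
overprediction. A constant observed vector yields NaN R² (undefined)
while RMSE and MBE are still computed. The implementation agrees with
scikit-learn's `r2_score`/`mean_squared_error` to 1e−12.

## Sensitivity analysis

VSR(j) = VSE(j)/RMSE_full, where VSE(j) is the model RMSE after replacing
input column j by its training mean (removal without refitting; a
refit-style analysis can be built from `evaluate_cv` on reduced matrices).
A model that ignores input j has VSR(j) = 1; larger values mean the input
matters more. For near-interpolating models (GRNN at small σ) the
resubstitution RMSE is ≈ 0, so the denominator must be a cross-validated
RMSE — `compute_vsr` raises an instructive error otherwise.

The pipeline's default sensitivity stage works at **replicate level**
(`replicate_vsr`): it reconstructs plantlet rows via `pseudo_replicates`,
selects σ by CV on those rows, computes VSRs, and averages them over 5
reconstructions (ranks are taken on the averaged VSRs). Rationale: a σ
selected on 66 treatment means lands in a heavily smoothed regime where
mean-substitution barely changes predictions and all VSRs compress toward
1 — the ranking then reflects noise. Replicate-level folds share
treatments between train and test, which is the regime replicate-trained
kernel models operate in and yields a small σ with discriminative VSRs;
averaging over reconstructions suppresses the Monte-Carlo noise of the
reconstruction itself.

## Optimization

All four algorithms maximize a batch objective over the input box
([0, 100]⁴ for light, [1, 6] for sucrose, continuous), clip every candidate
to the bounds, track a monotone incumbent, and are bit-reproducible from
their seed. Default budgets are population 200 × 1000 generations; the
pipeline's `test_profile` shrinks this to 50 × 200.

* **GA**: roulette-wheel selection on shifted-positive fitness (shift =
  min fitness − ε), two-point crossover applied to a fraction (0.6) of
  parent pairs, uniform resampling mutation at rate 0.05 per gene, 2
  elites.
* **BBO**: rank-based species counts s ∈ [1, 0] in arithmetic progression
  (step 1/(pop−1)); emigration μ = E·s, immigration λ = I·(1−s) with
  E = I = 1; per-variable immigration with probability λ; donor habitat
  drawn by roulette ∝ μ; blended migration SIVᵢ ← SIVᵢ + α(SIVⱼ − SIVᵢ)
  with α = 1; Gaussian mutation (rate 0.05, sd 0.1·range); 2 elites. An
  `as_printed` flag switches the migration to the additive form
  SIVᵢ + α(SIVⱼ + SIVᵢ) for archaeology; that variant immediately runs
  into the box walls and is not a usable search rule, which is why the
  blended form is the default.
* **ISA**: threshold α grows linearly 0.1 → 0.9 over iterations, shifting
  the population from composition search (uniform resampling in bounds)
  to mirror search (reflection through a random point between the element
  and the incumbent); the incumbent performs a Gaussian random walk with
  scale 0.01·(UB − LB); all moves accepted greedily.
* **SOS**: per organism, mutualism (mutual vector MV = (xᵢ+xⱼ)/2, benefit
  factors drawn uniformly from {1, 2}), commensalism
  (xᵢ + rand·(x_best − xⱼ)), and parasitism (a copy of xᵢ with a random
  non-empty subset of coordinates resampled uniformly replaces a random
  host only if strictly better); greedy acceptance throughout; no extra
  tuning parameters.

Because the Box-Cox transform is monotone, maximizing the surrogate in
original units or transformed units yields the same argmax; the package
optimizes in original units.

## Pipeline

Per trait: Box-Cox the target, scale inputs, select hyperparameters on a
single-repeat fold plan, evaluate all three families on the 5×10 plan,
select the family with the highest mean CV test R² (ties broken by lower
test RMSE), refit it on all data, rank inputs (replicate-level VSR when the
chosen family is GRNN), and run all four optimizers on the refitted
surrogate. Reports (CV table, sensitivity table, optimization table,
JSON summary with config digest and seeds) are written atomically via
temp-then-rename; reruns with the same config are byte-identical.

## Synthetic-data generator

A ground-truth surface is a baseline plus per-input Gaussian bumps
(amplitude, center, width per input) and optional pairwise interaction
bumps. For additive surfaces the argmax is the vector of bump centers and
the importance ordering is the amplitude ordering — both known exactly.
Replicate noise is a zero-truncated normal with sd = CV × surface value
(constant coefficient of variation, matching the way the real dataset's
SEs grow with trait means); default CV 0.3, consistent with the
per-plantlet CVs implied by the published SEs. Truncation keeps growth
quantities nonnegative and introduces a small positive bias that is
negligible when the mean exceeds ~3 sd.

The generator emulates the *statistical* structure of the experiment — a
smooth dose–response over the input box, factorial designs, few replicates,
CV-scaled noise. It does not emulate spectral physics, photoreceptor
dynamics, or treatment-level correlations between traits, so passing
recovery tests demonstrates the pipeline's correctness on data of this
structure, not biological validity.

**Parameter-recovery study** (`make_recovery_study`): strictly ordered
amplitudes (150, 90, 75, 62, 50) assigned to inputs by a seeded
permutation, equal widths of 0.45·span, centers in the central 20 % of the
box, a 600-point uniform design with 4 replicates and CV 0.05 noise. The
problem sizes reflect what the estimator can resolve: a 5-D kernel
surrogate localizes an optimum to ~10 % of the box per dimension only from
a space-filling design of some hundreds of points, the rank-1 input is
identifiable only when clearly dominant, and interior centers avoid the
boundary bias inherent to kernel regression. With these conditions the
pipeline recovers the dominant input and localizes the argmax within 10 %
of the box width per dimension on the seeded test surfaces; occasional
seeds still produce a spurious surrogate mode of near-equal height, which
is an honest property of noisy 5-D response-surface estimation.

## Known limitations

* CV metrics on the 66 treatment means are pessimistic: with one mean per
  treatment, held-out treatments are genuinely unseen spectra, and
  out-of-sample R² for all three families is near zero on the real data.
  Replicate-trained models (the regime the published per-fold metrics
  imply) see sister plantlets of test rows during training and score far
  higher. The package therefore asserts model-family *orderings* (GRNN ≥
  ANFIS) and importance *ranks* on the real data, and reserves numeric
  accuracy claims for synthetic data with known truth.
* The GRNN convexity bound means predicted optima can never exceed the
  best observed treatment mean; optimizers explore flat ridges of the
  kernel surface, so different algorithms can return different input
  vectors at the same objective value.
* ANFIS at the printed architecture is underdetermined at n = 66; its
  consequents are min-norm solutions, not identified parameters.
* The Nadaraya–Watson estimator carries boundary bias: optima planted near
  a box face are pulled inward, which is why the recovery study plants
  interior optima.
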