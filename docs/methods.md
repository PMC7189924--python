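# Methods

## The modelling problem

A cohort of n subjects carries two binary endpoints y₁, y₂ (e.g. heart
block and death during hospitalization after myocardial infarction) and p
covariates. The endpoints are dependent, and the target of inference is
the *joint* outcome pair: a prediction counts as correct only when both
components are correct. The package provides three predictors of the pair
and a harness that scores them on a common seeded train/test split.

## Bivariate logistic regression

The joint distribution of (Y₁, Y₂) given x is parameterized by the two
marginal probabilities and the cross-ratio (odds ratio):

- π_j = expit(x_j′β_j), j = 1, 2 (logit links),
- ψ = exp(x₃′β₃) (log link), ψ = (π₀₀π₁₁)/(π₁₀π₀₁).

ψ = 1 means conditional independence; ψ < 1 negative association. Given
(π₁, π₂, ψ), π₁₁ solves a quadratic; the admissible root is
[a − √(a²+b)]/(2(ψ−1)) with a = 1 + (π₁+π₂)(ψ−1), b = −4ψ(ψ−1)π₁π₂. The
larger root violates the Fréchet bounds max(0, π₁+π₂−1) ≤ π₁₁ ≤ min(π₁,π₂),
which are asserted post-hoc. Within |ψ−1| < 1e-8 the analytic limit
π₁₁ = π₁π₂ replaces the closed form (which is 0/0 there); tests confirm
continuity across the switch at 1e-6.

Each subject contributes log π_cell(y₁,y₂) to the likelihood. The default
design places every covariate in both marginal predictors and an intercept
only in the ψ predictor (dependence rarely supports covariate-level
modelling at clinical sample sizes); any column-to-predictor map is
configurable, and `dependence="none"` fixes ψ ≡ 1, which reduces the model
to two independent logistic regressions (verified against statsmodels to
~1e-8).

Fitting is unconstrained BFGS on the stacked (β₁, β₂, β₃) — all parameters
are free under the logit/log links — started at zero. The optimizer runs
on internally z-scored covariates: raw clinical units (cholesterol ≈ 200,
blood pressure ≈ 130) make the Hessian condition number large enough that
quasi-Newton stalls with huge gradients. The optimum is mapped back to raw
units (slope/sd, intercept adjusted), and standard errors come from the
inverse of a central finite-difference Hessian of the raw-unit
log-likelihood at that point (step 1e-5 relative). Wald z = coefficient/SE
with two-sided normal p-values. Non-convergence and a non-positive-definite
observed information are flagged with warnings, never silently accepted;
complete separation typically surfaces as the latter.

Prediction rules: `marginal-threshold` (default) sets ŷ_k = 1 iff its
marginal probability is strictly greater than 0.5, matching the
per-outcome accuracy framing; `joint-argmax` picks the most probable joint
cell, ties broken deterministically toward (0,0), then (1,0), then (0,1).

## Two-output perceptron and its seven trainers

Architecture p → M → 2 with sigmoids at both layers:

    y_ik = σ(β₀k + Σ_j β_jk σ(w_j0 + Σ_s x_is w_js)),  k = 1, 2.

The objective is the mean of squared residuals over all n rows **and both
outputs**, MSE = ‖r‖²/(2n), so tolerances are n-invariant and a network
stuck at 0.5 against all-zero targets scores exactly 0.25. With this
scaling the residual Jacobian satisfies gradient = Jᵀr/n, an identity the
tests check exactly alongside finite-difference agreement (< 1e-6
relative) for both the back-propagated gradient and the Jacobian.

Inputs are min-max scaled to [0,1] using training-set ranges only (test
rows use the same ranges, clipped): sigmoid hidden units saturate on raw
clinical units. Training is full batch; n ≈ 263 makes minibatching
pointless and full batch keeps every trainer deterministic. One epoch is
one accepted parameter update. Stopping: ‖g‖∞ ≤ tol_grad (1e-6), MSE ≤
tol_mse (1e-10), max_epochs, divergence to non-finite values (reported as
a stop reason with a warning, never an exception), or — when a validation
fraction is held out — no validation improvement for 6 consecutive epochs.

- `gd` / `gdm`: fixed learning rate (default 0.5 on scaled inputs);
  momentum 0.9.
- `cg`: Polak–Ribière with β⁺ = max(0, β) restart, a forced restart every
  n_params iterations, and Armijo backtracking line search (c₁ = 1e-4,
  initial step 1, halving).
- `bfgs`: inverse-Hessian update with the same line search; the update is
  skipped when sᵀy ≤ 1e-12 and the approximation resets to the identity if
  the direction loses descent.
- `oss`: the one-step secant direction d = −g + A s + B y built from the
  previous step/gradient-change pair (memoryless quasi-Newton), line
  search as above.
- `scg`: Møller's algorithm verbatim — no line search; curvature from a
  finite-difference Hessian-vector product (σ₀ = 1e-4) with the λ
  raise/lower schedule (quarter λ when the comparison ratio Δ ≥ 0.75,
  raise when Δ < 0.25, reject and raise when Δ < 0).
- `lm`: damped Gauss–Newton (JᵀJ + λI)δ = −Jᵀr with λ₀ = 1e-3, ×10 on a
  rejected step, ×0.1 on acceptance; an epoch ends at the first accepted
  step, and training stops when λ exceeds 1e12 without improvement.

Hidden-layer width is selected over 8–14 nodes by held-out MSE on an
internal validation split (default 20 % of the training part, never the
test set), ties toward the smaller width; candidates whose training fails
are skipped with a warning.

## Genetic algorithm and the hybrid

A chromosome is the flat weight vector (W_hidden row-major, b_hidden,
W_out row-major, b_out). Defaults: population 50, 100 generations,
tournament selection of size 2, whole-arithmetic blend crossover
(child = u·a + (1−u)·b, u ~ U(0,1)) with probability 0.8, per-gene
Gaussian mutation (sd 0.1) with probability 0.05, 2 elites copied
unchanged, initial genes uniform in ±0.5. Elitism makes the
best-fitness trace non-increasing; a non-finite fitness reinitializes the
offending chromosome with a warning.

The GA primitive's default fitness is the training MSE of the decoded,
**untrained** network, keeping evolution cheap. Implementation showed a
real limitation of that choice: for near-balanced binary targets an
untrained sigmoid network outputs ≈ 0.5 everywhere, so the fitness
landscape is a plateau at ≈ 0.25 and selection cannot distinguish good
basins from bad ones. The optional `lamarckian_epochs=k` setting evaluates
fitness as the MSE after k gradient epochs from the chromosome — i.e. the
*trainability* of the start — and is what the comparison workflow uses
(k = 2).

A second finding shapes the hybrid-vs-plain comparison: the benefit of
optimized initial weights is a property of the **initialization-limited
regime**. With a long Levenberg–Marquardt budget, training from a single
random start and from the GA's best start converge to statistically
indistinguishable optima; at a short budget (the comparison uses 5 LM
epochs) the starting point dominates the final MSE and the hybrid wins
the paired comparison in well over 80 % of matched seeds (23–25 of 25
across independent base seeds). `evaluation.paired_hybrid_comparison`
freezes these conditions: 25 paired seeds, one synthetic 200-subject
cohort per pair shared by both arms, GA population 20 for 15 generations
with trainability fitness, and identical trainer, budget and init scale
in both arms.

## Evaluation harness

- **Split**: train size = round(fraction·n) exactly (263 at 0.7 → 184/79).
  Stratification on the four joint outcome cells (largest-remainder
  quotas, seeded shuffles within cells) is the default so rare cells
  (deaths ≈ 8 %) appear in both parts; a plain random split is available.
- **Joint accuracy**: 100 × #(both components correct)/n, printed to two
  decimals; it can never exceed either marginal accuracy, and every
  report asserts that bound.
- **Association test**: Pearson chi-square on the 2×2 outcome table, 1 df,
  no continuity correction; an empty margin yields a flagged NaN.
- **Comparison report**: BLR, plain network and hybrid fitted on the same
  split; per-model joint/marginal accuracies and 4×4 joint confusion
  counts; a failing model is recorded and the rest still reported.

## Synthetic data

Covariates are generated independently (Gaussian for continuous columns,
Bernoulli for binary) because no covariance information about the
emulated cohort is available; outcomes are drawn row-wise from the
four-cell joint distribution implied by the true bivariate-logit
parameters, so empirical cell frequencies converge to the closed-form
cells (checked at n = 50 000 against π₁₁ = 1/3 for π₁ = π₂ = 0.5, ψ = 4).

Three named configurations:

- `mi_cohort_fixture` — n = 263, sixteen covariates with
  descriptive-table-like marginals, intercept-only outcome truth with
  π₁ = 221/263, π₂ = 22/263 and ψ = (14·34)/(207·8) ≈ 0.2874, so the
  expected cell counts are exactly (14, 207, 8, 34). Sampling is
  exact-probability, not quota: realized counts vary by seed, the targets
  are the contract. Two dispersion values printed for the emulated cohort
  (age, troponin) are implausibly small for SDs (they read as standard
  errors); the fixture substitutes clinically plausible SDs there and
  otherwise keeps printed values, including the oddly small "non-fasting
  blood sugar" mean, verbatim.
- `effect_cohort_spec` — n = 200, four standardized covariates with
  moderate effects on both margins and ψ = e^0.8; endpoint prevalences in
  the 15–25 % range. The learnable-signal condition for the model
  comparison and the hybrid study.
- `recovery_spec` — a balanced two-covariate design (prevalences near
  50 %) for parameter-recovery simulations. The deliberate distinction:
  in rare-event designs the log cross-ratio's information comes from the
  scarce joint cell and its sampling SD at n = 2000 is ≈ 0.26 — several
  times the balanced value — so a consistency check run there measures
  sampling noise, not estimator quality.

Because the fixture's outcomes carry no covariate signal, flexible models
overfit it by construction; passing tests on it demonstrate calibration of
margins and dependence, determinism, and the accuracy bounds — not
real-data predictive performance. Conversely the effect cohort shows
learnability but is far cleaner (independent Gaussian covariates, exact
logistic link) than clinical data.

## Numerical choices and limitations

- π margins are clipped to [1e-12, 1 − 1e-12] before the cell closed form;
  discriminant negatives beyond −1e-10 raise, smaller ones clamp to 0.
- The likelihood clips realized cells at 1e-300 inside the optimizer; the
  public log-likelihood returns −inf (flagged) for a zero-probability cell.
- Optimizer convergence accepts scipy's success flag or ‖g‖∞ < 1e-3 (BFGS
  sometimes reports precision loss at a genuine optimum).
- All randomness flows from integer seeds through numpy Generators; the
  CLI derives named sub-streams (split/init/GA) from one top-level seed by
  hashing, so changing GA settings does not perturb the split.
- Not covered: multiple hidden layers, cross-entropy objectives,
  regularization, covariate selection, >2 outcomes, Bayesian fitting,
  ROC/calibration analysis.
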