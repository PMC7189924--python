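# bivbin

Joint prediction of a **pair of correlated binary outcomes** from tabular
covariates — e.g. two in-hospital endpoints of the same patient, such as
occurrence of heart block and death after myocardial infarction. When the
question is "will *both* events be predicted correctly for this subject?",
per-outcome models are not enough: the two endpoints are dependent, and the
quantity of interest is the joint prediction accuracy, the percentage of
subjects for whom **both** predicted outcomes match the observed pair.

The package implements and compares three model families behind one
dataset container and one evaluation harness:

1. **Bivariate logistic regression (BLR).** Each marginal probability
   follows a logistic regression and the within-pair dependence is carried
   by the cross-ratio ψ on the log scale:

   π<sub>j</sub> = 1 / (1 + e<sup>−x<sub>j</sub>′β<sub>j</sub></sup>), j = 1, 2;  ψ = e<sup>x₃′β₃</sup>,
   ψ = (π₀₀π₁₁)/(π₁₀π₀₁).

   Given (π₁, π₂, ψ) the four joint cells are recovered in closed form:
   π₁₁ = [a − √(a² + b)] / (2(ψ−1)) with a = 1 + (π₁+π₂)(ψ−1) and
   b = −4ψ(ψ−1)π₁π₂ (π₁₁ = π₁π₂ at ψ = 1), then π₁₀ = π₁ − π₁₁,
   π₀₁ = π₂ − π₁₁, π₀₀ = 1 − π₁₁ − π₁₀ − π₀₁. Each subject contributes
   the log of its realized cell to the likelihood; fitting is by
   quasi-Newton maximum likelihood with observed-information standard
   errors and Wald p-values.

2. **Two-output perceptron (ANN).** One sigmoid hidden layer of M nodes
   and two sigmoid outputs, trained full-batch against the MSE by any of
   seven classic back-propagation-family algorithms: gradient descent
   (`gd`), gradient descent with momentum (`gdm`), Polak–Ribière conjugate
   gradient (`cg`), Møller's scaled conjugate gradient (`scg`), BFGS
   (`bfgs`), one-step secant (`oss`) and Levenberg–Marquardt (`lm`).
   Gradients are exact back-propagation; LM uses the analytic residual
   Jacobian.

3. **Hybrid ANN-GA.** A real-coded genetic algorithm (tournament
   selection, arithmetic crossover, Gaussian mutation, elitism) searches
   the space of *initial* weight vectors; gradient training then refines
   the best chromosome.

Models are scikit-learn-style estimators (`fit` / `predict` /
`get_params`) and compose with sklearn tooling. Because the cohort that
motivated the design is not public, a seeded synthetic-data module
generates covariate tables and correlated binary outcome pairs — including
a 263-subject cohort fixture calibrated to the printed marginal summaries
(84.0 % first-endpoint prevalence; conditional second-endpoint rates
6.3 % / 19.0 %; outcome cross-ratio ≈ 0.287).

## Worked example

```python
import numpy as np
from bivbin import (mi_cohort_fixture, association_chi2,
                    BivariateLogisticRegression, SplitSpec, compare_models)
from bivbin.evaluation import default_models

data = mi_cohort_fixture(seed=1)              # n=263, 16 covariates
chi2, p, table = association_chi2(data.y1, data.y2)
print(f"association: chi2 = {chi2:.3f}, p = {p:.4f}")

est = BivariateLogisticRegression().fit(data)
print(est.coef_table_.round(3).head(4))

models = default_models(seed=1, ga_generations=15, ga_pop_size=20)
report = compare_models(data, SplitSpec(train_fraction=0.7, seed=1), models)
print(report.to_frame())
```

prints

```text
association: chi2 = 4.386, p = 0.0362
                     Coefficient     SE      z      p
intercept(1)               0.373  1.716  0.218  0.828
gender_male(1)            -0.380  0.423 -0.899  0.369
mi_type_anterior(1)        0.091  0.368  0.247  0.805
diabetes_history(1)       -0.110  0.391 -0.281  0.779
            BLR    ANN  ANN-GA
Training  75.54  99.46   93.48
Test      77.22  59.49   60.76
```

The chi-square line tests the association between the two outcomes on this
particular seeded draw (the dependence is real: the generating cross-ratio
is 0.287). The coefficient table shows the fitted marginal-logit
coefficients with standard errors — all near zero here because this
fixture draws its outcomes from an intercept-only truth. The final table
is the joint prediction accuracy (percent of subjects with *both*
endpoints correct) on the 184/79 train/test split: the regression
generalizes (≈77 % test), while the flexible networks memorize the
signal-free covariates and overfit — exactly what should happen on data
with no covariate signal.

The same workflow is available from the shell:

```sh
bivbin simulate --out cohort.csv --seed 1
bivbin fit-blr --input cohort.csv --out results/
bivbin train-ann --input cohort.csv --algorithm lm --out results/
bivbin train-hybrid --input cohort.csv --out results/
bivbin evaluate --input cohort.csv --out results/ --seed 1
```

## Documentation

`docs/methods.md` describes the models, the synthetic-data generators and
their calibration targets, numerical choices, and known limitations.
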