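"""Seeded generators for covariate tables and correlated binary outcome
pairs, plus a myocardial-infarction-cohort-like fixture.

The fixture emulates a cohort of 263 MI inpatients with two in-hospital
endpoints — heart block (y1) and death (y2) — and sixteen admission
covariates.  The real cohort is not public; the generator targets its
printed marginal summaries: y1 prevalence 84.0%, death rates 6.3% among
those with block and 19.0% among those without (so the expected 2x2 cell
counts at n=263 are 14 / 207 / 8 / 34 and the outcome cross-ratio is
(14*34)/(207*8) ~= 0.287).  Covariates are drawn independently — Gaussian
for continuous measurements, Bernoulli for binary history items — because
no covariance information is available; realized counts vary by seed (the
target probabilities, not the counts, are the contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .bivlogit import BivLogitParams, DesignMap, linear_predictors
from .dataset import BivariateBinaryDataset
from .joint import joint_probs_arrays

__all__ = [
    "CovariateSpec",
    "GeneratorSpec",
    "generate_covariates",
    "generate_outcomes",
    "generate_dataset",
    "effect_cohort_spec",
    "mi_cohort_fixture",
    "MI_COHORT_TARGETS",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One synthetic covariate: Gaussian (mean, sd) or Bernoulli prevalence."""

    name: str
    kind: str  # "continuous" | "binary"
    mean: float | None = None
    sd: float | None = None
    prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "continuous":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ValueError(f"{self.name}: continuous needs mean and sd > 0")
        elif self.kind == "binary":
            if self.prevalence is None or not 0 <= self.prevalence <= 1:
                raise ValueError(f"{self.name}: binary needs prevalence in [0, 1]")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")


@dataclass
class GeneratorSpec:
    """Full recipe: covariates plus the true bivariate-logit parameters."""

    n: int
    covariates: list[CovariateSpec]
    true_params: BivLogitParams
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")


def generate_covariates(spec: GeneratorSpec) -> np.ndarray:
    """Seeded-deterministic (n, p) covariate draw, independent columns."""
    rng = np.random.default_rng(spec.seed)
    cols = []
    for c in spec.covariates:
        if c.kind == "continuous":
            cols.append(rng.normal(c.mean, c.sd, size=spec.n))
        else:
            cols.append((rng.random(spec.n) < c.prevalence).astype(float))
    return np.column_stack(cols) if cols else np.empty((spec.n, 0))


def generate_outcomes(params: BivLogitParams, X: np.ndarray, seed: int = 0):
    """Sample (y1, y2) from the four-cell joint distribution row by row."""
    rng = np.random.default_rng(seed)
    pi1, pi2, psi = linear_predictors(params, X)
    pi11, pi10, pi01, pi00 = joint_probs_arrays(pi1, pi2, psi)[:4]
    # cells ordered (0,0),(0,1),(1,0),(1,1) to match the cell index y1*2+y2
    cells = np.column_stack([pi00, pi01, pi10, pi11])
    cum = np.cumsum(cells, axis=1)
    u = rng.random(len(cum))
    idx = (u[:, None] >= cum).sum(axis=1)
    return (idx // 2).astype(np.int8), (idx % 2).astype(np.int8)


def generate_dataset(spec: GeneratorSpec) -> BivariateBinaryDataset:
    """Covariates plus outcomes in one seeded call."""
    X = generate_covariates(spec)
    y1, y2 = generate_outcomes(spec.true_params, X, seed=spec.seed + 1)
    return BivariateBinaryDataset(X, y1, y2, [c.name for c in spec.covariates])


def effect_cohort_spec(seed: int = 0, n: int = 200) -> GeneratorSpec:
    """A small cohort with genuine covariate effects on both endpoints.

    Four standardized covariates enter both marginal predictors with
    moderate coefficients and the outcomes share a positive cross-ratio
    (psi = e^0.8 ~ 2.2); endpoint prevalences sit in the 15-25% range.
    Used for learnable-signal experiments (model comparison, parameter
    recovery) where the intercept-only fixture would be uninformative.
    """
    covs = [CovariateSpec(f"z{i + 1}", "continuous", mean=0.0, sd=1.0)
            for i in range(4)]
    true = BivLogitParams(
        beta1=[-1.5, 1.2, -0.8, 0.5, 0.0],
        beta2=[-2.0, 0.6, 0.9, -0.7, 0.4],
        beta3=[0.8],
        design_map=DesignMap((0, 1, 2, 3), (0, 1, 2, 3), ()),
    )
    return GeneratorSpec(n=n, covariates=covs, true_params=true, seed=seed)


def recovery_spec(seed: int = 0, n: int = 2000) -> GeneratorSpec:
    """A balanced, well-identified design for parameter-recovery simulations.

    Endpoint prevalences sit near 50% and the joint 11-cell is common, so
    every coefficient — including the log cross-ratio intercept, whose
    information comes from the joint cell — has a small sampling SD at
    moderate n.  Rare-event designs (see :func:`effect_cohort_spec`) give
    the dependence parameter a sampling SD several times larger and are the
    wrong instrument for checking estimator consistency.
    """
    covs = [CovariateSpec(f"z{i + 1}", "continuous", mean=0.0, sd=1.0)
            for i in range(2)]
    true = BivLogitParams(
        beta1=[0.2, 0.8, -0.5],
        beta2=[-0.3, 0.5, 0.7],
        beta3=[0.6],
        design_map=DesignMap((0, 1), (0, 1), ()),
    )
    return GeneratorSpec(n=n, covariates=covs, true_params=true, seed=seed)


# -- the MI-cohort-like fixture -------------------------------------------

#: printed marginal targets the fixture is calibrated to
MI_COHORT_TARGETS = {
    "n": 263,
    "p_block": 221 / 263,              # y1 prevalence, 84.0%
    "p_death": 22 / 263,               # overall death prevalence (14 + 8 deaths)
    "death_rate_block": 14 / 221,      # 6.3% printed
    "death_rate_no_block": 8 / 42,     # 19.0% printed
    "psi": (14 * 34) / (207 * 8),      # outcome cross-ratio ~0.2874
    "expected_cells": {"(1,1)": 14, "(1,0)": 207, "(0,1)": 8, "(0,0)": 34},
}

# Covariate marginals emulating the cohort's descriptive tables: binary
# prevalences are the pooled printed counts / 263; continuous means are the
# group means pooled 221:42.  Printed dispersion for age-like variables is
# implausibly small for an SD (it reads as a standard error), so troponin
# carries a clinically realistic SD instead; the oddly small "non-fasting
# blood sugar" mean is kept verbatim.
MI_COHORT_COVARIATES: list[CovariateSpec] = [
    CovariateSpec("gender_male", "binary", prevalence=197 / 263),
    CovariateSpec("mi_type_anterior", "binary", prevalence=0.55),
    CovariateSpec("diabetes_history", "binary", prevalence=203 / 263),
    CovariateSpec("hypertension_history", "binary", prevalence=161 / 263),
    CovariateSpec("dyslipidemia", "binary", prevalence=203 / 263),
    CovariateSpec("heart_disease_history", "binary", prevalence=179 / 263),
    CovariateSpec("output_fraction", "continuous", mean=36.19, sd=10.0),
    CovariateSpec("systolic_bp", "continuous", mean=136.03, sd=28.4),
    CovariateSpec("diastolic_bp", "continuous", mean=78.51, sd=22.0),
    CovariateSpec("fasting_blood_sugar", "continuous", mean=172.40, sd=80.6),
    CovariateSpec("non_fasting_blood_sugar", "continuous", mean=28.39, sd=26.3),
    CovariateSpec("cholesterol", "continuous", mean=202.43, sd=62.1),
    CovariateSpec("triglyceride", "continuous", mean=39.21, sd=31.6),
    CovariateSpec("ldl", "continuous", mean=44.23, sd=14.0),
    CovariateSpec("smoking", "binary", prevalence=124 / 263),
    CovariateSpec("troponin", "continuous", mean=9.98, sd=12.0),
]


def mi_cohort_params() -> BivLogitParams:
    """Intercept-only true parameters hitting the printed outcome targets."""
    t = MI_COHORT_TARGETS
    p = len(MI_COHORT_COVARIATES)
    return BivLogitParams(
        beta1=[special.logit(t["p_block"])],
        beta2=[special.logit(t["p_death"])],
        beta3=[np.log(t["psi"])],
        design_map=DesignMap(margin1=(), margin2=(), dependence=()),
    )


def mi_cohort_fixture(seed: int = 0, n: int | None = None) -> BivariateBinaryDataset:
    """Seeded synthetic stand-in for the undeposited MI cohort.

    n = 263 subjects (override via ``n``), sixteen covariates with
    table-like marginals, and outcomes drawn from the intercept-only joint
    distribution whose expected cell counts are exactly (14, 207, 8, 34).
    """
    spec = GeneratorSpec(
        n=n or MI_COHORT_TARGETS["n"],
        covariates=MI_COHORT_COVARIATES,
        true_params=mi_cohort_params(),
        seed=seed,
    )
    return generate_dataset(spec)
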