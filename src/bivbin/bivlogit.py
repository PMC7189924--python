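"""Bivariate logistic regression with odds-ratio dependence.

Models a pair of correlated binary outcomes (Y1, Y2) given covariates x.
Each marginal follows a logistic regression and the within-pair dependence
is carried by the cross-ratio psi on the log scale:

    pi_j = 1 / (1 + exp(-x_j' beta_j)),  j = 1, 2
    psi  = exp(x_3' beta_3)

The four joint-cell probabilities are recovered from (pi1, pi2, psi) by the
quadratic root in :mod:`bivbin.joint`, and each observation contributes the
log of its realized cell to the likelihood.  Maximum likelihood is computed
by unconstrained quasi-Newton on the stacked (beta1, beta2, beta3) vector —
all three predictors are already unconstrained under the logit/log links.
Standard errors come from the inverse observed information (finite-difference
Hessian at the optimum), with Wald z and two-sided normal p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .dataset import BivariateBinaryDataset
from .joint import joint_probs_arrays

__all__ = [
    "DesignMap",
    "BivLogitParams",
    "BivariateLogisticRegression",
    "linear_predictors",
    "loglikelihood",
    "fit_bivariate_logit",
]

#: canonical (y1, y2) cell order used for joint probabilities and confusion
CELL_ORDER: tuple[tuple[int, int], ...] = ((0, 0), (0, 1), (1, 0), (1, 1))

PREDICTION_RULES = ("marginal-threshold", "joint-argmax")


@dataclass(frozen=True)
class DesignMap:
    """Which covariate columns enter each of the three linear predictors.

    Each entry is a list of column indices into X; an intercept is always
    included and is not listed.  ``dependence=None`` fixes psi at 1
    (no dependence parameters at all), which reduces the model to two
    independent logistic regressions.
    """

    margin1: tuple[int, ...]
    margin2: tuple[int, ...]
    dependence: tuple[int, ...] | None = ()

    @classmethod
    def default(cls, p: int) -> "DesignMap":
        """All covariates in both marginal predictors, intercept-only psi."""
        cols = tuple(range(p))
        return cls(margin1=cols, margin2=cols, dependence=())

    @property
    def sizes(self) -> tuple[int, int, int]:
        k3 = 0 if self.dependence is None else 1 + len(self.dependence)
        return 1 + len(self.margin1), 1 + len(self.margin2), k3


@dataclass
class BivLogitParams:
    """Stacked coefficients (intercept first) for the three predictors."""

    beta1: np.ndarray
    beta2: np.ndarray
    beta3: np.ndarray  # empty when psi is fixed at 1
    design_map: DesignMap = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beta1 = np.atleast_1d(np.asarray(self.beta1, dtype=float))
        self.beta2 = np.atleast_1d(np.asarray(self.beta2, dtype=float))
        self.beta3 = np.asarray(self.beta3, dtype=float).ravel()
        if self.design_map is None:
            p = len(self.beta1) - 1
            if len(self.beta2) - 1 != p:
                raise ValueError("design_map required for asymmetric designs")
            dep = tuple(range(len(self.beta3) - 1)) if len(self.beta3) else None
            if len(self.beta3) == 1:
                dep = ()
            self.design_map = DesignMap(
                tuple(range(p)), tuple(range(p)), dep
            )
        k1, k2, k3 = self.design_map.sizes
        if (len(self.beta1), len(self.beta2), len(self.beta3)) != (k1, k2, k3):
            raise ValueError(
                f"coefficient lengths {(len(self.beta1), len(self.beta2), len(self.beta3))} "
                f"do not match design sizes {(k1, k2, k3)}"
            )

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.beta1, self.beta2, self.beta3])

    @classmethod
    def from_stacked(cls, theta: np.ndarray, design_map: DesignMap) -> "BivLogitParams":
        k1, k2, k3 = design_map.sizes
        theta = np.asarray(theta, dtype=float)
        if len(theta) != k1 + k2 + k3:
            raise ValueError("stacked vector length does not match design")
        return cls(theta[:k1], theta[k1:k1 + k2], theta[k1 + k2:], design_map)

    def parameter_names(self, covariate_names: list[str] | None = None) -> list[str]:
        def name(j: int) -> str:
            if covariate_names is not None and j < len(covariate_names):
                return covariate_names[j]
            return f"x{j + 1}"

        dm = self.design_map
        out = ["intercept(1)"] + [f"{name(j)}(1)" for j in dm.margin1]
        out += ["intercept(2)"] + [f"{name(j)}(2)" for j in dm.margin2]
        if dm.dependence is not None:
            out += ["intercept(psi)"] + [f"{name(j)}(psi)" for j in dm.dependence]
        return out


def _design_matrix(X: np.ndarray, cols: tuple[int, ...]) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if cols and max(cols) >= X.shape[1]:
        raise ValueError(
            f"design references column {max(cols)} but X has {X.shape[1]} columns"
        )
    return np.column_stack([np.ones(X.shape[0])] + [X[:, j] for j in cols])


def linear_predictors(params: BivLogitParams, X: np.ndarray):
    """Per-row (pi1, pi2, psi) from the three linear predictors.

    Rows are independent; pi1, pi2 are in (0, 1) and psi > 0.
    """
    dm = params.design_map
    eta1 = _design_matrix(X, dm.margin1) @ params.beta1
    eta2 = _design_matrix(X, dm.margin2) @ params.beta2
    pi1 = special.expit(eta1)
    pi2 = special.expit(eta2)
    if dm.dependence is None or len(params.beta3) == 0:
        psi = np.ones_like(pi1)
    else:
        eta3 = _design_matrix(X, dm.dependence) @ params.beta3
        psi = np.exp(np.clip(eta3, -500, 500))
    return pi1, pi2, psi


def _cell_probs(params: BivLogitParams, X: np.ndarray):
    """Per-row joint cells stacked (n, 4) in CELL_ORDER."""
    pi1, pi2, psi = linear_predictors(params, X)
    # keep margins off the exact boundary so cells stay well defined
    eps = 1e-12
    pi1 = np.clip(pi1, eps, 1 - eps)
    pi2 = np.clip(pi2, eps, 1 - eps)
    pi11, pi10, pi01, pi00 = joint_probs_arrays(pi1, pi2, psi)[:4]
    return np.column_stack([pi00, pi01, pi10, pi11])


def loglikelihood(params: BivLogitParams, data: BivariateBinaryDataset) -> float:
    """Sum over rows of log pi_cell(row), cell = (y1, y2).

    Returns ``-inf`` (with a warning, not an exception) if any realized
    cell has probability <= 0.
    """
    cells = _cell_probs(params, data.X)
    idx = data.y1 * 2 + data.y2  # maps (y1,y2) into CELL_ORDER position
    realized = cells[np.arange(data.n), idx]
    if np.any(realized <= 0):
        warnings.warn("realized joint cell with probability <= 0; loglik = -inf")
        return -np.inf
    return float(np.sum(np.log(realized)))


def _negloglik(theta, design_map, X, cell_idx, n):
    params = BivLogitParams.from_stacked(theta, design_map)
    cells = _cell_probs(params, X)
    realized = np.clip(cells[np.arange(n), cell_idx], 1e-300, None)
    return -np.sum(np.log(realized))


def _destandardize(theta_std, dm: DesignMap, mu: np.ndarray, sd: np.ndarray):
    """Map coefficients fitted on z-scored covariates back to raw units.

    For each predictor with intercept b0 and slopes b on (x - mu)/sd, the
    raw-unit slopes are b/sd and the raw intercept is b0 - sum(b*mu/sd).
    """
    params = BivLogitParams.from_stacked(np.asarray(theta_std, float), dm)

    def back(beta: np.ndarray, cols) -> np.ndarray:
        if len(beta) == 0:
            return beta
        cols = list(cols)
        slopes = beta[1:] / sd[cols] if cols else beta[1:]
        b0 = beta[0] - (beta[1:] @ (mu[cols] / sd[cols]) if cols else 0.0)
        return np.concatenate([[b0], slopes])

    return np.concatenate([
        back(params.beta1, dm.margin1),
        back(params.beta2, dm.margin2),
        back(params.beta3, dm.dependence) if dm.dependence is not None else params.beta3,
    ])


def _fd_hessian(f, x0: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian."""
    k = len(x0)
    H = np.empty((k, k))
    hi = h * np.maximum(1.0, np.abs(x0))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = hi[i]
            ej = np.zeros(k); ej[j] = hi[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hi[i] * hi[j])
    return H


class BivariateLogisticRegression(BaseEstimator):
    """Maximum-likelihood bivariate logistic regression.

    Parameters
    ----------
    dependence : "intercept", "none", or sequence of int, default "intercept"
        Covariate columns entering the log cross-ratio predictor.
        "intercept" fits a single dependence parameter (the default, matching
        the common three-intercept layout); "none" fixes psi = 1, reducing
        the fit to two independent logistic regressions.
    margins : "all" or pair of sequences of int, default "all"
        Covariate columns entering the two marginal predictors.
    prediction_rule : {"marginal-threshold", "joint-argmax"}
        "marginal-threshold" predicts y_k = 1 iff its marginal probability
        is strictly greater than 0.5; "joint-argmax" predicts the cell with
        the largest joint probability, ties broken toward (0,0), then (1,0),
        then (0,1).
    tol : float
        Gradient-norm convergence tolerance for the optimizer.
    max_iter : int
        Optimizer iteration cap.

    Attributes
    ----------
    params_ : BivLogitParams
    loglik_ : float
    se_, wald_z_, p_values_ : ndarray aligned with ``params_.stacked()``
    converged_ : bool
    n_iter_ : int
    coef_table_ : pandas.DataFrame with Coefficient / SE / p columns
    """

    def __init__(
        self,
        dependence="intercept",
        margins="all",
        prediction_rule: str = "marginal-threshold",
        tol: float = 1e-6,
        max_iter: int = 500,
    ):
        self.dependence = dependence
        self.margins = margins
        self.prediction_rule = prediction_rule
        self.tol = tol
        self.max_iter = max_iter

    # -- fitting ----------------------------------------------------------
    def _design(self, p: int) -> DesignMap:
        if self.margins == "all":
            m1 = m2 = tuple(range(p))
        else:
            m1, m2 = (tuple(m) for m in self.margins)
        if self.dependence == "intercept":
            dep: tuple[int, ...] | None = ()
        elif self.dependence == "none":
            dep = None
        else:
            dep = tuple(self.dependence)
        return DesignMap(m1, m2, dep)

    def fit(self, X, Y=None, *, y1=None, y2=None):
        """Fit by maximum likelihood.

        Accepts either ``fit(X, Y)`` with Y of shape (n, 2), keyword vectors
        ``y1``/``y2``, or a :class:`BivariateBinaryDataset` as sole argument.
        """
        if isinstance(X, BivariateBinaryDataset):
            data = X
        elif Y is not None:
            Y = np.asarray(Y)
            data = BivariateBinaryDataset(X, Y[:, 0], Y[:, 1])
        else:
            data = BivariateBinaryDataset(X, y1, y2)

        dm = self._design(data.p)
        k = sum(dm.sizes)
        if data.n <= k:
            raise ValueError(f"need n > {k} rows to fit {k} parameters, got {data.n}")
        for name, y in (("y1", data.y1), ("y2", data.y2)):
            if y.min() == y.max():
                raise ValueError(f"outcome {name} has a single class; cannot fit")

        cell_idx = data.y1.astype(int) * 2 + data.y2.astype(int)
        # optimize on standardized covariates (raw clinical units make the
        # problem badly scaled for quasi-Newton), then map the optimum back
        mu = data.X.mean(axis=0) if data.p else np.zeros(0)
        sd = data.X.std(axis=0) if data.p else np.zeros(0)
        sd = np.where(sd > 0, sd, 1.0)
        Xs = (data.X - mu) / sd
        obj_std = lambda th: _negloglik(th, dm, Xs, cell_idx, data.n)
        res = optimize.minimize(
            obj_std, np.zeros(k), method="BFGS",
            options={"gtol": self.tol, "maxiter": self.max_iter},
        )
        theta = _destandardize(res.x, dm, mu, sd)
        obj = lambda th: _negloglik(th, dm, data.X, cell_idx, data.n)
        self.params_ = BivLogitParams.from_stacked(theta, dm)
        self.loglik_ = -float(res.fun)
        self.n_iter_ = int(res.nit)
        grad_norm = float(np.max(np.abs(res.jac)))
        # scipy flags "precision loss" near flat optima; accept if the
        # gradient meets a looser practical tolerance
        self.converged_ = bool(res.success or grad_norm < 1e-3)
        self.convergence_message_ = res.message
        if not self.converged_:
            warnings.warn(
                f"bivariate logit did not converge: {res.message} "
                f"(|grad|_inf = {grad_norm:.2e})"
            )

        H = _fd_hessian(obj, theta)
        try:
            cov = np.linalg.inv(H)
            diag = np.diag(cov)
            if np.any(diag <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
            self.se_ = np.sqrt(diag)
        except np.linalg.LinAlgError:
            warnings.warn("observed information not positive definite; SEs are NaN")
            self.se_ = np.full(k, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.wald_z_ = theta / self.se_
            self.p_values_ = 2 * stats.norm.sf(np.abs(self.wald_z_))
        self.coef_table_ = pd.DataFrame(
            {
                "Coefficient": theta,
                "SE": self.se_,
                "z": self.wald_z_,
                "p": self.p_values_,
            },
            index=self.params_.parameter_names(data.covariate_names),
        )
        self.n_features_in_ = data.p
        return self

    # -- prediction -------------------------------------------------------
    def predict_joint_proba(self, X) -> np.ndarray:
        """(n, 4) joint cell probabilities in CELL_ORDER (00, 01, 10, 11)."""
        return _cell_probs(self.params_, np.asarray(X, dtype=float))

    def predict_proba_marginal(self, X) -> np.ndarray:
        pi1, pi2, _ = linear_predictors(self.params_, np.asarray(X, dtype=float))
        return np.column_stack([pi1, pi2])

    def predict(self, X, rule: str | None = None) -> np.ndarray:
        """Per-row (yhat1, yhat2) under the configured prediction rule."""
        rule = rule or self.prediction_rule
        if rule not in PREDICTION_RULES:
            raise ValueError(f"unknown prediction rule {rule!r}; use one of {PREDICTION_RULES}")
        X = np.asarray(X, dtype=float)
        if rule == "marginal-threshold":
            pm = self.predict_proba_marginal(X)
            return (pm > 0.5).astype(int)
        cells = self.predict_joint_proba(X)
        # tie-break priority (0,0) > (1,0) > (0,1) > (1,1): reorder columns so
        # argmax's first-max rule lands on the preferred cell
        priority = [0, 2, 1, 3]  # positions of (0,0),(1,0),(0,1),(1,1) in CELL_ORDER
        best = np.argmax(cells[:, priority], axis=1)
        pairs = np.array([CELL_ORDER[p] for p in priority])
        return pairs[best]


def fit_bivariate_logit(
    data: BivariateBinaryDataset, design_map: DesignMap | None = None, **options
) -> BivariateLogisticRegression:
    """Thin functional wrapper over :class:`BivariateLogisticRegression`."""
    est = BivariateLogisticRegression(**options)
    if design_map is not None:
        est.margins = (design_map.margin1, design_map.margin2)
        est.dependence = (
            "none" if design_map.dependence is None
            else ("intercept" if design_map.dependence == () else design_map.dependence)
        )
    return est.fit(data)
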