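"""Classic full-batch trainers for the two-output perceptron.

Seven members of the back-propagation family, all minimizing the training
MSE from the same starting weights:

- ``gd``    steepest descent with a fixed learning rate
- ``gdm``   steepest descent with a momentum term
- ``cg``    nonlinear conjugate gradient (Polak-Ribiere with non-negativity
            restart, plus a forced restart every n_params iterations) with
            Armijo backtracking line search
- ``scg``   Moller's scaled conjugate gradient: no line search, curvature
            from a finite-difference Hessian-vector product, trust-region
            style raising/lowering of the damping lambda
- ``bfgs``  quasi-Newton with the inverse-Hessian BFGS update and Armijo
            line search
- ``oss``   one-step secant: a memoryless BFGS-like direction built from the
            previous (step, gradient-change) pair
- ``lm``    Levenberg-Marquardt: damped Gauss-Newton steps (J'J + lambda I)
            with multiplicative lambda adaptation

Training is deterministic given (weights, data, config).  Updates are
full batch; one epoch is one accepted parameter update.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import BivariateBinaryDataset
from .network import MLPWeights, forward, gradient, init_weights, jacobian, mse, n_params

__all__ = ["ALGORITHMS", "TrainConfig", "TrainHistory", "train", "select_hidden_nodes"]

ALGORITHMS = ("gd", "gdm", "cg", "scg", "bfgs", "oss", "lm")


@dataclass
class TrainConfig:
    """Settings shared by all trainers; algorithm-specific ones are ignored
    by algorithms that do not use them."""

    algorithm: str = "lm"
    max_epochs: int = 500
    learning_rate: float = 0.5     # gd / gdm
    momentum: float = 0.9          # gdm
    lm_lambda0: float = 1e-3       # lm initial damping
    lm_lambda_up: float = 10.0     # lm damping increase on a rejected step
    lm_lambda_down: float = 0.1    # lm damping decrease on an accepted step
    tol_grad: float = 1e-6         # stop when ||grad||_inf falls below
    tol_mse: float = 1e-10         # stop when training MSE falls below
    seed: int = 0
    validation_fraction: float = 0.0   # > 0 enables early stopping
    patience: int = 6              # epochs of no validation improvement

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; use one of {ALGORITHMS}")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.tol_grad <= 0 or self.tol_mse <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")


@dataclass
class TrainHistory:
    """Per-epoch MSE trace; entry 0 is the MSE before any update."""

    epoch_mse: list[float] = field(default_factory=list)
    final_mse: float = np.nan
    stop_reason: str = ""
    n_epochs: int = 0


def _armijo(f, theta, d, f0, g0d, alpha0=1.0, c1=1e-4, max_halvings=40):
    """Backtracking line search; returns (alpha, f_new) or (None, f0)."""
    if g0d >= 0:
        return None, f0
    alpha = alpha0
    for _ in range(max_halvings):
        f_new = f(theta + alpha * d)
        if np.isfinite(f_new) and f_new <= f0 + c1 * alpha * g0d:
            return alpha, f_new
        alpha *= 0.5
    return None, f0


def train(
    weights: MLPWeights,
    data: BivariateBinaryDataset,
    config: TrainConfig,
) -> tuple[MLPWeights, TrainHistory]:
    """Train a network full-batch with the configured algorithm.

    Returns new weights (the input is not modified) and the history.  If
    ``validation_fraction`` > 0, a seeded tail of the data is held out and
    training stops once the validation MSE has not improved for
    ``patience`` consecutive epochs (``stop_reason="early_stop"``).
    """
    shape = weights.shape
    fit_data, val_data = data, None
    if config.validation_fraction > 0:
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(data.n)
        n_val = max(1, int(round(config.validation_fraction * data.n)))
        if n_val >= data.n:
            raise ValueError("validation_fraction leaves no training rows")
        val_data = data.subset(perm[:n_val])
        fit_data = data.subset(perm[n_val:])

    # guard against non-finite iterates (a diverging trainer) so the loop
    # can report stop_reason="diverged" instead of raising
    def f(th):
        if not np.all(np.isfinite(th)):
            return np.inf
        return mse(MLPWeights.from_flat(th, shape), fit_data)

    def g(th):
        return gradient(MLPWeights.from_flat(th, shape), fit_data)

    theta = weights.flatten()
    hist = TrainHistory()
    f0 = f(theta)
    hist.epoch_mse.append(f0)
    state: dict = {"lambda": config.lm_lambda0}
    best_val, bad_epochs = np.inf, 0

    stop = None
    prev_theta = theta
    for epoch in range(1, config.max_epochs + 1):
        if not np.isfinite(f0):
            stop = "diverged"
            theta = prev_theta  # last finite iterate
            break
        prev_theta = theta
        if f0 <= config.tol_mse:
            stop = "mse_tol"
            break
        grad = g(theta)
        if np.max(np.abs(grad)) <= config.tol_grad:
            stop = "grad_tol"
            break

        theta_new, f_new = _STEPPERS[config.algorithm](
            theta, f0, grad, f, g, config, state, fit_data, shape
        )
        if theta_new is None:
            # no acceptable step found: the iterate is at (numerical) rest
            stop = "grad_tol"
            break
        theta, f0 = theta_new, f_new
        hist.epoch_mse.append(f0)
        hist.n_epochs = epoch

        if val_data is not None:
            v = mse(MLPWeights.from_flat(theta, shape), val_data)
            if v < best_val - 1e-12:
                best_val, bad_epochs = v, 0
            else:
                bad_epochs += 1
                if bad_epochs >= config.patience:
                    stop = "early_stop"
                    break
    if stop is None:
        if np.isfinite(f0):
            stop = "max_epochs"
        else:
            stop = "diverged"
            theta = prev_theta
    if stop == "diverged":
        warnings.warn("training diverged to a non-finite MSE; aborting")
    hist.stop_reason = stop
    hist.final_mse = hist.epoch_mse[-1]
    return MLPWeights.from_flat(theta, shape), hist


# -- per-algorithm steppers -----------------------------------------------
# Each takes the current iterate and returns (theta_new, f_new), or
# (None, f0) when no acceptable step exists.  `state` persists across epochs.

def _step_gd(theta, f0, grad, f, g, cfg, state, data, shape):
    theta_new = theta - cfg.learning_rate * grad
    return theta_new, f(theta_new)


def _step_gdm(theta, f0, grad, f, g, cfg, state, data, shape):
    v = state.get("velocity", np.zeros_like(theta))
    v = cfg.momentum * v - cfg.learning_rate * grad
    state["velocity"] = v
    theta_new = theta + v
    return theta_new, f(theta_new)


def _step_cg(theta, f0, grad, f, g, cfg, state, data, shape):
    k = state.get("cg_iter", 0)
    d_prev, g_prev = state.get("cg_dir"), state.get("cg_grad")
    if d_prev is None or k % len(theta) == 0:
        d = -grad
    else:
        beta = max(0.0, grad @ (grad - g_prev) / (g_prev @ g_prev))
        d = -grad + beta * d_prev
        if grad @ d >= 0:   # not a descent direction: restart
            d = -grad
    alpha, f_new = _armijo(f, theta, d, f0, grad @ d)
    if alpha is None:
        return None, f0
    state.update(cg_iter=k + 1, cg_dir=d, cg_grad=grad)
    return theta + alpha * d, f_new


def _step_bfgs(theta, f0, grad, f, g, cfg, state, data, shape):
    H = state.get("H")
    if H is None:
        H = np.eye(len(theta))
    d = -H @ grad
    if grad @ d >= 0:
        H = np.eye(len(theta))
        d = -grad
    alpha, f_new = _armijo(f, theta, d, f0, grad @ d)
    if alpha is None:
        return None, f0
    theta_new = theta + alpha * d
    g_new = g(theta_new)
    s, y = theta_new - theta, g_new - grad
    sy = s @ y
    if sy > 1e-12:
        rho = 1.0 / sy
        I = np.eye(len(theta))
        V = I - rho * np.outer(s, y)
        H = V @ H @ V.T + rho * np.outer(s, s)
    state["H"] = H
    return theta_new, f_new


def _step_oss(theta, f0, grad, f, g, cfg, state, data, shape):
    s, y = state.get("oss_s"), state.get("oss_y")
    if s is None:
        d = -grad
    else:
        sy = s @ y
        if abs(sy) < 1e-12:
            d = -grad
        else:
            sg, yg = s @ grad, y @ grad
            A = -(1.0 + (y @ y) / sy) * sg / sy + yg / sy
            B = sg / sy
            d = -grad + A * s + B * y
            if grad @ d >= 0:
                d = -grad
    alpha, f_new = _armijo(f, theta, d, f0, grad @ d)
    if alpha is None:
        return None, f0
    theta_new = theta + alpha * d
    state["oss_s"] = theta_new - theta
    state["oss_y"] = g(theta_new) - grad
    return theta_new, f_new


def _step_scg(theta, f0, grad, f, g, cfg, state, data, shape):
    """One accepted Moller iteration (internal rejections raise lambda)."""
    N = len(theta)
    lam = state.get("scg_lambda", 1e-6)
    lam_bar = state.get("scg_lambda_bar", 0.0)
    r = state.get("scg_r")
    p = state.get("scg_p")
    k = state.get("scg_k", 0)
    if p is None:
        r = -grad
        p = r.copy()
    sigma0 = 1e-4

    for _ in range(50):  # bounded rejection loop
        pnorm2 = p @ p
        if pnorm2 < 1e-300:
            return None, f0
        sigma = sigma0 / np.sqrt(pnorm2)
        s_vec = (g(theta + sigma * p) - grad) / sigma   # H p by finite diff
        delta = p @ s_vec
        delta += (lam - lam_bar) * pnorm2
        if delta <= 0:  # make the Hessian approximation positive definite
            lam_bar = 2.0 * (lam - delta / pnorm2)
            delta = -delta + lam * pnorm2
            lam = lam_bar
        mu = p @ r
        alpha = mu / delta
        f_new = f(theta + alpha * p)
        Delta = 2.0 * delta * (f0 - f_new) / (mu * mu)
        if Delta >= 0:  # successful step
            theta_new = theta + alpha * p
            g_new = g(theta_new)
            r_new = -g_new
            lam_bar = 0.0
            k += 1
            if k % N == 0:
                p_new = r_new.copy()
            else:
                beta = (r_new @ r_new - r_new @ r) / mu
                p_new = r_new + beta * p
            if Delta >= 0.75:
                lam = max(lam * 0.25, 1e-15)
            elif Delta < 0.25:
                lam += delta * (1.0 - Delta) / pnorm2
            state.update(scg_lambda=lam, scg_lambda_bar=lam_bar,
                         scg_r=r_new, scg_p=p_new, scg_k=k)
            return theta_new, f_new
        # unsuccessful: raise lambda and retry along the same direction
        lam_bar = lam
        lam += delta * (1.0 - Delta) / pnorm2
        if not np.isfinite(lam) or lam > 1e15:
            return None, f0
    return None, f0


def _step_lm(theta, f0, grad, f, g, cfg, state, data, shape):
    w = MLPWeights.from_flat(theta, shape)
    r = (forward(w, data.X) - data.Y.astype(float)).ravel()  # (2n,)
    J = jacobian(w, data)
    JtJ = J.T @ J
    Jtr = J.T @ r
    lam = state.get("lambda", cfg.lm_lambda0)
    I = np.eye(len(theta))
    for _ in range(30):
        try:
            delta = np.linalg.solve(JtJ + lam * I, -Jtr)
        except np.linalg.LinAlgError:
            lam *= cfg.lm_lambda_up
            continue
        f_new = f(theta + delta)
        if np.isfinite(f_new) and f_new < f0:
            state["lambda"] = max(lam * cfg.lm_lambda_down, 1e-15)
            return theta + delta, f_new
        lam *= cfg.lm_lambda_up
        if lam > 1e12:
            break
    state["lambda"] = lam
    return None, f0


_STEPPERS = {
    "gd": _step_gd,
    "gdm": _step_gdm,
    "cg": _step_cg,
    "bfgs": _step_bfgs,
    "oss": _step_oss,
    "scg": _step_scg,
    "lm": _step_lm,
}


def select_hidden_nodes(
    data: BivariateBinaryDataset,
    M_range=range(8, 15),
    config: TrainConfig | None = None,
    evaluator=None,
) -> tuple[int, dict[int, float]]:
    """Pick the hidden-layer size with the lowest held-out MSE.

    One seeded network is trained per candidate M on an internal
    training/validation split of `data`; ties break toward the smaller M.
    `evaluator` (M -> MSE) can replace the train-and-score step, e.g. for
    testing or custom criteria.  Candidates whose training fails are skipped
    with a warning; if all fail, an error is raised.
    """
    M_list = list(M_range)
    if not M_list:
        raise ValueError("M_range must be nonempty")
    config = config or TrainConfig()
    vf = config.validation_fraction if config.validation_fraction > 0 else 0.2

    if evaluator is None:
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(data.n)
        n_val = max(1, int(round(vf * data.n)))
        val, sub = data.subset(perm[:n_val]), data.subset(perm[n_val:])
        inner = replace(config, validation_fraction=0.0)

        def evaluator(M):
            w0 = init_weights(data.p, M, config.seed)
            w, hist = train(w0, sub, inner)
            if hist.stop_reason == "diverged":
                raise RuntimeError(f"training diverged at M={M}")
            return mse(w, val)

    table: dict[int, float] = {}
    for M in M_list:
        try:
            table[M] = float(evaluator(M))
        except Exception as exc:  # noqa: BLE001 - propagate at the end if all fail
            warnings.warn(f"hidden-size candidate M={M} failed: {exc}")
    if not table:
        raise RuntimeError("every hidden-size candidate failed to train")
    best = min(table, key=lambda M: (table[M], M))
    return best, table
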