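"""Two-output multilayer perceptron: forward pass and exact derivatives.

Architecture: p inputs -> M sigmoid hidden nodes -> 2 sigmoid outputs,

    y_ik = sigma( b_out_k + sum_j W_out_kj * sigma( b_hid_j + sum_s x_is W_hid_js ) )

trained against the mean squared error over all n rows and both outputs,

    MSE = (1/(2n)) * sum_ik (y_ik_hat - y_ik)^2 ,

so a network stuck at 0.5 against all-zero targets scores 0.25.  The module
provides the exact back-propagated gradient of the MSE and the residual
Jacobian (d residual / d weight, needed by Levenberg-Marquardt), both in a
fixed flat parameter order: W_hidden row-major, b_hidden, W_out row-major,
b_out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .dataset import BivariateBinaryDataset

__all__ = [
    "MLPWeights",
    "n_params",
    "init_weights",
    "forward",
    "mse",
    "gradient",
    "jacobian",
]


@dataclass
class MLPWeights:
    """All weights and biases of a p -> M -> 2 sigmoid network."""

    W_hidden: np.ndarray  # (M, p)
    b_hidden: np.ndarray  # (M,)
    W_out: np.ndarray     # (2, M)
    b_out: np.ndarray     # (2,)
    activation_hidden: str = "sigmoid"
    activation_out: str = "sigmoid"

    def __post_init__(self) -> None:
        self.W_hidden = np.asarray(self.W_hidden, dtype=float)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float)
        self.W_out = np.asarray(self.W_out, dtype=float)
        self.b_out = np.asarray(self.b_out, dtype=float)
        M, p = self.W_hidden.shape
        if self.b_hidden.shape != (M,) or self.W_out.shape != (2, M) \
                or self.b_out.shape != (2,):
            raise ValueError(
                f"inconsistent shapes: W_hidden {self.W_hidden.shape}, "
                f"b_hidden {self.b_hidden.shape}, W_out {self.W_out.shape}, "
                f"b_out {self.b_out.shape}"
            )
        for arr in (self.W_hidden, self.b_hidden, self.W_out, self.b_out):
            if not np.isfinite(arr).all():
                raise ValueError("weights must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        """(p, M) — input and hidden-node counts."""
        return self.W_hidden.shape[1], self.W_hidden.shape[0]

    def flatten(self) -> np.ndarray:
        return np.concatenate([
            self.W_hidden.ravel(), self.b_hidden,
            self.W_out.ravel(), self.b_out,
        ])

    @classmethod
    def from_flat(cls, theta: np.ndarray, shape: tuple[int, int]) -> "MLPWeights":
        p, M = shape
        theta = np.asarray(theta, dtype=float)
        if len(theta) != n_params(p, M):
            raise ValueError(
                f"flat vector length {len(theta)} != {n_params(p, M)} for shape {shape}"
            )
        i = 0
        W_h = theta[i:i + M * p].reshape(M, p); i += M * p
        b_h = theta[i:i + M].copy(); i += M
        W_o = theta[i:i + 2 * M].reshape(2, M); i += 2 * M
        b_o = theta[i:i + 2].copy()
        return cls(W_h, b_h, W_o, b_o)

    def copy(self) -> "MLPWeights":
        return MLPWeights(
            self.W_hidden.copy(), self.b_hidden.copy(),
            self.W_out.copy(), self.b_out.copy(),
            self.activation_hidden, self.activation_out,
        )


def n_params(p: int, M: int) -> int:
    """Total parameter count: M*p + M + 2*M + 2."""
    return M * p + M + 2 * M + 2


def init_weights(p: int, M: int, seed: int, scale: float = 0.5) -> MLPWeights:
    """Uniform [-scale, scale] initialization, deterministic for fixed seed."""
    if p < 1 or M < 1:
        raise ValueError(f"need p >= 1 and M >= 1, got p={p}, M={M}")
    if scale < 0:
        raise ValueError("scale must be non-negative")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(-scale, scale, size=n_params(p, M))
    return MLPWeights.from_flat(theta, (p, M))


def _hidden(weights: MLPWeights, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p, _ = weights.shape
    if X.shape[1] != p:
        raise ValueError(f"X has {X.shape[1]} columns; network expects {p}")
    return special.expit(X @ weights.W_hidden.T + weights.b_hidden)


def forward(weights: MLPWeights, X: np.ndarray) -> np.ndarray:
    """Network outputs, shape (n, 2), strictly inside (0, 1)."""
    Z = _hidden(weights, X)
    return special.expit(Z @ weights.W_out.T + weights.b_out)


def _targets(data: BivariateBinaryDataset) -> np.ndarray:
    if data.n == 0:
        raise ValueError("empty dataset")
    return data.Y.astype(float)


def mse(weights: MLPWeights, data: BivariateBinaryDataset) -> float:
    """Mean of squared residuals over all n rows and both outputs."""
    out = forward(weights, data.X)
    r = out - _targets(data)
    return float(np.sum(r * r) / (2 * data.n))


def _forward_parts(weights: MLPWeights, data: BivariateBinaryDataset):
    X = np.atleast_2d(np.asarray(data.X, dtype=float))
    Z = _hidden(weights, X)
    out = special.expit(Z @ weights.W_out.T + weights.b_out)
    r = out - _targets(data)
    return X, Z, out, r


def gradient(weights: MLPWeights, data: BivariateBinaryDataset) -> np.ndarray:
    """Exact flat gradient of :func:`mse` by back-propagation."""
    X, Z, out, r = _forward_parts(weights, data)
    n = data.n
    delta_out = r * out * (1.0 - out) / n          # (n, 2)
    g_Wout = delta_out.T @ Z                       # (2, M)
    g_bout = delta_out.sum(axis=0)                 # (2,)
    delta_hid = (delta_out @ weights.W_out) * Z * (1.0 - Z)   # (n, M)
    g_Whid = delta_hid.T @ X                       # (M, p)
    g_bhid = delta_hid.sum(axis=0)                 # (M,)
    return np.concatenate([g_Whid.ravel(), g_bhid, g_Wout.ravel(), g_bout])


def jacobian(weights: MLPWeights, data: BivariateBinaryDataset) -> np.ndarray:
    """Residual Jacobian, shape (2n, n_params).

    Row ordering is row-major by observation then output (residual index
    2*i + k).  Satisfies the chain-rule identity J.T @ r / n == gradient(mse).
    """
    X, Z, out, r = _forward_parts(weights, data)
    n = data.n
    p, M = weights.shape
    k_total = n_params(p, M)
    sp = out * (1.0 - out)                         # (n, 2) sigmoid' at outputs
    Zp = Z * (1.0 - Z)                             # (n, M)

    J = np.zeros((2 * n, k_total))
    off_Whid, off_bhid = 0, M * p
    off_Wout, off_bout = M * p + M, M * p + M + 2 * M
    rows = 2 * np.arange(n)
    for k in range(2):
        # back-propagated sensitivity of output k to hidden pre-activations
        D = sp[:, [k]] * weights.W_out[k][None, :] * Zp          # (n, M)
        J[rows + k, off_Whid:off_bhid] = np.einsum("nm,ns->nms", D, X).reshape(n, M * p)
        J[rows + k, off_bhid:off_Wout] = D
        J[rows + k, off_Wout + k * M: off_Wout + (k + 1) * M] = sp[:, [k]] * Z
        J[rows + k, off_bout + k] = sp[:, k]
    return J
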