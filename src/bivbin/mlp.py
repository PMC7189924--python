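"""Scikit-learn-style estimator for the two-output perceptron.

Wraps the network math in :mod:`bivbin.network` and the trainers in
:mod:`bivbin.training` behind a ``fit``/``predict`` surface.  Covariates are
min-max scaled to [0, 1] using training-set ranges only (raw clinical units
would saturate the sigmoids); test rows are scaled with the same ranges and
clipped to [0, 1].
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator

from .dataset import BivariateBinaryDataset
from .network import MLPWeights, forward, init_weights, mse
from .training import ALGORITHMS, TrainConfig, TrainHistory, train

__all__ = ["MLPJointClassifier", "MinMaxRanges", "weights_to_json", "weights_from_json"]


class MinMaxRanges:
    """Per-column [0,1] scaling frozen on the training data."""

    def __init__(self, X: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.lo = X.min(axis=0)
        span = X.max(axis=0) - self.lo
        self.span = np.where(span > 0, span, 1.0)  # constant columns map to 0

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.clip((X - self.lo) / self.span, 0.0, 1.0)


class MLPJointClassifier(BaseEstimator):
    """One-hidden-layer sigmoid network predicting both binary outcomes.

    Parameters
    ----------
    hidden_units : int, default 8
        Number of hidden nodes M.
    algorithm : str, default "lm"
        One of ``gd, gdm, cg, scg, bfgs, oss, lm``.
    max_epochs, learning_rate, momentum, tol_grad, tol_mse,
    validation_fraction : training settings, see
        :class:`bivbin.training.TrainConfig`.
    init_scale : float, default 0.5
        Half-width of the uniform weight initialization.
    random_state : int, default 0
        Seeds the weight initialization (and the validation split when
        early stopping is enabled).
    scale_inputs : bool, default True
        Min-max scale covariates using training ranges.
    initial_weights : MLPWeights or None
        Start training from these weights instead of a random draw (used by
        the GA hybrid).

    Attributes
    ----------
    weights_ : MLPWeights
    history_ : TrainHistory
    train_mse_ : float
    """

    def __init__(
        self,
        hidden_units: int = 8,
        algorithm: str = "lm",
        max_epochs: int = 500,
        learning_rate: float = 0.5,
        momentum: float = 0.9,
        tol_grad: float = 1e-6,
        tol_mse: float = 1e-10,
        validation_fraction: float = 0.0,
        init_scale: float = 0.5,
        random_state: int = 0,
        scale_inputs: bool = True,
        initial_weights: MLPWeights | None = None,
    ):
        self.hidden_units = hidden_units
        self.algorithm = algorithm
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.tol_grad = tol_grad
        self.tol_mse = tol_mse
        self.validation_fraction = validation_fraction
        self.init_scale = init_scale
        self.random_state = random_state
        self.scale_inputs = scale_inputs
        self.initial_weights = initial_weights

    def _config(self) -> TrainConfig:
        return TrainConfig(
            algorithm=self.algorithm,
            max_epochs=self.max_epochs,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            tol_grad=self.tol_grad,
            tol_mse=self.tol_mse,
            seed=self.random_state,
            validation_fraction=self.validation_fraction,
        )

    def _as_dataset(self, X, Y, y1, y2) -> BivariateBinaryDataset:
        if isinstance(X, BivariateBinaryDataset):
            return X
        if Y is not None:
            Y = np.asarray(Y)
            return BivariateBinaryDataset(X, Y[:, 0], Y[:, 1])
        return BivariateBinaryDataset(X, y1, y2)

    def fit(self, X, Y=None, *, y1=None, y2=None):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        data = self._as_dataset(X, Y, y1, y2)
        self.scaler_ = MinMaxRanges(data.X) if self.scale_inputs else None
        Xs = self.scaler_.transform(data.X) if self.scaler_ else data.X
        scaled = BivariateBinaryDataset(Xs, data.y1, data.y2, data.covariate_names)

        w0 = self.initial_weights
        if w0 is None:
            w0 = init_weights(data.p, self.hidden_units, self.random_state,
                              self.init_scale)
        elif w0.shape != (data.p, self.hidden_units):
            raise ValueError(
                f"initial_weights shape {w0.shape} does not match "
                f"(p={data.p}, M={self.hidden_units})"
            )
        self.weights_, self.history_ = train(w0, scaled, self._config())
        self.train_mse_ = mse(self.weights_, scaled)
        self.n_features_in_ = data.p
        return self

    def _scaled(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.scaler_.transform(X) if self.scaler_ else X

    def predict_proba(self, X) -> np.ndarray:
        """(n, 2) network outputs, one column per endpoint."""
        return forward(self.weights_, self._scaled(X))

    def predict(self, X) -> np.ndarray:
        """(n, 2) hard labels; y_k = 1 iff output_k > 0.5 (strictly)."""
        return (self.predict_proba(X) > 0.5).astype(int)


# -- persistence -----------------------------------------------------------

def weights_to_json(weights: MLPWeights, history: TrainHistory | None = None,
                    extra: dict | None = None) -> str:
    """Serialize a network (shape metadata + flat weights) as JSON."""
    p, M = weights.shape
    doc = {
        "shape": {"p": p, "M": M},
        "activation": [weights.activation_hidden, weights.activation_out],
        "weights_flat": weights.flatten().tolist(),
    }
    if history is not None:
        doc["history"] = {
            "epoch_mse": list(map(float, history.epoch_mse)),
            "final_mse": float(history.final_mse),
            "stop_reason": history.stop_reason,
            "n_epochs": history.n_epochs,
        }
    if extra:
        doc.update(extra)
    return json.dumps(doc, indent=2)


def weights_from_json(text: str) -> MLPWeights:
    doc = json.loads(text)
    shape = (doc["shape"]["p"], doc["shape"]["M"])
    return MLPWeights.from_flat(np.asarray(doc["weights_flat"]), shape)
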