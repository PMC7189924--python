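"""Container for tabular data with a pair of binary outcomes.

Every model in this package consumes the same input: an ``n x p`` covariate
matrix together with two length-``n`` binary outcome vectors ``y1`` and
``y2``.  The container validates the outcome coding once at construction so
downstream code can assume clean 0/1 vectors with no missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BivariateBinaryDataset"]


def _as_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if np.isnan(arr).any():
        bad = np.flatnonzero(np.isnan(arr))
        raise ValueError(f"{name} has missing values at rows {bad.tolist()}")
    if not np.isin(arr, (0.0, 1.0)).all():
        bad = np.flatnonzero(~np.isin(arr, (0.0, 1.0)))
        raise ValueError(
            f"{name} must contain only 0/1; offending rows {bad.tolist()} "
            f"with values {arr[bad].tolist()}"
        )
    return arr.astype(np.int8)


@dataclass
class BivariateBinaryDataset:
    """Covariate matrix plus two binary outcome vectors.

    Parameters
    ----------
    X : array-like of shape (n, p)
        Covariates in the units they were supplied in.  ``p = 0`` is allowed
        (intercept-only models).
    y1, y2 : array-like of shape (n,)
        The two binary endpoints, coded 0/1.
    covariate_names : list of str, optional
        Defaults to ``x1 .. xp``.
    """

    X: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.size == 0:
            self.X = self.X.reshape(len(np.asarray(self.y1)), 0)
        self.y1 = _as_binary(self.y1, "y1")
        self.y2 = _as_binary(self.y2, "y2")
        n = len(self.y1)
        if n < 1:
            raise ValueError("dataset must contain at least one row")
        if len(self.y2) != n or self.X.shape[0] != n:
            raise ValueError(
                f"inconsistent row counts: X {self.X.shape[0]}, "
                f"y1 {n}, y2 {len(self.y2)}"
            )
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite or missing values")
        if not self.covariate_names:
            self.covariate_names = [f"x{i + 1}" for i in range(self.X.shape[1])]
        if len(self.covariate_names) != self.X.shape[1]:
            raise ValueError("covariate_names length does not match X columns")

    @property
    def n(self) -> int:
        return len(self.y1)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def Y(self) -> np.ndarray:
        """Outcomes stacked as an (n, 2) integer matrix."""
        return np.column_stack([self.y1, self.y2])

    def subset(self, idx) -> "BivariateBinaryDataset":
        idx = np.asarray(idx)
        return BivariateBinaryDataset(
            self.X[idx], self.y1[idx], self.y2[idx], list(self.covariate_names)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"y1": self.y1, "y2": self.y2})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.X[:, j]
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        outcome_cols: tuple[str, str] = ("y1", "y2"),
        covariate_cols: list[str] | None = None,
    ) -> "BivariateBinaryDataset":
        c1, c2 = outcome_cols
        if c1 == c2:
            raise ValueError("the two outcome columns must be distinct")
        for c in (c1, c2):
            if c not in df.columns:
                raise ValueError(f"outcome column {c!r} not found in data")
        if covariate_cols is None:
            covariate_cols = [c for c in df.columns if c not in (c1, c2)]
        missing = [c for c in covariate_cols if c not in df.columns]
        if missing:
            raise ValueError(f"covariate columns not found: {missing}")
        return cls(
            df[covariate_cols].to_numpy(dtype=float),
            df[c1].to_numpy(),
            df[c2].to_numpy(),
            list(covariate_cols),
        )
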