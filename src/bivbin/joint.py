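"""Joint-cell probabilities for two correlated binary outcomes.

A pair of binary variables (Y1, Y2) has four joint cells pi_rs = Pr(Y1=r,
Y2=s).  Given the two marginal success probabilities pi1, pi2 and the
cross-ratio (odds ratio)

    psi = (pi00 * pi11) / (pi10 * pi01),

the joint distribution is fully determined: pi11 solves a quadratic whose
admissible root is

    pi11 = [a - sqrt(a^2 + b)] / (2 (psi - 1)),
    a = 1 + (pi1 + pi2)(psi - 1),   b = -4 psi (psi - 1) pi1 pi2,

with pi10 = pi1 - pi11, pi01 = pi2 - pi11 and pi00 = 1 - pi11 - pi10 - pi01.
At psi = 1 the outcomes are independent and pi11 = pi1 * pi2 (the analytic
limit of the 0/0 closed form).  The smaller root is the one inside the
Frechet bounds max(0, pi1 + pi2 - 1) <= pi11 <= min(pi1, pi2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["JointProbTable", "joint_probs", "joint_probs_arrays", "cross_ratio"]

#: below this |psi - 1| the independence limit pi11 = pi1*pi2 is used
PSI_ONE_TOL = 1e-8


@dataclass(frozen=True)
class JointProbTable:
    """The four cell probabilities of a 2x2 outcome distribution.

    Cells are indexed pi_rs with r the value of Y1 and s the value of Y2.
    ``a`` and ``b`` are the intermediates of the quadratic root.
    """

    pi11: float
    pi10: float
    pi01: float
    pi00: float
    pi1: float
    pi2: float
    psi: float
    a: float
    b: float

    def cells(self) -> np.ndarray:
        """Cells ordered (pi00, pi01, pi10, pi11), i.e. by (y1, y2) pairs."""
        return np.array([self.pi00, self.pi01, self.pi10, self.pi11])


def _check_inputs(pi1, pi2, psi) -> None:
    pi1, pi2, psi = np.asarray(pi1), np.asarray(pi2), np.asarray(psi)
    for name, v in (("pi1", pi1), ("pi2", pi2)):
        if not np.all(np.isfinite(v)) or np.any(v < 0) or np.any(v > 1):
            raise ValueError(f"{name} must be a probability in [0, 1]")
    if not np.all(np.isfinite(psi)) or np.any(psi <= 0):
        raise ValueError("psi must be a positive finite cross-ratio")


def joint_probs_arrays(pi1, pi2, psi):
    """Vectorized cell probabilities; returns (pi11, pi10, pi01, pi00, a, b)."""
    _check_inputs(pi1, pi2, psi)
    pi1 = np.asarray(pi1, dtype=float)
    pi2 = np.asarray(pi2, dtype=float)
    psi = np.asarray(psi, dtype=float)
    pi1, pi2, psi = np.broadcast_arrays(pi1, pi2, psi)

    a = 1.0 + (pi1 + pi2) * (psi - 1.0)
    b = -4.0 * psi * (psi - 1.0) * pi1 * pi2
    disc = a * a + b
    # the discriminant is non-negative for any valid (pi1, pi2, psi);
    # clamp rounding-level negatives, reject anything worse
    if np.any(disc < -1e-10):
        raise FloatingPointError("negative discriminant in joint-cell root")
    disc = np.maximum(disc, 0.0)

    denom = 2.0 * (psi - 1.0)
    near_one = np.abs(psi - 1.0) < PSI_ONE_TOL
    safe_denom = np.where(near_one, 1.0, denom)
    pi11 = np.where(near_one, pi1 * pi2, (a - np.sqrt(disc)) / safe_denom)
    # exact-zero margins can leave pi11 at rounding-level negatives
    pi11 = np.clip(pi11, 0.0, np.minimum(pi1, pi2))
    pi10 = pi1 - pi11
    pi01 = pi2 - pi11
    pi00 = 1.0 - pi10 - pi01 - pi11
    return pi11, pi10, pi01, pi00, a, b


def joint_probs(pi1: float, pi2: float, psi: float) -> JointProbTable:
    """Joint 2x2 cell probabilities from the margins and the cross-ratio.

    Parameters
    ----------
    pi1, pi2 : float
        Marginal probabilities Pr(Y1=1) and Pr(Y2=1), each in [0, 1].
    psi : float
        Cross-ratio, strictly positive.  ``psi = 1`` means independence.

    Returns
    -------
    JointProbTable
        Cells satisfying the margin constraints, the Frechet bounds, and
        (when all cells are positive) the cross-ratio identity.

    Examples
    --------
    >>> t = joint_probs(0.5, 0.5, 4.0)
    >>> round(t.pi11, 12)
    0.333333333333
    """
    pi11, pi10, pi01, pi00, a, b = joint_probs_arrays(pi1, pi2, psi)
    return JointProbTable(
        pi11=float(pi11), pi10=float(pi10), pi01=float(pi01), pi00=float(pi00),
        pi1=float(pi1), pi2=float(pi2), psi=float(psi), a=float(a), b=float(b),
    )


def cross_ratio(pi11, pi10, pi01, pi00):
    """Recompute psi = (pi00*pi11)/(pi10*pi01) from the four cells."""
    return (np.asarray(pi00) * np.asarray(pi11)) / (
        np.asarray(pi10) * np.asarray(pi01)
    )
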