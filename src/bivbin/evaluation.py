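"""Model evaluation: train/test splitting, joint-prediction accuracy,
outcome-association testing, and the three-model comparison report.

The headline metric is *joint* prediction accuracy: a subject counts as
correctly predicted only when BOTH binary endpoints are predicted
correctly.  It is therefore bounded above by the smaller of the two
marginal accuracies — an invariant the report checks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bivlogit import CELL_ORDER, BivariateLogisticRegression
from .dataset import BivariateBinaryDataset
from .ga import GAHybridClassifier
from .mlp import MLPJointClassifier

__all__ = [
    "SplitSpec",
    "EvaluationReport",
    "split",
    "joint_accuracy",
    "marginal_accuracy",
    "association_chi2",
    "joint_confusion",
    "compare_models",
    "default_models",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split settings; train size is round(train_fraction * n)."""

    train_fraction: float = 0.7
    seed: int = 0
    stratify: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def split(
    data: BivariateBinaryDataset, spec: SplitSpec
) -> tuple[BivariateBinaryDataset, BivariateBinaryDataset]:
    """Disjoint, exhaustive, seeded train/test partition.

    With ``stratify=True`` (default) rows are allocated per joint outcome
    cell by largest-remainder quotas, so rare cells (e.g. deaths) appear in
    both parts in near-population proportion.  n=263 at fraction 0.7 yields
    exactly 184 training and 79 test rows.
    """
    n = data.n
    n_train = int(round(spec.train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train_fraction={spec.train_fraction} leaves an empty part at n={n}"
        )
    rng = np.random.default_rng(spec.seed)
    if not spec.stratify:
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
    else:
        cell = data.y1.astype(int) * 2 + data.y2.astype(int)
        counts = np.bincount(cell, minlength=4)
        quota = n_train * counts / n
        base = np.floor(quota).astype(int)
        short = n_train - base.sum()
        # distribute the remaining slots by largest fractional part,
        # ties broken toward the larger cell then lower cell index
        frac_order = sorted(
            range(4), key=lambda c: (-(quota[c] - base[c]), -counts[c], c)
        )
        for c in frac_order[:short]:
            base[c] += 1
        tr_parts, te_parts = [], []
        for c in range(4):
            idx = np.flatnonzero(cell == c)
            idx = idx[rng.permutation(len(idx))]
            take = min(base[c], len(idx))
            tr_parts.append(idx[:take])
            te_parts.append(idx[take:])
        tr = np.sort(np.concatenate(tr_parts))
        te = np.sort(np.concatenate(te_parts))
    return data.subset(tr), data.subset(te)


def joint_accuracy(pred_pairs, true_pairs) -> float:
    """Percentage of rows where BOTH outcomes match, to 2 decimals."""
    pred = np.asarray(pred_pairs)
    true = np.asarray(true_pairs)
    if pred.shape != true.shape or pred.ndim != 2 or pred.shape[1] != 2:
        raise ValueError(f"shape mismatch: pred {pred.shape}, true {true.shape}")
    both = np.all(pred == true, axis=1)
    return round(100.0 * both.mean(), 2)


def marginal_accuracy(pred_pairs, true_pairs) -> tuple[float, float]:
    """Per-endpoint accuracies (percent, 2 decimals)."""
    pred = np.asarray(pred_pairs)
    true = np.asarray(true_pairs)
    if pred.shape != true.shape:
        raise ValueError("shape mismatch")
    acc = 100.0 * (pred == true).mean(axis=0)
    return round(float(acc[0]), 2), round(float(acc[1]), 2)


def association_chi2(y1, y2):
    """Pearson chi-square test of association between the two outcomes.

    Plain 2x2 Pearson statistic on the outcome table, 1 df, NO continuity
    correction; two-sided p from the chi-square distribution.  Returns
    (statistic, p_value, table) with table rows indexed by y1 in {1, 0}
    and columns by y2 in {1, 0}.  A zero margin leaves the test undefined:
    (nan, nan, table) with a warning.
    """
    y1 = np.asarray(y1).astype(int)
    y2 = np.asarray(y2).astype(int)
    table = np.array([
        [np.sum((y1 == 1) & (y2 == 1)), np.sum((y1 == 1) & (y2 == 0))],
        [np.sum((y1 == 0) & (y2 == 1)), np.sum((y1 == 0) & (y2 == 0))],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("a margin of the outcome table is empty; chi-square undefined")
        return np.nan, np.nan, table
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), table


def joint_confusion(pred_pairs, true_pairs) -> np.ndarray:
    """4x4 counts over joint cells; rows = true cell, cols = predicted cell,
    both in CELL_ORDER ((0,0), (0,1), (1,0), (1,1))."""
    pred = np.asarray(pred_pairs)
    true = np.asarray(true_pairs)
    ti = true[:, 0] * 2 + true[:, 1]
    pi = pred[:, 0] * 2 + pred[:, 1]
    conf = np.zeros((4, 4), dtype=int)
    np.add.at(conf, (ti, pi), 1)
    return conf


@dataclass
class EvaluationReport:
    """Per-model joint and marginal accuracies on both split parts."""

    metrics: dict[str, dict] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    split_sizes: tuple[int, int] = (0, 0)
    seed: int = 0

    def add(self, name: str, model, train: BivariateBinaryDataset,
            test: BivariateBinaryDataset) -> None:
        entry = {}
        for part_name, part in (("train", train), ("test", test)):
            pred = np.asarray(model.predict(part.X))
            truth = part.Y
            ja = joint_accuracy(pred, truth)
            m1, m2 = marginal_accuracy(pred, truth)
            assert ja <= min(m1, m2) + 1e-9, "joint accuracy exceeded a marginal"
            entry[f"joint_accuracy_{part_name}"] = ja
            entry[f"marginal_accuracy_y1_{part_name}"] = m1
            entry[f"marginal_accuracy_y2_{part_name}"] = m2
            entry[f"confusion_{part_name}"] = joint_confusion(pred, truth).tolist()
        self.metrics[name] = entry

    def to_frame(self) -> pd.DataFrame:
        """Accuracy table: rows = dataset part, columns = models."""
        cols = {
            name: [m["joint_accuracy_train"], m["joint_accuracy_test"]]
            for name, m in self.metrics.items()
        }
        return pd.DataFrame(cols, index=["Training", "Test"])

    def to_json(self) -> str:
        return json.dumps(
            {
                "split_sizes": list(self.split_sizes),
                "seed": self.seed,
                "metrics": self.metrics,
                "errors": self.errors,
            },
            indent=2,
        )


def default_models(seed: int = 0, hidden_units: int = 8, algorithm: str = "lm",
                   ga_generations: int = 100, ga_pop_size: int = 50) -> dict:
    """The three models compared throughout: BLR, plain network, hybrid."""
    return {
        "BLR": BivariateLogisticRegression(),
        "ANN": MLPJointClassifier(hidden_units=hidden_units, algorithm=algorithm,
                                  random_state=seed),
        "ANN-GA": GAHybridClassifier(hidden_units=hidden_units, algorithm=algorithm,
                                     generations=ga_generations,
                                     pop_size=ga_pop_size, random_state=seed),
    }


def paired_hybrid_comparison(
    n_pairs: int = 25,
    seed: int = 0,
    hidden_units: int = 6,
    max_epochs: int = 5,
) -> dict:
    """Paired comparison of hybrid vs plain-random-init training MSE.

    For each of ``n_pairs`` seeds, one synthetic cohort with covariate
    effects is generated; the hybrid (GA over initial weights, fitness =
    MSE after two inner training epochs, then Levenberg-Marquardt) and a
    plain network trained from a single random initialization share the
    same data, trainer and epoch budget.  The budget is deliberately short
    (initialization-limited regime): with a long budget both approaches
    converge to equivalent optima and initialization no longer matters.

    Returns a dict with the per-pair final training MSEs and the fraction
    of pairs in which the hybrid is at least as good.
    """
    from .ga import GAConfig, decode, evolve
    from .network import init_weights
    from .simulate import effect_cohort_spec, generate_dataset
    from .training import TrainConfig, train

    tc = TrainConfig(algorithm="lm", max_epochs=max_epochs)
    hybrid_mse, plain_mse = [], []
    for s in range(n_pairs):
        data = generate_dataset(effect_cohort_spec(seed=seed + 100 + s))
        ga = GAConfig(pop_size=20, generations=15, seed=seed + 1000 + s,
                      lamarckian_epochs=2)
        shape = (data.p, hidden_units)
        best, _ = evolve(data, shape, ga, tc)
        _, h = train(decode(best.genes, shape), data, tc)
        w0 = init_weights(data.p, hidden_units, seed=seed + 1000 + s)
        _, hp = train(w0, data, tc)
        hybrid_mse.append(h.final_mse)
        plain_mse.append(hp.final_mse)
    hybrid_mse, plain_mse = np.asarray(hybrid_mse), np.asarray(plain_mse)
    wins = hybrid_mse <= plain_mse + 1e-12
    return {
        "hybrid_mse": hybrid_mse,
        "plain_mse": plain_mse,
        "win_fraction": float(wins.mean()),
        "n_pairs": n_pairs,
    }


def compare_models(
    data: BivariateBinaryDataset,
    spec: SplitSpec | None = None,
    models: dict | None = None,
) -> EvaluationReport:
    """Fit every model on the same split and score joint/marginal accuracy.

    A model that raises during fit or predict is recorded under
    ``report.errors`` and the remaining models are still scored.
    """
    spec = spec or SplitSpec()
    models = models if models is not None else default_models(seed=spec.seed)
    train, test = split(data, spec)
    report = EvaluationReport(split_sizes=(train.n, test.n), seed=spec.seed)
    for name, model in models.items():
        try:
            model.fit(train.X, train.Y)
            report.add(name, model, train, test)
        except Exception as exc:  # noqa: BLE001 - per-model failure is recorded
            warnings.warn(f"model {name} failed: {exc}")
            report.errors[name] = str(exc)
    return report
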