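"""Real-coded genetic algorithm over initial network weights, and the
hybrid workflow: evolve a good starting weight vector, then gradient-train
from it.

A chromosome is the flat weight vector of a fixed p -> M -> 2 network
(ordering: W_hidden row-major, b_hidden, W_out row-major, b_out).  Fitness
is the training MSE of the decoded, untrained network — the GA optimizes
*initial* weights, so evolution stays cheap; an optional ``lamarckian_epochs``
setting runs a few gradient steps inside the fitness evaluation for
experimentation.  Operators are standard real-coded defaults: tournament
selection, whole-arithmetic blend crossover, per-gene Gaussian mutation,
and elitism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from .dataset import BivariateBinaryDataset
from .mlp import MinMaxRanges, MLPJointClassifier
from .network import forward
from .network import MLPWeights, mse, n_params
from .training import TrainConfig, TrainHistory, train

__all__ = [
    "Chromosome",
    "GAConfig",
    "encode",
    "decode",
    "fitness",
    "evolve",
    "train_hybrid",
    "GAHybridClassifier",
]


@dataclass
class Chromosome:
    genes: np.ndarray
    fitness: float = np.inf   # training MSE; lower is better

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=float).ravel()


@dataclass
class GAConfig:
    pop_size: int = 50
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.05
    mutation_sigma: float = 0.1
    elite_count: int = 2
    tournament_size: int = 2
    init_range: float = 0.5
    seed: int = 0
    lamarckian_epochs: int = 0   # gradient steps inside fitness (0 = off)

    def __post_init__(self) -> None:
        if self.pop_size < 1:
            raise ValueError("pop_size must be >= 1")
        if self.elite_count < 1 or self.elite_count > self.pop_size:
            raise ValueError("need 1 <= elite_count <= pop_size")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


def encode(weights: MLPWeights) -> np.ndarray:
    """Network -> flat gene vector (canonical ordering)."""
    return weights.flatten()


def decode(genes: np.ndarray, shape: tuple[int, int]) -> MLPWeights:
    """Flat gene vector -> network; exact inverse of :func:`encode`."""
    return MLPWeights.from_flat(np.asarray(genes, dtype=float), shape)


def fitness(
    chrom: Chromosome | np.ndarray,
    data: BivariateBinaryDataset,
    shape: tuple[int, int],
    lamarckian_epochs: int = 0,
    train_config: TrainConfig | None = None,
) -> float:
    """Training MSE of the decoded network (untrained by default)."""
    genes = chrom.genes if isinstance(chrom, Chromosome) else np.asarray(chrom)
    w = decode(genes, shape)
    if lamarckian_epochs > 0:
        cfg = replace(train_config or TrainConfig(), max_epochs=lamarckian_epochs,
                      validation_fraction=0.0)
        w, _ = train(w, data, cfg)
    return mse(w, data)


def _tournament(rng, fits: np.ndarray, k: int) -> int:
    contenders = rng.integers(0, len(fits), size=k)
    return int(contenders[np.argmin(fits[contenders])])


def evolve(
    data: BivariateBinaryDataset,
    shape: tuple[int, int],
    config: GAConfig,
    train_config: TrainConfig | None = None,
) -> tuple[Chromosome, list[float]]:
    """Run the GA; returns the best chromosome and the per-generation
    best-fitness trace (non-increasing, by elitism).

    The trace has ``generations + 1`` entries; entry 0 is the best of the
    initial population.  A chromosome whose fitness evaluates non-finite is
    reinitialized uniformly and logged via a warning.
    """
    p, M = shape
    L = n_params(p, M)
    rng = np.random.default_rng(config.seed)
    pop = rng.uniform(-config.init_range, config.init_range,
                      size=(config.pop_size, L))

    def eval_pop(pop: np.ndarray) -> np.ndarray:
        fits = np.empty(len(pop))
        for i, genes in enumerate(pop):
            fi = fitness(genes, data, shape, config.lamarckian_epochs, train_config)
            if not np.isfinite(fi):
                warnings.warn(f"non-finite fitness for chromosome {i}; reinitialized")
                pop[i] = rng.uniform(-config.init_range, config.init_range, size=L)
                fi = fitness(pop[i], data, shape, config.lamarckian_epochs, train_config)
            fits[i] = fi
        return fits

    fits = eval_pop(pop)
    trace = [float(fits.min())]

    for _ in range(config.generations):
        order = np.argsort(fits, kind="stable")
        elites = pop[order[: config.elite_count]].copy()
        children = [*elites]
        while len(children) < config.pop_size:
            i = _tournament(rng, fits, config.tournament_size)
            j = _tournament(rng, fits, config.tournament_size)
            a, b = pop[i].copy(), pop[j].copy()
            if rng.random() < config.crossover_prob:
                u = rng.random()
                a, b = u * a + (1 - u) * b, u * b + (1 - u) * a
            for child in (a, b):
                mask = rng.random(L) < config.mutation_prob
                child[mask] += rng.normal(0.0, config.mutation_sigma, size=mask.sum())
                if len(children) < config.pop_size:
                    children.append(child)
        pop = np.asarray(children)
        fits = eval_pop(pop)
        trace.append(float(min(trace[-1], fits.min())))

    best = int(np.argmin(fits))
    # elitism guarantees the all-time best survives in the final population
    return Chromosome(pop[best].copy(), float(fits[best])), trace


def train_hybrid(
    data: BivariateBinaryDataset,
    M: int,
    ga_config: GAConfig,
    train_config: TrainConfig,
) -> tuple[MLPWeights, TrainHistory, list[float]]:
    """Evolve initial weights, then gradient-train from the best chromosome.

    With ``generations=0, pop_size=1`` this reduces to plain training from a
    single seeded uniform random initialization.
    """
    shape = (data.p, M)
    best, trace = evolve(data, shape, ga_config)
    weights, history = train(decode(best.genes, shape), data, train_config)
    return weights, history, trace


class GAHybridClassifier(BaseEstimator):
    """Hybrid network classifier: GA-optimized initial weights, then
    gradient training (Levenberg-Marquardt by default).

    Shares the prediction surface and input scaling of
    :class:`bivbin.mlp.MLPJointClassifier`.  GA settings mirror
    :class:`GAConfig`; training settings mirror the plain estimator.

    Attributes
    ----------
    weights_ : MLPWeights
    history_ : TrainHistory
    ga_trace_ : list of per-generation best fitness
    best_chromosome_ : Chromosome
    """

    def __init__(
        self,
        hidden_units: int = 8,
        algorithm: str = "lm",
        max_epochs: int = 500,
        pop_size: int = 50,
        generations: int = 100,
        crossover_prob: float = 0.8,
        mutation_prob: float = 0.05,
        mutation_sigma: float = 0.1,
        elite_count: int = 2,
        tournament_size: int = 2,
        init_range: float = 0.5,
        lamarckian_epochs: int = 0,
        learning_rate: float = 0.5,
        momentum: float = 0.9,
        tol_grad: float = 1e-6,
        tol_mse: float = 1e-10,
        random_state: int = 0,
        scale_inputs: bool = True,
    ):
        self.hidden_units = hidden_units
        self.algorithm = algorithm
        self.max_epochs = max_epochs
        self.pop_size = pop_size
        self.generations = generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.mutation_sigma = mutation_sigma
        self.elite_count = elite_count
        self.tournament_size = tournament_size
        self.init_range = init_range
        self.lamarckian_epochs = lamarckian_epochs
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.tol_grad = tol_grad
        self.tol_mse = tol_mse
        self.random_state = random_state
        self.scale_inputs = scale_inputs

    def fit(self, X, Y=None, *, y1=None, y2=None):
        base = MLPJointClassifier(
            hidden_units=self.hidden_units, algorithm=self.algorithm,
            max_epochs=self.max_epochs, learning_rate=self.learning_rate,
            momentum=self.momentum, tol_grad=self.tol_grad, tol_mse=self.tol_mse,
            random_state=self.random_state, scale_inputs=self.scale_inputs,
        )
        data = base._as_dataset(X, Y, y1, y2)
        ga_cfg = GAConfig(
            pop_size=self.pop_size, generations=self.generations,
            crossover_prob=self.crossover_prob, mutation_prob=self.mutation_prob,
            mutation_sigma=self.mutation_sigma, elite_count=min(self.elite_count, self.pop_size),
            tournament_size=self.tournament_size, init_range=self.init_range,
            seed=self.random_state, lamarckian_epochs=self.lamarckian_epochs,
        )
        # GA fitness must see the same scaled inputs the trainer will see
        scaler = MinMaxRanges(data.X) if self.scale_inputs else None
        Xs = scaler.transform(data.X) if scaler else data.X
        scaled = BivariateBinaryDataset(Xs, data.y1, data.y2, data.covariate_names)
        shape = (data.p, self.hidden_units)
        self.best_chromosome_, self.ga_trace_ = evolve(scaled, shape, ga_cfg)
        base.initial_weights = decode(self.best_chromosome_.genes, shape)
        base.scale_inputs = False  # already scaled; avoid double scaling
        base.fit(scaled)
        base.scaler_ = scaler
        self._base = base
        self.weights_ = base.weights_
        self.history_ = base.history_
        self.train_mse_ = base.train_mse_
        self.scaler_ = scaler
        self.n_features_in_ = data.p
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = self.scaler_.transform(X) if self.scaler_ else X
        return forward(self.weights_, Xs)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) > 0.5).astype(int)
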