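"""Genetic-algorithm search over fixed-length descriptor subsets (GFA-style).

Each individual is a set of ``equation_length`` descriptor column indices;
its fitness is the training-set R^2 of the OLS model on those columns
(singular fits score 0). The search uses tournament selection (size 2),
subset-union crossover, single-gene mutation at probability
``mutation_probability``, elitism, and fitness memoization (the landscape is
static, so each distinct subset is fit at most once). Defaults mirror a
classical genetic-function-approximation setup for a 3-descriptor QSAR
equation: population 1000, up to 500 generations, mutation probability 0.1,
fitness = R^2.

No spline terms: candidate equations are plain multiple linear regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from sklearn.base import BaseEstimator

from .data import DataSet
from .errors import RadqsarError, SearchSpaceError, SingularityError
from .stats import LinearQsarRegressor, MlrModel, RegressionStats

__all__ = ["GaConfig", "CandidateModel", "GaResult", "GeneticDescriptorSelector",
           "init_population", "crossover", "mutate", "run_ga", "exhaustive_best"]


@dataclass(frozen=True)
class GaConfig:
    """Tunable settings of the subset search.

    ``equation_length`` is exact: every candidate equation has this many
    descriptors (all published models here use 3)."""

    equation_length: int = 3
    population_size: int = 1000
    max_generations: int = 500
    mutation_probability: float = 0.1
    elitism_count: int = 10
    tournament_size: int = 2
    stagnation_patience: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.equation_length < 1:
            raise RadqsarError("equation_length must be >= 1")
        if not 0.0 <= self.mutation_probability <= 1.0:
            raise RadqsarError("mutation_probability must be in [0, 1]")
        if self.population_size < 2:
            raise RadqsarError("population_size must be >= 2")


@dataclass(frozen=True)
class CandidateModel:
    """A scored descriptor subset; ``fitness`` is the training R^2."""

    descriptor_ids: tuple[str, ...]
    fitness: float
    fitted: MlrModel | None = None
    stats: RegressionStats | None = None


@dataclass
class GaResult:
    """Ranked, de-duplicated population after the run.

    Models are sorted by fitness descending, ties broken by descriptor-id
    tuple, so the ranking is deterministic."""

    ranked_models: list[CandidateModel]
    generations_run: int
    seed: int
    fitness_history: list[float] = field(default_factory=list)

    @property
    def best(self) -> CandidateModel:
        return self.ranked_models[0]


def init_population(cfg: GaConfig, n_descriptors: int,
                    rng: np.random.Generator) -> list[tuple[int, ...]]:
    """Draw ``population_size`` random subsets of size ``equation_length``.

    Individuals may repeat across the population, but within one individual
    all indices are distinct."""
    if comb(n_descriptors, cfg.equation_length) < 2:
        raise SearchSpaceError(
            f"search space C({n_descriptors},{cfg.equation_length}) < 2")
    return [tuple(sorted(rng.choice(n_descriptors, size=cfg.equation_length,
                                    replace=False)))
            for _ in range(cfg.population_size)]


def crossover(a: tuple[int, ...], b: tuple[int, ...],
              rng: np.random.Generator) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Produce two offspring by sampling (without replacement) from the union
    of the parents' genes; offspring size equals the parents'."""
    union = np.array(sorted(set(a) | set(b)))
    length = len(a)
    off1 = tuple(sorted(rng.choice(union, size=length, replace=False)))
    off2 = tuple(sorted(rng.choice(union, size=length, replace=False)))
    return off1, off2


def mutate(ids: tuple[int, ...], cfg: GaConfig, n_descriptors: int,
           rng: np.random.Generator) -> tuple[int, ...]:
    """With probability ``mutation_probability``, replace one uniformly chosen
    gene by a uniformly chosen unused descriptor index."""
    if rng.random() >= cfg.mutation_probability:
        return ids
    unused = np.array(sorted(set(range(n_descriptors)) - set(ids)))
    if unused.size == 0:
        return ids
    drop = int(rng.integers(len(ids)))
    new = int(unused[rng.integers(unused.size)])
    out = list(ids)
    out[drop] = new
    return tuple(sorted(out))


class GeneticDescriptorSelector(BaseEstimator):
    """scikit-learn-style selector wrapping the GA subset search.

    Parameters mirror :class:`GaConfig`. After :meth:`fit` the attributes
    ``result_`` (full :class:`GaResult`), ``best_subset_`` (descriptor ids)
    and ``best_model_`` are available; :meth:`transform` projects a feature
    frame/array onto the selected columns.
    """

    def __init__(self, equation_length: int = 3, population_size: int = 1000,
                 max_generations: int = 500, mutation_probability: float = 0.1,
                 elitism_count: int = 10, tournament_size: int = 2,
                 stagnation_patience: int = 50, rng_seed: int = 0):
        self.equation_length = equation_length
        self.population_size = population_size
        self.max_generations = max_generations
        self.mutation_probability = mutation_probability
        self.elitism_count = elitism_count
        self.tournament_size = tournament_size
        self.stagnation_patience = stagnation_patience
        self.rng_seed = rng_seed

    def _config(self) -> GaConfig:
        return GaConfig(**{k: getattr(self, k) for k in GaConfig.__dataclass_fields__})

    def fit(self, X, y, feature_names: list[str] | None = None
            ) -> "GeneticDescriptorSelector":
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            feature_names = [str(c) for c in X.columns]
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"X{j + 1}" for j in range(X.shape[1])]
        y = np.asarray(y, dtype=float).ravel()
        cfg = self._config()
        if X.shape[0] <= cfg.equation_length + 2:
            raise RadqsarError(
                f"need more than {cfg.equation_length + 2} training rows, "
                f"got {X.shape[0]}")
        self.feature_names_in_ = feature_names
        self.result_ = _evolve(X, y, feature_names, cfg)
        self.best_subset_ = list(self.result_.best.descriptor_ids)
        self.best_model_ = self.result_.best.fitted
        return self

    def transform(self, X):
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            return X[self.best_subset_]
        cols = [self.feature_names_in_.index(d) for d in self.best_subset_]
        return np.asarray(X, dtype=float)[:, cols]


def _fitness_factory(X: np.ndarray, y: np.ndarray, names: list[str]):
    cache: dict[tuple[int, ...], tuple[float, MlrModel | None, RegressionStats | None]] = {}

    def evaluate(ids: tuple[int, ...]):
        hit = cache.get(ids)
        if hit is not None:
            return hit
        try:
            est = LinearQsarRegressor(compute_press=False).fit(X[:, list(ids)], y)
        except (SingularityError, RadqsarError) as exc:
            warnings.warn(f"singular subset {tuple(names[i] for i in ids)} "
                          f"scored 0: {exc}", UserWarning, stacklevel=2)
            cache[ids] = (0.0, None, None)
            return cache[ids]
        model = MlrModel(tuple(names[i] for i in ids),
                         tuple(float(c) for c in est.coef_), est.intercept_)
        cache[ids] = (est.stats_.r2, model, est.stats_)
        return cache[ids]

    return evaluate, cache


def _evolve(X: np.ndarray, y: np.ndarray, names: list[str],
            cfg: GaConfig) -> GaResult:
    rng = np.random.default_rng(cfg.rng_seed)
    m = X.shape[1]
    evaluate, cache = _fitness_factory(X, y, names)

    population = init_population(cfg, m, rng)
    fitness = np.array([evaluate(ind)[0] for ind in population])
    history: list[float] = []
    best_so_far = -np.inf
    stagnant = 0
    gen = 0
    for gen in range(1, cfg.max_generations + 1):
        order = np.lexsort((
            [ind for ind in range(len(population))], -fitness))
        elite = [population[i] for i in order[:cfg.elitism_count]]

        n_children = cfg.population_size - len(elite)
        children: list[tuple[int, ...]] = []
        # tournament selection, size cfg.tournament_size, winner = higher R^2
        while len(children) < n_children:
            parents = []
            for _ in range(2):
                idx = rng.integers(0, len(population), size=cfg.tournament_size)
                parents.append(population[idx[np.argmax(fitness[idx])]])
            off1, off2 = crossover(parents[0], parents[1], rng)
            children.append(mutate(off1, cfg, m, rng))
            if len(children) < n_children:
                children.append(mutate(off2, cfg, m, rng))

        population = elite + children
        fitness = np.array([evaluate(ind)[0] for ind in population])
        best = float(fitness.max())
        history.append(best)
        if best > best_so_far + 1e-15:
            best_so_far = best
            stagnant = 0
        else:
            stagnant += 1
        if stagnant >= cfg.stagnation_patience:
            break

    ranked = sorted(
        (CandidateModel(tuple(names[i] for i in ids), fit, model, st)
         for ids, (fit, model, st) in cache.items()),
        key=lambda c: (-c.fitness, c.descriptor_ids))
    return GaResult(ranked_models=ranked, generations_run=gen,
                    seed=cfg.rng_seed, fitness_history=history)


def run_ga(ds_train: DataSet, response_id: str,
           cfg: GaConfig | None = None) -> GaResult:
    """Run the GA on a training :class:`DataSet` for one activity."""
    cfg = cfg or GaConfig()
    sel = GeneticDescriptorSelector(**{
        k: getattr(cfg, k) for k in GaConfig.__dataclass_fields__})
    sel.fit(ds_train.descriptors.values, ds_train.activities.response(response_id),
            feature_names=ds_train.descriptors.descriptor_ids)
    return sel.result_


def exhaustive_best(X, y, length: int, feature_names: list[str] | None = None,
                    limit: int = 100_000) -> CandidateModel:
    """Enumerate every descriptor subset of the given length and return the
    one with maximal training R^2 (ties -> lexicographically smallest subset).
    Serves as the exact oracle the GA is validated against."""
    import pandas as pd

    if isinstance(X, DataSet):  # convenience: (DataSet, "Y1", length)
        ds, response_id = X, y
        feature_names = ds.descriptors.descriptor_ids
        y = ds.activities.response(response_id)
        X = ds.descriptors.values
    if isinstance(X, pd.DataFrame):
        feature_names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"X{j + 1}" for j in range(X.shape[1])]
    m = X.shape[1]
    if comb(m, length) > limit:
        raise SearchSpaceError(
            f"C({m},{length}) exceeds the enumeration limit {limit}")
    evaluate, _ = _fitness_factory(X, np.asarray(y, dtype=float).ravel(),
                                   feature_names)
    # combinations() yields subsets in lexicographic order, so keeping only
    # strictly better candidates breaks ties toward the smallest subset.
    best: CandidateModel | None = None
    for ids in combinations(range(m), length):
        fit, model, st = evaluate(ids)
        if best is None or fit > best.fitness:
            best = CandidateModel(tuple(feature_names[i] for i in ids), fit,
                                  model, st)
    return best
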