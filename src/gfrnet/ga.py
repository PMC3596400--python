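"""Genetic-algorithm weight initialization and the composed GABP trainer.

All weights and thresholds of a network are flattened into one
real-valued chromosome.  A small generational GA — tournament selection,
uniform crossover, Gaussian mutation, elitism — searches the gene box
for an initialization whose decoded network already performs well on the
internal-validation set; the best chromosome found then seeds a full
backpropagation run ("GABP").  Elitism makes the best-fitness history
non-increasing, and every stage is driven by one seed, so runs are
exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .ann import (
    NetworkParameters,
    NetworkTopology,
    TrainingConfig,
    forward,
    mse,
    train_bp,
)

__all__ = ["GaConfig", "encode", "decode", "evolve", "gabp_train"]


def encode(params: NetworkParameters) -> np.ndarray:
    """Flatten a parameter set into a chromosome.

    Order: input→hidden weights (row-major), hidden thresholds,
    hidden→output weights, output threshold.  Bijective with
    :func:`decode`.
    """
    return np.concatenate(
        [
            params.w_hidden.ravel(),
            params.b_hidden,
            params.w_output,
            [params.b_output],
        ]
    )


def decode(chromosome: np.ndarray, topology: NetworkTopology) -> NetworkParameters:
    """Inverse of :func:`encode` for a given topology."""
    c = np.asarray(chromosome, dtype=float).ravel()
    h, d = topology.n_hidden, topology.n_input
    expected = topology.n_parameters
    if c.size != expected:
        raise ValueError(
            f"chromosome length {c.size} does not match topology {topology} "
            f"({expected} parameters)"
        )
    i = h * d
    return NetworkParameters(
        w_hidden=c[:i].reshape(h, d),
        b_hidden=c[i : i + h],
        w_output=c[i + h : i + 2 * h],
        b_output=float(c[-1]),
    )


@dataclass(frozen=True)
class GaConfig:
    """GA hyperparameters (all conventional small-GA defaults, configurable)."""

    population: int = 40
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    mutation_scale: float = 0.1
    elitism: int = 2
    bounds: Tuple[float, float] = (-3.0, 3.0)
    tournament: int = 2
    seed: int = 0
    #: optional BP burst inside the fitness evaluation (0 = evaluate the
    #: decoded network as-is, the default)
    refine_epochs: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0 <= self.crossover_prob <= 1 or not 0 <= self.mutation_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if not 1 <= self.elitism <= self.population:
            raise ValueError("elitism must satisfy 1 <= elitism <= population")
        if self.bounds[1] <= self.bounds[0]:
            raise ValueError("gene bounds must be ordered")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


def evolve(
    fitness_fn: Callable[[np.ndarray], float],
    chromosome_length: int,
    config: GaConfig = GaConfig(),
    initial_population: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, List[float]]:
    """Minimize ``fitness_fn`` over the gene box; lower fitness is better.

    Generational loop: elitism carries the ``config.elitism`` best
    chromosomes unchanged, the rest of the offspring come from
    size-``tournament`` tournament selection, uniform crossover and
    Gaussian mutation whose scale anneals linearly from
    ``mutation_scale`` of the box width to a tenth of that by the final
    generation (coarse search early, fine-tuning late).  Non-finite
    fitness values are ranked worst rather than crashing the run.

    Returns the best chromosome and the per-generation best-fitness
    history (non-increasing, by elitism).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    width = hi - lo
    pop = (
        np.array(initial_population, dtype=float, copy=True)
        if initial_population is not None
        else rng.uniform(lo, hi, size=(config.population, chromosome_length))
    )
    if pop.shape != (config.population, chromosome_length):
        raise ValueError(
            f"initial population shape {pop.shape} != "
            f"({config.population}, {chromosome_length})"
        )

    def evaluate(chrom: np.ndarray) -> float:
        f = float(fitness_fn(chrom))
        return f if np.isfinite(f) else np.inf

    fitness = np.array([evaluate(c) for c in pop])
    history: List[float] = []

    for gen in range(config.generations):
        order = np.argsort(fitness, kind="stable")
        pop, fitness = pop[order], fitness[order]
        history.append(float(fitness[0]))

        # anneal the mutation step from full scale down to 10% of it
        frac = gen / max(config.generations - 1, 1)
        sigma = config.mutation_scale * width * (1.0 - 0.9 * frac)

        children = [pop[i].copy() for i in range(config.elitism)]
        while len(children) < config.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population, size=config.tournament)
                parents.append(pop[contenders[np.argmin(fitness[contenders])]])
            a, b = parents[0].copy(), parents[1].copy()
            if rng.random() < config.crossover_prob:
                mask = rng.random(chromosome_length) < 0.5
                a[mask], b[mask] = b[mask], a[mask].copy()
            for child in (a, b):
                if len(children) >= config.population:
                    break
                mut = rng.random(chromosome_length) < config.mutation_prob
                child[mut] += rng.normal(0.0, sigma, size=int(mut.sum()))
                np.clip(child, lo, hi, out=child)
                children.append(child)
        new_pop = np.array(children)
        new_fitness = fitness.copy()
        # elites keep their cached fitness; offspring are (re)evaluated
        for i in range(config.elitism, config.population):
            new_fitness[i] = evaluate(new_pop[i])
        pop, fitness = new_pop, new_fitness

    best_idx = int(np.argmin(fitness))
    history.append(float(fitness[best_idx]))
    return pop[best_idx].copy(), history


@dataclass
class GabpInfo:
    """Provenance of a GABP training run."""

    topology: NetworkTopology
    ga_config: GaConfig
    bp_config: TrainingConfig
    ga_history: List[float] = field(default_factory=list)
    val_mse: float = float("nan")
    dev_mse: float = float("nan")


def gabp_train(
    X_dev: np.ndarray,
    y_dev: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    topology: NetworkTopology,
    ga_config: GaConfig = GaConfig(),
    bp_config: TrainingConfig = TrainingConfig(),
    initial_population: Optional[np.ndarray] = None,
) -> Tuple[NetworkParameters, GabpInfo]:
    """GA-optimized initialization followed by full backpropagation.

    The fitness of a chromosome is the internal-validation MSE of the
    decoded network (optionally after a short ``refine_epochs`` BP
    burst).  The GA's best chromosome initializes a complete
    :func:`~gfrnet.ann.train_bp` run.
    """
    X_dev = np.atleast_2d(np.asarray(X_dev, dtype=float))
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    y_dev = np.asarray(y_dev, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()

    def fitness(chromosome: np.ndarray) -> float:
        params = decode(chromosome, topology)
        if ga_config.refine_epochs > 0:
            burst = TrainingConfig(
                learning_rate=bp_config.learning_rate,
                max_epochs=ga_config.refine_epochs,
                patience=0,
                seed=bp_config.seed,
            )
            params, _ = train_bp(X_dev, y_dev, X_val, y_val, params, burst)
        return mse(forward(params, X_val), y_val)

    best_chromosome, ga_history = evolve(
        fitness, topology.n_parameters, ga_config, initial_population
    )
    params, _ = train_bp(
        X_dev, y_dev, X_val, y_val, decode(best_chromosome, topology), bp_config
    )
    info = GabpInfo(
        topology=topology,
        ga_config=ga_config,
        bp_config=bp_config,
        ga_history=ga_history,
        val_mse=mse(forward(params, X_val), y_val),
        dev_mse=mse(forward(params, X_dev), y_dev),
    )
    return params, info
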