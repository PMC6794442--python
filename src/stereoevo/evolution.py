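"""Genetic algorithm: lifetime evaluation, roulette selection, exchange.

Each generation of an evolving population: draw a fresh seeded bank of
lifetime stimuli, score every individual by its summed lifetime error
(sum over trials of |response - disparity|, in degrees), convert errors to
non-negative success scores (max-minus-error), spin a fitness-proportionate
roulette wheel once per slot of the next generation, randomly exchange
parameters between individuals to introduce diversity, and apply a small
Gaussian mutation.  There is no elitism.  Replicate populations evolve
independently from seeds split deterministically off the master seed.

Far- and near-polarity second-order units evolve separately; third-order
units evolve afterwards against relative-disparity labels, with the frozen
second-order genomes cloned at the reference position.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .frontend import MonocularAssembly, place_monocular_pairs
from .geometry import DEFAULT_GEOMETRY, SensorGeometry
from .network import (
    Genome,
    N_CONNECTIONS,
    init_ranges,
    param_bounds,
    array_to_genome,
    genome_to_array,
    init_population,
    population_responses,
    second_order_response,
    third_order_inputs,
    third_order_response,
)
from .stimuli import (
    MAX_DISPARITY,
    StimulusBank,
    make_absolute_bank,
    make_control_bank,
    make_relative_bank,
)

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


@dataclass(frozen=True)
class EvolutionConfig:
    """Genetic-algorithm settings.

    Defaults are the full-scale study conditions (20 populations of 500
    networks, 200-stimulus lifetimes, 2,500 generations, 80% exchange);
    :meth:`desk` returns the reduced configuration used for desk-scale runs
    and acceptance measurements.
    """

    n_populations: int = 20
    population_size: int = 500
    lifetime_stimuli: int = 200
    generations: int = 2500
    exchange_probability: float = 0.8
    mutation_probability: float = 0.02
    mutation_scale: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_populations", "population_size", "lifetime_stimuli"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        for name in ("exchange_probability", "mutation_probability"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_scale < 0:
            raise ValueError("mutation_scale must be >= 0")

    @classmethod
    def desk(cls, master_seed: int = 0, **overrides) -> "EvolutionConfig":
        """Reduced configuration: 5 populations x 200 networks x 600 generations."""
        base = dict(
            n_populations=5,
            population_size=200,
            lifetime_stimuli=200,
            generations=600,
            master_seed=master_seed,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class RunResult:
    """Outcome of one evolution experiment across replicate populations."""

    stage: str
    polarity: str
    config: EvolutionConfig
    bank_params: dict
    traces: np.ndarray  # (n_populations, generations) mean lifetime error
    final_params: list  # per population: (population_size, 4, 4) array
    final_errors: list  # per population: lifetime errors on the eval bank
    eval_bank_seeds: list
    population_seeds: list

    @property
    def best_genomes(self) -> list:
        """Each population's lowest-error individual on its evaluation bank."""
        out = []
        for params, errors in zip(self.final_params, self.final_errors):
            out.append(array_to_genome(params[int(np.argmin(errors))], self.stage, self.polarity))
        return out

    def top_genomes(self, k: int) -> list:
        """The k lowest-error individuals of every population, concatenated."""
        out = []
        for params, errors in zip(self.final_params, self.final_errors):
            for idx in np.argsort(errors)[:k]:
                out.append(array_to_genome(params[idx], self.stage, self.polarity))
        return out

    def save(self, path) -> None:
        """Write genomes + seeds as JSON and error traces as CSV."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        payload = {
            "stage": self.stage,
            "polarity": self.polarity,
            "config": self.config.__dict__,
            "bank_params": self.bank_params,
            "eval_bank_seeds": [int(s) for s in self.eval_bank_seeds],
            "population_seeds": [int(s) for s in self.population_seeds],
            "final_params": [p.tolist() for p in self.final_params],
            "final_errors": [e.tolist() for e in self.final_errors],
        }
        (path / "run.json").write_text(json.dumps(payload))
        frame = pd.DataFrame(
            self.traces.T,
            columns=[f"population_{i}" for i in range(self.traces.shape[0])],
        )
        frame.insert(0, "generation", np.arange(self.traces.shape[1]))
        frame.to_csv(path / "traces.csv", index=False)

    @classmethod
    def load(cls, path) -> "RunResult":
        path = Path(path)
        payload = json.loads((path / "run.json").read_text())
        frame = pd.read_csv(path / "traces.csv")
        traces = frame.drop(columns=["generation"]).to_numpy().T
        return cls(
            stage=payload["stage"],
            polarity=payload["polarity"],
            config=EvolutionConfig(**payload["config"]),
            bank_params=payload["bank_params"],
            traces=traces,
            final_params=[np.asarray(p) for p in payload["final_params"]],
            final_errors=[np.asarray(e) for e in payload["final_errors"]],
            eval_bank_seeds=payload["eval_bank_seeds"],
            population_seeds=payload["population_seeds"],
        )


# ---------------------------------------------------------------------------
# Fitness

def training_targets(bank: StimulusBank) -> np.ndarray:
    """Training disparity per trial: the magnitude of the signed label.

    Far/near (and rel_far/rel_near) units evolve separately, so each network
    reports the disparity magnitude of its own polarity; the sign lives in
    the network's identity.
    """
    return np.abs(bank.labels)


def bank_responses(
    genome: Genome,
    bank: StimulusBank,
    assembly: MonocularAssembly,
    second_order: Optional[tuple] = None,
) -> np.ndarray:
    """Forward responses of one genome on every trial of a bank.

    Third-order genomes need ``second_order=(far_genome, near_genome)``, the
    frozen absolute-disparity units cloned at the reference position.
    """
    activities = assembly.bank_activities(bank)
    if genome.stage == "second_order":
        if activities.shape[1] < 4:
            raise ValueError("assembly does not provide the four monocular inputs")
        return second_order_response(activities[:, :4], genome)
    if second_order is None:
        raise ValueError("third-order evaluation needs frozen second-order genomes")
    far_g, near_g = second_order
    return third_order_response(third_order_inputs(activities, far_g, near_g), genome)


def lifetime_error(
    genome: Genome,
    bank: StimulusBank,
    assembly: MonocularAssembly,
    second_order: Optional[tuple] = None,
) -> float:
    """Summed lifetime error: sum over trials of |response - disparity| (deg)."""
    _check_bank_compatible(genome, bank)
    responses = bank_responses(genome, bank, assembly, second_order)
    return float(np.sum(np.abs(responses - training_targets(bank))))


def _check_bank_compatible(genome: Genome, bank: StimulusBank) -> None:
    absolute = bank.kind in ("absolute_far", "absolute_near", "control")
    if genome.stage == "second_order" and not absolute:
        raise ValueError("second-order genomes train on absolute-disparity banks")
    if genome.stage == "third_order" and bank.kind != "relative":
        raise ValueError("third-order genomes train on relative-disparity banks")


def success_scores(errors: np.ndarray) -> np.ndarray:
    """Non-negative selection weights: worst-error-minus-own-error.

    Lower lifetime error yields a larger roulette sector; if every individual
    has the same error the scores fall back to uniform weights.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size < 1:
        raise ValueError("need at least one individual")
    if np.any(errors < 0):
        raise ValueError("lifetime errors must be non-negative")
    scores = errors.max() - errors
    if np.all(scores == 0):
        return np.ones_like(errors)
    return scores


def roulette_select(scores: np.ndarray, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Fitness-proportionate parent indices (n_draws independent spins).

    Implemented with cumulative sums and half-open sectors: a spin landing
    exactly on a boundary belongs to the higher index's sector.  All-zero
    scores fall back to uniform selection (logged).
    """
    scores = np.asarray(scores, dtype=float)
    if np.any(scores < 0):
        raise ValueError("scores must be non-negative")
    total = scores.sum()
    if total <= 0:
        logger.warning("all-zero selection scores; falling back to uniform selection")
        return rng.integers(0, scores.size, n_draws)
    cum = np.cumsum(scores)
    spins = rng.random(n_draws) * total
    return np.searchsorted(cum, spins, side="right")


# ---------------------------------------------------------------------------
# Variation

def _exchange_array(params: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """In-place random parameter exchange between individuals.

    Each individual, with probability ``p``, is paired with a uniformly
    chosen *other* individual, and each scalar parameter (gain, slope,
    offset, sign per connection) is swapped between the two with probability
    one half.  Swapping conserves the population-wide parameter multiset.
    """
    size = params.shape[0]
    if size < 2:
        if p > 0:
            logger.warning("population of size 1: exchange is a no-op")
        return params
    for i in range(size):
        if rng.random() >= p:
            continue
        j = int(rng.integers(size - 1))
        if j >= i:
            j += 1
        mask = rng.random((N_CONNECTIONS, 4)) < 0.5
        a = params[i].copy()
        params[i][mask] = params[j][mask]
        params[j][mask] = a[mask]
    return params


def exchange_parameters(population, p: float, rng: np.random.Generator):
    """Parameter exchange on either a genome list or a population array."""
    if isinstance(population, np.ndarray):
        return _exchange_array(population, p, rng)
    if not population:
        return population
    stage, polarity = population[0].stage, population[0].polarity
    params = np.stack([genome_to_array(g) for g in population])
    _exchange_array(params, p, rng)
    return [array_to_genome(row, stage, polarity) for row in params]


def mutate_population(
    params: np.ndarray,
    rng: np.random.Generator,
    probability: float = 0.02,
    scale: float = 0.05,
    stage: str = "second_order",
) -> np.ndarray:
    """In-place Gaussian mutation, clipped to the stage's parameter bounds.

    Each continuous parameter mutates with ``probability`` by a Gaussian
    step whose s.d. is ``scale`` times the parameter's initialisation range;
    signs flip with the same probability.  Pure exchange cannot create
    parameter values absent from the initial population; this can.
    """
    if probability <= 0:
        return params
    ranges = init_ranges(stage)
    bounds = param_bounds(stage)
    shape = params.shape[:2]
    for k, name in enumerate(("gain", "slope", "offset")):
        lo_i, hi_i = ranges[name]
        lo, hi = bounds[name]
        mask = rng.random(shape) < probability
        steps = rng.normal(0.0, scale * (hi_i - lo_i), int(mask.sum()))
        values = params[:, :, k]
        values[mask] = np.clip(values[mask] + steps, lo, hi)
    flip = rng.random(shape) < probability
    params[:, :, 3][flip] *= -1.0
    return params


# ---------------------------------------------------------------------------
# Generational loops

def _population_seeds(master_seed: int, n: int) -> list:
    """Deterministic per-population seed split (documented rule)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s % _SEED_MOD) for s in ss.generate_state(n, dtype=np.uint64)]


def _run_populations(
    config: EvolutionConfig,
    stage: str,
    polarity: str,
    bank_params: dict,
    make_bank: Callable[[int, int], StimulusBank],
    inputs_for_bank: Callable[[StimulusBank, int], np.ndarray],
) -> RunResult:
    """Shared engine: evolve every replicate population.

    ``make_bank(seed, n)`` draws a fresh lifetime bank; ``inputs_for_bank``
    maps a bank (and population index) to the (n, 4) input matrix shared by
    all individuals — monocular activities are computed once per bank, a
    pure optimisation that is bit-equivalent to per-individual evaluation.
    """
    seeds = _population_seeds(config.master_seed, config.n_populations)
    traces = np.zeros((config.n_populations, config.generations))
    final_params, final_errors, eval_seeds = [], [], []
    for pop_index, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        params = init_population(stage, polarity, config.population_size, rng)
        for gen in range(config.generations):
            bank_seed = int(rng.integers(_SEED_MOD))
            bank = make_bank(bank_seed, config.lifetime_stimuli)
            inputs = inputs_for_bank(bank, pop_index)
            targets = training_targets(bank)
            responses = population_responses(params, inputs)
            errors = np.abs(responses - targets[None, :]).sum(axis=1)
            traces[pop_index, gen] = errors.mean()
            parents = roulette_select(success_scores(errors), config.population_size, rng)
            params = params[parents].copy()
            _exchange_array(params, config.exchange_probability, rng)
            mutate_population(
                params, rng, config.mutation_probability, config.mutation_scale, stage
            )
        eval_seed = int(rng.integers(_SEED_MOD))
        bank = make_bank(eval_seed, config.lifetime_stimuli)
        inputs = inputs_for_bank(bank, pop_index)
        errors = np.abs(
            population_responses(params, inputs) - training_targets(bank)[None, :]
        ).sum(axis=1)
        final_params.append(params)
        final_errors.append(errors)
        eval_seeds.append(eval_seed)
        logger.info(
            "%s/%s population %d: final mean error %.3f, best %.3f",
            stage, polarity, pop_index, errors.mean(), errors.min(),
        )
    return RunResult(
        stage=stage,
        polarity=polarity,
        config=config,
        bank_params=bank_params,
        traces=traces,
        final_params=final_params,
        final_errors=final_errors,
        eval_bank_seeds=eval_seeds,
        population_seeds=seeds,
    )


def evolve_absolute(
    config: EvolutionConfig,
    polarity: str,
    max_disparity: float = MAX_DISPARITY,
    randomize_positions: bool = False,
    geometry: SensorGeometry = DEFAULT_GEOMETRY,
    assembly: Optional[MonocularAssembly] = None,
) -> RunResult:
    """Evolve second-order absolute-disparity units of one polarity.

    With ``randomize_positions`` the training banks place the target at a
    random azimuth each trial (the retinotopy control) while the monocular
    assembly stays at its fixed positions.
    """
    if polarity not in ("far", "near"):
        raise ValueError("polarity must be 'far' or 'near'")
    assembly = assembly or place_monocular_pairs(geometry, "absolute")
    if randomize_positions:
        def make_bank(seed, n):
            return make_control_bank(n, max_disparity, seed, polarity=polarity, geometry=geometry)
        kind = "control"
    else:
        def make_bank(seed, n):
            return make_absolute_bank(n, polarity, max_disparity, seed, geometry=geometry)
        kind = f"absolute_{polarity}"

    def inputs_for_bank(bank, _pop):
        return assembly.bank_activities(bank)[:, :4]

    bank_params = {"kind": kind, "max_disparity": max_disparity, "polarity": polarity}
    return _run_populations(config, "second_order", polarity, bank_params, make_bank, inputs_for_bank)


def evolve_relative(
    config: EvolutionConfig,
    polarity: str,
    frozen_second_order: Sequence,
    max_disparity: float = MAX_DISPARITY,
    geometry: SensorGeometry = DEFAULT_GEOMETRY,
    assembly: Optional[MonocularAssembly] = None,
) -> RunResult:
    """Evolve third-order relative-disparity units of one polarity.

    ``frozen_second_order`` supplies one (far_genome, near_genome) pair per
    population (or a single pair shared by all); these evolved earlier,
    never change here, and are cloned at the reference position.
    """
    if polarity not in ("rel_far", "rel_near"):
        raise ValueError("polarity must be 'rel_far' or 'rel_near'")
    if not frozen_second_order:
        raise ValueError("frozen second-order genomes are required")
    frozen = list(frozen_second_order)
    if isinstance(frozen[0], Genome):  # single shared pair
        frozen = [tuple(frozen)] * config.n_populations
    if len(frozen) != config.n_populations:
        raise ValueError("need one frozen (far, near) pair per population")
    for far_g, near_g in frozen:
        if far_g.stage != "second_order" or near_g.stage != "second_order":
            raise ValueError("frozen genomes must be second-order")
    assembly = assembly or place_monocular_pairs(geometry, "relative")
    if assembly.n_pairs != 3:
        raise ValueError("the relative stage needs the three-pair assembly")

    def make_bank(seed, n):
        return make_relative_bank(n, max_disparity, polarity, seed, geometry=geometry)

    def inputs_for_bank(bank, pop_index):
        far_g, near_g = frozen[pop_index]
        return third_order_inputs(assembly.bank_activities(bank), far_g, near_g)

    bank_params = {"kind": "relative", "max_disparity": max_disparity, "polarity": polarity}
    return _run_populations(config, "third_order", polarity, bank_params, make_bank, inputs_for_bank)


def rebuild_bank(run: RunResult, seed: int, geometry: SensorGeometry = DEFAULT_GEOMETRY) -> StimulusBank:
    """Regenerate a bank of the kind a run trained on, from its parameters."""
    bp = run.bank_params
    n = run.config.lifetime_stimuli
    if bp["kind"] == "relative":
        return make_relative_bank(n, bp["max_disparity"], bp["polarity"], seed, geometry=geometry)
    if bp["kind"] == "control":
        return make_control_bank(n, bp["max_disparity"], seed, polarity=bp["polarity"], geometry=geometry)
    return make_absolute_bank(n, bp["polarity"], bp["max_disparity"], seed, geometry=geometry)
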