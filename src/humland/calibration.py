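"""Genetic-algorithm calibration of the simulation against a target.

The optimizer searches the four behavioral parameters (number of forager
groups, accessible radius, openness criterion to burn, hunting pressure)
for values whose simulated equilibrium matches the pollen-based target,
minimizing one of two fitness functions computed over the eligibility
mask:

    f(O) = |O_r − O_h| / 100        (mean vegetation openness)
    f(T) = |T_r − T_h| / 100        (% of cells dominated by trees)

where the ``r`` subscript denotes the reference (target) value and ``h``
the simulated value.  A scenario is *successful* when its fitness is at
most 0.10, i.e. the simulated statistic is within 10 percentage points of
the reference.

Three experiment subsets reproduce the study design: (1) megafauna
impact only, (2) megafauna + natural fires, (3) megafauna + natural +
human-induced fires.  Hunting pressure is optimized in every subset; the
three human-burning parameters are optimized only in subset 3.

The GA itself is a standard real/integer-coded design: tournament
selection (size 2), uniform crossover, per-gene Gaussian mutation with a
sigma of 10 % of the gene's range, elitism of one, and clipping (plus
rounding for integer genes) after variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .comparison import dataset_summary, eligibility_mask
from .dynamics import SimParams, SimSummary, run_simulation
from .errors import ConfigurationError, DomainError
from .grid_model import PnvLandscape, TargetVegetation

__all__ = [
    "ScenarioParams",
    "GAConfig",
    "ScenarioRecord",
    "PARAM_NAMES",
    "DEFAULT_BOUNDS",
    "SUBSET_FLAGS",
    "evaluate_fitness",
    "run_ga",
    "run_experiment_batch",
    "records_to_frame",
]


PARAM_NAMES = (
    "number_of_groups",
    "accessible_radius",
    "openness_criteria_to_burn",
    "hunting_pressure",
)

#: Full search ranges of the four calibrated parameters.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "number_of_groups": (0, 4000),
    "accessible_radius": (0, 5),
    "openness_criteria_to_burn": (9, 100),
    "hunting_pressure": (0, 100),
}

_INTEGER_PARAMS = frozenset({"number_of_groups", "accessible_radius"})

#: Process switches per experiment subset (natural_fires, humans);
#: megafauna impact is on in every subset.
SUBSET_FLAGS: dict[int, tuple[bool, bool]] = {1: (False, False), 2: (True, False), 3: (True, True)}

#: Parameters optimized per subset; the rest stay at their configured values.
SUBSET_FREE: dict[int, tuple[str, ...]] = {
    1: ("hunting_pressure",),
    2: ("hunting_pressure",),
    3: PARAM_NAMES,
}


@dataclass(frozen=True)
class ScenarioParams:
    """One candidate parameter vector."""

    number_of_groups: int = 0
    accessible_radius: int = 0
    openness_criteria_to_burn: float = 9.0
    hunting_pressure: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}


@dataclass
class GAConfig:
    """Settings of one GA experiment."""

    population_size: int = 30
    iterations: int = 20
    fitness_kind: str = "openness"  # or "trees"
    subset: int = 3
    seed: int = 0
    tournament_size: int = 2
    crossover_rate: float = 0.8
    mutation_rate: float = 0.2
    mutation_sigma_frac: float = 0.1
    elitism: int = 1
    success_threshold: float = 0.10
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    fixed_params: ScenarioParams = field(default_factory=ScenarioParams)
    sim_params: SimParams = field(default_factory=SimParams)

    def __post_init__(self) -> None:
        if self.fitness_kind not in ("openness", "trees"):
            raise ConfigurationError(f"unknown fitness_kind {self.fitness_kind!r}")
        if self.subset not in SUBSET_FLAGS:
            raise ConfigurationError(f"subset must be 1, 2 or 3, got {self.subset!r}")
        if self.population_size < 2 or self.iterations < 0:
            raise ConfigurationError("population_size ≥ 2 and iterations ≥ 0 required")
        for name in PARAM_NAMES:
            lo, hi = self.bounds[name]
            dlo, dhi = DEFAULT_BOUNDS[name]
            if lo < dlo or hi > dhi or lo > hi:
                raise ConfigurationError(f"bounds for {name} must lie within [{dlo}, {dhi}]")


@dataclass
class ScenarioRecord:
    """One evaluated scenario: parameters, fitness and simulated summary."""

    params: ScenarioParams
    fitness: float
    sim_summary: SimSummary
    success: bool
    seed: int
    generation: int


def _sim_params_for(scenario: ScenarioParams, config: GAConfig, sim_seed: int) -> SimParams:
    natural, humans = SUBSET_FLAGS[config.subset]
    return replace(
        config.sim_params,
        megafauna_impact=True,
        natural_fires=natural,
        humans=humans,
        number_of_groups=int(scenario.number_of_groups),
        accessible_radius=int(scenario.accessible_radius),
        openness_criteria_to_burn=float(scenario.openness_criteria_to_burn),
        hunting_pressure=float(scenario.hunting_pressure),
        seed=sim_seed,
    )


def evaluate_fitness(
    params: ScenarioParams,
    pnv: PnvLandscape,
    target: TargetVegetation,
    config: GAConfig,
    *,
    sim_seed: int | None = None,
    generation: int = -1,
) -> ScenarioRecord:
    """Run one simulation and score it against the target.

    One simulation per evaluation (no replicate averaging).  Raises
    :class:`~humland.errors.DomainError` when ``params`` falls outside the
    configured bounds or the eligibility mask is empty.
    """
    for name in PARAM_NAMES:
        lo, hi = config.bounds[name]
        value = getattr(params, name)
        if not (lo <= value <= hi):
            raise DomainError(f"{name}={value!r} outside bounds [{lo}, {hi}]")
    mask = eligibility_mask(pnv, target)
    if not mask.any():
        raise DomainError("empty eligibility mask")
    target_summary = dataset_summary(target.target_openness, target.target_pft, mask)
    sim_params = _sim_params_for(params, config, config.seed if sim_seed is None else sim_seed)
    result = run_simulation(pnv, mask, sim_params)
    if config.fitness_kind == "openness":
        fitness = abs(target_summary.mean_openness - result.summary.mean_openness) / 100.0
    else:
        fitness = abs(target_summary.pct_tree_dominated - result.summary.pct_tree_dominated) / 100.0
    return ScenarioRecord(
        params=params,
        fitness=float(fitness),
        sim_summary=result.summary,
        success=bool(fitness <= config.success_threshold),
        seed=config.seed,
        generation=generation,
    )


# ---------------------------------------------------------------------------
# GA internals
# ---------------------------------------------------------------------------


def _clip_round(genome: np.ndarray, config: GAConfig) -> np.ndarray:
    out = genome.copy()
    for i, name in enumerate(PARAM_NAMES):
        lo, hi = config.bounds[name]
        out[i] = min(max(out[i], lo), hi)
        if name in _INTEGER_PARAMS:
            out[i] = round(out[i])
    return out


def _genome_to_params(genome: np.ndarray) -> ScenarioParams:
    return ScenarioParams(
        number_of_groups=int(genome[0]),
        accessible_radius=int(genome[1]),
        openness_criteria_to_burn=float(genome[2]),
        hunting_pressure=float(genome[3]),
    )


def _random_genome(rng: np.random.Generator, config: GAConfig) -> np.ndarray:
    free = SUBSET_FREE[config.subset]
    genome = np.array(
        [float(getattr(config.fixed_params, name)) for name in PARAM_NAMES], dtype=float
    )
    for i, name in enumerate(PARAM_NAMES):
        if name in free:
            lo, hi = config.bounds[name]
            genome[i] = rng.uniform(lo, hi)
    return _clip_round(genome, config)


def _tournament(rng: np.random.Generator, fitnesses: np.ndarray, k: int) -> int:
    contenders = rng.integers(0, fitnesses.size, size=k)
    return int(contenders[np.argmin(fitnesses[contenders])])


def run_ga(
    pnv: PnvLandscape,
    target: TargetVegetation,
    config: GAConfig,
    initial_population: list[ScenarioParams] | None = None,
) -> tuple[ScenarioRecord, list[ScenarioRecord]]:
    """Evolve a population of scenarios against the target.

    Returns the best record and the full pool of evaluated records (the
    scenario pool analyzed downstream).  Elitism preserves the best
    individual each generation, so the best-so-far fitness is monotone
    non-increasing.  Deterministic given ``config.seed``.

    ``initial_population`` optionally seeds (part of) generation 0 with
    known candidates.
    """
    rng = np.random.default_rng(config.seed)
    free_idx = [i for i, name in enumerate(PARAM_NAMES) if name in SUBSET_FREE[config.subset]]

    population = [_random_genome(rng, config) for _ in range(config.population_size)]
    if initial_population:
        for i, cand in enumerate(initial_population[: config.population_size]):
            population[i] = _clip_round(
                np.array([float(getattr(cand, n)) for n in PARAM_NAMES]), config
            )

    all_records: list[ScenarioRecord] = []
    failures = 0

    def evaluate(genomes: list[np.ndarray], generation: int) -> np.ndarray:
        nonlocal failures
        fits = np.empty(len(genomes))
        for i, genome in enumerate(genomes):
            sim_seed = int(rng.integers(0, 2**31 - 1))
            try:
                record = evaluate_fitness(
                    _genome_to_params(genome), pnv, target, config,
                    sim_seed=sim_seed, generation=generation,
                )
            except DomainError:
                failures += 1
                fits[i] = np.inf
                continue
            all_records.append(record)
            fits[i] = record.fitness
        return fits

    fitnesses = evaluate(population, 0)
    if not np.isfinite(fitnesses).any():
        raise ConfigurationError("every candidate evaluation failed in generation 0")

    for generation in range(1, config.iterations + 1):
        order = np.argsort(fitnesses)
        elites = [population[int(i)].copy() for i in order[: config.elitism]]
        elite_fits = fitnesses[order[: config.elitism]]
        offspring: list[np.ndarray] = []
        while len(offspring) < config.population_size - config.elitism:
            a = population[_tournament(rng, fitnesses, config.tournament_size)]
            b = population[_tournament(rng, fitnesses, config.tournament_size)]
            child = a.copy()
            if rng.random() < config.crossover_rate:
                swap = rng.random(len(PARAM_NAMES)) < 0.5
                child[swap] = b[swap]
            for i in free_idx:
                if rng.random() < config.mutation_rate:
                    lo, hi = config.bounds[PARAM_NAMES[i]]
                    child[i] += rng.normal(0.0, config.mutation_sigma_frac * (hi - lo))
            offspring.append(_clip_round(child, config))
        child_fits = evaluate(offspring, generation)
        population = elites + offspring
        fitnesses = np.concatenate([elite_fits, child_fits])

    if not all_records:
        raise ConfigurationError("every candidate evaluation failed")
    best = min(all_records, key=lambda r: r.fitness)
    return best, all_records


def run_experiment_batch(
    pnv: PnvLandscape,
    target: TargetVegetation,
    base_config: GAConfig,
    seeds: list[int],
) -> pd.DataFrame:
    """Repeat one GA experiment across seeds; returns the labeled pool.

    The schema supports the full (fitness kind × subset × seed) layout of
    a calibration campaign; records from different subsets never mix
    process switches because each run derives its flags from its own
    config.
    """
    if len(set(seeds)) != len(seeds):
        raise ConfigurationError("seeds must be distinct")
    frames = []
    for seed in seeds:
        config = replace(base_config, seed=int(seed))
        _, records = run_ga(pnv, target, config)
        frames.append(records_to_frame(records, fitness_kind=config.fitness_kind, subset=config.subset))
    return pd.concat(frames, ignore_index=True)


def records_to_frame(
    records: list[ScenarioRecord], fitness_kind: str | None = None, subset: int | None = None
) -> pd.DataFrame:
    """Flatten scenario records into a tidy table."""
    rows = []
    for r in records:
        row = {
            "seed": r.seed,
            "generation": r.generation,
            **r.params.as_dict(),
            "fitness": r.fitness,
            "success": r.success,
            "mean_openness": r.sim_summary.mean_openness,
            "pct_trees": r.sim_summary.pct_tree_dominated,
            "pct_herbs": r.sim_summary.pct_herb_dominated,
        }
        if fitness_kind is not None:
            row["fitness_kind"] = fitness_kind
        if subset is not None:
            row["subset"] = subset
        rows.append(row)
    return pd.DataFrame(rows)
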