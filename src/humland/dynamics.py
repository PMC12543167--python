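"""The vegetation-dynamics engine: a yearly-step grid simulation.

Each simulation step applies, in fixed order, (1) climatic regeneration of
previously disturbed cells, (2) anthropogenic burning around forager
campsites, (3) natural (thunderstorm-ignited) fires, and (4) megafauna
plant consumption modulated by hunting pressure.  Fires replace a cell's
vegetation with bare ground (openness 100) and spread through the Moore
neighborhood with PFT-dependent probabilities; recovery returns openness
linearly to the potential-natural value over a PFT-specific recovery time,
with bare ground succeeded by herbs after seven steps and herbs by the
climax PFT after the full recovery time.

Every cell tracks the last agent that changed its dominant PFT and the
last agent that substantially changed its openness, so equilibrium
landscapes can be attributed per-process.

State is stored as a grid-of-arrays (:class:`SimState`); the per-cell
record the arrays realize is documented on that class.  All stochasticity
flows through one :class:`numpy.random.Generator`, so identical
(landscape, parameters, seed) triples give bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .comparison import dataset_summary, eligibility_mask
from .errors import ConfigurationError, DomainError
from .grid_model import (
    CellClass,
    PFTCategory,
    PnvLandscape,
    TargetVegetation,
    TREE_PFTS,
    WOODY_PFTS,
)

__all__ = [
    "AgentKind",
    "SimParams",
    "SimState",
    "SimSummary",
    "SimResult",
    "initialize_state",
    "apply_regeneration",
    "burn_cell",
    "spread_fire",
    "apply_anthropogenic_fires",
    "apply_natural_fires",
    "apply_megafauna",
    "step",
    "run_simulation",
    "DEFAULT_RECOVERY_STEPS",
    "DEFAULT_FIRE_RETURN_INTERVAL",
    "DEFAULT_SPREAD_PROBABILITY",
]


class AgentKind(IntEnum):
    """Process responsible for the most recent qualifying change of a cell."""

    NONE = 0
    CLIMATE = 1
    MEGAFAUNA = 2
    NATURAL_FIRE = 3
    HUMAN_FIRE = 4


#: Years for a disturbed cell to regain its climax dominant PFT.
DEFAULT_RECOVERY_STEPS: dict[PFTCategory, int] = {
    PFTCategory.HERBS: 7,
    PFTCategory.SHRUBS: 43,
    PFTCategory.BROADLEAF_TREES: 30,
    PFTCategory.NEEDLELEAF_TREES: 43,
}

#: Characteristic years between successive fires per PFT (configuration
#: input; these defaults are synthetic test values, not field estimates).
DEFAULT_FIRE_RETURN_INTERVAL: dict[PFTCategory, float] = {
    PFTCategory.HERBS: 20.0,
    PFTCategory.SHRUBS: 50.0,
    PFTCategory.NEEDLELEAF_TREES: 100.0,
    PFTCategory.BROADLEAF_TREES: 200.0,
}

#: Probability that fire jumps to a Moore neighbor of the given PFT.
DEFAULT_SPREAD_PROBABILITY: dict[PFTCategory, float] = {
    PFTCategory.HERBS: 0.3,
    PFTCategory.SHRUBS: 0.2,
    PFTCategory.NEEDLELEAF_TREES: 0.2,
    PFTCategory.BROADLEAF_TREES: 0.1,
}

#: Steps after a burn until bare ground is recolonized by herbs.
BARE_TO_HERBS_STEPS = 7
#: |openness − PNV openness| band within which regrowth counts as climatic.
CLIMATE_OPENNESS_BAND = 10.0
#: Openness deviation that qualifies megafauna as an openness agent …
MEGAFAUNA_DEVIATION_BAND = 10.0
#: … when sustained, unaided by fire, for this many consecutive steps.
MEGAFAUNA_STREAK_STEPS = 10


@dataclass
class SimParams:
    """Tunable parameters of one simulation run.

    The scalar behavioral parameters mirror the published parameter table
    of the model (names preserved in the YAML config dialect):
    ``thunderstorm_fraction`` (% of terrestrial cells struck per step,
    default 0.04 from decadal lightning observations for Europe),
    ``number_of_groups`` [0, 4000], ``accessible_radius`` [0, 5] cells
    (Chebyshev), ``openness_criteria_to_burn`` [9, 100] % (humans burn
    woody cells whose openness is *below* this threshold),
    ``hunting_pressure`` [0, 100] % (reduction of potential maximal
    megafauna plant consumption), ``movement_frequency`` /
    ``campsites_to_move`` for campsite relocation (0 disables), and the
    three process switches.  Per-PFT maps hold recovery times, fire return
    intervals and spread probabilities.
    """

    thunderstorm_fraction: float = 0.04
    natural_fires: bool = True
    megafauna_impact: bool = True
    humans: bool = False
    number_of_groups: int = 0
    accessible_radius: int = 3
    openness_criteria_to_burn: float = 50.0
    hunting_pressure: float = 0.0
    movement_frequency: int = 0
    campsites_to_move: float = 0.0
    max_steps: int = 1000
    record_after_step: int = 450
    recovery_steps: dict[PFTCategory, int] = field(
        default_factory=lambda: dict(DEFAULT_RECOVERY_STEPS)
    )
    fire_return_interval: dict[PFTCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_FIRE_RETURN_INTERVAL)
    )
    spread_probability: dict[PFTCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_SPREAD_PROBABILITY)
    )
    initial_fuel_full: bool = True
    max_burns_per_group: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("thunderstorm_fraction", self.thunderstorm_fraction, 0, 100),
            ("number_of_groups", self.number_of_groups, 0, 4000),
            ("accessible_radius", self.accessible_radius, 0, 5),
            ("openness_criteria_to_burn", self.openness_criteria_to_burn, 9, 100),
            ("hunting_pressure", self.hunting_pressure, 0, 100),
            ("campsites_to_move", self.campsites_to_move, 0, 100),
        ]
        for name, value, lo, hi in checks:
            if not (lo <= value <= hi):
                raise ConfigurationError(f"{name}={value!r} outside [{lo}, {hi}]")
        if self.movement_frequency < 0 or self.max_steps < 1 or self.record_after_step < 0:
            raise ConfigurationError("step counts must be non-negative (max_steps ≥ 1)")
        for p in (PFTCategory.HERBS, PFTCategory.SHRUBS,
                  PFTCategory.BROADLEAF_TREES, PFTCategory.NEEDLELEAF_TREES):
            if self.recovery_steps.get(p, 0) < 1:
                raise ConfigurationError(f"recovery_steps missing/invalid for {p.name}")
            if self.fire_return_interval.get(p, 0) <= 0:
                raise ConfigurationError(f"fire_return_interval missing/invalid for {p.name}")
            if not (0.0 <= self.spread_probability.get(p, -1) <= 1.0):
                raise ConfigurationError(f"spread_probability missing/invalid for {p.name}")

    # Per-PFT maps as code-indexed lookup tables.  Bare-ground entries
    # reuse the herb values; bare PNV cells never exercise them anyway.
    def recovery_lookup(self) -> np.ndarray:
        return _lookup(self.recovery_steps, self.recovery_steps[PFTCategory.HERBS])

    def fri_lookup(self) -> np.ndarray:
        return _lookup(self.fire_return_interval, self.fire_return_interval[PFTCategory.HERBS])

    def spread_lookup(self) -> np.ndarray:
        return _lookup(self.spread_probability, 0.0)


def _lookup(mapping: dict[PFTCategory, float], bare_value: float) -> np.ndarray:
    table = np.empty(5, dtype=float)
    table[int(PFTCategory.BARE_GROUND)] = bare_value
    for p in (PFTCategory.HERBS, PFTCategory.SHRUBS,
              PFTCategory.BROADLEAF_TREES, PFTCategory.NEEDLELEAF_TREES):
        table[int(p)] = float(mapping[p])
    return table


@dataclass
class SimState:
    """Mutable per-cell simulation state, stored as parallel grids.

    Per cell: current dominant PFT; openness (%, bounded below by the PNV
    openness and above by 100 on land); current NPP (≤ PNV NPP); the
    disturbance clock ``steps_since_disturbance`` (−1 when undisturbed)
    with the openness recorded at the latest disturbance (nan when
    undisturbed); the fuel clock ``steps_since_last_fire``; the sustained
    megafauna-deviation streak counter; and the two attribution variables
    ``last_agent_pft`` / ``last_agent_openness``.

    ``campsites`` is an (n, 2) integer array of forager campsite
    coordinates (empty when humans are switched off).
    """

    pft: np.ndarray
    openness: np.ndarray
    npp: np.ndarray
    steps_since_disturbance: np.ndarray
    openness_at_disturbance: np.ndarray
    steps_since_last_fire: np.ndarray
    megafauna_deviation_streak: np.ndarray
    last_agent_pft: np.ndarray
    last_agent_openness: np.ndarray
    campsites: np.ndarray

    def copy(self) -> "SimState":
        return SimState(
            pft=self.pft.copy(),
            openness=self.openness.copy(),
            npp=self.npp.copy(),
            steps_since_disturbance=self.steps_since_disturbance.copy(),
            openness_at_disturbance=self.openness_at_disturbance.copy(),
            steps_since_last_fire=self.steps_since_last_fire.copy(),
            megafauna_deviation_streak=self.megafauna_deviation_streak.copy(),
            last_agent_pft=self.last_agent_pft.copy(),
            last_agent_openness=self.last_agent_openness.copy(),
            campsites=self.campsites.copy(),
        )


@dataclass(frozen=True)
class SimSummary:
    """Post-equilibrium output statistics of one run.

    ``mean_openness`` / dominance shares are means over the eligibility
    mask, averaged across the recording window; the attribution maps give
    the mean percentage of counted (land) cells whose last qualifying PFT
    or openness change is owed to each agent.
    """

    mean_openness: float
    pct_tree_dominated: float
    pct_herb_dominated: float
    attribution_pft: dict[AgentKind, float]
    attribution_openness: dict[AgentKind, float]
    n_steps_recorded: int


@dataclass
class SimResult:
    """Bundle returned by :func:`run_simulation`."""

    summary: SimSummary
    last_agent_pft: np.ndarray
    last_agent_openness: np.ndarray
    cell_mean_openness: np.ndarray | None = None
    cell_modal_pft: np.ndarray | None = None
    strike_counts: list[int] | None = None


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def initialize_state(
    pnv: PnvLandscape, params: SimParams, rng: np.random.Generator | None = None
) -> SimState:
    """Start every land cell at its potential-natural state.

    The fuel clock starts at the cell's fire return interval ("fuel fully
    accumulated"), so an undisturbed landscape can ignite from step one;
    set ``params.initial_fuel_full = False`` to start at zero instead.
    With humans on, ``number_of_groups`` campsites are placed uniformly at
    random (without replacement) on admissible land cells — never on
    water, high mountains, or human-exclusion cells.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    land = pnv.land_mask
    fri = params.fri_lookup()
    shape = pnv.shape
    if params.initial_fuel_full:
        ssf = np.ceil(fri[pnv.pnv_pft]).astype(np.int64)
    else:
        ssf = np.zeros(shape, dtype=np.int64)
    ssf[~land] = 0
    campsites = np.empty((0, 2), dtype=np.int64)
    if params.humans and params.number_of_groups > 0:
        admissible = np.flatnonzero(land & ~pnv.human_exclusion)
        if params.number_of_groups > admissible.size:
            raise ConfigurationError(
                f"number_of_groups={params.number_of_groups} exceeds the "
                f"{admissible.size} admissible cells"
            )
        chosen = rng.choice(admissible, size=params.number_of_groups, replace=False)
        campsites = np.column_stack(np.unravel_index(chosen, shape)).astype(np.int64)
    return SimState(
        pft=pnv.pnv_pft.copy(),
        openness=pnv.pnv_openness.copy(),
        npp=pnv.pnv_npp.copy(),
        steps_since_disturbance=np.full(shape, -1, dtype=np.int64),
        openness_at_disturbance=np.full(shape, np.nan),
        steps_since_last_fire=ssf,
        megafauna_deviation_streak=np.zeros(shape, dtype=np.int64),
        last_agent_pft=np.full(shape, int(AgentKind.NONE), dtype=np.int8),
        last_agent_openness=np.full(shape, int(AgentKind.NONE), dtype=np.int8),
        campsites=campsites,
    )


# ---------------------------------------------------------------------------
# Climatic regeneration
# ---------------------------------------------------------------------------


def apply_regeneration(state: SimState, pnv: PnvLandscape, params: SimParams) -> None:
    """One year of climate-driven regrowth on disturbed cells (in place).

    Openness decreases by the constant rate
    ``(openness_at_disturbance − pnv_openness) / T`` with ``T`` the climax
    PFT's recovery time, floored at the PNV openness.  Succession: bare
    ground → herbs at disturbance age 7; herbs → climax PFT at age ``T``.
    NPP regrows linearly (``pnv_npp / T`` per step, capped) on every land
    cell below its PNV NPP.  Regrowth that brings openness within 10
    points of PNV attributes the cell's openness to climate; any
    succession-driven PFT change attributes the PFT to climate.
    """
    land = pnv.land_mask
    recovering = land & ~np.isnan(state.openness_at_disturbance)
    T = params.recovery_lookup()[pnv.pnv_pft]

    # NPP regrowth is unconditional on land (closed system).
    below = land & (state.npp < pnv.pnv_npp)
    state.npp[below] = np.minimum(pnv.pnv_npp[below], state.npp[below] + pnv.pnv_npp[below] / T[below])

    if not np.any(recovering):
        return
    state.steps_since_disturbance[recovering] += 1

    rate = np.zeros(pnv.shape)
    rate[recovering] = (
        state.openness_at_disturbance[recovering] - pnv.pnv_openness[recovering]
    ) / T[recovering]
    regrow = recovering & (state.openness > pnv.pnv_openness)
    state.openness[regrow] = np.maximum(
        pnv.pnv_openness[regrow], state.openness[regrow] - rate[regrow]
    )
    # T repeated subtractions of (amplitude/T) must land exactly on the PNV
    # openness; snap within a relative tolerance of the amplitude.
    amplitude = state.openness_at_disturbance - pnv.pnv_openness
    snap = regrow & (state.openness - pnv.pnv_openness <= 1e-9 * np.abs(amplitude))
    state.openness[snap] = pnv.pnv_openness[snap]

    near_pnv = recovering & (np.abs(state.openness - pnv.pnv_openness) <= CLIMATE_OPENNESS_BAND)
    state.last_agent_openness[near_pnv] = int(AgentKind.CLIMATE)

    age = state.steps_since_disturbance
    to_herbs = recovering & (state.pft == int(PFTCategory.BARE_GROUND)) & (age >= BARE_TO_HERBS_STEPS)
    state.pft[to_herbs] = int(PFTCategory.HERBS)
    state.last_agent_pft[to_herbs] = int(AgentKind.CLIMATE)
    to_climax = (
        recovering
        & (state.pft == int(PFTCategory.HERBS))
        & (pnv.pnv_pft != int(PFTCategory.HERBS))
        & (pnv.pnv_pft != int(PFTCategory.BARE_GROUND))
        & (age >= T)
    )
    state.pft[to_climax] = pnv.pnv_pft[to_climax]
    state.last_agent_pft[to_climax] = int(AgentKind.CLIMATE)

    done = recovering & (state.openness <= pnv.pnv_openness) & (state.pft == pnv.pnv_pft)
    state.openness[done] = pnv.pnv_openness[done]
    state.openness_at_disturbance[done] = np.nan
    state.steps_since_disturbance[done] = -1


# ---------------------------------------------------------------------------
# Fire
# ---------------------------------------------------------------------------


def _burnable_mask(state: SimState, pnv: PnvLandscape) -> np.ndarray:
    """Fires cannot occur or spread on water, high mountains or bare ground."""
    return pnv.land_mask & (state.pft != int(PFTCategory.BARE_GROUND))


def _burn(state: SimState, mask: np.ndarray, agent: AgentKind) -> None:
    """Vectorized burn: vegetation replaced by bare ground."""
    code = np.int8(int(agent))
    state.openness[mask] = 100.0
    state.pft[mask] = int(PFTCategory.BARE_GROUND)
    state.npp[mask] = 0.0
    state.last_agent_pft[mask] = code
    state.last_agent_openness[mask] = code
    state.steps_since_last_fire[mask] = 0
    state.steps_since_disturbance[mask] = 0
    state.openness_at_disturbance[mask] = 100.0


def burn_cell(
    state: SimState, pnv: PnvLandscape, cell: tuple[int, int], agent: AgentKind
) -> None:
    """Burn a single cell in place (scalar convenience wrapper).

    Raises :class:`~humland.errors.DomainError` when the cell is water,
    high mountain or already bare, or when ``agent`` is not a fire agent.
    """
    if agent not in (AgentKind.NATURAL_FIRE, AgentKind.HUMAN_FIRE):
        raise DomainError(f"burn agent must be a fire agent, got {agent!r}")
    r, c = cell
    if pnv.cell_class[r, c] != int(CellClass.LAND):
        raise DomainError(f"cannot burn non-land cell {cell}")
    if state.pft[r, c] == int(PFTCategory.BARE_GROUND):
        raise DomainError(f"cannot burn already-bare cell {cell}")
    mask = np.zeros(pnv.shape, dtype=bool)
    mask[r, c] = True
    _burn(state, mask, agent)


_MOORE_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)], dtype=np.int64
)


def _spread_from(
    state: SimState,
    pnv: PnvLandscape,
    origins: np.ndarray,
    agent: AgentKind,
    params: SimParams,
    rng: np.random.Generator,
    visited: np.ndarray,
) -> np.ndarray:
    """Recursive Moore-neighborhood spread from already-burned origins.

    ``origins`` is an (n, 2) coordinate array of cells burned this
    sub-process; ``visited`` marks cells whose ignition roll has been made
    this step (each cell is visited at most once per step).  Returns the
    coordinates of all additionally burned cells.
    """
    spread_p = params.spread_lookup()
    nrows, ncols = pnv.shape
    burned_all: list[np.ndarray] = []
    frontier = origins
    while frontier.size:
        cand = frontier[:, None, :] + _MOORE_OFFSETS[None, :, :]
        cand = cand.reshape(-1, 2)
        ok = (
            (cand[:, 0] >= 0) & (cand[:, 0] < nrows) & (cand[:, 1] >= 0) & (cand[:, 1] < ncols)
        )
        cand = cand[ok]
        if cand.size == 0:
            break
        flat = cand[:, 0] * ncols + cand[:, 1]
        flat = np.unique(flat)
        rr, cc = flat // ncols, flat % ncols
        sel = (
            ~visited[rr, cc]
            & (pnv.cell_class[rr, cc] == int(CellClass.LAND))
            & (state.pft[rr, cc] != int(PFTCategory.BARE_GROUND))
        )
        rr, cc = rr[sel], cc[sel]
        if rr.size == 0:
            break
        visited[rr, cc] = True
        u = rng.random(rr.size)
        catch = u < spread_p[pnv.pnv_pft[rr, cc]]
        rr, cc = rr[catch], cc[catch]
        if rr.size == 0:
            break
        mask = np.zeros(pnv.shape, dtype=bool)
        mask[rr, cc] = True
        _burn(state, mask, agent)
        frontier = np.column_stack([rr, cc])
        burned_all.append(frontier)
    if burned_all:
        return np.concatenate(burned_all, axis=0)
    return np.empty((0, 2), dtype=np.int64)


def spread_fire(
    state: SimState,
    pnv: PnvLandscape,
    origin_cell: tuple[int, int],
    agent: AgentKind,
    params: SimParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spread fire from one just-burned origin; returns burned coordinates."""
    visited = np.zeros(pnv.shape, dtype=bool)
    visited[origin_cell] = True
    origins = np.array([origin_cell], dtype=np.int64)
    return _spread_from(state, pnv, origins, agent, params, rng, visited)


def apply_anthropogenic_fires(
    state: SimState,
    pnv: PnvLandscape,
    params: SimParams,
    rng: np.random.Generator,
    step_index: int,
    fire_touched: np.ndarray | None = None,
) -> int:
    """Forager burning around campsites, with spread (in place).

    Every campsite scans the full Chebyshev square of radius
    ``accessible_radius`` each step and burns all woody cells (shrubs or
    trees) whose openness is below ``openness_criteria_to_burn``; fire then
    spreads from each burned cell as for natural fires.  Campsites
    relocate every ``movement_frequency`` steps (``campsites_to_move`` %
    of them, rounded down, to random admissible cells); relocation is
    disabled at frequency 0.  Returns the number of cells burned.
    """
    if state.campsites.size == 0:
        return 0
    if (
        params.movement_frequency > 0
        and step_index % params.movement_frequency == 0
        and params.campsites_to_move > 0
    ):
        n_move = int(params.campsites_to_move / 100.0 * len(state.campsites))
        if n_move > 0:
            which = rng.choice(len(state.campsites), size=n_move, replace=False)
            admissible = np.flatnonzero(pnv.land_mask & ~pnv.human_exclusion)
            dest = rng.choice(admissible, size=n_move, replace=False)
            state.campsites[which] = np.column_stack(np.unravel_index(dest, pnv.shape))

    # Cells within reach of any campsite: dilation of the campsite grid
    # with a (2r+1)² square structuring element.
    camp_grid = np.zeros(pnv.shape, dtype=bool)
    camp_grid[state.campsites[:, 0], state.campsites[:, 1]] = True
    r = params.accessible_radius
    if r > 0:
        reach = ndimage.binary_dilation(camp_grid, structure=np.ones((2 * r + 1, 2 * r + 1), bool))
    else:
        reach = camp_grid
    woody = np.isin(state.pft, [int(p) for p in WOODY_PFTS])
    to_burn = (
        reach
        & pnv.land_mask
        & woody
        & (state.openness < params.openness_criteria_to_burn)
    )
    n_direct = int(to_burn.sum())
    if n_direct == 0:
        return 0
    _burn(state, to_burn, AgentKind.HUMAN_FIRE)
    visited = to_burn.copy()
    origins = np.column_stack(np.nonzero(to_burn)).astype(np.int64)
    spread = _spread_from(state, pnv, origins, AgentKind.HUMAN_FIRE, params, rng, visited)
    if fire_touched is not None:
        fire_touched |= to_burn
        if spread.size:
            fire_touched[spread[:, 0], spread[:, 1]] = True
    return n_direct + len(spread)


def apply_natural_fires(
    state: SimState,
    pnv: PnvLandscape,
    params: SimParams,
    rng: np.random.Generator,
    fire_touched: np.ndarray | None = None,
) -> int:
    """Thunderstorm ignitions with spread (in place).

    ``round(thunderstorm_fraction/100 × n_terrestrial)`` land cells are
    struck uniformly at random; a struck burnable cell ignites with
    probability ``min(1, steps_since_last_fire / FRI[pnv_pft])`` — a
    linear-saturating fuel-accumulation form.  Returns the number of cells
    selected for an ignition attempt.
    """
    land_flat = np.flatnonzero(pnv.land_mask)
    n_land = land_flat.size
    n_strike = int(round(params.thunderstorm_fraction / 100.0 * n_land))
    if n_strike == 0 or n_land == 0:
        return 0
    struck = rng.choice(land_flat, size=min(n_strike, n_land), replace=False)
    rr, cc = np.unravel_index(struck, pnv.shape)
    burnable = state.pft[rr, cc] != int(PFTCategory.BARE_GROUND)
    fri = params.fri_lookup()[pnv.pnv_pft[rr, cc]]
    p = np.minimum(1.0, state.steps_since_last_fire[rr, cc] / fri)
    ignite = burnable & (rng.random(rr.size) < p)
    rr, cc = rr[ignite], cc[ignite]
    if rr.size == 0:
        return n_strike
    mask = np.zeros(pnv.shape, dtype=bool)
    mask[rr, cc] = True
    _burn(state, mask, AgentKind.NATURAL_FIRE)
    visited = mask.copy()
    origins = np.column_stack([rr, cc])
    spread = _spread_from(state, pnv, origins, AgentKind.NATURAL_FIRE, params, rng, visited)
    if fire_touched is not None:
        fire_touched |= mask
        if spread.size:
            fire_touched[spread[:, 0], spread[:, 1]] = True
    return n_strike


# ---------------------------------------------------------------------------
# Megafauna herbivory
# ---------------------------------------------------------------------------


def apply_megafauna(
    state: SimState,
    pnv: PnvLandscape,
    params: SimParams,
    fire_touched: np.ndarray | None = None,
) -> None:
    """Hunting-modulated megafauna plant consumption (in place).

    Per land cell with openness below 100 and positive current NPP
    ``V_n``: the hunting-reduced consumption capacity is
    ``V_h = max_consumption × (1 − HP/100)`` (with HP forced to 0 on
    human-exclusion cells), the realized metabolization is
    ``V_m = (O_i/100) × V_h``, and the percentage of vegetation consumed
    is ``V_c = 100 × V_m / V_n`` (clipped to [0, 100]).  Openness rises by
    ``V_c`` points (capped at 100) and NPP shrinks by the factor
    ``1 − V_c/100``.  Consumption that drives openness to 100 bares the
    cell and attributes its PFT to megafauna; a deviation of more than 10
    points from PNV openness sustained over 10 consecutive fire-free steps
    attributes its openness to megafauna.
    """
    land = pnv.land_mask
    hp = np.where(pnv.human_exclusion, 0.0, params.hunting_pressure)
    active = land & (state.openness < 100.0) & (state.npp > 0.0)
    v_h = pnv.max_consumption * (1.0 - hp / 100.0)
    v_c = np.zeros(pnv.shape)
    v_c[active] = np.clip(
        (state.openness[active] / 100.0) * v_h[active] / state.npp[active] * 100.0, 0.0, 100.0
    )
    consumed = active & (v_c > 0.0)
    new_open = np.minimum(100.0, state.openness + v_c)
    became_bare = consumed & (new_open >= 100.0)
    state.npp[consumed] *= 1.0 - v_c[consumed] / 100.0
    state.openness[consumed] = new_open[consumed]
    state.pft[became_bare] = int(PFTCategory.BARE_GROUND)
    state.last_agent_pft[became_bare] = int(AgentKind.MEGAFAUNA)

    # Consumption is a disturbance for the regeneration engine.
    disturbed = consumed & (state.openness > pnv.pnv_openness)
    state.openness_at_disturbance[disturbed] = state.openness[disturbed]
    fresh = disturbed & (state.steps_since_disturbance < 0)
    state.steps_since_disturbance[fresh] = 0

    deviates = consumed & (np.abs(state.openness - pnv.pnv_openness) > MEGAFAUNA_DEVIATION_BAND)
    if fire_touched is not None:
        deviates &= ~fire_touched
    state.megafauna_deviation_streak[deviates] += 1
    state.megafauna_deviation_streak[land & ~deviates] = 0
    qualified = state.megafauna_deviation_streak >= MEGAFAUNA_STREAK_STEPS
    state.last_agent_openness[qualified] = int(AgentKind.MEGAFAUNA)


# ---------------------------------------------------------------------------
# Step loop
# ---------------------------------------------------------------------------


def step(
    state: SimState,
    pnv: PnvLandscape,
    params: SimParams,
    rng: np.random.Generator,
    step_index: int,
) -> int:
    """Advance the simulation one year (in place).

    Sub-processes run in fixed order: climatic regeneration (acting on
    disturbances from previous steps), anthropogenic fires, natural fires,
    megafauna consumption.  Clocks advance once per step.  Returns the
    number of natural-ignition attempts made this step.
    """
    fire_touched = np.zeros(pnv.shape, dtype=bool)
    apply_regeneration(state, pnv, params)
    if params.humans:
        apply_anthropogenic_fires(state, pnv, params, rng, step_index, fire_touched)
    n_strikes = 0
    if params.natural_fires:
        n_strikes = apply_natural_fires(state, pnv, params, rng, fire_touched)
    if params.megafauna_impact:
        apply_megafauna(state, pnv, params, fire_touched)
    state.steps_since_last_fire[pnv.land_mask] += 1
    return n_strikes


def run_simulation(
    pnv: PnvLandscape,
    target: TargetVegetation | np.ndarray,
    params: SimParams,
    *,
    collect_cell_stats: bool = False,
    record_strikes: bool = False,
) -> SimResult:
    """Run ``max_steps`` yearly steps and summarize the equilibrium window.

    ``target`` is either a :class:`TargetVegetation` (the eligibility mask
    is derived from it) or a boolean mask directly.  Output statistics are
    averaged over steps ``record_after_step + 1 … max_steps``: openness and
    dominance over the eligibility mask; attribution percentages over all
    land cells.  With ``collect_cell_stats`` the per-cell time-mean
    openness and modal PFT over the window are returned as grids.
    """
    if isinstance(target, TargetVegetation):
        mask = eligibility_mask(pnv, target)
    else:
        mask = np.asarray(target, dtype=bool) & pnv.land_mask
    if not mask.any():
        raise DomainError("empty eligibility mask")
    if params.max_steps <= params.record_after_step:
        raise DomainError(
            f"max_steps={params.max_steps} leaves no recording window after "
            f"step {params.record_after_step}"
        )
    rng = np.random.default_rng(params.seed)
    state = initialize_state(pnv, params, rng)
    land = pnv.land_mask
    n_land = int(land.sum())
    n_rec = 0
    sum_open = sum_trees = sum_herbs = 0.0
    agent_codes = [AgentKind.CLIMATE, AgentKind.MEGAFAUNA, AgentKind.NATURAL_FIRE, AgentKind.HUMAN_FIRE]
    attr_pft_sums = {a: 0.0 for a in agent_codes}
    attr_open_sums = {a: 0.0 for a in agent_codes}
    strikes: list[int] = [] if record_strikes else None
    if collect_cell_stats:
        open_accum = np.zeros(pnv.shape)
        pft_counts = np.zeros((5,) + pnv.shape, dtype=np.int32)
    for t in range(1, params.max_steps + 1):
        n_strikes = step(state, pnv, params, rng, t)
        if strikes is not None:
            strikes.append(n_strikes)
        if t <= params.record_after_step:
            continue
        n_rec += 1
        s = dataset_summary(state.openness, state.pft, mask)
        sum_open += s.mean_openness
        sum_trees += s.pct_tree_dominated
        sum_herbs += s.pct_herb_dominated
        for a in agent_codes:
            attr_pft_sums[a] += 100.0 * np.count_nonzero(state.last_agent_pft[land] == int(a)) / n_land
            attr_open_sums[a] += 100.0 * np.count_nonzero(state.last_agent_openness[land] == int(a)) / n_land
        if collect_cell_stats:
            open_accum += state.openness
            for code in range(5):
                pft_counts[code] += state.pft == code
    summary = SimSummary(
        mean_openness=sum_open / n_rec,
        pct_tree_dominated=sum_trees / n_rec,
        pct_herb_dominated=sum_herbs / n_rec,
        attribution_pft={a: attr_pft_sums[a] / n_rec for a in agent_codes},
        attribution_openness={a: attr_open_sums[a] / n_rec for a in agent_codes},
        n_steps_recorded=n_rec,
    )
    result = SimResult(
        summary=summary,
        last_agent_pft=state.last_agent_pft.copy(),
        last_agent_openness=state.last_agent_openness.copy(),
        strike_counts=strikes,
    )
    if collect_cell_stats:
        result.cell_mean_openness = open_accum / n_rec
        result.cell_modal_pft = np.argmax(pft_counts, axis=0).astype(np.int8)
    return result
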