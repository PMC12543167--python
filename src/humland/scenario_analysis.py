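"""Post-processing of calibration record pools.

Success rates, descriptive statistics with binned modes, modal-combination
selection, Pearson correlations, and per-agent attribution aggregation.
All operations take the tidy record table produced by
:func:`humland.calibration.records_to_frame`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import DEFAULT_BOUNDS, PARAM_NAMES, ScenarioParams
from .dynamics import AgentKind
from .errors import ConsistencyError, DomainError

__all__ = [
    "ParameterSummary",
    "success_rate",
    "describe_parameters",
    "select_modal_combinations",
    "pearson_matrix",
    "attribution_summary",
]

_INTEGER_PARAMS = frozenset({"number_of_groups", "accessible_radius"})
#: Continuous parameters are binned at 1/20 of their search range.
MODE_BIN_DIVISIONS = 20


@dataclass(frozen=True)
class ParameterSummary:
    """Descriptive statistics per calibrated parameter over successful records.

    ``modes`` holds one or more bin midpoints per parameter (several on
    ties); ``bin_width`` records the binning used.
    """

    stats: dict[str, dict[str, float]]  # mean/sd/min/max per parameter
    modes: dict[str, tuple[float, ...]]
    bin_width: dict[str, float]
    n_records: int


def _successful(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise DomainError("empty record table")
    if "success" in records.columns:
        return records[records["success"].astype(bool)]
    return records


def success_rate(records: pd.DataFrame, threshold: float = 0.10) -> float:
    """Percentage of records with fitness ≤ threshold."""
    if len(records) == 0:
        raise DomainError("empty record table")
    return float(100.0 * np.mean(records["fitness"].to_numpy() <= threshold))


def _binned_modes(values: np.ndarray, name: str, bounds) -> tuple[tuple[float, ...], float]:
    lo, hi = bounds.get(name, (float(values.min()), float(values.max())))
    if name in _INTEGER_PARAMS:
        ints = np.round(values).astype(int)
        counts = np.bincount(ints - ints.min())
        best = counts.max()
        modes = tuple(float(v + ints.min()) for v in np.flatnonzero(counts == best))
        return modes, 1.0
    width = (hi - lo) / MODE_BIN_DIVISIONS
    if width <= 0:
        return (float(values[0]),), 0.0
    edges = lo + width * np.arange(MODE_BIN_DIVISIONS + 1)
    counts, _ = np.histogram(values, bins=edges)
    best = counts.max()
    midpoints = (edges[:-1] + edges[1:]) / 2.0
    return tuple(float(m) for m in midpoints[counts == best]), float(width)


def describe_parameters(
    records: pd.DataFrame, bounds: dict[str, tuple[float, float]] | None = None
) -> ParameterSummary:
    """Mean, SD, min, max and binned mode(s) per parameter.

    Computed over the successful records only (the ``success`` column when
    present, otherwise all rows); raises
    :class:`~humland.errors.DomainError` when none qualify.
    """
    bounds = bounds or DEFAULT_BOUNDS
    good = _successful(records)
    if len(good) == 0:
        raise DomainError("no successful records to describe")
    stats: dict[str, dict[str, float]] = {}
    modes: dict[str, tuple[float, ...]] = {}
    widths: dict[str, float] = {}
    for name in PARAM_NAMES:
        values = good[name].to_numpy(dtype=float)
        stats[name] = {
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=0)),
            "min": float(values.min()),
            "max": float(values.max()),
        }
        modes[name], widths[name] = _binned_modes(values, name, bounds)
    return ParameterSummary(stats=stats, modes=modes, bin_width=widths, n_records=len(good))


def select_modal_combinations(
    records: pd.DataFrame,
    summary: ParameterSummary,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> list[ScenarioParams]:
    """Evaluated records closest to each modal parameter combination.

    For every element of the Cartesian set of per-parameter modes, the
    successful record minimizing the range-normalized Euclidean distance
    to that mode vector is selected (ties broken by lower fitness).
    Several modes on one parameter therefore yield several combinations.
    """
    bounds = bounds or DEFAULT_BOUNDS
    good = _successful(records).reset_index(drop=True)
    if len(good) == 0:
        raise DomainError("no successful records")
    values = good[list(PARAM_NAMES)].to_numpy(dtype=float)
    ranges = np.array([max(bounds[n][1] - bounds[n][0], 1e-12) for n in PARAM_NAMES])
    fitness = good["fitness"].to_numpy(dtype=float)
    chosen: list[ScenarioParams] = []
    for combo in itertools.product(*(summary.modes[n] for n in PARAM_NAMES)):
        dist = np.sqrt(np.sum(((values - np.array(combo)) / ranges) ** 2, axis=1))
        # lexicographic: minimal distance, then minimal fitness
        best = np.lexsort((fitness, dist))[0]
        row = good.iloc[int(best)]
        chosen.append(
            ScenarioParams(
                number_of_groups=int(row["number_of_groups"]),
                accessible_radius=int(row["accessible_radius"]),
                openness_criteria_to_burn=float(row["openness_criteria_to_burn"]),
                hunting_pressure=float(row["hunting_pressure"]),
            )
        )
    return chosen


def pearson_matrix(records: pd.DataFrame, include_fitness: bool = True) -> pd.DataFrame:
    """Pearson correlations between parameters (and fitness).

    Requires at least three successful records.  Entries for
    zero-variance columns are left undefined (NaN), not fabricated;
    the diagonal is 1 wherever the variable varies.
    """
    good = _successful(records)
    if len(good) < 3:
        raise DomainError("pearson_matrix needs at least 3 successful records")
    columns = list(PARAM_NAMES) + (["fitness"] if include_fitness else [])
    return good[columns].corr(method="pearson")


def attribution_summary(
    attribution_runs: list[tuple[np.ndarray, np.ndarray]],
    counted_mask: np.ndarray,
) -> pd.DataFrame:
    """Mean percentage of counted cells last modified by each agent.

    ``attribution_runs`` holds per-run ``(last_agent_pft,
    last_agent_openness)`` grids; ``counted_mask`` selects the cells that
    enter the denominator (land cells — water and high mountains are
    excluded).  Returns a long-format table (variable, agent, mean_pct).
    """
    if not attribution_runs:
        raise DomainError("no attribution runs supplied")
    counted_mask = np.asarray(counted_mask, dtype=bool)
    n_counted = int(counted_mask.sum())
    if n_counted == 0:
        raise DomainError("counted_mask selects no cells")
    agents = [AgentKind.CLIMATE, AgentKind.MEGAFAUNA, AgentKind.NATURAL_FIRE, AgentKind.HUMAN_FIRE]
    sums = {("pft", a): 0.0 for a in agents} | {("openness", a): 0.0 for a in agents}
    for pft_grid, open_grid in attribution_runs:
        for grid, variable in ((pft_grid, "pft"), (open_grid, "openness")):
            if np.asarray(grid).shape != counted_mask.shape:
                raise ConsistencyError("attribution grid shape differs from counted_mask")
            sel = np.asarray(grid)[counted_mask]
            for a in agents:
                sums[(variable, a)] += 100.0 * np.count_nonzero(sel == int(a)) / n_counted
    n_runs = len(attribution_runs)
    return pd.DataFrame(
        [
            {"variable": variable, "agent": a.name.lower(), "mean_pct": total / n_runs}
            for (variable, a), total in sums.items()
        ]
    )
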