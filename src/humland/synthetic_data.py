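"""Seeded generators for synthetic landscapes and calibration targets.

The production inputs of the pipeline — dynamic-vegetation-model rasters,
pollen-based reconstructions, megafauna consumption maps — are external
datasets.  These generators emulate their statistical structure (patchy
PFT mosaics with spatial autocorrelation, PFT-dependent openness, NPP and
consumption fields, partial target coverage) so the full engine and its
calibration can be exercised end to end.  They make no attempt at
geographic realism; the engine only needs patch structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .calibration import ScenarioParams
from .dynamics import SimParams, run_simulation
from .errors import ConfigurationError, DomainError
from .grid_model import CellClass, PFTCategory, PnvLandscape, TargetVegetation

__all__ = [
    "SynthConfig",
    "generate_pnv_landscape",
    "generate_target_offset",
    "generate_target_by_simulation",
]


@dataclass
class SynthConfig:
    """Configuration of the synthetic landscape generator.

    Default openness means (herbs 85, shrubs 55, broadleaf 20, needleleaf
    15 %) reproduce the qualitative open/closed contrast between herbaceous
    and forested cells.  NPP defaults (3–5 · 10⁵ kg km⁻² yr⁻¹, i.e.
    300–500 g m⁻² yr⁻¹) and consumption defaults (4–12 · 10³ kg km⁻² yr⁻¹)
    give per-step consumption percentages of order 1 % — the magnitude the
    herbivory process is built around.
    """

    n_rows: int = 50
    n_cols: int = 50
    water_fraction: float = 0.05
    mountain_fraction: float = 0.03
    patch_length_scale: float = 4.0
    pft_mix: dict[PFTCategory, float] = field(
        default_factory=lambda: {
            PFTCategory.HERBS: 0.25,
            PFTCategory.SHRUBS: 0.15,
            PFTCategory.BROADLEAF_TREES: 0.35,
            PFTCategory.NEEDLELEAF_TREES: 0.25,
        }
    )
    openness_by_pft: dict[PFTCategory, tuple[float, float]] = field(
        default_factory=lambda: {
            PFTCategory.HERBS: (85.0, 8.0),
            PFTCategory.SHRUBS: (55.0, 10.0),
            PFTCategory.BROADLEAF_TREES: (20.0, 8.0),
            PFTCategory.NEEDLELEAF_TREES: (15.0, 6.0),
        }
    )
    npp_range: tuple[float, float] = (3.0e5, 5.0e5)
    consumption_range: tuple[float, float] = (4.0e3, 1.2e4)
    coverage_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError("grid must have at least one row and column")
        if not (0 <= self.water_fraction <= 1 and 0 <= self.mountain_fraction <= 1):
            raise ConfigurationError("water/mountain fractions must lie in [0, 1]")
        if self.water_fraction + self.mountain_fraction > 1:
            raise ConfigurationError("water_fraction + mountain_fraction exceeds 1")
        total = sum(self.pft_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"pft_mix probabilities sum to {total}, expected 1")
        for lo, hi in (self.npp_range, self.consumption_range):
            if lo < 0 or hi < lo:
                raise ConfigurationError("ranges must be non-negative with min ≤ max")
        if not (0 <= self.coverage_fraction <= 1):
            raise ConfigurationError("coverage_fraction must lie in [0, 1]")


def _smooth_uniform_field(
    rng: np.random.Generator, shape: tuple[int, int], scale: float
) -> np.ndarray:
    """Gaussian-smoothed white noise, rank-transformed to Uniform(0, 1)."""
    noise = rng.standard_normal(shape)
    if scale > 0:
        noise = ndimage.gaussian_filter(noise, sigma=scale, mode="wrap")
    flat = noise.ravel()
    ranks = np.empty_like(flat)
    ranks[np.argsort(flat, kind="stable")] = (np.arange(flat.size) + 0.5) / flat.size
    return ranks.reshape(shape)


def generate_pnv_landscape(config: SynthConfig) -> PnvLandscape:
    """Generate a spatially autocorrelated potential-natural landscape.

    A smoothed-noise field thresholded at the cumulative ``pft_mix``
    quantiles yields the PFT mosaic; an independent field carves water
    (lowest quantile) and high mountains (highest).  Openness is drawn per
    PFT (normal, clipped to [0, 100]); NPP and maximal consumption are
    uniform within their ranges.  Deterministic per seed; marginal water /
    mountain / PFT shares match the requested fractions up to smoothing
    granularity.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.n_rows, config.n_cols)

    relief = _smooth_uniform_field(rng, shape, config.patch_length_scale)
    cell_class = np.full(shape, int(CellClass.LAND), dtype=np.int8)
    cell_class[relief < config.water_fraction] = int(CellClass.WATER)
    cell_class[relief > 1.0 - config.mountain_fraction] = int(CellClass.HIGH_MOUNTAIN)
    land = cell_class == int(CellClass.LAND)

    mosaic = _smooth_uniform_field(rng, shape, config.patch_length_scale)
    categories = list(config.pft_mix)
    edges = np.cumsum([config.pft_mix[c] for c in categories])
    edges[-1] = np.nextafter(1.0, 2.0)  # ranks lie strictly below 1
    codes = np.array([int(c) for c in categories], dtype=np.int8)
    idx = np.clip(np.searchsorted(edges, mosaic, side="right"), 0, len(codes) - 1)
    pft = codes[idx]

    openness = np.zeros(shape)
    for category, (mean, sd) in config.openness_by_pft.items():
        sel = pft == int(category)
        openness[sel] = np.clip(rng.normal(mean, sd, int(sel.sum())), 0.0, 100.0)
    npp = rng.uniform(*config.npp_range, size=shape)
    consumption = rng.uniform(*config.consumption_range, size=shape)

    openness[~land] = 0.0
    npp[~land] = 0.0
    consumption[~land] = 0.0
    pft[~land] = int(PFTCategory.BARE_GROUND)
    return PnvLandscape(
        pnv_pft=pft,
        pnv_openness=openness,
        pnv_npp=npp,
        max_consumption=consumption,
        cell_class=cell_class,
    )


def generate_target_offset(
    pnv: PnvLandscape,
    delta_openness: float,
    coverage_fraction: float = 1.0,
    seed: int = 0,
    herb_threshold: float = 50.0,
) -> TargetVegetation:
    """Target that is uniformly more open than the PNV landscape.

    Emulates the characteristic situation where pollen-based
    reconstructions indicate a more open environment than the
    climate-driven baseline: ``target_openness = min(100, pnv + delta)``
    on a seeded random coverage subset of land cells, with the dominant
    PFT flipped to herbs wherever the resulting openness exceeds
    ``herb_threshold``.
    """
    if delta_openness < 0:
        raise DomainError("delta_openness must be ≥ 0")
    rng = np.random.default_rng(seed)
    coverage = pnv.land_mask & (rng.random(pnv.shape) < coverage_fraction)
    target_open = np.minimum(100.0, pnv.pnv_openness + delta_openness)
    target_pft = np.where(
        target_open > herb_threshold, np.int8(PFTCategory.HERBS), pnv.pnv_pft
    ).astype(np.int8)
    target_open = np.where(coverage, target_open, 0.0)
    return TargetVegetation(target_openness=target_open, target_pft=target_pft, coverage=coverage)


def generate_target_by_simulation(
    pnv: PnvLandscape, true_params: ScenarioParams, sim_params: SimParams
) -> TargetVegetation:
    """Target produced by the engine itself under known true parameters.

    Runs the simulation with ``true_params`` injected into ``sim_params``
    and converts the recording-window per-cell time-mean openness and
    modal PFT into a fully covered target.  Because the truth is known by
    construction, such targets support parameter-recovery experiments.
    """
    params = replace(
        sim_params,
        number_of_groups=true_params.number_of_groups,
        accessible_radius=true_params.accessible_radius,
        openness_criteria_to_burn=true_params.openness_criteria_to_burn,
        hunting_pressure=true_params.hunting_pressure,
    )
    result = run_simulation(pnv, pnv.land_mask, params, collect_cell_stats=True)
    return TargetVegetation(
        target_openness=np.where(pnv.land_mask, result.cell_mean_openness, 0.0),
        target_pft=np.where(pnv.land_mask, result.cell_modal_pft, np.int8(PFTCategory.BARE_GROUND)),
        coverage=pnv.land_mask.copy(),
    )
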