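"""PNV vs pollen-target comparison: eligibility masking and summaries.

The climate-driven PNV dataset and the pollen-based reconstruction are
compared on the cells where both are defined and where the simulation can,
in principle, reproduce the target: disturbance only ever *opens*
vegetation, so a cell is usable either when its climax openness does not
exceed the pollen estimate, or when its climax PFT is woody (shrubs or
trees can still be converted to bare ground and herbs).  All summaries and
fitness values downstream are computed over this eligibility mask only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DomainError
from .grid_model import PFTCategory, PnvLandscape, TargetVegetation, TREE_PFTS, WOODY_PFTS

__all__ = [
    "DatasetSummary",
    "ComparisonDelta",
    "eligibility_mask",
    "dataset_summary",
    "compare_datasets",
    "summaries_to_frame",
]


@dataclass(frozen=True)
class DatasetSummary:
    """Mean openness and dominance shares over one set of eligible cells.

    ``pct_tree_dominated`` counts broadleaf + needleleaf cells;
    ``pct_herb_dominated`` counts herb cells; shrubs and bare ground count
    toward neither, so the two percentages sum to at most 100.
    """

    mean_openness: float
    pct_tree_dominated: float
    pct_herb_dominated: float
    n_cells: int


@dataclass(frozen=True)
class ComparisonDelta:
    """Signed target − PNV differences between two summaries."""

    delta_mean_openness: float
    delta_pct_tree_dominated: float
    delta_pct_herb_dominated: float


def eligibility_mask(pnv: PnvLandscape, target: TargetVegetation) -> np.ndarray:
    """Boolean grid of cells entering every comparison and fitness value.

    A cell is eligible iff it is land, has a pollen-based estimate, and
    either its PNV openness is ≤ the target openness or its PNV PFT is
    woody.  An all-false mask is allowed here; consumers reject it.
    """
    if pnv.shape != target.shape:
        raise ConsistencyError(f"landscape shape {pnv.shape} != target shape {target.shape}")
    woody = np.isin(pnv.pnv_pft, [int(p) for p in WOODY_PFTS])
    can_open = pnv.pnv_openness <= target.target_openness
    return pnv.land_mask & target.coverage & (can_open | woody)


def dataset_summary(
    openness: np.ndarray, pft: np.ndarray, mask: np.ndarray
) -> DatasetSummary:
    """Summarize one dataset over the masked cells.

    Raises :class:`~humland.errors.DomainError` on an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if openness.shape != mask.shape or pft.shape != mask.shape:
        raise ConsistencyError("openness/pft/mask shapes differ")
    n = int(mask.sum())
    if n == 0:
        raise DomainError("dataset_summary over an empty mask")
    open_sel = np.asarray(openness, dtype=float)[mask]
    pft_sel = np.asarray(pft)[mask]
    tree_codes = [int(p) for p in TREE_PFTS]
    return DatasetSummary(
        mean_openness=float(np.mean(open_sel)),
        pct_tree_dominated=float(100.0 * np.mean(np.isin(pft_sel, tree_codes))),
        pct_herb_dominated=float(100.0 * np.mean(pft_sel == int(PFTCategory.HERBS))),
        n_cells=n,
    )


def compare_datasets(pnv_summary: DatasetSummary, target_summary: DatasetSummary) -> ComparisonDelta:
    """Signed differences target − PNV; both summaries must share a mask."""
    if pnv_summary.n_cells != target_summary.n_cells:
        raise ConsistencyError(
            f"summaries computed on different masks "
            f"({pnv_summary.n_cells} vs {target_summary.n_cells} cells)"
        )
    return ComparisonDelta(
        delta_mean_openness=target_summary.mean_openness - pnv_summary.mean_openness,
        delta_pct_tree_dominated=target_summary.pct_tree_dominated - pnv_summary.pct_tree_dominated,
        delta_pct_herb_dominated=target_summary.pct_herb_dominated - pnv_summary.pct_herb_dominated,
    )


def summaries_to_frame(rows: list[tuple[str, str, DatasetSummary]]) -> pd.DataFrame:
    """Long-format table (window, source, mean_openness, pct_trees, pct_herbs, n_cells)."""
    return pd.DataFrame(
        [
            {
                "window": window,
                "source": source,
                "mean_openness": s.mean_openness,
                "pct_trees": s.pct_tree_dominated,
                "pct_herbs": s.pct_herb_dominated,
                "n_cells": s.n_cells,
            }
            for window, source, s in rows
        ]
    )
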