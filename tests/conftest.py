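"""Shared fixtures: tiny hand-built landscapes and generated worlds."""

from __future__ import annotations

import numpy as np
import pytest

from humland import PFTCategory, CellClass, PnvLandscape, SynthConfig, generate_pnv_landscape
from humland.dynamics import SimParams


def make_landscape(
    pft,
    openness,
    npp=4.0e5,
    consumption=0.0,
    cell_class=None,
    human_exclusion=None,
) -> PnvLandscape:
    """Build a landscape from scalar or array layers (broadcast to pft's shape)."""
    pft = np.atleast_2d(np.asarray(pft, dtype=np.int8))
    shape = pft.shape
    full = lambda v: np.broadcast_to(np.asarray(v, dtype=float), shape).copy()
    cc = (
        np.full(shape, int(CellClass.LAND), dtype=np.int8)
        if cell_class is None
        else np.atleast_2d(np.asarray(cell_class, dtype=np.int8))
    )
    return PnvLandscape(
        pnv_pft=pft,
        pnv_openness=full(openness),
        pnv_npp=full(npp),
        max_consumption=full(consumption),
        cell_class=cc,
        human_exclusion=human_exclusion,
    )


def single_cell(pft=PFTCategory.BROADLEAF_TREES, openness=40.0, **kw) -> PnvLandscape:
    return make_landscape([[int(pft)]], openness, **kw)


def quiet_params(**kw) -> SimParams:
    """All disturbance processes off unless overridden."""
    base = dict(natural_fires=False, megafauna_impact=False, humans=False,
                max_steps=10, record_after_step=0, seed=0)
    base.update(kw)
    return SimParams(**base)


@pytest.fixture(scope="session")
def small_world() -> PnvLandscape:
    """A 40x40 mixed landscape with water and mountains."""
    return generate_pnv_landscape(SynthConfig(n_rows=40, n_cols=40, seed=3))
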