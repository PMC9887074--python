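"""Shared fixtures: analytic curve factory and small cached ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from pfgdiff.engine import AttenuationCurve, default_delta_grid
from pfgdiff.params import GAMMA_PROTON, PFGParams


@pytest.fixture(scope="session")
def analytic_curve():
    """Factory: tabulate a closed-form lnS(Delta) model into a curve."""

    def make(fn, g, delta, grid=None, gamma=GAMMA_PROTON, **kw):
        if grid is None:
            grid = default_delta_grid(delta)
        lnS = np.array([
            fn(PFGParams(g=g, delta=delta, Delta=float(D), gamma=gamma), **kw)
            for D in grid
        ])
        return AttenuationCurve(Delta=np.asarray(grid, dtype=float), lnS=lnS,
                                g=g, delta=delta, gamma=gamma)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
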