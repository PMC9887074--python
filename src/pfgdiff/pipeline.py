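"""End-to-end synthesis: diffusion model + PFG condition -> attenuation curve.

Thin orchestration over the trajectory generators and the signal engine.
Trajectories are streamed in blocks so paper-scale ensembles (1e5 paths at
~1000 samples, or 5e4 CTRW paths at 1e5 samples) stay within a few hundred
MB of working memory.
"""

from __future__ import annotations

import numpy as np

from . import trajectories as traj
from .engine import AttenuationCurve, default_delta_grid, snap_to_grid, synthesize_from_blocks
from .params import CTRWParams, DiffusivityDistribution, NormalParams, PFGParams

__all__ = ["simulate_curve", "attenuation_matched_grid", "MODEL_DT_DEFAULTS"]

#: Sampling steps used to generate the synthetic study signals: 1e-3 s for
#: the continuous models, 1e-5 s for the jump process (whose waiting-time
#: scale is 1e-4 s).
MODEL_DT_DEFAULTS = {"bm": 1e-3, "fbm": 1e-3, "ss": 1e-3, "ctrw": 1e-5}


def attenuation_matched_grid(p_base: PFGParams, lnS_fn, n: int = 48,
                             lo: float | None = None, hi: float = 1.0,
                             floor: float = -5.0) -> np.ndarray:
    """Delta grid whose range is matched to the expected dynamic range.

    Mirrors how an experimentalist sets the diffusion-weighting range: the
    upper Delta is capped where the predicted attenuation ``lnS_fn(Delta)``
    reaches ``floor`` (S/S0 ~ 7e-3 at the default), so a Monte-Carlo or
    measured signal is not asked for points that sit below its noise floor.
    ``lnS_fn`` maps a Delta value to the predicted ln(S/S0) for the planned
    condition (use the closed form of the model being simulated).
    """
    start = max(2.0 * p_base.delta, 0.01) if lo is None else lo
    if start >= hi:
        raise ValueError(f"empty grid: start {start} >= hi {hi}")
    if lnS_fn(hi) >= floor:
        return np.linspace(start, hi, n)
    a, b = start, hi
    for _ in range(80):  # bisect the floor crossing
        mid = 0.5 * (a + b)
        if lnS_fn(mid) >= floor:
            a = mid
        else:
            b = mid
    # keep a minimal lever arm even when the signal dies immediately
    upper = max(a, 1.25 * start)
    return np.linspace(start, upper, n)


def simulate_curve(model: str, params, p_base: PFGParams, n_traj: int, seed,
                   Delta_grid=None, dt: float | None = None,
                   block_size: int | None = None) -> AttenuationCurve:
    """Simulate trajectories for ``model`` and synthesize its PFG attenuation.

    Parameters
    ----------
    model : {"bm", "fbm", "ss", "ctrw"}
    params : NormalParams | (K, H) tuple or AnomalousParams | DiffusivityDistribution | CTRWParams
    p_base : acquisition condition; Delta is taken from the grid
    n_traj : ensemble size
    seed : RNG seed (any SeedSequence-acceptable value)
    Delta_grid : optional; defaults to 48 points on [max(2 delta, 0.01), 1] s
    dt : sampling step; defaults per model (MODEL_DT_DEFAULTS)
    """
    if dt is None:
        dt = MODEL_DT_DEFAULTS[model]
    if Delta_grid is None:
        Delta_grid = default_delta_grid(p_base.delta)
    # snap timings and the grid onto the sampling lattice
    p_base = p_base.replace(t1=snap_to_grid(p_base.t1, dt, "t1"),
                            delta=snap_to_grid(p_base.delta, dt, "delta"))
    Delta_grid = np.unique([snap_to_grid(float(D), dt, "Delta", warn_frac=None)
                            for D in Delta_grid])  # dedupe post-snap collisions
    T = p_base.t1 + float(Delta_grid[-1]) + p_base.delta
    p_base = p_base.replace(Delta=float(Delta_grid[0]))

    if model == "bm":
        if not isinstance(params, NormalParams):
            raise TypeError("bm model requires NormalParams")
        bs = block_size or 5000
        blocks = traj.bm_blocks(n_traj, dt, T, params, seed, block_size=bs)
    elif model == "fbm":
        if isinstance(params, tuple):
            K, H = params
        else:  # AnomalousParams
            K, H = params.K, params.H
        bs = block_size or 5000
        blocks = traj.fbm_blocks(n_traj, dt, T, K, H, seed, block_size=bs)
    elif model == "ss":
        if not isinstance(params, DiffusivityDistribution):
            raise TypeError("ss model requires a DiffusivityDistribution")
        bs = block_size or 5000
        blocks = traj.ss_blocks(n_traj, dt, T, params, seed, block_size=bs)
    elif model == "ctrw":
        if not isinstance(params, CTRWParams):
            raise TypeError("ctrw model requires CTRWParams")
        bs = block_size or 200
        blocks = traj.ctrw_blocks(n_traj, params, T, dt, seed, block_size=bs)
    else:
        raise ValueError(f"unknown model {model!r}")

    curve = synthesize_from_blocks(blocks, dt, p_base, Delta_grid)
    curve.model = model
    curve.seed = seed if isinstance(seed, int) else None
    return curve
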