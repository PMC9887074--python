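"""Seeded Monte-Carlo generators of 1-D diffusion trajectories.

Four models, matching the simulation protocols used to build the synthetic
attenuation curves:

* ``bm``   — Langevin dynamics with an Ornstein-Uhlenbeck velocity, using the
  exact (bias-free) joint discretization of velocity and position;
* ``fbm``  — fractional Brownian motion via Davies-Harte circulant embedding
  (exact fractional Gaussian noise);
* ``ss``   — superstatistical Brownian motion: one diffusivity per trajectory
  drawn from P(D), overdamped Gaussian increments;
* ``ctrw`` — subdiffusive continuous-time random walk with Mittag-Leffler
  waiting times and Gaussian jumps, resampled to a uniform grid.

All generators stream trajectories in blocks so that paper-scale ensembles
(1e5 paths) never require the full position matrix in memory; the
``simulate_*`` wrappers assemble a full :class:`TrajectoryEnsemble` for
moderate sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.signal import lfilter

from .params import CTRWParams, DiffusivityDistribution, NormalParams

__all__ = [
    "TrajectoryEnsemble",
    "simulate_bm",
    "simulate_fbm",
    "simulate_ss",
    "simulate_ctrw",
    "sample_diffusivity",
    "msd",
    "bm_blocks",
    "fbm_blocks",
    "ss_blocks",
    "ctrw_blocks",
    "mittag_leffler_waiting_times",
    "fgn_autocovariance",
]

_DEFAULT_BLOCK = 2_000


@dataclass
class TrajectoryEnsemble:
    """N sampled 1-D position paths on the uniform grid t_j = j*dt.

    ``positions`` has shape (n_traj, n_steps); every path starts at x = 0
    (only displacements during the gradient pulses contribute to the phase,
    so the origin is immaterial).
    """

    dt: float
    positions: np.ndarray
    model: str
    params: object
    seed: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2:
            raise ValueError("positions must be a (n_traj, n_steps) array")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")

    @property
    def n_traj(self) -> int:
        return self.positions.shape[0]

    @property
    def n_steps(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        return (self.n_steps - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    def blocks(self, block_size: int = _DEFAULT_BLOCK) -> Iterator[np.ndarray]:
        for lo in range(0, self.n_traj, block_size):
            yield self.positions[lo:lo + block_size]


def _check_sim_args(n_traj: int, dt: float, T: float) -> int:
    if n_traj <= 0:
        raise ValueError("n_traj must be positive")
    if dt <= 0 or T <= 0:
        raise ValueError("dt and T must be positive")
    n_steps = int(round(T / dt)) + 1
    if n_steps < 2:
        raise ValueError("duration shorter than one step")
    return n_steps


# ---------------------------------------------------------------------------
# Brownian motion (Ornstein-Uhlenbeck velocity)
# ---------------------------------------------------------------------------

def _ou_step_moments(kBT: float, zeta: float, h: float):
    """Exact one-step covariance structure of (velocity, position increment)
    for the OU velocity process started from v: E[v'] = v e^{-zeta h},
    E[dx] = v (1 - e^{-zeta h})/zeta, plus zero-mean Gaussian fluctuations
    with the stationary-noise covariance below."""
    phi = math.exp(-zeta * h)
    var_v = kBT * (1.0 - phi * phi)
    var_x = kBT / zeta ** 2 * (2.0 * zeta * h - 3.0 + 4.0 * phi - phi * phi)
    cov = kBT / zeta * (1.0 - phi) ** 2
    return phi, var_v, var_x, cov


def bm_blocks(n_traj, dt, T, npar: NormalParams, seed,
              block_size: int = _DEFAULT_BLOCK) -> Iterator[np.ndarray]:
    """Stream exact-OU Brownian position paths in blocks of trajectories."""
    n_steps = _check_sim_args(n_traj, dt, T)
    if dt * npar.zeta >= 1.0:
        warnings.warn(
            f"dt*zeta = {dt * npar.zeta:.3g} >= 1: the velocity process is "
            "heavily sub-sampled; phase integrals may carry discretization bias",
            stacklevel=2,
        )
    phi, var_v, var_x, cov = _ou_step_moments(npar.kBT, npar.zeta, dt)
    sd_v = math.sqrt(var_v)
    # Cholesky factors of the (xi_v, xi_x) covariance
    c_xv = cov / sd_v if sd_v > 0 else 0.0
    c_xx = math.sqrt(max(var_x - c_xv * c_xv, 0.0))
    rng = np.random.default_rng(seed)
    for lo in range(0, n_traj, block_size):
        nb = min(block_size, n_traj - lo)
        z1 = rng.standard_normal((nb, n_steps - 1))
        z2 = rng.standard_normal((nb, n_steps - 1))
        v0 = math.sqrt(npar.kBT) * rng.standard_normal(nb)
        xi_v = sd_v * z1
        # v[j] for j = 0..n_steps-2 (value entering step j -> j+1)
        v_prev = np.empty((nb, n_steps - 1))
        v_prev[:, 0] = v0
        if n_steps > 2:
            # recursion v_j = phi v_{j-1} + xi_v_j via IIR filter
            v_prev[:, 1:] = lfilter([1.0], [1.0, -phi], xi_v[:, :-1], axis=1,
                                    zi=(phi * v0)[:, None])[0]
        dx = v_prev * (1.0 - phi) / npar.zeta + c_xv * z1 + c_xx * z2
        x = np.empty((nb, n_steps))
        x[:, 0] = 0.0
        np.cumsum(dx, axis=1, out=x[:, 1:])
        yield x


def simulate_bm(n_traj, dt, T, npar: NormalParams, seed) -> TrajectoryEnsemble:
    """Langevin Brownian motion; velocity starts in its stationary state."""
    pos = np.concatenate(list(bm_blocks(n_traj, dt, T, npar, seed)), axis=0)
    return TrajectoryEnsemble(dt=dt, positions=pos, model="bm", params=npar, seed=seed)


# ---------------------------------------------------------------------------
# Fractional Brownian motion (Davies-Harte)
# ---------------------------------------------------------------------------

def fgn_autocovariance(H: float, K: float, dt: float, lags) -> np.ndarray:
    """Exact autocovariance of fractional Gaussian noise increments over bins
    of width dt for an FBM with MSD = K t^{2H}:
    gamma(k) = (K/2) dt^{2H} (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * H
    return 0.5 * K * dt ** h2 * ((k + 1.0) ** h2 - 2.0 * k ** h2 + np.abs(k - 1.0) ** h2)


def _davies_harte_sqrt_eigs(n: int, H: float, K: float, dt: float) -> np.ndarray:
    """Square-rooted eigenvalues of the circulant embedding of the fGn
    covariance for n increments; pads the embedding if an eigenvalue dips
    negative (can happen for unlucky lengths)."""
    m = n
    for _ in range(6):
        gamma = fgn_autocovariance(H, K, dt, np.arange(m + 1))
        circ = np.concatenate([gamma, gamma[-2:0:-1]])
        eig = np.fft.fft(circ).real
        if eig.min() > -1e-12 * eig.max():
            return np.sqrt(np.clip(eig, 0.0, None))
        m *= 2
    raise RuntimeError(
        f"circulant embedding not nonnegative definite for n={n}, H={H} "
        "even after padding"
    )


def fbm_blocks(n_traj, dt, T, K, H, seed,
               block_size: int = _DEFAULT_BLOCK) -> Iterator[np.ndarray]:
    """Stream FBM position paths (exact fGn via circulant embedding)."""
    if not 0 < H < 1:
        raise ValueError(f"H must be in (0, 1), got {H}")
    if K <= 0:
        raise ValueError("K must be > 0")
    n_steps = _check_sim_args(n_traj, dt, T)
    n_inc = n_steps - 1
    sqrt_eig = _davies_harte_sqrt_eigs(n_inc, H, K, dt)
    m = sqrt_eig.size  # embedding size, 2 * padded increment count
    half = m // 2
    rng = np.random.default_rng(seed)
    for lo in range(0, n_traj, block_size):
        nb = min(block_size, n_traj - lo)
        w = np.empty((nb, m), dtype=complex)
        w[:, 0] = rng.standard_normal(nb) * (sqrt_eig[0] / math.sqrt(m))
        w[:, half] = rng.standard_normal(nb) * (sqrt_eig[half] / math.sqrt(m))
        zr = rng.standard_normal((nb, half - 1))
        zi = rng.standard_normal((nb, half - 1))
        mid = (zr + 1j * zi) * (sqrt_eig[1:half] / math.sqrt(2.0 * m))
        w[:, 1:half] = mid
        w[:, half + 1:] = np.conj(mid[:, ::-1])
        fgn = np.fft.fft(w, axis=1).real[:, :n_inc]
        x = np.empty((nb, n_steps))
        x[:, 0] = 0.0
        np.cumsum(fgn, axis=1, out=x[:, 1:])
        yield x


def simulate_fbm(n_traj, dt, T, K, H, seed) -> TrajectoryEnsemble:
    """Fractional Brownian motion with ensemble MSD = K t^{2H}."""
    pos = np.concatenate(list(fbm_blocks(n_traj, dt, T, K, H, seed)), axis=0)
    return TrajectoryEnsemble(dt=dt, positions=pos, model="fbm",
                              params={"K": K, "H": H}, seed=seed)


# ---------------------------------------------------------------------------
# Superstatistical Brownian motion
# ---------------------------------------------------------------------------

def sample_diffusivity(dist: DiffusivityDistribution, n: int, seed) -> np.ndarray:
    """Draw n per-trajectory diffusivities from P(D).

    Gamma kind: standard Gamma(k, theta) draws. Truncated-Gaussian kind:
    N(D*, sigma_D^2) conditioned on D >= 0 via rejection (acceptance is
    ~1 for sigma_D << D*); if the acceptance fraction drops below 1/2 an
    inverse-CDF draw through the truncated normal is used instead.
    """
    rng = np.random.default_rng(seed)
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.empty(0)
    if dist.kind == "gamma":
        return rng.gamma(shape=dist.k, scale=dist.theta, size=n)
    # truncated gaussian
    from scipy import stats
    accept = 1.0 - stats.norm.cdf(0.0, loc=dist.D_star, scale=dist.sigma_D)
    if accept >= 0.5:
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(dist.D_star, dist.sigma_D, size=n - filled)
            good = draw[draw >= 0.0]
            out[filled:filled + good.size] = good
            filled += good.size
        return out
    lo = -dist.D_star / dist.sigma_D
    u = rng.uniform(size=n)
    return stats.truncnorm.ppf(u, lo, np.inf, loc=dist.D_star, scale=dist.sigma_D)


def ss_blocks(n_traj, dt, T, dist: DiffusivityDistribution, seed,
              block_size: int = _DEFAULT_BLOCK) -> Iterator[np.ndarray]:
    """Stream superstatistical paths: per-path D, overdamped increments of
    variance 2 D dt."""
    n_steps = _check_sim_args(n_traj, dt, T)
    seq = np.random.SeedSequence(seed)
    d_seed, w_seed = seq.spawn(2)
    Ds = sample_diffusivity(dist, n_traj, d_seed)
    rng = np.random.default_rng(w_seed)
    for lo in range(0, n_traj, block_size):
        nb = min(block_size, n_traj - lo)
        sd = np.sqrt(2.0 * Ds[lo:lo + nb] * dt)[:, None]
        inc = sd * rng.standard_normal((nb, n_steps - 1))
        x = np.empty((nb, n_steps))
        x[:, 0] = 0.0
        np.cumsum(inc, axis=1, out=x[:, 1:])
        yield x


def simulate_ss(n_traj, dt, T, dist: DiffusivityDistribution, seed) -> TrajectoryEnsemble:
    """Superstatistical (Brownian yet non-Gaussian) ensemble."""
    pos = np.concatenate(list(ss_blocks(n_traj, dt, T, dist, seed)), axis=0)
    return TrajectoryEnsemble(dt=dt, positions=pos, model="ss", params=dist, seed=seed)


# ---------------------------------------------------------------------------
# Continuous-time random walk
# ---------------------------------------------------------------------------

def mittag_leffler_waiting_times(beta, gamma_t, size, rng) -> np.ndarray:
    """Mittag-Leffler waiting times by the Kozubowski-Rachev transform:

    tau = -gamma_t * ln(u) * [sin(beta pi)/tan(beta pi v) - cos(beta pi)]^{1/beta}

    with u, v independent uniforms on (0, 1). beta -> 1 recovers the
    exponential distribution of mean gamma_t.
    """
    u = rng.uniform(size=size)
    v = rng.uniform(size=size)
    bp = beta * math.pi
    factor = (math.sin(bp) / np.tan(bp * v) - math.cos(bp)) ** (1.0 / beta)
    return -gamma_t * np.log(u) * factor


def _ctrw_path_on_grid(arrivals, jumps, n_grid, dt):
    """Piecewise-constant CTRW position sampled on t_j = j*dt.

    ``arrivals`` are the (sorted) event times; position after the i-th event
    is jumps[:i+1].sum(). Returns the length-n_grid sampled path.
    """
    pos = np.concatenate([[0.0], np.cumsum(jumps)])
    # first grid index at/after each arrival; counts of grid points per
    # inter-event interval then build the sampled path by repetition
    grid_idx = np.ceil(arrivals / dt).astype(np.int64)
    grid_idx = np.clip(grid_idx, 0, n_grid)
    counts = np.diff(np.concatenate([[0], grid_idx, [n_grid]]))
    return np.repeat(pos, counts)[:n_grid]


def ctrw_blocks(n_traj, params: CTRWParams, T, dt_sample, seed,
                block_size: int = 200) -> Iterator[np.ndarray]:
    """Stream CTRW position paths resampled onto the uniform dt_sample grid.

    Jumps are Gaussian with standard deviation sqrt(2)*gamma_x (the variance
    of a symmetric 2-stable law of Chambers scale gamma_x), which makes the
    ensemble MSD 2 D_alpha t^beta with the printed D_alpha relation.
    """
    n_steps = _check_sim_args(n_traj, dt_sample, T)
    if dt_sample > params.gamma_t:
        warnings.warn(
            f"dt_sample = {dt_sample} > gamma_t = {params.gamma_t}: waiting "
            "times are under-resolved on the sampling grid",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    jump_sd = math.sqrt(2.0) * params.gamma_x
    n_grid = n_steps
    for lo in range(0, n_traj, block_size):
        nb = min(block_size, n_traj - lo)
        x = np.empty((nb, n_grid))
        for i in range(nb):
            # draw waiting times until the path covers [0, T]
            chunks = []
            total = 0.0
            while total <= T:
                tau = mittag_leffler_waiting_times(params.beta, params.gamma_t,
                                                   2048, rng)
                chunks.append(tau)
                total += float(tau.sum())
            arrivals = np.cumsum(np.concatenate(chunks))
            arrivals = arrivals[arrivals <= T + dt_sample]
            jumps = jump_sd * rng.standard_normal(arrivals.size)
            x[i] = _ctrw_path_on_grid(arrivals, jumps, n_grid, dt_sample)
        yield x


def simulate_ctrw(n_traj, params: CTRWParams, T, dt_sample, seed) -> TrajectoryEnsemble:
    """Subdiffusive CTRW resampled onto the uniform dt_sample grid."""
    pos = np.concatenate(
        list(ctrw_blocks(n_traj, params, T, dt_sample, seed)), axis=0)
    return TrajectoryEnsemble(dt=dt_sample, positions=pos, model="ctrw",
                              params=params, seed=seed)


# ---------------------------------------------------------------------------
# Ensemble statistics
# ---------------------------------------------------------------------------

def msd(e: TrajectoryEnsemble, fit_window: tuple[float, float] | None = None):
    """Ensemble mean squared displacement <[x(t) - x(0)]^2> on the time grid.

    Returns (times, msd_curve, fit) where ``fit`` is a (exponent, prefactor)
    log-log power-law regression over ``fit_window`` (in seconds; defaults
    to the last decade of the grid), skipping t = 0.
    """
    if e.n_traj == 0:
        raise ValueError("empty ensemble")
    disp = e.positions - e.positions[:, :1]
    curve = np.mean(disp * disp, axis=0)
    t = e.times
    if fit_window is None:
        fit_window = (max(e.duration / 10.0, e.dt), e.duration)
    lo, hi = fit_window
    sel = (t >= lo) & (t <= hi) & (curve > 0)
    if sel.sum() < 2:
        raise ValueError("fit window contains fewer than 2 usable points")
    slope, intercept = np.polyfit(np.log(t[sel]), np.log(curve[sel]), 1)
    return t, curve, (float(slope), float(math.exp(intercept)))
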