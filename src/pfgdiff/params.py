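"""Parameter bundles shared across the package.

Units are SI throughout: gradient strength in T/m, times in s, diffusion
coefficients in m^2/s (or m^2/s^alpha for the generalized coefficient),
gyromagnetic ratio in rad s^-1 T^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Proton gyromagnetic ratio, rad s^-1 T^-1 (CODATA). Default only — every
#: formula takes gamma from the PFGParams instance, never from this constant.
GAMMA_PROTON = 2.6752218744e8


@dataclass(frozen=True)
class PFGParams:
    """One pulsed-field-gradient acquisition condition.

    Two rectangular gradient lobes of strength ``g`` and duration ``delta``,
    opposite polarity, separated by ``Delta`` (leading-edge to leading-edge),
    the first starting at ``t1`` after excitation.
    """

    g: float            # gradient strength, T/m
    delta: float        # gradient pulse duration, s
    Delta: float        # pulse interspacing, s
    gamma: float = GAMMA_PROTON  # gyromagnetic ratio, rad s^-1 T^-1
    t1: float = 0.005   # sequence start offset, s

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.Delta < self.delta:
            raise ValueError(
                f"Delta ({self.Delta}) must be >= delta ({self.delta})"
            )
        if self.g < 0:
            raise ValueError(f"g must be >= 0, got {self.g}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.t1 < 0:
            raise ValueError(f"t1 must be >= 0, got {self.t1}")

    @property
    def b(self) -> float:
        """Diffusion weighting b = gamma^2 g^2 delta^2 (Delta - delta/3), s/m^2."""
        return (self.gamma * self.g * self.delta) ** 2 * (self.Delta - self.delta / 3.0)

    @property
    def q(self) -> float:
        """Wavevector magnitude q = gamma g delta / (2 pi), 1/m."""
        return self.gamma * self.g * self.delta / (2.0 * math.pi)

    @property
    def echo_time(self) -> float:
        """End of the second gradient lobe, t1 + Delta + delta, s."""
        return self.t1 + self.Delta + self.delta

    def replace(self, **kw) -> "PFGParams":
        d = dict(g=self.g, delta=self.delta, Delta=self.Delta,
                 gamma=self.gamma, t1=self.t1)
        d.update(kw)
        return PFGParams(**d)


@dataclass(frozen=True)
class NormalParams:
    """Langevin (Ornstein-Uhlenbeck velocity) Brownian motion parameters.

    The particle mass is set to 1, so k_B T = D * zeta carries units m^2/s^2
    and is the stationary velocity variance.
    """

    D: float      # diffusion coefficient, m^2/s
    zeta: float   # viscous drag rate, s^-1

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if not self.zeta > 0:
            raise ValueError(f"zeta must be > 0, got {self.zeta}")

    @property
    def kBT(self) -> float:
        return self.D * self.zeta


@dataclass(frozen=True)
class AnomalousParams:
    """Gaussian stationary-increment anomalous diffusion: MSD = 2 D_alpha t^alpha.

    Equivalent fractional-Brownian parameterization: Hurst exponent H = alpha/2
    and MSD prefactor K = 2 D_alpha (MSD = K t^{2H}).
    """

    alpha: float     # anomalous exponent, in (0, 2)
    D_alpha: float   # generalized diffusion coefficient, m^2/s^alpha

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 2:
            raise ValueError(f"alpha must be in (0, 2), got {self.alpha}")
        if not self.D_alpha > 0:
            raise ValueError(f"D_alpha must be > 0, got {self.D_alpha}")

    @property
    def H(self) -> float:
        return self.alpha / 2.0

    @property
    def K(self) -> float:
        return 2.0 * self.D_alpha

    @classmethod
    def from_hurst(cls, H: float, K: float) -> "AnomalousParams":
        return cls(alpha=2.0 * H, D_alpha=K / 2.0)


@dataclass(frozen=True)
class DiffusivityDistribution:
    """Per-trajectory diffusivity law P(D) of the superstatistical model.

    Two kinds: ``gamma`` with shape k and scale theta (mean k*theta), and
    ``truncated_gaussian`` — a normal of mean D_star and spread sigma_D
    restricted to D >= 0 and renormalized by the erfc factor.
    """

    kind: str
    k: float | None = None         # gamma shape, dimensionless
    theta: float | None = None     # gamma scale, m^2/s
    D_star: float | None = None    # gaussian mean, m^2/s
    sigma_D: float | None = None   # gaussian spread, m^2/s

    def __post_init__(self) -> None:
        if self.kind == "gamma":
            if self.k is None or self.theta is None:
                raise ValueError("gamma kind requires k and theta")
            if not (self.k > 0 and self.theta > 0):
                raise ValueError("k and theta must be > 0")
        elif self.kind == "truncated_gaussian":
            if self.D_star is None or self.sigma_D is None:
                raise ValueError("truncated_gaussian kind requires D_star and sigma_D")
            if not (self.D_star > 0 and self.sigma_D > 0):
                raise ValueError("D_star and sigma_D must be > 0")
        else:
            raise ValueError(f"unknown distribution kind {self.kind!r}")

    @classmethod
    def gamma_dist(cls, k: float, theta: float) -> "DiffusivityDistribution":
        return cls(kind="gamma", k=k, theta=theta)

    @classmethod
    def truncated_gaussian(cls, D_star: float, sigma_D: float) -> "DiffusivityDistribution":
        return cls(kind="truncated_gaussian", D_star=D_star, sigma_D=sigma_D)

    @property
    def a(self) -> float:
        """Relative spread sigma_D / D_star (truncated_gaussian only)."""
        if self.kind != "truncated_gaussian":
            raise AttributeError("a is defined for the truncated_gaussian kind")
        return self.sigma_D / self.D_star

    @property
    def mean(self) -> float:
        """Mean diffusivity. For the truncated Gaussian this is the mean of the
        renormalized density on D >= 0, not the untruncated D_star."""
        from scipy import stats
        if self.kind == "gamma":
            return self.k * self.theta
        lo = -self.D_star / self.sigma_D
        return float(stats.truncnorm.mean(lo, np.inf, loc=self.D_star, scale=self.sigma_D))

    def pdf(self, D):
        """Density of P(D) on [0, inf); vectorized over D."""
        from scipy import stats
        D = np.asarray(D, dtype=float)
        if self.kind == "gamma":
            out = stats.gamma.pdf(D, a=self.k, scale=self.theta)
        else:
            lo = -self.D_star / self.sigma_D
            out = stats.truncnorm.pdf(D, lo, np.inf, loc=self.D_star, scale=self.sigma_D)
        return out


@dataclass(frozen=True)
class CTRWParams:
    """Subdiffusive continuous-time random walk.

    Mittag-Leffler waiting times (exponent ``beta``, time scale ``gamma_t``)
    and Gaussian jumps whose stable length scale ``gamma_x`` is tied to the
    generalized diffusion coefficient by
    D_alpha = gamma_x^2 / (gamma_t^beta * Gamma(1 + beta)).
    """

    beta: float               # Mittag-Leffler exponent, in (0, 1)
    gamma_t: float            # waiting-time scale, s
    gamma_x: float            # jump length scale, m

    def __post_init__(self) -> None:
        if not 0 < self.beta < 1:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")
        if not self.gamma_t > 0:
            raise ValueError(f"gamma_t must be > 0, got {self.gamma_t}")
        if not self.gamma_x > 0:
            raise ValueError(f"gamma_x must be > 0, got {self.gamma_x}")

    @property
    def D_alpha(self) -> float:
        return self.gamma_x ** 2 / (self.gamma_t ** self.beta * math.gamma(1.0 + self.beta))

    @classmethod
    def from_D_alpha(cls, beta: float, gamma_t: float, D_alpha: float) -> "CTRWParams":
        gamma_x = math.sqrt(D_alpha * gamma_t ** beta * math.gamma(1.0 + beta))
        return cls(beta=beta, gamma_t=gamma_t, gamma_x=gamma_x)
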