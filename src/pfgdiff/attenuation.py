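"""Closed-form and quadrature attenuation models for PFG diffusion NMR.

Every function here returns ln(S(Delta)/S(0)) — the log of the normalized
echo amplitude — for one acquisition condition. The closed forms cover:

* free (Stejskal-Tanner) diffusion, ln S = -b D;
* Langevin Brownian motion with a finite velocity correlation time 1/zeta,
  the generalization of Stejskal-Tanner to arbitrary pulse duration;
* Gaussian stationary-increment anomalous diffusion (MSD = 2 D_alpha t^alpha),
  both the full four-power-law form and its Delta >~ 2 delta reduction;
* superstatistical ("Brownian yet non-Gaussian") ensembles with Gamma or
  zero-truncated Gaussian diffusivity distributions, which depend on the
  acquisition only through the b value.

Quadrature engines for arbitrary velocity / position autocorrelation kernels
and arbitrary P(D) serve as independent numerical oracles for the closed
forms and for user-supplied kernels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import log_ndtr

from .params import AnomalousParams, DiffusivityDistribution, NormalParams, PFGParams

__all__ = [
    "b_value",
    "lnS_stejskal_tanner",
    "lnS_bm",
    "lnS_anomalous_full",
    "lnS_anomalous",
    "lnS_general_velocity",
    "lnS_general_position",
    "msd_from_vacf",
    "lnS_ss_gamma",
    "lnS_ss_gaussian",
    "lnS_ss_numeric",
    "delta_f_anomalous",
    "ExponentialVACF",
    "PowerLawVACF",
    "ln_erfc",
    "QuadratureError",
]


class QuadratureError(RuntimeError):
    """Adaptive quadrature failed to reach the requested tolerance."""


def b_value(p: PFGParams) -> float:
    """Diffusion weighting b = gamma^2 g^2 delta^2 (Delta - delta/3), s/m^2."""
    return p.b


def ln_erfc(x) -> np.ndarray:
    """Numerically stable ln(erfc(x)) via the scaled normal log-CDF.

    erfc(x) = 2 Phi(-sqrt(2) x), so ln erfc(x) = ln 2 + log_ndtr(-sqrt(2) x);
    accurate for arguments deep in either tail where erfc under/overflows.
    """
    x = np.asarray(x, dtype=float)
    return np.log(2.0) + log_ndtr(-math.sqrt(2.0) * x)


# ---------------------------------------------------------------------------
# Gaussian stationary-increment closed forms
# ---------------------------------------------------------------------------

def lnS_stejskal_tanner(p: PFGParams, D: float) -> float:
    """Classical free-diffusion attenuation, ln S/S0 = -b D."""
    if D < 0:
        raise ValueError("D must be >= 0")
    return -p.b * D


def lnS_bm(p: PFGParams, npar: NormalParams) -> float:
    """Brownian (Langevin) attenuation with finite velocity correlation time.

    ln S/S0 = -gamma^2 g^2 delta^2 D (Delta - delta/3)
              + 2 gamma^2 g^2 D { delta/zeta^2
                 - [1 - e^{-delta zeta} + e^{-Delta zeta}(cosh(delta zeta)-1)]/zeta^3 }

    The cosh(delta*zeta)*exp(-Delta*zeta) product is expanded into
    (e^{(delta-Delta) zeta} + e^{-(delta+Delta) zeta})/2 so large delta*zeta
    never overflows (Delta >= delta guarantees both exponents are <= 0).
    """
    D, z = npar.D, npar.zeta
    g2 = (p.gamma * p.g) ** 2
    main = -g2 * p.delta ** 2 * D * (p.Delta - p.delta / 3.0)
    # e^{-Dz}(cosh(dz) - 1) without forming cosh explicitly
    dz, Dz = p.delta * z, p.Delta * z
    cosh_term = 0.5 * (math.exp(dz - Dz) + math.exp(-dz - Dz)) - math.exp(-Dz)
    corr = 2.0 * g2 * D * (p.delta / z ** 2 - (1.0 - math.exp(-dz) + cosh_term) / z ** 3)
    return main + corr


def lnS_anomalous_full(p: PFGParams, ap: AnomalousParams) -> float:
    """Anomalous attenuation, full four-power-law form.

    ln S/S0 = -gamma^2 g^2 D_alpha / ((alpha+1)(alpha+2)) *
              [ (Delta+delta)^{alpha+2} + (Delta-delta)^{alpha+2}
                - 2 Delta^{alpha+2} - 2 delta^{alpha+2} ]
    """
    a = ap.alpha
    pref = (p.gamma * p.g) ** 2 * ap.D_alpha / ((a + 1.0) * (a + 2.0))
    e = a + 2.0
    bracket = ((p.Delta + p.delta) ** e + (p.Delta - p.delta) ** e
               - 2.0 * p.Delta ** e - 2.0 * p.delta ** e)
    return -pref * bracket


def lnS_anomalous(p: PFGParams, ap: AnomalousParams) -> float:
    """Anomalous Stejskal-Tanner extension, valid for Delta >~ 2 delta.

    ln S/S0 = -gamma^2 g^2 delta^2 D_alpha [Delta^alpha
              - 2 delta^alpha / ((alpha+1)(alpha+2))]

    Below Delta = 2 delta the neglected boundary integrals are no longer
    small; a warning is emitted but the value is still returned.
    """
    if p.Delta < 2.0 * p.delta:
        warnings.warn(
            f"lnS_anomalous used at Delta = {p.Delta} < 2*delta = {2 * p.delta}; "
            "the reduced formula is only accurate for Delta >~ 2*delta",
            stacklevel=2,
        )
    a = ap.alpha
    g2d2 = (p.gamma * p.g * p.delta) ** 2
    return -g2d2 * ap.D_alpha * (
        p.Delta ** a - 2.0 * p.delta ** a / ((a + 1.0) * (a + 2.0))
    )


def delta_f_anomalous(ap: AnomalousParams, delta1: float, delta2: float) -> float:
    """Analytic value of the two-pulse-duration discriminator on the anomalous
    closed form: f(delta1, delta2) = 2 D_alpha (delta1^alpha - delta2^alpha)
    / ((alpha+1)(alpha+2)), independent of Delta."""
    a = ap.alpha
    return 2.0 * ap.D_alpha * (delta1 ** a - delta2 ** a) / ((a + 1.0) * (a + 2.0))


# ---------------------------------------------------------------------------
# Autocorrelation kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExponentialVACF:
    """Velocity autocorrelation of Langevin BM: C(s) = kBT exp(-zeta s)."""

    kBT: float
    zeta: float

    def __call__(self, s):
        return self.kBT * np.exp(-self.zeta * np.asarray(s, dtype=float))


@dataclass(frozen=True)
class PowerLawVACF:
    """Anomalous-diffusion kernel C(s) = alpha (alpha-1) D_alpha s^{alpha-2}.

    For alpha < 1 the kernel is not absolutely integrable at s = 0; panel
    integrals over [0, delta] are then defined by analytic continuation in
    alpha (finite part), which is exactly the rule that makes
    2 * int_0^t C(s)(t-s) ds = 2 D_alpha t^alpha hold for every alpha in (0,2).
    The closed-form panel moments below implement that rule.
    """

    alpha: float
    D_alpha: float

    def __call__(self, s):
        s = np.asarray(s, dtype=float)
        return self.alpha * (self.alpha - 1.0) * self.D_alpha * s ** (self.alpha - 2.0)

    # finite-part moments int_0^u C(s) s^m ds
    def moment0(self, u: float) -> float:
        return self.alpha * self.D_alpha * u ** (self.alpha - 1.0)

    def moment2(self, u: float) -> float:
        a = self.alpha
        return a * (a - 1.0) * self.D_alpha * u ** (a + 1.0) / (a + 1.0)

    def moment3(self, u: float) -> float:
        a = self.alpha
        return a * (a - 1.0) * self.D_alpha * u ** (a + 2.0) / (a + 2.0)


_QUAD_OPTS = dict(epsabs=1e-14, epsrel=1e-10, limit=400)


def _quad(f, lo, hi):
    """scipy.integrate.quad returning (value, error-estimate)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        return integrate.quad(f, lo, hi, **_QUAD_OPTS)


def _quad_zero_panel(f, hi):
    """Quadrature of f on [0, hi] with the substitution s = hi * u^3,
    which regularizes the fractional-power behaviour of diffusion kernels
    near s = 0 (u^3 maps mild algebraic endpoint singularities to smooth
    integrands)."""
    def g(u):
        return 3.0 * hi * u * u * f(hi * u ** 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        return integrate.quad(g, 0.0, 1.0, **_QUAD_OPTS)


def _check_panels(panels, rel_tol: float = 1e-5):
    """Sum panel (value, err) pairs; fail if the accumulated quadrature error
    exceeds ``rel_tol`` of the dominant panel magnitude."""
    total = sum(v for v, _ in panels)
    err = sum(e for _, e in panels)
    scale = max((abs(v) for v, _ in panels), default=0.0)
    if err > rel_tol * max(scale, abs(total)) and err > 1e-300:
        raise QuadratureError(
            f"quadrature achieved abs error {err:.3e} on a result of magnitude "
            f"{max(scale, abs(total)):.3e} (rel {err / max(scale, 1e-300):.3e} "
            f"> tol {rel_tol:.0e})"
        )
    return total


def lnS_general_velocity(C, p: PFGParams) -> float:
    """Attenuation from an arbitrary velocity autocorrelation C(s).

    Evaluates the five-panel PFG reduction of the second-cumulant double
    integral:

    ln S/S0 = -gamma^2 g^2 { delta^2 [ int_0^delta C (Delta - delta/3)
                                       + int_delta^Delta C (Delta - s) ]
              - int_0^delta C s^2 (delta - s/3)
              - 1/6 int_{Delta-delta}^{Delta} C (Delta-delta-s)^3
              + 1/6 int_{Delta}^{Delta+delta} C (Delta+delta-s)^3 }

    If ``C`` is a PowerLawVACF the [0, delta] panels use its analytic
    (finite-part) moments; otherwise C must be integrable near 0.
    """
    d, DD = p.delta, p.Delta
    g2 = (p.gamma * p.g) ** 2

    if isinstance(C, PowerLawVACF):
        i0 = (C.moment0(d), 0.0)                         # int_0^d C
        i_s2 = (d * C.moment2(d) - C.moment3(d) / 3.0, 0.0)  # int_0^d C s^2 (d - s/3)
    else:
        i0 = _quad_zero_panel(lambda s: C(s), d)
        i_s2 = _quad_zero_panel(lambda s: C(s) * s * s * (d - s / 3.0), d)

    mid = _quad(lambda s: C(s) * (DD - s), d, DD)
    t3 = _quad(lambda s: C(s) * (DD - d - s) ** 3, DD - d, DD)
    t4 = _quad(lambda s: C(s) * (DD + d - s) ** 3, DD, DD + d)
    panels = [
        (d ** 2 * (i0[0] * (DD - d / 3.0) + mid[0]), d ** 2 * (i0[1] * DD + mid[1])),
        (-i_s2[0], i_s2[1]),
        (-t3[0] / 6.0, t3[1] / 6.0),
        (t4[0] / 6.0, t4[1] / 6.0),
    ]
    return -g2 * _check_panels(panels)


def lnS_general_position(X, p: PFGParams) -> float:
    """Attenuation from a stationary position autocorrelation X(s) = <x(0)x(s)>.

    ln S/S0 = -gamma^2 g^2 { 2 int_0^delta X (delta - s)
              + int_{Delta-delta}^{Delta} X (Delta-delta-s)
              - int_{Delta}^{Delta+delta} X (Delta+delta-s) }

    Note the stationarity premise: for a freely diffusing process
    <x(0)x(s)> is not stationary, yet with X(s) = const - D_alpha s^alpha
    (the stationary surrogate implied by MSD = 2 D_alpha s^alpha; additive
    constants cancel identically between the three panels) this reproduces
    the anomalous closed form. The formula is implemented literally.
    """
    d, DD = p.delta, p.Delta
    g2 = (p.gamma * p.g) ** 2
    q1 = _quad_zero_panel(lambda s: X(s) * (d - s), d)
    q2 = _quad(lambda s: X(s) * (DD - d - s), DD - d, DD)
    q3 = _quad(lambda s: X(s) * (DD + d - s), DD, DD + d)
    panels = [(2.0 * q1[0], 2.0 * q1[1]), (q2[0], q2[1]), (-q3[0], q3[1])]
    return -g2 * _check_panels(panels)


def msd_from_vacf(C, t: float) -> float:
    """MSD from the velocity autocorrelation: <x^2(t)> = 2 int_0^t C(s)(t-s) ds.

    PowerLawVACF kernels use the analytic continuation (giving exactly
    2 D_alpha t^alpha); generic callables are integrated adaptively.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 0.0
    if isinstance(C, PowerLawVACF):
        return 2.0 * C.D_alpha * t ** C.alpha
    v, e = _quad_zero_panel(lambda s: C(s) * (t - s), t)
    return 2.0 * _check_panels([(v, e)])


# ---------------------------------------------------------------------------
# Superstatistical (Brownian yet non-Gaussian) closed forms
# ---------------------------------------------------------------------------

def lnS_ss_gamma(p: PFGParams, dist: DiffusivityDistribution) -> float:
    """Superstatistical attenuation for Gamma-distributed diffusivity:
    ln S/S0 = -k ln(1 + b theta). Depends on the sequence only through b."""
    if dist.kind != "gamma":
        raise ValueError("lnS_ss_gamma requires a gamma diffusivity distribution")
    return -dist.k * math.log1p(p.b * dist.theta)


def lnS_ss_gaussian(p: PFGParams, dist: DiffusivityDistribution) -> float:
    """Superstatistical attenuation for zero-truncated Gaussian diffusivity.

    With a = sigma_D / D_star:

    ln S/S0 = -D* b + a^2 D*^2 b^2 / 2
              + ln erfc(-1/(sqrt(2) a) + a D* b / sqrt(2))
              - ln erfc(-1/(sqrt(2) a))

    The erfc logs go through ln_erfc (scaled-CDF path), stable for
    arbitrarily large a D* b.
    """
    if dist.kind != "truncated_gaussian":
        raise ValueError("lnS_ss_gaussian requires a truncated_gaussian distribution")
    b = p.b
    Ds, a = dist.D_star, dist.a
    s2 = math.sqrt(2.0)
    gauss = -Ds * b + 0.5 * (a * Ds * b) ** 2
    return float(gauss
                 + ln_erfc(-1.0 / (s2 * a) + a * Ds * b / s2)
                 - ln_erfc(-1.0 / (s2 * a)))


def lnS_ss_numeric(p: PFGParams, pdf, *, D_scale: float | None = None) -> float:
    """Quadrature oracle: ln int_0^inf exp(-b D) pdf(D) dD.

    ``pdf`` must be a normalized density on [0, inf). ``D_scale`` sets the
    split point between the near-zero and tail panels (defaults to the
    pdf's rough mean estimated by quadrature on a coarse scan).
    """
    b = p.b
    if D_scale is None:
        # coarse scan for a magnitude scale (mean of the density)
        grid = np.geomspace(1e-16, 1e-4, 600)
        w = pdf(grid) * grid
        D_scale = float(np.trapezoid(w, grid)) or 1e-9
    # integrate in the dimensionless variable u = D / D_scale so the
    # integrand has O(1) support (quad's infinite-interval map needs that)
    f = lambda u: math.exp(-b * D_scale * u) * float(pdf(D_scale * u)) * D_scale
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        v1, e1 = integrate.quad(f, 0.0, 1.0, **_QUAD_OPTS)
        v2, e2 = integrate.quad(f, 1.0, np.inf, **_QUAD_OPTS)
    val, err = v1 + v2, e1 + e2
    if not val > 0:
        raise QuadratureError("S/S0 quadrature returned a non-positive value")
    if err > 1e-9 * val:
        raise QuadratureError(
            f"S/S0 quadrature achieved rel error {err / val:.3e} > 1e-9"
        )
    return math.log(val)


# ---------------------------------------------------------------------------
# Helpers between the log and linear signal scales
# ---------------------------------------------------------------------------

def to_signal(lnS):
    """ln(S/S0) -> S/S0."""
    return np.exp(np.asarray(lnS, dtype=float))


def to_lnS(S):
    """S/S0 -> ln(S/S0); rejects non-positive signals."""
    S = np.asarray(S, dtype=float)
    if np.any(S <= 0):
        raise ValueError("signal must be positive to take the log")
    return np.log(S)
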