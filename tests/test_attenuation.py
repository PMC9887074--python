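"""Closed-form attenuation models against quadrature oracles and algebraic
identities."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pfgdiff.attenuation import (
    ExponentialVACF,
    PowerLawVACF,
    b_value,
    delta_f_anomalous,
    ln_erfc,
    lnS_anomalous,
    lnS_anomalous_full,
    lnS_bm,
    lnS_general_position,
    lnS_general_velocity,
    lnS_ss_gamma,
    lnS_ss_gaussian,
    lnS_ss_numeric,
    lnS_stejskal_tanner,
    msd_from_vacf,
)
from pfgdiff.params import (
    GAMMA_PROTON,
    AnomalousParams,
    DiffusivityDistribution,
    NormalParams,
    PFGParams,
)

P = PFGParams(g=0.01, delta=0.01, Delta=0.1)
NP = NormalParams(D=2e-9, zeta=20.0)
GAMMA_DIST = DiffusivityDistribution.gamma_dist(0.5, 2e-9)
GAUSS_DIST = DiffusivityDistribution.truncated_gaussian(2e-9, 1e-10)


class TestBValue:
    def test_direct_arithmetic(self):
        # independently recomputed, spreadsheet-style
        gamma, g, d, D = 2.6752218744e8, 0.01, 0.01, 0.1
        expected = gamma * gamma * g * g * d * d * (D - d / 3.0)
        assert b_value(PFGParams(g=g, delta=d, Delta=D, gamma=gamma)) == pytest.approx(
            expected, rel=1e-15)
        assert expected == pytest.approx(69182516.7469, rel=1e-10)

    def test_zero_gradient(self):
        assert b_value(P.replace(g=0.0)) == 0.0

    def test_degenerate_Delta_rejected(self):
        # Delta = delta/3 would zero b but violates Delta >= delta
        with pytest.raises(ValueError):
            PFGParams(g=0.01, delta=0.01, Delta=0.01 / 3.0)

    @given(g=st.floats(1e-4, 1.0), delta=st.floats(1e-4, 0.05),
           ratio=st.floats(1.0, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_and_zero_iff_no_gradient(self, g, delta, ratio):
        p = PFGParams(g=g, delta=delta, Delta=ratio * delta)
        assert b_value(p) >= 0
        assert (b_value(p) == 0) == (g * delta == 0)


class TestStejskalTanner:
    def test_zero_diffusion_limit(self):
        assert lnS_stejskal_tanner(P, 0.0) == 0.0

    def test_large_zeta_limit_of_bm(self):
        # delta*zeta = 1e6: the correction term of the Brownian form vanishes
        big = NormalParams(D=2e-9, zeta=1e6 / P.delta)
        st_val = lnS_stejskal_tanner(P, 2e-9)
        assert lnS_bm(P, big) == pytest.approx(st_val, rel=1e-9)

    def test_alpha_one_reduction(self):
        ap = AnomalousParams(alpha=1.0, D_alpha=2e-9)
        assert lnS_anomalous(P, ap) == pytest.approx(lnS_stejskal_tanner(P, 2e-9),
                                                     rel=1e-14)


class TestBrownian:
    def test_quadrature_oracle(self):
        """Eq-by-quadrature: double-integral of the exponential velocity
        kernel against the waveform product, via 2-D trapezoid."""
        p = P
        kBT, zeta = NP.kBT, NP.zeta
        TE = p.t1 + p.Delta + p.delta
        t = np.linspace(0.0, TE, 4001)
        F = np.zeros_like(t)
        F = np.where((t >= p.t1) & (t < p.t1 + p.delta), p.g * (t - p.t1), F)
        F = np.where((t >= p.t1 + p.delta) & (t < p.t1 + p.Delta), p.g * p.delta, F)
        F = np.where((t >= p.t1 + p.Delta) & (t < p.t1 + p.Delta + p.delta),
                     p.g * (p.t1 + p.Delta + p.delta - t), F)
        C = kBT * np.exp(-zeta * np.abs(t[:, None] - t[None, :]))
        integrand = C * F[:, None] * F[None, :]
        inner = np.trapezoid(integrand, t, axis=1)
        oracle = -p.gamma ** 2 / 2.0 * np.trapezoid(inner, t)
        assert lnS_bm(p, NP) == pytest.approx(oracle, rel=1e-6)

    def test_monotone_decreasing_in_Delta(self):
        vals = [lnS_bm(P.replace(Delta=D), NP) for D in np.linspace(0.02, 1.0, 30)]
        assert np.all(np.diff(vals) < 0)

    def test_no_overflow_at_large_delta_zeta(self):
        # naive cosh(delta*zeta) overflows near delta*zeta ~ 1400
        p = PFGParams(g=0.01, delta=0.01, Delta=0.1)
        val = lnS_bm(p, NormalParams(D=2e-9, zeta=1e6))
        assert np.isfinite(val) and val < 0


class TestAnomalous:
    def test_alpha_one_is_cubic_identity(self):
        # (D+d)^3 + (D-d)^3 - 2D^3 - 2d^3 = 6 D d^2 - 2 d^3 exactly
        ap = AnomalousParams(alpha=1.0, D_alpha=2e-9)
        assert lnS_anomalous_full(P, ap) == pytest.approx(
            lnS_stejskal_tanner(P, 2e-9), rel=1e-12)

    def test_narrow_pulse_limit(self):
        """delta -> 0 at fixed q: the full form tends to -(2 pi q)^2 D_a Delta^a."""
        alpha, Da, Delta = 0.7, 2e-9, 0.5
        q = GAMMA_PROTON * 0.01 * 0.01 / (2 * math.pi)
        target = -(2 * math.pi * q) ** 2 * Da * Delta ** alpha
        rel_prev = None
        for delta in (1e-3, 1e-4, 1e-5):
            g = 2 * math.pi * q / (GAMMA_PROTON * delta)  # keep q fixed
            p = PFGParams(g=g, delta=delta, Delta=Delta)
            val = lnS_anomalous_full(p, AnomalousParams(alpha, Da))
            rel = abs(val - target) / abs(target)
            if rel_prev is not None:
                assert rel < rel_prev  # converging to the NPG limit
            rel_prev = rel
        assert rel < 1e-3

    @pytest.mark.parametrize("alpha", [0.5, 0.7, 1.2])
    def test_reduced_matches_full_in_validity_domain(self, alpha):
        ap = AnomalousParams(alpha=alpha, D_alpha=2e-9)
        for Delta in (0.02, 0.1, 0.5, 1.0):
            p = P.replace(Delta=Delta)
            full = lnS_anomalous_full(p, ap)
            red = lnS_anomalous(p, ap)
            assert red == pytest.approx(full, rel=0.01)

    def test_warns_below_validity_domain(self):
        ap = AnomalousParams(alpha=0.5, D_alpha=2e-9)
        with pytest.warns(UserWarning, match="2\\*delta"):
            lnS_anomalous(PFGParams(g=0.01, delta=0.01, Delta=0.015), ap)

    def test_exact_g_squared_scaling(self):
        ap = AnomalousParams(alpha=0.5, D_alpha=2e-9)
        for fn in (lnS_anomalous, lnS_anomalous_full):
            v1 = fn(P.replace(Delta=0.5), ap)
            v2 = fn(P.replace(Delta=0.5, g=0.02), ap)
            assert v2 == pytest.approx(4.0 * v1, rel=1e-14)
        v1 = lnS_bm(P, NP)
        v2 = lnS_bm(P.replace(g=0.02), NP)
        assert v2 == pytest.approx(4.0 * v1, rel=1e-14)

    def test_delta_f_closed_form(self):
        """f(delta1, delta2) on the reduced anomalous form is Delta-free and
        equals 2 D_a (d1^a - d2^a)/((a+1)(a+2))."""
        ap = AnomalousParams(alpha=0.5, D_alpha=2e-9)
        d1, d2, g = 0.01, 0.02, 0.01
        expected = delta_f_anomalous(ap, d1, d2)
        for Delta in (0.05, 0.2, 0.8):
            f = (GAMMA_PROTON * g) ** -2 * (
                lnS_anomalous(PFGParams(g=g, delta=d1, Delta=Delta), ap) / d1 ** 2
                - lnS_anomalous(PFGParams(g=g, delta=d2, Delta=Delta), ap) / d2 ** 2)
            assert f == pytest.approx(expected, rel=1e-12)


class TestGeneralKernels:
    def test_zero_kernel(self):
        assert lnS_general_velocity(lambda s: 0.0 * np.asarray(s), P) == 0.0
        assert lnS_general_position(lambda s: 0.0 * np.asarray(s), P) == 0.0

    def test_velocity_reproduces_brownian(self):
        p = PFGParams(g=0.01, delta=0.005, Delta=0.2)
        val = lnS_general_velocity(ExponentialVACF(NP.kBT, NP.zeta), p)
        assert val == pytest.approx(lnS_bm(p, NP), rel=1e-6)

    @pytest.mark.parametrize("alpha", [0.5, 0.7, 1.2])
    def test_velocity_reproduces_anomalous(self, alpha):
        p = P.replace(Delta=0.5)
        val = lnS_general_velocity(PowerLawVACF(alpha, 2e-9), p)
        ref = lnS_anomalous_full(p, AnomalousParams(alpha, 2e-9))
        assert val == pytest.approx(ref, rel=1e-6)

    def test_position_reproduces_anomalous(self):
        # stationary surrogate X(s) = -D_a s^a (constants cancel identically)
        ap = AnomalousParams(alpha=0.7, D_alpha=2e-9)
        p = P.replace(Delta=0.5)
        val = lnS_general_position(lambda s: -ap.D_alpha * np.asarray(s) ** ap.alpha, p)
        assert val == pytest.approx(lnS_anomalous_full(p, ap), rel=1e-6)

    def test_position_linearity(self):
        X = lambda s: -2e-9 * np.asarray(s) ** 0.7
        v1 = lnS_general_position(X, P)
        v3 = lnS_general_position(lambda s: 3.0 * X(s), P)
        assert v3 == pytest.approx(3.0 * v1, rel=1e-12)


class TestMSDFromVACF:
    def test_exponential_kernel_closed_form(self):
        t = 0.3
        val = msd_from_vacf(ExponentialVACF(NP.kBT, NP.zeta), t)
        ref = 2 * NP.D * t - 2 * NP.D / NP.zeta * (1 - math.exp(-NP.zeta * t))
        assert val == pytest.approx(ref, rel=1e-9)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 1.5])
    def test_power_law_kernel(self, alpha):
        assert msd_from_vacf(PowerLawVACF(alpha, 2e-9), 0.3) == pytest.approx(
            2 * 2e-9 * 0.3 ** alpha, rel=1e-12)

    def test_zero_time(self):
        assert msd_from_vacf(ExponentialVACF(NP.kBT, NP.zeta), 0.0) == 0.0


class TestSuperstatistical:
    def test_zero_b(self):
        p0 = P.replace(g=0.0)
        assert lnS_ss_gamma(p0, GAMMA_DIST) == 0.0
        assert lnS_ss_gaussian(p0, GAUSS_DIST) == 0.0

    def test_gamma_small_b_expansion(self):
        p = PFGParams(g=1e-4, delta=0.01, Delta=0.1)
        assert lnS_ss_gamma(p, GAMMA_DIST) == pytest.approx(
            -GAMMA_DIST.k * GAMMA_DIST.theta * p.b, rel=1e-3)

    def test_gaussian_narrow_limit_is_stejskal_tanner(self):
        narrow = DiffusivityDistribution.truncated_gaussian(2e-9, 2e-13)  # a = 1e-4
        p = P.replace(Delta=0.5)
        assert lnS_ss_gaussian(p, narrow) == pytest.approx(
            lnS_stejskal_tanner(p, 2e-9), rel=1e-6)

    @pytest.mark.parametrize("Delta", [0.05, 0.2, 1.0])
    def test_gamma_vs_quadrature(self, Delta):
        p = P.replace(Delta=Delta)
        assert lnS_ss_gamma(p, GAMMA_DIST) == pytest.approx(
            lnS_ss_numeric(p, GAMMA_DIST.pdf), rel=1e-8)

    @pytest.mark.parametrize("Delta", [0.05, 0.2, 1.0])
    def test_gaussian_vs_quadrature(self, Delta):
        p = P.replace(Delta=Delta)
        assert lnS_ss_gaussian(p, GAUSS_DIST) == pytest.approx(
            lnS_ss_numeric(p, GAUSS_DIST.pdf), rel=1e-8)

    def test_numeric_with_point_mass(self):
        # pdf concentrated at D0 -> -b D0 (narrow gaussian surrogate)
        from scipy import stats
        D0, eps = 2e-9, 1e-12
        pdf = lambda D: stats.norm.pdf(D, loc=D0, scale=eps)
        p = P.replace(Delta=0.5)
        assert lnS_ss_numeric(p, pdf, D_scale=D0) == pytest.approx(-p.b * D0, rel=1e-5)

    def test_depends_on_b_only(self):
        """Distinct (g, delta, Delta) with identical b give identical lnS."""
        p1 = PFGParams(g=0.01, delta=0.01, Delta=0.5)
        p2 = PFGParams(g=0.02, delta=0.005, Delta=0.5 - 0.01 / 3 + 0.005 / 3)
        assert p1.b == pytest.approx(p2.b, rel=1e-14)
        assert lnS_ss_gamma(p1, GAMMA_DIST) == lnS_ss_gamma(p2, GAMMA_DIST)
        assert lnS_ss_gaussian(p1, GAUSS_DIST) == lnS_ss_gaussian(p2, GAUSS_DIST)

    def test_g2_scaling_violated(self):
        """The superstatistical forms are NOT g^2-proportional (beyond first
        order) — the discriminating asymmetry with the Gaussian family."""
        p1, p2 = P.replace(Delta=0.5), P.replace(Delta=0.5, g=0.02)
        for fn, dist in ((lnS_ss_gamma, GAMMA_DIST),
                         (lnS_ss_gaussian,
                          DiffusivityDistribution.truncated_gaussian(2e-9, 1e-9))):
            v1, v2 = fn(p1, dist), fn(p2, dist)
            assert abs(v2 - 4.0 * v1) > 1e-3 * abs(v1)

    def test_ln_erfc_stability(self):
        """Deep-tail ln(erfc) stays finite and smooth where erfc underflows."""
        x = np.linspace(-30.0, 40.0, 200)
        vals = ln_erfc(x)
        assert np.all(np.isfinite(vals))
        # asymptotic series check at a huge argument
        big = 50.0
        asym = -big * big + math.log(1.0 / (big * math.sqrt(math.pi)))
        assert float(ln_erfc(big)) == pytest.approx(asym, abs=1e-3)

    @given(Delta=st.floats(0.05, 1.0), g=st.floats(1e-3, 0.1))
    @settings(max_examples=30, deadline=None)
    def test_always_nonpositive(self, Delta, g):
        p = PFGParams(g=g, delta=0.01, Delta=Delta)
        ap = AnomalousParams(0.7, 2e-9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for val in (lnS_stejskal_tanner(p, 2e-9), lnS_bm(p, NP),
                        lnS_anomalous(p, ap), lnS_anomalous_full(p, ap),
                        lnS_ss_gamma(p, GAMMA_DIST), lnS_ss_gaussian(p, GAUSS_DIST)):
                assert val <= 0.0
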