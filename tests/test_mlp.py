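"""Scattering moments, the matrix MLP, its envelope and the water baseline."""

import numpy as np
import pytest

from pctpath import (
    DepthGrid,
    PhaseState,
    lateral_error,
    mlp_estimate,
    mlp_profile,
    mlp_water,
    scattering_moments,
    water_energy_curve,
    water_scattering_power,
)
from pctpath.mlp import water_energy_factor_polynomial


@pytest.fixture(scope="module")
def sine_profile():
    u = np.linspace(0.0, 10.0, 101)
    return u, 2e-4 * (1.0 + 0.5 * np.sin(u))


class TestScatteringMoments:
    def test_constant_T_closed_forms(self):
        u = np.linspace(0.0, 10.0, 101)
        T = np.full(u.size, 3e-4)
        L = 4.0
        m = scattering_moments(u, T, 0.0, L)
        assert m.a0 == pytest.approx(3e-4 * L, rel=1e-9)
        assert m.a1 == pytest.approx(3e-4 * L**2 / 2, rel=1e-9)
        assert m.a2 == pytest.approx(3e-4 * L**3 / 3, rel=1e-3)

    def test_additive_over_adjoining_segments(self, sine_profile):
        u, T = sine_profile
        whole = scattering_moments(u, T, 1.0, 7.0)
        left = scattering_moments(u, T, 1.0, 4.0)
        right = scattering_moments(u, T, 4.0, 7.0)
        assert whole.a0 == pytest.approx(left.a0 + right.a0, rel=1e-9)

    def test_matches_fine_grid_quadrature(self, sine_profile):
        u, T = sine_profile
        uf = np.linspace(0.0, 10.0, 1001)
        Tf = np.interp(uf, u, T)
        coarse = scattering_moments(u, T, 0.7, 8.3)
        fine = scattering_moments(uf, Tf, 0.7, 8.3)
        for a, b in [(coarse.a0, fine.a0), (coarse.a1, fine.a1), (coarse.a2, fine.a2)]:
            assert a == pytest.approx(b, rel=1e-3)

    def test_degenerate_segment_gives_zero_moments(self):
        u = np.linspace(0.0, 10.0, 101)
        T = np.full(u.size, 3e-4)
        m = scattering_moments(u, T, 5.0, 5.0)
        assert (m.a0, m.a1, m.a2) == (0.0, 0.0, 0.0)
        assert m.degenerate

    def test_cauchy_schwarz_inequality(self, sine_profile):
        u, T = sine_profile
        m = scattering_moments(u, T, 0.0, 9.0)
        assert m.a1**2 <= m.a0 * m.a2


def _brute_force_map(y0, y2, u1, m1, m2, centre, half=(0.06, 0.012), nres=241):
    """Dense grid search of the bivariate Gaussian posterior maximum."""
    S1i = np.linalg.inv(m1.covariance())
    S2i = np.linalg.inv(m2.covariance())
    R0 = np.array([[1.0, u1 - y0.u], [0.0, 1.0]])
    R1 = np.array([[1.0, y2.u - u1], [0.0, 1.0]])
    mu = R0 @ y0.as_vector()
    ts = centre[0] + np.linspace(-half[0], half[0], nres)
    hs = centre[1] + np.linspace(-half[1], half[1], nres)
    TT, HH = np.meshgrid(ts, hs, indexing="ij")
    d1t, d1h = TT - mu[0], HH - mu[1]
    p2t = y2.t - (TT + (y2.u - u1) * HH)
    p2h = y2.theta - HH
    nll = (
        S1i[0, 0] * d1t**2 + 2 * S1i[0, 1] * d1t * d1h + S1i[1, 1] * d1h**2
        + S2i[0, 0] * p2t**2 + 2 * S2i[0, 1] * p2t * p2h + S2i[1, 1] * p2h**2
    )
    i, j = np.unravel_index(np.argmin(nll), nll.shape)
    return ts[i], hs[j]


class TestMatrixMLP:
    def test_boundary_consistency(self, sine_profile):
        u, T = sine_profile
        y0 = PhaseState(0.1, 0.01, 0.0)
        y2 = PhaseState(-0.2, -0.005, 10.0)
        m1 = scattering_moments(u, T, 0.0, 0.0)
        m2 = scattering_moments(u, T, 0.0, 10.0)
        assert mlp_estimate(y0, y2, 0.0, m1, m2) == y0
        assert mlp_estimate(y0, y2, 10.0, m1, m2) == y2

    def test_symmetric_zero_boundaries_give_zero_path(self, sine_profile):
        u, T = sine_profile
        y0 = PhaseState(0.0, 0.0, 0.0)
        y2 = PhaseState(0.0, 0.0, 10.0)
        for u1 in (2.0, 5.0, 8.0):
            m1 = scattering_moments(u, T, 0.0, u1)
            m2 = scattering_moments(u, T, u1, 10.0)
            est = mlp_estimate(y0, y2, u1, m1, m2)
            assert est.t == pytest.approx(0.0, abs=1e-15)
            assert est.theta == pytest.approx(0.0, abs=1e-15)

    def test_matches_brute_force_posterior_maximum(self, sine_profile):
        u, T = sine_profile
        rng = np.random.default_rng(12)
        for _ in range(25):
            u1 = rng.uniform(1.0, 9.0)
            y0 = PhaseState(rng.normal(0, 0.1), rng.normal(0, 0.02), 0.0)
            y2 = PhaseState(rng.normal(0, 0.1), rng.normal(0, 0.02), 10.0)
            m1 = scattering_moments(u, T, 0.0, u1)
            m2 = scattering_moments(u, T, u1, 10.0)
            est = mlp_estimate(y0, y2, u1, m1, m2)
            bt, bh = _brute_force_map(y0, y2, u1, m1, m2, (est.t, est.theta))
            assert est.t == pytest.approx(bt, abs=6e-4)
            assert est.theta == pytest.approx(bh, abs=1.2e-4)

    def test_linear_in_boundary_states(self, sine_profile):
        u, T = sine_profile
        u1 = 4.0
        m1 = scattering_moments(u, T, 0.0, u1)
        m2 = scattering_moments(u, T, u1, 10.0)
        y0 = PhaseState(0.05, 0.01, 0.0)
        y2 = PhaseState(-0.1, 0.004, 10.0)
        one = mlp_estimate(y0, y2, u1, m1, m2)
        double = mlp_estimate(
            PhaseState(2 * y0.t, 2 * y0.theta, 0.0),
            PhaseState(2 * y2.t, 2 * y2.theta, 10.0),
            u1, m1, m2,
        )
        assert double.t == pytest.approx(2 * one.t, rel=1e-12)
        assert double.theta == pytest.approx(2 * one.theta, rel=1e-12)

    def test_zero_scatter_falls_back_to_straight_line(self):
        u = np.linspace(0.0, 10.0, 101)
        T = np.zeros(u.size)
        y0 = PhaseState(0.0, 0.0, 0.0)
        y2 = PhaseState(1.0, 0.1, 10.0)
        m1 = scattering_moments(u, T, 0.0, 4.0)
        m2 = scattering_moments(u, T, 4.0, 10.0)
        est = mlp_estimate(y0, y2, 4.0, m1, m2)
        assert est.t == pytest.approx(0.4, rel=1e-12)


class TestLateralError:
    def test_vanishes_at_boundaries(self, sine_profile):
        u, T = sine_profile
        for u1 in (0.05, 9.95):
            m1 = scattering_moments(u, T, 0.0, u1)
            m2 = scattering_moments(u, T, u1, 10.0)
            assert lateral_error(m1, m2, u1) < 5e-4

    def test_factor_two_exactly_as_published(self):
        u = np.linspace(0.0, 10.0, 101)
        T = np.full(u.size, 2e-4)
        m1 = scattering_moments(u, T, 0.0, 5.0)
        m2 = scattering_moments(u, T, 5.0, 10.0)
        # constant T: (S1^-1 + R1^T S2^-1 R1)^-1_(1,1) = T a^3 / 24 at midpoint
        expect = np.sqrt(2e-4 * 5.0**3 / 24.0)
        assert lateral_error(m1, m2, 5.0, factor_two=False) == pytest.approx(
            expect, rel=1e-2
        )
        assert lateral_error(m1, m2, 5.0) == pytest.approx(
            np.sqrt(2.0) * expect, rel=1e-2
        )

    def test_scales_as_sqrt_of_T(self, sine_profile):
        u, T = sine_profile
        m1 = scattering_moments(u, T, 0.0, 4.0)
        m2 = scattering_moments(u, T, 4.0, 10.0)
        m1d = scattering_moments(u, 2 * T, 0.0, 4.0)
        m2d = scattering_moments(u, 2 * T, 4.0, 10.0)
        assert lateral_error(m1d, m2d, 4.0) == pytest.approx(
            np.sqrt(2.0) * lateral_error(m1, m2, 4.0), rel=1e-9
        )

    def test_independent_of_boundary_values(self, sine_profile):
        u, T = sine_profile
        q = np.arange(10, 100, 10)
        a = mlp_profile(u, T, 0.0, 0.0, 0.0, 0.0, q)
        b = mlp_profile(u, T, 0.3, 0.05, -0.2, -0.04, q)
        assert np.allclose(a.sigma_t, b.sigma_t)

    def test_symmetric_profile_under_symmetric_T(self):
        u = np.linspace(0.0, 20.0, 201)
        T = 1e-4 * (1.0 + ((u - 10.0) / 10.0) ** 2)  # symmetric about midpoint
        q = np.arange(5, 200, 5)
        res = mlp_profile(u, T, 0.0, 0.0, 0.0, 0.0, q)
        s = res.sigma_t
        assert np.argmax(s) == pytest.approx(s.size // 2, abs=1)
        assert np.allclose(s, s[::-1], rtol=5e-3)


class TestWaterBaseline:
    def test_modes_agree_in_water(self):
        y0 = PhaseState(0.0, 0.0, 0.0)
        y2 = PhaseState(0.15, 0.012, 20.0)
        q = np.arange(0.5, 20.0, 0.5)
        g = mlp_water(y0, y2, q, 200.0, mode="gottschalk")
        l = mlp_water(y0, y2, q, 200.0, mode="lynch_dahl")
        rms_diff = np.sqrt(np.mean((g.t - l.t) ** 2))
        rms = np.sqrt(np.mean(g.t**2))
        assert rms_diff / rms < 0.02
        # peak envelope widths agree; the Highland thickness correction
        # shrinks the Lynch-Dahl variant near the faces
        assert l.sigma_t.max() == pytest.approx(g.sigma_t.max(), rel=0.1)

    def test_energy_factor_polynomial_residual(self):
        _, resid = water_energy_factor_polynomial(200.0, 20.0)
        assert resid < 0.005

    def test_zero_depth_returns_boundary_state(self):
        y0 = PhaseState(0.3, 0.01, 5.0)
        y2 = PhaseState(0.3, 0.01, 5.0)
        st, sig = mlp_water(y0, y2, 5.0, 200.0)
        assert st == y0 and sig == 0.0

    def test_scalar_interface_matches_profile(self):
        y0 = PhaseState(0.0, 0.0, 0.0)
        y2 = PhaseState(0.1, 0.0, 20.0)
        st, sig = mlp_water(y0, y2, 10.0, 200.0, mode="gottschalk")
        res = mlp_water(y0, y2, np.array([10.0]), 200.0, mode="gottschalk")
        assert st.t == pytest.approx(res.t[0])
        assert sig == pytest.approx(res.sigma_t[0])
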