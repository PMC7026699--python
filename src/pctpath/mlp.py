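"""Matrix most-likely-path estimation with Fermi-Eyges scattering moments.

Given measured entry and exit phase states (lateral position and projected
direction on the phantom faces), the lateral position of a proton at an
intermediate depth is a bivariate Gaussian posterior whose maximiser has a
compact closed form:

    y_MLP = (S1^-1 + R1^T S2^-1 R1)^-1 (S1^-1 R0 y0 + R1^T S2^-1 y2)

where R0, R1 are drift (change-of-basis) matrices and S1, S2 are the
Fermi-Eyges covariance matrices of the segments before and after the
calculation depth, assembled from the moments

    A_n(u_i) = integral over the segment of (u_i - eta)^n T(eta) d eta.

The (1,1) element of 2 (S1^-1 + R1^T S2^-1 R1)^-1 defines the squared
lateral standard error used for the probability envelope (the factor 2 is
part of the published error matrix; it can be disabled for sensitivity
analysis via ``factor_two=False``).

Only the t-u projection is estimated; the v-u plane is an independent
process and reuses the same machinery when requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from . import constants as c
from .energy import (
    DepthGrid,
    MaterialProfile,
    forward_euler,
    water_energy_curve,
    water_scattering_power,
)

__all__ = [
    "PhaseState",
    "ScatteringMoments",
    "MLPResult",
    "scattering_moments",
    "mlp_estimate",
    "lateral_error",
    "mlp_water",
    "mlp_profile",
    "water_energy_factor_polynomial",
]

#: determinant threshold below which a covariance matrix is treated as
#: singular (zero-scatter segment) and the straight-line fallback is used
_DET_GUARD = 1e-30


@dataclass(frozen=True)
class PhaseState:
    """Projected phase state: lateral position t [cm], angle theta [rad], depth u [cm]."""

    t: float
    theta: float
    u: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.t, self.theta])


@dataclass(frozen=True)
class ScatteringMoments:
    """Fermi-Eyges moments of one segment, targeted at its far end.

    a0 [rad^2] is the angular variance, a1 [rad^2 cm] the angle-position
    covariance and a2 [rad^2 cm^2] the lateral-position variance
    accumulated over (u_start, u_end).
    """

    a0: float
    a1: float
    a2: float
    u_start: float
    u_end: float

    @property
    def degenerate(self) -> bool:
        return self.a2 * self.a0 - self.a1 * self.a1 < _DET_GUARD

    def covariance(self) -> np.ndarray:
        """2x2 covariance matrix in (t, theta) ordering."""
        return np.array([[self.a2, self.a1], [self.a1, self.a0]])


@dataclass
class MLPResult:
    """Per-query-depth most likely path and its lateral standard error."""

    u: np.ndarray  # (q,)
    t: np.ndarray  # (..., q)
    theta: np.ndarray
    sigma_t: np.ndarray
    method: str = "mlpx"
    sampled: np.ndarray | None = None  # MLPxSH: True where directly calculated


def scattering_moments(
    u_grid, T, u_start: float, u_end: float, target: float | None = None
) -> ScatteringMoments:
    """Integrate the moments A_n = int (target - eta)^n T(eta) d eta.

    ``T`` is a sampled scattering-power profile on ``u_grid``; composite
    trapezoid integration with linear interpolation at the segment ends.
    A reversed or empty segment yields zero (degenerate) moments.
    """
    if target is None:
        target = u_end
    if u_end <= u_start:
        return ScatteringMoments(0.0, 0.0, 0.0, u_start, u_end)
    u_grid = np.asarray(u_grid, dtype=float)
    T = np.asarray(T, dtype=float)
    inside = (u_grid > u_start) & (u_grid < u_end)
    eta = np.concatenate(([u_start], u_grid[inside], [u_end]))
    Tv = np.interp(eta, u_grid, T)
    d = target - eta
    a0 = np.trapezoid(Tv, eta)
    a1 = np.trapezoid(d * Tv, eta)
    a2 = np.trapezoid(d * d * Tv, eta)
    return ScatteringMoments(float(a0), float(a1), float(a2), u_start, u_end)


def _solve_mlp(a2_1, a1_1, a0_1, a2_2, a1_2, a0_2, d01, s12, t0, th0, t2, th2):
    """Vectorized closed-form solution of the 2x2 posterior system.

    Segment-1 moments target u1, segment-2 moments target u2; ``d01`` is
    u1 - u0 and ``s12`` is u2 - u1.  Returns (t, theta, var_t) where var_t
    is the (1,1) element of (S1^-1 + R1^T S2^-1 R1)^-1 (without the
    published factor 2).  Singular segments fall back to straight-line
    interpolation between the boundary states (var_t = 0).
    """
    d1 = a2_1 * a0_1 - a1_1 * a1_1
    d2 = a2_2 * a0_2 - a1_2 * a1_2
    ok = (d1 > _DET_GUARD) & (d2 > _DET_GUARD)
    d1s = np.where(ok, d1, 1.0)
    d2s = np.where(ok, d2, 1.0)

    # S1^-1 (t first)
    i11 = a0_1 / d1s
    i12 = -a1_1 / d1s
    i22 = a2_1 / d1s
    # S2^-1
    b11 = a0_2 / d2s
    b12 = -a1_2 / d2s
    b22 = a2_2 / d2s

    m11 = i11 + b11
    m12 = i12 + b11 * s12 + b12
    m22 = i22 + b11 * s12 * s12 + 2.0 * s12 * b12 + b22

    # S1^-1 R0 y0
    p1 = t0 + th0 * d01
    r1 = i11 * p1 + i12 * th0
    r2 = i12 * p1 + i22 * th0
    # R1^T S2^-1 y2
    c1 = b11 * t2 + b12 * th2
    c2 = b12 * t2 + b22 * th2
    r1 = r1 + c1
    r2 = r2 + s12 * c1 + c2

    det = m11 * m22 - m12 * m12
    det = np.where(np.abs(det) > _DET_GUARD, det, 1.0)
    t = (m22 * r1 - m12 * r2) / det
    th = (-m12 * r1 + m11 * r2) / det
    var = m22 / det

    # straight-line fallback for zero-scatter segments
    frac = d01 / (d01 + s12)
    t_line = t0 + (t2 - t0) * frac
    th_line = (t2 - t0) / (d01 + s12)
    t = np.where(ok, t, t_line)
    th = np.where(ok, th, th_line)
    var = np.where(ok, var, 0.0)
    return t, th, var


def mlp_estimate(
    y0: PhaseState,
    y2: PhaseState,
    u1: float,
    moments1: ScatteringMoments,
    moments2: ScatteringMoments,
) -> PhaseState:
    """Most likely phase state at depth u1 given boundary states y0, y2.

    Exact at the endpoints (u1 -> u0 returns y0, u1 -> u2 returns y2);
    singular covariances trigger the straight-line fallback.
    """
    if not (y0.u <= u1 <= y2.u):
        raise ValueError("query depth must lie between the boundary depths")
    if u1 == y0.u:
        return y0
    if u1 == y2.u:
        return y2
    t, th, _ = _solve_mlp(
        moments1.a2, moments1.a1, moments1.a0,
        moments2.a2, moments2.a1, moments2.a0,
        u1 - y0.u, y2.u - u1,
        y0.t, y0.theta, y2.t, y2.theta,
    )
    return PhaseState(float(t), float(th), u1)


def lateral_error(
    moments1: ScatteringMoments,
    moments2: ScatteringMoments,
    u1: float,
    factor_two: bool = True,
) -> float:
    """Lateral standard error sigma_t [cm] of the MLP at depth u1.

    Square root of the (1,1) element of 2 (S1^-1 + R1^T S2^-1 R1)^-1, the
    published error matrix; ``factor_two=False`` drops the leading 2 for
    sensitivity analysis.  Independent of the boundary state values.
    """
    _, _, var = _solve_mlp(
        moments1.a2, moments1.a1, moments1.a0,
        moments2.a2, moments2.a1, moments2.a0,
        u1 - moments1.u_start, moments2.u_end - u1,
        0.0, 0.0, 0.0, 0.0,
    )
    if factor_two:
        var = 2.0 * var
    return float(np.sqrt(var))


class _MomentTable:
    """Cumulative integrals of T, eta*T, eta^2*T for O(1) segment moments.

    ``T`` may be (m,) for a shared profile or (n, m) per track.
    """

    def __init__(self, u: np.ndarray, T: np.ndarray):
        self.u = u
        self.c0 = cumulative_trapezoid(T, u, initial=0.0, axis=-1)
        self.c1 = cumulative_trapezoid(T * u, u, initial=0.0, axis=-1)
        self.c2 = cumulative_trapezoid(T * u * u, u, initial=0.0, axis=-1)

    def segment(self, i: int, j: int, target: float):
        """Moments of the segment [u_i, u_j] targeted at ``target``."""
        dc0 = self.c0[..., j] - self.c0[..., i]
        dc1 = self.c1[..., j] - self.c1[..., i]
        dc2 = self.c2[..., j] - self.c2[..., i]
        a0 = dc0
        a1 = target * dc0 - dc1
        a2 = target * target * dc0 - 2.0 * target * dc1 + dc2
        return a0, a1, a2


def mlp_profile(
    u: np.ndarray,
    T: np.ndarray,
    y0_t, y0_th, y2_t, y2_th,
    query_idx: np.ndarray,
    factor_two: bool = True,
    highland_x0: float | None = None,
) -> MLPResult:
    """Vectorized MLP and envelope over a set of query grid indices.

    ``T`` is the scattering-power profile on the physics grid ``u``,
    shared (m,) or per track (n, m); boundary states are scalars or
    (n,) arrays.  ``highland_x0`` enables the Lynch-Dahl-style logarithmic
    segment-thickness correction (used by the homogeneous water mode),
    multiplying each segment's moments by (1 + 0.038 ln(len/X0))^2.
    """
    u = np.asarray(u, dtype=float)
    T = np.asarray(T, dtype=float)
    table = _MomentTable(u, T)
    m = u.size - 1
    u0, u2 = u[0], u[-1]
    query_idx = np.asarray(query_idx, dtype=int)

    y0_t, y0_th, y2_t, y2_th = map(np.asarray, (y0_t, y0_th, y2_t, y2_th))
    lead = np.broadcast_shapes(
        T.shape[:-1], y0_t.shape, y0_th.shape, y2_t.shape, y2_th.shape
    )
    nq = query_idx.size
    t_out = np.empty(lead + (nq,))
    th_out = np.empty(lead + (nq,))
    s_out = np.empty(lead + (nq,))

    for k, q in enumerate(query_idx):
        u1 = u[q]
        if q == 0:
            t_out[..., k] = y0_t
            th_out[..., k] = y0_th
            s_out[..., k] = 0.0
            continue
        if q == m:
            t_out[..., k] = y2_t
            th_out[..., k] = y2_th
            s_out[..., k] = 0.0
            continue
        a0_1, a1_1, a2_1 = table.segment(0, q, u1)
        a0_2, a1_2, a2_2 = table.segment(q, m, u2)
        if highland_x0 is not None:
            f1 = (1.0 + c.HIGHLAND_LOG_COEFF * math.log((u1 - u0) / highland_x0)) ** 2
            f2 = (1.0 + c.HIGHLAND_LOG_COEFF * math.log((u2 - u1) / highland_x0)) ** 2
            a0_1, a1_1, a2_1 = a0_1 * f1, a1_1 * f1, a2_1 * f1
            a0_2, a1_2, a2_2 = a0_2 * f2, a1_2 * f2, a2_2 * f2
        t, th, var = _solve_mlp(
            a2_1, a1_1, a0_1, a2_2, a1_2, a0_2,
            u1 - u0, u2 - u1, y0_t, y0_th, y2_t, y2_th,
        )
        if factor_two:
            var = 2.0 * var
        t_out[..., k] = t
        th_out[..., k] = th
        s_out[..., k] = np.sqrt(var)
    return MLPResult(u=u[query_idx], t=t_out, theta=th_out, sigma_t=s_out)


def water_energy_factor_polynomial(
    beam_energy: float, length: float, degree: int = 5, du: float = 0.01
):
    """Fifth-order polynomial fit of the energy factor 1/(beta^2 p^2) vs depth.

    The factor is evaluated on the deterministic water mean-energy curve
    for the nominal beam energy (p in MeV/c) and fitted by least squares
    weighted for relative error, since the factor grows several-fold over
    a 20 cm water path.  Returns (numpy.poly1d, RMS relative residual).
    """
    curve = water_energy_curve(beam_energy, length, du)
    uu = np.linspace(0.0, length, 512)
    E = curve(uu)
    # p c = sqrt(E (E + 2 m_p c^2)); beta^2 p^2 = (p c)^4 / (E + m_p c^2)^2
    pc2 = E * (E + 2.0 * c.MP_C2)
    b2p2 = pc2 * pc2 / (E + c.MP_C2) ** 2
    y = 1.0 / b2p2
    coeffs = np.polyfit(uu, y, degree, w=1.0 / y)
    poly = np.poly1d(coeffs)
    rel = (poly(uu) - y) / y
    return poly, float(np.sqrt(np.mean(rel * rel)))


def mlp_water(
    y0: PhaseState,
    y2: PhaseState,
    u1,
    beam_energy: float,
    mode: str = "gottschalk",
    du: float = 0.1,
    factor_two: bool = True,
):
    """Homogeneous-water MLP baseline at depth(s) u1.

    ``gottschalk`` mode runs the inhomogeneous machinery with rscp = 1 on
    the deterministic water energy curve; ``lynch_dahl`` mode uses the
    Schulte-style water scattering power built from a fifth-order
    polynomial fit of the energy factor 1/(beta^2 p^2) together with the
    Highland logarithmic thickness correction.  Returns
    (PhaseState, sigma_t) for scalar u1, or an :class:`MLPResult` for an
    array of depths.
    """
    length = y2.u - y0.u
    if length < 0:
        raise ValueError("exit depth must not precede entry depth")
    if length == 0.0:
        return (y0, 0.0) if np.ndim(u1) == 0 else MLPResult(
            u=np.atleast_1d(u1), t=np.atleast_1d(y0.t),
            theta=np.atleast_1d(y0.theta), sigma_t=np.zeros(1), method="mlph2o",
        )
    grid = DepthGrid.uniform(length, du)
    if mode == "gottschalk":
        curve = water_energy_curve(beam_energy, length)
        T = water_scattering_power(curve(grid.u), clamp=False)
        x0 = None
    elif mode == "lynch_dahl":
        poly, _ = water_energy_factor_polynomial(beam_energy, length)
        T = c.E_HIGHLAND**2 * poly(grid.u) / c.X0_WATER
        x0 = c.X0_WATER
    else:
        raise ValueError(f"unknown water mode {mode!r}")

    scalar = np.ndim(u1) == 0
    u1_arr = np.atleast_1d(np.asarray(u1, dtype=float)) - y0.u
    q = np.clip(np.round(u1_arr / grid.du).astype(int), 0, grid.N)
    res = mlp_profile(
        grid.u, T, y0.t, y0.theta, y2.t, y2.theta, q,
        factor_two=factor_two, highland_x0=x0,
    )
    res.method = "mlph2o"
    res.u = res.u + y0.u
    if scalar:
        return (
            PhaseState(float(res.t[0]), float(res.theta[0]), float(res.u[0])),
            float(res.sigma_t[0]),
        )
    return res
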