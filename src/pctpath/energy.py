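"""Depth-resolved proton energy estimation and scattering-power profiles.

A proton's kinetic energy along a known material profile is estimated by a
forward Euler march from the (accelerator) entry energy, a backward Euler
march from the measured exit energy, and a depth-weighted average of the
two branches that honours both boundary conditions exactly.  The energy
profile is then converted to a depth-resolved scattering power
``T(u) = That * T_w(E(u))`` using Gottschalk's water scattering power.

All functions are vectorized over tracks: the exit energy (and hence the
backward branch and the weighted profile) may carry a leading track axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import constants as c
from .materials import WATER, _stopping_power

__all__ = [
    "DepthGrid",
    "MaterialProfile",
    "EnergyProfile",
    "RangeExceededError",
    "forward_euler",
    "backward_euler",
    "weighted_energy",
    "water_stopping_power",
    "water_scattering_power",
    "water_energy_curve",
    "scattering_power_profile",
]


class RangeExceededError(ValueError):
    """The proton's energy is exhausted before it reaches the exit face."""


@dataclass(frozen=True)
class DepthGrid:
    """Uniform depth grid u_0 < ... < u_N [cm]; the beam travels in +u."""

    u: np.ndarray

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float)
        if u.ndim != 1 or u.size < 2:
            raise ValueError("depth grid needs at least two points")
        du = np.diff(u)
        if not np.allclose(du, du[0]) or du[0] <= 0:
            raise ValueError("depth grid must be uniform and increasing")
        object.__setattr__(self, "u", u)

    @classmethod
    def uniform(cls, length: float, du: float = 0.1) -> "DepthGrid":
        n = int(round(length / du))
        return cls(np.linspace(0.0, length, n + 1))

    @property
    def du(self) -> float:
        return float(self.u[1] - self.u[0])

    @property
    def N(self) -> int:
        return self.u.size - 1

    @property
    def length(self) -> float:
        return float(self.u[-1] - self.u[0])


@dataclass
class MaterialProfile:
    """Relative stopping (rstp) and scattering (rscp) power at each grid point."""

    rstp: np.ndarray
    rscp: np.ndarray

    def __post_init__(self):
        self.rstp = np.asarray(self.rstp, dtype=float)
        self.rscp = np.asarray(self.rscp, dtype=float)
        if self.rstp.shape != self.rscp.shape:
            raise ValueError("rstp/rscp shape mismatch")
        if np.any(self.rstp < 0) or np.any(self.rscp < 0):
            raise ValueError("relative powers must be non-negative")


@dataclass
class EnergyProfile:
    """Kinetic energy [MeV] at each grid point; may carry a track axis."""

    grid: DepthGrid
    E: np.ndarray

    @property
    def tau(self) -> np.ndarray:
        """Reduced kinetic energy E / (m_p c^2)."""
        return self.E / c.MP_C2


_WATER_RHO_E = WATER.electron_density
_WATER_I = 75.0
#: evaluation floor [MeV] -- the Bethe-Bloch expression is evaluated no
#: lower than this during Euler marching
_E_FLOOR = 1.0


def water_stopping_power(E):
    """S_w(E) [MeV/cm] for liquid water, vectorized; clamped below 1 MeV."""
    E = np.maximum(np.asarray(E, dtype=float), _E_FLOOR)
    return _stopping_power(E, _WATER_RHO_E, _WATER_I)


def water_scattering_power(E, clamp: bool = True):
    """Gottschalk water scattering power T_w(E) [rad^2/cm].

    ``T_w = (E_s / pv)^2 / X_s(water)`` with E_s ~ 15.0 MeV.  Energies
    below the 3 MeV validity floor are clamped there (with a warning when
    ``clamp``); the simplification is not extrapolated further down.
    """
    E = np.asarray(E, dtype=float)
    if clamp and np.any(E < c.SCATTER_E_MIN):
        warnings.warn(
            "scattering power requested below 3 MeV; clamping at the 3 MeV value",
            stacklevel=2,
        )
    E = np.maximum(E, c.SCATTER_E_MIN)
    from .materials import scattering_length

    inv_xs = scattering_length(WATER)
    return (c.E_S / c.pv(E)) ** 2 * inv_xs


def forward_euler(
    grid: DepthGrid, profile: MaterialProfile, E_in, floor: float | None = None
) -> EnergyProfile:
    """Forward Euler energy branch from the entry face.

    ``E_j = E_{j-1} - rstp_{j-1} S_w(E_{j-1}) du`` with E_0 = E_in.  If the
    energy is exhausted before the exit face a :class:`RangeExceededError`
    is raised, unless ``floor`` is given, in which case the branch is
    clamped there and the weighted average is left to absorb the
    discrepancy against the measured exit energy.
    """
    E_in = np.asarray(E_in, dtype=float)
    rstp = profile.rstp
    lead = np.broadcast_shapes(E_in.shape, rstp.shape[:-1])
    out = np.empty(lead + (grid.N + 1,))
    out[..., 0] = E_in
    du = grid.du
    for j in range(1, grid.N + 1):
        prev = out[..., j - 1]
        nxt = prev - rstp[..., j - 1] * water_stopping_power(prev) * du
        if floor is None:
            if np.any(nxt <= 0):
                raise RangeExceededError(
                    "proton stops inside the phantom (forward branch)"
                )
        else:
            nxt = np.maximum(nxt, floor)
        out[..., j] = nxt
    return EnergyProfile(grid, out)


def backward_euler(grid: DepthGrid, profile: MaterialProfile, E_out) -> EnergyProfile:
    """Backward Euler energy branch from the (measured) exit energy.

    ``E_j = E_{j+1} + rstp_{j+1} S_w(E_{j+1}) du`` with E_N = E_out; the
    energy increases toward the entry face.
    """
    E_out = np.asarray(E_out, dtype=float)
    if np.any(E_out <= 0):
        raise ValueError("exit energy must be positive")
    rstp = profile.rstp
    lead = np.broadcast_shapes(E_out.shape, rstp.shape[:-1])
    out = np.empty(lead + (grid.N + 1,))
    out[..., -1] = E_out
    du = grid.du
    for j in range(grid.N - 1, -1, -1):
        nxt = out[..., j + 1]
        out[..., j] = nxt + rstp[..., j + 1] * water_stopping_power(nxt) * du
    return EnergyProfile(grid, out)


def weighted_energy(forward: EnergyProfile, backward: EnergyProfile) -> EnergyProfile:
    """Convex depth-weighted average of the two Euler branches.

    ``E_j = (N-j)/N E_j^F + j/N E_j^B`` so the entry condition holds
    exactly at j=0 and the exit condition at j=N; in between the branch
    with fewer accumulated steps dominates.
    """
    if forward.grid.u.shape != backward.grid.u.shape or not np.allclose(
        forward.grid.u, backward.grid.u
    ):
        raise ValueError("energy branches live on different grids")
    N = forward.grid.N
    w = np.arange(N + 1) / N
    return EnergyProfile(forward.grid, (1.0 - w) * forward.E + w * backward.E)


def water_energy_curve(E0: float, length: float, du: float = 0.01):
    """Deterministic mean-energy-vs-depth curve in pure water.

    Fine-grid Euler integration of the Bethe-Bloch loss; returns a
    callable E(u) (linear interpolation).  Raises
    :class:`RangeExceededError` if the beam cannot cross ``length`` cm.
    """
    grid = DepthGrid.uniform(length, du)
    ones = np.ones_like(grid.u)
    prof = MaterialProfile(ones, ones)
    E = forward_euler(grid, prof, float(E0)).E

    def curve(u):
        return np.interp(u, grid.u, E)

    return curve


def scattering_power_profile(
    grid: DepthGrid, profile: MaterialProfile, energy: EnergyProfile
) -> np.ndarray:
    """Depth-resolved scattering power T_j = rscp_j * T_w(E_j) [rad^2/cm]."""
    if energy.E.shape[-1] != grid.N + 1:
        raise ValueError("energy profile does not match the grid")
    return profile.rscp * water_scattering_power(energy.E, clamp=False)
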