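"""Gaussian multiple-Coulomb-scattering proton track simulator.

A desk-scale, Fermi-Eyges-consistent stand-in for a full Monte Carlo
engine: per depth step the projected angle receives an independent
Gaussian kick with variance T(u) du, where T is the local material's
scattering power at the proton's current energy, and the lateral position
receives the correlated within-step displacement, so that the discrete
process reproduces the Fermi-Eyges moments exactly for piecewise-constant
T.  Energy loss is deterministic Bethe-Bloch, optionally with Gaussian
(Bohr-like) straggling, and an optional heavy-tail step contamination
gives the statistical data cuts a non-Gaussian population to remove.
Nuclear interactions and large-angle single scattering are deliberately
out of scope.

Coordinates: u is depth from the entry face [cm]; t and v are the lateral
axes; angles are projections onto the t-u and v-u planes [rad].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .energy import water_scattering_power, water_stopping_power
from .phantoms import SlabPhantom, VoxelPhantom

__all__ = [
    "Beam",
    "CutSpec",
    "TrackSet",
    "simulate_tracks",
    "project_to_face",
    "apply_cuts",
    "InvalidGeometryError",
]

#: Bohr-like energy-straggling variance rate in water [MeV^2/cm]
_BOHR_VAR_WATER = 0.0871


class InvalidGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class Beam:
    """Monoenergetic beam: energy [MeV], track count and geometry.

    ``parallel`` launches tracks parallel to the u axis spread uniformly
    over ``span`` cm; ``fan`` launches them from a point source
    ``source_distance`` cm upstream, spanning the exit face.
    """

    energy: float
    n_tracks: int
    geometry: str = "parallel"
    source_distance: float = 160.0
    span: float = 4.0


@dataclass(frozen=True)
class CutSpec:
    """Statistical data cuts: k-sigma on relative exit angles and energy loss."""

    k_sigma: float = 2.0

    def __post_init__(self):
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")


@dataclass
class TrackSet:
    """Columnar set of simulated proton tracks.

    Entry/exit states are face-projected phase states; ``true_t`` and
    ``true_v`` are the actual lateral positions at the query depths.
    Stopped tracks (range exceeded) are flagged and carry NaN exits.
    """

    query_u: np.ndarray  # (q,)
    t_in: np.ndarray
    v_in: np.ndarray
    th_t_in: np.ndarray
    th_v_in: np.ndarray
    E_in: np.ndarray
    t_out: np.ndarray
    v_out: np.ndarray
    th_t_out: np.ndarray
    th_v_out: np.ndarray
    E_out: np.ndarray
    true_t: np.ndarray  # (n, q)
    true_v: np.ndarray
    stopped: np.ndarray
    ids: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.ids is None:
            self.ids = np.arange(self.t_in.size)

    @property
    def n(self) -> int:
        return self.t_in.size

    def select(self, mask) -> "TrackSet":
        return TrackSet(
            query_u=self.query_u,
            **{
                k: getattr(self, k)[mask]
                for k in (
                    "t_in", "v_in", "th_t_in", "th_v_in", "E_in",
                    "t_out", "v_out", "th_t_out", "th_v_out", "E_out",
                    "true_t", "true_v", "stopped", "ids",
                )
            },
        )

    def summary_frame(self) -> pd.DataFrame:
        """One row per track: boundary states and energies."""
        return pd.DataFrame(
            {
                "id": self.ids,
                "t_in": self.t_in, "v_in": self.v_in,
                "th_t_in": self.th_t_in, "th_v_in": self.th_v_in,
                "E_in": self.E_in,
                "t_out": self.t_out, "v_out": self.v_out,
                "th_t_out": self.th_t_out, "th_v_out": self.th_v_out,
                "E_out": self.E_out,
                "stopped": self.stopped,
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per track per query depth."""
        n, q = self.true_t.shape
        return pd.DataFrame(
            {
                "id": np.repeat(self.ids, q),
                "u": np.tile(self.query_u, n),
                "t": self.true_t.ravel(),
                "v": self.true_v.ravel(),
            }
        )


def _initial_states(beam: Beam, length: float, rng) -> tuple[np.ndarray, ...]:
    n = beam.n_tracks
    if beam.geometry == "parallel":
        t = rng.uniform(-beam.span / 2, beam.span / 2, n)
        v = rng.uniform(-beam.span / 2, beam.span / 2, n)
        return t, v, np.zeros(n), np.zeros(n)
    if beam.geometry == "fan":
        # point source on the axis; directions span the exit face in t
        x_exit = rng.uniform(-beam.span / 2, beam.span / 2, n)
        th_t = np.arctan(x_exit / (beam.source_distance + length))
        t = np.tan(th_t) * beam.source_distance
        v = rng.uniform(-beam.span / 2, beam.span / 2, n)
        return t, v, th_t, np.zeros(n)
    raise ValueError(f"unknown beam geometry {beam.geometry!r}")


def simulate_tracks(
    phantom,
    beam: Beam,
    seed: int,
    du: float = 0.1,
    query_du: float = 0.5,
    straggling: bool = False,
    tail_fraction: float = 0.0,
    tail_scale: float = 9.0,
    E_min: float = 1.0,
) -> TrackSet:
    """Simulate proton tracks through a slab or voxel phantom.

    Per internal step ``du`` the projected angles receive independent
    Gaussian kicks of variance T(u) du (plus the correlated within-step
    lateral term); ``tail_fraction`` of steps are drawn with their kick
    variance inflated by ``tail_scale``.  Energy loss is deterministic
    Bethe-Bloch via the local relative stopping power, with optional
    Gaussian straggling.  Tracks whose energy falls below ``E_min`` are
    marked stopped.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    length = phantom.length
    m = int(round(length / du))
    ratio = query_du / du
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("query_du must be a multiple of du")
    stride = int(round(ratio))
    query_u = np.arange(0, m + 1, stride) * du

    n = beam.n_tracks
    t, v, th_t, th_v = _initial_states(beam, length, rng)
    th_t0, th_v0 = th_t.copy(), th_v.copy()
    E = np.full(n, float(beam.energy))
    if np.any(E <= E_min):
        raise ValueError("beam energy must exceed the stopping threshold")
    alive = np.ones(n, dtype=bool)

    true_t = np.empty((n, query_u.size))
    true_v = np.empty((n, query_u.size))
    true_t[:, 0] = t
    true_v[:, 0] = v

    is_voxel = isinstance(phantom, VoxelPhantom)
    sqrt12 = np.sqrt(12.0)
    for j in range(m):
        u_mid = (j + 0.5) * du
        if is_voxel:
            rstp, rscp = phantom.lookup(np.full(n, u_mid), t, v)
        else:
            idx = phantom.slab_index(u_mid)
            rstp = phantom.rstp[idx]
            rscp = phantom.rscp[idx]

        T = rscp * water_scattering_power(np.maximum(E, 3.0), clamp=False)
        T = np.where(alive, T, 0.0)
        scale = np.ones(n)
        if tail_fraction > 0:
            scale = np.where(
                rng.random(n) < tail_fraction, np.sqrt(tail_scale), 1.0
            )
            scale_v = np.where(
                rng.random(n) < tail_fraction, np.sqrt(tail_scale), 1.0
            )
        else:
            scale_v = scale

        sd_th = np.sqrt(T * du)
        a_t = scale * sd_th * rng.standard_normal(n)
        a_v = scale_v * sd_th * rng.standard_normal(n)
        # correlated within-step lateral displacement
        res_sd = np.sqrt(T * du) * du / sqrt12
        b_t = 0.5 * du * a_t + scale * res_sd * rng.standard_normal(n)
        b_v = 0.5 * du * a_v + scale_v * res_sd * rng.standard_normal(n)
        t = t + np.where(alive, th_t * du + b_t, 0.0)
        v = v + np.where(alive, th_v * du + b_v, 0.0)
        th_t = th_t + a_t
        th_v = th_v + a_v

        dE = rstp * water_stopping_power(E) * du
        if straggling:
            dE = dE + np.sqrt(_BOHR_VAR_WATER * rstp * du) * rng.standard_normal(n)
        E = np.where(alive, E - dE, E)
        newly_stopped = alive & (E <= E_min)
        if np.any(newly_stopped):
            E = np.where(newly_stopped, E_min, E)
            alive = alive & ~newly_stopped

        k = j + 1
        if k % stride == 0:
            true_t[:, k // stride] = t
            true_v[:, k // stride] = v

    stopped = ~alive
    if np.any(stopped):
        warnings.warn(
            f"{int(stopped.sum())} of {n} tracks stopped inside the phantom",
            stacklevel=2,
        )

    def _mask(x):
        return np.where(stopped, np.nan, x)

    return TrackSet(
        query_u=query_u,
        t_in=true_t[:, 0].copy(), v_in=true_v[:, 0].copy(),
        th_t_in=th_t0, th_v_in=th_v0,
        E_in=np.full(n, float(beam.energy)),
        t_out=_mask(t), v_out=_mask(v),
        th_t_out=_mask(th_t), th_v_out=_mask(th_v),
        E_out=_mask(E),
        true_t=true_t, true_v=true_v,
        stopped=stopped,
    )


def project_to_face(t, theta, distance):
    """Straight-line propagation of a lateral coordinate over ``distance``.

    Used to move detector-plane measurements onto the phantom faces; the
    angle is unchanged (negligible scatter in the air gap).
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(np.abs(theta) >= np.pi / 2):
        raise InvalidGeometryError("direction parallel to the face")
    out = np.asarray(t, dtype=float) + np.tan(theta) * distance
    return float(out) if out.ndim == 0 else out


def apply_cuts(tracks: TrackSet, cuts: CutSpec) -> tuple[TrackSet, dict]:
    """Remove tracks with anomalous exit angle or energy loss.

    A track is removed if its relative exit angle (t-u or v-u projection)
    or its total energy loss deviates from the sample mean by more than
    ``k_sigma`` standard deviations; stopped tracks are always removed.
    Returns the retained tracks and a per-criterion removal report.
    """
    ok = ~tracks.stopped
    if int(ok.sum()) < 10:
        raise ValueError("need at least 10 surviving tracks for the cuts")
    criteria = {
        "exit_angle_t": tracks.th_t_out - tracks.th_t_in,
        "exit_angle_v": tracks.th_v_out - tracks.th_v_in,
        "energy_loss": tracks.E_in - tracks.E_out,
    }
    keep = ok.copy()
    report = {"n_input": tracks.n, "n_stopped": int(tracks.stopped.sum())}
    for name, x in criteria.items():
        mu = np.nanmean(x[ok])
        sd = np.nanstd(x[ok])
        if sd == 0:
            warnings.warn(f"degenerate spread for {name}; criterion skipped")
            report[f"removed_{name}"] = 0
            continue
        bad = ok & (np.abs(x - mu) > cuts.k_sigma * sd)
        report[f"removed_{name}"] = int(bad.sum())
        keep &= ~bad
    report["n_retained"] = int(keep.sum())
    return tracks.select(keep), report
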