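"""Phantom geometries: transverse slab stacks and voxelized RStP grids.

A slab phantom is an ordered stack of materials transverse to the beam
axis u; a voxel phantom is a 3-D grid of relative stopping power with a
companion relative-scattering-power grid derived through the RStP-RScP
calibration curve.  Depths are measured from the entry face (u = 0, cm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import DepthGrid, MaterialProfile
from .materials import (
    CalibrationCurve,
    Material,
    TissueCatalogue,
    nominated_rstp,
    relative_scattering_power,
)

__all__ = [
    "SlabPhantom",
    "VoxelPhantom",
    "water_phantom",
    "bone_slab_phantom",
    "synthetic_head_phantom",
]

#: relative powers assigned to air gaps / exterior
AIR_RSTP = 0.00108
AIR_RSCP = 0.00121


@dataclass
class SlabPhantom:
    """Ordered stack of (rstp, rscp, thickness) slabs along the beam axis."""

    rstp: np.ndarray
    rscp: np.ndarray
    thickness: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.rstp = np.asarray(self.rstp, dtype=float)
        self.rscp = np.asarray(self.rscp, dtype=float)
        self.thickness = np.asarray(self.thickness, dtype=float)
        if np.any(self.thickness <= 0):
            raise ValueError("slab thicknesses must be positive")
        self.boundaries = np.cumsum(self.thickness)

    @classmethod
    def from_materials(
        cls, slabs: list[tuple[Material, float]]
    ) -> "SlabPhantom":
        return cls(
            rstp=[nominated_rstp(m) for m, _ in slabs],
            rscp=[relative_scattering_power(m) for m, _ in slabs],
            thickness=[th for _, th in slabs],
            names=[m.name for m, _ in slabs],
        )

    @property
    def length(self) -> float:
        return float(self.boundaries[-1])

    def slab_index(self, u) -> np.ndarray:
        """Slab index at depth u; a boundary belongs to the downstream slab."""
        idx = np.searchsorted(self.boundaries, np.asarray(u, dtype=float), side="right")
        return np.clip(idx, 0, self.rstp.size - 1)

    def profile(self, grid: DepthGrid) -> MaterialProfile:
        """Staircase relative-power profile sampled on a depth grid."""
        idx = self.slab_index(grid.u)
        return MaterialProfile(self.rstp[idx], self.rscp[idx])

    def material_boundaries(self) -> np.ndarray:
        """Interior depths at which the material changes."""
        keep = np.diff(self.rstp) != 0
        return self.boundaries[:-1][keep]


@dataclass
class VoxelPhantom:
    """3-D grid of relative stopping power with derived scattering power.

    ``rstp_grid`` is indexed (u, t, v) with uniform ``pitch`` [cm];
    ``origin_t``/``origin_v`` locate the lateral grid edges.  Points
    outside the grid are treated as air.  The companion rscp grid is
    obtained through the calibration curve, mimicking how both powers are
    approximated from a reconstructed image.
    """

    rstp_grid: np.ndarray
    pitch: float
    curve: CalibrationCurve
    origin_t: float = 0.0
    origin_v: float = 0.0

    def __post_init__(self):
        self.rstp_grid = np.asarray(self.rstp_grid, dtype=float)
        if self.rstp_grid.ndim != 3:
            raise ValueError("voxel grid must be 3-D (u, t, v)")
        if not np.all(np.isfinite(self.rstp_grid)) or np.any(self.rstp_grid <= 0):
            raise ValueError("voxel RStP values must be finite and positive")
        self.rscp_grid = self.curve.rscp_from_rstp(self.rstp_grid)

    @property
    def length(self) -> float:
        return self.rstp_grid.shape[0] * self.pitch

    def _indices(self, u, t, v):
        iu = np.clip(
            (np.asarray(u) / self.pitch).astype(int), 0, self.rstp_grid.shape[0] - 1
        )
        it = ((np.asarray(t) - self.origin_t) / self.pitch).astype(int)
        inside = (it >= 0) & (it < self.rstp_grid.shape[1])
        if self.rstp_grid.shape[2] == 1:
            # extruded 2-D phantom: v is a free axis
            iv = np.zeros_like(it)
        else:
            iv = ((np.asarray(v) - self.origin_v) / self.pitch).astype(int)
            inside = inside & (iv >= 0) & (iv < self.rstp_grid.shape[2])
        return iu, np.clip(it, 0, self.rstp_grid.shape[1] - 1), np.clip(
            iv, 0, self.rstp_grid.shape[2] - 1
        ), inside

    def lookup(self, u, t, v):
        """(rstp, rscp) at physical coordinates; air outside the grid."""
        iu, it, iv, inside = self._indices(u, t, v)
        rstp = np.where(inside, self.rstp_grid[iu, it, iv], AIR_RSTP)
        rscp = np.where(inside, self.rscp_grid[iu, it, iv], AIR_RSCP)
        return rstp, rscp

    def hull_bounds(self, threshold: float = 0.3) -> tuple[float, float]:
        """Axis-aligned bounding-box hull along the beam axis.

        Returns the (entry, exit) depths of the smallest u-slab interval
        containing every voxel with rstp above ``threshold``; a trivial
        stand-in for dedicated hull-detection algorithms.
        """
        body = np.any(self.rstp_grid > threshold, axis=(1, 2))
        if not body.any():
            return 0.0, self.length
        iu = np.nonzero(body)[0]
        return iu[0] * self.pitch, (iu[-1] + 1) * self.pitch


def water_phantom(length: float = 20.0) -> SlabPhantom:
    """Homogeneous water cube of the given depth [cm]."""
    return SlabPhantom([1.0], [1.0], [length], names=["water"])


def bone_slab_phantom(cat: TissueCatalogue) -> SlabPhantom:
    """20 cm water/cranium/cortical-bone slab stack.

    2 cm water, 7 cm cranium, 2 cm cortical bone, 7 cm cranium, 2 cm
    water, with relative powers computed from the bundled catalogue.
    """
    order = [
        ("water", 2.0),
        ("skeleton_cranium", 7.0),
        ("skeleton_cortical_bone", 2.0),
        ("skeleton_cranium", 7.0),
        ("water", 2.0),
    ]
    return SlabPhantom(
        rstp=[cat[n].rstp for n, _ in order],
        rscp=[cat[n].rscp for n, _ in order],
        thickness=[th for _, th in order],
        names=[n for n, _ in order],
    )


def synthetic_head_phantom(
    cat: TissueCatalogue,
    curve: CalibrationCurve,
    pitch: float = 0.1,
    length: float = 14.3,
    half_width: float = 8.0,
    seed: int = 1905,
) -> VoxelPhantom:
    """Synthetic voxelized head-like phantom (not a scanned dataset).

    An elliptical soft-tissue cross-section wrapped in a cranium-like bone
    annulus, with sinus-like air cavities and thin interior bone septa,
    extruded along v.  Serves as a programmatically generated stand-in for
    a DICOM head phantom in the voxel-geometry code paths; the interior
    structure gives depth profiles a boundary density comparable to a real
    head (roughly one material change per centimetre).
    """
    rng = np.random.default_rng(seed)
    nu = int(round(length / pitch))
    nt = int(round(2 * half_width / pitch))
    uu = (np.arange(nu) + 0.5) * pitch
    tt = (np.arange(nt) + 0.5) * pitch - half_width

    cu, a = length / 2.0, length / 2.0 - 0.2
    b = half_width - 1.8
    U, T = np.meshgrid(uu, tt, indexing="ij")
    r = ((U - cu) / a) ** 2 + (T / b) ** 2

    brain = cat["brain_grey_matter"].rstp
    bone = cat["skeleton_cranium"].rstp
    grid = np.full((nu, nt), AIR_RSTP)
    grid[r < 1.0] = bone
    grid[r < 0.82] = brain
    # sinus-like air cavities scattered through the interior
    for _ in range(6):
        cu_c = rng.uniform(0.2, 0.8) * length
        ct_c = rng.uniform(-0.6, 0.6) * b
        rad = rng.uniform(0.3, 0.8)
        mask = ((U - cu_c) ** 2 + (T - ct_c) ** 2 < rad**2) & (r < 0.82)
        grid[mask] = AIR_RSTP
    # thin bone septa (skull-base/facial-bone-like lamellae)
    for _ in range(4):
        cu_c = rng.uniform(0.2, 0.8) * length
        ct_c = rng.uniform(-0.7, 0.7) * b
        half_len = rng.uniform(1.0, 2.5)
        mask = (
            (np.abs(U - cu_c) < 0.15)
            & (np.abs(T - ct_c) < half_len)
            & (r < 0.82)
        )
        grid[mask] = bone
    return VoxelPhantom(
        rstp_grid=grid[:, :, None], pitch=pitch, curve=curve, origin_t=-half_width,
        origin_v=-half_width * 0,
    )
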