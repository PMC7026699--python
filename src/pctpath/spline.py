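"""MLP-Spline-Hybrid (MLPxSH): subsampled MLP plus cubic-spline paths.

The full Bayesian MLP is evaluated only at depths where the material
changes (plus entry and exit), and the complete trajectory is recovered
by a clamped cubic spline through those points using the measured entry
and exit directions as end slopes.  The probability envelope is rebuilt
from separate (natural) cubic splines through t_MLP +/- k sigma_t at the
sample depths; only the centre path has measured end directions, so the
envelope splines use natural end conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["SubsampleSet", "boundary_subsample", "spline_mlp"]

#: default RStP region edges: air < 0.3 <= tissue <= 1.1 < bone
DEFAULT_REGION_EDGES = (0.3, 1.1)
#: additionally flag any step in RStP larger than this, so that distinct
#: bone-like materials (e.g. cranium vs cortical bone) are still separated
DEFAULT_DIFF_THRESHOLD = 0.15


@dataclass
class SubsampleSet:
    """Ordered depths at which the full MLP is evaluated, with reasons."""

    depths: np.ndarray
    reasons: list[str]

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.size < 2 or np.any(np.diff(self.depths) <= 0):
            raise ValueError("subsample depths must be strictly increasing")

    @property
    def fraction(self) -> float:
        """Fraction of available calculation depths that were selected."""
        return getattr(self, "_fraction", np.nan)


def boundary_subsample(
    query_u,
    rstp_along_path,
    region_edges=DEFAULT_REGION_EDGES,
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
) -> SubsampleSet:
    """Select MLP calculation depths at material boundaries.

    A depth is selected when consecutive RStP values fall in different
    thresholded regions (air/tissue/bone) or differ by more than
    ``diff_threshold`` (catching boundaries between materials within one
    region); entry and exit are always included.
    """
    u = np.asarray(query_u, dtype=float)
    s = np.asarray(rstp_along_path, dtype=float)
    if u.size == 0 or s.size != u.size:
        raise ValueError("empty or mismatched RStP profile")
    region = np.digitize(s, region_edges)
    change = (np.diff(region) != 0) | (np.abs(np.diff(s)) > diff_threshold)
    idx = np.nonzero(change)[0] + 1  # downstream point of each change
    depths = [u[0]]
    reasons = ["entry"]
    for i in idx:
        if u[i] not in (u[0], u[-1]):
            depths.append(u[i])
            reasons.append("material_boundary")
    depths.append(u[-1])
    reasons.append("exit")
    out = SubsampleSet(np.array(depths), reasons)
    out._fraction = len(depths) / u.size
    return out


def spline_mlp(
    sample_u,
    t_samples,
    entry_dir,
    exit_dir,
    query_u,
    sigma_samples=None,
    k: float = 3.0,
):
    """Cubic-spline path (and envelope) through subsampled MLP points.

    ``t_samples`` has shape (ns,) or (ns, n tracks); ``entry_dir`` and
    ``exit_dir`` are the measured projected directions [rad], applied as
    clamped end slopes (small-angle: the angles themselves).  When
    ``sigma_samples`` is given, lower/upper envelope curves are built as
    natural splines through t -/+ k sigma and returned alongside.

    Returns ``t_query`` or ``(t_query, lower, upper)`` with the query axis
    leading any track axis.
    """
    sample_u = np.asarray(sample_u, dtype=float)
    if np.any(np.diff(sample_u) <= 0):
        raise ValueError("sample depths must be strictly increasing")
    t_samples = np.asarray(t_samples, dtype=float)
    if sample_u.size < 2:
        raise ValueError("need at least two sample points")
    centre = CubicSpline(
        sample_u,
        t_samples,
        axis=0,
        bc_type=((1, np.asarray(entry_dir, dtype=float)),
                 (1, np.asarray(exit_dir, dtype=float))),
    )
    tq = centre(query_u)
    if sigma_samples is None:
        return tq
    sigma_samples = np.asarray(sigma_samples, dtype=float)
    lo = CubicSpline(sample_u, t_samples - k * sigma_samples, axis=0,
                     bc_type="natural")(query_u)
    hi = CubicSpline(sample_u, t_samples + k * sigma_samples, axis=0,
                     bc_type="natural")(query_u)
    return tq, lo, hi
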