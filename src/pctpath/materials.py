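"""Material physics for proton CT path estimation.

Implements Gottschalk's scattering length and the derived *relative
scattering power* (RScP, ``that``), the Bethe-Bloch stopping power and the
derived *relative stopping power* (RStP, ``shat``), the Bragg additivity
rule for mean excitation energies, and the two-segment linear calibration
between RScP and RStP over a bundled human-tissue catalogue.

Relative powers are defined against liquid water at the same proton
energy; RScP is exactly energy independent in Gottschalk's simplified
formulation, while RStP is only weakly energy dependent and is nominated
as the 10-300 MeV average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .constants import K_BETHE, ME_C2, N_AVOGADRO, ALPHA, R_E, beta_sq

__all__ = [
    "Element",
    "Material",
    "TissueCatalogue",
    "CalibrationCurve",
    "ELEMENTS",
    "WATER",
    "element_scatter_term",
    "relative_scattering_power",
    "scattering_length",
    "bethe_bloch",
    "mean_excitation_bragg",
    "nominated_rstp",
    "fit_calibration",
    "rscp_from_rstp",
    "load_catalogue",
]


@dataclass(frozen=True)
class Element:
    """A chemical element: symbol, atomic number Z, mass number A [u]."""

    symbol: str
    Z: int
    A: float

    def __post_init__(self):
        if self.Z < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.Z}")
        if self.A <= 0:
            raise ValueError(f"mass number must be > 0, got {self.A}")


# Z, A and the mean excitation energy [eV] of the element *as a constituent
# of a compound* (ICRU-37/49 Bragg-additivity values).
_ELEMENT_TABLE = {
    "H": (1, 1.008, 19.2),
    "C": (6, 12.011, 81.0),
    "N": (7, 14.007, 82.0),
    "O": (8, 15.999, 106.0),
    "F": (9, 18.998, 112.0),
    "Na": (11, 22.990, 168.4),
    "Mg": (12, 24.305, 176.3),
    "Al": (13, 26.982, 166.0),
    "Si": (14, 28.085, 195.5),
    "P": (15, 30.974, 195.5),
    "S": (16, 32.06, 203.4),
    "Cl": (17, 35.45, 180.0),
    "K": (19, 39.098, 214.7),
    "Ca": (20, 40.078, 215.8),
    "Fe": (26, 55.845, 323.2),
    "I": (53, 126.904, 554.8),
}

ELEMENTS: dict[str, Element] = {
    sym: Element(sym, Z, A) for sym, (Z, A, _) in _ELEMENT_TABLE.items()
}

#: constituent mean excitation energies [eV]
ELEMENT_I: dict[str, float] = {sym: I for sym, (_, _, I) in _ELEMENT_TABLE.items()}


def element_scatter_term(Z: float, A: float) -> float:
    """Per-gram elemental summand of Gottschalk's scattering length.

    Returns ``(Z^2/A) * [2 ln(33219 (A Z)^(-1/3)) - 1]``, the quantity that,
    mass-weighted over a compound's constituents, fixes both the scattering
    length and the relative scattering power.  Strictly positive for all
    physical (Z, A).
    """
    if Z < 1 or A <= 0:
        raise ValueError(f"need Z >= 1 and A > 0, got Z={Z}, A={A}")
    return (Z * Z / A) * (2.0 * math.log(33219.0 * (A * Z) ** (-1.0 / 3.0)) - 1.0)


@dataclass
class Material:
    """A (possibly composite) material.

    Parameters
    ----------
    name : str
    composition : list of (Element, mass fraction) pairs.  Fractions are
        renormalized to unit sum on construction (tolerance 1e-2).
    density : mass density [g/cm^3]
    mean_excitation : I [eV]; if omitted it is derived with the Bragg
        additivity rule from the constituent values.
    """

    name: str
    composition: list[tuple[Element, float]]
    density: float
    mean_excitation: float | None = None
    group: str = "solid"
    fit_groups: tuple[str, ...] = ("solid",)
    anchor: bool = False

    def __post_init__(self):
        if not self.composition:
            raise ValueError(f"{self.name}: empty composition")
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        total = sum(w for _, w in self.composition)
        if not (0.99 <= total <= 1.01):
            raise ValueError(
                f"{self.name}: mass fractions sum to {total:.4f}, expected 1"
            )
        self.composition = [(el, w / total) for el, w in self.composition]
        for el, w in self.composition:
            if not (0.0 < w <= 1.0):
                raise ValueError(f"{self.name}: bad mass fraction {w} for {el.symbol}")

    @classmethod
    def from_mass_fractions(
        cls,
        name: str,
        fractions: dict[str, float],
        density: float,
        mean_excitation: float | None = None,
        **kw,
    ) -> "Material":
        comp = [(ELEMENTS[sym], w) for sym, w in fractions.items()]
        return cls(name, comp, density, mean_excitation, **kw)

    @property
    def z_over_a(self) -> float:
        """Mass-weighted mean Z/A [mol/g]."""
        return sum(w * el.Z / el.A for el, w in self.composition)

    @property
    def electron_density(self) -> float:
        """Electron number density [cm^-3]."""
        return self.density * N_AVOGADRO * self.z_over_a

    @property
    def I_eV(self) -> float:
        """Mean excitation energy [eV]; Bragg rule if not given explicitly."""
        if self.mean_excitation is not None:
            return self.mean_excitation
        return mean_excitation_bragg(self)

    def scatter_sum(self) -> float:
        """Mass-weighted sum of elemental scattering summands [per gram]."""
        return sum(w * element_scatter_term(el.Z, el.A) for el, w in self.composition)


#: liquid water reference (H 0.1119 / O 0.8881 by mass, I = 75 eV)
WATER = Material.from_mass_fractions(
    "water", {"H": 0.1119, "O": 0.8881}, 1.0, mean_excitation=75.0
)

#: exact reciprocal of the water scattering summation (prints as 0.01636)
WATER_SUM = WATER.scatter_sum()


def relative_scattering_power(m: Material) -> float:
    """Relative scattering power T-hat (dimensionless, water = 1).

    ``that = rho * sum_k w_k f(Z_k, A_k) / (water sum)``.  The water
    normalisation is carried at full precision; its reciprocal prints as
    the familiar constant 0.01636.
    """
    return m.density * m.scatter_sum() / WATER_SUM


def scattering_length(m: Material) -> float:
    """Inverse scattering length 1/X_s [cm^-1] (Gottschalk).

    Additive over constituents; water gives X_s ~ 46.9 cm.
    """
    return ALPHA * N_AVOGADRO * R_E**2 * m.density * m.scatter_sum()


def mean_excitation_bragg(
    m: Material, element_I: dict[str, float] | list[float] | None = None
) -> float:
    """Mean excitation energy [eV] of a compound via the Bragg additivity rule.

    ``ln I = sum_k w_k (Z_k/A_k) ln I_k / sum_k w_k (Z_k/A_k)``.
    ``element_I`` may override the bundled constituent values, either as a
    mapping by symbol or as a list aligned with the composition.
    """
    if element_I is None:
        i_vals = [ELEMENT_I[el.symbol] for el, _ in m.composition]
    elif isinstance(element_I, dict):
        i_vals = [element_I[el.symbol] for el, _ in m.composition]
    else:
        if len(element_I) != len(m.composition):
            raise ValueError(
                f"{m.name}: {len(element_I)} I values for "
                f"{len(m.composition)} constituents"
            )
        i_vals = list(element_I)
    num = sum(
        w * el.Z / el.A * math.log(I) for (el, w), I in zip(m.composition, i_vals)
    )
    den = m.z_over_a
    return math.exp(num / den)


def _stopping_power(E, electron_density: float, I_eV: float):
    """Bethe-Bloch stopping power [MeV/cm], no shell/density corrections.

    Vectorized over E [MeV]; no validity-window check (internal use).
    """
    E = np.asarray(E, dtype=float)
    b2 = beta_sq(E)
    # 2 m_e c^2 beta^2 / (I (1 - beta^2)), with I converted to MeV
    arg = 2.0 * ME_C2 * b2 / ((I_eV * 1e-6) * (1.0 - b2))
    return K_BETHE * electron_density / b2 * (np.log(arg) - b2)


def bethe_bloch(m: Material, E) -> float | np.ndarray:
    """Stopping power S(E) [MeV/cm] of protons of kinetic energy E [MeV].

    Valid over 1-300 MeV; outside that window an out-of-range error is
    raised.  Relativistic beta^2 is computed from E and the proton rest
    energy; shell and density corrections are not applied.
    """
    E_arr = np.asarray(E, dtype=float)
    if np.any(E_arr < 1.0) or np.any(E_arr > 300.0):
        raise ValueError(f"{m.name}: energy outside the 1-300 MeV validity window")
    out = _stopping_power(E_arr, m.electron_density, m.I_eV)
    return float(out) if np.isscalar(E) or np.ndim(E) == 0 else out


_NOMINATE_GRID = np.arange(10.0, 301.0, 1.0)


def rstp_curve(m: Material, E=None) -> np.ndarray:
    """Energy-dependent relative stopping power S_m(E)/S_w(E)."""
    if E is None:
        E = _NOMINATE_GRID
    return np.asarray(bethe_bloch(m, E)) / np.asarray(bethe_bloch(WATER, E))


def nominated_rstp(m: Material) -> float:
    """Nominated RStP S-hat: mean of S_m(E)/S_w(E) over E = 10..300 MeV (1 MeV steps)."""
    if m is WATER or m.name == "water":
        return 1.0
    return float(np.mean(rstp_curve(m)))


@dataclass
class CatalogueEntry:
    material: Material
    rstp: float
    rscp: float


class TissueCatalogue:
    """Named collection of materials with precomputed RStP/RScP scalars."""

    def __init__(self, materials: list[Material]):
        self.entries: dict[str, CatalogueEntry] = {}
        for m in materials:
            self.entries[m.name] = CatalogueEntry(
                material=m,
                rstp=nominated_rstp(m),
                rscp=relative_scattering_power(m),
            )
        for name, e in self.entries.items():
            if e.rstp <= 0 or e.rscp <= 0:
                raise ValueError(f"{name}: non-positive relative power")

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> CatalogueEntry:
        return self.entries[name]

    def __len__(self) -> int:
        return len(self.entries)

    def material(self, name: str) -> Material:
        return self.entries[name].material

    def names(self) -> list[str]:
        return list(self.entries)

    def group_points(self, group: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(rscp, rstp, names) of the entries belonging to a fit group."""
        names = [
            n for n, e in self.entries.items() if group in e.material.fit_groups
        ]
        t = np.array([self.entries[n].rscp for n in names])
        s = np.array([self.entries[n].rstp for n in names])
        return t, s, names

    def to_frame(self) -> pd.DataFrame:
        """Computed catalogue as a table: name, group, density, rstp, rscp."""
        rows = [
            {
                "name": n,
                "group": e.material.group,
                "density": e.material.density,
                "I_eV": e.material.I_eV,
                "rstp": e.rstp,
                "rscp": e.rscp,
            }
            for n, e in self.entries.items()
        ]
        return pd.DataFrame(rows)

    def write_table(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_catalogue(path=None) -> TissueCatalogue:
    """Load the bundled human-tissue catalogue (46 tissues + air + water).

    ``path`` may point to an alternative YAML constants file with records
    ``{name, group, fit_groups, density, I (optional), composition}``.
    """
    if path is None:
        text = (
            resources.files("pctpath.data").joinpath("tissues.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    mats = []
    for rec in raw["materials"]:
        mats.append(
            Material.from_mass_fractions(
                rec["name"],
                rec["composition"],
                rec["density"],
                mean_excitation=rec.get("I"),
                group=rec.get("group", "solid"),
                fit_groups=tuple(rec.get("fit_groups", [rec.get("group", "solid")])),
                anchor=rec.get("anchor", False),
            )
        )
    cat = TissueCatalogue(mats)
    if "water" not in cat or "air" not in cat:
        raise ValueError("catalogue must contain water and air")
    return cat


@dataclass
class CalibrationCurve:
    """Two-segment linear map S-hat = p1 * T-hat + p2 between relative powers.

    The low-density segment is constrained through the origin (p2_low = 0).
    ``intersection`` is the (T-hat*, S-hat*) crossing of the two fitted
    lines, anchored in practice near the lowest-RStP adipose tissue.
    """

    p1_solid: float
    p2_solid: float
    r2_solid: float
    n_solid: int
    p1_low: float
    r2_low: float
    n_low: int
    p2_low: float = 0.0
    intersection: tuple[float, float] = (0.0, 0.0)
    anchor_point: tuple[float, float] | None = None

    def rstp_from_rscp(self, that):
        """Forward map T-hat -> S-hat (piecewise linear, continuous)."""
        that = np.asarray(that, dtype=float)
        t_star = self.intersection[0]
        low = self.p1_low * that
        solid = self.p1_solid * that + self.p2_solid
        out = np.where(that < t_star, low, solid)
        return float(out) if out.ndim == 0 else out

    def rscp_from_rstp(self, shat):
        """Inverse map S-hat -> T-hat (piecewise linear, continuous)."""
        return rscp_from_rstp(self, shat)


def _r_squared(y, yhat) -> float:
    y = np.asarray(y)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_calibration(cat: TissueCatalogue) -> CalibrationCurve:
    """Fit the two-segment RScP-RStP calibration over a tissue catalogue.

    Solid tissues: ordinary least squares S-hat = p1 T-hat + p2.
    Low-density materials (lung/air group): least squares through the
    origin.  Returns slopes, intercept, per-segment r^2 and the line
    intersection.
    """
    t_s, s_s, _ = cat.group_points("solid")
    t_l, s_l, _ = cat.group_points("low_density")
    if len(t_s) < 2 or len(t_l) < 2:
        raise ValueError("need at least two points per calibration segment")

    p1_s, p2_s = np.polyfit(t_s, s_s, 1)
    r2_s = _r_squared(s_s, p1_s * t_s + p2_s)

    p1_l = float(np.sum(t_l * s_l) / np.sum(t_l * t_l))
    r2_l = _r_squared(s_l, p1_l * t_l)

    t_star = p2_s / (p1_l - p1_s)
    s_star = p1_l * t_star

    anchors = [
        (e.rscp, e.rstp) for e in cat.entries.values() if e.material.anchor
    ]
    return CalibrationCurve(
        p1_solid=float(p1_s),
        p2_solid=float(p2_s),
        r2_solid=r2_s,
        n_solid=len(t_s),
        p1_low=p1_l,
        r2_low=r2_l,
        n_low=len(t_l),
        intersection=(float(t_star), float(s_star)),
        anchor_point=anchors[0] if anchors else None,
    )


def rscp_from_rstp(curve: CalibrationCurve, shat):
    """Invert the calibration: RStP -> RScP, continuous at the intersection.

    The low-density branch (through the origin) is used below the
    intersection ordinate, the solid branch above.
    """
    shat_arr = np.asarray(shat, dtype=float)
    if np.any(shat_arr <= 0):
        raise ValueError("relative stopping power must be positive")
    s_star = curve.intersection[1]
    low = shat_arr / curve.p1_low
    solid = (shat_arr - curve.p2_solid) / curve.p1_solid
    out = np.where(shat_arr < s_star, low, solid)
    return float(out) if out.ndim == 0 else out
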