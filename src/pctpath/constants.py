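"""Physical constants and unit conventions.

All lengths are in cm, energies in MeV, angles in radians, densities in
g/cm^3, electron densities in cm^-3.  CODATA values, truncated to the
precision relevant here.
"""

import math

#: fine-structure constant
ALPHA = 1.0 / 137.035999

#: electron rest energy [MeV]
ME_C2 = 0.5109989

#: proton rest energy [MeV]
MP_C2 = 938.2720

#: Avogadro's number [mol^-1]
N_AVOGADRO = 6.02214e23

#: classical electron radius [cm]
R_E = 2.8179403e-13

#: characteristic scattering energy E_s = m_e c^2 sqrt(2 pi / alpha) [MeV], ~15.00
E_S = ME_C2 * math.sqrt(2.0 * math.pi / ALPHA)

#: 4 pi r_e^2 m_e c^2 [MeV cm^2] -- prefactor of the Bethe-Bloch formula
K_BETHE = 4.0 * math.pi * R_E**2 * ME_C2

#: reciprocal of the elemental scattering summation for liquid water
#: (printed constant; the package recomputes it exactly where needed)
WATER_SUM_RECIPROCAL = 0.01636

#: radiation length of water [cm] (Lynch-Dahl / Highland water mode)
X0_WATER = 36.1

#: Highland characteristic energy [MeV]
E_HIGHLAND = 13.6

#: slope of the Highland logarithmic thickness correction
HIGHLAND_LOG_COEFF = 0.038

#: validity window of the simplified Gottschalk scattering power [MeV]
SCATTER_E_MIN = 3.0
SCATTER_E_MAX = 300.0


def reduced_energy(E):
    """Reduced kinetic energy tau = E / (m_p c^2)."""
    return E / MP_C2


def pv(E):
    """Momentum times velocity, p*v = E (tau + 2) / (tau + 1), in MeV."""
    tau = reduced_energy(E)
    return E * (tau + 2.0) / (tau + 1.0)


def beta_sq(E):
    """Squared velocity ratio beta^2 for a proton of kinetic energy E [MeV]."""
    gamma = 1.0 + reduced_energy(E)
    return 1.0 - 1.0 / (gamma * gamma)
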