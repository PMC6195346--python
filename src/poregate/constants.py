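"""Physical constants used throughout the package.

All constants are taken from :mod:`scipy.constants` (CODATA) rather than
hard-coded, except where a module deliberately rounds for display.
Energies are kJ/mol, voltages mV at public interfaces (volts internally),
distances Å, concentrations mM (ions) or nM (ligands).
"""

from scipy import constants as _c

#: Molar gas constant, J mol^-1 K^-1.
R = _c.R

#: Faraday constant, C mol^-1.
F = _c.physical_constants["Faraday constant"][0]

#: Avogadro constant, mol^-1.
N_A = _c.N_A

#: Elementary charge, C.
Q_E = _c.e

#: Vacuum permittivity, F m^-1.
EPS0 = _c.epsilon_0

#: Boltzmann constant, J K^-1.
K_B = _c.k

#: Coulomb energy prefactor N_A q^2 / (4 pi eps0), in kJ Å mol^-1.
#: Dividing by (eps_r * r[Å]) gives the interaction energy of two unit
#: charges in kJ/mol.  ~1389.35 kJ Å/mol.
K_COULOMB = N_A * Q_E**2 / (4.0 * _c.pi * EPS0) * 1e10 / 1e3

#: Default absolute temperature (recordings at 20 °C), K.
T_DEFAULT = 293.15


def rt_kj(T: float = T_DEFAULT) -> float:
    """RT in kJ/mol at temperature ``T`` (K)."""
    return R * T / 1e3
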