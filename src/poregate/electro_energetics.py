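"""Energy transforms and Coulombic pore electrostatics.

Connects the fitted barrier parameters to charge bookkeeping at the Ca2+
binding site and the intracellular pore entrance:

* ``delta_Ea`` converts the relative innermost-barrier crossing rate
  sigma_beta into an activation-energy difference, dEa(in-out) =
  -RT ln sigma_beta.
* ``coulomb_energy`` / ``fit_valence_energy`` relate dEa(in-out) to the net
  valence of the binding site through an unscreened Coulomb interaction at
  a fixed site-to-barrier distance r, yielding an effective relative
  permittivity eps_r from the slope.
* ``ddg_obs`` / ``fit_pore_charge_energy`` do the analogous analysis for
  Ca2+-binding energetics versus the valence change at the intracellular
  pore entrance (ddG_obs = RT ln(EC50/EC50_background)).
* ``mutant_cycle_coupling`` quantifies double-mutant-cycle non-additivity.
* ``axial_potential`` is a deliberately simplified screened-Coulomb
  (Debye-Hueckel) axial pore-potential calculator used only for
  ordering/monotonicity trends; it does not reproduce membrane-embedded
  Poisson-Boltzmann potentials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import EPS0, F, K_B, K_COULOMB, N_A, Q_E, T_DEFAULT, rt_kj

__all__ = [
    "EnergyPoint",
    "CoulombFit",
    "PoreChargePoint",
    "ChargeSite",
    "PorePotentialProfile",
    "delta_Ea",
    "coulomb_energy",
    "fit_valence_energy",
    "ddg_obs",
    "fit_pore_charge_energy",
    "mutant_cycle_coupling",
    "axial_potential",
    "debye_length",
    "site_valence",
    "SITE_RESIDUES",
    "CONSTRUCT_SITE_CHARGES",
]

# -- valence bookkeeping ----------------------------------------------------

#: The five acidic binding-site residues; site valence is 0 when all are
#: neutralized.
SITE_RESIDUES = ("E654", "E702", "E705", "E734", "D738")

_RESIDUE_CHARGE = {"E": -1, "D": -1, "Q": 0, "S": 0, "A": 0, "R": +1, "K": +1}

#: Net binding-site residue charge per construct (zero occupancy).
CONSTRUCT_SITE_CHARGES: dict[str, int] = {}


def _register_constructs() -> None:
    base = {res: _RESIDUE_CHARGE[res[0]] for res in SITE_RESIDUES}
    variants = {
        "WT": {},
        "G644P": {},
        "Q649A": {},
        "E702Q": {"E702": 0},
        "G644P/E654Q": {"E654": 0},
        "G644P/E654R": {"E654": +1},
        "G644P/E654R/E702Q": {"E654": +1, "E702": 0},
        "G644P/E654Q/E705Q": {"E654": 0, "E705": 0},
        "G644P/E654R/E705Q": {"E654": +1, "E705": 0},
        # pore-entrance mutants: binding site itself is WT-like
        "K588S": {},
        "K645S": {},
        "K588E/E702Q": {"E702": 0},
        "K645E/E702Q": {"E702": 0},
    }
    aliases = {
        "PQ": "G644P/E654Q",
        "PR": "G644P/E654R",
        "PR2Q": "G644P/E654R/E702Q",
        "PQ5Q": "G644P/E654Q/E705Q",
        "PR5Q": "G644P/E654R/E705Q",
        "K588E": "K588E/E702Q",
        "K645E": "K645E/E702Q",
    }
    for name, subs in variants.items():
        charges = dict(base)
        charges.update(subs)
        CONSTRUCT_SITE_CHARGES[name] = sum(charges.values())
    for alias, target in aliases.items():
        CONSTRUCT_SITE_CHARGES[alias] = CONSTRUCT_SITE_CHARGES[target]


_register_constructs()

#: Valence change at the intracellular pore entrance relative to WT
#: (Lys -> Ser removes +1; Lys -> Glu reverses it to -1).
PORE_ENTRANCE_DELTA_Z = {
    "WT": 0,
    "E702Q": 0,
    "K588S": -1,
    "K645S": -1,
    "K588E": -2,
    "K645E": -2,
    "K588E/E702Q": -2,
    "K645E/E702Q": -2,
}


def site_valence(construct: str, n_ca: int = 0, n_mg: int = 0, n_gd: int = 0) -> int:
    """Net binding-site valence: residue charges plus bound cations.

    Bound Ca2+ or Mg2+ contribute +2 each, Gd3+ +3.  ``construct`` may be a
    full mutant string (e.g. ``"G644P/E654Q"``) or a shorthand (``"PQ"``).
    """
    if construct not in CONSTRUCT_SITE_CHARGES:
        raise KeyError(f"unknown construct {construct!r}")
    if min(n_ca, n_mg, n_gd) < 0 or n_ca + n_mg + n_gd > 2:
        raise ValueError("occupancy must be 0-2 bound cations")
    return CONSTRUCT_SITE_CHARGES[construct] + 2 * (n_ca + n_mg) + 3 * n_gd


# -- data containers --------------------------------------------------------


@dataclass(frozen=True)
class EnergyPoint:
    """One (site valence, dEa(in-out)) observation."""

    valence: int
    dEa: float
    label: str = ""


@dataclass(frozen=True)
class PoreChargePoint:
    """One (pore-entrance valence change, ddG_obs) observation."""

    d_z_pore: int
    ddg: float
    z_ca: int = 2
    label: str = ""


@dataclass(frozen=True)
class CoulombFit:
    """Linear energy-vs-valence fit and the derived permittivity.

    ``ci95`` holds 95% half-widths for ``slope``, ``intercept`` and
    ``eps_r`` (delta method from the slope CI); NaN when the fit has no
    residual degrees of freedom.  ``flagged`` marks a slope whose sign is
    unphysical for the fitted relation.
    """

    eps_r: float
    intercept: float
    r: float
    slope: float
    ci95: dict = field(default_factory=dict)
    flagged: bool = False


@dataclass(frozen=True)
class ChargeSite:
    """Point charge on the pore axis: position (Å) and charge (e)."""

    position: float
    charge: float


@dataclass(frozen=True)
class PorePotentialProfile:
    """Axial electrostatic potential: sample positions (Å) and phi (mV)."""

    z: np.ndarray
    phi_mV: np.ndarray


# -- transforms -------------------------------------------------------------


def delta_Ea(sigma_beta: float, T: float = T_DEFAULT) -> float:
    """dEa(in-out) = -RT ln(sigma_beta), in kJ/mol."""
    if sigma_beta <= 0:
        raise ValueError("sigma_beta must be positive")
    return -rt_kj(T) * math.log(sigma_beta)


def coulomb_energy(z_site: float, eps_r: float, r: float) -> float:
    """Coulomb interaction of a unit anion with a site of valence ``z_site``.

    Returns -K z_site / (eps_r r) in kJ/mol (K = N_A q^2/4 pi eps0); a
    negative site raises the barrier seen by a permeating anion.
    """
    if eps_r <= 0 or r <= 0:
        raise ValueError("eps_r and r must be positive")
    return -K_COULOMB * z_site / (eps_r * r)


def ddg_obs(ec50: float, ec50_bg: float, T: float = T_DEFAULT) -> float:
    """Apparent change in binding free energy, RT ln(EC50/EC50_bg), kJ/mol.

    Negative values mean higher apparent ligand potency than the background.
    """
    if ec50 <= 0 or ec50_bg <= 0:
        raise ValueError("EC50 values must be positive")
    return rt_kj(T) * math.log(ec50 / ec50_bg)


def mutant_cycle_coupling(E_parent: float, E_A: float, E_B: float, E_AB: float) -> float:
    """Double-mutant-cycle coupling energy (kJ/mol); 0 means additivity."""
    return (E_AB - E_parent) - (E_A - E_parent) - (E_B - E_parent)


# -- linear Coulombic fits --------------------------------------------------


def _linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept and their 95% half-widths (NaN when df <= 0)."""
    n = len(x)
    res = stats.linregress(x, y)
    df = n - 2
    if df > 0 and np.isfinite(res.stderr) and res.stderr > 0:
        tcrit = stats.t.ppf(0.975, df)
        return res.slope, res.intercept, tcrit * res.stderr, tcrit * res.intercept_stderr
    return res.slope, res.intercept, float("nan"), float("nan")


def fit_valence_energy(points: list[EnergyPoint], r: float) -> CoulombFit:
    """Fit dEa(in-out) = slope * valence + intercept; eps_r = -K/(slope r).

    The physical slope is negative (a more positive site lowers the anion
    barrier); a nonnegative slope is returned flagged.  The eps_r CI is
    propagated from the slope CI by the delta method.
    """
    if r <= 0:
        raise ValueError("r must be positive (Å)")
    x = np.array([p.valence for p in points], dtype=float)
    y = np.array([p.dEa for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct valences")
    slope, intercept, slope_ci, intercept_ci = _linear_fit(x, y)
    flagged = slope >= 0
    eps_r = float("nan") if slope == 0 else -K_COULOMB / (slope * r)
    eps_ci = abs(K_COULOMB / (slope**2 * r)) * slope_ci if slope != 0 else float("nan")
    return CoulombFit(
        eps_r=eps_r, intercept=intercept, r=r, slope=slope,
        ci95={"slope": slope_ci, "intercept": intercept_ci, "eps_r": eps_ci},
        flagged=flagged,
    )


def fit_pore_charge_energy(points: list[PoreChargePoint], r: float, z_ca: int = 2) -> CoulombFit:
    """Fit ddG_obs = slope * d_z_pore + intercept; eps_r = K z_Ca/(slope r).

    The physical slope is positive (removing positive pore-entrance charge,
    d_z_pore < 0, makes Ca2+ binding more favourable); a nonpositive slope
    is returned flagged.
    """
    if r <= 0:
        raise ValueError("r must be positive (Å)")
    x = np.array([p.d_z_pore for p in points], dtype=float)
    y = np.array([p.ddg for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct pore valence changes")
    slope, intercept, slope_ci, intercept_ci = _linear_fit(x, y)
    flagged = slope <= 0
    eps_r = float("nan") if slope == 0 else K_COULOMB * z_ca / (slope * r)
    eps_ci = abs(K_COULOMB * z_ca / (slope**2 * r)) * slope_ci if slope != 0 else float("nan")
    return CoulombFit(
        eps_r=eps_r, intercept=intercept, r=r, slope=slope,
        ci95={"slope": slope_ci, "intercept": intercept_ci, "eps_r": eps_ci},
        flagged=flagged,
    )


# -- simplified axial electrostatics ----------------------------------------


def debye_length(ionic_strength_mM: float, eps_r: float = 80.0, T: float = T_DEFAULT) -> float:
    """Debye screening length in Å for a 1:1 electrolyte.

    lambda_D = sqrt(eps0 eps_r kB T / (2 N_A e^2 I)), I in mol/m^3 (= mM).
    """
    if ionic_strength_mM <= 0 or eps_r <= 0:
        raise ValueError("ionic strength and eps_r must be positive")
    i_si = ionic_strength_mM  # mM == mol/m^3
    lam = math.sqrt(EPS0 * eps_r * K_B * T / (2.0 * N_A * Q_E**2 * i_si))
    return lam * 1e10


def axial_potential(
    charges: list[ChargeSite],
    samples,
    eps_r: float = 80.0,
    ionic_strength_mM: float = 150.0,
    T: float = T_DEFAULT,
) -> PorePotentialProfile:
    """Screened-Coulomb potential along the pore axis, in mV.

    phi(z) = sum_i K z_i exp(-d_i/lambda_D) / (F eps_r d_i), with d_i the
    axial distance to charge i.  A uniform-dielectric stand-in for the full
    membrane-embedded Poisson-Boltzmann problem: only ordering and
    monotonicity trends are meaningful, not absolute values.  Pass
    ``ionic_strength_mM=None`` to disable screening (pure Coulomb).
    """
    if eps_r <= 0:
        raise ValueError("eps_r must be positive")
    z = np.asarray(samples, dtype=float)
    if ionic_strength_mM is None:
        lam = math.inf
    else:
        lam = debye_length(ionic_strength_mM, eps_r, T)
    phi = np.zeros_like(z)
    for site in charges:
        d = np.abs(z - site.position)
        if np.any(d == 0):
            raise ValueError("sample coincides with a charge position")
        # kJ/mol per unit probe charge -> volts via F, then mV
        phi += K_COULOMB * site.charge * np.exp(-d / lam) / (eps_r * d) * 1e6 / F
    return PorePotentialProfile(z=z, phi_mV=phi)
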