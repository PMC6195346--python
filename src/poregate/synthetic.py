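"""Synthetic inside-out-patch data with known ground truth.

Emulates the statistical structure the analysis pipeline assumes:

* instantaneous I-V families from the three-barrier rate model, with
  sigma_h and sigma_beta Hill-modulated by ligand concentration at the
  pre-pulse voltage and a voltage-dependent EC50 (electrical distance of
  the binding site);
* per-train irreversible rundown (default 12%, within the 10-15% observed
  experimentally), ohmic leak, additive Gaussian current noise, and
  optional injection of leaky patches;
* zero-ligand bracket recordings before and after the concentration series
  (the QC protocol);
* forward-generated valence-energy and pore-charge datasets for the
  Coulombic fits.

Every generator returns the latent truth alongside the data; the truth is
never consumed by the pipeline under test.  Identical config + seed yields
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import F, K_COULOMB, R, T_DEFAULT, rt_kj
from .electro_energetics import (EnergyPoint, PoreChargePoint, coulomb_energy,
                                 site_valence)
from .ligand_modulation import hill_response
from .rate_model import IonCondition, PermeationParams, current

__all__ = [
    "BarrierTruth",
    "ConstructTruth",
    "Protocol",
    "NoiseModel",
    "GeneratorConfig",
    "TRUTH_LIBRARY",
    "sigma_at",
    "ec50_at_voltage",
    "generate_patch",
    "generate_cohort",
    "generate_dose_response_family",
    "generate_steady_state_run",
    "generate_valence_dataset",
    "VALENCE_SERIES_TRUTHS",
]


@dataclass(frozen=True)
class BarrierTruth:
    """Hill modulation of one sigma parameter by the ligand.

    ``ec50_ref`` is the EC50 (nM) at the reference voltage (+80 mV, where
    the experimental values are reported); EC50 at other voltages follows
    from the electrical distance of the binding site.
    """

    sigma_min: float
    sigma_max: float
    ec50_ref: float
    h: float


@dataclass(frozen=True)
class ConstructTruth:
    """Latent parameters of one construct/ligand combination."""

    construct: str = "G644P"
    ligand: str = "Ca"
    A: float = 2e-5
    sigma_h: BarrierTruth = field(
        default_factory=lambda: BarrierTruth(0.2, 1.0, 170.0, 1.7))
    sigma_beta: BarrierTruth = field(
        default_factory=lambda: BarrierTruth(0.05, 1.0, 60.0, 2.1))
    zf_product: float = 0.5
    v_ref: float = 80.0
    basal_active: bool = True
    po_ec50_ref: float = 300.0
    po_h: float = 2.0
    biphasic: bool = False
    biphasic_ec50: float = 1e5
    biphasic_depth: float = 0.5
    biphasic_h: float = 2.0


def _pore_mutant_truth(position: str, d_z: int, eps_r: float, r: float) -> ConstructTruth:
    """Steady-state EC50 of a pore-entrance mutant from the Coulombic model."""
    base = ConstructTruth()
    ddg = K_COULOMB * 2 * d_z / (eps_r * r)  # kJ/mol, z_Ca = 2
    ec50 = base.po_ec50_ref * math.exp(ddg / rt_kj())
    name = {-1: f"{position}S", -2: f"{position}E"}[d_z]
    return replace(base, construct=name, basal_active=False,
                   po_ec50_ref=ec50,
                   sigma_h=BarrierTruth(1.0, 1.0, base.sigma_h.ec50_ref, base.sigma_h.h),
                   sigma_beta=BarrierTruth(1.0, 1.0, base.sigma_beta.ec50_ref,
                                           base.sigma_beta.h))


def _build_truth_library() -> dict[tuple[str, str], ConstructTruth]:
    g644p = ConstructTruth()
    lib: dict[tuple[str, str], ConstructTruth] = {
        ("G644P", "Ca"): g644p,
        # Mg2+ occupies a single site: h = 1, sigma_beta saturates at an
        # intermediate level, much lower apparent affinity.
        ("G644P", "Mg"): replace(
            g644p, ligand="Mg",
            sigma_h=BarrierTruth(0.2, 0.55, 2.0e5, 1.0),
            sigma_beta=BarrierTruth(0.05, 0.45, 2.0e5, 1.0),
        ),
        # WT instantaneous currents are pseudo-linear at all activating Ca:
        # the conducting state is the fully occupied open state.
        ("WT", "Ca"): replace(
            g644p, construct="WT", basal_active=False,
            sigma_h=BarrierTruth(1.0, 1.0, 170.0, 1.7),
            sigma_beta=BarrierTruth(1.0, 1.0, 60.0, 2.1),
        ),
        # single-Ca binding-site mutants: lower affinity, intermediate
        # saturating conductance, secondary low-affinity decay phase.
        ("PQ", "Ca"): replace(
            g644p, construct="PQ",
            sigma_h=BarrierTruth(0.2, 0.6, 900.0, 1.0),
            sigma_beta=BarrierTruth(0.05, 0.45, 900.0, 1.0),
            biphasic=True,
        ),
        ("PR", "Ca"): replace(
            g644p, construct="PR",
            sigma_h=BarrierTruth(0.2, 0.7, 2500.0, 1.0),
            sigma_beta=BarrierTruth(0.05, 0.6, 2500.0, 1.0),
            biphasic=True,
        ),
    }
    lib[("K588S", "Ca")] = _pore_mutant_truth("K588", -1, 131.9, 11.9)
    lib[("K588E", "Ca")] = _pore_mutant_truth("K588", -2, 131.9, 11.9)
    lib[("K645S", "Ca")] = _pore_mutant_truth("K645", -1, 71.2, 10.6)
    lib[("K645E", "Ca")] = _pore_mutant_truth("K645", -2, 71.2, 10.6)
    return lib


#: Default latent parameters per (construct, ligand).  EC50 / Hill values
#: for G644P are the experimentally reported +80 mV values (60 nM / 2.1 for
#: the inner barrier, 170 nM / 1.7 for the central barrier); sigma bounds
#: are invented defaults chosen to reproduce the qualitative strongly
#: rectifying -> pseudo-linear transition.
TRUTH_LIBRARY = _build_truth_library()


@dataclass(frozen=True)
class Protocol:
    """Voltage and concentration protocol of a session."""

    voltages: tuple = tuple(float(v) for v in range(-100, 121, 20))
    prepulse_mV: float = 80.0
    concentrations: tuple = (10.0, 30.0, 100.0, 300.0, 1000.0, 10000.0)
    n_patches: int = 6


@dataclass(frozen=True)
class NoiseModel:
    """Nuisance processes: additive noise, rundown, leak, leaky patches.

    ``current_sd`` is the additive noise s.d. as a fraction of the
    saturating +120 mV current; ``rundown_per_train`` the irreversible
    fractional decay over one -100 -> +120 mV train; ``leak`` an ohmic leak
    conductance in current units per mV; ``leaky_rate`` the fraction of
    patches injected with ``leaky_leak`` instead of ``leak``.
    """

    current_sd: float = 0.02
    rundown_per_train: float = 0.12
    leak: float = 0.0
    leaky_rate: float = 0.0
    leaky_leak: float = 1.0

    def __post_init__(self) -> None:
        for name in ("current_sd", "rundown_per_train", "leaky_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of a synthetic recording session."""

    construct: str = "G644P"
    ligand: str = "Ca"
    truth: ConstructTruth | None = None
    protocol: Protocol = field(default_factory=Protocol)
    noise: NoiseModel = field(default_factory=NoiseModel)
    condition: IonCondition = field(default_factory=IonCondition)
    seed: int = 0

    def resolve_truth(self) -> ConstructTruth:
        if self.truth is not None:
            return self.truth
        key = (self.construct, self.ligand)
        if key not in TRUTH_LIBRARY:
            raise KeyError(f"no default truth for {key}; pass truth= explicitly")
        return TRUTH_LIBRARY[key]


def ec50_at_voltage(ec50_ref: float, V_mV: float, zf_product: float,
                    v_ref: float = 80.0, T: float = T_DEFAULT) -> float:
    """Shift an EC50 from the reference voltage to V.

    log10 EC50(V) = log10 EC50(v_ref) - (1/ln 10) z_Ca f_V (V - v_ref) F/RT.
    """
    dv = (V_mV - v_ref) * 1e-3
    return ec50_ref * 10.0 ** (-zf_product * F * dv / (math.log(10.0) * R * T))


def sigma_at(bt: BarrierTruth, conc_nM: float, V_mV: float, zf_product: float,
             v_ref: float = 80.0, T: float = T_DEFAULT) -> float:
    """Hill-modulated sigma at a ligand concentration and (pre-pulse) voltage."""
    ec50 = ec50_at_voltage(bt.ec50_ref, V_mV, zf_product, v_ref, T)
    return float(hill_response(conc_nM, ec50, bt.h, bt.sigma_min, bt.sigma_max))


def _biphasic_factor(truth: ConstructTruth, conc_nM: float) -> float:
    """Low-affinity secondary decay of sigma_beta at high concentrations.

    A Hill-type suppression well separated from the activating phase; the
    experimental decay appears only in the >10 µM range.
    """
    if not truth.biphasic or conc_nM <= 0:
        return 1.0
    occ = 1.0 / (1.0 + (truth.biphasic_ec50 / conc_nM) ** truth.biphasic_h)
    return 1.0 - truth.biphasic_depth * occ


def _params_at(truth: ConstructTruth, conc_nM: float, prepulse_mV: float,
               condition: IonCondition) -> PermeationParams:
    sh = sigma_at(truth.sigma_h, conc_nM, prepulse_mV, truth.zf_product,
                  truth.v_ref, condition.T)
    sb = sigma_at(truth.sigma_beta, conc_nM, prepulse_mV, truth.zf_product,
                  truth.v_ref, condition.T)
    sb *= _biphasic_factor(truth, conc_nM)
    return PermeationParams(A=truth.A, sigma_h=sh, sigma_beta=sb,
                            condition=condition)


def _reference_amplitude(truth: ConstructTruth, condition: IonCondition) -> float:
    """Saturating-current scale used to express noise s.d."""
    p = PermeationParams(A=truth.A, sigma_h=truth.sigma_h.sigma_max,
                         sigma_beta=truth.sigma_beta.sigma_max,
                         condition=condition)
    return abs(float(current(p, 120.0)))


def generate_patch(config: GeneratorConfig, patch_index: int
                   ) -> tuple[pd.DataFrame, dict]:
    """Simulate one patch's session: zero bracket, ligand series, zero bracket.

    Returns the long-format sweep table (columns patch_id, epoch, ligand,
    conc_nM, prepulse_mV, prepulse_pA, V_mV, I_pA) and the truth record.
    """
    truth = config.resolve_truth()
    proto, noise, cond = config.protocol, config.noise, config.condition
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, patch_index]))
    leaky = bool(rng.random() < noise.leaky_rate)
    leak = noise.leaky_leak if leaky else noise.leak
    noise_sd = noise.current_sd * _reference_amplitude(truth, cond)
    n_steps = len(proto.voltages)
    per_step = (1.0 - noise.rundown_per_train) ** (1.0 / n_steps)

    patch_id = f"p{patch_index:03d}"
    series = [0.0, *proto.concentrations, 0.0]
    rows = []
    truth_conditions = {}
    scale = 1.0
    epoch = 0
    for conc in series:
        active = truth.basal_active or conc > 0
        params = _params_at(truth, conc, proto.prepulse_mV, cond)
        truth_conditions.setdefault(conc, {
            "sigma_h": params.sigma_h, "sigma_beta": params.sigma_beta,
            "active": active,
        })
        i_pp_model = float(current(params, proto.prepulse_mV)) if active else 0.0
        for v in proto.voltages:
            i_model = float(current(params, v)) if active else 0.0
            i_pp = scale * (i_pp_model + leak * proto.prepulse_mV)
            i_test = scale * (i_model + leak * v)
            if noise_sd > 0:
                i_pp += rng.normal(0.0, noise_sd)
                i_test += rng.normal(0.0, noise_sd)
            rows.append((patch_id, epoch, config.ligand, conc,
                         proto.prepulse_mV, i_pp, v, i_test))
            scale *= per_step
            epoch += 1
    table = pd.DataFrame(rows, columns=[
        "patch_id", "epoch", "ligand", "conc_nM", "prepulse_mV",
        "prepulse_pA", "V_mV", "I_pA"])
    record = {
        "patch_id": patch_id, "leaky": leaky, "leak": leak,
        "A": truth.A, "noise_sd": noise_sd, "rundown_per_step": per_step,
        "zf_product": truth.zf_product,
        "conditions": truth_conditions,
        "truth": asdict(truth),
    }
    return table, record


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate ``protocol.n_patches`` independent patches."""
    tables, records = [], []
    for idx in range(config.protocol.n_patches):
        t, r = generate_patch(config, idx)
        tables.append(t)
        records.append(r)
    return pd.concat(tables, ignore_index=True), records


def generate_dose_response_family(
    config: GeneratorConfig,
    voltage: float = 80.0,
    concentrations=None,
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Sigma-versus-concentration series at one (pre-pulse) voltage.

    Returns a table (conc_nM, sigma_h, sigma_beta) and the truth.  With the
    construct's ``biphasic`` flag set, sigma_beta carries the secondary
    low-affinity decay.
    """
    truth = config.resolve_truth()
    cond = config.condition
    if concentrations is None:
        concentrations = np.logspace(0, 5, 12)
    conc = np.asarray(sorted(concentrations), dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10_007]))
    sh = np.array([sigma_at(truth.sigma_h, c, voltage, truth.zf_product,
                            truth.v_ref, cond.T) for c in conc])
    sb = np.array([sigma_at(truth.sigma_beta, c, voltage, truth.zf_product,
                            truth.v_ref, cond.T) * _biphasic_factor(truth, c)
                   for c in conc])
    if noise_sd > 0:
        sh = sh + rng.normal(0.0, noise_sd, sh.shape)
        sb = sb + rng.normal(0.0, noise_sd, sb.shape)
    table = pd.DataFrame({"conc_nM": conc, "sigma_h": sh, "sigma_beta": sb})
    truth_rec = {
        "voltage": voltage,
        "ec50_sigma_h": ec50_at_voltage(truth.sigma_h.ec50_ref, voltage,
                                        truth.zf_product, truth.v_ref, cond.T),
        "ec50_sigma_beta": ec50_at_voltage(truth.sigma_beta.ec50_ref, voltage,
                                           truth.zf_product, truth.v_ref, cond.T),
        "truth": asdict(truth),
    }
    return table, truth_rec


def generate_steady_state_run(
    config: GeneratorConfig,
    voltage: float = 80.0,
    concentrations=(10.0, 30.0, 100.0, 300.0, 1000.0),
    reference_conc: float = 1e5,
    amplitude: float = 500.0,
    noise_sd: float = 0.0,
) -> tuple[list[tuple], dict]:
    """Time-ordered steady-state responses with interleaved references.

    Emulates the rundown-correction protocol: reference (saturating
    ligand) applications bracket every test concentration, and every
    application decays the patch by ``noise.rundown_per_train``.  Returns
    records (epoch, conc_nM, response, role) and the truth.
    """
    truth = config.resolve_truth()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 20_011]))
    ec50_v = ec50_at_voltage(truth.po_ec50_ref, voltage, truth.zf_product,
                             truth.v_ref, config.condition.T)
    decay = 1.0 - config.noise.rundown_per_train
    records = []
    scale = 1.0
    epoch = 0

    def emit(conc, role):
        nonlocal scale, epoch
        po = float(hill_response(conc, ec50_v, truth.po_h))
        resp = amplitude * po * scale
        if noise_sd > 0:
            resp += rng.normal(0.0, noise_sd)
        records.append((epoch, conc, resp, role))
        scale *= decay
        epoch += 1

    emit(reference_conc, "reference")
    for c in concentrations:
        emit(c, "test")
        emit(reference_conc, "reference")
    truth_rec = {"ec50": ec50_v, "h": truth.po_h, "voltage": voltage,
                 "amplitude": amplitude, "decay_per_application": decay}
    return records, truth_rec


# -- forward-generated Coulombic datasets ------------------------------------

#: Default truths of the valence-energy forward models: effective relative
#: permittivities as experimentally estimated, distances from the
#: Ca2+-bound structure (binding site to Ser592 oxygen, 13.6 Å; to the
#: Lys588/Lys645 nitrogens, 11.9/10.6 Å).
VALENCE_SERIES_TRUTHS = {
    "divalent-occupancy": {"eps_r": 64.8, "r": 13.6},
    "zero-ca-mutants": {"eps_r": 162.7, "r": 13.6},
    "one-ca-mutants": {"eps_r": 96.7, "r": 13.6},
    "pore-charge": {"K588": {"eps_r": 131.9, "r": 11.9},
                    "K645": {"eps_r": 71.2, "r": 10.6}},
}

_SITE_MUTANT_SERIES = ("PQ", "PR", "PQ5Q", "PR2Q", "PR5Q")


def generate_valence_dataset(
    series: str,
    noise_sd: float = 0.0,
    position: str = "K645",
    seed: int = 0,
    constructs=None,
):
    """Forward-generate an energy-versus-valence dataset.

    ``series`` is one of ``divalent-occupancy`` (G644P with 0, one Mg2+ or
    two Ca2+ bound), ``zero-ca-mutants`` / ``one-ca-mutants`` (binding-site
    mutant panels at fixed occupancy) or ``pore-charge`` (ddG_obs versus
    pore-entrance valence change at ``position`` K588 or K645).  Energies
    are intercept + Coulomb term + Gaussian noise; returns (points, truth).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 30_013]))
    sigma_beta_0 = ConstructTruth().sigma_beta.sigma_min  # dEa anchor

    if series == "pore-charge":
        spec = VALENCE_SERIES_TRUTHS[series]
        if position not in spec:
            raise ValueError(f"unknown pore position {position!r}")
        eps_r, r = spec[position]["eps_r"], spec[position]["r"]
        z_ca = 2
        d_zs = (0, -1, -2) if constructs is None else tuple(constructs)
        if len(set(d_zs)) < 2:
            raise ValueError("degenerate request: need >= 2 distinct valences")
        labels = {0: "WT", -1: f"{position}S", -2: f"{position}E"}
        points = []
        for dz in d_zs:
            ddg = K_COULOMB * z_ca * dz / (eps_r * r)
            if noise_sd > 0:
                ddg += rng.normal(0.0, noise_sd)
            points.append(PoreChargePoint(d_z_pore=dz, ddg=ddg, z_ca=z_ca,
                                          label=labels.get(dz, str(dz))))
        truth = {"eps_r": eps_r, "r": r, "z_ca": z_ca, "intercept": 0.0,
                 "series": series, "position": position}
        return points, truth

    if series not in VALENCE_SERIES_TRUTHS:
        raise ValueError(f"unknown valence series {series!r}")
    eps_r = VALENCE_SERIES_TRUTHS[series]["eps_r"]
    r = VALENCE_SERIES_TRUTHS[series]["r"]

    if series == "divalent-occupancy":
        entries = [("G644P 0 bound", site_valence("G644P")),
                   ("G644P 1 Mg", site_valence("G644P", n_mg=1)),
                   ("G644P 2 Ca", site_valence("G644P", n_ca=2))]
        anchor_valence = site_valence("G644P")
    else:
        n_ca = 1 if series == "one-ca-mutants" else 0
        names = _SITE_MUTANT_SERIES if constructs is None else tuple(constructs)
        entries = [(f"{c} {n_ca} Ca", site_valence(c, n_ca=n_ca)) for c in names]
        if series == "zero-ca-mutants":
            entries.insert(0, ("G644P 0 bound", site_valence("G644P")))
        anchor_valence = entries[0][1]
    if len({v for _, v in entries}) < 2:
        raise ValueError("degenerate request: need >= 2 distinct valences")

    # anchor the line so the most negative-site condition has the zero-Ca
    # G644P barrier height (-RT ln sigma_beta_min)
    anchor_dEa = -rt_kj() * math.log(sigma_beta_0)
    intercept = anchor_dEa - coulomb_energy(anchor_valence, eps_r, r)
    points = []
    for label, z in entries:
        de = intercept + coulomb_energy(z, eps_r, r)
        if noise_sd > 0:
            de += rng.normal(0.0, noise_sd)
        points.append(EnergyPoint(valence=z, dEa=de, label=label))
    truth = {"eps_r": eps_r, "r": r, "intercept": intercept, "series": series}
    return points, truth
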