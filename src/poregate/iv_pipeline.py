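"""Normalization, QC and model fitting of instantaneous I-V families.

The data-reduction chain for inside-out-patch recordings:

1. pre-pulse normalization — divide each sweep's currents by its pre-pulse
   amplitude relative to the recording median, correcting multiplicative
   rundown between sweeps;
2. reference-voltage normalization — divide a recording by its current at
   +120 mV;
3. background subtraction — subtract a matched zero-ligand recording (only
   meaningful for constructs without basal activity);
4. QC — recordings at each ligand concentration are bracketed by
   zero-ligand recordings; a patch is discarded when the brackets drift or
   when the zero-ligand current reveals a leaky patch;
5. weighted least-squares fit of the three-barrier rate model with
   sigma_h, sigma_beta fitted in log space and A linear;
6. cross-patch aggregation (mean ± s.e.m.).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from statistics import median

import numpy as np
from scipy import optimize, stats

from .rate_model import IonCondition, PermeationParams, current

__all__ = [
    "Sweep",
    "IVRecording",
    "IVFitResult",
    "QCPolicy",
    "NORM_ORDER",
    "normalize_prepulse",
    "sweeps_to_recordings",
    "normalize_reference",
    "background_subtract",
    "qc_filter",
    "fit_iv",
    "aggregate_patches",
]

NORM_ORDER = ("raw", "prepulse", "reference", "background-subtracted")


@dataclass(frozen=True)
class Sweep:
    """One voltage step: test current plus the preceding pre-pulse current."""

    patch_id: str
    epoch: int
    ligand: str
    conc: float
    V: float
    I: float
    I_prepulse: float
    prepulse_V: float = 80.0

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise ValueError("ligand concentration must be nonnegative")
        if self.epoch < 0:
            raise ValueError("epoch must be nonnegative")


@dataclass(frozen=True)
class IVRecording:
    """One patch's I-V family at one ligand condition."""

    patch_id: str
    ligand: str
    conc: float
    points: tuple[tuple[float, float], ...]
    norm_state: str = "raw"
    first_epoch: int = 0

    def __post_init__(self) -> None:
        volts = [v for v, _ in self.points]
        if len(set(volts)) != len(volts):
            raise ValueError("voltages must be unique within a recording")
        if self.norm_state not in NORM_ORDER:
            raise ValueError(f"unknown norm_state {self.norm_state!r}")

    def voltages(self) -> np.ndarray:
        return np.array([v for v, _ in self.points])

    def currents(self) -> np.ndarray:
        return np.array([i for _, i in self.points])

    def _advance(self, new_state: str, points) -> "IVRecording":
        if NORM_ORDER.index(new_state) <= NORM_ORDER.index(self.norm_state):
            raise ValueError(
                f"norm_state may only advance ({self.norm_state} -> {new_state})"
            )
        return replace(self, points=tuple(points), norm_state=new_state)


@dataclass(frozen=True)
class IVFitResult:
    """Best-fit rate-model parameters with asymptotic 95% half-widths."""

    sigma_h: float
    sigma_beta: float
    A: float
    ci95: dict = field(default_factory=dict)
    rss: float = float("nan")
    n_fixed: int = 3
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and (self.sigma_h <= 0 or self.sigma_beta <= 0):
            raise ValueError("fitted sigma values must be positive")


@dataclass(frozen=True)
class QCPolicy:
    """Patch-acceptance thresholds (the paper states no numeric rule).

    Metrics are scale-free and one-sided, because irreversible rundown makes
    currents shrink in any healthy patch while leak and deterioration make
    them grow:

    * leak — a zero-ligand recording whose amplitude exceeds
      ``amp_floor_frac`` of the patch's largest median pre-pulse amplitude
      and whose inward branch (V <= ``leak_V_max``) is larger than
      ``leak_ratio_max`` of its outward branch (ohmic leak is linear; the
      zero-ligand channel current is strongly outwardly rectifying);
    * deteriorated — the mean |I| of the closing zero-ligand bracket exceeds
      that of the opening bracket by more than ``bracket_drift``
      (fractional), provided it is above the same amplitude floor.
    """

    bracket_drift: float = 0.20
    leak_ratio_max: float = 0.40
    leak_V_max: float = -40.0
    amp_floor_frac: float = 0.15


# -- normalization ----------------------------------------------------------


def _recording_runs(sweeps: list[Sweep]) -> list[tuple[tuple, list[Sweep]]]:
    """Split sweeps into recordings: contiguous (patch, ligand, conc) runs.

    Contiguity is judged in epoch order within each patch, so the
    zero-ligand recordings bracketing a session stay distinct.
    """
    runs: list[tuple[tuple, list[Sweep]]] = []
    for s in sorted(sweeps, key=lambda s: (s.patch_id, s.epoch)):
        key = (s.patch_id, s.ligand, s.conc)
        if runs and runs[-1][0] == key:
            runs[-1][1].append(s)
        else:
            runs.append((key, [s]))
    return runs


def normalize_prepulse(sweeps: list[Sweep]) -> list[Sweep]:
    """Divide currents by each sweep's pre-pulse relative to the recording median.

    Recordings are contiguous (patch_id, ligand, conc) runs in epoch order.
    Sweeps with a zero pre-pulse current are excluded with a warning.
    Corrects multiplicative drift (rundown) between sweeps without altering
    within-sweep shape.
    """
    out: list[Sweep] = []
    for key, group in _recording_runs(sweeps):
        good = [s for s in group if s.I_prepulse != 0]
        if len(good) < len(group):
            warnings.warn(
                f"recording {key}: {len(group) - len(good)} sweep(s) with zero "
                "pre-pulse current excluded", stacklevel=2,
            )
        if not good:
            continue
        med = median(s.I_prepulse for s in good)
        for s in good:
            out.append(replace(s, I=s.I * med / s.I_prepulse, I_prepulse=med))
    out.sort(key=lambda s: (s.patch_id, s.epoch))
    return out


def sweeps_to_recordings(sweeps: list[Sweep], norm_state: str = "raw") -> list[IVRecording]:
    """Collapse sweeps into I-V recordings (contiguous condition runs)."""
    recs = []
    for (pid, ligand, conc), group in _recording_runs(sweeps):
        recs.append(
            IVRecording(
                patch_id=pid, ligand=ligand, conc=conc,
                points=tuple((s.V, s.I) for s in group),
                norm_state=norm_state, first_epoch=group[0].epoch,
            )
        )
    recs.sort(key=lambda r: (r.patch_id, r.first_epoch))
    return recs


def normalize_reference(rec: IVRecording, ref_V: float = 120.0) -> IVRecording:
    """Divide all currents by the current at ``ref_V`` (default +120 mV)."""
    lookup = dict(rec.points)
    if ref_V not in lookup:
        raise ValueError(f"recording lacks the reference voltage {ref_V} mV")
    i_ref = lookup[ref_V]
    if i_ref == 0:
        raise ZeroDivisionError("reference current is zero")
    return rec._advance("reference", ((v, i / i_ref) for v, i in rec.points))


def background_subtract(rec: IVRecording, zero_ligand_rec: IVRecording) -> IVRecording:
    """Point-wise subtraction of a zero-ligand background recording."""
    v1 = rec.voltages()
    v2 = zero_ligand_rec.voltages()
    if v1.shape != v2.shape or np.any(v1 != v2):
        raise ValueError("recordings do not share a voltage grid")
    pts = ((v, i - j) for (v, i), (_, j) in zip(rec.points, zero_ligand_rec.points))
    return rec._advance("background-subtracted", pts)


# -- quality control ---------------------------------------------------------


def _inward_amplitude(run: list[Sweep], v_max: float) -> float:
    vals = [abs(s.I) for s in run if s.V <= v_max]
    return float(np.mean(vals)) if vals else 0.0


def qc_filter(
    patch_sweeps: list[Sweep], policy: QCPolicy = QCPolicy()
) -> tuple[list[IVRecording], list[tuple[str, str]]]:
    """Accept or reject one patch based on its bracketing zero-ligand recordings.

    ``patch_sweeps`` are the raw sweeps of one patch (pre-pulse currents
    provide the rundown-free amplitude scale).  Returns (kept recordings,
    [(patch_id, reason)]).  Rejection reasons: "unbracketed" (fewer than two
    zero-ligand recordings, or a test recording outside them), "leaky"
    (zero-ligand inward current too large relative to the pre-pulse scale),
    "deteriorated" (the closing bracket's currents grew relative to the
    opening bracket).  Deterministic given policy and input ordering; an
    explicit stand-in for the qualitative experimental rule.
    """
    if not patch_sweeps:
        return [], []
    pid = patch_sweeps[0].patch_id
    runs = _recording_runs(patch_sweeps)
    zeros = [run for key, run in runs if key[2] == 0]
    tests = [run for key, run in runs if key[2] > 0]
    recordings = sweeps_to_recordings(patch_sweeps)
    if len(zeros) < 2:
        return [], [(pid, "unbracketed")]
    z_epochs = [min(s.epoch for s in run) for run in zeros]
    lo, hi = min(z_epochs), max(z_epochs)
    if any(not (lo <= min(s.epoch for s in run) <= hi) for run in tests):
        return [], [(pid, "unbracketed")]

    # patch-wide pre-pulse scale (largest recording median; in practice the
    # first recordings, before rundown accumulates)
    pp_scale = max(abs(median(s.I_prepulse for s in run)) for _key, run in runs)
    if pp_scale == 0:
        return [], [(pid, "leaky")]
    floor = policy.amp_floor_frac * pp_scale
    for run in zeros:
        amp = float(np.mean([abs(s.I) for s in run]))
        inward = _inward_amplitude(run, policy.leak_V_max)
        outward = float(np.mean([abs(s.I) for s in run if s.V >= -policy.leak_V_max]))
        if amp > floor and outward > 0 and inward / outward > policy.leak_ratio_max:
            return [], [(pid, "leaky")]

    first = min(zeros, key=lambda run: min(s.epoch for s in run))
    last = max(zeros, key=lambda run: min(s.epoch for s in run))
    a0 = float(np.mean([abs(s.I) for s in first]))
    a1 = float(np.mean([abs(s.I) for s in last]))
    if a1 > floor and (a1 - a0) / max(a0, floor) > policy.bracket_drift:
        return [], [(pid, "deteriorated")]
    return recordings, []


# -- model fitting -----------------------------------------------------------

_SIGMA_STARTS = ((1.0, 1.0), (0.3, 0.1), (1.0, 0.1), (0.1, 0.3), (3.0, 1.0), (0.1, 0.03))


def fit_iv(
    rec: IVRecording,
    condition: IonCondition = IonCondition(),
    weights=None,
    n_fixed: int = 3,
) -> IVFitResult:
    """Fit the three-barrier model to one I-V recording.

    sigma_h and sigma_beta are fitted in log space (positivity), A on a log
    scale as well; the fit is multi-start over a log-spaced sigma grid and
    the lowest-RSS solution is kept.  log sigma is box-bounded to ±7 (a
    barrier offset of ~17 kJ/mol either way) because sigma_h becomes
    unidentifiable when a small sigma_beta dominates the denominator.
    Unweighted residuals by default; ``weights`` (per point, 1/sd) are
    optional.  95% half-widths come from the linearized covariance,
    transformed to the natural scale by the delta method.
    """
    v = rec.voltages()
    y = rec.currents()
    if v.size < 6 or v.min() >= 0 or v.max() <= 0:
        raise ValueError("need >= 6 voltages spanning both signs of V")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    def model(x):
        a, sh, sb = np.exp(x)
        p = PermeationParams(A=a, sigma_h=sh, sigma_beta=sb, n=n_fixed,
                             condition=condition)
        return current(p, v)

    def resid(x):
        return (model(x) - y) * w

    scale_y = float(np.max(np.abs(y)))
    if scale_y == 0:
        raise ValueError("all-zero currents cannot be fitted")
    best = None
    for sh0, sb0 in _SIGMA_STARTS:
        p1 = PermeationParams(A=1.0, sigma_h=sh0, sigma_beta=sb0, n=n_fixed,
                              condition=condition)
        ref = float(np.max(np.abs(current(p1, v))))
        a0 = scale_y / ref if ref > 0 else 1.0
        x0 = np.log([a0, sh0, sb0])
        lo = np.array([x0[0] - 20.0, -7.0, -7.0])
        hi = np.array([x0[0] + 20.0, 7.0, 7.0])
        try:
            sol = optimize.least_squares(resid, np.clip(x0, lo, hi),
                                         bounds=(lo, hi), max_nfev=10000)
        except Exception:  # noqa: BLE001
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return IVFitResult(sigma_h=float("nan"), sigma_beta=float("nan"),
                           A=float("nan"), converged=False)

    a, sh, sb = np.exp(best.x)
    rss = float(2 * best.cost)
    dof = y.size - 3
    ci = {}
    if dof > 0:
        try:
            cov = np.linalg.inv(best.jac.T @ best.jac) * rss / dof
            se_log = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            half = stats.t.ppf(0.975, dof) * se_log
            ci = {"A": a * half[0], "sigma_h": sh * half[1], "sigma_beta": sb * half[2]}
        except np.linalg.LinAlgError:
            ci = {}
    return IVFitResult(sigma_h=float(sh), sigma_beta=float(sb), A=float(a),
                       ci95=ci, rss=rss, n_fixed=n_fixed, converged=True)


# -- aggregation -------------------------------------------------------------


def aggregate_patches(items):
    """Mean ± s.e.m. across patches.

    For a list of :class:`IVRecording` on a shared voltage grid, returns
    (voltages, mean, sem) arrays; for a sequence of scalars (fitted
    parameters), returns (mean, sem).  With a single patch the mean is
    returned and the s.e.m. is NaN.
    """
    items = list(items)
    if not items:
        raise ValueError("nothing to aggregate")
    if isinstance(items[0], IVRecording):
        grid = items[0].voltages()
        for r in items[1:]:
            if r.voltages().shape != grid.shape or np.any(r.voltages() != grid):
                raise ValueError("recordings do not share a voltage grid")
        mat = np.vstack([r.currents() for r in items])
        mean = mat.mean(axis=0)
        sem = (mat.std(axis=0, ddof=1) / math.sqrt(len(items))
               if len(items) > 1 else np.full(grid.shape, float("nan")))
        return grid, mean, sem
    arr = np.asarray(items, dtype=float)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return mean, sem
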