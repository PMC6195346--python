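"""Hill-equation analysis of ligand dependence.

Covers four related analyses:

* Hill fits of steady-state concentration-response data,
  response = floor + (ceiling - floor) / (1 + 10^{(log EC50 - log c) h});
* Hill fits of the ligand dependence of the fitted barrier parameters
  sigma_beta and sigma_h (floor = sigma_min, ceiling = sigma_max);
* the voltage dependence of EC50,
  log10 EC50(V) = log10 EC50(0) - (1/ln 10) z_Ca f_V V F / RT,
  from which the product z_Ca * f_V (valence times electrical distance of
  the binding site) is read off the slope;
* rundown correction of steady-state responses by bracketing saturating
  reference applications.

All Hill fitting is done in log10-concentration space; a zero concentration
is the floor by the limit of the Hill form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .constants import F, R, T_DEFAULT

__all__ = [
    "HillParams",
    "VoltageEC50Fit",
    "SigmaSeries",
    "hill_response",
    "fit_hill",
    "fit_sigma_series",
    "exclude_low_affinity_phase",
    "fit_ec50_voltage",
    "rundown_correct",
]


@dataclass(frozen=True)
class HillParams:
    """Hill-fit result; ``ci95`` holds 95% half-widths per parameter."""

    ec50: float
    h: float
    floor: float
    ceiling: float
    ci95: dict = field(default_factory=dict)
    h_fixed: bool = False
    identifiable: bool = True
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if self.identifiable:
            if self.ec50 <= 0 or self.h <= 0:
                raise ValueError("ec50 and h must be positive")
            if self.ceiling < self.floor:
                raise ValueError("ceiling must be >= floor")


@dataclass(frozen=True)
class VoltageEC50Fit:
    """Linear fit of log10 EC50 versus voltage."""

    log_ec50_0: float
    zf_product: float
    z_ca: int = 2
    ci95: dict = field(default_factory=dict)

    @property
    def f_v(self) -> float:
        """Electrical distance of the binding site."""
        return self.zf_product / self.z_ca

    def ec50_at(self, V_mV: float, T: float = T_DEFAULT) -> float:
        """EC50 (same units as the input data) at membrane potential V."""
        slope = -self.zf_product * F / (math.log(10.0) * R * T) * 1e-3
        return 10.0 ** (self.log_ec50_0 + slope * V_mV)


@dataclass(frozen=True)
class SigmaSeries:
    """A sigma-vs-concentration series at one voltage for one ligand."""

    ligand: str
    voltage: float
    conc: np.ndarray
    sigma: np.ndarray
    ci95: np.ndarray | None = None
    included: np.ndarray | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if conc.shape != sigma.shape:
            raise ValueError("conc and sigma must have matching shapes")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "sigma", sigma)
        inc = self.included
        inc = np.ones(conc.shape, dtype=bool) if inc is None else np.asarray(inc, bool)
        object.__setattr__(self, "included", inc)


def hill_response(conc, ec50: float, h: float, floor: float = 0.0, ceiling: float = 1.0):
    """Hill curve in the paper's log10 parameterization; conc = 0 -> floor."""
    c = np.asarray(conc, dtype=float)
    out = np.full(c.shape, float(floor))
    pos = c > 0
    with np.errstate(over="ignore"):
        out[pos] = floor + (ceiling - floor) / (
            1.0 + 10.0 ** ((math.log10(ec50) - np.log10(c[pos])) * h)
        )
    return out if out.ndim else float(out)


def _spanning(responses: np.ndarray) -> bool:
    """False when all responses sit within 10% of one bound (flat series)."""
    span = responses.max() - responses.min()
    scale = max(abs(responses.max()), abs(responses.min()), 1e-300)
    return span > 0.1 * scale


def fit_hill(
    conc,
    response,
    fix_h_to_one: bool = False,
    T: float = T_DEFAULT,
) -> HillParams:
    """Least-squares Hill fit in log10-concentration space.

    Floor and ceiling are always fitted.  Requires >= 4 concentrations;
    data that do not span the transition are returned with
    ``identifiable=False`` and NaN parameters rather than raising.
    """
    c = np.asarray(conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if c.size < 4:
        raise ValueError("need at least four concentrations")
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    if not _spanning(y):
        return HillParams(
            ec50=float("nan"), h=float("nan"), floor=float(y.min()),
            ceiling=float(y.max()), identifiable=False, h_fixed=fix_h_to_one,
        )

    cpos = c[c > 0]
    lo, hi = math.log10(cpos.min()), math.log10(cpos.max())
    y_lo, y_hi = float(y.min()), float(y.max())

    def unpack(x):
        if fix_h_to_one:
            lec, fl, ce = x
            return lec, 1.0, fl, ce
        lec, logh, fl, ce = x
        return lec, math.exp(logh), fl, ce

    def resid(x):
        lec, h, fl, ce = unpack(x)
        return hill_response(c, 10.0**lec, h, fl, ce) - y

    best = None
    for lec0 in np.linspace(lo, hi, 5):
        x0 = [lec0, y_lo, y_hi] if fix_h_to_one else [lec0, 0.0, y_lo, y_hi]
        try:
            sol = optimize.least_squares(resid, x0, method="lm", max_nfev=5000)
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("Hill fit failed from every start")

    lec, h, fl, ce = unpack(best.x)
    ci = _ci95_from_jacobian(best, y.size)
    names = ["log10_ec50", "floor", "ceiling"] if fix_h_to_one \
        else ["log10_ec50", "log_h", "floor", "ceiling"]
    ci95 = dict(zip(names, ci))
    # delta method to natural scales
    ec50 = 10.0**lec
    ci95["ec50"] = ec50 * math.log(10.0) * ci95["log10_ec50"]
    ci95["h"] = h * ci95.get("log_h", 0.0) if not fix_h_to_one else 0.0
    return HillParams(
        ec50=ec50, h=h, floor=fl, ceiling=ce, ci95=ci95,
        h_fixed=fix_h_to_one, rss=float(2 * best.cost),
    )


def _ci95_from_jacobian(sol, n_obs: int) -> np.ndarray:
    """Asymptotic 95% half-widths from a least_squares solution."""
    J = sol.jac
    dof = n_obs - J.shape[1]
    rss = float(2 * sol.cost)
    if dof <= 0:
        return np.full(J.shape[1], float("nan"))
    try:
        cov = np.linalg.inv(J.T @ J) * rss / dof
    except np.linalg.LinAlgError:
        return np.full(J.shape[1], float("nan"))
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return stats.t.ppf(0.975, dof) * se


def exclude_low_affinity_phase(series: SigmaSeries, tol: float = 0.05) -> SigmaSeries:
    """Mask the low-affinity decay phase of a sigma series.

    Points up to the series maximum are retained; beyond the maximum,
    points whose sigma has fallen more than ``tol`` (fractional, default
    5%) below the maximum are masked.  Idempotent; never masks the maximum.
    """
    sigma = np.where(series.included, series.sigma, -np.inf)
    imax = int(np.argmax(sigma))
    smax = series.sigma[imax]
    keep = series.included.copy()
    after = np.arange(series.conc.size) > imax
    keep &= ~(after & (series.sigma < (1.0 - tol) * smax))
    return replace(series, included=keep)


def fit_sigma_series(series: SigmaSeries, fix_h_to_one: bool = False) -> HillParams:
    """Hill fit of sigma versus ligand concentration on the included points.

    Returns floor = sigma_min, ceiling = sigma_max.  Apply
    :func:`exclude_low_affinity_phase` first for constructs with a
    secondary decay.
    """
    c = series.conc[series.included]
    s = series.sigma[series.included]
    if c.size < 4:
        raise ValueError("need at least four included points")
    return fit_hill(c, s, fix_h_to_one=fix_h_to_one)


def fit_ec50_voltage(points, z_ca: int = 2, T: float = T_DEFAULT) -> VoltageEC50Fit:
    """Fit the voltage dependence of EC50.

    ``points`` is a sequence of (V_mV, ec50) pairs; the model is linear in
    log10 EC50 with slope -(1/ln 10) z_Ca f_V F / RT per volt, so the
    fitted slope gives z_Ca * f_V directly.
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need at least three voltages")
    v = np.array([p[0] for p in pts], dtype=float) * 1e-3
    ec = np.array([p[1] for p in pts], dtype=float)
    if np.any(ec <= 0):
        raise ValueError("EC50 values must be positive")
    res = stats.linregress(v, np.log10(ec))
    zf = -res.slope * math.log(10.0) * R * T / F
    dof = len(pts) - 2
    if dof > 0 and np.isfinite(res.stderr):
        tcrit = stats.t.ppf(0.975, dof)
        ci = {
            "zf_product": tcrit * res.stderr * math.log(10.0) * R * T / F,
            "log_ec50_0": tcrit * res.intercept_stderr,
        }
    else:
        ci = {"zf_product": float("nan"), "log_ec50_0": float("nan")}
    return VoltageEC50Fit(log_ec50_0=res.intercept, zf_product=zf, z_ca=z_ca, ci95=ci)


def rundown_correct(records) -> list[tuple[float, float]]:
    """Rundown-correct a time-ordered steady-state concentration-response run.

    ``records`` is a sequence of (epoch, conc, response, role) with role
    "reference" (saturating ligand) or "test".  Each test response is
    divided by the linear interpolation, in epoch, of its bracketing
    reference amplitudes; the corrected responses are then normalized to
    the maximal corrected response.  Unbracketed tests are dropped with a
    warning.  Returns (conc, normalized corrected response) pairs in input
    order.
    """
    recs = sorted(records, key=lambda r: r[0])
    refs = [(e, resp) for e, _c, resp, role in recs if role == "reference"]
    if not refs:
        raise ValueError("no reference applications present")
    out: list[tuple[float, float]] = []
    for epoch, conc_val, resp, role in recs:
        if role != "test":
            continue
        before = [(e, a) for e, a in refs if e <= epoch]
        after = [(e, a) for e, a in refs if e >= epoch]
        if not before or not after:
            warnings.warn(
                f"test at epoch {epoch} not bracketed by references; excluded",
                stacklevel=2,
            )
            continue
        e0, a0 = before[-1]
        e1, a1 = after[0]
        local = a0 if e1 == e0 else a0 + (a1 - a0) * (epoch - e0) / (e1 - e0)
        if local == 0:
            warnings.warn(f"zero reference amplitude at epoch {epoch}; excluded",
                          stacklevel=2)
            continue
        out.append((conc_val, resp / local))
    if not out:
        return out
    peak = max(abs(v) for _c, v in out)
    return [(c, v / peak) for c, v in out]
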