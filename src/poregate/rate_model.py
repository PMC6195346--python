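"""Three-barrier rate-theory model of anion permeation.

The open TMEM16A pore is described as a sequence of ``n`` Eyring barriers
(default ``n = 3``) equally spaced in a linear transmembrane field, with no
deep wells and no saturation.  The shape of the instantaneous I-V relation
is controlled by two dimensionless parameters:

* ``sigma_h`` — rate of crossing the middle barrier relative to the
  outermost barrier at 0 mV;
* ``sigma_beta`` — rate of crossing the innermost (intracellular-entrance)
  barrier relative to the outermost barrier at 0 mV.

For a linear voltage drop both ratios are voltage independent.  The current
carried by an ion of valence ``z`` between intracellular/extracellular
concentrations ``ci``/``co`` is

    I(V) = z F A e^{zFV/2nRT} (ci - co e^{-zFV/RT}) /
           [ e^{-zFV(n-1)/nRT}
             + (1/sigma_h) (1 - e^{-zFV(n-2)/nRT}) / (e^{zFV/nRT} - 1)
             + 1/sigma_beta ]

where ``A`` is an amplitude factor absorbing the absolute outer-barrier
crossing rate and an effective volume.  The middle term is the geometric
series over the n-2 interior barriers; at V = 0 it has the removable limit
n-2.  With symmetric solutions and sigma_h = sigma_beta = 1, n = 3, the
expression collapses to ``I = 2 z F A c sinh(zFV/6RT)``.  The current
reverses at the Nernst potential (RT/zF) ln(co/ci).

Sign convention: outward current (anion influx at positive V for z = -1)
is positive; voltages are mV at all public interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import F, R, T_DEFAULT, rt_kj

__all__ = [
    "IonCondition",
    "PermeationParams",
    "BarrierProfile",
    "current",
    "iv_curve",
    "rectification_index",
    "nernst_potential",
    "barrier_profile",
    "render_profile",
]


@dataclass(frozen=True)
class IonCondition:
    """Permeant-ion condition: concentrations (mM), valence and temperature.

    ``ci`` is the bath (intracellular) side of an inside-out patch.
    """

    ci: float = 150.0
    co: float = 150.0
    z: int = -1
    T: float = T_DEFAULT

    def __post_init__(self) -> None:
        if not (self.ci > 0 and self.co > 0):
            raise ValueError("ion concentrations must be positive")
        if self.T <= 0:
            raise ValueError("temperature must be positive (K)")
        if int(self.z) != self.z or self.z == 0:
            raise ValueError("ion valence must be a nonzero integer")


@dataclass(frozen=True)
class PermeationParams:
    """Free parameters of the barrier model plus the ionic condition."""

    A: float
    sigma_h: float
    sigma_beta: float
    n: int = 3
    condition: IonCondition = field(default_factory=IonCondition)

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("amplitude factor A must be positive")
        if self.sigma_h <= 0 or self.sigma_beta <= 0:
            raise ValueError("sigma_h and sigma_beta must be positive")
        if int(self.n) != self.n or self.n < 3:
            raise ValueError("barrier count n must be an integer >= 3")


@dataclass(frozen=True)
class BarrierProfile:
    """Barrier peak positions (electrical distance) and relative heights.

    Heights are kJ/mol relative to the outermost barrier, which is 0 by
    construction.  ``render_width`` is the purely cosmetic Gaussian sigma
    used by :func:`render_profile`.
    """

    positions: tuple[float, ...]
    rel_heights: tuple[float, ...]
    render_width: float = 0.08

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if not (np.all(np.diff(pos) > 0) and pos.min() > 0 and pos.max() < 1):
            raise ValueError("positions must be strictly increasing within (0, 1)")
        if len(self.positions) != len(self.rel_heights):
            raise ValueError("positions and rel_heights must have equal length")


def nernst_potential(cond: IonCondition) -> float:
    """Reversal (Nernst) potential in mV: (RT/zF) ln(co/ci)."""
    return R * cond.T / (cond.z * F) * np.log(cond.co / cond.ci) * 1e3


def _interior_series(u: np.ndarray, n: int) -> np.ndarray:
    """Sum_{k=1}^{n-2} exp(-k u / n) with the analytic u -> 0 limit n-2."""
    u = np.asarray(u, dtype=float)
    num = -np.expm1(-u * (n - 2) / n)
    den = np.expm1(u / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = num / den
    return np.where(u == 0.0, float(n - 2), s)


def current(params: PermeationParams, V):
    """Model current at membrane potential ``V`` (mV, scalar or array).

    Returns current on the scale set by ``params.A`` (z F A c units).  The
    removable singularity of the interior geometric-series term at the
    reversal of the single-barrier factor (V = 0) is evaluated analytically.
    """
    cond = params.condition
    v = np.asarray(V, dtype=float) * 1e-3
    if not np.all(np.isfinite(v)):
        raise ValueError("voltages must be finite")
    u = cond.z * F * v / (R * cond.T)
    n = params.n
    numer = (
        cond.z * F * params.A * np.exp(u / (2 * n))
        * (cond.ci - cond.co * np.exp(-u))
    )
    denom = (
        np.exp(-u * (n - 1) / n)
        + _interior_series(u, n) / params.sigma_h
        + 1.0 / params.sigma_beta
    )
    out = numer / denom
    return out if out.ndim else float(out)


def iv_curve(params: PermeationParams, voltages) -> list[tuple[float, float]]:
    """Evaluate the model on a voltage list, returning (V, I) pairs in order."""
    voltages = list(voltages)
    if not voltages:
        return []
    currents = np.atleast_1d(current(params, np.asarray(voltages, dtype=float)))
    return [(float(v), float(i)) for v, i in zip(voltages, currents)]


def rectification_index(curve, v_neg: float = -100.0, v_pos: float = 120.0) -> float:
    """Rectification index I(-100)/I(+120) of an I-V curve.

    The curve must contain the two voltages exactly; interpolation is not
    performed.
    """
    lookup = {}
    for v, i in curve:
        lookup[round(float(v), 6)] = float(i)
    for v_req in (v_neg, v_pos):
        if round(v_req, 6) not in lookup:
            raise ValueError(f"curve lacks required voltage {v_req} mV")
    i_pos = lookup[round(v_pos, 6)]
    if i_pos == 0.0:
        raise ZeroDivisionError("I at the positive reference voltage is zero")
    return lookup[round(v_neg, 6)] / i_pos


def barrier_profile(params: PermeationParams, render_width: float = 0.08) -> BarrierProfile:
    """Barrier positions and heights relative to the outermost barrier.

    For n = 3 equally spaced barriers in a linear field the peaks sit at
    electrical distances 1/6, 1/2 and 5/6 (outer -> inner on the
    extracellular-to-intracellular axis).  Relative heights follow from the
    rate ratios: dE = -RT ln(sigma), in kJ/mol.
    """
    if params.n != 3:
        raise ValueError("barrier_profile is defined for the n = 3 model")
    rt = rt_kj(params.condition.T)
    heights = (0.0, -rt * np.log(params.sigma_h), -rt * np.log(params.sigma_beta))
    return BarrierProfile(
        positions=(1.0 / 6.0, 0.5, 5.0 / 6.0),
        rel_heights=tuple(float(h) for h in heights),
        render_width=render_width,
    )


def render_profile(profile: BarrierProfile, grid, baseline: float = 0.0) -> np.ndarray:
    """Render a profile as a sum of Gaussians over ``grid`` (kJ/mol).

    Each barrier contributes a Gaussian of amplitude ``baseline +
    rel_height`` centred at its electrical position; peak values therefore
    equal baseline + height up to the (<1% at the default width) overlap of
    neighbouring Gaussians.  Purely a visualization aid.
    """
    x = np.asarray(grid, dtype=float)
    if x.size and (x.min() < 0 or x.max() > 1):
        raise ValueError("grid must lie within [0, 1]")
    w = profile.render_width
    trace = np.zeros_like(x)
    for pos, h in zip(profile.positions, profile.rel_heights):
        trace += (baseline + h) * np.exp(-((x - pos) ** 2) / (2 * w**2))
    return trace
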