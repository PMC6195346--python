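"""Decomposition of I-V curves into Ca2+-occupancy open states.

A whole-cell or macro-patch I-V relation is modelled as a nonnegative
weighted sum of three basis I-V curves computed from the rate model:

    I_total(V) = i * I_0Ca(V) + j * I_1Ca(V) + k * I_2Ca(V)

with basis parameters taken from constructs trapped in the corresponding
occupancy (zero-, one- and two-Ca2+-bound open states).  The weights are
unconstrained in sum — they absorb open probability and channel count — and
are estimated by nonnegative least squares.  For constructs without basal
activity the zero-occupancy term may be omitted (``omit_zero``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .rate_model import PermeationParams, current

__all__ = ["BasisSet", "StateWeights", "compose_iv", "fit_state_weights",
           "weight_fractions"]


@dataclass(frozen=True)
class BasisSet:
    """Rate-model parameters of the 0-, 1- and 2-Ca2+-occupied open states."""

    params_0ca: PermeationParams
    params_1ca: PermeationParams
    params_2ca: PermeationParams

    def matrix(self, voltages) -> np.ndarray:
        """Basis currents as columns of an (n_voltages, 3) matrix."""
        v = np.asarray(voltages, dtype=float)
        cols = [np.atleast_1d(current(p, v))
                for p in (self.params_0ca, self.params_1ca, self.params_2ca)]
        return np.column_stack(cols)


@dataclass(frozen=True)
class StateWeights:
    """Nonnegative mixture weights for the three occupancy states."""

    i: float
    j: float
    k: float
    ci95: dict = field(default_factory=dict)
    omit_zero: bool = False
    identifiable: bool = True

    def __post_init__(self) -> None:
        if min(self.i, self.j, self.k) < 0:
            raise ValueError("state weights must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.i, self.j, self.k])


def compose_iv(weights: StateWeights, basis: BasisSet, voltages) -> np.ndarray:
    """Point-wise weighted sum of the three basis curves."""
    return basis.matrix(voltages) @ weights.as_array()


def fit_state_weights(
    voltages, currents, basis: BasisSet, omit_zero: bool = False
) -> StateWeights:
    """Nonnegative least-squares estimate of the occupancy weights.

    With ``omit_zero`` the zero-occupancy weight is fixed at 0.  95%
    half-widths come from the linearized covariance restricted to the
    active (nonzero) weights.  A basis that is numerically collinear on the
    given voltage grid is returned with ``identifiable=False``.
    """
    v = np.asarray(voltages, dtype=float)
    y = np.asarray(currents, dtype=float)
    if v.size < 4:
        raise ValueError("need at least four voltages")
    B = basis.matrix(v)
    cols = [1, 2] if omit_zero else [0, 1, 2]
    Bc = B[:, cols]
    # collinearity on this grid makes the weights unidentifiable
    sv = np.linalg.svd(Bc / np.linalg.norm(Bc, axis=0), compute_uv=False)
    identifiable = bool(sv[-1] > 1e-8)
    w_sub, _ = optimize.nnls(Bc, y)
    w = np.zeros(3)
    w[cols] = w_sub
    ci: dict = {}
    resid = y - Bc @ w_sub
    dof = y.size - len(cols)
    if identifiable and dof > 0:
        active = [c for c, wi in zip(cols, w_sub) if wi > 0]
        if active:
            Ba = B[:, active]
            s2 = float(resid @ resid) / dof
            try:
                cov = np.linalg.inv(Ba.T @ Ba) * s2
                half = stats.t.ppf(0.975, dof) * np.sqrt(np.diag(cov))
                ci = {"ijk"[c]: float(h) for c, h in zip(active, half)}
            except np.linalg.LinAlgError:
                pass
    return StateWeights(i=float(w[0]), j=float(w[1]), k=float(w[2]),
                        ci95=ci, omit_zero=omit_zero, identifiable=identifiable)


def weight_fractions(weights: StateWeights) -> tuple[float, float, float]:
    """Weights normalized to sum to one (occupancy fractions)."""
    w = weights.as_array()
    total = float(w.sum())
    if total <= 0:
        raise ValueError("at least one weight must be positive")
    frac = w / total
    return float(frac[0]), float(frac[1]), float(frac[2])
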