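"""Sweep-table I/O, run configuration and the end-to-end pipeline.

Input is a long-format delimited text table with exactly the columns

    patch_id, epoch, ligand, conc_nM, prepulse_mV, prepulse_pA, V_mV, I_pA

(one row per voltage step).  Results are emitted as JSON with provenance
(input digest, options, seed).  No binary acquisition formats are read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .electro_energetics import delta_Ea
from .iv_pipeline import (IVRecording, QCPolicy, Sweep, aggregate_patches,
                          fit_iv, normalize_prepulse, normalize_reference,
                          qc_filter, sweeps_to_recordings)
from .ligand_modulation import (SigmaSeries, exclude_low_affinity_phase,
                                fit_sigma_series)
from .rate_model import IonCondition

__all__ = ["SWEEP_COLUMNS", "RunConfig", "PipelineError", "read_sweeps",
           "write_sweeps", "sweeps_to_frame", "run_pipeline"]

SWEEP_COLUMNS = ("patch_id", "epoch", "ligand", "conc_nM", "prepulse_mV",
                 "prepulse_pA", "V_mV", "I_pA")

_NUMERIC = {"epoch": int, "conc_nM": float, "prepulse_mV": float,
            "prepulse_pA": float, "V_mV": float, "I_pA": float}


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and any partial results."""

    def __init__(self, stage: str, message: str, partial: dict | None = None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.partial = partial or {}


def read_sweeps(path, sep: str = ",") -> tuple[list[Sweep], list[dict]]:
    """Read a sweep table; returns (sweeps, malformed-row report).

    Missing columns raise immediately, naming them; rows that fail type
    coercion or the Sweep invariants are collected into the report with
    their row index and reason, never silently dropped.
    """
    frame = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in SWEEP_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    sweeps: list[Sweep] = []
    errors: list[dict] = []
    for idx, row in frame.iterrows():
        try:
            kwargs = {"patch_id": str(row["patch_id"]),
                      "ligand": str(row["ligand"])}
            for col, typ in _NUMERIC.items():
                kwargs[{"conc_nM": "conc", "prepulse_mV": "prepulse_V",
                        "prepulse_pA": "I_prepulse", "V_mV": "V",
                        "I_pA": "I", "epoch": "epoch"}[col]] = typ(row[col])
            sweeps.append(Sweep(**kwargs))
        except (TypeError, ValueError) as exc:
            errors.append({"row": int(idx), "reason": str(exc)})
    return sweeps, errors


def sweeps_to_frame(sweeps: list[Sweep]) -> pd.DataFrame:
    rows = [(s.patch_id, s.epoch, s.ligand, s.conc, s.prepulse_V,
             s.I_prepulse, s.V, s.I) for s in sweeps]
    return pd.DataFrame(rows, columns=list(SWEEP_COLUMNS))


def write_sweeps(sweeps, path, sep: str = ",") -> None:
    """Write sweeps (list of Sweep or a sweep-table DataFrame) as text."""
    frame = sweeps if isinstance(sweeps, pd.DataFrame) else sweeps_to_frame(sweeps)
    frame.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run; round-trips through JSON.

    Unknown keys in a serialized config are rejected.
    """

    input_path: str = ""
    seed: int = 0
    ci: float = 150.0
    co: float = 150.0
    z: int = -1
    T: float = 293.15
    bracket_drift: float = 0.20
    leak_ratio_max: float = 0.40
    exclusion_tol: float = 0.05
    fix_h_to_one: bool = False
    prepulse_normalize: bool = True

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def condition(self) -> IonCondition:
        return IonCondition(ci=self.ci, co=self.co, z=self.z, T=self.T)

    def qc_policy(self) -> QCPolicy:
        return QCPolicy(bracket_drift=self.bracket_drift,
                        leak_ratio_max=self.leak_ratio_max)


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis chain on a sweep table.

    normalize (pre-pulse) -> QC -> per-recording rate-model fits ->
    cross-patch sigma series -> Hill fits -> barrier energetics.
    Deterministic given input + config; the result bundle carries
    provenance.  Stage failures raise :class:`PipelineError` with partial
    results attached.
    """
    bundle: dict = {
        "provenance": {
            "package": "poregate", "version": __version__,
            "config": config.to_dict(),
            "input_digest": _digest(config.input_path) if config.input_path else None,
        }
    }
    sweeps, errors = read_sweeps(config.input_path)
    bundle["read_errors"] = errors
    if not sweeps:
        raise PipelineError("read", "no valid sweeps in input", bundle)

    stage = "qc"
    try:
        by_patch: dict[str, list] = {}
        for s in sweeps:
            by_patch.setdefault(s.patch_id, []).append(s)
        kept_sweeps, rejected = [], []
        for pid in sorted(by_patch):
            ok, bad = qc_filter(by_patch[pid], config.qc_policy())
            if ok:
                kept_sweeps.extend(by_patch[pid])
            rejected.extend(bad)
        bundle["qc"] = {"kept_patches": sorted({s.patch_id for s in kept_sweeps}),
                        "rejected": [{"patch_id": p, "reason": r}
                                     for p, r in rejected]}
        if not kept_sweeps:
            raise ValueError("no patch passed QC")
    except Exception as exc:
        raise PipelineError(stage, str(exc), bundle) from exc

    stage = "normalize"
    try:
        if config.prepulse_normalize:
            kept_sweeps = normalize_prepulse(kept_sweeps)
        kept = sweeps_to_recordings(
            kept_sweeps, "prepulse" if config.prepulse_normalize else "raw")
    except Exception as exc:
        raise PipelineError(stage, str(exc), bundle) from exc

    stage = "fit_iv"
    try:
        cond = config.condition()
        fits = []
        for rec in kept:
            if rec.conc == 0 and not any(abs(i) > 0 for _, i in rec.points):
                continue  # silent zero-ligand recording (no basal activity)
            res = fit_iv(rec, cond)
            fits.append({"patch_id": rec.patch_id, "ligand": rec.ligand,
                         "conc_nM": rec.conc, "sigma_h": res.sigma_h,
                         "sigma_beta": res.sigma_beta, "A": res.A,
                         "ci95": res.ci95, "rss": res.rss,
                         "converged": res.converged})
        bundle["iv_fits"] = fits
    except Exception as exc:
        raise PipelineError(stage, str(exc), bundle) from exc

    # sigma-vs-concentration series from fits of the cross-patch mean
    # normalized I-V curve at each concentration (the fits of individual
    # recordings above are reported but not averaged: sigma_h is weakly
    # identified in single noisy low-Ca recordings)
    stage = "sigma_series"
    try:
        ligand = kept[0].ligand if kept else "Ca"
        by_conc: dict[float, list[IVRecording]] = {}
        for rec in kept:
            by_conc.setdefault(rec.conc, []).append(rec)
        peak = max(max(abs(i) for _, i in rec.points) for rec in kept)
        mean_fits: dict[float, object] = {}
        for conc, recs in sorted(by_conc.items()):
            if conc == 0 and all(
                max(abs(i) for _, i in r.points) < 0.05 * peak for r in recs
            ):
                continue  # silent zero-ligand recordings (no basal activity)
            normed = [normalize_reference(r) for r in recs]
            grid, mean, _sem = aggregate_patches(normed)
            mean_rec = IVRecording(patch_id="mean", ligand=ligand, conc=conc,
                                   points=tuple(zip(grid, mean)),
                                   norm_state="reference")
            mean_fits[conc] = fit_iv(mean_rec, cond)
        concs = [c for c, f in mean_fits.items() if f.converged]
        series_out = {}
        for name in ("sigma_beta", "sigma_h"):
            vals = [getattr(mean_fits[c], name) for c in concs]
            series = SigmaSeries(ligand=ligand, voltage=80.0,
                                 conc=np.array(concs), sigma=np.array(vals))
            if name == "sigma_beta":
                # the secondary low-affinity decay is a sigma_beta phenomenon
                series = exclude_low_affinity_phase(series, config.exclusion_tol)
            entry = {"conc_nM": list(series.conc), "sigma": list(series.sigma),
                     "included": [bool(b) for b in series.included]}
            if int(series.included.sum()) >= 4:
                hp = fit_sigma_series(series, fix_h_to_one=config.fix_h_to_one)
                entry["hill"] = {"ec50_nM": hp.ec50, "h": hp.h,
                                 "sigma_min": hp.floor, "sigma_max": hp.ceiling,
                                 "ci95": hp.ci95,
                                 "identifiable": hp.identifiable}
                if name == "sigma_beta" and hp.identifiable:
                    entry["dEa_kJmol"] = {
                        "zero_ligand": delta_Ea(hp.floor, config.T)
                        if hp.floor > 0 else None,
                        "saturating": delta_Ea(hp.ceiling, config.T)
                        if hp.ceiling > 0 else None,
                    }
            series_out[name] = entry
        bundle["sigma_series"] = series_out
    except Exception as exc:
        raise PipelineError(stage, str(exc), bundle) from exc
    return bundle
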