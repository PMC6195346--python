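"""Normalization, QC and rate-model fitting of I-V families."""

import numpy as np
import pytest

from conftest import table_to_sweeps
from poregate.iv_pipeline import (IVRecording, QCPolicy, Sweep,
                                  aggregate_patches, background_subtract,
                                  fit_iv, normalize_prepulse,
                                  normalize_reference, qc_filter,
                                  sweeps_to_recordings)
from poregate.rate_model import IonCondition, PermeationParams, current
from poregate.synthetic import GeneratorConfig, NoiseModel, Protocol, generate_patch


def make_recording(params, voltages, conc=1000.0, noise=None, rng=None,
                   patch_id="p0"):
    i = np.atleast_1d(current(params, voltages)).astype(float)
    if noise:
        i = i + rng.normal(0.0, noise, i.shape)
    return IVRecording(patch_id=patch_id, ligand="Ca", conc=conc,
                       points=tuple(zip(voltages, i)))


class TestNormalizePrepulse:
    def test_equal_prepulses_leave_currents_unchanged(self):
        sweeps = [Sweep("p", e, "Ca", 100.0, V=v, I=v * 2.0, I_prepulse=100.0)
                  for e, v in enumerate((-100.0, 0.0, 120.0))]
        out = normalize_prepulse(sweeps)
        assert [s.I for s in out] == [s.I for s in sweeps]

    def test_ten_percent_rundown_rescaled_to_median(self):
        sweeps = [
            Sweep("p", 0, "Ca", 100.0, V=120.0, I=240.0, I_prepulse=100.0),
            Sweep("p", 1, "Ca", 100.0, V=-100.0, I=-90.0, I_prepulse=90.0),
        ]
        out = normalize_prepulse(sweeps)
        med = 95.0
        assert out[0].I == pytest.approx(240.0 * med / 100.0)
        assert out[1].I == pytest.approx(-90.0 * med / 90.0)

    def test_zero_prepulse_excluded_with_warning(self):
        sweeps = [Sweep("p", 0, "Ca", 1.0, V=120.0, I=1.0, I_prepulse=0.0),
                  Sweep("p", 1, "Ca", 1.0, V=100.0, I=1.0, I_prepulse=2.0)]
        with pytest.warns(UserWarning, match="zero pre-pulse"):
            out = normalize_prepulse(sweeps)
        assert len(out) == 1 and out[0].V == 100.0

    def test_recovers_amplitude_across_trains(self, protocol_voltages):
        """Three trains at one condition with 12% rundown: after pre-pulse
        correction the fitted amplitude factor is identical across trains."""
        cond = IonCondition()
        p = PermeationParams(A=2e-5, sigma_h=0.5, sigma_beta=0.3, condition=cond)
        n = len(protocol_voltages)
        per_step = (1.0 - 0.12) ** (1.0 / n)
        sweeps, scale, epoch = [], 1.0, 0
        for _train in range(3):
            for v in protocol_voltages:
                i_pp = scale * float(current(p, 80.0))
                sweeps.append(Sweep("p", epoch, "Ca", 1000.0, V=float(v),
                                    I=scale * float(current(p, v)),
                                    I_prepulse=i_pp))
                scale *= per_step
                epoch += 1
        corrected = normalize_prepulse(sweeps)
        fits = []
        for train in range(3):
            sub = corrected[train * n:(train + 1) * n]
            rec = IVRecording("p", "Ca", 1000.0, tuple((s.V, s.I) for s in sub))
            fits.append(fit_iv(rec, cond).A)
        assert np.ptp(fits) / np.mean(fits) < 0.01


class TestNormalizeReference:
    def test_reference_maps_to_one(self, rectifying_params, protocol_voltages):
        rec = make_recording(rectifying_params, protocol_voltages)
        out = normalize_reference(rec)
        assert dict(out.points)[120.0] == pytest.approx(1.0)

    def test_scale_invariance(self, rectifying_params, protocol_voltages):
        rec = make_recording(rectifying_params, protocol_voltages)
        scaled = IVRecording("p0", "Ca", 1000.0,
                             tuple((v, 37.0 * i) for v, i in rec.points))
        a = normalize_reference(rec).points
        b = normalize_reference(scaled).points
        assert np.allclose([i for _, i in a], [i for _, i in b], rtol=1e-12)

    def test_symmetric_value_at_minus_100(self, symmetric_params,
                                          protocol_voltages):
        out = normalize_reference(
            make_recording(symmetric_params, protocol_voltages))
        assert dict(out.points)[-100.0] == pytest.approx(-0.81, abs=0.005)

    def test_idempotent(self, rectifying_params, protocol_voltages):
        rec = make_recording(rectifying_params, protocol_voltages)
        once = normalize_reference(rec)
        again = IVRecording("p0", "Ca", 1000.0, once.points)  # fresh state tag
        assert np.allclose([i for _, i in normalize_reference(again).points],
                           [i for _, i in once.points], rtol=1e-12)

    def test_missing_reference_errors(self, rectifying_params):
        rec = make_recording(rectifying_params, np.array([-100.0, 0.0, 100.0]))
        with pytest.raises(ValueError):
            normalize_reference(rec)

    def test_norm_state_only_advances(self, rectifying_params, protocol_voltages):
        rec = make_recording(rectifying_params, protocol_voltages)
        out = normalize_reference(rec)
        assert out.norm_state == "reference"
        with pytest.raises(ValueError):
            normalize_reference(out)


class TestBackgroundSubtract:
    def test_self_subtraction_zero(self, rectifying_params, protocol_voltages):
        rec = make_recording(rectifying_params, protocol_voltages)
        out = background_subtract(rec, rec)
        assert all(i == 0 for _, i in out.points)
        assert out.norm_state == "background-subtracted"

    def test_zero_background_identity(self, rectifying_params, protocol_voltages):
        rec = make_recording(rectifying_params, protocol_voltages)
        zero = IVRecording("p0", "none", 0.0,
                           tuple((v, 0.0) for v in protocol_voltages))
        out = background_subtract(rec, zero)
        assert np.allclose([i for _, i in out.points],
                           [i for _, i in rec.points])

    def test_mismatched_grid_errors(self, rectifying_params, protocol_voltages):
        rec = make_recording(rectifying_params, protocol_voltages)
        other = make_recording(rectifying_params, protocol_voltages[:-1])
        with pytest.raises(ValueError):
            background_subtract(rec, other)

    def test_recovers_leak_free_truth(self, protocol_voltages):
        """A leak-contaminated silent-at-rest recording minus its zero-ligand
        trace recovers the leak-free channel current within noise."""
        cfg = GeneratorConfig(
            construct="WT",
            noise=NoiseModel(current_sd=0.005, rundown_per_train=0.0, leak=0.5),
            seed=4,
        )
        table, truth = generate_patch(cfg, 0)
        recs = sweeps_to_recordings(table_to_sweeps(table))
        sat = next(r for r in recs if r.conc == 10000.0)
        zero = next(r for r in recs if r.conc == 0.0)
        out = background_subtract(sat, zero)
        cond = IonCondition()
        p = PermeationParams(A=truth["A"],
                             sigma_h=truth["conditions"][10000.0]["sigma_h"],
                             sigma_beta=truth["conditions"][10000.0]["sigma_beta"],
                             condition=cond)
        want = current(p, protocol_voltages)
        resid = np.array([i for _, i in out.points]) - want
        assert np.max(np.abs(resid)) < 4 * truth["noise_sd"] * np.sqrt(2)


class TestQCFilter:
    @staticmethod
    def _patch_sweeps(seed=0, **noise_kwargs):
        cfg = GeneratorConfig(seed=seed, noise=NoiseModel(**noise_kwargs))
        table, truth = generate_patch(cfg, 0)
        return table_to_sweeps(table), truth

    def test_clean_patch_kept(self):
        sweeps, _ = self._patch_sweeps(current_sd=0.01, rundown_per_train=0.12,
                                       leak=0.02)
        kept, rejected = qc_filter(sweeps)
        assert rejected == [] and len(kept) == 8

    def test_unbracketed_rejected(self):
        sweeps, _ = self._patch_sweeps(current_sd=0.01)
        no_tail = [s for s in sweeps if s.epoch < 84]  # drop closing bracket
        kept, rejected = qc_filter(no_tail)
        assert kept == [] and rejected == [("p000", "unbracketed")]

    def test_grown_brackets_rejected_as_deteriorated(self):
        sweeps, _ = self._patch_sweeps(current_sd=0.0, rundown_per_train=0.0)
        last = max(s.epoch for s in sweeps)
        doubled = [s if s.epoch <= last - 12 else
                   Sweep(s.patch_id, s.epoch, s.ligand, s.conc, s.V,
                         2.0 * s.I, s.I_prepulse, s.prepulse_V)
                   for s in sweeps]
        kept, rejected = qc_filter(doubled)
        assert rejected == [("p000", "deteriorated")]

    def test_leaky_cohort_exactly_identified(self):
        """10% injected leaky patches: all and only those are rejected."""
        cfg = GeneratorConfig(
            seed=11,
            protocol=Protocol(n_patches=10),
            noise=NoiseModel(current_sd=0.02, rundown_per_train=0.12,
                             leak=0.02, leaky_rate=0.2, leaky_leak=1.0),
        )
        truth_leaky, rejected = set(), {}
        for idx in range(cfg.protocol.n_patches):
            table, truth = generate_patch(cfg, idx)
            if truth["leaky"]:
                truth_leaky.add(truth["patch_id"])
            _, rej = qc_filter(table_to_sweeps(table))
            rejected.update(dict(rej))
        assert set(rejected) == truth_leaky
        assert all(reason == "leaky" for reason in rejected.values())

    def test_deterministic(self):
        sweeps, _ = self._patch_sweeps(current_sd=0.02, rundown_per_train=0.12)
        assert qc_filter(sweeps, QCPolicy()) == qc_filter(sweeps, QCPolicy())


class TestFitIV:
    def test_noiseless_roundtrip(self, symmetric_condition, protocol_voltages):
        p = PermeationParams(A=1.0, sigma_h=0.5, sigma_beta=0.1,
                             condition=symmetric_condition)
        res = fit_iv(make_recording(p, protocol_voltages), symmetric_condition)
        assert res.converged
        assert res.A == pytest.approx(1.0, rel=1e-6)
        assert res.sigma_h == pytest.approx(0.5, rel=1e-6)
        assert res.sigma_beta == pytest.approx(0.1, rel=1e-6)

    def test_scale_equivariance(self, symmetric_condition, protocol_voltages):
        p = PermeationParams(A=1.0, sigma_h=0.5, sigma_beta=0.1,
                             condition=symmetric_condition)
        rec = make_recording(p, protocol_voltages)
        scaled = IVRecording("p0", "Ca", 1000.0,
                             tuple((v, 37.0 * i) for v, i in rec.points))
        res = fit_iv(scaled, symmetric_condition)
        assert res.A == pytest.approx(37.0, rel=1e-6)
        assert res.sigma_beta == pytest.approx(0.1, rel=1e-6)

    @pytest.mark.parametrize("sigma_h", [0.05, 0.2, 1.0, 3.0])
    @pytest.mark.parametrize("sigma_beta", [0.05, 0.2, 1.0, 3.0])
    def test_consistency_grid(self, sigma_h, sigma_beta, symmetric_condition,
                              protocol_voltages):
        p = PermeationParams(A=2e-5, sigma_h=sigma_h, sigma_beta=sigma_beta,
                             condition=symmetric_condition)
        res = fit_iv(make_recording(p, protocol_voltages), symmetric_condition)
        assert res.sigma_h == pytest.approx(sigma_h, rel=1e-4)
        assert res.sigma_beta == pytest.approx(sigma_beta, rel=1e-4)

    def test_normalized_curve_same_sigmas(self, symmetric_condition,
                                          protocol_voltages):
        p = PermeationParams(A=2e-5, sigma_h=0.3, sigma_beta=0.08,
                             condition=symmetric_condition)
        rec = make_recording(p, protocol_voltages)
        res_raw = fit_iv(rec, symmetric_condition)
        res_norm = fit_iv(normalize_reference(rec), symmetric_condition)
        assert res_norm.sigma_h == pytest.approx(res_raw.sigma_h, rel=1e-6)
        assert res_norm.sigma_beta == pytest.approx(res_raw.sigma_beta, rel=1e-6)
        i120 = dict(rec.points)[120.0]
        assert res_norm.A == pytest.approx(res_raw.A / abs(i120), rel=1e-6)

    def test_median_recovery_under_noise(self, symmetric_condition,
                                         protocol_voltages):
        """2% additive noise: median recovered sigma_beta within 5% of truth."""
        p = PermeationParams(A=2e-5, sigma_h=0.5, sigma_beta=0.3,
                             condition=symmetric_condition)
        i0 = current(p, protocol_voltages)
        sd = 0.02 * np.max(np.abs(i0))
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(100):
            rec = IVRecording("p", "Ca", 100.0, tuple(
                zip(protocol_voltages, i0 + rng.normal(0, sd, i0.shape))))
            vals.append(fit_iv(rec, symmetric_condition).sigma_beta)
        assert np.median(vals) == pytest.approx(0.3, rel=0.05)

    def test_insufficient_points_error(self, symmetric_condition):
        p = PermeationParams(A=1.0, sigma_h=1.0, sigma_beta=1.0,
                             condition=symmetric_condition)
        rec = make_recording(p, np.array([20.0, 40.0, 60.0, 80.0, 100.0, 120.0]))
        with pytest.raises(ValueError):
            fit_iv(rec, symmetric_condition)


class TestAggregatePatches:
    def test_identical_patches_zero_sem(self, rectifying_params,
                                        protocol_voltages):
        recs = [make_recording(rectifying_params, protocol_voltages,
                               patch_id=f"p{k}") for k in range(3)]
        _, mean, sem = aggregate_patches(recs)
        assert np.allclose(sem, 0.0)
        assert np.allclose(mean, [i for _, i in recs[0].points])

    def test_two_scalar_patches(self):
        mean, sem = aggregate_patches([1.0, 3.0])
        assert mean == 2.0 and sem == pytest.approx(1.0)

    def test_single_patch_flagged(self, rectifying_params, protocol_voltages):
        _, _, sem = aggregate_patches(
            [make_recording(rectifying_params, protocol_voltages)])
        assert np.all(np.isnan(sem))

    def test_sem_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(0)
        sems = []
        for n in (8, 32, 128):
            sems.append(np.mean([aggregate_patches(list(rng.normal(0, 1, n)))[1]
                                 for _ in range(200)]))
        assert sems[0] / sems[1] == pytest.approx(2.0, rel=0.15)
        assert sems[1] / sems[2] == pytest.approx(2.0, rel=0.15)
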