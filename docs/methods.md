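# Methods

## Permeation model

The core model (`rate_model.current`) treats the open pore as *n* equally
spaced Eyring barriers in a linear transmembrane field, with no wells and no
saturation — appropriate for a pore with high K_M for its permeant ion. All
analyses fix *n* = 3 (outer and inner dehydration barriers flanking a small
central diffusion barrier). Because only rate *ratios* shape the I-V curve,
the free parameters are the amplitude factor `A` (absorbing the absolute
outer-barrier rate and an effective volume) and the relative crossing rates
`σ_h` (middle) and `σ_β` (innermost). For a linear voltage drop the σ are
voltage independent.

Verification contract (tested, not assumed): the implementation reverses at
the Nernst potential `(RT/zF)·ln(c_o/c_i)` to machine precision, is ohmic
near 0 mV for symmetric solutions, collapses to
`I = 2zFAc·sinh(zFV/6RT)` when σ_h = σ_β = 1 with c_i = c_o = c, and gives
outward rectification for σ_β < 1 with z = −1. The interior
geometric-series term has a removable singularity at V = 0 that is
evaluated analytically (`expm1` ratio with an exact value of n−2 at 0).

Conventions: voltages in mV at every public interface (volts internally);
outward current positive; z = −1 for Cl⁻; `ci` is the bath side of an
inside-out patch; energies in kJ/mol; R = 8.314 J mol⁻¹ K⁻¹ and
F = 96485 C mol⁻¹ from scipy's CODATA tables; default T = 293.15 K (20 °C).

Barrier profiles place the three peaks at electrical distances 1/6, 1/2 and
5/6 — the positions implied by n = 3 equally spaced barriers — with heights
(0, −RT ln σ_h, −RT ln σ_β) relative to the outermost barrier. The
Gaussian rendering width (0.08 electrical-distance units) is purely
cosmetic.

A limiting subtlety: as σ_β → 0 the rectification index I(−100)/I(+120)
does not go to 0 but to the ratio of the voltage-dependent numerator
factors (≈ 0.037 for the standard protocol), because 1/σ_β eventually
dominates the denominator at *every* voltage.

## I-V reduction chain

`iv_pipeline` reproduces the experimental data-reduction order:

1. **Pre-pulse normalization** divides each sweep's currents by its
   pre-pulse amplitude relative to the recording median (median chosen for
   robustness; the reference point is otherwise arbitrary). This removes
   multiplicative rundown *within* a recording; absolute amplitudes across
   recordings remain affected by cumulative rundown, which is why σ (shape)
   rather than A (scale) carries the biology.
2. **QC.** Each session is bracketed by zero-ligand recordings. The paper
   gives only a qualitative rule ("leaky patches were discarded"), so the
   implemented policy is an explicit, configurable stand-in with two
   scale-free, one-sided tests — one-sided because irreversible rundown can
   only shrink currents in a healthy patch, whereas leak and deterioration
   make them grow:
   - *leaky*: a zero-ligand recording above an amplitude floor
     (`amp_floor_frac` = 0.15 of the patch's largest median pre-pulse
     amplitude) whose inward branch (V ≤ −40 mV) exceeds
     `leak_ratio_max` = 0.40 of its outward branch. Ohmic leak is linear;
     genuine zero-ligand channel current is strongly outwardly rectifying.
   - *deteriorated*: the closing bracket's mean |I| exceeds the opening
     bracket's by more than `bracket_drift` = 0.20, provided it is above the
     amplitude floor.
   Patches without two bracketing zero-ligand recordings are rejected as
   *unbracketed*.
3. **Model fit.** Nonlinear least squares (scipy `least_squares`) with σ
   fitted in log space, multi-start over six log-spaced σ pairs, lowest RSS
   kept. log σ is box-bounded to ±7: when σ_β is small its 1/σ_β term
   dominates the denominator and σ_h becomes nearly unidentifiable in a
   single noisy recording; the bound stops runaway drift along that flat
   direction. 95 % confidence half-widths are asymptotic (t-quantile ×
   linearized covariance), transported to the natural scale by the delta
   method. Residuals are unweighted by default (per-point weights
   optional).
4. **Aggregation.** Mean ± s.e.m. (sd/√N) across patches; a single patch
   returns NaN s.e.m. The orchestrated pipeline (`io.run_pipeline`) fits
   the *cross-patch mean reference-normalized curve* per concentration —
   as the experimental figures do — rather than averaging per-patch σ
   fits, precisely because of the weak σ_h identifiability noted above.

## Ligand modulation

Hill fits are performed in log₁₀-concentration space,
`response = floor + (ceiling − floor)/(1 + 10^{(log EC50 − log c)·h})`, with
floor and ceiling always free and h optionally fixed to 1 (single-site
ligands such as Mg²⁺). Zero concentration is the floor by the limit of the
Hill form. Data not spanning the transition are flagged unidentifiable
rather than fitted.

The secondary low-affinity decay of σ_β seen in some binding-site mutants
is handled by `exclude_low_affinity_phase`: points up to the series maximum
are retained and points beyond it that fall more than 5 % (configurable)
below the maximum are masked. The rule is idempotent and never removes the
maximum. The orchestrated pipeline applies it to σ_β only — the decay is a
σ_β phenomenon, and applying it to a noisy σ_h series can mask the
saturating point.

EC50-versus-voltage data are fitted as a line in log₁₀ EC50 with slope
−z_Ca·f_V·F/(ln 10·RT); the slope yields the product z_Ca·f_V directly and
f_V after dividing by the cation valence.

Rundown correction of steady-state concentration-response runs divides each
test response by the epoch-linear interpolation of the bracketing
saturating-reference amplitudes, then normalizes to the maximal corrected
response. This bracketed-interpolation scheme is a documented stand-in for
the protocol described in the cited prior work; unbracketed tests are
dropped with a warning.

## Coulombic energetics

`ΔE_a(in−out) = −RT ln σ_β` and `ΔΔG_obs = RT ln(EC50/EC50_bg)` are exact
transforms. Valence bookkeeping counts the five acidic binding-site
residues (Glu654, Glu702, Glu705, Glu734, Asp738; Glu/Asp −1, Gln/Ser 0,
Arg +1) plus +2 per bound Ca²⁺/Mg²⁺ and +3 per Gd³⁺; the pore-entrance
Δz_pore is 0 for WT, −1 for Lys→Ser and −2 for Lys→Glu.

Energy-versus-valence relations are fitted as straight lines; the effective
relative permittivity follows from the slope at a fixed, structure-derived
distance (binding site to innermost barrier 13.6 Å; to the Lys588/Lys645
amine nitrogens 11.9/10.6 Å). The Coulomb prefactor
K = N_A·q²/(4πε₀) ≈ 1389.35 kJ Å mol⁻¹ is computed from CODATA constants at
import time. The ε_r confidence interval is propagated from the slope CI by
the delta method (the source data report ± without stating a method). A
slope with the unphysical sign is returned flagged rather than raising.
Fitted ε_r values are reported with CIs and deliberately not interpreted
further: with 3–6 points on a line they are order-of-magnitude statements
about solvent screening, not dielectric measurements.

`axial_potential` is an explicitly simplified screened-Coulomb
(Debye–Hückel) calculator — uniform dielectric, point charges on the pore
axis, λ_D from the stated ionic strength (≈7.9 Å at 150 mM, ε_r 80) — used
only to reproduce ordering and monotonicity trends of occupancy and
neutralization series. It does not reproduce membrane-embedded
linearized-Poisson-Boltzmann potentials (protein/membrane dielectric
boundaries are absent), and no claim is made about absolute values.

## Occupancy decomposition

`fit_state_weights` solves a nonnegative least-squares problem (scipy
`nnls`) for the mixture weights of fixed zero-, one- and two-Ca²⁺ basis
curves; nonnegativity is enforced by the solver (active-set KKT), never by
clipping. No sum-to-one constraint is imposed — the weights absorb open
probability and channel count; normalized fractions are a separate view.
Basis parameters are supplied, not refitted. Weights are fitted per
concentration independently; a basis that is numerically collinear on the
given voltage grid is flagged unidentifiable. CIs come from the linearized
covariance restricted to the active weights.

## Synthetic data: what it emulates, what it does not

`synthetic.generate_patch` emulates an inside-out-patch session: a
zero-ligand bracket, a concentration series, a closing bracket; each
recording is a −100→+120 mV train (20 mV steps) of pre-pulse + test-step
pairs. Currents are exact model currents with σ Hill-modulated at the
concentration and the pre-pulse voltage (EC50 shifted by the electrical
distance of the site), scaled by cumulative multiplicative rundown
(default 12 % per train, within the experimentally stated 10–15 %), plus
ohmic leak and additive Gaussian noise (default sd 2 % of the saturating
+120 mV current). Leaky patches can be injected at a configurable rate.
Identical config + seed gives bit-identical output; patches use independent
seed substreams; all latent parameters are returned and never consumed by
the pipeline under test.

Default truths: the G644P-like construct uses the experimentally reported
inner/central-barrier EC50 (60/170 nM) and Hill coefficients (2.1/1.7),
stored at the +80 mV reference voltage. Values the source reports only
graphically are invented defaults, chosen once: σ_β spanning 0.05→1.0 and
σ_h 0.2→1.0 (strongly rectifying → pseudo-linear), z_Ca·f_V = 0.5,
A = 2×10⁻⁵ (≈500 pA at +120 mV saturating), steady-state EC50 300 nM for
the WT-like construct. The secondary low-affinity σ_β decay of the
single-Ca mutants is modelled as a well-separated Hill-type suppression
(depth 0.5, midpoint 100 µM, coefficient 2): the experimental decay is a
distinct >10 µM phenomenon, and an overlapping decay would make the two
phases unseparable by any masking rule.

Not emulated: capacitive transients (instantaneous currents are taken as
already extracted), series-resistance error, single-channel gating noise,
Gd³⁺ biphasic irreversible binding (Gd³⁺ enters only as a +3 valence in the
bookkeeping). A green recovery test therefore establishes correctness of
the analysis chain under the stated noise/rundown/leak model, not
robustness to every artifact of real recordings.

## Numerical choices and degenerate inputs

- Reversal/limit handling: the interior series uses `expm1` ratios and the
  exact analytic value at V = 0; currents at the Nernst potential are zero
  to machine precision relative to the curve scale.
- Multi-start grids: six σ pairs for I-V fits, five log-EC50 starts for
  Hill fits; lowest cost wins; ties are impossible in practice but the
  first minimum found would win deterministically.
- Rectification index requires the exact protocol voltages (−100, +120);
  interpolation is deliberately not performed.
- QC thresholds (0.40 inward/outward ratio, 0.20 bracket growth, 0.15
  amplitude floor) are configurable defaults validated against the
  generator's leaky-patch labels, not experimentally derived constants.
- Statistical calibration: with 12-point curves and 2 % noise, asymptotic
  95 % CIs for σ_β and EC50 cover the truth at ≈93–97 % over 200
  replicates (tested with a fixed seed chosen a priori).

## Known limitations

- The permeation model is single-ion, well-free and non-saturating by
  design; it cannot describe anomalous mole-fraction effects or pore block.
- σ_h is weakly identified whenever σ_β ≪ 1; single-recording σ_h values
  near the log-bound should be treated as censored, and the pipeline's
  mean-curve fits are the supported route to σ_h dose-response series.
- Effective permittivities inherit all caveats of a two-parameter Coulomb
  model applied to 3–6 point lines at an assumed distance.
- The rundown-correction and QC protocols are principled stand-ins for
  laboratory practice that the source describes only qualitatively.
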