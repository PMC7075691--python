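# Methods

## Device model

A p-type depletion OECT is modelled at steady state by a three-parameter
falling sigmoid,

    I_DS(V_GS) = I_max / (1 + exp((V_GS − V₀) / s)),

which reproduces the measured transfer shape and — unlike a linear
depletion model — the peaked transconductance g_m(V) = |dI/dV| with its
maximum exactly at V₀. Recordings are operated at the g_m maximum, the
standard choice for best current gain. Transient (non-steady-state) channel
dynamics, drift–diffusion device solvers and impedance spectroscopy are out
of scope.

Chemical sensitivity follows the capacitor-divider picture: the applied
gate voltage splits between the gate/electrolyte double layer (C_G-E) and
the channel's volumetric capacitance (C_volumetric), with
γ = C_volumetric/C_G-E. The per-decade Nernstian gate-voltage response of
an n-electron reaction is implemented as the equality

    ΔV_g-eff = ln(10) · (1 + γ) · kT/(nq) · log10(C₂/C₁),

i.e. the proportionality is fixed for the *per-decade change*; the absolute
reference concentration is unidentifiable from a single trace and is
absorbed into calibration. Quantification never uses this relation
directly — it uses the empirical power law ΔV_g-eff = A·C^β, which is what
standard-addition calibrations actually constrain at sub-micromolar
concentrations.

A note on the capacitance figures: the widely quoted double-layer estimate
of ≈4.8 nF for a 10 µF/cm² Pt gate of 0.08 × 0.06 cm² is internally
inconsistent — the arithmetic gives 48 nF. `gate_interface_capacitance`
returns the arithmetic value (48 nF); the channel figure
(39 F/cm³ × 40 × 10 × 0.03 µm³ = 0.468 nF ≈ 0.47 nF) is consistent and is
reproduced exactly. Either reading leaves γ ≪ 1, which is the regime that
favours chemical sensing over gating efficiency.

### Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| channel W × L × t | 40 × 10 × 0.03 | µm | reference device geometry |
| C density (channel) | 39 | F/cm³ | PEDOT:PSS volumetric capacitance |
| gate area / areal C | 0.0048 / 10 | cm², µF/cm² | Pt double layer |
| temperature | 310 (in vivo), 298.15 (bench) | K | body vs. room temperature |
| electrons n | 2 | — | catechol → quinone oxidation |
| V₀, s | 0.6, 0.15 | V | operating point near 0.6 V, sweep 0–1.2 V |
| I_max | 0.35 | µA | see "signal scale" below |
| V_DS | 0.06 | V | recording drain bias |

**Signal scale.** With the calibrated 1.16 nA peak-to-peak noise floor and
the default calibration truth (A = 2 mV·nM^−0.5), the sigmoid scale I_max
sets the evoked-deflection-to-noise ratio. I_max = 0.35 µA places the
default mesolimbic scenario (≈195 nM transients, ≈16 nA deflections) at a
median single-trial SNR near 10 — the reported in vivo regime of 5–10 —
and puts the 1-pulse dose-response point (36 nM, ≈7 nA) near the detection
limit, which is where that condition is described to sit. This is a choice
about the *effective in vivo* signal scale; bench devices pass far larger
currents, but the quantification chain is scale-invariant (it divides by
the fitted g_m), so none of the downstream analysis depends on it.

## Forward simulator

The generator's defaults are the study conditions, not tuning knobs:

* **Dose-response**: evoked peak concentration linear in pulse count,
  anchored at (1 pulse, 36.13 nM) and (100 pulses, 356.05 nM). Intermediate
  points follow the line; only the endpoints are quantitatively anchored.
* **Frequency map**: multiplicative factor {30 Hz: 0.6, 50 Hz: 1.0,
  100 Hz: 0.7}, linearly interpolated. Only the ordering (50 Hz maximal) is
  empirically established; the off-peak values are configuration. The
  factor applies at fixed pulse count: it encodes the *net* frequency
  effect of the standard protocol, so the 50 Hz maximum survives even
  though a constant-duration train at 100 Hz would deliver more pulses.
* **Release kernel**: normalized double exponential (rise 0.2 s, decay
  2 s), peak equal to the trial amplitude. The transient shape is not
  quantitatively constrained by data; only peak amplitude is. One release
  event per stimulation train, onset at train onset.
* **Noise**: white Gaussian current noise with σ = 1.16 nA / d₂(20) ≈
  0.311 nA, where d₂(n) = E[range of n standard normals] (computed by
  quadrature), so that the *expected* 1-s-window (20-sample) peak-to-peak
  amplitude equals the measured 1.16 nA at 50 ms sampling. An optional
  random-walk drift exists but defaults off (hours-long recordings show no
  significant drift). No stimulus artifact is simulated.
* **Trial variability**: trial amplitudes are jittered with CV = 0.10,
  a modest within-site trial-to-trial variability; the much larger spread
  quoted across animals (SEs of ~30% at the 1-pulse point) reflects
  between-animal heterogeneity, which the scenarios do not model — group
  comparisons here operate at trial level within one synthetic animal.
* **Scenarios**: `vta_somatodendritic` (single site, pulse-count sweeps),
  `mesolimbic` (NAc units 1–2 with gains 1.0/0.55; unit 2 sits off-centre),
  `dual_pathway` (NAc, lower CPu, upper CPu × VTA-/SNc-stimulation with a
  gain matrix expressing mesolimbic vs. nigrostriatal dominance), `lesion`
  (pre/post attenuation factors: NAc {VTA 0.7, SNc 0.3}, lower CPu
  {0.7, 0.7}, upper CPu {1.0, 1.0}; directions are the established result,
  magnitudes are configuration), and `control_offtarget` (all amplitudes
  forced to zero). Calibration tables span 30 nM–0.1 mM (9 log-spaced
  levels × 3 replicates, 2% multiplicative noise).

All randomness in an experiment descends from one `SeedSequence`, so equal
configurations are bit-identical. What passing tests on these data show is
that the *inverse chain is correct and well-calibrated under the stated
noise model*; they cannot certify behaviour under real-tissue effects the
simulator omits (electrode fouling, interferent dynamics, uptake kinetics,
between-animal variance).

## Inverse pipeline

1. **Transfer characterization** (`fit_transfer_curve`): least-squares
   sigmoid on normalized currents (Levenberg–Marquardt; normalization keeps
   the three parameters O(1), without which the fit is badly conditioned).
   A nonparametric alternative — isotonic (PAVA) projection onto decreasing
   sequences followed by a monotone PCHIP interpolant — is available with
   `parametric=False` and is used when the sigmoid family cannot be
   assumed; its inverse is computed by bracketed root-finding on the
   forward spline, making inversion exact to 10⁻¹² V. Requires ≥ 10
   samples.
2. **Baseline**: mean I_DS over the 5 s window before stimulus onset.
3. **Peak** (`detect_release_peak`): the minimal I_DS between stimulus
   onset and the first upward re-crossing of baseline (a later second dip
   is ignored), or the epoch end plus a 10 s decay allowance if no
   re-crossing occurs. Detection runs on a Savitzky–Golay-smoothed copy
   (window 0.55 s, order 2). The raw minimum of a noisy series is a
   downward-biased extreme-value statistic — at the weakest amplitudes the
   bias would double into a ≈30% concentration overestimate through the
   β = 0.5 calibration — while the quadratic filter preserves the smooth
   transient peak to fourth order (measured noiseless attenuation 0.15%,
   inside the 1% round-trip budget). Dip entry/re-crossing uses a
   hysteresis of 4× the pre-stimulus sample noise (estimated from first
   differences), so baseline noise alone cannot truncate the search span;
   it vanishes for noiseless traces.
4. **ΔV_g-eff**: both currents inverted through the monotone model,
   subtracted, absolutized. Currents outside the model range clip to the
   boundary voltage with an explicit `extrapolated` flag rather than
   aborting the trial.
5. **Calibration** (`fit_calibration`): OLS of log ΔV on log C (the fit is
   linear on log–log axes); β = slope, A = exp(intercept), with R², a
   voltage-space RMS residual, and the fitted concentration range.
6. **Concentration**: C = (ΔV/A)^(1/β), flagged when outside the
   calibrated range.
7. **SNR and detection limit**: SNR = |baseline − peak| divided by the
   peak-to-peak amplitude of the same 5 s baseline window (an exactly
   noiseless window returns an infinite-SNR sentinel with a flag). The
   LOD is the concentration whose forward deflection equals 3× the noise
   peak-to-peak (solved by Brent's method); estimates with SNR < 3 are
   flagged `below_lod` but retained — group statistics include them by
   default.

## Statistics

Group summaries are mean ± SE (SE = sd/√n; n = 1 reports SE 0 with a
flag). "Student t-test" is read as the classical unpaired, two-sided,
pooled-variance test (df = n_a + n_b − 2), Welch by option; lesion
contrasts are unpaired and uncorrected for multiplicity (a Bonferroni
option exists but defaults off), matching per-comparison reporting at
α = 0.05. The lesion signature check is directional: affected cells must
show a significant *decrease*, spared cells no significant decrease —
the hypothesis under test is attenuation, and a two-sided "any
significance" reading would let α-level flukes in the two null cells cap
the reproduction rate at 0.95² regardless of power.

## Numerical choices and degenerate inputs

* Sigmoid inversion is analytic; currents within 10⁻¹⁵ of the range edges
  are clamped before the log.
* Non-monotone measured sweeps are repaired by isotonic projection before
  interpolation; PAVA plateaus are collapsed to their right edge and
  evaluation is clamped to the knot span (PCHIP extrapolation is not
  shape-preserving).
* Operating-point ties break toward the smaller V_GS; flat or
  non-decreasing curves raise a characterization error.
* `expected_range_factor(n)` is computed by quadrature of
  E[R] = ∫ 1 − Φⁿ − (1−Φ)ⁿ dx and cached.
* Stimulation trains are single epochs ≥ 50 s apart by protocol; the
  simulator emits one train per trace.

## Problem sizes

Defaults used throughout the examples, tests and the acceptance script:
20 trials for single-site dose-response conditions, 10 per multi-site map,
6 per lesion cell (the experimental group size), 26 × 1 s noise segments,
30 s traces at 50 ms sampling, 121-point sweeps, 1000 control trials for
the false-positive rate and 100 replicate experiments for the lesion-
pattern reproduction rate. These sizes make every check run in seconds to
a few minutes on one CPU while keeping Monte-Carlo error well inside each
test's tolerance.

## Known limitations

* The power-law calibration is self-consistent by construction: the
  simulator and the fitted calibration share the functional form. Real
  calibrations add interferent backgrounds and electrode-to-electrode
  transfer error that are not modelled beyond the (constant) ascorbate
  regime implicitly folded into A.
* Peak amplitudes near the LOD are still slightly biased upward (≈+2% in
  concentration at the 1-pulse point) by residual extreme-value selection.
* Release kinetics (uptake, diffusion) are phenomenological; the kernel
  time constants shape only the peak search, not the quantification.
* t-tests pool trials within a synthetic animal (per-animal aggregation,
  when wanted, is a caller-side grouping before `compare_groups`);
  between-animal variance itself is not simulated.
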