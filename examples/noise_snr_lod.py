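"""Baseline noise calibration, in vivo SNR, and the detection limit.

Checks the noise generator against its peak-to-peak target, measures the
SNR distribution of the default mesolimbic scenario, and solves for the
concentration at which an evoked deflection reaches 3x the noise floor.
"""

import numpy as np

from oectmap import (
    DeviceParams,
    ScenarioConfig,
    estimate_lod,
    fit_calibration,
    fit_transfer_curve,
    noise_series,
    quantify_trace,
    synthesize_experiment,
)

# 26 one-second baseline segments at 50 ms sampling
x = noise_series(26 * 20, dt=0.05, seed=7)
pp = np.ptp(x.reshape(26, 20), axis=1)
print(f"baseline noise: mean p-p {pp.mean() * 1e9:.3f} nA over {len(pp)} x 1 s segments")

cfg = ScenarioConfig(scenario="mesolimbic", seed=42, n_trials=10)
exp = synthesize_experiment(cfg)
model = fit_transfer_curve(exp.sweep)
fit = fit_calibration(exp.calibration_pairs())
ests = [quantify_trace(t, model, fit)[0] for t in exp.traces]
snrs = np.array([e.snr for e in ests])
print(f"mesolimbic SNR: median {np.median(snrs):.2f}, range {snrs.min():.2f}-{snrs.max():.2f}")

lod = estimate_lod(fit, model, noise_pp=pp.mean())
print(f"detection limit: {lod:.2f} nM (deflection = 3x noise p-p at the operating point)")
print()
print("evoked deflections of ~10-20 nA against a ~1.2 nA noise floor give the")
print("single-trial SNR that makes per-stimulus release quantification possible.")
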