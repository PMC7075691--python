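"""Full forward/inverse chain at the dose-response endpoints.

Simulates somatodendritic-release trials at 1 and 100 stimulation pulses,
quantifies every trace with the fitted transfer model and calibration, and
fits the dose-response line across pulse counts.
"""

import numpy as np

from oectmap import (
    ScenarioConfig,
    dose_response_fit,
    fit_calibration,
    fit_transfer_curve,
    quantify_trace,
    synthesize_experiment,
)

means = {}
for pulses in (1, 10, 50, 100):
    cfg = ScenarioConfig(
        scenario="vta_somatodendritic", seed=42, n_trials=20, pulse_count=pulses
    )
    exp = synthesize_experiment(cfg)
    model = fit_transfer_curve(exp.sweep)
    fit = fit_calibration(exp.calibration_pairs())
    concs = [quantify_trace(t, model, fit)[0].concentration for t in exp.traces]
    means[pulses] = (np.mean(concs), np.std(concs, ddof=1) / np.sqrt(len(concs)))
    print(
        f"{pulses:3d} pulses: recovered {means[pulses][0]:7.2f} ± {means[pulses][1]:5.2f} nM "
        f"(mean ± SE, n = {len(concs)})"
    )

slope, intercept, r = dose_response_fit(
    list(means), [m[0] for m in means.values()]
)
print(f"\ndose-response fit: {slope:.3f} nM/pulse, intercept {intercept:.2f} nM, r = {r:.4f}")
print("release intensity is linear in pulse count; the 1-pulse point sits near")
print("the detection limit, so its estimate carries the largest relative error.")
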