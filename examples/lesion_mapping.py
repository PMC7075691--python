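"""Multi-site mapping with a VTA-SNc disconnection lesion.

Simulates pre/post-lesion recordings in NAc, lower CPu and upper CPu under
VTA- and SNc-stimulation, quantifies every trial, and runs the per-cell
Student t-tests that expose the pathway cross-talk signature.
"""

from oectmap import (
    ScenarioConfig,
    fit_calibration,
    fit_transfer_curve,
    lesion_effect_table,
    lesion_pattern_reproduced,
    quantify_trace,
    synthesize_experiment,
)

cfg = ScenarioConfig(scenario="lesion", seed=7, n_trials=6)
exp = synthesize_experiment(cfg)
model = fit_transfer_curve(exp.sweep)
fit = fit_calibration(exp.calibration_pairs())
ests = [quantify_trace(t, model, fit)[0] for t in exp.traces]
pre = [e for e in ests if e.meta["condition"] == "pre"]
post = [e for e in ests if e.meta["condition"] == "post"]

table = lesion_effect_table(
    pre, post, regions=["nac", "cpu_lower", "cpu_upper"], stim_sites=["vta", "snc"]
)
print(f"{'region':<10} {'stim':<5} {'pre (nM)':>9} {'post (nM)':>9} {'t':>7} {'p':>8}  sig")
for (region, stim), cmp in table.items():
    print(
        f"{region:<10} {stim:<5} {cmp.group_a.mean:9.1f} {cmp.group_b.mean:9.1f} "
        f"{cmp.t_statistic:7.2f} {cmp.p_value:8.4f}  {'*' if cmp.significant else 'n.s.'}"
    )
print(f"\nqualitative signature reproduced: {lesion_pattern_reproduced(table)}")
print("severing the VTA-SNc connection attenuates release in NAc (strongest under")
print("SNc stimulation) and lower CPu, while upper CPu is unaffected.")
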