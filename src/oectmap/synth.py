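"""Forward simulator of OECT-array recordings of evoked catecholamine release.

Generates transfer-curve sweeps, stimulus-locked drain-current traces and
standard-addition calibration tables with the statistical structure of the
in vivo experiments the analysis pipeline targets:

* dose-response: evoked peak concentration linear in stimulation pulse
  count, anchored at 36.13 nM (1 pulse) and 356.05 nM (100 pulses);
* frequency dependence: evoked release maximal at 50 Hz;
* baseline noise: Gaussian, calibrated so the expected 1-s-window
  peak-to-peak amplitude at 50 ms sampling is 1.16 nA;
* multi-site heterogeneity across a 4-unit array, off-target controls with
  zero release, and lesion-induced attenuation of specific
  (region, stimulation-site) cells.

Every stochastic quantity derives from the single scenario seed, so a given
configuration reproduces bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.stats import norm

from .device import DeviceParams, TransferCurve, CurveSource, optimal_operating_point, transfer_current
from .errors import InvalidParameterError, ScenarioError
from .trace import DEFAULT_DT, RecordingTrace, ReleaseEvent, StimulusProtocol

__all__ = [
    "Scenario",
    "NoiseParams",
    "ScenarioConfig",
    "SyntheticExperiment",
    "DOSE_ANCHORS",
    "DEFAULT_FREQUENCY_FACTORS",
    "DEFAULT_CALIBRATION_TRUTH",
    "TARGET_NOISE_PP",
    "expected_range_factor",
    "default_noise_sigma",
    "dose_response_amplitude",
    "frequency_response_factor",
    "release_concentration_series",
    "noise_series",
    "synthesize_trace",
    "synthesize_transfer_sweep",
    "synthesize_standard_additions",
    "synthesize_experiment",
]

#: Printed dose-response endpoints: (pulse count, evoked peak concentration nM).
DOSE_ANCHORS: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 36.13), (100.0, 356.05))

#: Net amplitude factor by stimulation frequency (Hz); 50 Hz is maximal.
DEFAULT_FREQUENCY_FACTORS: dict[float, float] = {30.0: 0.6, 50.0: 1.0, 100.0: 0.7}

#: Ground-truth power-law calibration (A in mV·nM^-beta, beta).
DEFAULT_CALIBRATION_TRUTH: tuple[float, float] = (2.0, 0.5)

#: Target mean peak-to-peak baseline noise over a 1 s window, A.
TARGET_NOISE_PP: float = 1.16e-9

#: Standard-addition calibration range, nM (30 nM to 0.1 mM).
CALIBRATION_RANGE: tuple[float, float] = (30.0, 1e5)


class Scenario(str, Enum):
    VTA_SOMATODENDRITIC = "vta_somatodendritic"
    MESOLIMBIC = "mesolimbic"
    DUAL_PATHWAY = "dual_pathway"
    LESION = "lesion"
    CONTROL_OFFTARGET = "control_offtarget"


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def expected_range_factor(n: int) -> float:
    """E[max - min] of n i.i.d. standard normals (the control-chart d2 constant).

    Computed by quadrature of ``E[R] = ∫ 1 - Φ(x)^n - (1-Φ(x))^n dx``;
    d2(20) ≈ 3.735.
    """
    if n < 2:
        return 0.0
    val, _ = quad(lambda x: 1.0 - norm.cdf(x) ** n - norm.sf(x) ** n, -12, 12, limit=200)
    return float(val)


def default_noise_sigma(dt: float = DEFAULT_DT, target_pp: float = TARGET_NOISE_PP) -> float:
    """Gaussian sigma whose expected 1-s-window peak-to-peak equals ``target_pp``.

    At dt = 50 ms a 1 s window holds 20 samples, so sigma ≈ 1.16 nA / 3.735
    ≈ 0.31 nA.
    """
    n = max(int(round(1.0 / dt)), 2)
    return target_pp / expected_range_factor(n)


@dataclass(frozen=True)
class NoiseParams:
    """Baseline noise model: white Gaussian current noise plus optional slow drift.

    ``sigma=None`` means "calibrated to the target peak-to-peak level for
    the sampling interval in use".  Drift (a low-frequency random walk) is
    off by default: the device operates for hours without significant
    drift.
    """

    sigma: float | None = None
    drift_amplitude: float = 0.0

    def resolved_sigma(self, dt: float) -> float:
        if self.sigma is not None:
            if self.sigma < 0:
                raise InvalidParameterError("sigma must be >= 0")
            return self.sigma
        return default_noise_sigma(dt)


def dose_response_amplitude(pulse_count: float) -> float:
    """Evoked peak concentration (nM) for a pulse count in [1, 100].

    Linear between the anchors (1 -> 36.13 nM, 100 -> 356.05 nM), matching
    the reported linear fit of release intensity versus pulse number.
    """
    (p0, c0), (p1, c1) = DOSE_ANCHORS
    if not p0 <= pulse_count <= p1:
        raise InvalidParameterError(f"pulse_count must be in [{p0:g}, {p1:g}], got {pulse_count!r}")
    return c0 + (c1 - c0) * (pulse_count - p0) / (p1 - p0)


def frequency_response_factor(
    frequency: float, factors: dict[float, float] | None = None
) -> float:
    """Multiplicative amplitude factor for the stimulation frequency.

    Anchored at {30: 0.6, 50: 1.0, 100: 0.7} by default (50 Hz maximal) and
    linearly interpolated in between.  Overrides must keep 50 Hz the
    maximum with factor 1.0.
    """
    if frequency <= 0:
        raise InvalidParameterError(f"frequency must be > 0, got {frequency!r}")
    factors = dict(DEFAULT_FREQUENCY_FACTORS if factors is None else factors)
    freqs = np.array(sorted(factors))
    vals = np.array([factors[f] for f in freqs])
    if 50.0 not in factors or factors[50.0] != max(vals):
        raise InvalidParameterError("frequency factors must be maximal (1.0) at 50 Hz")
    if not freqs[0] <= frequency <= freqs[-1]:
        raise InvalidParameterError(
            f"frequency {frequency:g} Hz outside the interpolable range "
            f"[{freqs[0]:g}, {freqs[-1]:g}] Hz"
        )
    return float(np.interp(frequency, freqs, vals))


def release_concentration_series(event: ReleaseEvent, time_grid: np.ndarray) -> np.ndarray:
    """Concentration time course (nM) of one release transient.

    Normalized double exponential: zero before onset, rising with
    ``rise_tau``, decaying with ``decay_tau``, maximum equal to
    ``peak_concentration``.
    """
    t = np.asarray(time_grid, dtype=float)
    dt_rel = t - event.onset
    rise, dec = event.rise_tau, event.decay_tau
    t_peak = np.log(dec / rise) * rise * dec / (dec - rise)
    peak_val = np.exp(-t_peak / dec) - np.exp(-t_peak / rise)
    x = np.clip(dt_rel, 0.0, None)
    kern = (np.exp(-x / dec) - np.exp(-x / rise)) / peak_val
    return np.where(dt_rel >= 0, event.peak_concentration * kern, 0.0)


def noise_series(
    n: int,
    dt: float = DEFAULT_DT,
    sigma: float | None = None,
    drift_amplitude: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Zero-mean Gaussian baseline noise, optionally with a slow random-walk drift.

    ``seed`` may be an int, a SeedSequence or a Generator.  ``sigma=None``
    uses the calibrated default for this ``dt``.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = default_noise_sigma(dt) if sigma is None else sigma
    out = rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
    if drift_amplitude > 0:
        # random walk rescaled so its RMS excursion over the trace is drift_amplitude
        walk = np.cumsum(rng.normal(0.0, 1.0, n))
        walk -= walk.mean()
        rms = np.sqrt(np.mean(walk**2))
        if rms > 0:
            out = out + drift_amplitude * walk / rms
    return out


# ---------------------------------------------------------------------------
# trace and sweep synthesis
# ---------------------------------------------------------------------------


def synthesize_trace(
    protocol: StimulusProtocol,
    events: list[ReleaseEvent],
    device: DeviceParams,
    calibration_truth: tuple[float, float] = DEFAULT_CALIBRATION_TRUTH,
    noise_params: NoiseParams = NoiseParams(),
    seed=None,
    duration: float = 30.0,
    dt: float = DEFAULT_DT,
    site_id: str | None = None,
    meta: dict | None = None,
) -> RecordingTrace:
    """Forward-model one stimulation trial into a drain-current trace.

    The operating point is the transconductance maximum of the device's
    transfer curve.  Each release event contributes an effective-gate shift
    ``A * C(t)**beta`` (A in mV·nM^-beta) that pushes the p-type channel
    toward depletion, so evoked deflections are strictly downward.
    """
    for ev in events:
        if ev.onset < protocol.onset_time:
            raise ScenarioError(
                f"event onset {ev.onset:g} s precedes protocol onset {protocol.onset_time:g} s"
            )
    a_mv, beta = calibration_truth
    if a_mv <= 0 or beta <= 0:
        raise InvalidParameterError("calibration_truth (A, beta) must be > 0")
    t = np.arange(int(round(duration / dt))) * dt
    conc = np.zeros_like(t)
    for ev in events:
        conc = conc + release_concentration_series(ev, t)
    v_op = optimal_operating_point(device)
    dv = a_mv * 1e-3 * conc**beta
    i = transfer_current(v_op + dv, device)
    sigma = noise_params.resolved_sigma(dt)
    i = i + noise_series(t.size, dt, sigma, noise_params.drift_amplitude, seed)
    i = np.clip(i, 0.0, None)
    return RecordingTrace(
        site_id=site_id or (events[0].site_id if events else "site"),
        i_ds=i,
        v_gs_operating=v_op,
        v_ds=device.v_ds,
        stim_epochs=[protocol.epoch],
        dt=dt,
        ground_truth=list(events),
        meta=meta or {},
    )


def synthesize_transfer_sweep(
    device: DeviceParams,
    noise_sigma: float | None = None,
    n_points: int = 121,
    seed=None,
    v_span: tuple[float, float] = (0.0, 1.2),
) -> TransferCurve:
    """Sample the device transfer curve over the sweep range with current noise.

    ``noise_sigma=None`` defaults to 0.5% of the saturation current, a
    typical sourcemeter-sweep repeatability.
    """
    if n_points < 5:
        raise InvalidParameterError("n_points must be >= 5")
    v = np.linspace(*v_span, n_points)
    i = transfer_current(v, device)
    sigma = 0.005 * device.transfer_imax if noise_sigma is None else noise_sigma
    if sigma > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, sigma, n_points)
    i = np.clip(i, 0.0, None)
    source = CurveSource.MEASURED if sigma > 0 else CurveSource.PARAMETRIC
    return TransferCurve(v, i, v_ds=device.v_ds, source=source)


def synthesize_standard_additions(
    calibration_truth: tuple[float, float] = DEFAULT_CALIBRATION_TRUTH,
    noise_cv: float = 0.02,
    n_concentrations: int = 9,
    n_replicates: int = 3,
    conc_range: tuple[float, float] = CALIBRATION_RANGE,
    seed=None,
) -> pd.DataFrame:
    """Standard-addition calibration table over 30 nM - 0.1 mM.

    Columns ``concentration_nM`` and ``delta_v_mV``; shifts follow the
    ground-truth power law with multiplicative Gaussian noise of
    coefficient of variation ``noise_cv`` (three replicates per level by
    default, as in ex vivo calibrations).
    """
    a_mv, beta = calibration_truth
    rng = np.random.default_rng(seed)
    conc = np.geomspace(conc_range[0], conc_range[1], n_concentrations)
    rows = []
    for c in conc:
        for _ in range(n_replicates):
            noise = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
            dv = a_mv * c**beta * max(1.0 + noise, 1e-6)
            rows.append((c, dv))
    return pd.DataFrame(rows, columns=["concentration_nM", "delta_v_mV"])


def calibration_pairs(table: pd.DataFrame) -> list[tuple[float, float]]:
    """(concentration nM, shift in volts) pairs for :func:`oectmap.pipeline.fit_calibration`."""
    return [
        (float(c), float(v) * 1e-3)
        for c, v in zip(table["concentration_nM"], table["delta_v_mV"])
    ]


# ---------------------------------------------------------------------------
# scenario-level synthesis
# ---------------------------------------------------------------------------

# per-(site, stimulation-site) response gains relative to the dose-response
# amplitude; mesolimbic (VTA -> NAc) and nigrostriatal (SNc -> CPu)
# projections dominate their respective targets.
_PATHWAY_GAINS: dict[str, dict[str, float]] = {
    "nac": {"vta": 1.0, "snc": 0.6},
    "cpu_lower": {"vta": 0.6, "snc": 1.0},
    "cpu_upper": {"vta": 0.5, "snc": 1.0},
}

# lesion attenuation per (site, stimulation-site): severing the VTA-SNc
# connection suppresses NAc responses to SNc stimulation most strongly,
# attenuates NAc/lower-CPu responses moderately and spares upper CPu.
_LESION_FACTORS: dict[str, dict[str, float]] = {
    "nac": {"vta": 0.7, "snc": 0.3},
    "cpu_lower": {"vta": 0.7, "snc": 0.7},
    "cpu_upper": {"vta": 1.0, "snc": 1.0},
}

_MESOLIMBIC_GAINS = {"nac_unit1": 1.0, "nac_unit2": 0.55}  # unit 2 sits off-center


@dataclass
class ScenarioConfig:
    """Configuration of one synthetic experiment.

    ``trial_cv`` is the trial-to-trial coefficient of variation of the true
    release amplitude (within-site biological variability).  ``n_trials``
    defaults per scenario (20 for single-site scenarios, 10 for multi-site
    maps, 6 per cell for lesion contrasts, matching the experimental group
    sizes).
    """

    scenario: Scenario = Scenario.VTA_SOMATODENDRITIC
    seed: int = 0
    n_trials: int | None = None
    pulse_count: int = 50
    frequency: float = 50.0
    trial_cv: float = 0.10
    site_gain_map: dict | None = None
    lesion_factors: dict | None = None
    frequency_factors: dict | None = None
    noise_params: NoiseParams = NoiseParams()
    calibration_truth: tuple[float, float] = DEFAULT_CALIBRATION_TRUTH
    device: DeviceParams = field(default_factory=DeviceParams)
    duration: float = 30.0
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        self.scenario = Scenario(self.scenario)
        if self.trial_cv < 0:
            raise ScenarioError("trial_cv must be >= 0")
        if self.n_trials is not None and self.n_trials < 1:
            raise ScenarioError("n_trials must be >= 1")

    def resolved_n_trials(self) -> int:
        if self.n_trials is not None:
            return self.n_trials
        return {
            Scenario.VTA_SOMATODENDRITIC: 20,
            Scenario.MESOLIMBIC: 10,
            Scenario.DUAL_PATHWAY: 10,
            Scenario.LESION: 6,
            Scenario.CONTROL_OFFTARGET: 20,
        }[self.scenario]

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.value,
            "seed": self.seed,
            "n_trials": self.n_trials,
            "pulse_count": self.pulse_count,
            "frequency": self.frequency,
            "trial_cv": self.trial_cv,
            "site_gain_map": self.site_gain_map,
            "lesion_factors": self.lesion_factors,
            "frequency_factors": self.frequency_factors,
            "noise_params": {
                "sigma": self.noise_params.sigma,
                "drift_amplitude": self.noise_params.drift_amplitude,
            },
            "calibration_truth": list(self.calibration_truth),
            "device": self.device.to_dict(),
            "duration": self.duration,
            "dt": self.dt,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "noise_params" in d and isinstance(d["noise_params"], dict):
            d["noise_params"] = NoiseParams(**d["noise_params"])
        if "device" in d and isinstance(d["device"], dict):
            d["device"] = DeviceParams.from_dict(d["device"])
        if "calibration_truth" in d:
            d["calibration_truth"] = tuple(d["calibration_truth"])
        return cls(**d)


@dataclass
class SyntheticExperiment:
    """Output bundle of :func:`synthesize_experiment`."""

    config: ScenarioConfig
    traces: list[RecordingTrace]
    sweep: TransferCurve
    calibration_table: pd.DataFrame

    def calibration_pairs(self) -> list[tuple[float, float]]:
        return calibration_pairs(self.calibration_table)


def _scenario_cells(config: ScenarioConfig) -> list[dict]:
    """(site, stimulation site, condition, amplitude factor) cells of a scenario."""
    s = config.scenario
    if s is Scenario.VTA_SOMATODENDRITIC:
        gains = config.site_gain_map or {"vta_unit1": 1.0}
        return [
            {"site": site, "stim_site": "mfb", "condition": "", "gain": g}
            for site, g in gains.items()
        ]
    if s is Scenario.CONTROL_OFFTARGET:
        gains = config.site_gain_map or {"vta_unit1": 1.0}
        return [
            {"site": site, "stim_site": "offtarget", "condition": "", "gain": 0.0}
            for site in gains
        ]
    if s is Scenario.MESOLIMBIC:
        gains = config.site_gain_map or _MESOLIMBIC_GAINS
        return [
            {"site": site, "stim_site": "vta", "condition": "", "gain": g}
            for site, g in gains.items()
        ]
    if s is Scenario.DUAL_PATHWAY:
        gains = config.site_gain_map or _PATHWAY_GAINS
        return [
            {"site": site, "stim_site": stim, "condition": "", "gain": g}
            for site, per_stim in gains.items()
            for stim, g in per_stim.items()
        ]
    if s is Scenario.LESION:
        gains = config.site_gain_map or _PATHWAY_GAINS
        lesions = config.lesion_factors or _LESION_FACTORS
        cells = []
        for site, per_stim in gains.items():
            for stim, g in per_stim.items():
                try:
                    lf = lesions[site][stim]
                except KeyError as exc:
                    raise ScenarioError(f"missing lesion factor for ({site}, {stim})") from exc
                if lf < 0:
                    raise ScenarioError("lesion factors must be >= 0")
                cells.append({"site": site, "stim_site": stim, "condition": "pre", "gain": g})
                cells.append(
                    {"site": site, "stim_site": stim, "condition": "post", "gain": g * lf}
                )
        return cells
    raise ScenarioError(f"unknown scenario {s!r}")


def synthesize_experiment(config: ScenarioConfig) -> SyntheticExperiment:
    """Emit per-site, per-trial traces plus the sweep and calibration table.

    Trial amplitudes are ``dose_response(pulse_count) x frequency_factor x
    site gain x lesion factor``, jittered trial-to-trial by ``trial_cv``.
    The off-target control scenario forces all ground-truth amplitudes to
    zero.  All randomness descends from ``config.seed``.
    """
    base = dose_response_amplitude(config.pulse_count) * frequency_response_factor(
        config.frequency, config.frequency_factors
    )
    protocol = StimulusProtocol(
        frequency=config.frequency, pulse_count=config.pulse_count
    )
    cells = _scenario_cells(config)
    n_trials = config.resolved_n_trials()
    ss = np.random.SeedSequence(config.seed)
    sweep_ss, calib_ss, trials_ss = ss.spawn(3)
    sweep = synthesize_transfer_sweep(config.device, seed=sweep_ss)
    table = synthesize_standard_additions(config.calibration_truth, seed=calib_ss)
    traces: list[RecordingTrace] = []
    for cell, cell_ss in zip(cells, trials_ss.spawn(len(cells))):
        for trial, trial_ss in enumerate(cell_ss.spawn(n_trials)):
            rng = np.random.default_rng(trial_ss)
            amp = cell["gain"] * base
            if amp > 0 and config.trial_cv > 0:
                amp *= max(1.0 + config.trial_cv * rng.standard_normal(), 0.0)
            events = (
                [ReleaseEvent(site_id=cell["site"], onset=protocol.onset_time, peak_concentration=amp)]
                if amp > 0
                else []
            )
            if config.scenario is Scenario.CONTROL_OFFTARGET:
                events = []
            traces.append(
                synthesize_trace(
                    protocol,
                    events,
                    config.device,
                    config.calibration_truth,
                    config.noise_params,
                    seed=rng,
                    duration=config.duration,
                    dt=config.dt,
                    site_id=cell["site"],
                    meta={
                        "stim_site": cell["stim_site"],
                        "condition": cell["condition"],
                        "trial": trial,
                        "frequency": config.frequency,
                        "pulse_count": config.pulse_count,
                        "true_peak_nM": amp if events else 0.0,
                    },
                )
            )
    return SyntheticExperiment(config=config, traces=traces, sweep=sweep, calibration_table=table)
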