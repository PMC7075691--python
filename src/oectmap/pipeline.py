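"""Inverse analysis: from drain-current recordings to calibrated concentrations.

The chain mirrors how evoked-release recordings are quantified in practice:

1. characterize the transfer curve and operate at peak transconductance;
2. convert the pre-stimulus baseline current and the evoked peak current
   (the minimal I_DS before the trace reverses back to baseline) to
   effective gate voltages through the monotone transfer model;
3. subtract and absolutize to obtain the effective-gate shift dV_geff;
4. convert dV_geff to a concentration through the power-law calibration
   ``dV_geff = A * C**beta`` fitted on standard additions;
5. attach an SNR (evoked deflection over baseline peak-to-peak noise) and a
   detection-limit flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.interpolate import PchipInterpolator
from scipy.optimize import isotonic_regression
from scipy.signal import savgol_filter
from scipy.stats import linregress

from .device import TransferCurve
from .errors import (
    CharacterizationError,
    DataError,
    DetectionError,
    ExtrapolationError,
    FitError,
    InvalidParameterError,
    WindowError,
)
from .trace import RecordingTrace

__all__ = [
    "TransferModel",
    "SigmoidTransferModel",
    "InterpolatedTransferModel",
    "CalibrationFit",
    "ReleaseEstimate",
    "fit_transfer_curve",
    "invert_transfer",
    "estimate_baseline",
    "detect_release_peak",
    "delta_v_geff",
    "fit_calibration",
    "concentration_from_shift",
    "compute_snr",
    "estimate_lod",
    "quantify_trace",
    "DEFAULT_BASELINE_WINDOW",
    "DEFAULT_SMOOTH_WINDOW",
    "LOD_SNR_CRITERION",
]

#: Pre-stimulus window used for the baseline mean and its peak-to-peak noise, s.
DEFAULT_BASELINE_WINDOW: float = 5.0
#: Savitzky-Golay window applied before peak detection, s (order 2).
DEFAULT_SMOOTH_WINDOW: float = 0.55
#: Detection-limit criterion: evoked deflection >= 3x peak-to-peak noise.
LOD_SNR_CRITERION: float = 3.0
#: Peak search continues this long past the stimulation epoch when the trace
#: has not yet re-crossed baseline, s.
DECAY_ALLOWANCE: float = 10.0


# ---------------------------------------------------------------------------
# transfer models
# ---------------------------------------------------------------------------


class TransferModel:
    """A strictly decreasing V_GS -> I_DS map queryable and invertible on its range."""

    v_range: tuple[float, float]

    def current(self, v_gs):
        raise NotImplementedError

    def voltage(self, i_ds: float) -> float:
        """Unique V with current(V) = i_ds; raises ExtrapolationError outside range."""
        raise NotImplementedError

    def gm(self, v_gs):
        """Transconductance |dI/dV| at v_gs."""
        raise NotImplementedError

    def operating_point(self) -> float:
        """The g_m-maximizing V_GS."""
        raise NotImplementedError

    def __call__(self, v_gs):
        return self.current(v_gs)

    @property
    def i_range(self) -> tuple[float, float]:
        lo, hi = self.v_range
        return (float(self.current(hi)), float(self.current(lo)))

    def _check_invertible(self, i_ds: float) -> None:
        imin, imax = self.i_range
        if not (imin <= i_ds <= imax):
            clipped_v = self.v_range[1] if i_ds < imin else self.v_range[0]
            raise ExtrapolationError(
                f"I_DS = {i_ds:g} A outside the model range [{imin:g}, {imax:g}] A",
                clipped_voltage=float(clipped_v),
            )


@dataclass
class SigmoidTransferModel(TransferModel):
    """Parametric falling sigmoid ``imax / (1 + exp((V - v0)/s))``."""

    i_max: float
    v0: float
    s: float
    v_range: tuple[float, float] = (0.0, 1.2)

    def __post_init__(self) -> None:
        if self.i_max <= 0 or self.s <= 0:
            raise InvalidParameterError("i_max and s must be > 0")

    def current(self, v_gs):
        v = np.asarray(v_gs, dtype=float)
        out = self.i_max / (1.0 + np.exp((v - self.v0) / self.s))
        return float(out) if np.isscalar(v_gs) else out

    def voltage(self, i_ds: float) -> float:
        self._check_invertible(i_ds)
        # analytic inverse; clamp away from the exact endpoints
        frac = min(max(i_ds / self.i_max, 1e-15), 1 - 1e-15)
        return self.v0 + self.s * math.log(1.0 / frac - 1.0)

    def gm(self, v_gs):
        v = np.asarray(v_gs, dtype=float)
        ez = np.exp((v - self.v0) / self.s)
        out = self.i_max / self.s * ez / (1.0 + ez) ** 2
        return float(out) if np.isscalar(v_gs) else out

    def operating_point(self) -> float:
        return float(self.v0)


class InterpolatedTransferModel(TransferModel):
    """Nonparametric monotone model: isotonic projection + shape-preserving spline.

    Measured sweeps are noisy and need not be monotone sample-by-sample; they
    are projected onto the nearest decreasing sequence (PAVA) and then
    interpolated with a monotone PCHIP spline.
    """

    def __init__(self, v_gs: np.ndarray, i_ds: np.ndarray):
        v = np.asarray(v_gs, dtype=float)
        i = np.asarray(i_ds, dtype=float)
        iso = isotonic_regression(i, increasing=False).x
        # collapse PAVA plateaus so the interpolant is strictly monotone
        keep_v, keep_i = [v[0]], [iso[0]]
        for vk, ik in zip(v[1:], iso[1:]):
            if ik < keep_i[-1]:
                keep_v.append(vk)
                keep_i.append(ik)
            else:
                keep_v[-1] = vk  # extend plateau; keep right edge
        if len(keep_i) < 2 or keep_i[0] <= keep_i[-1]:
            raise CharacterizationError("sweep is flat or non-decreasing after projection")
        self._v = np.asarray(keep_v)
        self._i = np.asarray(keep_i)
        self._fwd = PchipInterpolator(self._v, self._i)
        self._dfwd = self._fwd.derivative()
        self.v_range = (float(v[0]), float(v[-1]))

    def current(self, v_gs):
        # clamp to the knot span: PCHIP extrapolation is not shape-preserving
        out = self._fwd(np.clip(v_gs, self._v[0], self._v[-1]))
        return float(out) if np.isscalar(v_gs) else np.asarray(out)

    def voltage(self, i_ds: float) -> float:
        self._check_invertible(i_ds)
        lo, hi = float(self._v[0]), float(self._v[-1])
        if i_ds >= self._i[0]:
            return lo
        if i_ds <= self._i[-1]:
            return hi
        # exact functional inverse of the forward spline by bracketed root-finding
        return float(optimize.brentq(lambda vv: self._fwd(vv) - i_ds, lo, hi, xtol=1e-12))

    def gm(self, v_gs):
        out = np.abs(self._dfwd(np.clip(v_gs, self._v[0], self._v[-1])))
        return float(out) if np.isscalar(v_gs) else np.asarray(out)

    def operating_point(self) -> float:
        grid = np.linspace(*self.v_range, 2001)
        gm = self.gm(grid)
        return float(grid[int(np.argmax(gm))])


def fit_transfer_curve(sweep: TransferCurve, parametric: bool = True) -> TransferModel:
    """Fit a strictly monotone transfer model to a sampled sweep.

    By default a 3-parameter falling sigmoid is fitted by least squares
    (robust to sample noise and matching the peaked-transconductance shape);
    with ``parametric=False`` an isotonic-projected PCHIP interpolant is
    returned instead.  Requires at least 10 samples.
    """
    if len(sweep) < 10:
        raise CharacterizationError(f"need >= 10 sweep samples, got {len(sweep)}")
    v, i = sweep.v_gs_grid, sweep.i_ds_values
    if i[-1] >= i[0] or np.ptp(i) == 0:
        raise CharacterizationError("sweep is not overall decreasing")
    if not parametric:
        return InterpolatedTransferModel(v, i)
    # fit on normalized currents so all three parameters are O(1)
    scale = float(i.max())
    v0_0 = float(np.interp(0.5, (i / scale)[::-1], v[::-1]))
    s0 = max((v[-1] - v[0]) / 10.0, 1e-3)

    def _sig(vv, imax, v0, s):
        return imax / (1.0 + np.exp((vv - v0) / s))

    try:
        popt, _ = optimize.curve_fit(
            _sig, v, i / scale, p0=[1.0, v0_0, s0], method="lm", maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise CharacterizationError(f"sigmoid fit failed: {exc}") from exc
    imax, v0, s = float(popt[0]) * scale, float(popt[1]), float(popt[2])
    if imax <= 0 or s <= 0 or not (v[0] - 1.0 < v0 < v[-1] + 1.0):
        raise CharacterizationError("sigmoid fit produced unphysical parameters")
    return SigmoidTransferModel(imax, v0, s, v_range=(float(v[0]), float(v[-1])))


def invert_transfer(i_ds: float, model: TransferModel, clip: bool = False):
    """Effective gate voltage with ``model(V) = i_ds``.

    With ``clip=True`` an out-of-range current returns
    ``(boundary voltage, True)`` instead of raising; in-range currents
    return ``(V, False)``.  With ``clip=False`` the bare voltage is
    returned and out-of-range currents raise :class:`ExtrapolationError`
    (which still carries the clipped boundary value).
    """
    try:
        v = model.voltage(float(i_ds))
    except ExtrapolationError as exc:
        if clip:
            return exc.clipped_voltage, True
        raise
    return (v, False) if clip else v


# ---------------------------------------------------------------------------
# baseline / peak
# ---------------------------------------------------------------------------


def estimate_baseline(
    trace: RecordingTrace, stim_onset: float, window: float = DEFAULT_BASELINE_WINDOW
) -> float:
    """Mean I_DS over the ``window`` seconds preceding ``stim_onset``."""
    if window <= 0:
        raise InvalidParameterError("window must be > 0")
    start = stim_onset - window
    if start < -1e-9:
        raise WindowError(
            f"baseline window [{start:g}, {stim_onset:g}) extends before the trace start"
        )
    t = trace.times
    mask = (t >= start - 1e-12) & (t < stim_onset - 1e-12)
    if not mask.any():
        raise WindowError("baseline window contains no samples")
    return float(trace.i_ds[mask].mean())


def _smooth(i: np.ndarray, dt: float, smooth_window: float) -> np.ndarray:
    """Order-2 Savitzky-Golay smoothing; preserves smooth peaks to 4th order."""
    if smooth_window is None or smooth_window <= 0:
        return i
    win = int(round(smooth_window / dt))
    win += 1 - win % 2  # odd
    if win < 5 or win >= i.size:
        return i
    return savgol_filter(i, win, 2, mode="interp")


def _baseline_noise_sd(trace: RecordingTrace, epoch_start: float) -> float:
    """Sample-to-sample noise SD estimated from first differences pre-stimulus."""
    t = trace.times
    mask = (t >= epoch_start - DEFAULT_BASELINE_WINDOW) & (t < epoch_start)
    seg = trace.i_ds[mask]
    if seg.size < 3:
        return 0.0
    return float(np.std(np.diff(seg)) / math.sqrt(2.0))


def detect_release_peak(
    trace: RecordingTrace,
    epoch: tuple[float, float],
    baseline: float,
    smooth_window: float = DEFAULT_SMOOTH_WINDOW,
    decay_allowance: float = DECAY_ALLOWANCE,
) -> tuple[float, float]:
    """Evoked peak: the minimal I_DS before the trace reverses back to baseline.

    The search starts at the epoch start and ends at the first upward
    re-crossing of the baseline after the trace has dipped below it (so a
    second, later dip is ignored), or at the epoch end plus a decay
    allowance if no re-crossing occurs.  Detection runs on a lightly
    smoothed copy of the trace: the raw minimum of a noisy series is a
    downward-biased extreme-value statistic, and the quadratic
    Savitzky-Golay filter removes that bias without attenuating the smooth
    release transient.  Dip entry uses a small noise-derived hysteresis so
    baseline noise alone does not terminate the search span.

    Returns ``(peak_current, peak_time)``; ties break to the earliest time.
    """
    start_t, end_t = epoch
    t = trace.times
    lo = int(np.searchsorted(t, start_t - 1e-12))
    hi = int(np.searchsorted(t, end_t + decay_allowance + 1e-12))
    hi = min(hi, t.size)
    if hi - lo < 1:
        raise DetectionError(f"empty peak search span for epoch {epoch!r}")
    y = _smooth(trace.i_ds, trace.dt, smooth_window)[lo:hi]
    hyst = 4.0 * _baseline_noise_sd(trace, start_t)

    below = np.flatnonzero(y < baseline - hyst)
    span_end = y.size
    if below.size:
        entry = below[0]
        recross = np.flatnonzero(y[entry:] >= baseline)
        if recross.size:
            span_end = entry + int(recross[0])
    span = y[: max(span_end, 1)]
    idx = int(np.argmin(span))
    return float(span[idx]), float(t[lo + idx])


def delta_v_geff(baseline_i: float, peak_i: float, model: TransferModel) -> float:
    """|V(peak) - V(baseline)|: the absolutized effective-gate-voltage shift."""
    return abs(model.voltage(float(peak_i)) - model.voltage(float(baseline_i)))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationFit:
    """Fitted power-law calibration ``dV_geff = A * C**beta``.

    ``a_mv`` is A in mV·nM^-beta (the unit sensor calibrations are quoted
    in); ``residual_se_mv`` is the root-mean-square voltage residual of the
    fit over the calibration points, in mV; ``valid_range`` is the fitted
    concentration span in nM.
    """

    a_mv: float
    beta: float
    r_squared: float = 1.0
    residual_se_mv: float = 0.0
    valid_range: tuple[float, float] = (30.0, 1e5)

    def __post_init__(self) -> None:
        if self.a_mv <= 0 or self.beta <= 0:
            raise InvalidParameterError("a_mv and beta must be > 0")
        if not 0.0 <= self.r_squared <= 1.0:
            raise InvalidParameterError("r_squared must lie in [0, 1]")
        if not self.valid_range[0] < self.valid_range[1]:
            raise InvalidParameterError("valid_range must satisfy min < max")

    @property
    def a_volts(self) -> float:
        return self.a_mv * 1e-3

    def shift(self, concentration_nm):
        """Forward dV_geff in volts for a concentration in nM."""
        return self.a_volts * np.asarray(concentration_nm, dtype=float) ** self.beta

    def in_range(self, concentration_nm: float) -> bool:
        return self.valid_range[0] <= concentration_nm <= self.valid_range[1]


def fit_calibration(table) -> CalibrationFit:
    """Fit (A, beta) by ordinary least squares of log(dV) on log(C).

    ``table`` is an iterable of ``(concentration_nM, delta_v_volts)`` pairs
    (or a 2-column array).  All concentrations and shifts must be positive
    and at least 3 distinct concentrations are required.
    """
    arr = np.asarray([(c, v) for c, v in table], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise FitError("need at least 3 (concentration, shift) points")
    conc, dv = arr[:, 0], arr[:, 1]
    if np.any(conc <= 0) or np.any(dv <= 0):
        raise DataError("concentrations and shifts must be > 0 for the log-log fit")
    if np.unique(conc).size < 3:
        raise FitError("need at least 3 distinct concentrations")
    res = linregress(np.log(conc), np.log(dv))
    beta = float(res.slope)
    a_volts = float(np.exp(res.intercept))
    if beta <= 0 or a_volts <= 0:
        raise FitError("fitted calibration is not an increasing power law")
    fitted = a_volts * conc**beta
    resid_mv = (dv - fitted) * 1e3
    return CalibrationFit(
        a_mv=a_volts * 1e3,
        beta=beta,
        r_squared=float(res.rvalue**2),
        residual_se_mv=float(np.sqrt(np.mean(resid_mv**2))),
        valid_range=(float(conc.min()), float(conc.max())),
    )


def concentration_from_shift(delta_v: float, fit: CalibrationFit) -> float:
    """Invert the calibration: ``C = (dV / A) ** (1/beta)`` in nM (dV in volts)."""
    if delta_v < 0:
        raise InvalidParameterError("delta_v must be >= 0")
    if delta_v == 0:
        return 0.0
    return float((delta_v / fit.a_volts) ** (1.0 / fit.beta))


# ---------------------------------------------------------------------------
# SNR / LOD / full chain
# ---------------------------------------------------------------------------


@dataclass
class ReleaseEstimate:
    """Quantified release for one stimulation epoch of one trace."""

    site_id: str
    baseline_i: float
    peak_i: float
    peak_time: float
    delta_v_geff: float  # V, absolutized
    concentration: float  # nM
    snr: float
    below_lod: bool
    extrapolated: bool = False
    snr_undefined: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.delta_v_geff < 0 or self.concentration < 0:
            raise InvalidParameterError("delta_v_geff and concentration must be >= 0")


def _baseline_pp(trace: RecordingTrace, stim_onset: float, window: float) -> float:
    t = trace.times
    mask = (t >= stim_onset - window - 1e-12) & (t < stim_onset - 1e-12)
    if not mask.any():
        raise WindowError("baseline window contains no samples")
    return float(np.ptp(trace.i_ds[mask]))


def compute_snr(
    trace: RecordingTrace,
    estimate: ReleaseEstimate,
    stim_onset: float | None = None,
    window: float = DEFAULT_BASELINE_WINDOW,
) -> float:
    """Evoked deflection over baseline peak-to-peak noise.

    Returns ``inf`` (and is flagged upstream) when the baseline window is
    exactly noiseless but a deflection exists; a zero deflection gives 0.
    """
    if stim_onset is None:
        stim_onset = trace.stim_epochs[0][0]
    deflection = abs(estimate.baseline_i - estimate.peak_i)
    pp = _baseline_pp(trace, stim_onset, window)
    if pp == 0.0:
        return 0.0 if deflection == 0.0 else math.inf
    return deflection / pp


def estimate_lod(
    fit: CalibrationFit,
    model: TransferModel,
    noise_pp: float,
    operating_point: float | None = None,
    criterion: float = LOD_SNR_CRITERION,
) -> float:
    """Concentration whose evoked deflection equals ``criterion`` x noise_pp.

    The forward deflection ``|I(V_op) - I(V_op + A*C**beta)|`` is solved for
    C numerically over the calibration's valid range.  Returns ``nan`` when
    the criterion cannot be reached within that range (LOD undefined).
    """
    if noise_pp < 0:
        raise InvalidParameterError("noise_pp must be >= 0")
    if noise_pp == 0.0:
        return 0.0
    if operating_point is None:
        operating_point = model.operating_point()
    i_op = model.current(operating_point)

    def deflection(c: float) -> float:
        v = operating_point + float(fit.shift(c))
        v = min(v, model.v_range[1])
        return abs(i_op - model.current(v))

    target = criterion * noise_pp
    c_hi = fit.valid_range[1]
    if deflection(c_hi) < target:
        return math.nan
    c_lo = min(fit.valid_range[0], 1e-6) * 1e-6
    return float(optimize.brentq(lambda c: deflection(c) - target, c_lo, c_hi, xtol=1e-12))


def quantify_trace(
    trace: RecordingTrace,
    model: TransferModel,
    fit: CalibrationFit,
    baseline_window: float = DEFAULT_BASELINE_WINDOW,
    smooth_window: float = DEFAULT_SMOOTH_WINDOW,
    lod_snr: float = LOD_SNR_CRITERION,
) -> list[ReleaseEstimate]:
    """Run the full inverse chain on every stimulation epoch of a trace.

    baseline -> peak -> dV_geff -> concentration -> SNR.  Epochs whose SNR
    falls below ``lod_snr`` are flagged ``below_lod`` but retained.
    Currents outside the transfer model's range are clipped to the boundary
    voltage and flagged ``extrapolated`` rather than aborting the trial.
    """
    if not trace.stim_epochs:
        raise DetectionError("trace has no stimulation epochs")
    estimates: list[ReleaseEstimate] = []
    for epoch in trace.stim_epochs:
        baseline = estimate_baseline(trace, epoch[0], baseline_window)
        peak_i, peak_t = detect_release_peak(trace, epoch, baseline, smooth_window)
        v_base, ex1 = invert_transfer(baseline, model, clip=True)
        v_peak, ex2 = invert_transfer(peak_i, model, clip=True)
        dv = abs(v_peak - v_base)
        conc = concentration_from_shift(dv, fit)
        est = ReleaseEstimate(
            site_id=trace.site_id,
            baseline_i=baseline,
            peak_i=peak_i,
            peak_time=peak_t,
            delta_v_geff=dv,
            concentration=conc,
            snr=0.0,
            below_lod=False,
            extrapolated=bool(ex1 or ex2),
            meta=dict(trace.meta),
        )
        snr = compute_snr(trace, est, stim_onset=epoch[0], window=baseline_window)
        est.snr = snr
        est.snr_undefined = math.isinf(snr)
        est.below_lod = (not math.isinf(snr)) and snr < lod_snr
        if not fit.in_range(conc) and conc > 0:
            est.extrapolated = True
        estimates.append(est)
    return estimates
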