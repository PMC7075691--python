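"""Core recording containers shared by the simulator and the analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = ["StimulusProtocol", "ReleaseEvent", "RecordingTrace", "DEFAULT_DT"]

#: Default sampling interval, s (50 ms sampling).
DEFAULT_DT: float = 0.05

#: Minimum interval between stimulation trains, s (avoids transmitter depletion).
MIN_INTER_TRIAL_INTERVAL: float = 50.0


@dataclass(frozen=True)
class StimulusProtocol:
    """An electrical stimulation train.

    Defaults are the standard protocol: 50 Hz, 2 ms pulses, 200 µA.  The
    train duration is ``pulse_count / frequency``.
    """

    frequency: float = 50.0  # Hz
    pulse_width: float = 2.0  # ms
    pulse_count: int = 50
    amplitude: float = 200.0  # µA
    onset_time: float = 10.0  # s

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise InvalidParameterError(f"frequency must be > 0, got {self.frequency!r}")
        if self.pulse_count < 1:
            raise InvalidParameterError(f"pulse_count must be >= 1, got {self.pulse_count!r}")
        if self.pulse_width <= 0 or self.amplitude <= 0:
            raise InvalidParameterError("pulse_width and amplitude must be > 0")
        if self.onset_time < 0:
            raise InvalidParameterError("onset_time must be >= 0")

    @property
    def duration(self) -> float:
        """Train duration in seconds."""
        return self.pulse_count / self.frequency

    @property
    def epoch(self) -> tuple[float, float]:
        """(start, end) of the stimulation train in trace time."""
        return (self.onset_time, self.onset_time + self.duration)


@dataclass(frozen=True)
class ReleaseEvent:
    """One phasic release transient at a recording site.

    The concentration time course is a normalized double exponential whose
    maximum equals ``peak_concentration`` (nM).
    """

    site_id: str
    onset: float  # s
    peak_concentration: float  # nM
    rise_tau: float = 0.2  # s
    decay_tau: float = 2.0  # s

    def __post_init__(self) -> None:
        if self.peak_concentration < 0:
            raise InvalidParameterError("peak_concentration must be >= 0")
        if not self.rise_tau < self.decay_tau:
            raise InvalidParameterError(
                f"rise_tau ({self.rise_tau}) must be < decay_tau ({self.decay_tau})"
            )
        if self.rise_tau <= 0:
            raise InvalidParameterError("rise_tau must be > 0")


@dataclass
class RecordingTrace:
    """A drain-current time series with its operating point and stimulation epochs.

    ``i_ds`` is sampled at fixed ``dt`` starting at t = 0.  ``ground_truth``
    (simulated traces only) lists the release events that generated the
    trace; the analysis pipeline never reads it.
    """

    site_id: str
    i_ds: np.ndarray
    v_gs_operating: float
    v_ds: float
    stim_epochs: list[tuple[float, float]]
    dt: float = DEFAULT_DT
    ground_truth: list[ReleaseEvent] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.i_ds = np.asarray(self.i_ds, dtype=float)
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be > 0, got {self.dt!r}")
        if np.any(self.i_ds < 0):
            raise InvalidParameterError("i_ds must be non-negative")
        self.stim_epochs = [(float(a), float(b)) for a, b in self.stim_epochs]
        dur = self.duration
        for a, b in self.stim_epochs:
            if not (0 <= a < b <= dur):
                raise InvalidParameterError(
                    f"stim epoch ({a}, {b}) outside trace duration {dur:g} s"
                )

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.i_ds.size) * self.dt

    @property
    def duration(self) -> float:
        return self.i_ds.size * self.dt
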