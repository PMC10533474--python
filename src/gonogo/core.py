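"""Shared data model and task-timing conventions.

Conventions used throughout the package:

* All event times are seconds on a single session clock.
* Trial-relative times subtract the trial's stimulus-onset time.
* Every analysis window is half-open, ``[start, end)``, so counts over a
  partition of an interval into contiguous bins sum exactly to the count
  over the whole interval.
* Relative to stimulus onset, the waiting period is ``[0, waiting_dur)``
  (static grating), the answer period ``[waiting_dur, waiting_dur +
  answer_dur)`` (drifting grating), and the "early waiting period" is
  ``[0, early_window)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Stimulus",
    "Laser",
    "OutcomeValue",
    "TaskTiming",
    "Trial",
    "Outcome",
    "Session",
    "SpikeUnit",
    "PhotometryTrace",
    "window_spike_count",
    "trial_window_counts",
]


class Stimulus(str, enum.Enum):
    """Stimulus identity: vertical grating (GO) or horizontal grating (NOGO)."""

    GO = "GO"
    NOGO = "NOGO"


class Laser(str, enum.Enum):
    """Optogenetic laser state of a trial's block."""

    OFF = "OFF"
    ON = "ON"


class OutcomeValue(str, enum.Enum):
    """Behavioral outcome of a trial.

    HIT/MISS occur only on GO trials (answer-period lick / no lick),
    FA/CR only on NOGO trials (answer-period lick / no lick).
    """

    HIT = "HIT"
    MISS = "MISS"
    FA = "FA"
    CR = "CR"


@dataclass(frozen=True)
class TaskTiming:
    """Task timing constants, in seconds (``phot_rate`` in Hz).

    Parameters
    ----------
    waiting_dur
        Duration of the waiting period (static grating) after stimulus
        onset.  Licks here never change the trial outcome.
    answer_dur
        Duration of the answer period (drifting grating); licks here
        determine HIT/MISS/FA/CR.
    lick_latency_cap
        First-lick latencies are measured within this window after
        stimulus onset; trials without a lick carry the cap value.
    early_window
        The "early waiting period" used for the short-window choice
        analysis.
    psth_bin
        Bin width for peri-stimulus time histograms and for the binned
        photometry latency curve.
    spike_baseline
        Pre-stimulus window length for spike baseline rates.
    phot_baseline
        Pre-stimulus window length for the photometry F0 baseline.
    phot_rate
        Photometry sampling rate.
    """

    waiting_dur: float = 0.5
    answer_dur: float = 2.5
    lick_latency_cap: float = 1.0
    early_window: float = 0.3
    psth_bin: float = 0.025
    spike_baseline: float = 0.5
    phot_baseline: float = 1.0
    phot_rate: float = 200.0

    def __post_init__(self) -> None:
        for name in (
            "waiting_dur",
            "answer_dur",
            "lick_latency_cap",
            "early_window",
            "psth_bin",
            "spike_baseline",
            "phot_baseline",
            "phot_rate",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"TaskTiming.{name} must be strictly positive")
        if self.early_window > self.waiting_dur:
            raise ValueError("early_window must not exceed waiting_dur")
        for name in ("waiting_dur", "early_window"):
            ratio = getattr(self, name) / self.psth_bin
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(f"psth_bin must divide {name}")

    @property
    def answer_end(self) -> float:
        """End of the answer period, relative to stimulus onset."""
        return self.waiting_dur + self.answer_dur


@dataclass
class Trial:
    """One behavioral trial.

    ``lick_times`` are seconds relative to this trial's stimulus onset,
    sorted ascending.
    """

    index: int
    stimulus: Stimulus
    laser: Laser
    block_index: int
    onset: float
    lick_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.lick_times = np.asarray(self.lick_times, dtype=float)
        if self.lick_times.size and np.any(np.diff(self.lick_times) < 0):
            raise ValueError("lick_times must be sorted ascending")


@dataclass
class Outcome:
    value: OutcomeValue
    licked_in_waiting: bool


@dataclass
class Session:
    """A single behavioral session: trial table plus (optionally) outcomes.

    ``outcomes`` is ``None`` until :func:`gonogo.behavior.classify_outcomes`
    has run; it then has the same length as ``trials``.
    """

    session_id: str
    mouse_id: str
    timing: TaskTiming
    trials: list[Trial]
    outcomes: list[Outcome] | None = None

    def __post_init__(self) -> None:
        onsets = np.array([t.onset for t in self.trials])
        if onsets.size > 1 and np.any(np.diff(onsets) <= 0):
            raise ValueError("trial onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def onsets(self) -> np.ndarray:
        return np.array([t.onset for t in self.trials])

    def require_outcomes(self) -> list[Outcome]:
        if self.outcomes is None:
            raise ValueError(
                "session outcomes not classified; run behavior.classify_outcomes first"
            )
        return self.outcomes


@dataclass
class SpikeUnit:
    """One sorted unit: spike times (session clock) and mean waveforms."""

    unit_id: str
    spike_times: np.ndarray
    mean_waveform_spont: np.ndarray | None = None
    mean_waveform_laser: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike_times must be sorted ascending")
        if (
            self.mean_waveform_spont is not None
            and self.mean_waveform_laser is not None
            and len(self.mean_waveform_spont) != len(self.mean_waveform_laser)
        ):
            raise ValueError("waveform vectors must have equal length")


@dataclass
class PhotometryTrace:
    """Uniformly sampled fluorescence time series for one fiber."""

    t0: float
    rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    def time_axis(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate


def window_spike_count(unit: SpikeUnit, t_start: float, t_end: float) -> int:
    """Number of spikes in the half-open window ``[t_start, t_end)``."""
    if not t_start < t_end:
        raise ValueError("t_start must be < t_end")
    times = unit.spike_times
    lo = np.searchsorted(times, t_start, side="left")
    hi = np.searchsorted(times, t_end, side="left")
    return int(hi - lo)


def trial_window_counts(
    unit: SpikeUnit, session: Session, window: tuple[float, float]
) -> np.ndarray:
    """Per-trial spike counts in a trial-relative half-open window.

    ``window`` is ``(t_start, t_end)`` in seconds relative to stimulus
    onset, e.g. ``(0.0, 0.5)`` for the waiting period or ``(-0.5, 0.0)``
    for the spike baseline.
    """
    a, b = window
    if not a < b:
        raise ValueError("window start must be < window end")
    onsets = session.onsets()
    lo = np.searchsorted(unit.spike_times, onsets + a, side="left")
    hi = np.searchsorted(unit.spike_times, onsets + b, side="left")
    return (hi - lo).astype(int)
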