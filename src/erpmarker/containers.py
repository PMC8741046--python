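"""In-memory containers shared across the pipeline: epochs and averaged ERPs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SAMPLE_RATE = 250.0  # Hz, fixed throughout the pipeline


@dataclass(frozen=True)
class EpochWindow:
    """Half-open epoch time window [start, end) in ms relative to the lock event."""

    task: str
    lock: str
    start: float
    end: float

    @property
    def n_samples(self) -> int:
        return int(round((self.end - self.start) * SAMPLE_RATE / 1000.0))

    def times(self) -> np.ndarray:
        """Sample times in ms; sample 0 sits at `start`, the lock event at 0 ms."""
        return self.start + np.arange(self.n_samples) * (1000.0 / SAMPLE_RATE)

    def baseline_interval(self) -> tuple[float, float]:
        """Interval (ms) whose mean is subtracted per channel.

        Stimulus-locked epochs use the whole pre-stimulus period. Response-locked
        epochs contain motor preparation right up to the response, so only the
        earliest 100 ms of the window serve as baseline.
        """
        if self.lock == "stimulus":
            return (self.start, 0.0)
        return (self.start, self.start + 100.0)


#: Fixed window table: (task, lock) -> EpochWindow.
WINDOWS: dict[tuple[str, str], EpochWindow] = {
    ("VGNG", "stimulus"): EpochWindow("VGNG", "stimulus", -200.0, 800.0),
    ("VGNG", "response"): EpochWindow("VGNG", "response", -400.0, 500.0),
    ("AOB", "stimulus"): EpochWindow("AOB", "stimulus", -200.0, 1200.0),
}


@dataclass
class EpochSet:
    """Single-subject single-condition epoched EEG.

    data: (n_trials, n_channels, n_times) voltages in microvolts.
    correct: per-trial behavioral correctness flag.
    rt: per-trial response time in ms (NaN where no response was given).
    """

    subject_id: str
    task: str
    condition: str
    lock: str
    data: np.ndarray
    correct: np.ndarray
    rt: np.ndarray
    sample_rate: float = SAMPLE_RATE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.correct = np.asarray(self.correct, dtype=bool)
        self.rt = np.asarray(self.rt, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (trials, channels, times)")
        win = self.window
        if self.data.shape[2] != win.n_samples:
            raise ValueError(
                f"time axis has {self.data.shape[2]} samples, window "
                f"{win.task}/{win.lock} requires {win.n_samples}"
            )
        if len(self.correct) != self.n_trials or len(self.rt) != self.n_trials:
            raise ValueError("per-trial annotations must match trial count")

    @property
    def window(self) -> EpochWindow:
        return WINDOWS[(self.task, self.lock)]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        return self.window.times()


@dataclass
class ERP:
    """Trial-averaged, band-filtered, baseline-corrected evoked response.

    data: (n_channels, n_times) in microvolts; n_trials counts the correct
    trials that entered the average.
    """

    subject_id: str
    task: str
    condition: str
    lock: str
    band: str
    data: np.ndarray
    n_trials: int
    sample_rate: float = SAMPLE_RATE
    window: EpochWindow = field(init=False)

    def __post_init__(self) -> None:
        self.window = WINDOWS[(self.task, self.lock)]
        self.data = np.asarray(self.data, dtype=float)
        if self.n_trials < 1:
            raise ValueError("an ERP requires at least one averaged trial")
        if self.data.shape[1] != self.window.n_samples:
            raise ValueError("ERP time axis does not match its epoch window")

    def times(self) -> np.ndarray:
        return self.window.times()
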