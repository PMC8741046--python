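"""Epoched EEG -> condition/band-specific averaged ERPs.

The processing chain is: re-reference to the average of the two mastoid
electrodes, band-pass filter into overlapping physiological bands, cut into
stimulus- or response-locked epochs, and average across correct trials of the
same condition. Filtering is zero-phase (forward-backward Butterworth), so
component latencies are not biased by group delay. Because filtering and
trial-averaging are both linear, `average_erp` averages first and filters the
single average, which is mathematically identical and much cheaper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .containers import SAMPLE_RATE, ERP, EpochSet, EpochWindow
from .montage import Montage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandDef:
    """A physiological frequency band (edges in Hz)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("band low edge must be below high edge")


#: The overlapping analysis bands. STEPs are extracted per band; the ERP
#: variability statistic uses the broadband (0.5-30 Hz) signal.
BANDS: dict[str, BandDef] = {
    "delta": BandDef("delta", 0.5, 4.0),
    "theta": BandDef("theta", 3.0, 8.0),
    "alpha": BandDef("alpha", 7.0, 13.0),
    "beta": BandDef("beta", 12.0, 30.0),
    "broadband": BandDef("broadband", 0.5, 30.0),
}


def rereference_to_mastoids(epochs: EpochSet, montage: Montage) -> EpochSet:
    """Subtract the mean of the two mastoid signals from every channel.

    The mastoid channels remain in the array (so the channel axis keeps
    matching the montage) but carry no analyzable signal afterwards; all
    downstream feature code restricts itself to ``montage.scalp_mask``.
    """
    for name in montage.mastoids:
        if name not in montage.channel_names:
            raise ValueError(f"mastoid channel {name!r} missing from montage")
    m1, m2 = montage.mastoid_indices
    ref = 0.5 * (epochs.data[:, m1, :] + epochs.data[:, m2, :])
    data = epochs.data - ref[:, None, :]
    return replace(epochs, data=data)


def _band_sos(band: BandDef, sample_rate: float, order: int) -> np.ndarray:
    nyq = sample_rate / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band {band.name} ({band.low}-{band.high} Hz) exceeds the "
            f"Nyquist frequency {nyq} Hz"
        )
    return signal.butter(order, [band.low, band.high], btype="bandpass",
                         fs=sample_rate, output="sos")


def bandpass_filter(
    data: np.ndarray,
    band: BandDef,
    sample_rate: float = SAMPLE_RATE,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase band-pass filter along the last (time) axis.

    Forward-backward Butterworth, order 2 by default: no group delay, unit
    gain at the band center, >20 dB attenuation one octave outside the
    edges. The low order keeps impulse-response ringing short, which matters
    for peak-latency measurement on short epochs; raise `order` for sharper
    stopbands.
    """
    sos = _band_sos(band, sample_rate, order)
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def segment_epochs(
    continuous: np.ndarray,
    events: list[tuple[int, str]],
    window: EpochWindow,
    subject_id: str = "",
    condition: str = "",
    sample_rate: float = SAMPLE_RATE,
) -> EpochSet:
    """Cut a continuous (channels x times) recording into lock-event epochs.

    Each event sample is placed at time 0 of the half-open window
    [start, end). Events whose window would leave the recording are dropped
    and logged, never zero-padded.
    """
    continuous = np.asarray(continuous)
    n_times = continuous.shape[1]
    pre = int(round(-window.start * sample_rate / 1000.0))
    length = window.n_samples
    kept, dropped = [], 0
    for sample, _kind in events:
        lo = sample - pre
        if lo < 0 or lo + length > n_times:
            dropped += 1
            continue
        kept.append(continuous[:, lo:lo + length])
    if dropped:
        logger.warning("segment_epochs: dropped %d/%d events at recording edges",
                       dropped, len(events))
    data = np.stack(kept) if kept else np.empty((0, continuous.shape[0], length))
    n = data.shape[0]
    return EpochSet(
        subject_id=subject_id, task=window.task, condition=condition,
        lock=window.lock, data=data,
        correct=np.ones(n, dtype=bool), rt=np.full(n, np.nan),
    )


def baseline_correct(data: np.ndarray, window: EpochWindow) -> np.ndarray:
    """Subtract the per-channel mean of the pre-lock baseline interval."""
    t = window.times()
    lo, hi = window.baseline_interval()
    mask = (t >= lo) & (t < hi)
    return data - data[..., mask].mean(axis=-1, keepdims=True)


def average_erp(epochs: EpochSet, band: BandDef) -> ERP:
    """Average the correct trials, band-filter and baseline-correct.

    Only trials flagged correct enter the average; incorrect trials are
    ignored entirely. Equivalent to filtering every trial first (linearity).
    """
    mask = epochs.correct
    n = int(mask.sum())
    if n < 1:
        raise ValueError(
            f"no correct trials to average for {epochs.task}/{epochs.condition}"
        )
    mean = epochs.data[mask].mean(axis=0, dtype=float)
    filtered = bandpass_filter(mean, band, epochs.sample_rate)
    corrected = baseline_correct(filtered, epochs.window)
    return ERP(
        subject_id=epochs.subject_id, task=epochs.task,
        condition=epochs.condition, lock=epochs.lock, band=band.name,
        data=corrected, n_trials=n, sample_rate=epochs.sample_rate,
    )
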