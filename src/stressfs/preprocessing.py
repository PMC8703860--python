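"""Raw multichannel EEG -> clean, referenced, fixed-length labeled epochs.

The preprocessing chain mirrors common wearable-EEG practice: a zero-phase
FIR band-pass (default 0.5-35 Hz) to remove DC drift and mains noise, a
common average reference (CAR), and fixed-length epoching against a task
schedule.  Artifact rejection (ICA etc.) is deliberately out of scope: the
library expects pre-cleaned input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import (
    InsufficientChannelsError,
    InvalidBandError,
    ScheduleError,
    TooShortSignalError,
)

__all__ = [
    "EEGRecording",
    "EpochSet",
    "bandpass_filter",
    "common_average_reference",
    "segment_epochs",
]

REST, STRESS = 0, 1


@dataclass(frozen=True)
class EEGRecording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        Ordered, unique channel labels.  Defaults to ``ch00, ch01, ...``.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = ()

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if data.shape[0] < 2:
            raise InsufficientChannelsError(
                f"a recording needs >= 2 channels, got {data.shape[0]}"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(data)):
            raise ValueError("recording contains non-finite samples")
        names = tuple(self.channel_names) or tuple(
            f"ch{i:02d}" for i in range(data.shape[0])
        )
        if len(names) != data.shape[0]:
            raise ValueError("channel_names length does not match channel count")
        if len(set(names)) != len(names):
            raise ValueError("channel_names must be unique")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs


@dataclass(frozen=True)
class EpochSet:
    """Fixed-length windows with optional per-epoch class labels.

    ``epochs`` has shape (n_epochs, n_channels, samples_per_epoch); labels,
    when present, are 0 (rest) / 1 (stress), one per epoch.
    """

    epochs: np.ndarray
    fs: float
    window_s: float
    labels: np.ndarray | None = None
    channel_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        epochs = np.asarray(self.epochs, dtype=float)
        if epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch x channel x sample)")
        if epochs.shape[0] < 1:
            raise ValueError("need at least one epoch")
        expected = int(round(self.window_s * self.fs))
        if epochs.shape[2] != expected:
            raise ValueError(
                f"samples_per_epoch {epochs.shape[2]} != round(window_s * fs) = {expected}"
            )
        labels = self.labels
        if labels is not None:
            labels = np.asarray(labels, dtype=int)
            if labels.shape != (epochs.shape[0],):
                raise ValueError("labels length must equal number of epochs")
        names = tuple(self.channel_names) or tuple(
            f"ch{i:02d}" for i in range(epochs.shape[1])
        )
        if len(names) != epochs.shape[1]:
            raise ValueError("channel_names length does not match channel count")
        object.__setattr__(self, "epochs", epochs)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


def _design_fir(fs: float, lo: float, hi: float, transition_hz: float) -> np.ndarray:
    """Windowed-sinc (Hamming) band-pass taps with ~``transition_hz`` transition band."""
    # Hamming window: transition width ~ 3.3 / numtaps (normalized frequency).
    numtaps = int(np.ceil(3.3 * fs / transition_hz))
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=fs)


def bandpass_filter(
    rec: EEGRecording,
    lo: float = 0.5,
    hi: float = 35.0,
    transition_hz: float = 1.0,
) -> EEGRecording:
    """Zero-phase FIR band-pass of every channel.

    The filter is a windowed-sinc (Hamming) design applied forward-backward
    (``filtfilt``), so it introduces no group delay and epoch boundaries are
    preserved.  Stop-band attenuation is doubled by the two passes.

    Raises
    ------
    InvalidBandError
        If the band is empty or ``hi`` reaches the Nyquist frequency.
    TooShortSignalError
        If the recording is shorter than three filter lengths.
    """
    nyq = rec.fs / 2.0
    if not (0.0 < lo < hi):
        raise InvalidBandError(f"need 0 < lo < hi, got [{lo}, {hi}]")
    if hi >= nyq:
        raise InvalidBandError(f"hi = {hi} Hz reaches Nyquist ({nyq} Hz)")
    taps = _design_fir(rec.fs, lo, hi, transition_hz)
    if rec.n_samples <= 3 * len(taps):
        raise TooShortSignalError(
            f"signal of {rec.n_samples} samples too short for a "
            f"{len(taps)}-tap zero-phase filter (needs > {3 * len(taps)})"
        )
    # even reflection keeps the extension continuous for oscillatory signals,
    # which keeps forward-backward edge transients small
    filtered = signal.filtfilt(taps, [1.0], rec.data, axis=1, padtype="even")
    return replace(rec, data=filtered)


def common_average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous cross-channel mean from every channel.

    After re-referencing, the mean across channels is zero at every sample.
    Idempotent and linear, so it commutes with any per-channel linear filter.
    """
    if rec.n_channels < 2:
        raise InsufficientChannelsError("common average reference needs >= 2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def segment_epochs(
    rec: EEGRecording,
    window_s: float,
    schedule: list[tuple[float, int | None]],
) -> EpochSet:
    """Cut fixed-length windows out of a recording.

    Parameters
    ----------
    schedule : list of (start_s, label)
        One entry per epoch: window start in seconds (half-open window
        ``[start, start + window_s)``) and class label (0 = rest,
        1 = stress, or None for unlabeled).  All labels must be None, or
        none of them.

    Raises
    ------
    ScheduleError
        On an empty schedule or a window extending past the recording end.
    """
    if window_s <= 0:
        raise ValueError(f"window_s must be positive, got {window_s}")
    if not schedule:
        raise ScheduleError("schedule is empty")
    n_samp = int(round(window_s * rec.fs))
    raw_labels = [lab for _, lab in schedule]
    if any(lab is None for lab in raw_labels) and not all(
        lab is None for lab in raw_labels
    ):
        raise ScheduleError("schedule mixes labeled and unlabeled entries")
    chunks = []
    for start_s, lab in schedule:
        start = int(round(start_s * rec.fs))
        stop = start + n_samp
        if start < 0 or stop > rec.n_samples:
            raise ScheduleError(
                f"window [{start_s}, {start_s + window_s}) s (entry "
                f"({start_s}, {lab})) lies outside the "
                f"{rec.duration:.3f} s recording"
            )
        chunks.append(rec.data[:, start:stop].copy())
    labels = None if raw_labels[0] is None else np.asarray(raw_labels, dtype=int)
    return EpochSet(
        epochs=np.stack(chunks, axis=0),
        fs=rec.fs,
        window_s=window_s,
        labels=labels,
        channel_names=rec.channel_names,
    )
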