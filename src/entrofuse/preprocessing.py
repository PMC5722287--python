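"""Filtering and epoch segmentation of multichannel EEG recordings.

A :class:`Recording` is a labeled channels x samples matrix (microvolts)
with its sampling rate and montage. Recordings are notch- and band-pass
filtered with zero-phase IIR filters and then cut into non-overlapping
fixed-length epochs, the unit of classification downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

STATES = ("normal", "fatigue")


@dataclass(frozen=True)
class Recording:
    """A labeled multichannel EEG recording.

    Parameters
    ----------
    subject_id : str
        Identifier of the recorded subject.
    state : str
        Vigilance-state label, ``"normal"`` or ``"fatigue"``.
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        Ordered 10-20 montage labels, one per signal row.
    """

    subject_id: str
    state: str
    signal: np.ndarray
    fs: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if sig.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples array")
        if len(self.channel_names) != sig.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {sig.shape[0]} signal rows"
            )
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _check_cutoff(hz: float, fs: float, name: str) -> None:
    if not 0 < hz < fs / 2:
        raise ValueError(f"{name}={hz} Hz must lie in (0, fs/2) = (0, {fs / 2})")


def bandpass_filter(
    rec: Recording, low_hz: float = 0.15, high_hz: float = 45.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass filter.

    An order-``order`` Butterworth band-pass is applied forward and
    backward (``sosfiltfilt``), so the pass band is effectively squared
    and no phase shift is introduced — epoch boundaries stay aligned
    with the raw signal.
    """
    _check_cutoff(low_hz, rec.fs, "low_hz")
    _check_cutoff(high_hz, rec.fs, "high_hz")
    if not low_hz < high_hz:
        raise ValueError("low_hz must be below high_hz")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    return replace(rec, signal=sps.sosfiltfilt(sos, rec.signal, axis=1))


def notch_filter(rec: Recording, center_hz: float = 50.0, quality: float = 30.0) -> Recording:
    """Zero-phase IIR notch (quality factor 30 by default) at ``center_hz``."""
    _check_cutoff(center_hz, rec.fs, "center_hz")
    b, a = sps.iirnotch(center_hz, quality, fs=rec.fs)
    return replace(rec, signal=sps.filtfilt(b, a, rec.signal, axis=1))


@dataclass(frozen=True)
class EpochSet:
    """Non-overlapping fixed-length windows cut from one or more recordings.

    ``epochs`` has shape (n_epochs, n_channels, epoch_len); each epoch
    carries the state label and subject id of its source recording.
    """

    epochs: np.ndarray
    fs: float
    epoch_length_s: float
    labels: np.ndarray
    subject_ids: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", np.asarray(self.epochs, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels))
        object.__setattr__(self, "subject_ids", np.asarray(self.subject_ids))
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, length)")
        n = self.epochs.shape[0]
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError("labels/subject_ids length must match epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @staticmethod
    def concat(parts: Sequence["EpochSet"]) -> "EpochSet":
        """Stack epoch sets from several recordings (same montage and fs)."""
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if p.channel_names != first.channel_names or p.fs != first.fs:
                raise ValueError("epoch sets differ in montage or sampling rate")
        return EpochSet(
            epochs=np.concatenate([p.epochs for p in parts], axis=0),
            fs=first.fs,
            epoch_length_s=first.epoch_length_s,
            labels=np.concatenate([p.labels for p in parts]),
            subject_ids=np.concatenate([p.subject_ids for p in parts]),
            channel_names=first.channel_names,
        )


def segment_epochs(rec: Recording, epoch_length_s: float = 1.0) -> EpochSet:
    """Cut a recording into contiguous epochs from sample 0.

    The trailing partial window is discarded, so the epoch count is
    ``floor(n_samples / L)`` with ``L = round(epoch_length_s * fs)``.
    """
    length = int(round(epoch_length_s * rec.fs))
    if length < 1:
        raise ValueError("epoch length shorter than one sample")
    n = rec.n_samples // length
    if n == 0:
        raise ValueError(
            f"recording of {rec.duration_s:.3f} s is shorter than one "
            f"{epoch_length_s} s epoch"
        )
    cut = rec.signal[:, : n * length]
    epochs = cut.reshape(rec.n_channels, n, length).transpose(1, 0, 2)
    return EpochSet(
        epochs=epochs,
        fs=rec.fs,
        epoch_length_s=epoch_length_s,
        labels=np.repeat(rec.state, n),
        subject_ids=np.repeat(rec.subject_id, n),
        channel_names=rec.channel_names,
    )


def preprocess_recording(
    rec: Recording,
    notch_hz: float = 50.0,
    band: tuple[float, float] = (0.15, 45.0),
    epoch_length_s: float = 1.0,
) -> EpochSet:
    """Standard chain: notch, band-pass, segment."""
    filtered = bandpass_filter(notch_filter(rec, notch_hz), *band)
    return segment_epochs(filtered, epoch_length_s)


def segment_recordings(
    recs: Iterable[Recording],
    notch_hz: float = 50.0,
    band: tuple[float, float] = (0.15, 45.0),
    epoch_length_s: float = 1.0,
) -> EpochSet:
    """Preprocess and pool several recordings into one EpochSet."""
    return EpochSet.concat([preprocess_recording(r, notch_hz, band, epoch_length_s) for r in recs])
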