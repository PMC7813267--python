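"""Filtering, epoching, detrending, baselining, and the bipolar hEOG.

Filters are 4th-order Butterworth sections applied forward-backward
(zero phase), high-pass and low-pass cascaded.  Epochs run from −200 ms to
+1000 ms around stimulus onset with both endpoints included (1201 samples
at 1000 Hz); time 0 is the stimulus-onset sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_core import EventList, Recording

__all__ = [
    "Epochs",
    "filter_recording",
    "epoch_recording",
    "detrend_epochs",
    "baseline_epochs",
    "derive_heog",
]

EPOCH_TMIN_S = -0.2
EPOCH_TMAX_S = 1.0
BASELINE_MS = (-200.0, 0.0)


@dataclass
class Epochs:
    """Segmented trials: (n_trials, n_channels, n_samples) in µV.

    ``keep`` is the running keep-mask; artifact-rejection stages clear
    entries and record a reason in ``rejection_reason`` (empty string for
    kept trials).
    """

    data: np.ndarray
    channel_labels: tuple[str, ...]
    times_ms: np.ndarray
    conditions: np.ndarray
    sampling_rate: float
    keep: np.ndarray = field(default=None)  # type: ignore[assignment]
    rejection_reason: list[str] = field(default=None)  # type: ignore

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.conditions = np.asarray(self.conditions)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis mismatch")
        if self.data.shape[2] != len(self.times_ms):
            raise ValueError("time axis mismatch")
        if len(self.conditions) != self.n_trials:
            raise ValueError("conditions length mismatch")
        if self.keep is None:
            self.keep = np.ones(self.n_trials, dtype=bool)
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.shape != (self.n_trials,):
            raise ValueError("keep mask length mismatch")
        if self.rejection_reason is None:
            self.rejection_reason = [""] * self.n_trials

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label} missing") from None

    def time_slice(self, start_ms: float, end_ms: float) -> slice:
        """Inclusive sample range covering the closed window [start, end] ms."""
        t = self.times_ms
        if start_ms < t[0] - 1e-9 or end_ms > t[-1] + 1e-9:
            raise ValueError(f"window [{start_ms}, {end_ms}] outside epoch")
        i0 = int(np.searchsorted(t, start_ms - 1e-9))
        i1 = int(np.searchsorted(t, end_ms + 1e-9))
        return slice(i0, i1)

    def reject(self, idx: np.ndarray, reason: str) -> None:
        """Clear the keep-mask at ``idx``, recording ``reason`` once per trial."""
        for i in np.flatnonzero(idx):
            if self.keep[i]:
                self.keep[i] = False
                self.rejection_reason[i] = reason

    def copy(self) -> "Epochs":
        return Epochs(
            self.data.copy(), self.channel_labels, self.times_ms.copy(),
            self.conditions.copy(), self.sampling_rate, self.keep.copy(),
            list(self.rejection_reason),
        )


def filter_recording(rec: Recording, highpass_hz: float,
                     lowpass_hz: float) -> Recording:
    """Zero-phase band-pass (cascaded 4th-order Butterworth high/low-pass)."""
    nyq = rec.sampling_rate / 2
    if not 0 < highpass_hz < lowpass_hz:
        raise ValueError("need 0 < highpass < lowpass")
    if lowpass_hz >= nyq:
        raise ValueError(f"low-pass {lowpass_hz} Hz must be below "
                         f"Nyquist ({nyq} Hz)")
    sos_hp = signal.butter(4, highpass_hz, "highpass", fs=rec.sampling_rate,
                           output="sos")
    sos_lp = signal.butter(4, lowpass_hz, "lowpass", fs=rec.sampling_rate,
                           output="sos")
    out = signal.sosfiltfilt(sos_hp, rec.data, axis=1)
    out = signal.sosfiltfilt(sos_lp, out, axis=1)
    return Recording(rec.channel_labels, rec.reference_label,
                     rec.sampling_rate, out, rec.subject_id)


def epoch_recording(rec: Recording, events: EventList,
                    tmin_s: float = EPOCH_TMIN_S,
                    tmax_s: float = EPOCH_TMAX_S) -> Epochs:
    """Cut one trial per event over the closed interval [tmin, tmax].

    Raises if any epoch would extend past the recording, naming the event.
    """
    fs = rec.sampling_rate
    off0 = int(round(tmin_s * fs))
    off1 = int(round(tmax_s * fs))
    n_samp = off1 - off0 + 1
    trials = np.empty((len(events), len(rec.channel_labels), n_samp))
    for k, ev in enumerate(events):
        a = ev.onset_sample + off0
        b = ev.onset_sample + off1
        if a < 0 or b >= rec.n_samples:
            raise ValueError(
                f"epoch for event {k} (onset sample {ev.onset_sample}) "
                f"exceeds recording bounds")
        trials[k] = rec.data[:, a:b + 1]
    times_ms = (np.arange(off0, off1 + 1) / fs) * 1000.0
    return Epochs(trials, rec.channel_labels, times_ms,
                  events.conditions, fs)


def detrend_epochs(epochs: Epochs) -> Epochs:
    """Remove a per-trial, per-channel least-squares line over the epoch."""
    out = epochs.copy()
    n = out.data.shape[2]
    t = np.arange(n, dtype=float)
    t -= t.mean()
    denom = (t ** 2).sum()
    y = out.data
    mean = y.mean(axis=2, keepdims=True)
    slope = (y * t).sum(axis=2, keepdims=True) / denom
    out.data = y - mean - slope * t
    return out


def baseline_epochs(epochs: Epochs,
                    window_ms: tuple[float, float] = BASELINE_MS) -> Epochs:
    """Subtract the mean of the baseline window per trial and channel."""
    sl = epochs.time_slice(*window_ms)
    if sl.stop - sl.start < 1:
        raise ValueError("empty baseline window")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, sl].mean(axis=2, keepdims=True)
    return out


def derive_heog(obj: Epochs | Recording) -> Epochs | Recording:
    """Append a bipolar horizontal EOG channel, hEOG = F7 − F8 samplewise."""
    if isinstance(obj, Recording):
        i7, i8 = obj.channel_index("F7"), obj.channel_index("F8")
        heog = obj.data[i7] - obj.data[i8]
        return Recording(obj.channel_labels + ("hEOG",), obj.reference_label,
                         obj.sampling_rate, np.vstack([obj.data, heog[None]]),
                         obj.subject_id)
    i7, i8 = obj.channel_index("F7"), obj.channel_index("F8")
    heog = obj.data[:, i7] - obj.data[:, i8]
    return Epochs(
        np.concatenate([obj.data, heog[:, None, :]], axis=1),
        obj.channel_labels + ("hEOG",), obj.times_ms, obj.conditions,
        obj.sampling_rate, obj.keep.copy(), list(obj.rejection_reason),
    )
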