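"""Subject and grand averaging of event-related potentials.

All statistics downstream operate on subject-level condition averages
(the subject is the unit of analysis), never on pooled trials.  Analysis
windows are closed intervals in milliseconds mapped to inclusive sample
ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CONDITIONS
from .preprocess import Epochs

__all__ = [
    "SubjectERP",
    "GrandERP",
    "average_subject",
    "grand_average",
    "window_mean",
    "subject_window_means",
    "erp_to_frame",
]


@dataclass
class SubjectERP:
    """Condition-wise averaged waveforms for one subject.

    ``waveforms[condition]`` is (n_channels, n_samples) in µV, averaged over
    kept trials only.
    """

    subject_id: str
    waveforms: dict[str, np.ndarray]
    channel_labels: tuple[str, ...]
    times_ms: np.ndarray
    n_clean: dict[str, int]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label} missing") from None

    def time_slice(self, start_ms: float, end_ms: float) -> slice:
        t = self.times_ms
        if start_ms < t[0] - 1e-9 or end_ms > t[-1] + 1e-9:
            raise ValueError(f"window [{start_ms}, {end_ms}] outside epoch")
        i0 = int(np.searchsorted(t, start_ms - 1e-9))
        i1 = int(np.searchsorted(t, end_ms + 1e-9))
        return slice(i0, i1)


@dataclass
class GrandERP:
    """Across-subject mean waveforms and standard errors per condition.

    SE = sd/sqrt(n) over the subject averages, each subject weighted once
    regardless of its clean-trial count.
    """

    mean: dict[str, np.ndarray]
    se: dict[str, np.ndarray]
    channel_labels: tuple[str, ...]
    times_ms: np.ndarray
    n_subjects: int


def average_subject(epochs: Epochs, subject_id: str = "") -> SubjectERP:
    """Pointwise mean over kept trials, separately per condition."""
    waveforms, n_clean = {}, {}
    for c in CONDITIONS:
        m = (epochs.conditions == c) & epochs.keep
        if not m.any():
            raise ValueError(f"no clean trials in condition {c}")
        waveforms[c] = epochs.data[m].mean(axis=0)
        n_clean[c] = int(m.sum())
    return SubjectERP(subject_id, waveforms, epochs.channel_labels,
                      epochs.times_ms.copy(), n_clean)


def grand_average(erps: list[SubjectERP]) -> GrandERP:
    """Unweighted mean across subjects with per-point standard error."""
    if len(erps) < 2:
        raise ValueError("grand average needs at least 2 subjects")
    mean, se = {}, {}
    for c in CONDITIONS:
        stack = np.stack([e.waveforms[c] for e in erps])
        mean[c] = stack.mean(axis=0)
        se[c] = stack.std(axis=0, ddof=1) / np.sqrt(len(erps))
    return GrandERP(mean, se, erps[0].channel_labels,
                    erps[0].times_ms.copy(), len(erps))


def window_mean(erp: SubjectERP, condition: str, electrode: str,
                window_ms: tuple[float, float]) -> float:
    """Mean amplitude (µV) of one condition waveform over a closed window."""
    sl = erp.time_slice(*window_ms)
    ch = erp.channel_index(electrode)
    return float(erp.waveforms[condition][ch, sl].mean())


def subject_window_means(erps: list[SubjectERP],
                         electrodes: tuple[str, ...],
                         windows_ms: list[tuple[float, float]]) -> np.ndarray:
    """Window means as (n_subjects, n_conditions, n_electrodes, n_windows).

    Condition order follows :data:`~erpwp.io_core.CONDITIONS`.
    """
    out = np.empty((len(erps), len(CONDITIONS), len(electrodes),
                    len(windows_ms)))
    for i, erp in enumerate(erps):
        for j, c in enumerate(CONDITIONS):
            for k, el in enumerate(electrodes):
                for w, win in enumerate(windows_ms):
                    out[i, j, k, w] = window_mean(erp, c, el, win)
    return out


def erp_to_frame(erps: list[SubjectERP]) -> pd.DataFrame:
    """Tidy export: subject, condition, channel, time_ms, amplitude_uv."""
    rows = []
    for erp in erps:
        for c, wf in erp.waveforms.items():
            for ch_i, ch in enumerate(erp.channel_labels):
                rows.append(pd.DataFrame({
                    "subject": erp.subject_id,
                    "condition": c,
                    "channel": ch,
                    "time_ms": erp.times_ms,
                    "amplitude_uv": wf[ch_i],
                }))
    return pd.concat(rows, ignore_index=True)
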