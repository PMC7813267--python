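"""Trial-rejection procedures and subject inclusion rules.

Two quantitative screens are implemented:

* amplitude rejection — a trial is rejected if, on any checked channel,
  (a) any sample exceeds ±``abs_threshold_uv`` (strict inequality), or
  (b) any 100 ms sliding window (stepped by one sample) has a
  max−min range exceeding ``range_threshold_uv`` (strict inequality);
* annotation rejection — a trial is rejected if any annotated interval
  (e.g. a logged body movement) has strictly positive overlap with
  [onset − 0.5 s, onset + 1.0 s].

The multi-level cleaning screens Fz, Cz plus the EOG channels (F7, F8,
hEOG); the amplitude-based cleaning screens only the analysis channels
(Fz, Cz).  The human steps of the multi-level procedure (video annotation,
visual inspection) enter only as the annotation file; the qualitative
EOG-to-scalp correlation screen has no published threshold and is not
implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_core import CONDITIONS, AnnotationList, EventList
from .preprocess import Epochs

__all__ = [
    "CleaningReport",
    "reject_amplitude",
    "reject_by_annotations",
    "include_subject",
    "summarize_cleaning",
    "MULTI_LEVEL_CHANNELS",
    "ANALYSIS_CHANNELS",
]

ANALYSIS_CHANNELS = ("Fz", "Cz")
MULTI_LEVEL_CHANNELS = ("Fz", "Cz", "F7", "F8", "hEOG")


@dataclass
class CleaningReport:
    """Per-subject/condition bookkeeping of the cleaning outcome."""

    subject_id: str
    n_total: dict[str, int]
    n_rejected_amplitude: dict[str, int]
    n_rejected_annotation: dict[str, int]
    n_clean: dict[str, int]

    def __post_init__(self) -> None:
        for c in self.n_total:
            total = (self.n_clean[c] + self.n_rejected_amplitude[c]
                     + self.n_rejected_annotation[c])
            if total != self.n_total[c]:
                raise ValueError(f"counts inconsistent for condition {c}")

    @property
    def percent_rejected(self) -> float:
        tot = sum(self.n_total.values())
        rej = tot - sum(self.n_clean.values())
        return 100.0 * rej / tot if tot else 0.0

    @classmethod
    def from_epochs(cls, epochs: Epochs, subject_id: str = "") -> "CleaningReport":
        conds = epochs.conditions
        reasons = np.array(epochs.rejection_reason)
        out = {}
        for key in ("n_total", "n_rejected_amplitude",
                    "n_rejected_annotation", "n_clean"):
            out[key] = {}
        for c in CONDITIONS:
            m = conds == c
            out["n_total"][c] = int(m.sum())
            out["n_clean"][c] = int((m & epochs.keep).sum())
            out["n_rejected_amplitude"][c] = int(
                (m & ~epochs.keep & (reasons == "amplitude")).sum())
            out["n_rejected_annotation"][c] = int(
                (m & ~epochs.keep & (reasons == "annotation")).sum())
        return cls(subject_id, **out)


def amplitude_mask(epochs: Epochs, abs_threshold_uv: float,
                   range_threshold_uv: float, window_ms: float = 100.0,
                   channels: tuple[str, ...] = ANALYSIS_CHANNELS,
                   ) -> np.ndarray:
    """Boolean array: True where a trial violates either amplitude rule.

    The sliding range window spans ``window_ms`` inclusive of both
    endpoints (101 samples at 1000 Hz) and is stepped by one sample.
    """
    if abs_threshold_uv <= 0 or range_threshold_uv <= 0:
        raise ValueError("thresholds must be positive")
    w = int(round(window_ms * epochs.sampling_rate / 1000.0)) + 1
    n_samp = epochs.data.shape[2]
    if w > n_samp:
        raise ValueError("range window longer than epoch")
    idx = [epochs.channel_index(ch) for ch in channels]
    x = epochs.data[:, idx, :]
    bad_abs = (np.abs(x) > abs_threshold_uv).any(axis=(1, 2))
    # running max/min over w-sample windows via 1-D max filters
    mx = ndimage.maximum_filter1d(x, size=w, axis=2, mode="nearest")
    mn = ndimage.minimum_filter1d(x, size=w, axis=2, mode="nearest")
    # valid window centers: filters are centered; restrict to spans fully
    # inside the epoch
    left = w // 2
    valid = slice(left, left + (n_samp - w + 1))
    rng = (mx - mn)[:, :, valid]
    bad_range = (rng > range_threshold_uv).any(axis=(1, 2))
    return bad_abs | bad_range


def reject_amplitude(epochs: Epochs, abs_threshold_uv: float,
                     range_threshold_uv: float, window_ms: float = 100.0,
                     channels: tuple[str, ...] = ANALYSIS_CHANNELS,
                     ) -> Epochs:
    """Apply the amplitude/range screen, updating the keep-mask in a copy."""
    bad = amplitude_mask(epochs, abs_threshold_uv, range_threshold_uv,
                         window_ms, channels)
    out = epochs.copy()
    out.reject(bad, "amplitude")
    return out


def reject_by_annotations(epochs: Epochs, events: EventList,
                          annotations: AnnotationList,
                          pre_s: float = 0.5, post_s: float = 1.0) -> Epochs:
    """Reject trials whose [onset−pre, onset+post] window overlaps any
    annotation; overlap must be strictly positive (half-open intervals)."""
    if len(events) != epochs.n_trials:
        raise ValueError("events/epochs length mismatch")
    fs = events.sampling_rate
    onsets = events.onsets / fs
    starts = onsets - pre_s
    ends = onsets + post_s
    bad = np.zeros(epochs.n_trials, dtype=bool)
    for ann in annotations:
        overlap = (np.minimum(ends, ann.end_s)
                   - np.maximum(starts, ann.start_s))
        bad |= overlap > 0
    out = epochs.copy()
    out.reject(bad, "annotation")
    return out


def include_subject(report: CleaningReport,
                    min_per_condition: int = 10) -> bool:
    """Inclusion rule: at least ``min_per_condition`` clean trials in every
    condition."""
    missing = set(CONDITIONS) - set(report.n_clean)
    if missing:
        raise ValueError(f"report lacks conditions {sorted(missing)}")
    return all(report.n_clean[c] >= min_per_condition for c in CONDITIONS)


@dataclass
class CohortCleaningSummary:
    """Cohort aggregate mirroring the published per-condition layout."""

    per_condition: dict[str, dict[str, float]]
    percent_rejected: float
    n_subjects: int
    included: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


def summarize_cleaning(reports: list[CleaningReport],
                       min_per_condition: int = 10) -> CohortCleaningSummary:
    """Aggregate per-subject reports: clean-trial mean/sd/min/max per
    condition and the overall rejected percentage."""
    if not reports:
        raise ValueError("no reports")
    per_cond = {}
    for c in CONDITIONS:
        counts = np.array([r.n_clean[c] for r in reports], dtype=float)
        per_cond[c] = {
            "mean": float(counts.mean()),
            "sd": float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
            "min": float(counts.min()),
            "max": float(counts.max()),
        }
    total = sum(sum(r.n_total.values()) for r in reports)
    clean = sum(sum(r.n_clean.values()) for r in reports)
    included = [r.subject_id for r in reports
                if include_subject(r, min_per_condition)]
    excluded = [r.subject_id for r in reports
                if not include_subject(r, min_per_condition)]
    return CohortCleaningSummary(
        per_condition=per_cond,
        percent_rejected=100.0 * (total - clean) / total if total else 0.0,
        n_subjects=len(reports),
        included=included,
        excluded=excluded,
    )
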