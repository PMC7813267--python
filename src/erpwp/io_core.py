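"""Domain containers and file I/O for the awake-dog ERP pipeline.

Continuous EEG travels as EDF (16-bit European Data Format, physical unit
fixed to microvolts); events, movement annotations and owner-reported
covariates travel as tab-separated tables with a header row; results are
serialized to JSON.  Reading EDF goes through :func:`mne.io.read_raw_edf`;
writing uses the small EDF writer in this module (one data record per
second, digital range the full 16 bits).

Conventions
-----------
* Sample indices are 0-based; event onsets are stored in seconds in the TSV
  (``onset_s``) and converted to sample indices on read.
* Epoch and analysis windows are expressed in milliseconds relative to
  stimulus onset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "Recording",
    "Event",
    "EventList",
    "Annotation",
    "AnnotationList",
    "CovariateTable",
    "CleaningConfig",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_annotations",
    "write_annotations",
    "read_covariates",
    "write_covariates",
    "write_json",
]

#: The three word-type conditions, in canonical order.
CONDITIONS = ("WORDS", "SIMILAR", "NONSENSE")

#: Channels every analysis recording must provide (referenced to Pz).
REQUIRED_CHANNELS = ("Fz", "Cz", "F7", "F8")


class FormatError(ValueError):
    """Raised when an input file violates the expected format or contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    Parameters
    ----------
    channel_labels : ordered channel names; must be unique.
    reference_label : label of the recording reference electrode (Pz).
    sampling_rate : sampling frequency in Hz, > 0.
    data : array of shape (n_channels, n_samples), microvolts.
    subject_id : free-text subject identifier.
    """

    channel_labels: tuple[str, ...]
    reference_label: str
    sampling_rate: float
    data: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be (n_channels, n_samples)")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label} missing") from None

    def get(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]


@dataclass(frozen=True)
class Event:
    onset_sample: int
    condition: str
    stimulus_id: str
    speaker: int
    version: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class EventList:
    """Stimulus events; onsets strictly increasing, in samples."""

    events: list[Event]
    sampling_rate: float

    def __post_init__(self) -> None:
        onsets = [e.onset_sample for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset_sample for e in self.events], dtype=int)

    @property
    def conditions(self) -> np.ndarray:
        return np.array([e.condition for e in self.events])


@dataclass(frozen=True)
class Annotation:
    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("annotation end must exceed start")


@dataclass
class AnnotationList:
    annotations: list[Annotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)

    def __getitem__(self, i):
        return self.annotations[i]


@dataclass
class CovariateTable:
    """Owner-reported covariates on a 5-point scale, one row per subject.

    ``usage_frequency`` and ``behavioural_consistency`` are each the mean of
    a 5-point Likert rating over the four instruction words, so values must
    lie in [1, 5].
    """

    table: pd.DataFrame

    FIELDS = ("usage_frequency", "behavioural_consistency")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        for col in ("subject_id",) + self.FIELDS:
            if col not in df.columns:
                raise FormatError(f"covariate table missing column {col!r}")
        for col in self.FIELDS:
            vals = df[col].astype(float)
            if ((vals < 1) | (vals > 5)).any():
                raise ValueError(f"{col} values must lie in [1, 5]")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.table["subject_id"]]

    def values(self, fieldname: str) -> np.ndarray:
        if fieldname not in self.FIELDS:
            raise KeyError(fieldname)
        return self.table[fieldname].to_numpy(dtype=float)


@dataclass(frozen=True)
class CleaningConfig:
    """Constants of one artifact-cleaning variant.

    The two analysis variants mirror the published procedures:

    * ``multi_level_quant`` — 0.01–40 Hz band, reject at ±150 µV absolute or
      150 µV peak-to-peak in 100 ms sliding windows, with video-annotation
      based rejection of trials overlapping movement intervals.
    * ``amplitude_based`` — 0.3–40 Hz band, stricter ±100 µV absolute /
      120 µV peak-to-peak thresholds, no annotation step.
    * ``visualization`` — amplitude-based variant with a 20 Hz low-pass, used
      only for waveform display exports.
    """

    variant: str
    highpass_hz: float
    lowpass_hz: float
    abs_threshold_uv: float
    range_threshold_uv: float
    range_window_ms: float = 100.0
    use_annotations: bool = False

    def __post_init__(self) -> None:
        if self.abs_threshold_uv <= 0 or self.range_threshold_uv <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise ValueError("need 0 < highpass < lowpass")

    @classmethod
    def multi_level(cls) -> "CleaningConfig":
        return cls("multi_level_quant", 0.01, 40.0, 150.0, 150.0,
                   use_annotations=True)

    @classmethod
    def amplitude_based(cls) -> "CleaningConfig":
        return cls("amplitude_based", 0.3, 40.0, 100.0, 120.0)

    @classmethod
    def visualization(cls) -> "CleaningConfig":
        return cls("visualization", 0.3, 20.0, 100.0, 120.0)


# ---------------------------------------------------------------------------
# EDF writing (16-bit, µV, 1-second records)
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_recording(path: str | Path, rec: Recording) -> Path:
    """Write a :class:`Recording` as a 16-bit EDF file (physical unit µV).

    Record duration is one second; recordings whose length is not a whole
    number of seconds are zero-padded to the next full second.  The subject
    id and the reference label are stored in the EDF identification fields
    and recovered by :func:`read_recording`.
    """
    path = Path(path)
    fs = rec.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    n_ch = len(rec.channel_labels)
    n_rec = max(1, math.ceil(rec.n_samples / spr))
    data = np.zeros((n_ch, n_rec * spr))
    data[:, : rec.n_samples] = rec.data

    # symmetric physical range per channel; 16-bit digital range
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    phys_max = phys_max * 1.0001  # keep extremes strictly inside the range
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.rint((data + phys_max[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    header = b""
    header += _pad("0", 8)                                     # version
    header += _pad(f"subject:{rec.subject_id}", 80)            # patient id
    header += _pad(f"ref:{rec.reference_label}", 80)           # recording id
    header += _pad("01.01.00", 8) + _pad("00.00.00", 8)        # date, time
    header += _pad(str(256 * (1 + n_ch)), 8)                   # header bytes
    header += _pad("", 44)                                     # reserved
    header += _pad(str(n_rec), 8)
    header += _pad("1", 8)                                     # record dur, s
    header += _pad(str(n_ch), 4)

    def fld(values, width):
        return b"".join(_pad(str(v), width) for v in values)

    header += fld(rec.channel_labels, 16)
    header += fld(["" for _ in range(n_ch)], 80)               # transducer
    header += fld(["uV"] * n_ch, 8)                            # phys dim
    header += fld([f"{-m:.6g}"[:8] for m in phys_max], 8)
    header += fld([f"{m:.6g}"[:8] for m in phys_max], 8)
    header += fld([dig_min] * n_ch, 8)
    header += fld([dig_max] * n_ch, 8)
    header += fld(["" for _ in range(n_ch)], 80)               # prefiltering
    header += fld([spr] * n_ch, 8)
    header += fld(["" for _ in range(n_ch)], 32)               # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        # records: channel-major within each 1 s record
        interleaved = (
            digital.reshape(n_ch, n_rec, spr)
            .transpose(1, 0, 2)
            .copy()
        )
        fh.write(interleaved.tobytes())
    return path


def read_recording(path: str | Path,
                   required_channels: tuple[str, ...] = REQUIRED_CHANNELS,
                   ) -> Recording:
    """Read an EDF file into a :class:`Recording` (data in µV).

    Raises
    ------
    FormatError
        If the file cannot be parsed as EDF or a required channel is absent.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise FormatError(f"unreadable EDF header in {path}: {exc}") from exc
    labels = tuple(raw.ch_names)
    for ch in required_channels:
        if ch not in labels:
            raise FormatError(f"channel {ch} missing from {path}")
    data = raw.get_data(units="uV")
    subject_id, reference = "", "Pz"
    info_sub = raw.info.get("subject_info") or {}
    his = info_sub.get("his_id", "") or ""
    if his.startswith("subject:"):
        subject_id = his[len("subject:"):]
    meas_id = (raw.info.get("meas_id") or {})
    # reference label is re-parsed from the raw header (mne drops it)
    with open(path, "rb") as fh:
        fh.seek(88)
        rec_id = fh.read(80).decode("ascii", errors="replace").strip()
    if rec_id.startswith("ref:"):
        reference = rec_id[len("ref:"):].strip() or "Pz"
    return Recording(
        channel_labels=labels,
        reference_label=reference,
        sampling_rate=float(raw.info["sfreq"]),
        data=data,
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# TSV readers/writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def read_events(path: str | Path, sampling_rate: float,
                n_samples: int | None = None,
                epoch_end_s: float = 1.0) -> EventList:
    """Read an events TSV (onset_s, condition, stimulus_id, speaker, version).

    Onsets are converted from seconds to 0-based sample indices at
    ``sampling_rate``.  If ``n_samples`` is given, every epoch
    ``[onset, onset + epoch_end_s]`` must fit inside the recording.
    """
    df = _read_tsv(path, ("onset_s", "condition", "stimulus_id",
                          "speaker", "version"))
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise FormatError(f"unknown condition values {sorted(bad)}")
    events = [
        Event(
            onset_sample=int(round(row.onset_s * sampling_rate)),
            condition=str(row.condition),
            stimulus_id=str(row.stimulus_id),
            speaker=int(row.speaker),
            version=int(row.version),
        )
        for row in df.itertuples()
    ]
    ev = EventList(events, sampling_rate)
    if n_samples is not None:
        limit = n_samples - int(round(epoch_end_s * sampling_rate))
        for e in ev:
            if e.onset_sample > limit:
                raise FormatError(
                    f"event at sample {e.onset_sample} exceeds recording"
                )
    return ev


def write_events(path: str | Path, ev: EventList) -> Path:
    df = pd.DataFrame(
        {
            "onset_s": [e.onset_sample / ev.sampling_rate for e in ev],
            "condition": [e.condition for e in ev],
            "stimulus_id": [e.stimulus_id for e in ev],
            "speaker": [e.speaker for e in ev],
            "version": [e.version for e in ev],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_annotations(path: str | Path) -> AnnotationList:
    """Read an annotation TSV (start_s, end_s, label); may be empty."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for c in ("start_s", "end_s", "label"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing column {c!r}")
    anns = [Annotation(float(r.start_s), float(r.end_s), str(r.label))
            for r in df.itertuples()]
    return AnnotationList(anns)


def write_annotations(path: str | Path, anns: AnnotationList) -> Path:
    df = pd.DataFrame(
        {
            "start_s": [a.start_s for a in anns],
            "end_s": [a.end_s for a in anns],
            "label": [a.label for a in anns],
        },
        columns=["start_s", "end_s", "label"],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_covariates(path: str | Path) -> CovariateTable:
    df = _read_tsv(path, ("subject_id", "usage_frequency",
                          "behavioural_consistency"))
    return CovariateTable(df)


def write_covariates(path: str | Path, cov: CovariateTable) -> Path:
    cov.table.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_json(path: str | Path, obj) -> Path:
    """Serialize a results object (dataclasses, arrays) to JSON."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
    return path
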