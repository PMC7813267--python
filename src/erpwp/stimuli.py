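"""Stimulus inventory and semi-randomized experimental list construction.

The design crosses 4 Hungarian two-syllable items per word-type condition
with 2 female speakers and 2 recorded versions, giving a 48-sound inventory
(16 per condition).  A session presents each sound 5 times (240 trials, 80
per condition) in a semi-randomized order in which neither the same speaker
nor the same condition occurs more than 3 times in a row, with stimulus
onset asynchrony drawn uniformly from 2.5–3.0 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import CONDITIONS, Event, EventList

__all__ = [
    "WORD_SETS",
    "StimulusSpec",
    "ExperimentList",
    "build_inventory",
    "generate_list",
    "schedule_onsets",
    "validate_list",
    "to_event_list",
]

#: Word items per condition.  WORDS are familiar instructions; SIMILAR items
#: change the first vowel of the matching instruction; NONSENSE items remix
#: the same speech sounds into phonetically dissimilar forms.
WORD_SETS: dict[str, tuple[str, ...]] = {
    "WORDS": ("Fekszik", "Marad", "Gyere", "Mehetsz"),
    "SIMILAR": ("Fakszik", "Merad", "Gyare", "Mihetsz"),
    "NONSENSE": ("Matszer", "Hefegy", "Dime", "Rekaksz"),
}

#: Each unique sound is played this many times per session.
PLAYS_PER_SOUND = 5

#: Maximum run length of identical speaker or identical condition.
MAX_RUN = 3

#: Stimulus onset asynchrony range, seconds.
SOA_RANGE_S = (2.5, 3.0)

#: Mean sound-file duration (ms), used as the nominal stimulus duration.
DEFAULT_DURATION_MS = 650.0


@dataclass(frozen=True)
class StimulusSpec:
    word: str
    condition: str
    speaker: int
    version: int
    nominal_duration_ms: float = DEFAULT_DURATION_MS

    def __post_init__(self) -> None:
        if self.nominal_duration_ms <= 0:
            raise ValueError("duration must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def stimulus_id(self) -> str:
        return f"{self.word}_s{self.speaker}v{self.version}"


@dataclass
class ExperimentList:
    """Ordered trials plus the per-trial SOA draws (ms)."""

    trials: list[StimulusSpec]
    soa_ms: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def conditions(self) -> list[str]:
        return [t.condition for t in self.trials]

    @property
    def speakers(self) -> list[int]:
        return [t.speaker for t in self.trials]


def build_inventory(durations_ms: dict[str, float] | None = None
                    ) -> list[StimulusSpec]:
    """Full 4 (words) x 3 (conditions) x 2 (speakers) x 2 (versions) crossing.

    ``durations_ms`` optionally maps stimulus_id to a per-sound duration.
    """
    inv = []
    for condition in CONDITIONS:
        for word in WORD_SETS[condition]:
            for speaker in (1, 2):
                for version in (1, 2):
                    stim = StimulusSpec(word, condition, speaker, version)
                    if durations_ms and stim.stimulus_id in durations_ms:
                        stim = StimulusSpec(
                            word, condition, speaker, version,
                            durations_ms[stim.stimulus_id],
                        )
                    inv.append(stim)
    return inv


def _max_run(seq) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if b == a else 1
        best = max(best, run)
    return best if seq else 0


def validate_list(lst: ExperimentList) -> None:
    """Re-check every list constraint by direct scan; raise on violation."""
    n = len(lst)
    if n != PLAYS_PER_SOUND * 48:
        raise ValueError(f"list has {n} trials, expected 240")
    conds = lst.conditions
    for c in CONDITIONS:
        if conds.count(c) != 80:
            raise ValueError(f"condition {c} has {conds.count(c)} trials")
    counts: dict[str, int] = {}
    for t in lst.trials:
        counts[t.stimulus_id] = counts.get(t.stimulus_id, 0) + 1
    if set(counts.values()) != {PLAYS_PER_SOUND}:
        raise ValueError("each sound must occur exactly 5 times")
    if _max_run(conds) > MAX_RUN:
        raise ValueError("condition run length exceeds 3")
    if _max_run(lst.speakers) > MAX_RUN:
        raise ValueError("speaker run length exceeds 3")
    if lst.soa_ms is not None:
        lo, hi = (s * 1000 for s in SOA_RANGE_S)
        if np.any((lst.soa_ms < lo) | (lst.soa_ms > hi)):
            raise ValueError("SOA outside the 2500-3000 ms range")


def generate_list(inventory: list[StimulusSpec], seed: int,
                  max_restarts: int = 1000) -> ExperimentList:
    """Semi-randomized 240-trial list obeying the run-length constraints.

    Builds the list greedily from the multiset of 5 copies of each sound,
    sampling each next trial uniformly among sounds that do not extend a
    speaker or condition run beyond 3; restarts on dead ends.  Reproducible
    given ``seed``.
    """
    if len(inventory) != 48:
        raise ValueError("inventory must contain 48 sounds")
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        remaining = np.full(48, PLAYS_PER_SOUND)
        order: list[int] = []
        ok = True
        while remaining.sum() > 0:
            allowed = np.flatnonzero(remaining > 0)
            if len(order) >= MAX_RUN:
                tail = order[-MAX_RUN:]
                tail_conds = {inventory[i].condition for i in tail}
                tail_spk = {inventory[i].speaker for i in tail}
                if len(tail_conds) == 1:
                    bad_c = tail_conds.pop()
                    allowed = allowed[
                        [inventory[i].condition != bad_c for i in allowed]]
                if len(tail_spk) == 1 and len(allowed):
                    bad_s = tail_spk.pop()
                    allowed = allowed[
                        [inventory[i].speaker != bad_s for i in allowed]]
            if len(allowed) == 0:
                ok = False
                break
            # weight by remaining copies so the tail stays feasible
            w = remaining[allowed].astype(float)
            pick = rng.choice(allowed, p=w / w.sum())
            order.append(int(pick))
            remaining[pick] -= 1
        if ok:
            trials = [inventory[i] for i in order]
            lst = ExperimentList(trials)
            validate_list(lst)
            return lst
    raise RuntimeError("list constraints unsatisfiable after bounded retries")


def schedule_onsets(lst: ExperimentList, seed: int,
                    lead_in_s: float = 2.0) -> np.ndarray:
    """Draw per-trial onset times (s): i.i.d. uniform SOAs on [2.5, 3.0].

    The first onset is at ``lead_in_s``; successive onsets are separated by
    the SOA draws, which are also stored on the list (``soa_ms``).
    """
    rng = np.random.default_rng(seed)
    n = len(lst)
    soas = rng.uniform(*SOA_RANGE_S, size=n)
    onsets = lead_in_s + np.concatenate([[0.0], np.cumsum(soas[:-1])])
    lst.soa_ms = soas * 1000.0
    return onsets


def to_event_list(lst: ExperimentList, onsets_s: np.ndarray,
                  sampling_rate: float) -> EventList:
    """Convert a scheduled list to an :class:`EventList` at a sampling rate."""
    events = [
        Event(
            onset_sample=int(round(t_on * sampling_rate)),
            condition=stim.condition,
            stimulus_id=stim.stimulus_id,
            speaker=stim.speaker,
            version=stim.version,
        )
        for stim, t_on in zip(lst.trials, onsets_s)
    ]
    return EventList(events, sampling_rate)
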