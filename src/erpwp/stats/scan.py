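"""Sliding time-window scan with planned pairwise contrasts.

The scan walks a fixed grid of 100 ms windows stepped by 50 ms from 0 to
1000 ms post-onset (19 windows: 0–100, 50–150, …, 900–1000).  In each
window a two-way (word-type × electrode) within-subject ANOVA is run on the
subject window means; when the word-type main effect or its interaction
with electrode is significant (the omnibus gate), pairwise condition
differences are examined in follow-up two-way rm-ANOVAs as planned
contrasts.  Per condition pair, maximal chains of consecutive significant
grid windows are merged: the onset of the first and the offset of the last
significant window delimit the selected window (a single significant
window yields a selected window on its own).

No multiplicity correction is applied across windows by default, matching
the analysis this pipeline reproduces; ``correction="holm"`` optionally
Holm-adjusts the omnibus gate p-values across the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..io_core import CONDITIONS
from .anova import AnovaResult, rm_anova_twoway

__all__ = ["WINDOW_GRID_MS", "CONDITION_PAIRS", "WindowStat",
           "SelectedWindow", "scan_windows"]

#: The fixed scan grid: (start_ms, end_ms) per window.
WINDOW_GRID_MS: tuple[tuple[float, float], ...] = tuple(
    (float(s), float(s + 100)) for s in range(0, 901, 50)
)

#: Condition pairs for the planned contrasts.
CONDITION_PAIRS: tuple[tuple[str, str], ...] = (
    ("WORDS", "SIMILAR"),
    ("WORDS", "NONSENSE"),
    ("SIMILAR", "NONSENSE"),
)


@dataclass
class WindowStat:
    """Per-window omnibus results and (if gated) pairwise contrasts."""

    window_ms: tuple[float, float]
    omnibus: dict[str, AnovaResult]
    gated: bool
    pairwise: dict[tuple[str, str], dict[str, AnovaResult]] = field(
        default_factory=dict)

    def pair_significant(self, pair: tuple[str, str], alpha: float) -> bool:
        if pair not in self.pairwise:
            return False
        res = self.pairwise[pair]
        return (res["word_type"].p < alpha) or (res["interaction"].p < alpha)


@dataclass
class SelectedWindow:
    """Merged onset/offset of an effect for one condition pair."""

    pair: tuple[str, str]
    onset_ms: float
    offset_ms: float
    window_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.onset_ms < self.offset_ms:
            raise ValueError("onset must precede offset")

    def overlaps(self, start_ms: float, end_ms: float) -> bool:
        return self.onset_ms < end_ms and start_ms < self.offset_ms


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def scan_windows(window_means: np.ndarray, alpha: float = 0.05,
                 correction: str = "none",
                 ) -> tuple[list[WindowStat], dict[tuple[str, str],
                                                   list[SelectedWindow]]]:
    """Run the grid scan on subject window means.

    Parameters
    ----------
    window_means
        Array (n_subjects, 3 conditions, n_electrodes, n_windows) with the
        condition axis ordered as :data:`~erpwp.io_core.CONDITIONS` and the
        window axis matching :data:`WINDOW_GRID_MS`.
    alpha
        Two-sided significance level for both the omnibus gate and the
        pairwise contrasts.
    correction
        ``"none"`` (default) or ``"holm"`` across the window grid, applied
        to the omnibus gate p-values.

    Returns
    -------
    (window_stats, selected)
        Per-window statistics, and per condition pair the merged selected
        windows.
    """
    x = np.asarray(window_means, dtype=float)
    if x.ndim != 4 or x.shape[1] != len(CONDITIONS):
        raise ValueError("window_means must be (subjects, 3, electrodes, "
                         "windows)")
    n_windows = x.shape[3]
    if n_windows != len(WINDOW_GRID_MS):
        raise ValueError(f"expected {len(WINDOW_GRID_MS)} grid windows")

    stats: list[WindowStat] = []
    for w in range(n_windows):
        omnibus = rm_anova_twoway(x[:, :, :, w])
        stats.append(WindowStat(WINDOW_GRID_MS[w], omnibus, gated=False))

    p_main = np.array([s.omnibus["word_type"].p for s in stats])
    p_int = np.array([s.omnibus["interaction"].p for s in stats])
    if correction == "holm":
        p_main, p_int = _holm(p_main), _holm(p_int)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")

    cond_idx = {c: i for i, c in enumerate(CONDITIONS)}
    for w, s in enumerate(stats):
        s.gated = bool(p_main[w] < alpha or p_int[w] < alpha)
        if not s.gated:
            continue
        xw = x[:, :, :, w]
        for pair in CONDITION_PAIRS:
            sub = xw[:, (cond_idx[pair[0]], cond_idx[pair[1]]), :]
            s.pairwise[pair] = rm_anova_twoway(sub)

    selected: dict[tuple[str, str], list[SelectedWindow]] = {
        pair: [] for pair in CONDITION_PAIRS}
    for pair in CONDITION_PAIRS:
        sig = [s.pair_significant(pair, alpha) for s in stats]
        chain: list[int] = []
        for w in range(n_windows + 1):
            if w < n_windows and sig[w]:
                chain.append(w)
            elif chain:
                selected[pair].append(SelectedWindow(
                    pair,
                    onset_ms=WINDOW_GRID_MS[chain[0]][0],
                    offset_ms=WINDOW_GRID_MS[chain[-1]][1],
                    window_indices=tuple(chain),
                ))
                chain = []
    return stats, selected
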