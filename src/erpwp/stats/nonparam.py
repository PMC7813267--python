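"""Median-split moderator analysis: rank-sum test, effect size, CI.

Subjects are dichotomized at the covariate median (values at or above the
median form the high group — with a ceiling effect at the top of the
scale, this reproduces the published 8/9 split).  Per-subject ERP
window-mean differences are then compared between groups with the
Wilcoxon rank-sum (Mann–Whitney) test.

Conventions follow R's ``wilcox.test(low, high, conf.int=TRUE)``: the
reported W is the U statistic of the first (low) group; p is exact when
there are no ties and both groups have at most 50 subjects; the effect
size is r = Z/√N with Z from the tie- and continuity-corrected normal
approximation (negative when the low group sits lower); the confidence
interval is the Hodges–Lehmann interval for the location shift
(low − high) built from the exact null distribution of U.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

from ..io_core import CovariateTable

__all__ = ["GroupComparison", "median_split", "ranksum",
           "direction_concordance"]


@dataclass
class GroupComparison:
    W: float
    p: float
    effect_size_r: float
    ci: tuple[float, float]
    hl_estimate: float
    n_low: int
    n_high: int
    exact: bool

    def __post_init__(self) -> None:
        if not 0 <= self.W <= self.n_low * self.n_high:
            raise ValueError("W outside attainable range")
        if not -1 <= self.effect_size_r <= 1:
            raise ValueError("effect size r must lie in [-1, 1]")


def median_split(covariates: CovariateTable, fieldname: str,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Split subjects at the median of a covariate.

    Returns (low_idx, high_idx): row indices with value below the median
    and at-or-above the median respectively.
    """
    values = covariates.values(fieldname)
    if len(values) < 2:
        raise ValueError("need at least 2 subjects")
    if np.ptp(values) == 0:
        raise ValueError("degenerate split: all covariate values identical")
    med = float(np.median(values))
    high = values >= med
    if high.all() or not high.any():
        raise ValueError("degenerate split: one group is empty")
    return np.flatnonzero(~high), np.flatnonzero(high)


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Exact null distribution of U: counts of labelings per U value."""
    # DP over the generating function of the Mann-Whitney statistic
    counts = np.zeros(n1 * n2 + 1, dtype=object)
    counts[0] = 1
    # c(u; m, n) = c(u - n; m - 1, n) + c(u; m, n - 1)
    table = {(0, j): np.array([1], dtype=object) for j in range(n2 + 1)}
    for i in range(1, n1 + 1):
        prev = table[(i - 1, 0)]
        table[(i, 0)] = np.array([1], dtype=object)
        for j in range(1, n2 + 1):
            a = table[(i - 1, j)]
            b = table[(i, j - 1)]
            size = i * j + 1
            out = np.zeros(size, dtype=object)
            out[j:j + len(a)] += a
            out[: len(b)] += b
            table[(i, j)] = out
        for key in [k for k in table if k[0] == i - 1]:
            del table[key]
    return tuple(int(v) for v in table[(n1, n2)])


def _u_cdf(n1: int, n2: int) -> np.ndarray:
    counts = np.array(_u_counts(n1, n2), dtype=float)
    return np.cumsum(counts) / counts.sum()


def _qwilcox(prob: float, n1: int, n2: int) -> int:
    """Smallest u with P(U <= u) >= prob under the exact null."""
    cdf = _u_cdf(n1, n2)
    return int(np.searchsorted(cdf, prob - 1e-12))


def ranksum(low: np.ndarray, high: np.ndarray,
            conf_level: float = 0.95) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two groups of per-subject
    ERP differences; see the module docstring for conventions."""
    x = np.asarray(low, dtype=float)
    y = np.asarray(high, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    N = n1 + n2

    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()
    exact = (not has_ties) and max(n1, n2) <= 50
    if has_ties:
        warnings.warn("ties present; using the normal approximation")

    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    U = float(res.statistic)
    p = float(res.pvalue)

    # tie-corrected, continuity-corrected Z for the effect size
    mu = n1 * n2 / 2.0
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (N * (N - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * (N + 1 - tie_term))
    diff = U - mu
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    z = (diff - cc) / sigma if sigma > 0 else 0.0
    r = float(z / np.sqrt(N))

    # Hodges-Lehmann location-shift estimate and CI (low - high)
    diffs = np.sort(np.subtract.outer(x, y).ravel())
    hl = float(np.median(diffs))
    alpha = 1.0 - conf_level
    if exact:
        qu = max(1, _qwilcox(alpha / 2.0, n1, n2))
    else:
        qu = int(round(mu + sps.norm.ppf(alpha / 2.0) * sigma))
        qu = max(1, min(qu, n1 * n2))
    ci = (float(diffs[qu - 1]), float(diffs[n1 * n2 - qu]))
    return GroupComparison(U, p, r, ci, hl, n1, n2, exact)


def direction_concordance(diffs_by_window: np.ndarray,
                          ) -> tuple[list[int], int]:
    """Count subjects whose per-window difference matches the grand-average
    direction, per window, and the overlap of matchers across windows.

    ``diffs_by_window`` is (n_subjects, n_windows): each column holds one
    analysis window's per-subject ERP window-mean differences for a
    condition pair.  The grand-average direction of a window is the sign of
    its column mean.  Returns (per-window match counts, number of subjects
    matching in every window).
    """
    d = np.asarray(diffs_by_window, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
    if d.shape[1] < 1:
        raise ValueError("need at least one window")
    grand_sign = np.sign(d.mean(axis=0))
    match = np.sign(d) == grand_sign[None, :]
    counts = match.sum(axis=0).astype(int).tolist()
    overlap = int(match.all(axis=1).sum())
    return counts, overlap
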