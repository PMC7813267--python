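"""Within-subject ANOVA with Huynh–Feldt sphericity correction.

The two-way design is fully within-subject (word-type × electrode), so
every effect is tested against its own effect-by-subject error stratum:

    F_A  = MS_A  / MS_{A×S},   F_B = MS_B / MS_{B×S},
    F_AB = MS_AB / MS_{A×B×S}

with partial η² = SS_effect / (SS_effect + SS_error).  For factors with
three or more levels, degrees of freedom are multiplied by the Huynh–Feldt
ε̂ (computed from the sample covariance of the level scores, truncated into
[1/(k−1), 1]); two-level effects are spherical by construction so no
correction applies there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "hf_epsilon",
    "rm_anova_twoway",
    "rm_anova_oneway",
    "fixed_window_test",
    "trialcount_anova",
    "paired_t",
]


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p_uncorrected: float
    partial_eta_sq: float
    hf_epsilon: float | None = None
    p_hf: float | None = None

    @property
    def p(self) -> float:
        """Huynh–Feldt corrected p when available, else the uncorrected p."""
        return self.p_hf if self.p_hf is not None else self.p_uncorrected


def hf_epsilon(scores: np.ndarray) -> float:
    """Huynh–Feldt ε̂ from an (n_subjects × k_levels) score matrix.

    Computed via the Greenhouse–Geisser ε̂ of the double-centered sample
    covariance, then the Huynh–Feldt adjustment for a single-group
    within-subject design, truncated into [1/(k−1), 1].
    """
    x = np.asarray(scores, dtype=float)
    n, k = x.shape
    if k < 3:
        raise ValueError("HF epsilon needs a factor with >= 3 levels")
    if n < 2:
        raise ValueError("HF epsilon needs >= 2 subjects")
    lower = 1.0 / (k - 1)
    S = np.cov(x, rowvar=False, ddof=1)
    row = S.mean(axis=0, keepdims=True)
    col = S.mean(axis=1, keepdims=True)
    Sdc = S - row - col + S.mean()
    denom = (k - 1) * float((Sdc ** 2).sum())
    if denom <= 1e-30:
        warnings.warn("degenerate covariance; using lower-bound epsilon")
        return lower
    gg = float(np.trace(Sdc)) ** 2 / denom
    hf_num = n * (k - 1) * gg - 2.0
    hf_den = (k - 1) * (n - 1 - (k - 1) * gg)
    hf = hf_num / hf_den if hf_den > 0 else 1.0
    return float(min(1.0, max(lower, hf)))


def _result(effect: str, ss_eff: float, df_eff: float, ss_err: float,
            df_err: float, scores: np.ndarray | None) -> AnovaResult:
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    F = ms_eff / ms_err if ms_err > 0 else 0.0
    p_unc = float(sps.f.sf(F, df_eff, df_err)) if ms_err > 0 else 1.0
    peta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    eps = p_hf = None
    if scores is not None and scores.shape[1] >= 3:
        eps = hf_epsilon(scores)
        p_hf = float(sps.f.sf(F, df_eff * eps, df_err * eps)) \
            if ms_err > 0 else 1.0
    return AnovaResult(effect, float(F), df_eff, df_err, p_unc,
                       float(peta), eps, p_hf)


def rm_anova_twoway(data: np.ndarray,
                    factor_a: str = "word_type",
                    factor_b: str = "electrode",
                    ) -> dict[str, AnovaResult]:
    """Two-way fully within-subject ANOVA on (n_subjects, k_a, k_b) data.

    Returns results keyed by ``factor_a``, ``factor_b`` and
    ``"interaction"``.  The design must be complete (no NaNs).
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3:
        raise ValueError("data must be (subjects, levels_a, levels_b)")
    if np.isnan(y).any():
        raise ValueError("missing cell in the within-subject design")
    n, ka, kb = y.shape
    if n < 2 or ka < 2 or kb < 1:
        raise ValueError("need >= 2 subjects and >= 2 levels of factor A")

    g = y.mean()
    a = y.mean(axis=(0, 2))          # (ka,)
    b = y.mean(axis=(0, 1))          # (kb,)
    s = y.mean(axis=(1, 2))          # (n,)
    ab = y.mean(axis=0)              # (ka, kb)
    as_ = y.mean(axis=2)             # (n, ka)
    bs = y.mean(axis=1)              # (n, kb)

    ss_a = n * kb * ((a - g) ** 2).sum()
    ss_b = n * ka * ((b - g) ** 2).sum()
    ss_ab = n * ((ab - a[:, None] - b[None, :] + g) ** 2).sum()
    ss_as = kb * ((as_ - a[None, :] - s[:, None] + g) ** 2).sum()
    ss_bs = ka * ((bs - b[None, :] - s[:, None] + g) ** 2).sum()
    resid = (y - ab[None] - as_[:, :, None] - bs[:, None, :]
             + a[None, :, None] + b[None, None, :] + s[:, None, None] - g)
    ss_abs = (resid ** 2).sum()

    # HF score matrices: factor-A scores averaged over B; interaction scores
    # are the B-contrast per A level (defined for two-level B)
    a_scores = as_
    ab_scores = (y[:, :, 0] - y[:, :, 1]) if kb == 2 else None

    out = {
        factor_a: _result(factor_a, ss_a, ka - 1, ss_as,
                          (ka - 1) * (n - 1), a_scores),
        "interaction": _result("interaction", ss_ab, (ka - 1) * (kb - 1),
                               ss_abs, (ka - 1) * (kb - 1) * (n - 1),
                               ab_scores),
    }
    if kb >= 2:
        b_scores = bs if kb >= 3 else None
        out[factor_b] = _result(factor_b, ss_b, kb - 1, ss_bs,
                                (kb - 1) * (n - 1), b_scores)
    return out


def rm_anova_oneway(data: np.ndarray, factor: str = "condition"
                    ) -> AnovaResult:
    """One-way within-subject ANOVA on (n_subjects, k_levels) data."""
    y = np.asarray(data, dtype=float)
    if y.ndim != 2:
        raise ValueError("data must be (subjects, levels)")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels")
    g = y.mean()
    a = y.mean(axis=0)
    s = y.mean(axis=1)
    ss_a = n * ((a - g) ** 2).sum()
    ss_err = ((y - a[None, :] - s[:, None] + g) ** 2).sum()
    scores = y if k >= 3 else None
    return _result(factor, ss_a, k - 1, ss_err, (k - 1) * (n - 1), scores)


def fixed_window_test(window_means: np.ndarray) -> dict[str, AnovaResult]:
    """Two-way rm-ANOVA on one window's (subjects × word-type × electrode)
    mean amplitudes — e.g. the a-priori 200–400 ms check."""
    return rm_anova_twoway(window_means)


def trialcount_anova(clean_counts: np.ndarray) -> AnovaResult:
    """One-way rm-ANOVA on clean-trial counts (subjects × 3 conditions),
    checking that cleaning did not unbalance the conditions."""
    return rm_anova_oneway(np.asarray(clean_counts, dtype=float),
                           factor="condition")


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D samples, n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d, 0):
            return 0.0, len(a) - 1, 1.0
        raise ValueError("zero variance of differences")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), len(a) - 1, float(res.pvalue)
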