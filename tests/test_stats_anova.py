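import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from erpwp.stats.anova import (
    fixed_window_test,
    hf_epsilon,
    paired_t,
    rm_anova_oneway,
    rm_anova_twoway,
    trialcount_anova,
)


def hf_epsilon_oracle(x):
    """Independent textbook evaluation: Greenhouse–Geisser ε̂ from the
    double-centred covariance, then the Huynh–Feldt adjustment."""
    n, k = x.shape
    S = np.cov(x.T, ddof=1)
    sbar = S.mean()
    rowbar = S.mean(axis=1)
    num = (k * (np.trace(S) / k - sbar)) ** 2
    den = (k - 1) * ((S ** 2).sum() - 2 * k * (rowbar ** 2).sum()
                     + k * k * sbar ** 2)
    gg = num / den
    hf = (n * (k - 1) * gg - 2) / ((k - 1) * (n - 1 - (k - 1) * gg))
    return min(1.0, max(1.0 / (k - 1), hf))


def twoway_ss_oracle(y):
    """Explicit sums-of-squares decomposition by direct summation."""
    n, ka, kb = y.shape
    g = y.mean()
    ss = {k: 0.0 for k in ("a", "b", "ab", "as", "bs", "abs")}
    a = [y[:, i, :].mean() for i in range(ka)]
    b = [y[:, :, j].mean() for j in range(kb)]
    s = [y[i].mean() for i in range(n)]
    for i in range(ka):
        ss["a"] += n * kb * (a[i] - g) ** 2
    for j in range(kb):
        ss["b"] += n * ka * (b[j] - g) ** 2
    for i in range(ka):
        for j in range(kb):
            ss["ab"] += n * (y[:, i, j].mean() - a[i] - b[j] + g) ** 2
    for subj in range(n):
        for i in range(ka):
            ss["as"] += kb * (y[subj, i, :].mean() - a[i] - s[subj] + g) ** 2
        for j in range(kb):
            ss["bs"] += ka * (y[subj, :, j].mean() - b[j] - s[subj] + g) ** 2
        for i in range(ka):
            for j in range(kb):
                ss["abs"] += (y[subj, i, j] - y[:, i, j].mean()
                              - y[subj, i, :].mean() - y[subj, :, j].mean()
                              + a[i] + b[j] + s[subj] - g) ** 2
    return ss


class TestHfEpsilon:
    def test_compound_symmetric_data_is_spherical(self, rng):
        shared = rng.normal(size=(40, 1))
        x = shared + rng.normal(size=(40, 3))
        assert hf_epsilon(x) == pytest.approx(1.0)

    def test_lower_bound_for_maximally_nonspherical(self, rng):
        base = rng.normal(size=30)
        x = np.column_stack([base, 2 * base, 3 * base])
        x += rng.normal(0, 1e-6, x.shape)
        assert hf_epsilon(x) == pytest.approx(0.5, abs=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_textbook_oracle_and_pingouin(self, seed):
        rng = np.random.default_rng(seed)
        mix = rng.normal(size=(3, 3))
        x = rng.normal(size=(17, 3)) @ mix
        eps = hf_epsilon(x)
        assert eps == pytest.approx(hf_epsilon_oracle(x), abs=1e-12)
        assert eps == pytest.approx(
            float(pg.epsilon(pd.DataFrame(x), correction="hf")), abs=1e-9)

    def test_too_few_levels_rejected(self, rng):
        with pytest.raises(ValueError):
            hf_epsilon(rng.normal(size=(10, 2)))


class TestTwoWayRmAnova:
    def test_all_cells_equal_gives_zero_f(self):
        res = rm_anova_twoway(np.full((6, 3, 2), 2.5))
        for r in res.values():
            assert r.F == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_ss_decomposition_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(17, 3, 2))
        ss = twoway_ss_oracle(y)
        res = rm_anova_twoway(y)
        n = 17
        f_a = (ss["a"] / 2) / (ss["as"] / (2 * (n - 1)))
        f_b = (ss["b"] / 1) / (ss["bs"] / (n - 1))
        f_ab = (ss["ab"] / 2) / (ss["abs"] / (2 * (n - 1)))
        assert res["word_type"].F == pytest.approx(f_a, rel=1e-10)
        assert res["electrode"].F == pytest.approx(f_b, rel=1e-10)
        assert res["interaction"].F == pytest.approx(f_ab, rel=1e-10)
        assert res["word_type"].partial_eta_sq == pytest.approx(
            ss["a"] / (ss["a"] + ss["as"]), rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_level_factor_f_equals_squared_paired_t(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(17, 2, 2))
        res = rm_anova_twoway(y)
        t, df, p = paired_t(y[:, 0, :].mean(axis=1), y[:, 1, :].mean(axis=1))
        assert res["word_type"].F == pytest.approx(t ** 2, rel=1e-8)
        assert res["word_type"].p_uncorrected == pytest.approx(p, rel=1e-8)
        assert df == 16

    def test_hf_correction_raises_p_for_nonnull_f(self):
        """With ε < 1 the corrected p exceeds the uncorrected p whenever
        F ≥ 1 (for F < 1 shrinking both dfs can lower p, so the check is
        conditioned on the relevant regime)."""
        checked = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            mix = rng.normal(size=(3, 3))
            y = np.einsum("nkm,kj->njm", rng.normal(size=(17, 3, 2)), mix)
            y[:, 0, :] += 1.0
            res = rm_anova_twoway(y)["word_type"]
            assert res.hf_epsilon <= 1.0
            if res.p_uncorrected < 0.05 and res.hf_epsilon < 1.0:
                assert res.p_hf >= res.p_uncorrected - 1e-12
                checked += 1
        assert checked >= 5

    def test_missing_cell_rejected(self, rng):
        y = rng.normal(size=(8, 3, 2))
        y[2, 1, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_twoway(y)

    def test_fixed_window_alias(self, rng):
        y = rng.normal(size=(17, 3, 2))
        a = fixed_window_test(y)
        b = rm_anova_twoway(y)
        assert a["word_type"].F == b["word_type"].F


class TestOneWayRmAnova:
    def test_equal_counts_give_zero_f(self):
        res = trialcount_anova(np.full((17, 3), 20))
        assert res.F == 0.0

    def test_matches_pingouin(self, rng):
        counts = rng.integers(10, 60, size=(17, 3)).astype(float)
        res = rm_anova_oneway(counts)
        df = pd.DataFrame(counts).reset_index().melt(
            id_vars="index", var_name="cond", value_name="y")
        ref = pg.rm_anova(data=df, dv="y", within="cond", subject="index")
        assert res.F == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert res.p_uncorrected == pytest.approx(float(ref["p_unc"][0]),
                                                  rel=1e-9)

    def test_three_level_factor_carries_hf_epsilon(self, rng):
        res = trialcount_anova(rng.integers(10, 60, size=(17, 3)))
        assert res.hf_epsilon is not None
        assert 0.5 <= res.hf_epsilon <= 1.0


class TestPairedT:
    def test_identical_samples(self):
        t, df, p = paired_t(np.arange(5.0), np.arange(5.0))
        assert (t, p) == (0.0, 1.0)
        assert df == 4

    def test_matches_formula_oracle(self, rng):
        a = rng.normal(size=17)
        b = rng.normal(size=17)
        t, df, p = paired_t(a, b)
        d = a - b
        t_exp = d.mean() / (d.std(ddof=1) / np.sqrt(17))
        assert t == pytest.approx(t_exp, rel=1e-12)
        assert df == 16

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t(np.arange(5.0) + 1.0, np.arange(5.0))
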