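"""Moderated statistic, permutation FDR, imputation, Dunnett, BH, ORA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from parpomics.stats import (
    DiffTestParams,
    ImputeParams,
    anova_dunnett,
    bh_adjust,
    fisher_ora,
    impute_downshift,
    permutation_fdr,
    s0_statistic,
)
from parpomics.synthetic import simulate_differential_matrix


class TestS0Statistic:
    def test_identical_groups_give_zero(self):
        d, fc = s0_statistic([1, 2, 3], [1, 2, 3], s0=0.1)
        assert d == 0.0 and fc == 0.0

    def test_s0_zero_equals_student_t(self):
        d, fc = s0_statistic([1, 2, 3], [4, 5, 6], s0=0.0)
        assert fc == -3.0
        assert d == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        t = sps.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=True).statistic
        assert d == pytest.approx(t, rel=1e-12)

    def test_zero_variance_forced_by_formula(self):
        d, fc = s0_statistic([5, 5, 5], [3, 3, 3], s0=0.1)
        assert d == pytest.approx(20.0)
        assert fc == 2.0

    def test_too_few_values_untestable(self):
        d, fc = s0_statistic([1.0, 2.0], [3.0, 4.0, 5.0], s0=0.1)
        assert np.isnan(d)

    @pytest.mark.parametrize("seed", range(5))
    def test_s0_monotonically_shrinks_magnitude(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=4), rng.normal(1, 1, size=4)
        mags = [abs(s0_statistic(a, b, s0=s)[0]) for s in (0.0, 0.1, 0.5, 2.0)]
        assert all(x >= y for x, y in zip(mags, mags[1:]))


class TestPermutationFDR:
    def test_identical_features_nothing_significant(self):
        m = pd.DataFrame(np.ones((50, 8)), columns=[*"abcd", *"efgh"])
        res = permutation_fdr(m, list("abcd"), list("efgh"), DiffTestParams(seed=0))
        assert res.table["significant"].sum() == 0

    def test_seed_reproducibility(self):
        m, ga, gb, _ = simulate_differential_matrix(n_features=200, seed=3)
        with pytest.warns(UserWarning):
            r1 = permutation_fdr(m, ga, gb, DiffTestParams(seed=5))
        with pytest.warns(UserWarning):
            r2 = permutation_fdr(m, ga, gb, DiffTestParams(seed=5))
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_significant_implies_q_below_target(self):
        m, ga, gb, _ = simulate_differential_matrix(n_features=300, seed=4)
        with pytest.warns(UserWarning):
            res = permutation_fdr(m, ga, gb, DiffTestParams(seed=4))
        sig = res.table[res.table["significant"]]
        assert (sig["q_value"] <= 0.05).all()
        # d sign matches fold-change sign for finite-variance features
        finite = res.table.dropna(subset=["d"])
        nz = finite[finite["log2_fc"] != 0]
        assert (np.sign(nz["d"]) == np.sign(nz["log2_fc"])).all()

    def test_spike_in_recovery(self):
        """Features shifted by 8 within-group sd (a regime with essentially
        full per-feature power at 4 vs 4 replicates) are nearly all recovered
        at a realized FDR within the target."""
        rng = np.random.default_rng(10)
        null = rng.normal(0, 1, (950, 8))
        shifted = rng.normal(0, 1, (50, 8))
        shifted[:, :4] += 8.0
        m = pd.DataFrame(np.vstack([null, shifted]),
                         index=[f"f{i}" for i in range(1000)],
                         columns=[*"abcd", *"efgh"])
        truth = {f"f{i}" for i in range(950, 1000)}
        with pytest.warns(UserWarning):
            res = permutation_fdr(m, list("abcd"), list("efgh"),
                                  DiffTestParams(seed=10))
        sig = set(res.significant)
        assert len(sig & truth) >= 45
        fp = len(sig - truth)
        assert fp / max(len(sig), 1) <= 0.10


class TestImputation:
    def test_no_missing_unchanged(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(20, 2, (30, 4)))
        pd.testing.assert_frame_equal(impute_downshift(m), m)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(20, 2, (50, 4))).mask(rng.random((50, 4)) < 0.3)
        a = impute_downshift(m, ImputeParams(seed=9))
        b = impute_downshift(m, ImputeParams(seed=9))
        pd.testing.assert_frame_equal(a, b)
        assert a[m.notna()].equals(m[m.notna()])

    def test_imputed_moments_match_downshifted_normal(self):
        rng = np.random.default_rng(2)
        col = pd.Series(rng.normal(20, 2, 20_000))
        m = pd.DataFrame({"s": col})
        m.iloc[:10_000, 0] = np.nan
        params = ImputeParams(width=0.3, downshift=1.8, seed=3)
        out = impute_downshift(m, params)
        present = col.iloc[10_000:]
        target_mean = present.mean() - 1.8 * present.std(ddof=1)
        imputed = out.iloc[:10_000, 0]
        se = 0.3 * present.std(ddof=1) / np.sqrt(10_000)
        assert abs(imputed.mean() - target_mean) < 3 * se

    def test_all_missing_sample_is_error(self):
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="s2"):
            impute_downshift(m)


class TestDunnett:
    def test_identical_constant_groups_p_one(self):
        p = anova_dunnett([3.0, 3.0, 3.0], [[3.0, 3.0, 3.0], [3.0, 3.0, 3.0]])
        assert np.allclose(p, 1.0)

    def test_single_comparison_equals_t_test(self):
        rng = np.random.default_rng(4)
        ctrl, trt = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        p = anova_dunnett(ctrl, [trt])
        raw = sps.ttest_ind(trt, ctrl, equal_var=True).pvalue
        assert p[0] == pytest.approx(raw, rel=1e-9)

    def test_balanced_two_comparisons_match_monte_carlo_oracle(self):
        """Adjusted p for k=2, n=4 equals a 10^6-draw Monte-Carlo evaluation
        of P(max|T| >= |t_j|) under the equicorrelated multivariate t."""
        rng = np.random.default_rng(6)
        ctrl = rng.normal(0, 1, 4)
        t1 = rng.normal(1.2, 1, 4)
        t2 = rng.normal(0.5, 1, 4)
        adj = anova_dunnett(ctrl, [t1, t2], seed=1)
        groups = [ctrl, t1, t2]
        df = 12 - 2 - 1
        sp2 = sum((len(g) - 1) * np.var(g, ddof=1) for g in groups) / df
        ts = [(np.mean(t) - np.mean(ctrl)) / np.sqrt(sp2 * 0.5) for t in (t1, t2)]
        mc = np.random.default_rng(123)
        z = mc.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=1_000_000)
        w = mc.chisquare(df, size=1_000_000)
        max_t = np.abs(z / np.sqrt(w / df)[:, None]).max(axis=1)
        for t_obs, a in zip(ts, adj):
            p_mc = float(np.mean(max_t >= abs(t_obs)))
            assert a == pytest.approx(p_mc, abs=0.005)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(5)
        ctrl = rng.normal(0, 1, 4)
        trts = [rng.normal(0.5, 1, 4) for _ in range(3)]
        adj = anova_dunnett(ctrl, trts)
        pooled = np.concatenate([ctrl, *trts])
        df = len(pooled) - 4
        sp2 = sum((len(g) - 1) * np.var(g, ddof=1) for g in (ctrl, *trts)) / df
        for g, a in zip(trts, adj):
            t = (np.mean(g) - np.mean(ctrl)) / np.sqrt(sp2 * (1 / len(g) + 1 / len(ctrl)))
            raw = 2 * sps.t.sf(abs(t), df)
            assert a >= raw - 1e-6


class TestBH:
    def test_all_ones_stay_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_step_up_arithmetic(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def hypergeom_two_sided(a, b, c, d):
    """Exhaustive two-sided Fisher p over the hypergeometric support."""
    n_fg, n_set, total = a + b, a + c, a + b + c + d
    support = range(max(0, n_fg + n_set - total), min(n_fg, n_set) + 1)
    pmf = {k: sps.hypergeom.pmf(k, total, n_set, n_fg) for k in support}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))


class TestFisherORA:
    def test_foreground_equal_background_p_one(self):
        bg = {f"g{i}" for i in range(30)}
        out = fisher_ora(bg, bg, {"set1": {f"g{i}" for i in range(10)}})
        assert out.loc["set1", "p_value"] == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        # 2x2 table (8, 2, 10, 80)
        fg = {f"g{i}" for i in range(10)}
        bg = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(8)} | {f"g{i}" for i in range(10, 20)}
        out = fisher_ora(fg, bg, {"s": gene_set})
        assert out.loc["s", "overlap"] == 8
        assert out.loc["s", "p_value"] == pytest.approx(
            hypergeom_two_sided(8, 2, 10, 80), rel=1e-9
        )

    def test_depleted_set_zero_odds(self):
        fg = {f"g{i}" for i in range(10)}
        bg = {f"g{i}" for i in range(40)}
        gene_set = {f"g{i}" for i in range(10, 35)}
        out = fisher_ora(fg, bg, {"s": gene_set})
        assert out.loc["s", "odds_ratio"] == 0.0
        assert out.loc["s", "p_value"] == pytest.approx(
            hypergeom_two_sided(0, 10, 25, 5), rel=1e-9
        )

    def test_foreground_outside_background_rejected(self):
        with pytest.raises(ValueError):
            fisher_ora({"x"}, {"y"}, {})
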