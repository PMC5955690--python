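"""Inferential layer against independent oracles (scipy, statsmodels, pingouin)."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as hst

from proctrl.stats import (
    paired_t, fdr_bh, binned_contrast, gg_epsilon, rm_anova_oneway,
    rm_anova_twoway, wilcoxon_signed_rank, plv_contrast, power_rt_correlation,
    make_bins, bin_means,
)


class TestPairedT:
    def test_identical_samples(self):
        r = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == 1.0 and not r.degenerate

    def test_constant_nonzero_difference_flagged_degenerate(self):
        r = paired_t([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert r.degenerate and np.isnan(r.t)

    def test_matches_hand_computation_n5(self):
        x = np.array([10.0, 12.0, 9.0, 11.0, 13.0])
        y = np.array([8.0, 11.0, 10.0, 9.0, 12.0])
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        r = paired_t(x, y)
        assert r.t == pytest.approx(t_hand, abs=1e-6)
        t_sp, p_sp = sps.ttest_rel(x, y)
        assert r.t == pytest.approx(t_sp, abs=1e-10)
        assert r.p == pytest.approx(p_sp, abs=1e-10)
        assert r.df == 4

    @given(hst.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_scipy_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 30)
        x, y = rng.standard_normal((2, n))
        r = paired_t(x, y)
        t_sp, p_sp = sps.ttest_rel(x, y)
        assert np.isclose(r.t, t_sp) and np.isclose(r.p, p_sp)


class TestFdrBH:
    def test_all_tiny_p_rejected(self):
        rej, adj = fdr_bh(np.full(9, 0.001), q=0.05)
        assert rej.all()
        np.testing.assert_allclose(adj, 0.001)

    def test_step_up_enumeration(self):
        rej, _ = fdr_bh(np.array([0.01, 0.02, 0.5]), q=0.05)
        assert list(rej) == [True, True, False]

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.random(60) ** 2
        rej, adj = fdr_bh(p, q=0.05)
        rej_sm, adj_sm, *_ = multipletests(p, 0.05, method="fdr_bh")
        assert (rej == rej_sm).all()
        np.testing.assert_allclose(adj, adj_sm)

    @given(hst.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_q(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(40)
        r1, _ = fdr_bh(p, q=0.01)
        r5, _ = fdr_bh(p, q=0.05)
        assert not np.any(r1 & ~r5)  # q=0.01 rejections subset of q=0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([])


class TestGGEpsilon:
    def test_two_levels_always_one(self):
        rng = np.random.default_rng(1)
        assert gg_epsilon(rng.standard_normal((10, 2))) == 1.0

    def test_compound_symmetry_approaches_one(self):
        rng = np.random.default_rng(2)
        subj = rng.standard_normal((4000, 1))
        d = subj + 0.5 * rng.standard_normal((4000, 4))
        assert gg_epsilon(d) == pytest.approx(1.0, abs=0.02)

    def test_matches_box_formula_and_pingouin(self):
        import pingouin as pg
        rng = np.random.default_rng(3)
        d = rng.standard_normal((12, 4)) @ rng.standard_normal((4, 4))
        # direct Box formula on the double-centered covariance
        S = np.cov(d, rowvar=False)
        k = 4
        J = np.eye(k) - np.ones((k, k)) / k
        D = J @ S @ J
        eps_direct = np.trace(D) ** 2 / ((k - 1) * np.sum(D * D))
        assert gg_epsilon(d) == pytest.approx(eps_direct, abs=1e-12)
        assert gg_epsilon(d) == pytest.approx(
            float(pg.epsilon(pd.DataFrame(d), correction="gg")), abs=1e-9)

    def test_lower_bound_clip(self):
        # rank-1 data: maximally non-spherical
        base = np.outer(np.arange(8.0), [1.0, -1.0, 0.5, 0.0])
        assert gg_epsilon(base) == pytest.approx(1.0 / 3.0)


class TestRmAnova:
    def test_all_equal_cells_give_zero_f(self):
        d = np.ones((8, 3, 2))
        for e in rm_anova_twoway(d):
            assert e.F == 0.0

    def test_two_condition_f_is_squared_t(self):
        rng = np.random.default_rng(4)
        d = rng.standard_normal((15, 2))
        a = rm_anova_oneway(d)
        t = paired_t(d[:, 0], d[:, 1])
        assert a.F == pytest.approx(t.t ** 2, rel=1e-10)
        assert a.p == pytest.approx(t.p, rel=1e-10)

    def test_oneway_matches_pingouin(self):
        import pingouin as pg
        rng = np.random.default_rng(5)
        d = rng.standard_normal((20, 4)) + rng.standard_normal((20, 1))
        long = pd.DataFrame(d, columns=list("abcd")).reset_index().melt(
            "index", var_name="cond")
        aov = pg.rm_anova(dv="value", within="cond", subject="index",
                          data=long, correction=True)
        mine = rm_anova_oneway(d)
        assert mine.F == pytest.approx(float(aov["F"].iloc[0]), rel=1e-9)
        assert mine.epsilon == pytest.approx(float(aov["eps"].iloc[0]), abs=1e-9)
        assert mine.p == pytest.approx(float(aov["p_GG_corr"].iloc[0]), abs=1e-9)

    def test_twoway_matches_pingouin(self):
        import pingouin as pg
        rng = np.random.default_rng(6)
        d = rng.standard_normal((14, 3, 2)) + 0.5 * rng.standard_normal((14, 1, 1))
        rows = [{"s": s, "A": f"a{a}", "B": f"b{b}", "v": d[s, a, b]}
                for s in range(14) for a in range(3) for b in range(2)]
        aov = pg.rm_anova(dv="v", within=["A", "B"], subject="s",
                          data=pd.DataFrame(rows))
        effects = {e.name: e for e in rm_anova_twoway(d, ("A", "B"))}
        for src, name in (("A", "A"), ("B", "B"), ("A * B", "A x B")):
            row = aov[aov.Source == src].iloc[0]
            assert effects[name].F == pytest.approx(float(row["F"]), rel=1e-9)
            assert effects[name].p_uncorrected == pytest.approx(
                float(row["p_unc"]), abs=1e-9)

    def test_missing_cells_rejected(self):
        d = np.ones((5, 3, 2))
        d[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_twoway(d)


class TestWilcoxon:
    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_exact_matches_enumeration_n6(self):
        x = np.array([3.1, 4.5, 2.2, 5.0, 1.1, 6.3])
        y = np.array([2.0, 4.9, 1.0, 3.5, 2.2, 5.1])
        r = wilcoxon_signed_rank(x, y)
        assert r.exact
        # exhaustive oracle over all 2^6 sign assignments
        d = x - y
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = []
        for mask in range(2 ** 6):
            ws.append(sum(r_ for i, r_ in enumerate(ranks) if (mask >> i) & 1))
        ws = np.array(ws)
        p_exact = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
        # (scipy's exact mode assumes untied ranks; this fixture has ties,
        # so the enumeration conditional on the observed midranks governs)
        assert r.p == pytest.approx(min(1.0, p_exact), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        x = np.array([3.1, 4.5, 2.2, 5.0, 1.1, 6.3, 0.4])
        y = np.array([2.0, 4.9, 1.0, 3.6, 2.4, 5.05, 1.1])
        r = wilcoxon_signed_rank(x, y)
        assert r.exact
        assert r.p == pytest.approx(sps.wilcoxon(x, y, mode="exact").pvalue, abs=1e-12)

    def test_asymptotic_close_to_exact_at_n15(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(15) + 0.6
        y = rng.standard_normal(15)
        exact = wilcoxon_signed_rank(x, y, exact_limit=15)
        asym = wilcoxon_signed_rank(x, y, exact_limit=0)
        assert exact.exact and not asym.exact
        assert asym.p == pytest.approx(exact.p, abs=0.01)
        assert asym.z is not None


class TestBinnedContrast:
    def _tc(self, rng, n_subj, offset=0.0, onset=0.5):
        times = -1.0 + np.arange(750) / 250.0
        base = rng.standard_normal((n_subj, 750))
        shift = np.where(times >= onset, offset, 0.0)
        return base + shift, times

    def test_identical_conditions_nothing_significant(self):
        rng = np.random.default_rng(8)
        a, times = self._tc(rng, 12)
        tbl = binned_contrast(a, a.copy(), times)
        assert not tbl.significant.any()
        assert len(tbl) == 9

    def test_per_bin_t_matches_standalone(self):
        rng = np.random.default_rng(9)
        a, times = self._tc(rng, 10)
        b, _ = self._tc(rng, 10)
        bins = make_bins()
        tbl = binned_contrast(a, b, times, bins=bins)
        am, bm = bin_means(a, times, bins), bin_means(b, times, bins)
        for i in range(len(bins)):
            r = paired_t(am[:, i], bm[:, i])
            assert tbl.t.iloc[i] == pytest.approx(r.t, abs=1e-12)
            assert tbl.p.iloc[i] == pytest.approx(r.p, abs=1e-12)

    def test_injected_late_offset_detected_in_late_bins(self):
        hits = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            a, times = self._tc(rng, 22, offset=-1.5, onset=0.5)
            b, _ = self._tc(rng, 22)
            tbl = binned_contrast(a, b, times)
            sig = tbl[tbl.significant]
            hits.append(len(sig) > 0 and abs(sig.bin_start_s.min() - 0.5) <= 0.1)
        assert np.mean(hits) >= 0.9

    def test_bins_outside_epoch_rejected(self):
        rng = np.random.default_rng(10)
        a, times = self._tc(rng, 5)
        with pytest.raises(ValueError, match="outside"):
            binned_contrast(a, a, times, bins=[(5.0, 5.1)])


class TestPlvContrast:
    def test_identical_conditions_no_hits(self):
        rng = np.random.default_rng(11)
        a = rng.random((10, 6))
        tbl = plv_contrast(a, a + 1e-4 * rng.standard_normal(a.shape),
                           [f"e{i}" for i in range(6)])
        assert tbl.significant.sum() == 0

    def test_per_connection_p_matches_standalone_wilcoxon(self):
        rng = np.random.default_rng(12)
        a, b = rng.random((2, 12, 5))
        tbl = plv_contrast(a, b, [f"e{i}" for i in range(5)])
        for j in range(5):
            r = wilcoxon_signed_rank(a[:, j], b[:, j])
            assert tbl.p.iloc[j] == pytest.approx(r.p, abs=1e-12)

    def test_seed_electrode_skipped(self):
        rng = np.random.default_rng(13)
        a, b = rng.random((2, 8, 4))
        tbl = plv_contrast(a, b, ["seed", "x", "y", "z"], skip=("seed",))
        assert "seed" not in set(tbl.electrode)


class TestPowerRtCorrelation:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = power_rt_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(14)
        x, y = rng.standard_normal((2, 21))
        r, _ = power_rt_correlation(x, y)
        hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(hand, abs=1e-12)

    def test_null_type_one_rate(self):
        rng = np.random.default_rng(15)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            x, y = rng.standard_normal((2, 21))
            _, p = power_rt_correlation(x, y)
            hits += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(hits / n_sim - 0.05) < 4 * se

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            power_rt_correlation(np.ones(5), np.arange(5.0))
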