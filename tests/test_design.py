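"""Task design generation and generative behavior."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from proctrl.design import (
    DesignSpec, BehaviorParams, RTParams, generate_design, simulate_behavior,
    behavioral_summary, derived_condition, write_trial_table, read_trial_table,
    DesignError, CONDITIONS,
)
from proctrl.stats import paired_t


def full_design(seed=0, **kw):
    return generate_design(DesignSpec(seed=seed, **kw))


class TestGenerateDesign:
    def test_full_session_counts(self):
        tbl = full_design()
        assert len(tbl) == 960
        counts = tbl.condition.value_counts()
        assert counts["EG"] == counts["EC"] == counts["EN"] == 320

    def test_eg_targets_all_standard(self):
        tbl = full_design()
        assert (tbl.loc[tbl.condition == "EG", "target_type"] == "standard").all()

    def test_rare_target_fraction_exact(self):
        tbl = full_design()
        for cond, rare in (("EN", "nogo"), ("EC", "change")):
            sub = tbl[tbl.condition == cond]
            assert (sub.target_type == rare).mean() == 0.25
            assert set(sub.target_type) == {"standard", rare}

    def test_soa_and_iti_invariants(self):
        spec = DesignSpec(seed=3)
        tbl = generate_design(spec)
        np.testing.assert_allclose(
            tbl.target_onset_s - tbl.cue_onset_s, spec.soa_s)
        gaps = np.diff(tbl.cue_onset_s) - spec.soa_s - spec.target_duration_ms / 1000
        assert gaps.min() >= 1.3 - 1e-9 and gaps.max() <= 1.6 + 1e-9

    def test_hand_switch_and_counterbalance(self):
        tbl = full_design()
        assert set(tbl.loc[tbl.block < 3, "standard_hand"]) == {"right"}
        assert set(tbl.loc[tbl.block >= 3, "standard_hand"]) == {"left"}
        tbl2 = generate_design(DesignSpec(counterbalance_order="LHB_first"))
        assert set(tbl2.loc[tbl2.block < 3, "standard_hand"]) == {"left"}

    def test_same_seed_byte_identical(self):
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            full_design(seed=42).to_csv(buf, sep="\t", index=False)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_impossible_exact_allocation_raises(self):
        spec = DesignSpec(n_blocks=1, trials_per_block=30, p_rare_target=0.33,
                          hand_switch_block=1)
        with pytest.raises(DesignError, match="not an integer"):
            generate_design(spec)

    def test_random_allocation_matches_probabilities(self):
        # chi-square goodness of fit across seeds; alpha=0.01 per seed
        rejections = 0
        for seed in range(100):
            tbl = generate_design(DesignSpec(seed=seed), exact_allocation=False)
            obs = [int((tbl.condition == c).sum()) for c in CONDITIONS]
            _, p = chisquare(obs)
            rejections += p < 0.01
        assert rejections <= 5  # expected 1 of 100 under the null

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DesignSpec(p_condition={"EG": 0.5, "EC": 0.5, "EN": 0.5})
        with pytest.raises(ValueError):
            DesignSpec(iti_range_ms=(1600.0, 1300.0))


class TestSimulateBehavior:
    def test_zero_error_rates_all_standard_correct(self):
        tbl = full_design(seed=5)
        params = BehaviorParams(
            premature_rate={c: 0.0 for c in CONDITIONS},
            omission_rate={k: 0.0 for k in ("go", "no-change", "no-nogo", "change")},
            choice_error_rate={k: 0.0 for k in ("go", "no-change", "no-nogo", "change")},
            failed_inhibition_rate=0.0, seed=1)
        out = simulate_behavior(tbl, params)
        std = out[out.target_type == "standard"]
        assert std.correct.all()
        assert (std.response == std.standard_hand).all()

    def test_premature_rate_one_makes_all_eg_premature(self):
        tbl = full_design(seed=6)
        params = BehaviorParams(premature_rate={"EG": 1.0, "EC": 0.0, "EN": 0.0})
        out = simulate_behavior(tbl, params)
        assert (out.loc[out.condition == "EG", "response"] == "premature").all()
        assert not (out.loc[out.condition != "EG", "response"] == "premature").any()

    def test_rt_present_iff_press(self):
        out = simulate_behavior(full_design(seed=7), BehaviorParams(seed=2))
        pressed = out.response.isin(["right", "left"])
        assert out.loc[pressed, "rt_ms"].notna().all()
        assert out.loc[~pressed, "rt_ms"].isna().all()

    def test_change_response_uses_other_hand(self):
        out = simulate_behavior(full_design(seed=8), BehaviorParams(seed=3))
        ch = out[(derived_condition(out) == "change") & out.correct]
        assert (ch.response != ch.standard_hand).all()

    def test_cohort_rt_means_near_population(self):
        # Monte-Carlo against the generative distribution: 22 subjects
        params = BehaviorParams(seed=0)
        means = {dc: [] for dc in ("go", "no-change", "no-nogo", "change")}
        for s in range(22):
            spec = DesignSpec(n_blocks=2, trials_per_block=60, hand_switch_block=1,
                              seed=100 + s)
            out = simulate_behavior(generate_design(spec),
                                    BehaviorParams(seed=200 + s))
            summ = behavioral_summary(out, by=None).iloc[0]
            for dc in means:
                means[dc].append(summ[f"rt_{dc}"])
        for dc, pop in (("go", 250.0), ("no-change", 358.0),
                        ("no-nogo", 354.0), ("change", 403.0)):
            m = np.mean(means[dc])
            sem = np.std(means[dc], ddof=1) / np.sqrt(len(means[dc]))
            assert abs(m - pop) < 3 * max(sem, 1.0), dc

    def test_refuses_filled_table(self):
        out = simulate_behavior(full_design(seed=9), BehaviorParams())
        with pytest.raises(ValueError, match="already contains responses"):
            simulate_behavior(out, BehaviorParams())


class TestBehavioralSummary:
    def test_constant_rts(self):
        tbl = full_design(seed=1)
        out = simulate_behavior(tbl, BehaviorParams(seed=1))
        out.loc[out.rt_ms.notna(), "rt_ms"] = 300.0
        s = behavioral_summary(out, by=None).iloc[0]
        for dc in ("go", "no-change", "no-nogo", "change"):
            assert s[f"rt_{dc}"] == 300.0

    def test_two_trial_mean(self):
        tbl = pd.DataFrame({
            "condition": ["EG", "EG"], "target_type": ["standard"] * 2,
            "standard_hand": ["right"] * 2, "response": ["right", "right"],
            "rt_ms": [200.0, 400.0], "correct": [True, True],
        })
        s = behavioral_summary(tbl, by=None).iloc[0]
        assert s["rt_go"] == 300.0

    def test_missing_condition_is_nan_not_zero(self):
        tbl = pd.DataFrame({
            "condition": ["EG"], "target_type": ["standard"],
            "standard_hand": ["right"], "response": ["right"],
            "rt_ms": [250.0], "correct": [True],
        })
        s = behavioral_summary(tbl, by=None).iloc[0]
        assert np.isnan(s["rt_change"]) and np.isnan(s["failed_inhibition"])

    def test_matches_independent_groupby(self):
        out = simulate_behavior(full_design(seed=13), BehaviorParams(seed=4))
        out["subject"] = np.repeat(np.arange(4), len(out) // 4)
        summ = behavioral_summary(out, by="subject")
        out["dc"] = derived_condition(out)
        for _, row in summ.iterrows():
            g = out[out.subject == row.subject]
            sel = g[(g.dc == "go") & g.correct & g.rt_ms.notna()]
            assert np.isclose(row["rt_go"], sel.rt_ms.mean())
            eg = g[g.condition == "EG"]
            assert np.isclose(row["premature_EG"], (eg.response == "premature").mean())


class TestRTOrdering:
    def test_cohort_recovers_injected_ordering(self):
        """go < no-change ~ no-nogo < change recovered by paired t-tests."""
        rows = []
        for s in range(20):
            spec = DesignSpec(n_blocks=2, trials_per_block=48, hand_switch_block=1,
                              seed=300 + s)
            out = simulate_behavior(generate_design(spec),
                                    BehaviorParams(seed=400 + s))
            rows.append(behavioral_summary(out, by=None).iloc[0])
        summ = pd.DataFrame(rows)
        assert paired_t(summ["rt_go"], summ["rt_no-change"]).t < -4
        assert paired_t(summ["rt_no-nogo"], summ["rt_change"]).t < -2
        # no-change and no-nogo population means are only 4 ms apart
        diff = paired_t(summ["rt_no-change"], summ["rt_no-nogo"]).mean_diff
        assert abs(diff) < 15.0


def test_trial_table_roundtrip(tmp_path, small_trials):
    path = tmp_path / "trials.tsv"
    write_trial_table(small_trials, path)
    back = read_trial_table(path)
    assert len(back) == len(small_trials)
    assert (back.condition == small_trials.condition.to_numpy()).all()
    np.testing.assert_allclose(back.cue_onset_s, small_trials.cue_onset_s, rtol=1e-12)
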