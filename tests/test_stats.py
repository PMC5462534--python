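"""Mouse-first aggregation, size regression, and the Sidak test battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nmjquant import (
    NMJRecord,
    regress_size_vs_nuclei,
    run_tests,
    sidak_adjust,
    summarize_groups,
)
from nmjquant.stats import permutation_regression_pvalues


def _record(i, mouse, pre="innervated", post="intact", count=3, vol=100.0,
            genotype="wt", age="adult"):
    return NMJRecord(
        id=f"{mouse}_{i}", pre_class=pre, post_class=post, myonuclear_count=count,
        volume_um3=vol, cumulative_intensity=10 * vol, devoid_fraction=0.0,
        max_uncovered_um=0.0, n_branches_ge_5um=4, mouse=mouse,
        genotype=genotype, age=age,
    )


class TestSummarizeGroups:
    def test_single_mouse_proportion(self):
        recs = [_record(i, "m1", pre="partially_innervated" if i < 5 else "innervated")
                for i in range(20)]
        s = summarize_groups(recs)
        assert s.per_mouse["prop_partially_innervated"].iloc[0] == pytest.approx(0.25)
        assert s.single_mouse_groups  # one mouse → s.e.m. undefined, flagged

    def test_group_mean_and_sem_hand_arithmetic(self):
        recs = []
        for mouse, n_pi in (("m1", 4), ("m2", 8)):  # proportions 0.2 and 0.4
            recs += [_record(i, mouse,
                             pre="partially_innervated" if i < n_pi else "innervated")
                     for i in range(20)]
        s = summarize_groups(recs)
        row = s.per_group.iloc[0]
        assert row["prop_partially_innervated"] == pytest.approx(0.3)
        assert row["prop_partially_innervated_sem"] == pytest.approx(0.1)
        assert row["n_mice"] == 2

    def test_all_innervated_zero_degeneration(self):
        recs = [_record(i, m) for m in ("m1", "m2") for i in range(10)]
        s = summarize_groups(recs)
        row = s.per_group.iloc[0]
        assert row["prop_partially_innervated"] == 0.0
        assert row["prop_completely_denervated"] == 0.0
        assert row["prop_post_degenerated"] == 0.0

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(0)
        recs = [_record(i, f"m{i % 3}", count=int(rng.integers(0, 7)))
                for i in range(60)]
        s1 = summarize_groups(recs)
        shuffled = [recs[j] for j in rng.permutation(len(recs))]
        s2 = summarize_groups(shuffled)
        pd.testing.assert_frame_equal(s1.per_group, s2.per_group)
        pd.testing.assert_frame_equal(s1.per_mouse, s2.per_mouse)


class TestRegression:
    def test_exact_line(self):
        df = pd.DataFrame({
            "myonuclear_count": [0, 1, 2, 3, 4],
            "volume_um3": [2.0, 12.0, 22.0, 32.0, 42.0],
            "cumulative_intensity": [1.0, 2.0, 3.0, 4.0, 5.0],
        })
        res = regress_size_vs_nuclei(df)
        assert res["volume_um3"].slope == pytest.approx(10.0)
        assert res["volume_um3"].intercept == pytest.approx(2.0)
        assert res["volume_um3"].r2 == pytest.approx(1.0)

    def test_simulated_slope_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 8, 200)
        df = pd.DataFrame({
            "myonuclear_count": x,
            "volume_um3": 3.0 * x + rng.normal(0, 0.1, 200),
            "cumulative_intensity": 30.0 * x + rng.normal(0, 1.0, 200),
        })
        res = regress_size_vs_nuclei(df)
        assert res["volume_um3"].slope == pytest.approx(3.0, abs=0.1)
        assert res["volume_um3"].p < 1e-6

    def test_zero_variance_counts_explicit_error(self):
        df = pd.DataFrame({
            "myonuclear_count": [3, 3, 3, 3],
            "volume_um3": [1.0, 2.0, 3.0, 4.0],
            "cumulative_intensity": [1.0, 2.0, 3.0, 4.0],
        })
        with pytest.raises(ValueError, match="zero variance"):
            regress_size_vs_nuclei(df)

    def test_permutation_null_uniform(self):
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        x = rng.integers(0, 8, 120).astype(float)
        y = 3.0 * x + rng.normal(0, 1.0, 120)
        ps = permutation_regression_pvalues(x, y, n_permutations=500, rng=rng)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestSidakAndBattery:
    def test_sidak_identity_at_m_one(self):
        assert sidak_adjust(0.037, 1) == pytest.approx(0.037)

    @settings(deadline=None, max_examples=60)
    @given(
        p=st.floats(min_value=0.0, max_value=1.0),
        m1=st.integers(min_value=1, max_value=20),
        m2=st.integers(min_value=1, max_value=20),
    )
    def test_sidak_monotone_in_m_and_p(self, p, m1, m2):
        lo_m, hi_m = sorted((m1, m2))
        assert sidak_adjust(p, hi_m) >= sidak_adjust(p, lo_m) - 1e-12
        assert sidak_adjust(p, lo_m) >= p - 1e-12

    def test_identical_groups_t_is_zero_p_is_one(self):
        d = pd.DataFrame({
            "genotype": ["wt"] * 4 + ["ko"] * 4,
            "value": [1.0, 2.0, 3.0, 4.0] * 2,
        })
        res = run_tests(d, "value", ["genotype"])
        c = res["comparisons"][0]
        assert c.statistic == pytest.approx(0.0)
        assert c.p_raw == pytest.approx(1.0)

    def test_two_way_anova_detects_group_shift(self):
        rng = np.random.default_rng(3)
        rows = []
        for g in ("wt", "ko"):
            for a in ("young", "old"):
                shift = 3.0 if (g, a) == ("ko", "old") else 0.0
                rows += [{"genotype": g, "age": a, "value": rng.normal(shift, 1.0)}
                         for _ in range(8)]
        d = pd.DataFrame(rows)
        res = run_tests(d, "value", ["genotype", "age"])
        assert res["test"] == "two_way_anova_sidak"
        sig = {c.name: c.significant for c in res["comparisons"]}
        assert any(sig.values())
        for c in res["comparisons"]:
            assert c.p_sidak >= c.p_raw - 1e-12

    def test_empty_cell_is_design_error(self):
        d = pd.DataFrame({
            "genotype": ["wt", "wt", "ko", "ko"],
            "age": ["young", "young", "young", "old"],
            "value": [1.0, 2.0, 3.0, 4.0],
        })
        with pytest.raises(ValueError, match="empty cells"):
            run_tests(d, "value", ["genotype", "age"])
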