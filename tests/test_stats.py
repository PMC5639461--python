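"""Group statistics: mixed-design RM-ANOVA, t-tests, skew-normal
frequency-distribution comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import somnotype as st
from _oracles import mixed_anova_ss_bruteforce


def tidy_from_nested(table):
    rows = []
    for g, subjects in table.items():
        for s, levels in subjects.items():
            for l, v in levels.items():
                rows.append(
                    {"genotype": g, "subject": s, "category": l, "value": v}
                )
    return pd.DataFrame(rows)


def random_nested(rng, a=2, n=4, b=3, effect=0.0):
    table = {}
    for gi in range(a):
        table[f"g{gi}"] = {
            f"g{gi}s{si}": {
                f"l{li}": float(rng.standard_normal() + effect * gi * (li == 0))
                for li in range(b)
            }
            for si in range(n)
        }
    return table


class TestMixedAnova:
    def test_ss_decomposition_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            table = random_nested(rng, a=2, n=3, b=4)
            res = st.two_way_rm_anova(tidy_from_nested(table))
            want = mixed_anova_ss_bruteforce(table)
            assert res.table.loc["between", "SS"] == pytest.approx(want["group"])
            assert res.table.loc["subject", "SS"] == pytest.approx(want["subject"])
            assert res.table.loc["within", "SS"] == pytest.approx(want["within"])
            assert res.table.loc["interaction", "SS"] == pytest.approx(
                want["interaction"]
            )
            assert res.table.loc["residual", "SS"] == pytest.approx(
                want["residual"]
            )

    def test_f_statistics_match_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        df = tidy_from_nested(random_nested(rng, a=2, n=5, b=4, effect=1.0))
        res = st.two_way_rm_anova(df)
        pg = pingouin.mixed_anova(
            data=df, dv="value", within="category", subject="subject",
            between="genotype"
        ).set_index("Source")
        assert res.table.loc["between", "F"] == pytest.approx(
            pg.loc["genotype", "F"], rel=1e-6
        )
        assert res.table.loc["within", "F"] == pytest.approx(
            pg.loc["category", "F"], rel=1e-6
        )
        assert res.table.loc["interaction", "F"] == pytest.approx(
            pg.loc["Interaction", "F"], rel=1e-6
        )

    def test_percent_variation_sums_to_100(self):
        rng = np.random.default_rng(3)
        res = st.two_way_rm_anova(tidy_from_nested(random_nested(rng)))
        assert res.table["percent_variation"].sum() == pytest.approx(100.0)
        assert (res.table["SS"] >= 0).all()

    def test_bonferroni_adjustment_caps_at_one_and_dominates_raw(self):
        rng = np.random.default_rng(9)
        res = st.two_way_rm_anova(tidy_from_nested(random_nested(rng, b=4)))
        ph = res.posthoc
        assert (ph["p_bonferroni"] >= ph["p_raw"] - 1e-12).all()
        expected = np.minimum(1.0, 4 * ph["p_raw"])
        np.testing.assert_allclose(ph["p_bonferroni"], expected)

    def test_unbalanced_design_rejected(self):
        rng = np.random.default_rng(1)
        df = tidy_from_nested(random_nested(rng)).iloc[:-1]
        with pytest.raises(st.ValidationError):
            st.two_way_rm_anova(df)

    def test_interaction_type_one_error_calibrated(self):
        """Null simulation: interaction rejected at ~5% when no effect is
        planted."""
        rng = np.random.default_rng(101)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            res = st.two_way_rm_anova(
                tidy_from_nested(random_nested(rng, a=2, n=4, b=4))
            )
            rejections += res.table.loc["interaction", "P"] < 0.05
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.09  # 5% +/- Monte-Carlo error


class TestTTests:
    def test_identical_groups_give_p_one(self):
        assert st.welch_t_test([3.0, 3.0, 3.0], [3.0, 3.0])[2] == 1.0

    def test_separated_groups_give_tiny_p(self):
        a = np.array([100.0, 100.001, 99.999])
        _, _, p = st.welch_t_test(a, a - 100.0)
        assert p < 1e-10

    def test_matches_closed_form_welch(self):
        a = np.array([4.2, 5.1, 6.3, 5.5])
        b = np.array([7.7, 8.1, 6.9, 9.0, 8.2])
        t, df, p = st.welch_t_test(a, b)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_ref = (va + vb) ** 2 / (
            va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        )
        assert t == pytest.approx(t_ref)
        assert df == pytest.approx(df_ref)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_ref), df_ref))

    def test_log_test_reports_geometric_means(self):
        t, df, p, ga, gb = st.log_geomean_t_test([1.0, 100.0], [10.0, 10.0])
        assert ga == pytest.approx(10.0)
        assert gb == pytest.approx(10.0)

    def test_log_test_scale_invariant(self):
        rng = np.random.default_rng(2)
        a = np.exp(rng.standard_normal(8))
        b = np.exp(rng.standard_normal(8) + 0.5)
        t1 = st.log_geomean_t_test(a, b)[0]
        t2 = st.log_geomean_t_test(37.0 * a, 37.0 * b)[0]
        assert t1 == pytest.approx(t2)

    def test_log_test_rejects_nonpositive_values(self):
        with pytest.raises(st.ParameterError):
            st.log_geomean_t_test([1.0, -2.0], [1.0, 2.0])


class TestSkewNormalComparison:
    def test_df_pair_follows_bin_count(self):
        rng = np.random.default_rng(0)
        a = sps.skewnorm.rvs(3, size=300, random_state=rng)
        b = sps.skewnorm.rvs(3, size=300, random_state=rng)
        res = st.compare_distributions_skewnormal(a, b, n_bins=21)
        assert (res.df1, res.df2) == (3, 36)  # 2*21 bins - 6 params

    def test_pooled_ss_bounds_separate_ss(self):
        rng = np.random.default_rng(1)
        a = sps.skewnorm.rvs(3, loc=0, size=400, random_state=rng)
        b = sps.skewnorm.rvs(3, loc=1, size=400, random_state=rng)
        res = st.compare_distributions_skewnormal(a, b)
        assert res.ss_separate <= res.ss_pooled

    def test_f_invariant_to_group_relabelling(self):
        rng = np.random.default_rng(6)
        a = sps.skewnorm.rvs(4, loc=10, scale=4, size=400, random_state=rng)
        b = sps.skewnorm.rvs(4, loc=12, scale=4, size=400, random_state=rng)
        f_ab = st.compare_distributions_skewnormal(a, b).f
        f_ba = st.compare_distributions_skewnormal(b, a).f
        assert f_ab == pytest.approx(f_ba, rel=1e-6)

    def test_location_shift_detected(self):
        """Power: clearly shifted samples are flagged in the large
        majority of replicates."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(40):
            a = sps.skewnorm.rvs(4, loc=10, scale=4, size=500, random_state=rng)
            c = sps.skewnorm.rvs(4, loc=12, scale=4, size=500, random_state=rng)
            res = st.compare_distributions_skewnormal(a, c)
            hits += res.p is not None and res.p < 0.01
        assert hits >= 32

    def test_null_rejection_bounded(self):
        """The histogram least-squares F-test is known to be somewhat
        anticonservative; the null rejection rate stays well below the
        gross-miscalibration regime and most replicates accept."""
        rng = np.random.default_rng(12)
        accepts = 0
        n_rep = 60
        for _ in range(n_rep):
            a = sps.skewnorm.rvs(4, loc=10, scale=4, size=500, random_state=rng)
            b = sps.skewnorm.rvs(4, loc=10, scale=4, size=500, random_state=rng)
            res = st.compare_distributions_skewnormal(a, b)
            accepts += res.p is not None and res.p > 0.05
        assert accepts / n_rep >= 0.6


class TestRiseTimeFilter:
    def test_counts_match_bruteforce(self):
        rng = np.random.default_rng(3)
        events = pd.DataFrame(
            {"amplitude": rng.random(200), "rise_ms": rng.uniform(0.5, 4.0, 200)}
        )
        kept = st.filter_events_by_rise_time(events)
        want = sum(1 for r in events["rise_ms"] if r <= 2.0)
        assert len(kept) == want

    def test_all_fast_events_unchanged_and_all_slow_empty(self):
        fast = pd.DataFrame({"rise_ms": [1.0, 0.5, 1.9]})
        slow = pd.DataFrame({"rise_ms": [3.0, 2.5]})
        assert len(st.filter_events_by_rise_time(fast)) == 3
        assert len(st.filter_events_by_rise_time(slow)) == 0
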