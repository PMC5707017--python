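"""Group statistics against closed forms and scipy distribution oracles."""

import numpy as np
import pytest
from scipy import stats as sps

import furawave as fw


class TestSummarize:
    @pytest.mark.parametrize(
        "values, mean, se",
        [
            ([2, 2, 2], 2.0, 0.0),
            ([1, 2, 3], 2.0, 1 / np.sqrt(3)),
            ([5], 5.0, 0.0),
        ],
    )
    def test_mean_and_standard_error(self, values, mean, se):
        s = fw.summarize(values)
        assert s.mean == pytest.approx(mean, abs=1e-12)
        assert s.se == pytest.approx(se, abs=1e-12)
        assert s.n == len(values)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fw.summarize([])


class TestStudentT:
    def test_identical_groups(self):
        r = fw.student_t_unpaired([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_hand_computed_example(self):
        r = fw.student_t_unpaired([1, 2, 3], [2, 3, 4])
        assert abs(r.statistic) == pytest.approx(1.224744871, rel=1e-8)
        assert r.df == 4
        assert r.p_value == pytest.approx(0.2878641347, rel=1e-6)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=12), rng.normal(0.5, 1.2, size=9)
        r = fw.student_t_unpaired(a, b)
        t0, p0 = sps.ttest_ind(a, b, equal_var=True)
        assert r.statistic == pytest.approx(t0, rel=1e-10)
        assert r.p_value == pytest.approx(p0, rel=1e-6)

    def test_scale_invariance(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 5.0, 6.0]
        r1 = fw.student_t_unpaired(a, b)
        r2 = fw.student_t_unpaired([3 * x for x in a], [3 * x for x in b])
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_degenerate_unequal_means_guard(self):
        r = fw.student_t_unpaired([1, 1, 1], [2, 2, 2])
        assert np.isinf(r.statistic) and r.p_value == 0.0 and r.notes

    def test_type_one_error_calibrated_under_null(self):
        # 10,000 seeded null simulations, alpha = 0.05 -> rate 0.05 +/- 0.01
        rng = np.random.default_rng(2024)
        n, sims = 10, 10_000
        x = rng.normal(size=(sims, n))
        y = rng.normal(size=(sims, n))
        va, vb = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
        sp2 = ((n - 1) * va + (n - 1) * vb) / (2 * n - 2)
        t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(sp2 * 2 / n)
        p = 2 * sps.t.sf(np.abs(t), 2 * n - 2)
        rate = float((p < 0.05).mean())
        assert rate == pytest.approx(0.05, abs=0.01)
        # spot-check the vectorised null against the implementation
        r = fw.student_t_unpaired(x[0], y[0])
        assert r.statistic == pytest.approx(t[0], rel=1e-10)


class TestAnova:
    def test_hand_computed_example(self):
        r = fw.one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert r.statistic == pytest.approx(3.0, rel=1e-12)
        assert r.df == (2.0, 6.0)
        assert r.p_value == pytest.approx(sps.f.sf(3.0, 2, 6), rel=1e-6)

    def test_identical_groups_give_zero_F(self):
        r = fw.one_way_anova([[1, 1, 1], [1, 1, 1]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_two_group_F_equals_t_squared(self):
        a, b = [1.0, 2.0, 3.5, 4.0], [2.0, 4.0, 5.0]
        f = fw.one_way_anova([a, b]).statistic
        t = fw.student_t_unpaired(a, b).statistic
        assert f == pytest.approx(t * t, rel=1e-10)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, size=8) for m in (0, 0.5, 1.0)]
        r = fw.one_way_anova(groups)
        f0, p0 = sps.f_oneway(*groups)
        assert r.statistic == pytest.approx(f0, rel=1e-10)
        assert r.p_value == pytest.approx(p0, rel=1e-6)


class TestNewmanKeuls:
    def test_identical_groups_nothing_significant(self):
        t = fw.newman_keuls([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert not t.significant.any()

    def test_outlier_group_flagged_against_both(self):
        rng = np.random.default_rng(5)
        near1 = rng.normal(0.0, 1.0, size=10)
        near2 = rng.normal(0.2, 1.0, size=10)
        far = rng.normal(8.0, 1.0, size=10)
        t = fw.newman_keuls([near1, near2, far], labels=["a", "b", "far"])
        flagged = t[t.significant]
        assert set(map(tuple, flagged[["group_a", "group_b"]].values)) == {
            ("a", "far"), ("b", "far")}

    def test_q_critical_matches_studentized_range_oracle(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 1, size=6) for m in (0, 1, 2, 3)]
        t = fw.newman_keuls(groups)
        df_w = sum(len(g) for g in groups) - len(groups)
        for _, row in t.iterrows():
            assert row.q_crit == pytest.approx(
                sps.studentized_range.ppf(0.95, row.span, df_w), rel=1e-9)

    def test_invariant_to_input_permutation(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1, size=7) for m in (0, 0.5, 3.0)]
        t1 = fw.newman_keuls(groups, labels=["a", "b", "c"])
        t2 = fw.newman_keuls(groups[::-1], labels=["c", "b", "a"])
        key = lambda t: {frozenset((r.group_a, r.group_b)): r.significant
                         for _, r in t.iterrows()}
        assert key(t1) == key(t2)

    def test_stepwise_rule_blocks_nested_pairs(self):
        # random configurations: no pair inside a non-significant span may be
        # declared significant
        for seed in range(20):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(rng.uniform(0, 1.5), 1, size=5) for _ in range(4)]
            t = fw.newman_keuls(groups)
            spans = {(r.group_a, r.group_b): r for _, r in t.iterrows()}
            order = sorted({r.group_a for r in spans.values()}
                           | {r.group_b for r in spans.values()})
            for _, r in t.iterrows():
                if r.blocked:
                    assert not r.significant


class TestResponderFraction:
    def test_full_versus_none_separation(self):
        r = fw.responder_fraction({
            "hi": [[True] * 10, [True] * 12],
            "lo": [[False] * 10, [False] * 11],
        })
        means = {s.label: s.mean for s in r.summaries}
        assert means["hi"] == 100.0 and means["lo"] == 0.0

    def test_single_recording_skips_test_with_warning(self):
        with pytest.warns(UserWarning, match="recordings"):
            r = fw.responder_fraction({"a": [[True, False]], "b": [[True], [False]]})
        assert r.statistic is None and r.p_value is None

    def test_empty_recording_excluded(self):
        with pytest.warns(UserWarning, match="0 cells"):
            r = fw.responder_fraction({
                "a": [[True, True], [], [False, True]],
                "b": [[False, False], [False, True]],
            })
        assert next(s for s in r.summaries if s.label == "a").n == 2

    def test_simulated_phenotypes_separate_significantly(self):
        flags = {}
        for label, name, base in (("n", "n_like", 0), ("bc", "bc_like", 100)):
            flags[label] = []
            for r in range(6):
                coh = fw.simulate_cohort(fw.preset(name, n_cells=25, seed=base + r))
                flags[label].append(
                    [fw.compute_spike_metrics(tr).is_responder for tr in coh])
        res = fw.responder_fraction(flags)
        assert res.p_value < 0.05
        means = {s.label: s.mean for s in res.summaries}
        assert means["n"] > means["bc"]


class TestDeltaCt:
    def test_difference_and_orientation(self):
        assert fw.delta_ct(25, 20).delta_ct == 5.0
        assert fw.delta_ct(20, 20).delta_ct == 0.0
        assert fw.delta_ct(30, 20).delta_ct > fw.delta_ct(25, 20).delta_ct
        assert "low expression" in fw.CtRecord.interpretation

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fw.delta_ct(float("nan"), 20)
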