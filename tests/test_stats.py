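from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from gvscreen.stats import (bh_fdr, category_wilcoxon, interval_ttest_maps,
                            kendalls_w, median_ranks_by_category,
                            spearman_ses, subject_ranks)
from gvscreen.stimuli import StimulusSpec


def _toy_library(sizes: dict[int, int]):
    lib, sid = [], 1
    for cat, n in sizes.items():
        for _ in range(n):
            lib.append(StimulusSpec(stim_id=sid, family="sinusoid",
                                    params={"carrier_hz": 10.0},
                                    category_id=cat,
                                    category_label=f"cat{cat}"))
            sid += 1
    return lib


class TestSubjectRanks:
    def test_column_ordering(self):
        d = np.array([[0.1], [0.3], [0.2]])
        np.testing.assert_array_equal(subject_ranks(d).ravel(), [1, 3, 2])

    def test_tied_distances_averaged(self):
        d = np.array([[0.5], [0.5], [0.1]])
        np.testing.assert_array_equal(subject_ranks(d).ravel(), [2.5, 2.5, 1])

    def test_rank_sum_identity(self, rng):
        d = rng.uniform(0, 1, (304, 5))
        r = subject_ranks(d)
        np.testing.assert_allclose(r.sum(axis=0), 304 * 305 / 2)


class TestMedianRanks:
    def test_odd_and_even_medians(self):
        lib = _toy_library({1: 3, 2: 2})
        ranks = np.array([[10.0], [20.0], [300.0], [10.0], [20.0]])
        med = median_ranks_by_category(ranks, np.arange(1, 6), lib)
        assert med.loc[1, 0] == 20.0
        assert med.loc[2, 0] == 15.0

    def test_singletons_excluded(self, library):
        ranks = np.arange(1, 305, dtype=float).reshape(-1, 1)
        med = median_ranks_by_category(ranks, np.arange(1, 305), library)
        assert len(med) == 35

    def test_empty_category_raises(self):
        lib = _toy_library({1: 2, 2: 2})
        with pytest.raises(ValueError, match="category"):
            median_ranks_by_category(np.ones((2, 1)), np.array([1, 2]), lib)


class TestKendallsW:
    def test_identical_rankings(self, rng):
        col = rng.permutation(35).astype(float)
        w, chi2, p = kendalls_w(np.tile(col[:, None], (1, 5)))
        assert w == pytest.approx(1.0)
        assert p < 1e-10

    def test_reversed_rankings(self):
        a = np.arange(35.0)
        w, _, p = kendalls_w(np.column_stack([a, a[::-1]]))
        assert w == pytest.approx(0.0)

    def test_null_calibration(self):
        # independent rankings: p-values approximately Uniform(0,1)
        ps, ws = [], []
        for s in range(1000):
            r = np.random.default_rng(s)
            x = np.column_stack([r.permutation(35) for _ in range(5)])
            w, _, p = kendalls_w(x.astype(float))
            ps.append(p)
            ws.append(w)
        assert sps.kstest(ps, "uniform").pvalue > 0.01
        # E[W] under independence is 1/m
        assert np.mean(ws) == pytest.approx(1 / 5, abs=0.02)

    def test_too_few_items(self):
        with pytest.raises(ValueError, match="3 items"):
            kendalls_w(np.ones((2, 5)))

    def test_too_few_raters(self):
        with pytest.raises(ValueError, match="raters"):
            kendalls_w(np.ones((5, 1)))


class TestBhFdr:
    def _brute_force(self, p, alpha):
        # classic step-up: largest k with p_(k) <= k*alpha/m
        m = len(p)
        order = np.argsort(p)
        k_max = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * alpha / m:
                k_max = k
        reject = np.zeros(m, dtype=bool)
        reject[order[:k_max]] = True
        return reject

    def test_example_all_rejected(self):
        q, rej = bh_fdr(np.array([0.005, 0.02, 0.03, 0.1]), 0.1)
        # brute-force step-up at alpha=0.1 rejects all four
        assert rej.all()

    def test_all_ones_no_rejections(self):
        q, rej = bh_fdr(np.ones(10), 0.1)
        assert not rej.any()
        assert np.all(q == 1.0)

    def test_single_p_identity(self):
        q, rej = bh_fdr(np.array([0.04]), 0.05)
        assert q[0] == pytest.approx(0.04)
        assert rej[0]

    def test_matches_brute_force_step_up(self):
        for s in range(1000):
            r = np.random.default_rng(s)
            p = r.uniform(0, 1, r.integers(2, 25))
            p[r.random(p.size) < 0.3] /= 50  # sprinkle small p-values
            _, rej = bh_fdr(p, 0.05)
            np.testing.assert_array_equal(rej, self._brute_force(p, 0.05))

    def test_q_monotone_in_sorted_order(self, rng):
        p = rng.uniform(0, 1, 50)
        q, _ = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_q_at_least_p(self, rng):
        p = rng.uniform(0, 1, 50)
        q, _ = bh_fdr(p)
        assert (q >= p - 1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            bh_fdr(np.array([0.5, 1.2]))


class TestCategoryWilcoxon:
    def test_small_case_exact_p(self):
        # category {1,2} vs pool {3,4,5}: minimal rank sum, exact one-tailed
        # p = 1/C(5,2) = 0.1 -- verified against the permutation oracle below
        lib = _toy_library({1: 2, 2: 3})
        ranks = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        df = category_wilcoxon(ranks, np.arange(1, 6), lib)
        p_cat1 = float(df[df["category_id"] == 1]["p"].iloc[0])
        # permutation oracle: distribution of the member rank-sum over all
        # C(5,2) assignments
        sums = [sum(c) for c in combinations(range(1, 6), 2)]
        p_oracle = np.mean([s <= 3 for s in sums])
        assert p_oracle == pytest.approx(0.1)
        assert p_cat1 == pytest.approx(p_oracle, abs=1e-12)

    def test_type_one_error_calibration(self):
        # null: category ranks from the same distribution as the complement
        lib = _toy_library({1: 10, 2: 90})
        hits = 0
        n_sims = 1000
        for s in range(n_sims):
            r = np.random.default_rng(s)
            ranks = r.permutation(100) + 1.0
            df = category_wilcoxon(ranks, np.arange(1, 101), lib)
            hits += float(df[df["category_id"] == 1]["p"].iloc[0]) < 0.05
        assert 0.03 <= hits / n_sims <= 0.07

    def test_bh_applied_across_categories(self, library):
        ranks = np.random.default_rng(3).permutation(304) + 1.0
        df = category_wilcoxon(ranks, np.arange(1, 305), library)
        assert len(df) == 35
        assert (df["q"] >= df["p"] - 1e-15).all()
        assert ((df["q"] <= 0.1) == df["significant"]).all()


class TestSpearman:
    def test_identical(self, rng):
        x = rng.standard_normal(50)
        rho, _ = spearman_ses(x, x)
        assert rho == pytest.approx(1.0)

    def test_reversed(self, rng):
        x = np.sort(rng.standard_normal(50))
        rho, _ = spearman_ses(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_null_calibration(self):
        rhos, ps = [], []
        for s in range(1000):
            r = np.random.default_rng(s)
            rho, p = spearman_ses(r.standard_normal(304),
                                  r.standard_normal(304))
            rhos.append(rho)
            ps.append(p)
        assert abs(np.mean(rhos)) < 0.01
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_ses(np.ones(10), np.arange(10.0))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            spearman_ses(np.ones(3), np.ones(4))


class TestChannelMaps:
    CHANNELS = [f"ch{i}" for i in range(36)]

    def test_identical_intervals_null(self, rng):
        vals = rng.standard_normal((20, 36))
        maps = interval_ttest_maps({"pre": vals, "stim": vals.copy(),
                                    "post": vals.copy()}, self.CHANNELS,
                                   "RelBetaPower", "PD")
        for m in maps:
            assert np.all(m.t == 0.0)
            assert np.all(m.p == 1.0)
            assert np.all(m.q == 1.0)

    def test_shifted_interval_detected(self, rng):
        pre = rng.standard_normal((40, 36))
        stim = pre + 1.5
        maps = interval_ttest_maps({"pre": pre, "stim": stim, "post": pre},
                                   self.CHANNELS, "RelBetaPower", "PD")
        pre_stim = [m for m in maps if m.comparison == "pre-vs-stim"][0]
        assert (pre_stim.q < 0.05).sum() == 36
        pre_post = [m for m in maps if m.comparison == "pre-vs-post"][0]
        assert (pre_post.q < 0.05).sum() == 0

    def test_too_few_trials(self, rng):
        vals = rng.standard_normal((2, 36))
        with pytest.raises(ValueError, match="3"):
            interval_ttest_maps({"pre": vals, "stim": vals, "post": vals},
                                self.CHANNELS, "PTAsym", "HC")

    def test_frame_shape(self, rng):
        vals = rng.standard_normal((10, 36))
        maps = interval_ttest_maps({"pre": vals, "stim": vals + 0.1,
                                    "post": vals}, self.CHANNELS, "PTAsym",
                                   "HC")
        df = maps[0].to_frame()
        assert len(df) == 36
        assert set(df.columns) == {"biomarker", "group", "comparison",
                                   "channel", "t", "p", "q", "neglog10_q"}


class TestBhFdrProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    p_lists = st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                       max_size=25)

    @given(p=p_lists)
    @settings(max_examples=200, deadline=None)
    def test_q_values_bounded_and_dominate_p(self, p):
        q, _ = bh_fdr(np.array(p))
        assert ((q >= -1e-15) & (q <= 1.0)).all()
        assert (q >= np.array(p) - 1e-12).all()

    @given(p=p_lists)
    @settings(max_examples=200, deadline=None)
    def test_rejections_match_classic_step_up(self, p):
        p = np.array(p)
        _, rej = bh_fdr(p, 0.05)
        m = p.size
        order = np.argsort(p, kind="stable")
        k_max = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * 0.05 / m:
                k_max = k
        expected = np.zeros(m, dtype=bool)
        expected[order[:k_max]] = True
        np.testing.assert_array_equal(rej, expected)
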