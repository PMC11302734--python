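"""Paired tests against exact enumeration, calibration, correlation and leverage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gutpair.containers import AbundanceTable
from gutpair.differential import (
    differential_screen,
    group_mean_correlation,
    leave_one_out_screen,
    outlier_sensitivity,
    paired_test,
    rank_sum_test,
    wilcoxon_signed_rank,
)
from gutpair.exceptions import ValidationError
from gutpair.simulate import generate_cohort, null_community_config, simulate_dataset

from conftest import small_cohort


def enumeration_p(d: np.ndarray) -> float:
    """Exhaustive 2^n sign-flip two-sided p for the signed-rank statistic."""
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    t = ranks.sum()
    signs = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
    w_all = signs @ ranks
    return float(np.mean(np.abs(w_all - t / 2) >= abs(w - t / 2) - 1e-12))


class TestWilcoxon:
    def test_all_positive_differences_n5(self):
        # all 5 differences positive: exactly the two extreme sign patterns
        w, p, n_used, _ = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 1, 1, 1, 1])
        assert w == 15.0
        assert p == pytest.approx(2 / 32)
        assert n_used == 5

    def test_equal_vectors_p_one(self):
        res = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.direction == "none"

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        a = rng.normal(0, 1, n)
        b = rng.normal(0.4, 1, n)
        _, p, _, _ = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(enumeration_p(a - b), abs=1e-12)

    def test_matches_enumeration_under_ties(self):
        a = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        b = np.array([2.0, 2.0, 3.0, 2.0, 4.0, 2.0])  # |d| ties: 1,1,1,1,1,7
        _, p, _, _ = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(enumeration_p(a - b), abs=1e-12)

    def test_matches_scipy_exact_on_tiefree_data(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(5, 20))
            a, b = rng.normal(0, 1, n), rng.normal(0.2, 1, n)
            _, p, _, _ = wilcoxon_signed_rank(a, b)
            assert p == pytest.approx(stats.wilcoxon(a, b, mode="exact").pvalue, abs=1e-12)

    def test_normal_approximation_branch(self):
        rng = np.random.default_rng(2)
        n = 40
        a, b = rng.normal(0.5, 1, n), rng.normal(0, 1, n)
        _, p, _, _ = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, mode="approx", correction=False).pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_zero_differences_dropped(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = np.array([1.0, 2.0, 1.0, 2.0, 3.0, 4.0])
        w, p, n_used, n_dropped = wilcoxon_signed_rank(a, b)
        assert (n_used, n_dropped) == (4, 2)
        w2, p2, _, _ = wilcoxon_signed_rank(a[2:], b[2:])
        assert (w, p) == (w2, p2)

    def test_scale_invariance(self):
        a = np.array([1.0, 5.0, 2.5, 7.0, 4.0])
        b = np.array([0.5, 6.0, 2.0, 3.0, 4.5])
        _, p1, _, _ = wilcoxon_signed_rank(a, b)
        _, p2, _, _ = wilcoxon_signed_rank(100 * a, 100 * b)
        assert p1 == p2

    def test_exchangeability(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        r_ab = paired_test(a, b)
        r_ba = paired_test(b, a)
        assert r_ab.p_value == pytest.approx(r_ba.p_value)
        assert {r_ab.direction, r_ba.direction} == {"higher_in_a", "higher_in_b"}


class TestOtherMethods:
    def test_paired_t_matches_scipy(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(1, 1, 15), rng.normal(0, 1, 15)
        res = paired_test(a, b, method="paired_t")
        ref = stats.ttest_rel(a, b)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_rank_sum_matches_permutation_oracle(self):
        from itertools import combinations

        rng = np.random.default_rng(10)
        for _ in range(10):
            n1, n2 = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            x, y = rng.normal(0, 1, n1), rng.normal(1, 1, n2)
            res = rank_sum_test(x, y)
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            obs = ranks[:n1].sum()
            total = 0
            count = 0
            mean_r = ranks.sum() * n1 / (n1 + n2)
            for idx in combinations(range(n1 + n2), n1):
                w = ranks[list(idx)].sum()
                total += 1
                count += abs(w - mean_r) >= abs(obs - mean_r) - 1e-12
            assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError):
            paired_test([1, 2], [3, 4], method="bogus")


def build_table(values: np.ndarray, metadata: pd.DataFrame, level="genus") -> AbundanceTable:
    return AbundanceTable(
        pd.DataFrame(values, index=[f"f{i}" for i in range(values.shape[0])],
                     columns=metadata.index),
        level=level,
    )


class TestScreen:
    def test_single_feature(self):
        md = generate_cohort(small_cohort(4), seed=0)
        rng = np.random.default_rng(0)
        t = build_table(rng.random((1, len(md))), md)
        res = differential_screen(t, md)
        assert len(res) == 1

    def test_type_one_error_calibrated(self):
        # no planted effects, site-symmetric occupancy: rejection rate ~ alpha
        fracs = []
        for seed in range(3):
            ds = simulate_dataset(seed=700 + seed,
                                  community_config=null_community_config(n_genes=1000))
            res = differential_screen(ds.table, ds.metadata)
            fracs.append(np.mean([r.significant for r in res]))
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_all_zero_features_skipped(self):
        md = generate_cohort(small_cohort(4), seed=1)
        values = np.vstack([np.zeros(len(md)), np.random.default_rng(1).random(len(md))])
        res = differential_screen(build_table(values, md), md)
        assert [r.feature_id for r in res] == ["f1"]

    def test_fdr_flag_adds_q_values(self):
        md = generate_cohort(small_cohort(6), seed=2)
        rng = np.random.default_rng(2)
        t = build_table(rng.random((20, len(md))), md)
        res = differential_screen(t, md, fdr=True)
        qs = [r.q_value for r in res]
        assert all(q is not None for q in qs)
        assert all(q >= p for q, p in zip(qs, [r.p_value for r in res]))


class TestCorrelation:
    def test_perfect_correlation(self):
        md = generate_cohort(small_cohort(4), seed=3)
        base = np.array([0.5, 0.3, 0.2])
        values = np.tile(base[:, None], (1, len(md)))
        res = group_mean_correlation(build_table(values, md), md)
        assert res.r_squared == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # mucosa means (0.2, 0.3, 0.5) vs feces means (0.5, 0.3, 0.2):
        # r = -13/14, r^2 = 169/196
        md = generate_cohort(small_cohort(2), seed=4)
        values = np.zeros((3, 4))
        mu_cols = [i for i, s in enumerate(md["site"]) if s == "mucosa"]
        fe_cols = [i for i, s in enumerate(md["site"]) if s == "feces"]
        values[:, mu_cols] = np.array([0.2, 0.3, 0.5])[:, None]
        values[:, fe_cols] = np.array([0.5, 0.3, 0.2])[:, None]
        res = group_mean_correlation(build_table(values, md), md)
        assert res.r == pytest.approx(-13 / 14, abs=1e-12)
        assert res.r_squared == pytest.approx(169 / 196, abs=1e-3)

    def test_too_few_features_rejected(self):
        md = generate_cohort(small_cohort(2), seed=5)
        values = np.random.default_rng(5).random((3, 4))
        with pytest.raises(ValidationError):
            group_mean_correlation(build_table(values, md), md, excluded="f0")


class TestLeaveOneOut:
    def test_matches_bruteforce(self):
        md = generate_cohort(small_cohort(6), seed=6)
        rng = np.random.default_rng(6)
        t = build_table(rng.random((50, len(md))), md)
        screen = leave_one_out_screen(t, md)
        full = group_mean_correlation(t, md).r_squared
        for feature in t.data.index:
            expect = group_mean_correlation(t, md, excluded=feature).r_squared - full
            assert screen.loc[feature, "delta_r2"] == pytest.approx(expect, abs=1e-12)

    def test_collinear_features_no_leverage(self):
        md = generate_cohort(small_cohort(3), seed=7)
        x = np.linspace(0.1, 1.0, 10)
        values = np.zeros((10, 6))
        values[:, [i for i, s in enumerate(md["site"]) if s == "mucosa"]] = x[:, None]
        values[:, [i for i, s in enumerate(md["site"]) if s == "feces"]] = (2 * x)[:, None]
        screen = leave_one_out_screen(build_table(values, md), md)
        assert np.allclose(screen["delta_r2"], 0.0, atol=1e-9)

    def test_planted_discriminator_ranks_first(self, default_dataset):
        from gutpair.profiling import aggregate_rank, shared_exclusive_taxa

        genus = aggregate_rank(default_dataset.table, default_dataset.annotation, "genus")
        shared, _, _ = shared_exclusive_taxa(genus, default_dataset.metadata)
        screen = leave_one_out_screen(genus, default_dataset.metadata, sorted(shared))
        assert screen.index[0] == "g01"
        assert screen.iloc[0]["delta_r2"] > 0

    def test_excluding_discriminator_raises_r2(self, default_dataset):
        from gutpair.profiling import aggregate_rank, shared_exclusive_taxa

        genus = aggregate_rank(default_dataset.table, default_dataset.annotation, "genus")
        shared, _, _ = shared_exclusive_taxa(genus, default_dataset.metadata)
        full = group_mean_correlation(genus, default_dataset.metadata, sorted(shared))
        reduced = group_mean_correlation(genus, default_dataset.metadata, sorted(shared),
                                         excluded="g01")
        assert reduced.r_squared > full.r_squared


class TestOutlierSensitivity:
    def test_single_extreme_pair_flips_significance(self):
        # moderate mixed signal that clears alpha only thanks to one extreme pair
        d = np.array([5.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.45, -0.3, -0.2, -0.1])
        res = outlier_sensitivity(d, np.zeros(10))
        assert res.dropped_index == 0
        assert res.p_full < 0.05 < res.p_reduced
        assert res.flag_changed

    def test_homogeneous_effect_robust(self):
        rng = np.random.default_rng(9)
        b = rng.normal(0, 0.1, 12)
        a = b + 1.0 + rng.normal(0, 0.05, 12)
        res = outlier_sensitivity(a, b)
        assert res.p_full < 0.05 and res.p_reduced < 0.05
        assert not res.flag_changed

    def test_reduced_p_matches_direct_recomputation(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(1, 1, 8), rng.normal(0, 1, 8)
        res = outlier_sensitivity(a, b)
        keep = np.ones(8, bool)
        keep[np.argmax(np.abs(a - b))] = False
        direct = paired_test(a[keep], b[keep])
        assert res.p_reduced == direct.p_value

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            outlier_sensitivity([1, 2], [2, 1])
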