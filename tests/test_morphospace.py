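"""Ternary morphospace coordinates and rank-based group comparisons."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from conchrock import morphospace as ms
from conchrock.morphospace import CoilingRecord, TernaryPoint


def rec(w, u, th, group="g", taxon="t"):
    return CoilingRecord(taxon=taxon, group=group, whorl_expansion=w,
                         umbilical_exposure=u, thickness_ratio=th)


def brute_ranks(values):
    """Midranks by pairwise counting, independent of scipy."""
    values = list(values)
    out = []
    for v in values:
        less = sum(1 for x in values if x < v)
        equal = sum(1 for x in values if x == v)
        out.append(1 + less + (equal - 1) / 2.0)
    return out


def brute_dunn_z(samples):
    """Dunn pairwise z from first principles on the pooled midranks."""
    labels = list(samples)
    pooled = [v for g in labels for v in samples[g]]
    ranks = brute_ranks(pooled)
    n = len(pooled)
    mean_rank, sizes, start = {}, {}, 0
    for g in labels:
        k = len(samples[g])
        mean_rank[g] = sum(ranks[start:start + k]) / k
        sizes[g] = k
        start += k
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c ** 3 - c for c in counts.values()) / (12.0 * (n - 1))
    base = n * (n + 1) / 12.0 - tie
    out = {}
    for a, b in itertools.combinations(labels, 2):
        out[(a, b)] = (mean_rank[a] - mean_rank[b]) / math.sqrt(base * (1 / sizes[a] + 1 / sizes[b]))
    return out


class TestWestermannCoords:
    def test_single_nonzero_score_hits_corner(self):
        p = ms.westermann_coords(rec(2.0, 0.0, 1e-12))
        assert p.expansion_frac == pytest.approx(1.0, abs=1e-9)
        assert p.inflation_frac == pytest.approx(0.0, abs=1e-9)

    def test_hand_normalisation(self):
        p = ms.westermann_coords(rec(1.5, 0.25, 0.25))
        assert p.as_tuple() == pytest.approx((0.5, 0.25, 0.25))

    def test_dominant_corner_follows_dominant_score(self):
        assert max(range(3), key=lambda i: ms.westermann_coords(rec(3.0, 0.1, 0.1)).as_tuple()[i]) == 0
        assert max(range(3), key=lambda i: ms.westermann_coords(rec(1.1, 0.9, 0.1)).as_tuple()[i]) == 1
        assert max(range(3), key=lambda i: ms.westermann_coords(rec(1.1, 0.1, 2.0)).as_tuple()[i]) == 2

    def test_simplex_closure_for_generated_records(self):
        for r in ms.generate_coiling_table(n_per_group=20, seed=3):
            p = ms.westermann_coords(r)
            assert sum(p.as_tuple()) == pytest.approx(1.0, abs=1e-12)
            assert all(f >= 0 for f in p.as_tuple())

    def test_scaling_config_changes_weights(self):
        r = rec(1.5, 0.25, 0.25)
        p = ms.westermann_coords(r, scaling=(2.0, 1.0, 1.0))
        assert p.expansion_frac == pytest.approx(1.0 / 1.5)

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            rec(0.9, 0.2, 0.5)
        with pytest.raises(ValueError):
            rec(1.5, 1.2, 0.5)
        with pytest.raises(ValueError):
            rec(1.5, 0.2, 0.0)
        assert rec(2.0, 0.2, 0.3).compression == pytest.approx(0.7)

    def test_degenerate_point_rejected(self):
        with pytest.raises(ValueError):
            ms.westermann_coords(rec(1.0, 0.0, 0.5), scaling=(1.0, 1.0, 0.0))

    def test_ternary_xy_corners(self):
        assert ms.ternary_xy(TernaryPoint(1, 0, 0)) == pytest.approx((0.0, 0.0))
        assert ms.ternary_xy(TernaryPoint(0, 0, 1)) == pytest.approx((0.5, math.sqrt(3) / 2))


class TestDunnTest:
    def test_identical_groups_all_null(self):
        samples = {g: np.array([1.0, 2.0, 3.0]) for g in "abc"}
        for c in ms.dunn_test(samples, adjustment=None):
            assert c.statistic == pytest.approx(0.0, abs=1e-12)
            assert c.p_value == pytest.approx(1.0)

    def test_toy_data_hand_ranks(self):
        samples = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        out = {(c.group_a, c.group_b): c.statistic for c in ms.dunn_test(samples)}
        assert out[("a", "b")] == pytest.approx(-3 / math.sqrt(5), rel=1e-12)
        assert out[("a", "c")] == pytest.approx(-6 / math.sqrt(5), rel=1e-12)
        assert out[("b", "c")] == pytest.approx(-3 / math.sqrt(5), rel=1e-12)

    def test_monotone_transform_invariance(self, rng):
        samples = {g: rng.normal(loc=i, size=8) for i, g in enumerate("abc")}
        before = [c.statistic for c in ms.dunn_test(samples)]
        after = [c.statistic for c in ms.dunn_test({g: np.exp(v) for g, v in samples.items()})]
        np.testing.assert_allclose(after, before, rtol=1e-12)

    def test_agrees_with_brute_force_on_small_datasets(self, rng):
        for _ in range(20):
            sizes = rng.integers(2, 5, size=3)
            while sizes.sum() > 12:
                sizes = rng.integers(2, 5, size=3)
            samples = {g: list(rng.integers(0, 6, size=n).astype(float))
                       for g, n in zip("abc", sizes)}
            if len({v for vals in samples.values() for v in vals}) == 1:
                continue
            expected = brute_dunn_z(samples)
            got = {(c.group_a, c.group_b): c.statistic for c in ms.dunn_test(samples)}
            for pair, z in expected.items():
                assert got[pair] == pytest.approx(z, rel=1e-12, abs=1e-12)

    def test_holm_adjustment_never_decreases_p(self, rng):
        samples = {g: rng.normal(loc=0.4 * i, size=15) for i, g in enumerate("abcd")}
        for c in ms.dunn_test(samples, adjustment="holm"):
            assert c.adjusted_p >= c.p_value

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            ms.dunn_test({"a": [1, 2], "b": [3, 4]})


class TestRankSumTest:
    def test_extreme_separation_exact_p(self):
        c = ms.rank_sum_test([1, 2, 3], [10, 11, 12])
        assert c.statistic == 6.0  # minimal possible rank sum
        assert c.p_value == pytest.approx(0.1)

    def test_swap_symmetry(self):
        a, b = [1.0, 3.0, 5.0, 9.0], [2.0, 4.0, 8.0]
        assert ms.rank_sum_test(a, b).p_value == pytest.approx(ms.rank_sum_test(b, a).p_value)

    def test_identical_samples_null(self):
        c = ms.rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.p_value == pytest.approx(1.0)

    def test_all_tied_degenerate(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="conchrock.morphospace"):
            c = ms.rank_sum_test([5.0, 5.0], [5.0, 5.0])
        assert c.p_value == 1.0

    def test_large_sample_matches_scipy_normal_approximation(self, rng):
        a = rng.normal(0.0, 1.0, 40)
        b = rng.normal(0.6, 1.0, 35)
        c = ms.rank_sum_test(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        assert c.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_enumeration_matches_scipy_exact_without_ties(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=5)
        c = ms.rank_sum_test(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert c.p_value == pytest.approx(ref.pvalue, rel=1e-12)


class TestProxySummaryAndGenerator:
    def test_identical_values_one_bin_zero_iqr(self):
        records = [rec(2.0, 0.2, 0.4, taxon=f"t{i}") for i in range(5)]
        s = ms.proxy_summary(records, variables=("W",))["W"]["g"]
        assert (s["counts"] > 0).sum() == 1
        assert s["iqr"] == 0.0
        assert s["n"] == 5

    def test_shifted_medians_preserved(self):
        records = ms.generate_coiling_table(
            groups={"lo": (0.0, 0, 0), "hi": (0.8, 0, 0)}, n_per_group=60, seed=11)
        s = ms.proxy_summary(records, variables=("W",))["W"]
        assert s["hi"]["median"] - s["lo"]["median"] > 0.4

    def test_missing_group_warned_and_skipped(self, caplog):
        import logging

        records = [rec(2.0, 0.2, 0.4)]
        with caplog.at_level(logging.WARNING, logger="conchrock.morphospace"):
            s = ms.proxy_summary(records, variables=("W",), groups=["g", "ghost"])
        assert "ghost" not in s["W"]
        assert any("ghost" in r.message for r in caplog.records)

    def test_generator_shift_detectable_with_stated_power(self):
        """At the generator's default W shift and group size, the rank-sum test
        rejects at alpha = 0.05 in > 80% of replicates."""
        rejections = 0
        n_rep = 100
        for i in range(n_rep):
            records = ms.generate_coiling_table(seed=1000 + i)
            by_group = {}
            for r in records:
                by_group.setdefault(r.group, []).append(r.whorl_expansion)
            (va, vb) = by_group.values()
            if ms.rank_sum_test(va, vb).p_value < ms.ALPHA:
                rejections += 1
        assert rejections / n_rep > 0.8

    def test_compare_groups_dispatches_by_group_count(self):
        three = ms.generate_coiling_table(
            groups={"a": (0, 0, 0), "b": (0.4, 0, 0), "c": (0.8, 0, 0)},
            n_per_group=20, seed=5)
        out = ms.compare_groups(three, variables=("W",))
        assert len(out) == 3  # pairwise Dunn
        two = ms.generate_coiling_table(n_per_group=20, seed=6)
        out2 = ms.compare_groups(two, variables=("W",))
        assert len(out2) == 1

    def test_csv_round_trip(self, tmp_path):
        records = ms.generate_coiling_table(n_per_group=5, seed=2)
        path = tmp_path / "coiling.csv"
        ms.write_coiling_table(records, path)
        back = ms.read_coiling_table(path)
        assert len(back) == len(records)
        assert back[0].taxon == records[0].taxon

    def test_ternary_plot_writes_file(self, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        records = ms.generate_coiling_table(n_per_group=10, seed=4)
        out = tmp_path / "morphospace.svg"
        ms.plot_ternary(records, path=out)
        assert out.exists() and out.stat().st_size > 0
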