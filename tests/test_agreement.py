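import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lcmproteo import (
    SpectralCountTable,
    abundance_classes,
    bland_altman_table,
    overlap_table,
    paired_difference_stats,
    reproducibility_limit,
    run_correlation,
    set_enrichment,
)


def _series(vals, prefix="P"):
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))])


class TestPairedDifferenceStats:
    def test_identical_runs(self):
        r = _series([3.0, 5.0, 9.0, 2.0])
        rep = paired_difference_stats(r, r)
        assert rep.mean_diff == 0.0 and rep.sd_diff == 0.0
        assert rep.n_common == 4 and rep.n_discordant == 0

    def test_hand_computed_example(self):
        base = _series([10.0, 10, 10, 10, 10])
        diffs = [1.0, -1.0, 2.0, -2.0, 10.0]
        rep = paired_difference_stats(base + diffs, base)
        assert rep.mean_diff == pytest.approx(2.0)
        assert rep.sd_diff == pytest.approx(np.sqrt(22.5), rel=1e-9)  # ~4.743

    def test_constant_shift(self):
        r1 = _series([4.0, 7.0, 12.0, 30.0])
        rep = paired_difference_stats(r1 + 3.0, r1)
        assert rep.mean_diff == pytest.approx(3.0)
        assert rep.sd_diff == 0.0

    def test_zero_treated_as_missing_and_discordance_counted(self):
        r1 = _series([5.0, 8.0, 0.0, 4.0, 9.0])
        r2 = _series([6.0, 7.0, 3.0, 0.0, 8.0])
        rep = paired_difference_stats(r1, r2)
        assert rep.n_common == 3
        assert rep.n_discordant == 2

    def test_too_few_common_proteins(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            paired_difference_stats(_series([1.0, 2.0]), _series([1.0, 2.0]))


class TestReproducibilityLimit:
    def test_all_zero_diffs(self):
        limit, pct = reproducibility_limit([0.0, 0.0, 0.0, 0.0])
        assert limit == 0.0 and pct == 100.0

    def test_hand_example(self):
        limit, pct = reproducibility_limit([1.0, -1.0, 2.0, -2.0, 10.0])
        assert limit == pytest.approx(1.96 * np.sqrt(22.5), rel=1e-9)  # ~9.30
        assert pct == 100.0

    def test_standard_normal_large_n(self):
        d = np.random.default_rng(0).normal(size=100_000)
        limit, pct = reproducibility_limit(d)
        assert limit == pytest.approx(1.96, abs=0.02)
        assert pct == pytest.approx(95.0, abs=0.5)

    def test_multiplier_k(self):
        d = [1.0, -1.0, 2.0, -2.0, 10.0]
        limit3, _ = reproducibility_limit(d, k=3.0)
        assert limit3 == pytest.approx(3.0 * np.sqrt(22.5), rel=1e-9)


class TestRunCorrelation:
    def test_affine_relation(self):
        r1 = _series([1.0, 2.0, 5.0, 9.0])
        assert run_correlation(2 * r1 + 3, r1) == pytest.approx(1.0)
        assert run_correlation(-r1, r1) == pytest.approx(-1.0)

    def test_hand_computed_pairs(self):
        # cov = 1.0, var_x = var_y = 5/3  ->  r = 0.6
        r1 = _series([1.0, 2.0, 3.0, 4.0])
        r2 = _series([2.0, 1.0, 4.0, 3.0])
        assert run_correlation(r1, r2) == pytest.approx(0.6)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            run_correlation(_series([1.0, 1.0, 1.0]), _series([1.0, 2.0, 3.0]))


class TestAbundanceClasses:
    @pytest.mark.parametrize(
        "counts,threshold,rule,expected",
        [
            ([[6, 4]], 5, "max", "high"),
            ([[4, 4]], 5, "max", "low"),
            ([[5, 0]], 5, "max", "high"),   # boundary inclusive
            ([[6, 2]], 5, "mean", "low"),
            ([[1, 1]], 0, "max", "high"),
        ],
    )
    def test_classification(self, counts, threshold, rule, expected):
        tab = SpectralCountTable(np.array(counts), ["P1"], ["r1", "r2"])
        assert abundance_classes(tab, threshold, rule).iloc[0] == expected

    def test_negative_threshold_rejected(self):
        tab = SpectralCountTable(np.array([[1, 1]]), ["P1"], ["r1", "r2"])
        with pytest.raises(ValueError):
            abundance_classes(tab, threshold=-1)


class TestOverlapTable:
    def test_small_example(self):
        np.testing.assert_array_equal(
            overlap_table({"a", "b", "c"}, {"b", "c", "d"}), [[1, 2], [1, 2]]
        )

    def test_identical_sets(self):
        tab = overlap_table({"a", "b"}, {"a", "b"})
        assert tab[0, 0] == 0 and tab[1, 0] == 0

    def test_printed_preservation_counts(self):
        # 244 OCT-unique, 76 FFPE-unique, 374 shared
        oct_set = {f"o{i}" for i in range(244)} | {f"s{i}" for i in range(374)}
        ffpe_set = {f"f{i}" for i in range(76)} | {f"s{i}" for i in range(374)}
        np.testing.assert_array_equal(
            overlap_table(oct_set, ffpe_set), [[244, 374], [76, 374]]
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.sets(st.integers(0, 50), min_size=1),
        st.sets(st.integers(0, 50), min_size=1),
    )
    def test_counts_sum_to_set_sizes(self, sa, sb):
        tab = overlap_table(sa, sb)
        assert tab[0, 0] + tab[0, 1] == len(sa)
        assert tab[1, 0] + tab[1, 1] == len(sb)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_table(set(), {"a"})


class TestSetEnrichment:
    def test_query_equals_annotation_equals_background(self):
        s = {"a", "b", "c"}
        fold, p = set_enrichment(s, s, s)
        assert fold == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_disjoint_query_has_unit_upper_tail(self):
        bg = {f"p{i}" for i in range(10)}
        fold, p = set_enrichment({"p0"}, {"p9"}, bg)
        assert fold == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_hypergeometric(self):
        bg = {f"p{i}" for i in range(20)}
        ann = {f"p{i}" for i in range(5)}
        query = {"p0", "p1", "p2", "p3", "p10"}  # overlap 4
        fold, p = set_enrichment(query, ann, bg)
        from math import comb
        expected = (comb(5, 4) * comb(15, 1) + comb(5, 5) * comb(15, 0)) / comb(20, 5)
        assert p == pytest.approx(expected, rel=1e-12)  # 76/15504
        assert fold == pytest.approx(4 / (5 * 5 / 20))

    def test_subset_validation(self):
        with pytest.raises(ValueError):
            set_enrichment({"x"}, {"a"}, {"a", "b"})
        with pytest.raises(ValueError):
            set_enrichment(set(), set(), set())


def test_bland_altman_table_flags():
    rng = np.random.default_rng(4)
    base = _series(rng.normal(20, 3, 200))
    other = base + rng.normal(0, 1, 200)
    tab = bland_altman_table(base, other)
    d = tab["difference"]
    inside2 = (d - d.mean()).abs() <= 2 * d.std(ddof=1)
    assert (tab["within_2sd"] == inside2).all()
    assert tab["within_3sd"].mean() >= tab["within_2sd"].mean()
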