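import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table, table_from_clones
from tilscape import repertoire as rep
from tilscape.io_formats import ClonotypeRecord, ValidationError


class TestShannonDiversity:
    def test_uniform_four_clones(self):
        t = make_table("s", [5, 5, 5, 5])
        assert rep.shannon_diversity(t).shannon_di == pytest.approx(math.log(4))

    def test_single_clone_zero(self):
        t = make_table("s", [10])
        assert rep.shannon_diversity(t).shannon_di == 0.0

    def test_counts_1234(self):
        t = make_table("s", [1, 2, 3, 4])
        assert rep.shannon_diversity(t).shannon_di == pytest.approx(1.279854, abs=1e-6)

    def test_empty_table_errors(self):
        t = make_table("s", [])
        with pytest.raises(ValidationError):
            rep.shannon_diversity(t)

    def test_bounded_by_log_richness(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 50, size=rng.integers(2, 30))
            t = make_table("s", counts.tolist())
            d = rep.shannon_diversity(t)
            assert 0.0 <= d.shannon_di <= math.log(d.richness) + 1e-12


class TestFrequencySpectrum:
    def test_single_bin(self):
        t = make_table("s", [10, 6, 3, 1])
        assert rep.frequency_spectrum(t, []).tolist() == [1.0]

    def test_two_equal_clones(self):
        t = make_table("s", [1, 1])
        out = rep.frequency_spectrum(t, [0.1])
        assert out.tolist() == [0.0, 1.0]

    def test_half_and_half(self):
        # 5 clones at 1%, 5 clones at 19%
        t = make_table("s", [1] * 5 + [19] * 5)
        out = rep.frequency_spectrum(t, [0.1])
        assert out.tolist() == [0.5, 0.5]

    def test_nonincreasing_edges_rejected(self):
        t = make_table("s", [1, 1])
        with pytest.raises(ValueError):
            rep.frequency_spectrum(t, [0.5, 0.1])


class TestTopN:
    def test_selects_highest_counts(self):
        t = make_table("s", [5, 3, 2])
        assert [r.count for r in rep.top_n(t, 2)] == [5, 3]

    def test_truncates_to_richness(self):
        t = make_table("s", [5, 3, 2])
        assert len(rep.top_n(t, 10)) == 3

    def test_ties_broken_lexicographically(self):
        t = table_from_clones("s", {"ZZZ": 5, "BBB": 3, "AAA": 3})
        top2 = rep.top_n(t, 2)
        assert [r.cdr3_nt for r in top2] == ["ZZZ", "AAA"]


class TestCumulativeTopFrequency:
    def test_partial_sums(self):
        t = make_table("s", [4, 3, 2, 1])
        assert rep.cumulative_top_frequency(t, 3).tolist() == pytest.approx([0.4, 0.7, 0.9])

    def test_uniform(self):
        t = make_table("s", [1, 1, 1, 1])
        assert rep.cumulative_top_frequency(t, 4).tolist() == pytest.approx([0.25, 0.5, 0.75, 1.0])

    @given(st.lists(st.integers(1, 100), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_nondecreasing_and_bounded(self, counts):
        t = make_table("s", counts)
        cum = rep.cumulative_top_frequency(t, 10)
        assert np.all(np.diff(cum) >= -1e-12)
        assert cum[-1] <= 1.0 + 1e-9


class TestOverlaps:
    def test_identical_tables_full_overlap(self):
        a = table_from_clones("a", {"x": 5, "y": 3})
        b = table_from_clones("b", {"x": 5, "y": 3})
        m = rep.pairwise_topn_overlap([a, b], 2)
        assert m.values.loc["a", "b"] == 100.0
        assert m.values.loc["a", "a"] == 100.0

    def test_disjoint_zero(self):
        a = table_from_clones("a", {"x": 5})
        b = table_from_clones("b", {"y": 5})
        assert rep.pairwise_topn_overlap([a, b], 1).values.loc["a", "b"] == 0.0

    def test_two_of_three_shared(self):
        a = table_from_clones("a", {"a": 5, "b": 4, "c": 3})
        b = table_from_clones("b", {"b": 5, "c": 4, "d": 3})
        m = rep.pairwise_topn_overlap([a, b], 3)
        assert m.values.loc["a", "b"] == pytest.approx(200 / 3)

    def test_topn_vs_full_half(self):
        a = table_from_clones("a", {"x": 5, "y": 4})
        b = table_from_clones("b", {"x": 1, "z": 9})
        m = rep.topn_vs_full_overlap([a, b], 2)
        assert m.values.loc["a", "b"] == 50.0

    def test_topn_vs_full_superset(self):
        a = table_from_clones("a", {"x": 5, "y": 4})
        b = table_from_clones("b", {"x": 1, "y": 1, "z": 9})
        m = rep.topn_vs_full_overlap([a, b], 2)
        assert m.values.loc["a", "b"] == 100.0

    def test_topn_vs_full_three_quarters(self):
        a = table_from_clones("a", {"p": 9, "q": 8, "r": 7, "s": 6})
        b = table_from_clones("b", {"p": 1, "q": 1, "r": 1, "t": 5})
        m = rep.topn_vs_full_overlap([a, b], 4)
        assert m.values.loc["a", "b"] == 75.0

    def test_empty_table_rejected(self):
        a = table_from_clones("a", {"x": 5})
        b = make_table("b", [])
        with pytest.raises(ValidationError):
            rep.pairwise_topn_overlap([a, b], 1)


class TestPooledBloodStats:
    def test_enumerated_example(self):
        t1 = table_from_clones("t1", {"a": 5, "b": 3})
        t2 = table_from_clones("t2", {"a": 4, "b": 2})
        blood = table_from_clones("blood", {"a": 6, "b": 2, "c": 2})
        out = rep.pooled_topn_blood_stats([t1, t2], blood, 2)
        assert out["pooled_unique"] == 2
        assert out["detected"] == 2
        assert out["detected_pct"] == 100.0
        assert out["share_of_blood_clone_count_pct"] == pytest.approx(200 / 3)
        assert out["share_of_blood_frequency_mass_pct"] == pytest.approx(80.0)

    def test_disjoint_blood(self):
        t1 = table_from_clones("t1", {"a": 5})
        blood = table_from_clones("blood", {"z": 5})
        out = rep.pooled_topn_blood_stats([t1], blood, 1)
        assert out["detected"] == 0
        assert out["detected_pct"] == 0.0
        assert out["share_of_blood_frequency_mass_pct"] == 0.0


class TestCommonClones:
    def test_only_shared_clone_returned(self):
        tables = [table_from_clones(s, {"x": 3, f"p{s}": 2}) for s in "abc"]
        df = rep.common_clones(tables)
        assert len(df) == 1
        assert df["clonotype"][0].startswith("x")

    def test_no_shared_clones(self):
        a = table_from_clones("a", {"x": 1})
        b = table_from_clones("b", {"y": 1})
        assert rep.common_clones([a, b]).empty

    def test_ranked_by_mean_frequency(self):
        a = table_from_clones("a", {"x": 8, "y": 1, "z": 1})
        b = table_from_clones("b", {"x": 6, "y": 2, "z": 2})
        df = rep.common_clones([a, b])
        assert df["clonotype"].tolist()[0].startswith("x")
        assert df["mean_frequency"].is_monotonic_decreasing


class TestGroupComparisons:
    def test_kruskal_all_equal(self):
        a = table_from_clones("a", {"x": 1, "p": 1})
        import pandas as pd
        from tilscape.repertoire import OverlapMatrix
        vals = pd.DataFrame(100.0, index=list("abc"), columns=list("abc"))
        h, p = rep.overlap_difference_test(OverlapMatrix(vals, "topn_topn"))
        assert (h, p) == (0.0, 1.0)

    def test_kruskal_hand_ranked_groups(self):
        import pandas as pd
        from tilscape.repertoire import OverlapMatrix
        # off-diagonal groups [1,2], [4,5], [7,8]: ranks 1..6, no ties
        vals = pd.DataFrame(
            [[0, 1, 2], [4, 0, 5], [7, 8, 0]], index=list("abc"),
            columns=list("abc"), dtype=float)
        h, p = rep.overlap_difference_test(OverlapMatrix(vals, "topn_topn"))
        rank_sums = [1 + 2, 3 + 4, 5 + 6]
        h_manual = 12 / (6 * 7) * sum(s * s / 2 for s in rank_sums) - 3 * 7
        assert h == pytest.approx(h_manual)
        assert 0 < p <= 1

    def test_kruskal_asymptotic_matches_permutation_null(self, rng):
        import pandas as pd
        from scipy import stats as sps
        from tilscape.repertoire import OverlapMatrix
        ids = list("abcdefgh")
        vals = pd.DataFrame(rng.uniform(10, 60, size=(8, 8)),
                            index=ids, columns=ids)
        np.fill_diagonal(vals.to_numpy(), 100.0)
        m = OverlapMatrix(vals, "topn_topn")
        h_obs, p_asym = rep.overlap_difference_test(m)
        pooled = np.concatenate([m.off_diagonal(s) for s in ids])
        sizes = [7] * 8
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            groups = np.split(perm, np.cumsum(sizes)[:-1])
            h, _ = sps.kruskal(*groups)
            count += h >= h_obs - 1e-12
        assert abs(count / n_perm - p_asym) < 0.02

    def test_wilcoxon_identical_groups(self):
        w, p = rep.diversity_group_test([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert p == 1.0

    def test_wilcoxon_exact_shift(self):
        w, p = rep.diversity_group_test([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert p == pytest.approx(0.1)

    def test_wilcoxon_scale_invariance(self):
        x = [1.0, 2.5, 3.5, 7.0, 8.0, 9.5]
        labels = ["a", "a", "b", "a", "b", "b"]
        w1, p1 = rep.diversity_group_test(x, labels)
        w2, p2 = rep.diversity_group_test([v * 13.7 for v in x], labels)
        assert (w1, p1) == (w2, p2)

    def test_wilcoxon_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rep.diversity_group_test([1, 2], ["a", "a"])


class TestDuplicateMerging:
    def test_duplicate_rows_merged_before_analysis(self):
        recs = [
            ClonotypeRecord("AAA", "K", "TRBV1", "TRBJ1", count=3),
            ClonotypeRecord("AAA", "K", "TRBV1", "TRBJ1", count=2),
            ClonotypeRecord("CCC", "P", "TRBV2", "TRBJ1", count=5),
        ]
        t = rep.ClonotypeTable.from_records("s", recs)
        merged = rep.ClonotypeTable.from_records("s", [
            ClonotypeRecord("AAA", "K", "TRBV1", "TRBJ1", count=5),
            ClonotypeRecord("CCC", "P", "TRBV2", "TRBJ1", count=5),
        ])
        assert t.richness == merged.richness == 2
        assert rep.shannon_diversity(t).shannon_di == pytest.approx(
            rep.shannon_diversity(merged).shannon_di)
        assert rep.cumulative_top_frequency(t, 2).tolist() == \
            rep.cumulative_top_frequency(merged, 2).tolist()
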