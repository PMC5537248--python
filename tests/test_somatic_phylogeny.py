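import itertools

import numpy as np
import pandas as pd
import pytest

from tilscape import somatic_phylogeny as sp
from tilscape.io_formats import AnalysisConfig, ValidationError, VariantCall
from tilscape.somatic_phylogeny import (
    MutationMatrix,
    _all_rooted_topologies,
    _canonical,
    _plain_newick,
    build_parsimony_tree,
    classify_mutations,
    filter_variants,
    fitch_length,
)


def variant(pos, effect="missense", germline=(30, 0), chrom="chr1", samples=None):
    return VariantCall(chrom, pos, "A", "T", f"GENE{pos}", effect,
                       samples=samples or {"s1": (30, 10)}, germline=germline)


class TestFilterVariants:
    def test_clean_missense_retained(self):
        res = filter_variants([variant(1000)])
        assert len(res.retained) == 1 and not res.rejected

    def test_low_germline_coverage_rejected(self):
        res = filter_variants([variant(1000, germline=(9, 0))])
        assert not res.retained
        assert res.rejected[0][1] == ["germline_coverage"]

    def test_germline_nonref_reads_rejected(self):
        res = filter_variants([variant(1000, germline=(30, 2))])
        assert res.rejected[0][1] == ["germline_nonref"]

    def test_synonymous_rejected(self):
        res = filter_variants([variant(1000, effect="synonymous")])
        assert res.rejected[0][1] == ["effect"]

    def test_clustered_pair_both_rejected(self):
        res = filter_variants([variant(1000), variant(1080)])
        assert not res.retained
        assert all(r == ["cluster"] for _, r in res.rejected)

    def test_isolated_pair_retained(self):
        res = filter_variants([variant(1000), variant(1101)])
        assert len(res.retained) == 2

    def test_cluster_ignores_other_contigs(self):
        res = filter_variants([variant(1000), variant(1050, chrom="chr2")])
        assert len(res.retained) == 2

    def test_rejected_variant_does_not_trigger_cluster(self):
        # the synonymous neighbor is gone before the window rule applies
        res = filter_variants([variant(1000), variant(1050, effect="synonymous")])
        assert len(res.retained) == 1

    def test_order_independent(self, rng):
        calls = [variant(int(p), effect=e, germline=(int(d), int(a)))
                 for p, e, d, a in zip(
                     rng.choice(100000, 30, replace=False),
                     rng.choice(["missense", "synonymous", "stopgain"], 30),
                     rng.integers(5, 40, 30), rng.integers(0, 3, 30))]
        kept1 = {c.mutation_id for c in filter_variants(calls).retained}
        shuffled = list(calls)
        rng.shuffle(shuffled)
        kept2 = {c.mutation_id for c in filter_variants(shuffled).retained}
        assert kept1 == kept2

    def test_missing_germline_errors(self):
        v = VariantCall("chr1", 5, "A", "T", "G", "missense", samples={"s1": (10, 5)})
        with pytest.raises(ValidationError, match="germline"):
            filter_variants([v])


class TestClassifyMutations:
    @staticmethod
    def matrix(patterns, samples):
        df = pd.DataFrame(
            {f"M{i}": list(map(int, p)) for i, p in enumerate(patterns)},
        ).T
        df.columns = samples
        return MutationMatrix(df)

    def test_toy_patterns(self):
        m = self.matrix(["1111", "1100", "0010"], list("abcd"))
        masses = {"a": "m1", "b": "m1", "c": "m2", "d": "m2"}
        labels, counts = classify_mutations(m, masses)
        assert counts == {"shared": 1, "mass_specific": 1, "region_unique": 1}
        assert labels["M0"] == "shared"
        assert labels["M1"] == "mass_specific"
        assert labels["M2"] == "region_unique"

    def test_cross_mass_presence_is_shared(self):
        m = self.matrix(["1010"], list("abcd"))
        masses = {"a": "m1", "b": "m1", "c": "m2", "d": "m2"}
        _, counts = classify_mutations(m, masses)
        assert counts == {"shared": 1}

    def test_unassigned_sample_errors(self):
        m = self.matrix(["11"], list("ab"))
        with pytest.raises(ValidationError):
            classify_mutations(m, {"a": "m1"})


class TestFitchLength:
    def test_identical_leaves_root_edge_only(self):
        m = TestClassifyMutations.matrix(["111"], list("abc"))
        assert fitch_length((("a", "b"), "c"), m) == 1  # one gain on the root edge

    def test_two_leaves_k_differences(self):
        m = TestClassifyMutations.matrix(["10", "10", "01"], list("ab"))
        assert fitch_length(("a", "b"), m) == 3

    def test_four_leaf_manual(self):
        # trunk 11: in all; char 1100 and 0011: one change each on ((a,b),(c,d))
        m = TestClassifyMutations.matrix(["1111", "1100", "0011"], list("abcd"))
        assert fitch_length((("a", "b"), ("c", "d")), m) == 3
        # the incompatible grouping pays one extra change for each clade character
        assert fitch_length((("a", "c"), ("b", "d")), m) == 5

    def test_leaf_mismatch_errors(self):
        m = TestClassifyMutations.matrix(["11"], list("ab"))
        with pytest.raises(ValidationError):
            fitch_length(("a", "x"), m)

    def test_matches_exhaustive_state_assignment(self, rng):
        """Fitch equals brute-force minimization over internal node states."""
        for _ in range(50):
            n_leaves = int(rng.integers(3, 5))
            leaves = [f"s{i}" for i in range(n_leaves)]
            data = rng.integers(0, 2, size=(6, n_leaves))
            while (data.sum(axis=1) == 0).any():
                data = rng.integers(0, 2, size=(6, n_leaves))
            m = MutationMatrix(pd.DataFrame(data, columns=leaves,
                                            index=[f"M{i}" for i in range(6)]))
            tops = list(_all_rooted_topologies(leaves))
            top = tops[int(rng.integers(0, len(tops)))]
            assert fitch_length(top, m) == brute_force_length(top, m)


def brute_force_length(top, matrix):
    """Minimum changes by enumerating all internal-node state assignments."""

    def internal_nodes(node):
        if isinstance(node, str):
            return []
        return [node] + internal_nodes(node[0]) + internal_nodes(node[1])

    internals = internal_nodes(top)
    total = 0
    for mut in matrix.mutations:
        leaf_state = {s: int(matrix.presence.at[mut, s]) for s in matrix.samples}
        best = None
        for assignment in itertools.product((0, 1), repeat=len(internals)):
            state = dict(zip(map(id, internals), assignment))

            def node_state(node):
                return leaf_state[node] if isinstance(node, str) else state[id(node)]

            changes = int(node_state(top) != 0)  # germline root is absent
            stack = [top]
            while stack:
                node = stack.pop()
                if isinstance(node, str):
                    continue
                for child in node:
                    changes += int(node_state(child) != node_state(node))
                    stack.append(child)
            best = changes if best is None else min(best, changes)
        total += best
    return total


class TestBuildParsimonyTree:
    def test_single_sample_one_edge(self):
        m = TestClassifyMutations.matrix(["1", "1", "1"], ["a"])
        tree = build_parsimony_tree(m)
        assert tree.score == 3
        assert tree.newick() == "(a:3)germline;"

    def test_perfect_phylogeny_recovered(self):
        m = TestClassifyMutations.matrix(
            ["1111", "1100", "0011", "1000", "0100", "0010", "0001"], list("abcd"))
        tree = build_parsimony_tree(m)
        assert tree.score == 7
        assert _plain_newick(tree.topology) == "((a,b),(c,d))"
        lengths = tree.branch_lengths
        assert lengths["((a,b),(c,d))"] == 1  # trunk
        assert lengths["(a,b)"] == 1 and lengths["(c,d)"] == 1
        assert all(lengths[leaf] == 1 for leaf in "abcd")

    def test_homoplasy_costs_extra_changes(self):
        # 1100 and 0110 cannot both be single-origin on one tree
        m = TestClassifyMutations.matrix(["1100", "0110"], list("abcd"))
        tree = build_parsimony_tree(m)
        oracle = min(fitch_length(t, m) for t in _all_rooted_topologies(list("abcd")))
        assert tree.score == oracle == 3  # one extra change beyond 2 mutations

    def test_score_matches_exhaustive_minimum(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 6))
            leaves = [f"s{i}" for i in range(n)]
            data = rng.integers(0, 2, size=(8, n))
            data[data.sum(axis=1) == 0, 0] = 1
            m = MutationMatrix(pd.DataFrame(data, columns=leaves,
                                            index=[f"M{i}" for i in range(8)]))
            tree = build_parsimony_tree(m)
            oracle = min(fitch_length(t, m) for t in _all_rooted_topologies(leaves))
            assert tree.score == oracle
            assert sum(tree.branch_lengths.values()) == tree.score

    def test_duplicate_sample_zero_length_cherry(self):
        m = TestClassifyMutations.matrix(
            ["1111", "1100", "0011", "1000"], list("abcd"))
        base = build_parsimony_tree(m)
        dup = m.presence.copy()
        dup["a2"] = dup["a"]
        tree = build_parsimony_tree(MutationMatrix(dup))
        assert tree.score == base.score
        assert tree.branch_lengths["(a,a2)" if "(a,a2)" in tree.branch_lengths
                                   else "(a2,a)"] >= 0
        # the duplicated leaves sit together with zero-length terminal edges
        assert "(a,a2)" in _plain_newick(tree.topology) or \
               "(a2,a)" in _plain_newick(tree.topology)
        assert tree.branch_lengths["a"] == 0 and tree.branch_lengths["a2"] == 0

    def test_too_many_samples_errors(self):
        df = pd.DataFrame(np.ones((1, 13), dtype=int),
                          columns=[f"s{i}" for i in range(13)], index=["M0"])
        with pytest.raises(ValidationError, match="heuristic"):
            build_parsimony_tree(MutationMatrix(df))

    def test_zero_mutation_sample_dropped_separately(self):
        df = pd.DataFrame({"a": [1, 1], "b": [1, 0], "c": [0, 0]},
                          index=["M0", "M1"])
        m = MutationMatrix(df)
        kept, dropped = m.drop_empty_samples()
        assert dropped == ["c"]
        assert kept.samples == ["a", "b"]


class TestDiversityMutationCorrelation:
    def test_monotone(self):
        rho, _ = sp.diversity_mutation_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_antimonotone(self):
        rho, _ = sp.diversity_mutation_correlation([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_errors(self):
        with pytest.raises(ValidationError):
            sp.diversity_mutation_correlation([1, 1, 1, 1], [1, 2, 3, 4])
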