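"""Somatic-mutation filtering, classification, and parsimony phylogeny.

Filtered nonsynonymous mutations across multi-region samples form a binary
presence/absence matrix.  Sample relationships are inferred by maximum
parsimony over rooted topologies with an implicit germline outgroup whose
state is all-absent; branch lengths count the mutations assigned to each
edge under a most-parsimonious (Fitch) reconstruction.  The exact search
uses stepwise leaf addition with branch-and-bound, which is practical for
the 2-12 sample regime of multi-region studies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AnalysisConfig, ValidationError, VariantCall

__all__ = [
    "PROTEIN_ALTERING_EFFECTS",
    "FilterResult",
    "filter_variants",
    "MutationMatrix",
    "classify_mutations",
    "PhyloTree",
    "fitch_length",
    "build_parsimony_tree",
    "diversity_mutation_correlation",
]

#: Effect annotations accepted as protein-altering (case/punctuation-insensitive).
PROTEIN_ALTERING_EFFECTS = frozenset(
    {
        "missense", "nonsynonymous", "nonsynonymous_snv",
        "nonsense", "stopgain", "stopgain_snv", "stoploss", "stoploss_snv",
        "frameshift", "frameshift_insertion", "frameshift_deletion",
        "nonframeshift_insertion", "nonframeshift_deletion",
        "splice", "splicing", "splice_site",
    }
)


def is_protein_altering(effect: str) -> bool:
    return effect.strip().lower().replace(" ", "_").replace("-", "_") in PROTEIN_ALTERING_EFFECTS


@dataclass
class FilterResult:
    retained: list[VariantCall]
    rejected: list[tuple[VariantCall, list[str]]]

    def reasons_for(self, call: VariantCall) -> list[str]:
        for c, reasons in self.rejected:
            if c is call or (c.chrom, c.pos, c.ref, c.alt) == (call.chrom, call.pos, call.ref, call.alt):
                return reasons
        return []


def filter_variants(calls: Sequence[VariantCall],
                    config: AnalysisConfig | None = None) -> FilterResult:
    """Apply the somatic-call filtering cascade.

    A call is retained when (1) the germline sample has at least
    ``germline_min_depth`` coverage, (2) the germline shows zero
    non-reference reads, (3) the effect annotation is protein-altering,
    and (4) no other call surviving rules 1-3 lies within
    ``cluster_window_bp`` on the same contig (clustered calls are treated
    as alignment artifacts and all members are rejected).

    The retained set is independent of input order.
    """
    config = config or AnalysisConfig()
    rejected: list[tuple[VariantCall, list[str]]] = []
    survivors: list[VariantCall] = []
    for call in calls:
        if call.germline is None:
            raise ValidationError(
                f"variant {call.chrom}:{call.pos} has no germline record"
            )
        reasons = []
        depth, alt_reads = call.germline
        if depth < config.germline_min_depth:
            reasons.append("germline_coverage")
        if alt_reads > 0:
            reasons.append("germline_nonref")
        if not is_protein_altering(call.effect):
            reasons.append("effect")
        if reasons:
            rejected.append((call, reasons))
        else:
            survivors.append(call)

    # cluster rule over the survivors, per contig
    clustered: set[int] = set()
    by_contig: dict[str, list[int]] = {}
    for idx, call in enumerate(survivors):
        by_contig.setdefault(call.chrom, []).append(idx)
    for idxs in by_contig.values():
        idxs = sorted(idxs, key=lambda i: survivors[i].pos)
        for a, b in zip(idxs, idxs[1:]):
            if survivors[b].pos - survivors[a].pos <= config.cluster_window_bp:
                clustered.add(a)
                clustered.add(b)

    retained = [c for i, c in enumerate(survivors) if i not in clustered]
    rejected.extend((survivors[i], ["cluster"]) for i in sorted(clustered))
    return FilterResult(retained=retained, rejected=rejected)


# ---------------------------------------------------------------------------
# mutation matrix and classification
# ---------------------------------------------------------------------------

@dataclass
class MutationMatrix:
    """Binary presence/absence of mutations (rows) across samples (columns)."""

    presence: pd.DataFrame
    classes: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.presence.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("mutation matrix entries must be 0 or 1")
        if (vals.sum(axis=1) == 0).any():
            absent = self.presence.index[vals.sum(axis=1) == 0][0]
            raise ValidationError(f"mutation {absent!r} is absent from every sample")

    @classmethod
    def from_variants(cls, calls: Sequence[VariantCall],
                      samples: Sequence[str] | None = None,
                      min_alt_reads: int = 1) -> "MutationMatrix":
        """Presence = at least ``min_alt_reads`` non-reference reads."""
        if samples is None:
            samples = sorted({s for c in calls for s in c.samples})
        rows = {}
        for c in calls:
            row = [int(c.samples.get(s, (0, 0))[1] >= min_alt_reads) for s in samples]
            if sum(row):
                rows[c.mutation_id] = row
        return cls(pd.DataFrame.from_dict(rows, orient="index", columns=list(samples)))

    @property
    def samples(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def mutations(self) -> list[str]:
        return list(self.presence.index)

    def drop_empty_samples(self) -> tuple["MutationMatrix", list[str]]:
        """Remove samples with no detected mutations (returned separately)."""
        empty = [s for s in self.samples if self.presence[s].sum() == 0]
        kept = self.presence.drop(columns=empty)
        return MutationMatrix(kept, self.classes), empty


def classify_mutations(matrix: MutationMatrix,
                       mass_of_sample: Mapping[str, str]) -> tuple[pd.Series, dict[str, int]]:
    """Label each mutation by its distribution across tumor masses.

    shared: present in at least one sample of every mass.
    mass_specific: present in >= 2 samples, all within one mass.
    region_unique: present in exactly one sample.
    partially_shared: present in > 1 but not all masses (only possible
    with three or more masses).
    """
    unassigned = [s for s in matrix.samples if s not in mass_of_sample]
    if unassigned:
        raise ValidationError(f"samples not assigned to a tumor mass: {unassigned}")
    masses = sorted(set(mass_of_sample[s] for s in matrix.samples))
    if len(masses) < 2:
        raise ValidationError("classification requires at least two tumor masses")
    labels = {}
    for mut in matrix.mutations:
        present = [s for s in matrix.samples if matrix.presence.at[mut, s] == 1]
        present_masses = {mass_of_sample[s] for s in present}
        if present_masses == set(masses):
            labels[mut] = "shared"
        elif len(present) == 1:
            labels[mut] = "region_unique"
        elif len(present_masses) == 1:
            labels[mut] = "mass_specific"
        else:
            labels[mut] = "partially_shared"
    series = pd.Series(labels, name="class")
    counts = series.value_counts().to_dict()
    matrix.classes = series
    return series, counts


# ---------------------------------------------------------------------------
# parsimony phylogeny
# ---------------------------------------------------------------------------

# A topology over sample leaves is a nested pair structure: either a sample
# name (str) or a 2-tuple of topologies.  The germline root attaches above
# the outermost structure.
Topology = object


def _topology_leaves(top) -> list[str]:
    if isinstance(top, str):
        return [top]
    return _topology_leaves(top[0]) + _topology_leaves(top[1])


def _canonical(top):
    """Order-normalized topology (children sorted by their Newick string)."""
    if isinstance(top, str):
        return top
    a, b = _canonical(top[0]), _canonical(top[1])
    return (a, b) if _plain_newick(a) <= _plain_newick(b) else (b, a)


def _plain_newick(top) -> str:
    if isinstance(top, str):
        return top
    return f"({_plain_newick(top[0])},{_plain_newick(top[1])})"


@dataclass
class PhyloTree:
    """Rooted sample tree with a germline (all-absent) root state.

    ``topology`` is the nested-tuple structure over sample leaves;
    ``branch_lengths`` maps each node's Newick string (leaf name or
    canonical group string) to the integer number of mutations assigned to
    the edge above it.  The root edge (germline to the base of the sample
    tree) is keyed by the full topology string.
    """

    topology: Topology
    branch_lengths: dict[str, int]
    score: int

    @property
    def leaves(self) -> list[str]:
        return _topology_leaves(self.topology)

    def newick(self) -> str:
        def fmt(top) -> str:
            key = _plain_newick(top)
            length = self.branch_lengths.get(key, 0)
            if isinstance(top, str):
                return f"{top}:{length}"
            return f"({fmt(top[0])},{fmt(top[1])}):{length}"

        return f"({fmt(self.topology)})germline;"


def _char_matrix(matrix: MutationMatrix) -> tuple[np.ndarray, list[str]]:
    samples = matrix.samples
    chars = matrix.presence.to_numpy(dtype=np.int8).T  # samples x mutations
    return chars, samples


def _fitch_sets(top, states: dict[str, np.ndarray]):
    """Bottom-up Fitch pass; returns (set-codes, changes).

    Set codes per character: 1 = {absent}, 2 = {present}, 3 = both.
    """
    if isinstance(top, str):
        return states[top], 0
    left, cl = _fitch_sets(top[0], states)
    right, cr = _fitch_sets(top[1], states)
    inter = left & right
    union = left | right
    result = np.where(inter != 0, inter, union)
    changes = cl + cr + int((inter == 0).sum())
    return result, changes


def fitch_length(topology: Topology, matrix: MutationMatrix) -> int:
    """Fitch small-parsimony length of a rooted topology with germline root.

    Counts state changes over all mutation characters, including changes on
    the root edge (the germline state is all-absent).
    """
    leaves = sorted(_topology_leaves(topology))
    if leaves != sorted(matrix.samples):
        raise ValidationError(
            f"topology leaves {leaves} do not match matrix samples {sorted(matrix.samples)}"
        )
    chars, samples = _char_matrix(matrix)
    states = {s: (chars[i] + 1).astype(np.int8) for i, s in enumerate(samples)}
    root_sets, changes = _fitch_sets(topology, states)
    # germline root is fixed at "absent" (code bit 1)
    changes += int((root_sets & 1 == 0).sum())
    return changes


def _all_rooted_topologies(leaves: Sequence[str]):
    """All rooted binary topologies over the leaves (for oracles/small n)."""
    leaves = list(leaves)
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]

    def insert_everywhere(top, leaf):
        yield (top, leaf)
        if not isinstance(top, str):
            for sub in insert_everywhere(top[0], leaf):
                yield (sub, top[1])
            for sub in insert_everywhere(top[1], leaf):
                yield (top[0], sub)

    def build(tops, remaining):
        if not remaining:
            yield from tops
            return
        leaf, rest2 = remaining[0], remaining[1:]
        new = []
        for t in tops:
            new.extend(insert_everywhere(t, leaf))
        yield from build(new, rest2)

    yield from build([first], rest)


def build_parsimony_tree(matrix: MutationMatrix, max_samples: int = 12) -> PhyloTree:
    """Exact maximum-parsimony tree with a germline outgroup root.

    Searches rooted topologies by stepwise leaf addition with
    branch-and-bound (adding a leaf can never decrease the Fitch length,
    so partial scores are valid lower bounds).  Among equally parsimonious
    topologies the one with the lexicographically smallest canonical
    Newick string is returned.  Branch lengths are the per-edge change
    counts of the deterministic Fitch downpass reconstruction rooted at
    the all-absent germline state.
    """
    samples = matrix.samples
    if len(samples) < 1:
        raise ValidationError("mutation matrix has no samples")
    if len(samples) > max_samples:
        raise ValidationError(
            f"{len(samples)} samples exceeds the exact-search limit of {max_samples}; "
            "a heuristic mode is not implemented"
        )
    chars, sample_order = _char_matrix(matrix)
    states = {s: (chars[i] + 1).astype(np.int8) for i, s in enumerate(sample_order)}
    n_mut = matrix.presence.shape[0]

    if len(samples) == 1:
        s = samples[0]
        m = int(matrix.presence[s].sum())
        return PhyloTree(topology=s, branch_lengths={s: m}, score=m)

    order = sorted(samples)

    def partial_length(top) -> int:
        root_sets, changes = _fitch_sets(top, states)
        return changes + int((root_sets & 1 == 0).sum())

    def insertions(top, leaf):
        yield (top, leaf)
        if not isinstance(top, str):
            for sub in insertions(top[0], leaf):
                yield (sub, top[1])
            for sub in insertions(top[1], leaf):
                yield (top[0], sub)

    # greedy pass for an initial upper bound
    greedy = order[0]
    for leaf in order[1:]:
        greedy = min(insertions(greedy, leaf), key=partial_length)
    best_score = partial_length(greedy)
    best_trees = [greedy]

    def search(top, remaining):
        nonlocal best_score, best_trees
        score = partial_length(top)
        if score > best_score:
            return
        if not remaining:
            if score < best_score:
                best_score = score
                best_trees = [top]
            elif not any(_canonical(top) == _canonical(t) for t in best_trees):
                best_trees.append(top)
            return
        leaf, rest = remaining[0], remaining[1:]
        for candidate in insertions(top, leaf):
            search(candidate, rest)

    search(order[0], order[1:])

    winner = min((_canonical(t) for t in best_trees), key=_plain_newick)
    lengths = _edge_changes(winner, states)
    assert sum(lengths.values()) == best_score, "reconstruction length != parsimony score"
    assert best_score >= n_mut, "parsimony score below one change per mutation"
    return PhyloTree(topology=winner, branch_lengths=lengths, score=best_score)


def _edge_changes(top, states: dict[str, np.ndarray]) -> dict[str, int]:
    """Per-edge change counts under the Fitch downpass reconstruction.

    The downpass assigns each node the parent state when the node's
    first-pass set allows it, otherwise the node's own (unique) state;
    with binary characters this yields one deterministic
    most-parsimonious reconstruction.
    """
    first_pass: dict[int, np.ndarray] = {}

    def up(node):
        if isinstance(node, str):
            first_pass[id(node)] = states[node]
            return states[node]
        left = up(node[0])
        right = up(node[1])
        inter = left & right
        union = left | right
        result = np.where(inter != 0, inter, union)
        first_pass[id(node)] = result
        return result

    root_sets = up(top)
    lengths: dict[str, int] = {}
    n_chars = next(iter(states.values())).shape[0]

    def down(node, parent_state: np.ndarray):
        sets = first_pass[id(node)]
        has_parent = (sets & parent_state) != 0
        # parent state kept when the first-pass set allows it; otherwise the
        # set is a singleton of the other state (binary characters)
        state = np.where(has_parent, parent_state, sets)
        lengths[_plain_newick(node)] = int((state != parent_state).sum())
        if not isinstance(node, str):
            down(node[0], state)
            down(node[1], state)

    germline_state = np.full(n_chars, 1, dtype=np.int8)  # {absent}
    down(top, germline_state)
    return lengths


# ---------------------------------------------------------------------------
# diversity vs mutation burden
# ---------------------------------------------------------------------------

def diversity_mutation_correlation(diversities: Sequence[float],
                                   mutation_counts: Sequence[float]) -> tuple[float, float]:
    """Spearman correlation between repertoire diversity and mutation burden.

    Exact permutation p-value for n <= 10, t-approximation otherwise.
    """
    from .pathway_enrichment import spearman_correlation

    return spearman_correlation(diversities, mutation_counts)
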