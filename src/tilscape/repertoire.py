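"""TCRB repertoire statistics for multi-region tumor samples.

Clonotypes are keyed by (CDR3 nucleotide sequence, V segment, J segment)
by default; amino-acid-level keying collapses clones that converge on the
same CDR3 protein sequence.  Diversity is the Shannon-Wiener index
H = -sum_i p_i ln p_i in nats over clonotype frequencies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ClonotypeRecord, ValidationError

__all__ = [
    "ClonotypeTable",
    "OverlapMatrix",
    "DiversityResult",
    "shannon_diversity",
    "frequency_spectrum",
    "top_n",
    "cumulative_top_frequency",
    "pairwise_topn_overlap",
    "topn_vs_full_overlap",
    "pooled_topn_blood_stats",
    "common_clones",
    "overlap_difference_test",
    "diversity_group_test",
    "DEFAULT_SPECTRUM_EDGES",
]

#: Default frequency-class boundaries; bins are (0,1e-5], (1e-5,1e-4], ..., (1e-2,1].
DEFAULT_SPECTRUM_EDGES: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2)

ClonotypeKey = tuple[str, ...]


def clonotype_key(record: ClonotypeRecord, level: str = "nt") -> ClonotypeKey:
    """Identity key of a clonotype: nt-level (default) or aa-level."""
    if level == "nt":
        return (record.cdr3_nt, record.v_segment, record.j_segment)
    if level == "aa":
        return (record.cdr3_aa, record.v_segment, record.j_segment)
    raise ValueError(f"unknown clone key level {level!r}")


@dataclass
class ClonotypeTable:
    """One sample's repertoire: unique clonotypes with counts and frequencies."""

    sample_id: str
    records: list[ClonotypeRecord]
    total_count: int
    key_level: str = "nt"
    _by_key: dict[ClonotypeKey, ClonotypeRecord] = field(repr=False, default_factory=dict)

    @classmethod
    def from_records(cls, sample_id: str, records: Iterable[ClonotypeRecord],
                     key_level: str = "nt") -> "ClonotypeTable":
        """Build a table, merging duplicate clonotype rows and renormalizing.

        Counts are authoritative: frequencies are recomputed as
        count / total_count.
        """
        merged: dict[ClonotypeKey, ClonotypeRecord] = {}
        for rec in records:
            k = clonotype_key(rec, key_level)
            if k in merged:
                prev = merged[k]
                merged[k] = ClonotypeRecord(
                    cdr3_nt=prev.cdr3_nt, cdr3_aa=prev.cdr3_aa,
                    v_segment=prev.v_segment, j_segment=prev.j_segment,
                    d_segment=prev.d_segment, count=prev.count + rec.count,
                    frequency=0.0,
                )
            else:
                merged[k] = rec
        total = sum(r.count for r in merged.values())
        final: dict[ClonotypeKey, ClonotypeRecord] = {}
        for k, rec in merged.items():
            freq = rec.count / total if total > 0 else 0.0
            final[k] = ClonotypeRecord(
                cdr3_nt=rec.cdr3_nt, cdr3_aa=rec.cdr3_aa,
                v_segment=rec.v_segment, j_segment=rec.j_segment,
                d_segment=rec.d_segment, count=rec.count, frequency=freq,
            )
        table = cls(sample_id=sample_id, records=list(final.values()),
                    total_count=total, key_level=key_level)
        table._by_key = final
        return table

    @property
    def richness(self) -> int:
        return len(self.records)

    def keys(self) -> set[ClonotypeKey]:
        return set(self._by_key)

    def frequency_of(self, key: ClonotypeKey) -> float:
        rec = self._by_key.get(key)
        return rec.frequency if rec is not None else 0.0

    def __contains__(self, key: ClonotypeKey) -> bool:
        return key in self._by_key

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class OverlapMatrix:
    """Pairwise repertoire overlap percentages.

    mode "topn_topn": symmetric overlap of the two samples' TOP-N sets.
    mode "topn_full": row sample's TOP-N found anywhere in the column
    sample's full repertoire (asymmetric).
    """

    values: pd.DataFrame
    mode: str

    def off_diagonal(self, sample: str) -> np.ndarray:
        row = self.values.loc[sample]
        return row[row.index != sample].to_numpy(dtype=float)


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    shannon_di: float
    richness: int


# ---------------------------------------------------------------------------
# diversity and frequency structure
# ---------------------------------------------------------------------------

def shannon_diversity(table: ClonotypeTable) -> DiversityResult:
    """Shannon-Wiener diversity H = -sum p ln p (nats) over clone frequencies."""
    if table.richness == 0:
        raise ValidationError(f"sample {table.sample_id}: diversity of an empty repertoire is undefined")
    p = np.array([r.frequency for r in table.records], dtype=float)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return DiversityResult(table.sample_id, max(h, 0.0), table.richness)


def frequency_spectrum(table: ClonotypeTable,
                       bin_edges: Sequence[float] = DEFAULT_SPECTRUM_EDGES) -> np.ndarray:
    """Proportion of unique clonotypes per frequency class.

    ``bin_edges`` are the interior boundaries; the classes are
    (0, e1], (e1, e2], ..., (e_last, 1].  Proportions sum to 1.
    """
    edges = list(bin_edges)
    if any(b >= a for b, a in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    full = [0.0, *edges, 1.0]
    if any(b >= a for b, a in zip(full, full[1:])):
        raise ValueError("bin edges must lie strictly inside (0, 1)")
    freqs = np.array([r.frequency for r in table.records], dtype=float)
    if freqs.size == 0:
        raise ValidationError("frequency spectrum of an empty repertoire is undefined")
    if (freqs <= 0).any() or (freqs > 1).any():
        raise ValueError("observed frequencies fall outside (0, 1]")
    counts, _ = np.histogram(freqs, bins=full)
    # np.histogram uses half-open [a,b) bins; recompute with (a,b] semantics
    counts = np.array(
        [((freqs > lo) & (freqs <= hi)).sum() for lo, hi in zip(full, full[1:])]
    )
    return counts / freqs.size


def top_n(table: ClonotypeTable, n: int) -> list[ClonotypeRecord]:
    """The n most expanded clonotypes (all, if the sample has fewer).

    Ties are broken deterministically: higher count first, then
    lexicographic CDR3 nucleotide sequence, then V segment.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(table.records, key=lambda r: (-r.count, r.cdr3_nt, r.v_segment))
    return ordered[:n]


def cumulative_top_frequency(table: ClonotypeTable, n: int) -> np.ndarray:
    """Entry k: summed frequency of the k most expanded clones (k=1..min(n, richness))."""
    top = top_n(table, n)
    return np.cumsum([r.frequency for r in top])


def _topn_keys(table: ClonotypeTable, n: int) -> set[ClonotypeKey]:
    return {clonotype_key(r, table.key_level) for r in top_n(table, n)}


# ---------------------------------------------------------------------------
# overlap statistics
# ---------------------------------------------------------------------------

def pairwise_topn_overlap(tables: Sequence[ClonotypeTable], n: int = 250) -> OverlapMatrix:
    """Symmetric TOP-N / TOP-N overlap in percent.

    Cell (A, B) = 100 * |topN(A) & topN(B)| / min(n, |topN(A)|, |topN(B)|);
    the denominator shrinks for samples with fewer than n clones so they
    remain comparable.
    """
    if len(tables) < 2:
        raise ValueError("need at least two samples")
    for t in tables:
        if t.richness == 0:
            raise ValidationError(f"sample {t.sample_id} has an empty repertoire")
    ids = [t.sample_id for t in tables]
    tops = [_topn_keys(t, n) for t in tables]
    m = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    for i, j in itertools.combinations_with_replacement(range(len(ids)), 2):
        denom = min(n, len(tops[i]), len(tops[j]))
        pct = 100.0 * len(tops[i] & tops[j]) / denom
        m.iloc[i, j] = pct
        m.iloc[j, i] = pct
    return OverlapMatrix(m, mode="topn_topn")


def topn_vs_full_overlap(tables: Sequence[ClonotypeTable], n: int = 250) -> OverlapMatrix:
    """Asymmetric overlap: row sample's TOP-N present anywhere in column sample."""
    if len(tables) < 2:
        raise ValueError("need at least two samples")
    for t in tables:
        if t.richness == 0:
            raise ValidationError(f"sample {t.sample_id} has an empty repertoire")
    ids = [t.sample_id for t in tables]
    tops = [_topn_keys(t, n) for t in tables]
    full = [t.keys() for t in tables]
    m = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    for i in range(len(ids)):
        for j in range(len(ids)):
            m.iloc[i, j] = 100.0 * len(tops[i] & full[j]) / len(tops[i])
    return OverlapMatrix(m, mode="topn_full")


def pooled_topn_blood_stats(tumor_tables: Sequence[ClonotypeTable],
                            blood_table: ClonotypeTable,
                            n: int = 250) -> dict[str, float]:
    """Detectability of the pooled tumor TOP-N in the blood repertoire.

    Returns the pooled unique TOP-N clone count across tumors, how many of
    those are present in blood, the detected percentage, and the detected
    clones' share of the blood repertoire by unique-clone count and by
    summed frequency mass (all percentages on a 0-100 scale).
    """
    if not tumor_tables:
        raise ValueError("need at least one tumor sample")
    pooled: set[ClonotypeKey] = set()
    for t in tumor_tables:
        pooled |= _topn_keys(t, n)
    if not pooled:
        raise ValidationError("pooled TOP-N set is empty")
    blood_keys = blood_table.keys()
    detected = pooled & blood_keys
    freq_mass = sum(blood_table.frequency_of(k) for k in detected)
    return {
        "pooled_unique": float(len(pooled)),
        "detected": float(len(detected)),
        "detected_pct": 100.0 * len(detected) / len(pooled),
        "share_of_blood_clone_count_pct": 100.0 * len(detected) / blood_table.richness,
        "share_of_blood_frequency_mass_pct": 100.0 * freq_mass,
    }


def common_clones(tables: Sequence[ClonotypeTable], rank_by: str = "mean") -> pd.DataFrame:
    """Clonotypes present in every sample, ranked by abundance.

    Ranking aggregates per-sample frequencies by their mean (default) or
    maximum.  Returns one row per common clone with per-sample frequencies.
    """
    if len(tables) < 2:
        raise ValueError("need at least two samples")
    if rank_by not in ("mean", "max"):
        raise ValueError("rank_by must be 'mean' or 'max'")
    shared = set.intersection(*[t.keys() for t in tables])
    rows = []
    for key in shared:
        freqs = {t.sample_id: t.frequency_of(key) for t in tables}
        agg = float(np.mean(list(freqs.values()))) if rank_by == "mean" else max(freqs.values())
        rows.append({"clonotype": "|".join(key), **freqs, f"{rank_by}_frequency": agg})
    df = pd.DataFrame(rows, columns=["clonotype", *[t.sample_id for t in tables],
                                     f"{rank_by}_frequency"])
    if not df.empty:
        df = df.sort_values([f"{rank_by}_frequency", "clonotype"],
                            ascending=[False, True]).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# sample-comparison tests
# ---------------------------------------------------------------------------

def overlap_difference_test(matrix: OverlapMatrix) -> tuple[float, float]:
    """Kruskal-Wallis test of whether one sample's overlap values differ.

    Group g holds the off-diagonal overlap values of row sample g; returns
    the H statistic and its asymptotic chi-square p-value.
    """
    ids = list(matrix.values.index)
    if len(ids) < 3:
        raise ValueError("need at least three samples")
    groups = [matrix.off_diagonal(s) for s in ids]
    for s, g in zip(ids, groups):
        if len(g) < 2:
            raise ValueError(f"sample {s}: fewer than two overlap values")
    flat = np.concatenate(groups)
    if np.allclose(flat, flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def diversity_group_test(diversities: Sequence[float],
                         group_labels: Sequence) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between exactly two groups.

    W is the rank sum of the first group (midranks).  The p-value is exact
    (full enumeration of group assignments) when the combined sample size
    is at most 10, and a normal approximation with tie correction and
    continuity correction otherwise.
    """
    x = np.asarray(diversities, dtype=float)
    labels = np.asarray(group_labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("exactly two groups are required")
    mask = labels == uniq[0]
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(x)
    w = float(ranks[mask].sum())
    n = n1 + n2
    expected = n1 * (n + 1) / 2.0
    if n <= 10:
        dev = abs(w - expected)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n1):
            total += 1
            if abs(ranks[list(combo)].sum() - expected) >= dev - 1e-9:
                count += 1
        return w, count / total
    # normal approximation with tie correction
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return w, 1.0
    z = (abs(w - expected) - 0.5) / math.sqrt(var)
    return w, float(2 * stats.norm.sf(max(z, 0.0)))
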