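"""Single-sample gene-set variation scoring and the diversity screen.

The score follows the GSVA recipe for continuous (microarray-like)
expression: each gene's values are smoothed into a per-sample statistic by
a Gaussian-kernel CDF estimate with bandwidth s_i/4, the statistics are
ranked within each sample, the ranks are symmetrized around the middle of
the list, and a weighted Kolmogorov-Smirnov-like random walk over the
ranked gene list yields one enrichment score per (gene set, sample) under
the max-deviation-difference convention.

Spearman correlations use midranks; p-values are exact (full permutation
enumeration) up to n = 10 and t-approximated beyond.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSetCollection, ValidationError, validate_expression

logger = logging.getLogger(__name__)

__all__ = [
    "gene_density_statistic",
    "gsva_scores",
    "spearman_correlation",
    "diversity_pathway_screen",
]


def gene_density_statistic(matrix: pd.DataFrame, chunk: int = 4096) -> pd.DataFrame:
    """Gaussian-kernel CDF statistic per gene and sample.

    z_ij = (1/n) sum_k Phi((x_ij - x_ik) / h_i) with bandwidth
    h_i = s_i / 4 (s_i the gene's across-sample standard deviation).
    Genes with zero variance receive the degenerate value 0.5 everywhere.
    """
    validate_expression(matrix)
    n = matrix.shape[1]
    if n < 3:
        raise ValidationError("kernel statistic requires at least three samples")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    out = np.empty_like(x)
    for start in range(0, x.shape[0], chunk):
        block = x[start:start + chunk]
        sd_b = sd[start:start + chunk]
        ok = sd_b > 0
        h = np.where(ok, sd_b / 4.0, 1.0)
        diffs = (block[:, :, None] - block[:, None, :]) / h[:, None, None]
        z = stats.norm.cdf(diffs).mean(axis=2)
        z[~ok] = 0.5
        out[start:start + chunk] = z
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _walk_score(positions: np.ndarray, weights: np.ndarray, p: int) -> float:
    """Enrichment score of one (set, sample) pair.

    ``positions``: 1-based ranks (ascending) of the set genes in the
    sample's descending-statistic ordering; ``weights``: the symmetric
    rank weights of those genes, in the same order.  The walk gains a
    normalized weight at each in-set gene and loses 1/(p-m) at each
    out-of-set gene; the score is max(0, max deviation) + min(0, min
    deviation).  Deviations between in-set hits decline linearly, so only
    the positions just after and just before each hit need inspection.
    """
    m = positions.size
    dec = 1.0 / (p - m)
    w = weights / weights.sum()
    cw = np.cumsum(w)
    ks = np.arange(1, m + 1)
    after = cw - (positions - ks) * dec          # walk value just after hit k
    before = np.concatenate(([0.0], cw[:-1])) - (positions - 1 - (ks - 1)) * dec
    mx = float(after.max())
    mn = float(min(before.min(), 0.0))
    return max(mx, 0.0) + min(mn, 0.0)


def gsva_scores(matrix: pd.DataFrame, sets: GeneSetCollection,
                min_set_size: int = 5, tau: float = 1.0) -> pd.DataFrame:
    """Gene-set variation scores: one row per usable gene set, one column
    per sample.

    Set genes absent from the matrix are dropped (with a log line); sets
    with fewer than ``min_set_size`` mapped genes are skipped with a
    warning.  A set covering the whole gene universe has no outside genes
    to walk through and is rejected.
    """
    z = gene_density_statistic(matrix)
    p = z.shape[0]
    zv = z.to_numpy()
    gene_pos = {g: i for i, g in enumerate(z.index)}

    # per sample: descending-statistic order and symmetric rank weights
    n_samples = z.shape[1]
    rank_of = np.empty((p, n_samples), dtype=np.int64)   # 1-based descending rank
    weight_of = np.empty((p, n_samples))
    for j in range(n_samples):
        order = np.argsort(-zv[:, j], kind="stable")
        ranks = np.empty(p, dtype=np.int64)
        ranks[order] = np.arange(1, p + 1)
        rank_of[:, j] = ranks
        weight_of[:, j] = np.abs(p / 2.0 - ranks) ** tau

    rows = {}
    for name, genes in sets.items():
        mapped = [g for g in genes if g in gene_pos]
        dropped = len(genes) - len(mapped)
        if dropped:
            logger.info("set %s: %d unmapped gene(s) dropped", name, dropped)
        if len(mapped) < min_set_size:
            logger.warning("set %s: only %d mapped genes (< %d), skipped",
                           name, len(mapped), min_set_size)
            continue
        if len(mapped) >= p:
            raise ValidationError(f"set {name!r} covers the whole gene universe")
        idx = np.array([gene_pos[g] for g in mapped])
        scores = np.empty(n_samples)
        for j in range(n_samples):
            ranks = rank_of[idx, j]
            order = np.argsort(ranks)
            scores[j] = _walk_score(ranks[order].astype(float),
                                    weight_of[idx, j][order], p)
        rows[name] = scores
    return pd.DataFrame.from_dict(rows, orient="index", columns=z.columns)


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-sample p-values
# ---------------------------------------------------------------------------

_D2_NULL_CACHE: dict[int, np.ndarray] = {}


def _d2_null_counts(n: int) -> np.ndarray:
    """Exact null distribution of D = sum (rank difference)^2 over all
    permutations of 1..n (no ties): counts[d] = number of permutations."""
    if n in _D2_NULL_CACHE:
        return _D2_NULL_CACHE[n]
    max_d = int(sum((i - j) ** 2 for i, j in zip(range(n), reversed(range(n)))))
    # DP over subsets of assigned values
    counts = {0: np.zeros(max_d + 1, dtype=np.int64)}
    counts[0][0] = 1
    frontier = {0: counts[0]}
    for pos in range(n):
        new: dict[int, np.ndarray] = {}
        for mask, vec in frontier.items():
            for val in range(n):
                bit = 1 << val
                if mask & bit:
                    continue
                d = (pos - val) ** 2
                target = new.setdefault(mask | bit, np.zeros(max_d + 1, dtype=np.int64))
                target[d:] += vec[: max_d + 1 - d]
        frontier = new
    result = frontier[(1 << n) - 1]
    _D2_NULL_CACHE[n] = result
    return result


def _exact_p_no_ties(rho: float, n: int) -> float:
    denom = n * (n * n - 1)
    counts = _d2_null_counts(n)
    d_vals = np.arange(counts.size)
    rhos = 1.0 - 6.0 * d_vals / denom
    keep = np.abs(rhos) >= abs(rho) - 1e-12
    return float(counts[keep].sum() / counts.sum())


def _exact_p_with_ties(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Enumerate permutations of the tied y-ranks (vectorized in batches)."""
    n = rx.size
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    norm = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    count = 0
    total = 0
    batch: list[tuple] = []
    batch_size = 100_000

    def flush(batch) -> int:
        arr = np.array(batch)
        r = (arr - ry.mean()) @ rx_c / norm
        return int((np.abs(r) >= abs(rho) - 1e-12).sum())

    for perm in itertools.permutations(ry):
        batch.append(perm)
        total += 1
        if len(batch) == batch_size:
            count += flush(batch)
            batch = []
    if batch:
        count += flush(batch)
    return count / total


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho on midranks with a two-sided p-value.

    Exact permutation p for n <= 10 (dynamic-programming enumeration when
    neither vector has ties, full enumeration otherwise); t-distribution
    approximation for larger n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("need at least four paired observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValidationError("Spearman correlation is undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        x_tied = len(np.unique(rx)) != n
        y_tied = len(np.unique(ry)) != n
        if not x_tied and not y_tied:
            p = _exact_p_no_ties(rho, n)
        else:
            p = _exact_p_with_ties(rx, ry, rho)
    else:
        r = min(max(rho, -1.0), 1.0)
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1 - r * r))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


@dataclass
class ScreenResult:
    """Per-pathway correlation with repertoire diversity, Table-style."""

    table: pd.DataFrame  # columns: term, rho, p, passed (sorted by rho desc)
    threshold: float

    @property
    def passing(self) -> list[str]:
        return self.table.loc[self.table["passed"], "term"].tolist()

    def format_report(self) -> str:
        """Two-decimal display of the screen, highest correlations first."""
        lines = ["term\tR\tp-value"]
        for _, row in self.table.iterrows():
            p = row["p"]
            p_str = "<0.01" if p < 0.005 else f"{p:.2f}"
            lines.append(f"{row['term']}\t{row['rho']:.2f}\t{p_str}")
        return "\n".join(lines) + "\n"


def diversity_pathway_screen(scores: pd.DataFrame, diversities: pd.Series,
                             threshold: float = 0.75) -> ScreenResult:
    """Correlate each pathway's score profile with per-sample diversity.

    A pathway passes when its Spearman rho exceeds ``threshold`` (the p
    value is reported but not used for thresholding).  Results are sorted
    by descending rho.
    """
    missing = [s for s in scores.columns if s not in diversities.index]
    extra = [s for s in diversities.index if s not in scores.columns]
    if missing or extra:
        raise ValidationError(
            f"sample mismatch between scores and diversities: missing={missing}, extra={extra}"
        )
    div = diversities.loc[scores.columns].to_numpy(dtype=float)
    rows = []
    for term in scores.index:
        rho, p = spearman_correlation(scores.loc[term].to_numpy(dtype=float), div)
        rows.append({"term": term, "rho": rho, "p": p, "passed": rho > threshold})
    table = pd.DataFrame(rows).sort_values(
        ["rho", "term"], ascending=[False, True]
    ).reset_index(drop=True)
    return ScreenResult(table=table, threshold=threshold)
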