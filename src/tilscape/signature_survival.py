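"""Stable-gene signature extraction and survival stratification.

From the genes of diversity-correlated pathways, the signature keeps those
whose expression varies least across the multi-region samples: the
coefficient of variation (CV = sd / mean) is computed per gene on the
normalized log2-scale values and genes with log2(CV) below a cutoff
(default -5.5, i.e. CV < ~0.022) are selected.  Patients are then
stratified by unsupervised hierarchical clustering of the signature-gene
expression (1 - Pearson correlation distance, average linkage, cut at
k = 2) and the clusters are compared by Kaplan-Meier estimation and the
two-group log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_formats import SurvivalRecord, ValidationError

__all__ = [
    "SignatureResult",
    "gene_cv_selection",
    "knee_point",
    "cluster_patients",
    "km_estimate",
    "logrank_test",
]


@dataclass
class SignatureResult:
    """Per-candidate CV report plus the selected low-variability genes."""

    table: pd.DataFrame  # columns: gene, mean, sd, cv, log2_cv, selected
    cutoff: float

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "gene"].tolist()

    @property
    def candidates(self) -> list[str]:
        return self.table["gene"].tolist()


def gene_cv_selection(matrix: pd.DataFrame, candidate_genes: Sequence[str],
                      cutoff: float = -5.5) -> SignatureResult:
    """Select candidate genes whose log2 coefficient of variation falls
    below ``cutoff``.

    CV = sd / mean across samples on the analysis (log2 intensity) scale;
    genes with zero variance have log2(CV) = -inf and are selected.  The
    report is sorted by ascending log2(CV).
    """
    missing = [g for g in candidate_genes if g not in matrix.index]
    if missing:
        raise ValidationError(f"candidate genes absent from matrix: {missing[:5]}")
    if matrix.shape[1] < 3:
        raise ValidationError("CV selection requires at least three samples")
    rows = []
    for gene in candidate_genes:
        vals = matrix.loc[gene].to_numpy(dtype=float)
        mean = float(vals.mean())
        if mean <= 0:
            raise ValidationError(
                f"gene {gene!r} has non-positive mean expression; CV is undefined on this scale"
            )
        sd = float(vals.std(ddof=1))
        cv = sd / mean
        log2_cv = float(np.log2(cv)) if cv > 0 else float("-inf")
        rows.append({"gene": gene, "mean": mean, "sd": sd, "cv": cv,
                     "log2_cv": log2_cv, "selected": log2_cv < cutoff})
    table = pd.DataFrame(rows).sort_values(
        ["log2_cv", "gene"], ascending=[True, True]
    ).reset_index(drop=True)
    return SignatureResult(table=table, cutoff=cutoff)


def knee_point(sorted_values: Sequence[float]) -> float:
    """Knee of a sorted curve: the value maximizing the distance to the
    chord between the curve's endpoints.

    A helper for choosing a CV cutoff on new datasets; the pipeline's
    default cutoff is a configured constant.
    """
    y = np.asarray(sorted_values, dtype=float)
    if y.size < 3:
        raise ValueError("need at least three points to locate a knee")
    x = np.linspace(0.0, 1.0, y.size)
    y0, y1 = y[0], y[-1]
    yn = (y - y0) / (y1 - y0) if y1 != y0 else np.zeros_like(y)
    # distance from (x, yn) to the chord from (0,0) to (1,1)
    dist = np.abs(yn - x) / np.sqrt(2)
    return float(y[int(np.argmax(dist))])


# ---------------------------------------------------------------------------
# patient clustering
# ---------------------------------------------------------------------------

def cluster_patients(matrix: pd.DataFrame, k: int = 2,
                     metric: str = "correlation",
                     linkage: str = "average") -> pd.Series:
    """Agglomerative clustering of patients over z-scored signature genes.

    ``matrix`` is signature genes x patients.  Default distance is
    1 - Pearson correlation between patients with average linkage;
    Euclidean distance with Ward linkage is available.  Labels are 1-based
    and renumbered so that cluster 1 contains the first patient in column
    order (label identity is otherwise arbitrary).
    """
    genes, patients = matrix.shape
    if genes < 2:
        raise ValidationError("clustering requires at least two signature genes")
    if patients < k:
        raise ValidationError(f"fewer patients ({patients}) than clusters ({k})")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    z = np.zeros_like(x)
    z[keep] = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]

    if metric == "correlation":
        corr = np.corrcoef(z.T)
        corr = np.clip(corr, -1.0, 1.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        link = hierarchy.linkage(condensed, method=linkage)
    elif metric == "euclidean":
        link = hierarchy.linkage(z.T, method=linkage, metric="euclidean")
    else:
        raise ValueError(f"unknown clustering metric {metric!r}")

    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    # renumber by first appearance in patient order
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    labels = pd.Series([relabel[v] for v in raw], index=matrix.columns, name="cluster")
    if labels.nunique() != k:
        raise ValidationError(f"clustering produced {labels.nunique()} non-empty clusters, expected {k}")
    return labels


# ---------------------------------------------------------------------------
# survival analysis
# ---------------------------------------------------------------------------

def _records_frame(records: Sequence[SurvivalRecord],
                   labels: pd.Series | dict) -> pd.DataFrame:
    labels = pd.Series(labels)
    rows = []
    for r in records:
        if r.patient not in labels.index:
            raise ValidationError(f"patient {r.patient!r} has no cluster label")
        rows.append({"patient": r.patient, "time": r.time, "event": r.event,
                     "cluster": labels[r.patient]})
    return pd.DataFrame(rows)


def km_estimate(records: Sequence[SurvivalRecord],
                labels: pd.Series | dict) -> dict[object, pd.DataFrame]:
    """Kaplan-Meier product-limit curves per cluster.

    Each curve is a step function reported at event times: columns
    ``time``, ``survival``, ``at_risk``.
    """
    df = _records_frame(records, labels)
    curves: dict[object, pd.DataFrame] = {}
    for cluster, grp in df.groupby("cluster"):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], grp["event"])
        surv = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"]
        curve = pd.DataFrame({
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": at_risk.reindex(surv.index).to_numpy(dtype=float),
        })
        curves[cluster] = curve.reset_index(drop=True)
    return curves


def logrank_test(records: Sequence[SurvivalRecord],
                 labels: pd.Series | dict) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    df = _records_frame(records, labels)
    clusters = sorted(df["cluster"].unique())
    if len(clusters) != 2:
        raise ValidationError(f"log-rank test requires exactly two clusters, got {len(clusters)}")
    if df["event"].sum() == 0:
        raise ValidationError("log-rank test requires at least one observed event")
    a = df[df["cluster"] == clusters[0]]
    b = df[df["cluster"] == clusters[1]]
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)
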