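"""Readers and writers for the tab-delimited formats the pipeline consumes.

All tables are UTF-8, tab-delimited, unquoted, with ``.`` as the decimal
separator.  Expression matrices are represented as :class:`pandas.DataFrame`
objects with genes as rows and samples as columns; values are treated as
log2-scale intensities throughout.

The clonotype format mirrors VDJtools-style repertoire exports
(count / freq / cdr3nt / cdr3aa / v / d / j); column names are matched
permissively against common synonyms.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "ClonotypeRecord",
    "GeneSetCollection",
    "VariantCall",
    "SurvivalRecord",
    "AnalysisConfig",
    "read_clonotype_table",
    "write_clonotype_table",
    "read_gmt",
    "write_gmt",
    "read_expression_table",
    "write_expression_table",
    "quantile_normalize",
    "read_variant_table",
    "write_variant_table",
    "read_survival_table",
    "write_survival_table",
    "write_results",
    "load_config",
]


class FormatError(ValueError):
    """A file does not match the documented layout."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClonotypeRecord:
    """One TCRB clonotype: CDR3 sequences, V(D)J assignment, and abundance."""

    cdr3_nt: str
    cdr3_aa: str
    v_segment: str
    j_segment: str
    d_segment: str = ""
    count: int = 0
    frequency: float = 0.0

    def __post_init__(self) -> None:
        if not self.cdr3_nt:
            raise ValidationError("clonotype with empty CDR3 nucleotide sequence")
        if self.count < 0:
            raise ValidationError(f"negative clonotype count {self.count}")


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) over a gene-identifier universe."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


@dataclass(frozen=True)
class VariantCall:
    """One candidate somatic variant with per-sample read support.

    ``samples`` maps sample id to ``(depth, non_reference_reads)``;
    ``germline`` holds the same pair for the matched normal.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    samples: Mapping[str, tuple[int, int]]
    germline: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position {self.pos} < 1")
        pairs = list(self.samples.values())
        if self.germline is not None:
            pairs.append(self.germline)
        for depth, alt_reads in pairs:
            if not (depth >= alt_reads >= 0):
                raise ValidationError(
                    f"variant {self.chrom}:{self.pos} has depth {depth} < "
                    f"non-reference reads {alt_reads} (or negative reads)"
                )

    @property
    def mutation_id(self) -> str:
        return f"{self.gene}_{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class SurvivalRecord:
    """Follow-up time (months) and event indicator for one patient."""

    patient: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValidationError(f"patient {self.patient}: follow-up time must be > 0")
        if self.event not in (0, 1):
            raise ValidationError(f"patient {self.patient}: event must be 0 or 1")


@dataclass
class AnalysisConfig:
    """All tunable constants of the pipeline, with the study defaults.

    top_n: size of the "most expanded clones" window (TOP250).
    screen_rho_threshold: Spearman cut for the pathway-diversity screen.
    log2_cv_cutoff: log2 coefficient-of-variation cut for stable genes.
    germline_min_depth: minimum normal-sample coverage for somatic calls.
    cluster_window_bp: window for the clustered-variant artifact filter.
    n_clusters: number of patient clusters in the survival stratification.
    """

    top_n: int = 250
    screen_rho_threshold: float = 0.75
    log2_cv_cutoff: float = -5.5
    germline_min_depth: int = 10
    cluster_window_bp: int = 100
    n_clusters: int = 2
    min_set_size: int = 5
    gsva_tau: float = 1.0
    clone_key_level: str = "nt"          # "nt" or "aa"
    cluster_metric: str = "correlation"  # or "euclidean"
    cluster_linkage: str = "average"     # or "ward"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")
        for name in ("screen_rho_threshold", "log2_cv_cutoff"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Load a flat YAML/JSON config; keys not in AnalysisConfig are rejected."""
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data)


# ---------------------------------------------------------------------------
# clonotype tables
# ---------------------------------------------------------------------------

_CLONO_SYNONYMS: dict[str, tuple[str, ...]] = {
    "count": ("count", "#count", "reads", "read_count", "clone_count"),
    "frequency": ("freq", "frequency", "#freq", "fraction", "clone_fraction"),
    "cdr3_nt": ("cdr3nt", "cdr3_nt", "cdr3.nt", "nseq", "n_seq", "nucleotide"),
    "cdr3_aa": ("cdr3aa", "cdr3_aa", "cdr3.aa", "aaseq", "aa_seq", "aminoacid"),
    "v_segment": ("v", "v_segment", "allvhits", "v_segments", "vgene", "v.segm"),
    "d_segment": ("d", "d_segment", "alldhits", "d_segments", "dgene", "d.segm"),
    "j_segment": ("j", "j_segment", "alljhits", "j_segments", "jgene", "j.segm"),
}
_CLONO_REQUIRED = ("count", "frequency", "cdr3_nt", "cdr3_aa", "v_segment", "j_segment")


def _resolve_clonotype_columns(columns: Sequence[str]) -> dict[str, str]:
    lowered = {c.lower().lstrip("#"): c for c in columns}
    resolved: dict[str, str] = {}
    for canon, names in _CLONO_SYNONYMS.items():
        for name in names:
            if name.lstrip("#") in lowered:
                resolved[canon] = lowered[name.lstrip("#")]
                break
    missing = [c for c in _CLONO_REQUIRED if c not in resolved]
    if missing:
        raise FormatError(f"clonotype table is missing required column(s): {missing}")
    return resolved


def read_clonotype_table(path: str | Path, sample_id: str | None = None,
                         key_level: str = "nt"):
    """Read a VDJtools-style clonotype TSV into a :class:`ClonotypeTable`.

    Counts are authoritative: stored frequencies that disagree with
    ``count / total_count`` are recomputed (with a warning).
    """
    from .repertoire import ClonotypeTable  # deferred: avoids import cycle

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_clonotype_columns(df.columns)
    records: list[ClonotypeRecord] = []
    stored_freqs: list[float] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        try:
            count = int(float(row_d[cols["count"]]))
            freq = float(row_d[cols["frequency"]])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path.name} line {i}: malformed numeric field ({exc})")
        if count < 0:
            raise ValidationError(f"{path.name} line {i}: negative count {count}")
        records.append(
            ClonotypeRecord(
                cdr3_nt=str(row_d[cols["cdr3_nt"]]),
                cdr3_aa=str(row_d[cols["cdr3_aa"]]),
                v_segment=str(row_d[cols["v_segment"]]),
                j_segment=str(row_d[cols["j_segment"]]),
                d_segment="" if "d_segment" not in cols or pd.isna(row_d[cols["d_segment"]])
                else str(row_d[cols["d_segment"]]),
                count=count,
                frequency=freq,
            )
        )
        stored_freqs.append(freq)

    sample = sample_id or path.stem
    table = ClonotypeTable.from_records(sample, records, key_level=key_level)
    # warn when the file's frequency column disagrees with the counts
    if records:
        recomputed = {r.cdr3_nt + r.v_segment + r.j_segment: r.frequency for r in table.records}
        for rec, stored in zip(records, stored_freqs):
            k = rec.cdr3_nt + rec.v_segment + rec.j_segment
            if k in recomputed and abs(recomputed[k] - stored) > 1e-6:
                logger.warning(
                    "%s: stored frequencies disagree with counts; recomputed from counts",
                    path.name,
                )
                break
    return table


def write_clonotype_table(table, path: str | Path) -> None:
    rows = [
        {
            "count": r.count,
            "freq": repr(r.frequency),
            "cdr3nt": r.cdr3_nt,
            "cdr3aa": r.cdr3_aa,
            "v": r.v_segment,
            "d": r.d_segment,
            "j": r.j_segment,
        }
        for r in table.records
    ]
    pd.DataFrame(rows, columns=["count", "freq", "cdr3nt", "cdr3aa", "v", "d", "j"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set name, description, then member genes per line."""
    sets: dict[str, list[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV with a leading gene-identifier column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression(df)
    return df


def write_expression_table(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def validate_expression(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValidationError(f"duplicate gene identifier {dup!r}")
    if matrix.columns.duplicated().any():
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise ValidationError(f"duplicate sample identifier {dup!r}")
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValidationError("expression matrix contains non-finite values")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples (columns) to the mean quantile vector.

    After normalization every column holds the same multiset of values.
    Ties within a column receive the mean of the quantile values they span,
    matching the convention of limma's ``normalizeQuantiles``.
    """
    validate_expression(matrix)
    if matrix.shape[1] < 2:
        logger.warning("quantile_normalize: single sample, returning input unchanged")
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    n_genes = values.shape[0]
    mean_quantiles = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    positions = np.arange(n_genes, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        # average rank (0-based) of each entry, then interpolate into the
        # mean quantile vector so ties share one averaged value
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(n_genes)
        ranks[order] = positions
        ranks = _average_tied(col, ranks)
        out[:, j] = np.interp(ranks, positions, mean_quantiles)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _average_tied(values: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    """Replace ranks of tied values by their mean rank."""
    df = pd.Series(ranks).groupby(pd.Series(values)).transform("mean")
    return df.to_numpy()


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

_VARIANT_FIXED = ["chrom", "pos", "ref", "alt", "gene", "effect"]


def read_variant_table(path: str | Path) -> list[VariantCall]:
    """Read a pre-tabulated call table.

    Per-sample read support is carried in paired columns
    ``<sample>_depth`` / ``<sample>_alt``; the matched normal uses sample
    name ``germline``.  Extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    lowered = {c.lower(): c for c in df.columns}
    missing = [c for c in _VARIANT_FIXED if c not in lowered]
    if missing:
        raise FormatError(f"variant table is missing column(s): {missing}")
    sample_names = sorted(
        {
            c.lower()[: -len("_depth")]
            for c in df.columns
            if c.lower().endswith("_depth")
            and c.lower()[: -len("_depth")] + "_alt" in lowered
        }
    )
    calls: list[VariantCall] = []
    for i, row in df.iterrows():
        lineno = i + 2
        try:
            pos = int(row[lowered["pos"]])
            support = {
                s: (int(row[lowered[s + "_depth"]]), int(row[lowered[s + "_alt"]]))
                for s in sample_names
            }
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"variant table line {lineno}: malformed numeric field ({exc})")
        germline = support.pop("germline", None)
        calls.append(
            VariantCall(
                chrom=str(row[lowered["chrom"]]),
                pos=pos,
                ref=str(row[lowered["ref"]]),
                alt=str(row[lowered["alt"]]),
                gene=str(row[lowered["gene"]]),
                effect=str(row[lowered["effect"]]),
                samples=support,
                germline=germline,
            )
        )
    return calls


def write_variant_table(calls: Iterable[VariantCall], path: str | Path) -> None:
    calls = list(calls)
    samples = sorted({s for c in calls for s in c.samples})
    rows = []
    for c in calls:
        row: dict[str, object] = {
            "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
            "gene": c.gene, "effect": c.effect,
        }
        for s in samples:
            depth, alt = c.samples.get(s, (0, 0))
            row[f"{s}_depth"], row[f"{s}_alt"] = depth, alt
        if c.germline is not None:
            row["germline_depth"], row["germline_alt"] = c.germline
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# survival tables
# ---------------------------------------------------------------------------

def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    lowered = {c.lower(): c for c in df.columns}
    missing = [c for c in ("patient", "time", "event") if c not in lowered]
    if missing:
        raise FormatError(f"survival table is missing column(s): {missing}")
    records = []
    for i, row in df.iterrows():
        lineno = i + 2
        try:
            time = float(row[lowered["time"]])
            event = int(row[lowered["event"]])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"survival table line {lineno}: malformed numeric field ({exc})")
        try:
            records.append(SurvivalRecord(str(row[lowered["patient"]]), time, event))
        except ValidationError as exc:
            raise ValidationError(f"survival table line {lineno}: {exc}")
    return records


def write_survival_table(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"patient": r.patient, "time": repr(r.time), "event": r.event} for r in records]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_results(outdir: str | Path, objects: Mapping[str, object]) -> list[Path]:
    """Write a mapping of name -> DataFrame / dict / string into ``outdir``.

    DataFrames become ``<name>.tsv``; mappings become ``<name>.json``;
    strings are written verbatim as ``<name>.txt``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, obj in objects.items():
        if isinstance(obj, pd.DataFrame):
            p = outdir / f"{name}.tsv"
            obj.to_csv(p, sep="\t")
        elif isinstance(obj, Mapping):
            p = outdir / f"{name}.json"
            p.write_text(json.dumps(obj, indent=2, default=float) + "\n")
        else:
            p = outdir / f"{name}.txt"
            p.write_text(str(obj))
        written.append(p)
    return written
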