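"""Seeded generators emulating the statistical structure of multi-region
tumor immune data.

Four generators cover the pipeline's inputs: (a) TCRB repertoires with
right-skewed (Zipf) clone abundances, tunable inter-sample sharing and one
hyperexpanded public clone; (b) a planted trunk-and-branch mutation
phylogeny with optional per-sample dropout; (c) expression matrices with
pathway-structured signal correlated with a supplied diversity vector plus
a block of guaranteed low-CV genes; (d) a two-class survival cohort with
class-shifted signature expression and class-specific exponential hazards.

Every generator is a pure function of (config, seed): identical inputs
yield identical outputs.  Ground truth needed by tests (shared-clone maps,
the planted tree, planted gene sets, class labels) is always returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ClonotypeRecord, GeneSetCollection, SurvivalRecord
from .repertoire import ClonotypeTable
from .somatic_phylogeny import MutationMatrix, PhyloTree, _plain_newick

__all__ = [
    "RepertoireSimConfig",
    "MutationSimConfig",
    "ExpressionSimConfig",
    "CohortSimConfig",
    "SurvivalCohort",
    "simulate_repertoires",
    "simulate_mutation_matrix",
    "simulate_expression",
    "simulate_cohort",
]

_NT = np.array(list("ACGT"))


def _random_cdr3(rng: np.random.Generator, length: int = 36) -> str:
    return "".join(rng.choice(_NT, size=length))


def _translate(nt: str) -> str:
    # placeholder aa string: one letter per codon via a fixed base-4 code
    aa = "ACDEFGHIKLMNPQRSTVWY"
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    return "".join(
        aa[(16 * idx[nt[i]] + 4 * idx[nt[i + 1]] + idx[nt[i + 2]]) % 20]
        for i in range(0, len(nt) - 2, 3)
    )


# ---------------------------------------------------------------------------
# repertoires
# ---------------------------------------------------------------------------

@dataclass
class RepertoireSimConfig:
    """Repertoire generator settings.

    ``zipf_exponent`` shapes the right-skewed clone-abundance law
    (larger = steeper dominance); ``tumor_tumor_sharing`` and
    ``tumor_blood_sharing`` are the fractions of each sample's clones
    drawn from pools common to all tumors / shared with blood;
    ``public_clone_frequency`` is the blood frequency of the single
    hyperexpanded public clone observed across all samples.
    """

    n_tumor_samples: int = 10
    n_blood_samples: int = 1
    clones_per_sample: int = 5000
    zipf_exponent: float = 1.5
    tumor_tumor_sharing: float = 0.15
    tumor_blood_sharing: float = 0.06
    public_clone_frequency: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tumor_tumor_sharing <= 1.0
                and 0.0 <= self.tumor_blood_sharing <= 1.0):
            raise ValueError("sharing rates must lie in [0, 1]")
        if self.zipf_exponent <= 1.0:
            raise ValueError("zipf exponent must be > 1")


def _make_clone_pool(rng: np.random.Generator, n: int) -> list[tuple[str, str, str, str]]:
    pool = []
    seen = set()
    while len(pool) < n:
        nt = _random_cdr3(rng)
        if nt in seen:
            continue
        seen.add(nt)
        v = f"TRBV{rng.integers(1, 31)}"
        j = f"TRBJ{rng.integers(1, 14)}"
        d = f"TRBD{rng.integers(1, 3)}"
        pool.append((nt, _translate(nt), v, j, d))
    return pool


def simulate_repertoires(config: RepertoireSimConfig) -> tuple[list[ClonotypeTable], dict]:
    """Generate tumor (and optionally blood) clonotype tables plus ground truth.

    Sharing is realized through clone pools: every tumor sample includes
    the tumor-shared pool (size = sharing rate x clones per sample); blood
    includes the tumor-blood pool, drawn from the tumor-shared pool where
    possible.  Clone abundances are i.i.d. draws from a bounded Zipf law;
    the public clone is pinned to the configured blood frequency and is
    the most abundant clone everywhere.
    """
    rng = np.random.default_rng(config.seed)
    c = config.clones_per_sample
    n_tt = round(config.tumor_tumor_sharing * c)
    n_tb = round(config.tumor_blood_sharing * c)
    has_blood = config.n_blood_samples > 0

    shared_pool = _make_clone_pool(rng, max(n_tt, n_tb, 1))
    public = shared_pool[0] if (n_tt > 0 or n_tb > 0) else None

    zipf = stats.zipfian(config.zipf_exponent, c)

    def draw_counts(k: int) -> np.ndarray:
        return zipf.rvs(size=k, random_state=rng)

    # shared clones carry one common abundance draw: the same expanded clone
    # is expanded everywhere, so TOP-N membership is shared too
    shared_counts = draw_counts(len(shared_pool))

    def build_sample(sample_id: str, shared: list, privates: list,
                     public_clone) -> ClonotypeTable:
        clones = shared + privates
        counts = np.concatenate([shared_counts[: len(shared)],
                                 draw_counts(len(privates))])
        if public_clone is not None and public_clone in clones:
            i = clones.index(public_clone)
            counts[i] = counts.max() + counts.sum() // 10 + 1  # dominate the sample
        records = [
            ClonotypeRecord(cdr3_nt=nt, cdr3_aa=aa, v_segment=v, j_segment=j,
                            d_segment=d, count=int(cnt))
            for (nt, aa, v, j, d), cnt in zip(clones, counts)
        ]
        return ClonotypeTable.from_records(sample_id, records)

    tables: list[ClonotypeTable] = []
    truth: dict = {
        "tumor_shared_keys": {(nt, v, j) for nt, _, v, j, _ in shared_pool[:n_tt]},
        "blood_shared_keys": set(),
        "public_clone_key": (public[0], public[2], public[3]) if public else None,
        "tumor_samples": [],
        "blood_sample": None,
    }

    for t in range(config.n_tumor_samples):
        sample_id = f"T{t + 1:02d}"
        privates = _make_clone_pool(rng, c - n_tt)
        tables.append(build_sample(sample_id, shared_pool[:n_tt], privates, public))
        truth["tumor_samples"].append(sample_id)

    if has_blood:
        blood_shared = shared_pool[:n_tb]
        privates = _make_clone_pool(rng, c - len(blood_shared))
        clones = list(blood_shared) + privates
        counts = np.concatenate([shared_counts[: len(blood_shared)],
                                 draw_counts(len(privates))])
        if public is not None and public in clones:
            i = clones.index(public)
            counts[i] = 1  # placeholder, fixed below
            other_total = counts.sum() - 1
            f = config.public_clone_frequency
            counts[i] = max(int(round(f / (1.0 - f) * other_total)), 1)
        records = [
            ClonotypeRecord(cdr3_nt=nt, cdr3_aa=aa, v_segment=v, j_segment=j,
                            d_segment=d, count=int(cnt))
            for (nt, aa, v, j, d), cnt in zip(clones, counts)
        ]
        blood = ClonotypeTable.from_records("blood", records)
        tables.append(blood)
        truth["blood_sample"] = "blood"
        truth["blood_shared_keys"] = {(nt, v, j) for nt, _, v, j, _ in blood_shared}

    return tables, truth


# ---------------------------------------------------------------------------
# mutation matrices
# ---------------------------------------------------------------------------

@dataclass
class MutationSimConfig:
    """Planted trunk-and-branch phylogeny settings.

    Defaults mirror a two-mass tumor with 9 trunk mutations shared by both
    masses and 22 / 13 mass-branch mutations, the structure reported for
    a primary-metastasis glioblastoma pair.  ``private_mutations`` adds
    that many region-unique mutations to every sample's terminal edge;
    ``internal_edge_mutations`` places mutations on every internal edge of
    the random within-mass subtrees, which makes the full planted topology
    identifiable from the matrix.
    """

    samples_per_mass: dict = dc_field(default_factory=lambda: {"occipital": 3, "temporal": 6})
    trunk_mutations: int = 9
    mass_branch_mutations: dict = dc_field(default_factory=lambda: {"occipital": 22, "temporal": 13})
    private_mutations: int = 0
    internal_edge_mutations: int = 0
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.trunk_mutations < 0 or self.private_mutations < 0:
            raise ValueError("mutation counts must be >= 0")


def _random_topology(rng: np.random.Generator, leaves: list[str]):
    """Random rooted binary topology by sequential random edge insertion."""
    top = leaves[0]
    for leaf in leaves[1:]:
        edges = _edge_list(top)
        where = rng.integers(0, len(edges))
        top = _insert_at(top, edges[where], leaf)
    return top


def _edge_list(top, path=()) -> list[tuple]:
    out = [path]
    if not isinstance(top, str):
        out += _edge_list(top[0], path + (0,))
        out += _edge_list(top[1], path + (1,))
    return out


def _insert_at(top, path: tuple, leaf: str):
    if not path:
        return (top, leaf)
    i = path[0]
    child = _insert_at(top[i], path[1:], leaf)
    return (child, top[1]) if i == 0 else (top[0], child)


def simulate_mutation_matrix(config: MutationSimConfig) -> tuple[MutationMatrix, dict]:
    """Generate a presence/absence matrix from a planted tree, plus truth.

    Truth contains the planted :class:`PhyloTree` (with per-edge mutation
    counts), the mass assignment, the pre-dropout matrix, and per-mutation
    class labels implied by the construction.
    """
    rng = np.random.default_rng(config.seed)
    masses = dict(config.samples_per_mass)
    sample_names: dict[str, list[str]] = {}
    for mass, n in masses.items():
        prefix = mass[:1].upper()
        sample_names[mass] = [f"{prefix}{i + 1}" for i in range(n)]
    all_samples = [s for names in sample_names.values() for s in names]

    # planted topology: masses joined at the root, random subtree per mass
    subtrees = {}
    for mass, names in sample_names.items():
        subtrees[mass] = _random_topology(rng, list(names)) if len(names) > 1 else names[0]
    mass_order = sorted(masses)
    top = subtrees[mass_order[0]]
    for mass in mass_order[1:]:
        top = (top, subtrees[mass])

    # assign mutation budgets to edges
    edge_budget: dict[str, int] = {_plain_newick(top): config.trunk_mutations}
    for mass in mass_order:
        sub = subtrees[mass]
        edge_budget[_plain_newick(sub)] = config.mass_branch_mutations.get(mass, 0)

        def visit(node, is_mass_root):
            if isinstance(node, str):
                edge_budget[node] = edge_budget.get(node, 0) + config.private_mutations
                return
            if not is_mass_root:
                key = _plain_newick(node)
                edge_budget[key] = edge_budget.get(key, 0) + config.internal_edge_mutations
            visit(node[0], False)
            visit(node[1], False)

        visit(sub, True)

    # materialize mutations: each mutation is present in the leaves below its edge
    def leaves_below(node) -> list[str]:
        if isinstance(node, str):
            return [node]
        return leaves_below(node[0]) + leaves_below(node[1])

    rows = {}
    class_labels = {}
    mut_idx = 0
    mass_of = {s: mass for mass, names in sample_names.items() for s in names}

    def emit(node):
        nonlocal mut_idx
        key = _plain_newick(node)
        carriers = set(leaves_below(node))
        carrier_masses = {mass_of[s] for s in carriers}
        for _ in range(edge_budget.get(key, 0)):
            mut_idx += 1
            name = f"MUT{mut_idx:04d}"
            rows[name] = [1 if s in carriers else 0 for s in all_samples]
            if carrier_masses == set(mass_order):
                class_labels[name] = "shared"
            elif len(carriers) == 1:
                class_labels[name] = "region_unique"
            else:
                class_labels[name] = "mass_specific"
        if not isinstance(node, str):
            emit(node[0])
            emit(node[1])

    emit(top)

    clean = pd.DataFrame.from_dict(rows, orient="index", columns=all_samples)
    noisy = clean.copy()
    if config.dropout > 0:
        flips = (rng.random(clean.shape) < config.dropout) & (clean.to_numpy() == 1)
        noisy = clean.where(~flips, 0)
        noisy = noisy[noisy.sum(axis=1) > 0]  # a mutation seen nowhere is unobservable

    tree = PhyloTree(topology=top,
                     branch_lengths={k: edge_budget.get(k, 0) for k in
                                     [_plain_newick(n) for n in _all_nodes(top)]},
                     score=sum(edge_budget.values()))
    truth = {
        "tree": tree,
        "mass_of_sample": mass_of,
        "clean_matrix": MutationMatrix(clean) if len(clean) else None,
        "class_labels": pd.Series(class_labels),
    }
    matrix = MutationMatrix(noisy)
    return matrix, truth


def _all_nodes(top) -> list:
    out = [top]
    if not isinstance(top, str):
        out += _all_nodes(top[0])
        out += _all_nodes(top[1])
    return out


# ---------------------------------------------------------------------------
# expression with planted pathway signal
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimConfig:
    """Expression generator settings.

    Planted-set genes follow baseline + effect x standardized diversity +
    Gaussian noise, giving a gene-diversity correlation of about
    effect / sqrt(effect^2 + noise_sd^2).  ``n_low_cv_genes`` are spread
    across the planted sets and rescaled to an exact small coefficient of
    variation so they fall below the stable-gene cutoff by construction.
    """

    n_genes: int = 2000
    n_gene_sets: int = 200
    set_size: int = 20
    n_planted_sets: int = 5
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    n_low_cv_genes: int = 23
    low_cv: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if self.effect_size > 0 and self.noise_sd == 0:
            pass  # deterministic signal; correlation is exactly 1
        if self.n_planted_sets * self.set_size > self.n_genes:
            raise ValueError("planted sets exceed the gene universe")


def simulate_expression(config: ExpressionSimConfig,
                        diversity: Sequence[float]) -> tuple[pd.DataFrame, GeneSetCollection, dict]:
    """Expression matrix + gene sets with planted diversity-correlated sets.

    Returns (matrix, gene-set collection, truth); truth lists the planted
    set names, their member genes, and the exact-low-CV gene names.
    """
    rng = np.random.default_rng(config.seed)
    div = np.asarray(diversity, dtype=float)
    n_samples = div.size
    if n_samples < 3:
        raise ValueError("need at least three samples")
    z_div = (div - div.mean()) / div.std() if div.std() > 0 else np.zeros_like(div)

    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]
    x = rng.normal(config.baseline_mean, config.baseline_sd,
                   size=(config.n_genes, n_samples))

    # planted sets occupy the first n_planted_sets * set_size genes (disjoint)
    planted_sets: dict[str, list[str]] = {}
    planted_genes: list[str] = []
    for s in range(config.n_planted_sets):
        members = genes[s * config.set_size:(s + 1) * config.set_size]
        planted_sets[f"PLANTED_SET_{s + 1}"] = members
        planted_genes.extend(members)

    # distribute the low-CV genes round-robin across the planted sets so no
    # single set is swallowed by near-constant genes
    if planted_sets:
        order = [members[i] for i in range(config.set_size)
                 for members in planted_sets.values()]
    else:
        order = genes
    low_cv_genes = order[:config.n_low_cv_genes]
    low_set = set(low_cv_genes)

    gene_idx = {g: i for i, g in enumerate(genes)}
    for g in planted_genes:
        if g in low_set:
            continue
        i = gene_idx[g]
        x[i] = config.baseline_mean + config.effect_size * z_div \
            + rng.normal(0.0, config.noise_sd, size=n_samples)

    # exact-CV construction: center residuals, rescale to sd = cv * mean
    for g in low_cv_genes:
        i = gene_idx[g]
        mean = config.baseline_mean + 2.0
        resid = rng.normal(size=n_samples)
        resid -= resid.mean()
        sd = resid.std(ddof=1)
        resid = resid / sd if sd > 0 else resid
        x[i] = mean + resid * (config.low_cv * mean)

    # background (null) gene sets over the remaining genes
    sets = dict(planted_sets)
    background = genes[len(planted_genes):]
    n_null = config.n_gene_sets - config.n_planted_sets
    for s in range(n_null):
        members = rng.choice(background, size=min(config.set_size, len(background)),
                             replace=False)
        sets[f"NULL_SET_{s + 1}"] = list(members)

    matrix = pd.DataFrame(x, index=genes, columns=samples)
    truth = {
        "planted_sets": list(planted_sets),
        "planted_genes": planted_genes,
        "low_cv_genes": low_cv_genes,
        "diversity": pd.Series(div, index=samples),
    }
    return matrix, GeneSetCollection(sets), truth


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Two-class survival cohort settings.

    Event times are exponential with baseline median ~14 months
    (hazard 0.05 / month) for class 1 and hazard x ``hazard_ratio`` for
    class 2; censoring is independent and uniform on (0, event time) for
    the configured fraction of patients.  ``class_separation`` shifts the
    signature-gene expression of class 2 in units of the gene noise sd.
    """

    n_patients: int = 50
    n_signature_genes: int = 23
    class_separation: float = 3.0
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.05
    censoring_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least two patients")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be > 0")


@dataclass
class SurvivalCohort:
    expression: pd.DataFrame          # signature genes x patients
    records: list[SurvivalRecord]
    labels: pd.Series                 # true class per patient (1 or 2)


def simulate_cohort(config: CohortSimConfig) -> tuple[SurvivalCohort, pd.Series]:
    """Simulate a two-class cohort; returns (cohort, true class labels)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patients = [f"P{i + 1:03d}" for i in range(n)]
    classes = np.ones(n, dtype=int)
    classes[rng.permutation(n)[: n // 2]] = 2

    genes = [f"SIG{i + 1:03d}" for i in range(config.n_signature_genes)]
    x = rng.normal(8.0, 1.0, size=(config.n_signature_genes, n))
    # gene-specific signed class effect: a signature is an expression
    # pattern, not a uniform offset (which correlation distance ignores)
    signs = rng.choice([-1.0, 1.0], size=config.n_signature_genes)
    x[:, classes == 2] += (config.class_separation * signs)[:, None]

    hazards = np.where(classes == 2,
                       config.baseline_hazard * config.hazard_ratio,
                       config.baseline_hazard)
    event_times = rng.exponential(1.0 / hazards)
    censored = rng.random(n) < config.censoring_fraction
    times = np.where(censored, rng.uniform(0.0, event_times), event_times)
    times = np.maximum(times, 1e-6)
    events = (~censored).astype(int)

    records = [SurvivalRecord(p, float(t), int(e))
               for p, t, e in zip(patients, times, events)]
    labels = pd.Series(classes, index=patients, name="true_class")
    cohort = SurvivalCohort(
        expression=pd.DataFrame(x, index=genes, columns=patients),
        records=records,
        labels=labels,
    )
    return cohort, labels
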