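# tilscape

Integrative analysis of the immune landscape of multi-region tumor
samples: T-cell receptor (TCRB) repertoire statistics, somatic-mutation
phylogeny, single-sample pathway-activity scoring, and survival
stratification by a stable immune gene signature — together with seeded
synthetic-data generators so every stage runs and is testable without any
external download.

The package is aimed at studies that profile several spatially separated
samples from the same tumor (for example a primary mass and its
metastasis) with immune-repertoire sequencing, exome sequencing and
expression arrays, and ask how tumor-infiltrating lymphocyte (TIL)
heterogeneity relates to mutational heterogeneity and to the local immune
microenvironment.

## What it computes

**Repertoire** (`tilscape.repertoire`). Clonotypes are keyed by
(CDR3 nucleotide sequence, V segment, J segment). Per sample the
Shannon-Wiener diversity index

    H = - Σ_i p_i ln p_i        (nats, p_i = clonotype frequencies)

quantifies TIL diversity. The TOP-N most expanded clones (N = 250 by
default) drive two overlap statistics between samples A and B:

* TOP-N/TOP-N: `100 · |topN(A) ∩ topN(B)| / min(N, |topN(A)|, |topN(B)|)`
* TOP-N/full: `100 · |topN(A) ∩ repertoire(B)| / |topN(A)|` (asymmetric)

plus cumulative TOP-N frequency curves, clone-frequency spectra, clones
common to all samples, pooled-TOP-N detectability in peripheral blood,
and Kruskal-Wallis / Wilcoxon rank-sum comparisons across samples
(rank-sum p-values are exact for combined n ≤ 10).

**Somatic phylogeny** (`tilscape.somatic_phylogeny`). Candidate variant
calls pass a filtering cascade (germline coverage ≥ 10× with zero
non-reference reads, protein-altering annotation, and removal of
clustered calls within 100 bp as alignment artifacts), are classified as
shared / mass-specific / region-unique across tumor masses, and feed an
exact maximum-parsimony tree over the samples with a germline (all-absent)
root: branch-and-bound search over rooted topologies with Fitch small
parsimony, integer branch lengths equal to the per-edge mutation changes.

**Pathway enrichment** (`tilscape.pathway_enrichment`). A from-scratch
GSVA-style score: per-gene Gaussian-kernel CDF statistics (bandwidth
s/4), per-sample ranking with symmetric rank weights, and a weighted
random walk per gene set (τ = 1, max-difference scoring). The screen
correlates each pathway's score profile with per-sample repertoire
diversity (Spearman, exact p for n ≤ 10) and flags pathways with
ρ > 0.75.

**Signature & survival** (`tilscape.signature_survival`). From the genes
of screen-passing pathways, those with log2 coefficient of variation
below −5.5 across the multi-region samples form the stable
("constant immune") signature. Patients are stratified by hierarchical
clustering (1 − Pearson distance, average linkage, k = 2) of the
signature expression, and the two clusters are compared by Kaplan-Meier
curves and the log-rank test.

**Synthetic data** (`tilscape.synthetic_data`). Seeded generators for
(a) Zipf-abundance repertoires with tunable inter-sample sharing and one
hyperexpanded public clone, (b) trunk-and-branch mutation matrices from a
planted phylogeny (defaults 9 trunk / 22 + 13 branch mutations) with
optional dropout, (c) expression with pathway-structured,
diversity-correlated signal and exact low-CV genes, (d) two-class
survival cohorts. All return the ground truth used by the tests.

## Worked example

```python
from tilscape import repertoire as rep, somatic_phylogeny as sp, synthetic_data as sd

tables, truth = sd.simulate_repertoires(
    sd.RepertoireSimConfig(seed=1, n_tumor_samples=4, clones_per_sample=2000))
tumor = [t for t in tables if t.sample_id != "blood"]
for t in tumor:
    d = rep.shannon_diversity(t)
    print(f"{t.sample_id}: ShannonDI = {d.shannon_di:.3f} over {d.richness} clonotypes")

overlap = rep.pairwise_topn_overlap(tumor, 250)
print("TOP250 overlap (%, T01 vs T02):", round(overlap.values.loc["T01", "T02"], 1))

matrix, mtruth = sd.simulate_mutation_matrix(sd.MutationSimConfig(seed=1))
labels, counts = sp.classify_mutations(matrix, mtruth["mass_of_sample"])
tree = sp.build_parsimony_tree(matrix)
print("mutation classes:", counts)
print("parsimony score:", tree.score)
print("newick:", tree.newick())
```

prints

```
T01: ShannonDI = 5.165 over 2000 clonotypes
T02: ShannonDI = 5.204 over 2000 clonotypes
T03: ShannonDI = 5.136 over 2000 clonotypes
T04: ShannonDI = 5.194 over 2000 clonotypes
TOP250 overlap (%, T01 vs T02): 18.8
mutation classes: {'mass_specific': 35, 'shared': 9}
parsimony score: 44
newick: (((((((T1:0,T2:0):0,T3:0):0,T4:0):0,T5:0):0,T6:0):13,((O1:0,O2:0):0,O3:0):22):9)germline;
```

Each tumor sample's diversity sits near ln(2000) ≈ 7.6 minus the penalty
for clone expansion; the 18.8% TOP250 overlap reflects the configured
15% tumor-tumor sharing plus the shared expanded clones. The default
planted mutation matrix yields 9 mutations shared between the two masses
and 35 tumor-specific ones; the parsimony tree re-derives the planted
trunk lengths (9 on the root edge, 22 and 13 on the mass branches).

A command-line interface mirrors the library:
`tilscape simulate all`, `tilscape repertoire`, `tilscape mutations`,
`tilscape enrich`, `tilscape signature`, `tilscape survive`, and
`tilscape all` for an end-to-end run on freshly simulated data.

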