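# Methods

This note documents the models and procedures implemented in `tilscape`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical conventions that matter for
reproducibility.

## Clonotypes and repertoire statistics

A clonotype is identified by the triple (CDR3 nucleotide sequence,
V segment, J segment); amino-acid-level keying (`key_level="aa"`) is
available for convergent-recombination analyses. Counts are
authoritative: on load, duplicate rows are merged by key and frequencies
are recomputed as count / total, so stored frequency columns that
disagree with the counts are overridden (with a warning). All statistics
are invariant to pre-merging of duplicated rows.

Diversity is the Shannon-Wiener index H = −Σ p ln p in nats, the
ecological convention; no normalization by richness is applied. Zero
frequencies contribute nothing; an empty repertoire has no defined
diversity and is rejected.

TOP-N selection (default N = 250) breaks count ties deterministically by
(higher count, lexicographic CDR3 nt, V segment). Overlap denominators
use min(N, available clones) so that samples with fewer than N clonotypes
remain comparable. The common-clone table ranks the intersection of all
samples by mean per-sample frequency (maximum available as an option),
since "most abundant across samples" admits several readings. Default
frequency-spectrum class boundaries are 1e-5, 1e-4, 1e-3, 1e-2 on (0, 1];
they are configurable.

Sample comparisons: the overlap-difference test is a Kruskal-Wallis test
whose g-th group is the off-diagonal overlap values of sample g (an
all-equal input returns H = 0, p = 1 by convention). The two-group
diversity comparison is a two-sided Wilcoxon rank-sum test with midranks;
for combined n ≤ 10 the p-value is exact by full enumeration of group
assignments (which handles ties correctly), otherwise a normal
approximation with tie and continuity correction is used.

## Expression preprocessing

Expression values are treated as log2-scale intensities throughout.
Quantile normalization maps every sample to the mean quantile vector;
ties within a sample receive the mean of the quantile values they span
(the `normalizeQuantiles` convention). After normalization all columns
hold exactly one multiset of values, which the tests assert.

## Variant filtering, classification, and phylogeny

The filtering cascade retains a call when the matched germline has
≥ 10× coverage with zero non-reference reads, the annotation is
protein-altering (missense, nonsense/stopgain, stoploss, frameshift and
non-frameshift indels, canonical splice), and the call is not part of a
cluster. The cluster rule — applied after the other three, so that an
already-rejected neighbor cannot condemn a good call — rejects **all**
calls when two or more survivors lie within 100 bp on one contig,
treating multi-variant clusters as alignment artifacts. The window is
configurable; the retained set is independent of input order, and every
rejection carries its reason(s).

Classification across tumor masses: *shared* = present in ≥ 1 sample of
every mass; *region-unique* = present in exactly one sample;
*mass-specific* = present in ≥ 2 samples of exactly one mass. With three
or more masses these three labels are not exhaustive, so mutations in
more than one but not all masses are labeled *partially_shared*; with two
masses (the designed use) this label cannot occur.

The phylogeny is an exact maximum-parsimony tree over rooted binary
topologies on the samples with an implicit germline leaf fixed to the
all-absent state. Search is stepwise leaf addition with branch-and-bound:
the Fitch length of a partial tree never decreases when a leaf is added,
so partial scores are valid lower bounds; a greedy pass provides the
initial incumbent. All optimal topologies are collected and the one with
the lexicographically smallest canonical Newick string (children ordered
by their Newick strings) is returned, making ties deterministic. The
exact search is limited to 12 samples; beyond that the function refuses
rather than silently switching to a heuristic. Samples without any
detected mutation should be dropped before tree building
(`MutationMatrix.drop_empty_samples`), since an all-zero leaf is
indistinguishable from germline.

Branch lengths are per-edge change counts under the deterministic
uniform Fitch downpass (a node keeps the parent state whenever its
first-pass set allows it). For binary characters this yields a single
most-parsimonious reconstruction whose total equals the parsimony score;
it is the package's fixed convention for resolving reconstruction
ambiguity (alternatives such as ACCTRAN distribute ambiguous changes
differently but never change the score).

## Single-sample pathway scores and the diversity screen

The pathway score follows the GSVA recipe for continuous expression.
Per gene i and sample j the kernel statistic is

    z_ij = (1/n) Σ_k Φ((x_ij − x_ik) / h_i),    h_i = s_i / 4

with s_i the gene's across-sample standard deviation (ddof = 1); genes
with zero variance receive 0.5 everywhere. Within each sample, genes are
ranked by decreasing z (stable order on ties) and given symmetric rank
weights r = |p/2 − rank|. For a set G the walk over the ranked list gains
r^τ / Σ_G r^τ at member genes (τ = 1) and loses 1/(p − |G|) elsewhere;
the score is max(0, max deviation) + min(0, min deviation)
("max-difference"). Because deviations decline linearly between member
genes, only positions adjacent to members need evaluation, making the
walk O(|G|) per set and sample. Sets with fewer than 5 mapped genes are
skipped with a warning; unmapped genes are dropped with a log line. The
implementation agrees with the independent gseapy port of GSVA to within
0.05 absolute score (correlation > 0.999) on random data, which the test
suite checks.

Spearman correlations use midranks. For n ≤ 10 the two-sided p-value is
exact: without ties, the null distribution of Σd² is precomputed by a
subset-sum dynamic program and cached per n (O(2^n · n · max d²), instant
for n ≤ 10); with ties, all permutations are enumerated in vectorized
batches. For n > 10 the usual t approximation applies. The screen flags
pathways with ρ strictly above the threshold (default 0.75); p-values
are reported but deliberately not used for thresholding, and no
multiple-testing correction is applied — this mirrors the screening rule
the pipeline reproduces, and its false-positive consequences are
discussed below.

## Signature extraction and survival

The candidate pool is the union of the screen-passing pathways' genes
present on the array. Per gene, CV = sd/mean on the normalized log2
scale (a −5.5 log2-CV cutoff corresponds to CV ≈ 0.022, which is only
plausible on log-scale intensities); genes with log2(CV) < cutoff are
selected, and a zero-variance gene (CV = 0) is always selected. The
cutoff is a configured constant; `knee_point` (maximum distance to the
chord of the sorted log2-CV curve) is provided to re-estimate it on new
datasets but is never applied implicitly.

Patients are clustered on z-scored signature genes with
1 − Pearson-correlation distance and average linkage, cut at k = 2
(Euclidean/Ward available). Labels are renumbered by first appearance in
column order so runs are deterministic. Kaplan-Meier curves and the
two-group log-rank test come from lifelines; the log-rank statistic is
the standard observed-vs-expected form with hypergeometric variance and
a 1-df chi-square p-value.

## Synthetic generators: what they emulate, and what they do not

All generators are pure functions of (config, seed) with one explicit
RNG stream per call.

*Repertoires.* Clone abundances are i.i.d. draws from a Zipf law
(scipy's `zipfian`, exponent 1.5, truncated at `clones_per_sample`),
giving the right-skewed, few-dominant-clones structure of TIL data.
Sharing is realized through clone pools: every tumor holds a common pool
of size (sharing rate × clones per sample), blood holds a sub-pool, and
— critically — a shared clone carries **one** abundance draw used in
every sample, so expanded clones are expanded everywhere and TOP-N
overlap concentrates near the nominal sharing rate. One public clone is
pinned to a configured blood frequency (default 10%) and dominates every
sample. CDR3 sequences are arbitrary unique nucleotide strings with a
deterministic codon translation; no sequence-level realism (V(D)J
biology, PCR bias, sequencing error) is modeled, so passing tests say
nothing about error-correction or alignment stages.

*Mutation matrices.* A planted tree — two masses joined at a germline
root, random binary subtree per mass — carries configurable mutation
budgets: trunk (default 9), mass branches (defaults 22 and 13), optional
per-leaf private and per-internal-edge mutations. Presence follows the
tree exactly; dropout flips 1→0 independently, and mutations dropped
from every sample are removed (they are unobservable). With per-edge
budgets ≥ 1 the matrix is a perfect phylogeny whose unique
most-parsimonious topology is the planted one, which the recovery tests
exploit. Homoplasy, copy-number loss and subclonal fractions are not
modeled.

*Expression.* Background genes are i.i.d. Gaussian (mean 8, sd 1, a
log2-intensity scale). Planted-set genes add effect × standardized
diversity + noise (defaults 2.0 and 1.0, i.e. gene-level correlation
≈ 0.9). Low-CV genes are spread round-robin across the planted sets and
their residuals are rescaled to an exact sample CV of 0.005
(log2 ≈ −7.6), so selection at −5.5 is guaranteed by construction.
Gene-gene correlation structure beyond the planted sets is absent.

*Cohorts.* Two balanced latent classes; signature genes receive a
gene-specific signed shift of ±separation (default 3 sd). A uniform
(all-genes-up) shift would be mathematically invisible to the
correlation-based clustering distance, which centers each patient's
profile — the signed pattern is both necessary and the realistic reading
of an expression signature. Event times are exponential (baseline hazard
0.05/month, median ≈ 14 months, in the range of glioblastoma survival)
with a class hazard ratio (default 3); censoring is independent and
uniform on (0, event time) for the configured fraction (default 30%).
Proportional hazards hold exactly; no covariates or competing risks.

## Problem sizes and calibration behavior

The test suite and acceptance script run everything at desk scale:
oracle-equivalence sweeps use 1,000 random instances per operation;
parsimony recovery uses 100 matrices of up to 8 samples; the screen
suites use 10-sample, 2,000-gene, 200-set replicates; survival suites use
n = 50 cohorts with 200 power and 400 null replicates. Under these
conditions the null log-rank rejection rate sits at the nominal 5% and
the end-to-end survival recovery exceeds 80%.

One property deserves an explicit caveat: with 10 samples the exact
Spearman null gives P(ρ > 0.75) ≈ 0.0075 per pathway, so a screen of 200
null pathways flags at least one false positive in roughly four out of
five datasets. That is an inherent property of the ρ-threshold rule
without multiplicity control, not an implementation artifact: on null
data the *planted* sets almost never pass (≈ 96% of replicates), but
"no pathway at all passes" holds only in ~15-25% of replicates. Users
screening hundreds of pathways on ten samples should treat isolated hits
near the threshold with caution.

## Known limitations

- The exact parsimony search is exponential; 12 samples is the hard cap
  and highly homoplastic matrices near the cap can be slow.
- Exact Spearman p-values with ties at n = 9-10 enumerate up to 3.6M
  permutations; the tieless path (the common case) is O(1) after a
  cached DP.
- The survival module implements two-group stratification only — no Cox
  regression, covariate adjustment, or competing risks.
- Variant input is a pre-tabulated call table; alignment, raw calling
  and annotation are upstream of this package by design.
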