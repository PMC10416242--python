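# Methods

This note records the statistical model behind `umbranet`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter for
reproducing results.

## The estimation problem

A microbiome survey yields a samples × taxa count matrix that is
*compositional* (sequencing depth is arbitrary, so only relative
information is meaningful) and *sparse* (most counts are zero). Naive
correlation networks on such data are dominated by closure artifacts.
`umbranet` therefore works on the centered log-ratio (CLR) scale and
estimates a *conditional* dependence graph: an edge joins two taxa whose
CLR abundances remain associated after controlling for all other taxa.

### CLR transform

With pseudocount c (default 1, the customary choice for zero-laden OTU
tables):

    clr(x)_j = log(x_j + c) − (1/p) Σ_k log(x_k + c)

Rows sum to zero by construction (enforced to 1e-8). The transform is
applied to raw counts, not proportions; row centering makes the two
equivalent up to the pseudocount's depth interaction, which is the
standard compromise.

### Meinshausen–Bühlmann neighborhood selection

For each taxon j, the standardized CLR column z_j is lasso-regressed on
all other standardized columns:

    min_β  (1/2n) ‖z_j − Z_{−j} β‖² + λ ‖β‖₁

(coordinate descent via scikit-learn, tolerance 1e-6, max 50 000
iterations; non-convergence raises an error naming the node). The
neighborhood of j is the set of predictors with nonzero coefficients.
Neighborhoods are symmetrized with the OR rule by default (edge if
either side selects the other); AND is available. OR is the more
inclusive convention and preserves more structure for the downstream
degradation analysis; the two rules nest (AND ⊆ OR), and both are
exposed. Edges are unweighted; an edge sign (sign of the coefficient
sum) is carried as metadata only.

With both response and predictors standardized, the smallest penalty
producing all-empty neighborhoods is the maximum absolute off-diagonal
correlation; the default penalty path is 20 log-spaced values from that
null penalty down to 1/100 of it.

### StARS penalty selection

For each penalty on the path, networks are refitted on N = 20 row
subsamples of size b = ⌊min(0.8, 10√n/n) · n⌋ drawn without
replacement. With p̂_e the selection frequency of edge e across
subsamples, the instability at a penalty is

    ξ(λ) = 2 · mean_e p̂_e (1 − p̂_e)   over all p(p−1)/2 node pairs,

which is bounded by 1/2. The curve is monotonized by a running supremum
from the sparse end of the path, and the selected penalty is the
smallest (densest graph) whose monotonized instability stays ≤ 0.05. If
even the sparsest penalty exceeds the threshold the sparsest penalty is
returned. Subsampling is seeded; a fit is deterministic given data,
path and seed.

## Permutation bootstrap edge filter

Each taxon's abundance vector is permuted independently across samples,
conserving every marginal while destroying sample–abundance
association. B permuted tables (default 5000) are re-fitted and the
recurrence of each *original* edge is counted. An edge recurring in
more than ⌊αB⌋ networks (250 at the defaults) is judged consistent with
the permutation null and removed; nodes are never removed, so isolates
can appear.

By default the original network's StARS-selected penalty is reused in
every replicate rather than re-running stability selection 5000 times.
Re-selection per replicate is available (`reuse_penalty=False`) but is
computationally disproportionate for large B and answers a slightly
different question (stability of the whole selection procedure rather
than of the edges at the chosen sparsity). Replicate seeds are derived
from the master seed by counter; replicates that fail to converge are
dropped, logged, and the threshold scales with the effective B.

The filter's calibration is checked on association-free synthetic data:
the observed retained fraction of original edges is compared with the
retention probability predicted edge-by-edge from an independent second
bootstrap run, P(Bin(B, p̂) ≤ ⌊αB⌋), and the two agree within binomial
noise (acceptance suite and `scripts/acceptance.py`).

## Hub scores and centralities

The hub score is the Kleinberg/HITS score. On an undirected graph hub
and authority scores coincide with the principal (Perron) eigenvector
of the adjacency matrix A. The textbook HITS iteration squares the
matrix (A·Aᵀ = A²), which is blind to the sign of the spectrum: on
bipartite components the top eigenspace of A² is two-dimensional and a
power iteration started from ones stalls inside it (a 3-leaf star would
score every node 1). Power iteration therefore runs on A + I — same
eigenvectors, but the Perron branch is strictly dominant — from a fixed
all-ones start vector to tolerance 1e-10, with scores rescaled so the
maximum is 1. Isolated nodes score exactly 0; an edgeless network
scores all-zero with a warning. Degenerate top eigenspaces (e.g. tied
components) are resolved deterministically by the ones start vector.
The implementation is verified against dense eigendecomposition on
thousands of random graphs of ≤ 15 nodes.

Other centralities follow the conventions recorded in the output
metadata: degree is the incident edge count; betweenness is the
unnormalized Brandes pair-dependency sum with each unordered pair
counted once; closeness is computed within each connected component as
(n_c − 1)/Σ distances (so it lies in [0, 1]); isolates get 0 for
everything. Top-k hub tables (k = 20 by default) sort by score with
ties broken by node identifier, carry the full seven-rank lineage with
`MDM` where flagged, and report the count of MDM rows per rank.

## MDM relabeling and taxonomy handling

The keyword vocabulary marking an unknown classification is
deliberately open-ended: the default set is {"uncultured", "unknown",
"unidentified", "NA", "unknown_family", "Incertae Sedis", "metagenome",
empty label}, user-extensible. Matching strips QIIME2 rank prefixes
(`d__` …), lowercases, and maps underscores to spaces; keywords of two
characters or fewer ("NA", the empty label) are matched exactly —
substring matching would flag half of bacteriology ("Cya**na**...") —
while longer keywords are substring-matched. Missing trailing ranks in
short lineages are padded with the empty label and hence treated as
unassigned. The first matching rank and all ranks below it become
`MDM`; the flags are downward monotone by construction and
property-tested.

Rank aggregation sums taxa sharing the identical lineage prefix down to
the target rank (phylum–genus; the reference networks stop at genus).
Node identity is the full prefix of display labels, so an `MDM` label
does not merge across distinct known parents — `Proteobacteria;MDM` and
`Cyanobacteria;MDM` are different genus-level nodes — but fully unknown
lineages with identical prefixes do merge, which is the only consistent
choice once labels are the sole identity. Total counts are conserved
exactly. Domain-unassigned taxa are kept (as MDM), not dropped.

Filtering retains taxa present (nonzero) in at least `min_samples`
samples (2 for small amplicon surveys; 15/24 = 62.5% and 34/55 = 61.8%
are the reference shotgun settings and are reported by
`FilterConfig.prevalence_percent`), excludes domain Eukaryota by
default, and removes any taxon labeled "Chloroplast" at order, family
or genus.

## Degradation analysis

Given a network and the set of MDM nodes at the analysis rank, three
objects are compared: the original network, the induced subgraph
without the MDM nodes, and `n_reps` = 100 null networks each removing a
uniformly random subset of *known* nodes of the same size (so network
order is matched exactly and metric changes cannot be explained by size
alone). Per-node degree, betweenness and closeness distributions are
compared for the three pairs (original vs no-MDM, original vs null,
no-MDM vs null) with a two-sided Wilcoxon rank-sum test; null
replicates are pooled into one distribution per metric, which yields a
single p-value per comparison rather than a distribution of per-replicate
p-values. An unpaired test is the only coherent choice because the node
sets differ across networks.

The rank-sum test uses midranks for ties. For group sizes of at most 8
each, the null distribution of U is enumerated exactly over all
C(n₁+n₂, n₁) rank assignments and the two-sided p is twice the smaller
tail, capped at 1; larger groups use the normal approximation with
continuity correction and the standard tie correction. Two samples
whose pooled values are all identical give p = 1 by convention.
P-values map to the conventional bands ns / * / ** / *** / ****
(p > 0.05 / ≤ 0.05 / ≤ 0.01 / ≤ 0.001 / ≤ 0.0001). No multiple-testing
correction is applied across ranks or metrics.

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions
under which the pipeline's recovery properties are demonstrated.

**Association structure.** A sparse precision matrix Ω over p taxa with
unit diagonal and off-diagonal −0.5 on the chosen edge set (band, hub
or Erdős–Rényi support at a requested density; at least one edge).
Negative precision entries give positive partial correlations —
cooperative co-occurrence, the dominant mode in mat communities. The
diagonal is loaded uniformly until the condition number is at most the
target (default 100), which guarantees positive definiteness while
keeping partial correlations strong (≈ 0.5 for a band graph); the
loading amount is recorded on the ground-truth object.

**Counts.** Logistic-normal-multinomial: per sample a latent Gaussian
z ~ N(0, Ω⁻¹), composition softmax(z), depth uniform on the configured
range (default 2 000–10 000 reads, modest amplicon depths), counts
multinomial. Row sums equal drawn depths exactly. This is the
compositional model whose CLR-scale dependence structure neighborhood
selection targets, so support-recovery tests are meaningful rather than
merely convenient. The chosen defaults let a 20-taxon band graph be
recovered with F1 ≥ 0.8 from 1000 samples (≥ 50 samples per taxon), the
package's end-to-end parameter-recovery surface.

**Taxonomy.** Lineages follow a nested hierarchy (label pools per rank
grow geometrically with depth, so phylum labels are shared and
aggregation is non-trivial); independently per rank, with the
configured per-rank probability (default rising from 5% at domain to
90% at species, the qualitative shape of real classifier output), the
label is replaced by one of the unknown-classification keywords.

**What it does not emulate**: raw reads, chimeras, PCR/primer bias,
over-dispersion beyond the logistic-normal, phylogenetic signal in the
association structure, and temporal/diel sample structure. Passing
recovery tests therefore show that the estimator chain is correct under
its own model assumptions, not that real communities meet those
assumptions.

## Numerical and reproducibility conventions

- All stochastic stages take explicit seeds; child seeds derive from a
  master seed via `numpy.random.SeedSequence` spawning (counter-based),
  and are recorded in the run manifest together with artifact SHA-256
  digests. Identical config + seed reproduces every artifact
  byte-for-byte (tested).
- CLR partial correlations of compositional data carry a closure term
  of ≈ +1/(p−1) even for independent taxa; oracle tests account for it
  explicitly.
- Problem sizes in the test and acceptance suites (20 taxa × 1000
  samples for recovery; B = 200 with 10 taxa × 100 samples for
  calibration; 100 null replicates on a 28-node planted-hub fixture)
  are the smallest sizes at which the respective statistical properties
  are stably demonstrable; the library defaults remain at the reference
  values (B = 5000, α = 0.05, 100 null replicates, top-20 hubs).

## Known limitations

- Only the MB estimator is provided (no SparCC/graphical-lasso
  variants); edges are binary.
- Exact Wilcoxon enumeration is limited to groups of ≤ 8; beyond that
  the normal approximation is used even under heavy ties.
- BIOM support covers the JSON-based 1.0 format, not HDF5 BIOM 2.x.
- With very few taxa (p ≲ 10) the CLR closure distortion is large
  relative to real signal and StARS legitimately favors very sparse or
  empty graphs; rank-aggregated tables should keep enough nodes.
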