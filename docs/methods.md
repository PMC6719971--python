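# Methods

`clustermod` re-implements, as a tested and reusable pipeline, a hybrid
strategy for discovering and validating plant biosynthetic gene clusters
(BGCs) and for finding the co-expression modules, hub genes and candidate
upstream regulators co-regulated with them.  This note records the models,
the tunable parameters and their defaults, the numerical choices, and the
places where the design was genuinely open.

## The validation model

Plant BGCs are runs of physically adjacent, non-homologous genes encoding
different enzymes of one secondary-metabolite pathway; functionally
characterized clusters typically contain 3–10 genes and almost always a
cytochrome P450.  The pipeline turns these observations into four filters
applied in order of increasing data cost:

1. **Geometry (scan).**  Maximal runs of enzyme-annotated genes in which
   consecutive enzyme genes are at most `max_gap` bp apart (default 20 kb)
   with at most `max_intervening` non-enzyme genes between them (default 3),
   emitted when the run holds `min_genes`–`max_genes` enzyme genes (defaults
   3–10).  This gap-based scanner is a transparent surrogate for dedicated
   genome-mining tools, whose internal HMM/domain logic is out of scope;
   externally predicted candidate lists can be ingested instead and flow
   through the same downstream filters.
2. **Co-pathway.**  A candidate passes when some metabolic pathway (a) is
   shared by at least two member genes and (b) the members sharing it are
   classified into at least two distinct reactions.  Both criteria are
   evaluated *per shared pathway*: pooling reactions across unrelated
   pathways would pass clusters with no pathway in common.  A cluster-wide
   reading of (b) is available (`per_pathway=False`) since the two readings
   are not distinguishable from the published description.
3. **Non-homology.**  Members must not all share a single protein-family
   label.  Shared family ids are the homology proxy; no pairwise alignment
   is attempted.  The screen runs after the co-pathway filter and before the
   expression filter, so the reported funnel counts are (scanned,
   co-pathway pass, co-expression pass).
4. **Co-expression.**  Pearson correlation r is computed for every unordered
   member pair; the cluster passes when at least `min_fraction` (default
   0.5) of pairs lie at or above the 95th percentile of the correlation
   distribution over *all* metabolic gene pairs (the empirical null) and are
   individually significant (two-sided p < 0.05, t transform with n − 2 df).
   The source description gives both the percentile threshold and the
   p-value count without stating how they combine; the conjunction plus a
   pair-fraction rule is this package's documented quantification, with both
   pieces configurable.  The null uses the signed r distribution (not |r|),
   percentile by linear interpolation between order statistics (nearest-rank
   differs at small n), and seeded uniform subsampling above
   `max_pairs = 2,000,000` pairs.

## The network model

The co-expression network follows the standard weighted gene co-expression
(WGCNA-style) recipe, implemented from scratch:

- **Adjacency**: `a_ij = |cor(x_i, x_j)|^β` (unsigned, the default) or
  `((1 + cor)/2)^β` (signed).  The default β = 6 is the conventional
  unsigned choice; `power: auto` sweeps β ∈ {1..10, 12..20} and returns the
  smallest power whose scale-free topology fit (signed R² of the log-log
  degree regression, negated for a positive slope) reaches
  `scale_free_fit_target` (0.8), falling back to the best fit with a
  warning.
- **Topological overlap**:
  `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, diagonal 1.
- **Module detection**: average-linkage hierarchical clustering of
  `1 − TOM`.  A cluster qualifies as a module when it holds at least
  `min_module_size` genes (default 30) *and* its mean internal
  dissimilarity is below `module_cohesion` (default 0.9) times the mean
  off-diagonal dissimilarity of the whole matrix.  With a numeric
  `cut_height` a single static cut is made; with the default `auto` the
  package scans candidate heights across the dendrogram and keeps the cut
  maximizing a coverage-weighted mean silhouette over the qualifying
  clusters.  A fixed near-top cut proved unstable under the latent-factor
  model: background genes have low connectivity k, which inflates their
  topological overlap with large modules (the TOM denominator is
  min(k_i, k_j)), so unstructured genes attach just below any near-top cut
  and bridge otherwise well-separated modules.  The silhouette-selected cut
  keeps modules pure, and the cohesion gate rejects the incoherent near-top
  clusters that pure-noise data produces, leaving those genes in the
  reserved `unassigned` (grey) set.
- **Eigengenes**: rows standardized per gene; the eigengene is the unit-norm
  first right-singular vector over samples, sign-aligned to the mean
  standardized member profile (first-nonzero-positive when the alignment is
  exactly ambiguous, e.g. two anti-correlated halves); `var_explained` is
  the first singular value's share of total variance.
- **Merging**: the closest module pair with eigengene dissimilarity
  `1 − cor(ME_i, ME_j) < merge_cut_height` (default 0.25) is merged and
  eigengenes recomputed before re-evaluation, until no pair qualifies.
  Labels are reassigned by decreasing size (M1, M2, ...).
- **Blocks**: above `max_block_size` genes (default 8000) the matrix is
  split by k-means on standardized profiles (fixed random state), modules
  detected per block and reconciled by the same eigengene merging, so the
  stage stays deterministic.
- **Module–trait**: every member gene of a validated cluster contributes its
  expression profile as one trait (`<cluster>:<gene>`); a (module, trait)
  cell is significant when p < 0.05 AND r² > 0.5, with the sign of r
  reported.  R² is read as the squared Pearson correlation of eigengene and
  trait (|r| > 0.7071); if the intended reading was |r| > 0.5 the rule is a
  single configurable threshold (`traits.r2_min`).

## Hubs, regulators, enrichment

Module membership MM = |cor(gene, ME)| and gene significance GS =
|cor(gene, trait)| both use absolute values.  The GS trait policy defaults
to the maximum across the BGC trait set (hubs are evaluated against the
cluster traits collectively); a single named trait is available.
Intramodular connectivity k_within is the sum of a gene's adjacency weights
to same-module genes.  Hubs satisfy MM > 0.8 and GS > 0.2, ranked by
k_within descending (ties by MM, then gene id) and truncated to the top 30
per module; all three knobs are configurable.

Regulator analysis computes the correlation matrix between a user-supplied
regulator gene set (e.g. bHLH DPF or IGPS orthologs) and the members of each
validated cluster; a regulator is flagged "highly co-expressed" when at
least half its entries exceed the co-expression null threshold — this
package's quantification of an otherwise qualitative heat-map reading, and
configurable.

Term enrichment is a hypergeometric upper tail per term with
Benjamini–Hochberg correction across tested terms, keeping rows with
p < 1e-4 and FDR < 0.05.  Ontology databases themselves are out of scope;
the pipeline enriches against the enzyme-class labels in the gene table and
accepts any gene→term table through the library/CLI.

## The synthetic generator

The generator emulates a two-species co-culture allelopathy study design:
16 samples per species = 4 time points (3 h, 3 d, 7 d, 14 d) × 2 conditions
(mono-culture / co-culture) × 2 replicates.  Expression follows a
latent-factor model: each planted module and each co-expressed planted
cluster owns a standardized latent factor over samples; member genes are
`loading · factor + ε`, ε ~ N(0, noise_sd²) (default noise_sd 0.3), and
background genes are unit-variance noise.  A module may be *trait-linked*
to a cluster: its factor is generated correlated with the cluster's factor
at a stated r, the generative analogue of a module–trait association.
Values are mapped to a non-negative FPKM-like scale by a per-gene affine
transform (`base · (1 + 0.15 z)`, base ~ U(5, 50)): since every downstream
statistic is a Pearson correlation, an affine map preserves the analysis
exactly, whereas an exponential map would blur the exact limit properties
(noiseless within-cluster r = 1 holds for *unequal* loadings only under an
affine map).  Cluster blocks are placed with 0.5–2.5 kb intergenic gaps;
all other genes are 25–40 kb apart, so background enzyme genes cannot form
runs under the default scanner geometry.  Decoy clusters each violate
exactly one validation criterion: same pathway but one reaction
(`no_copathway`), independent member profiles (`no_coexpression`), or one
shared protein family (`homologous`).  A single RNG stream keyed by the
scenario seed makes every bundle byte-reproducible.

What the generator does *not* emulate: count noise and library-size effects
(no negative-binomial layer — the analysis is correlation-based on
FPKM-like values), temporal autocorrelation in the factors (samples are
exchangeable), overlapping module membership, and genome-scale gene counts.
Passing recovery tests therefore demonstrates correctness of the method's
logic under its own modelling assumptions, not performance on real
RNA-seq libraries, where normalization quality and unmodelled correlation
structure dominate.

## Problem sizes and numerics

Test and benchmark scenarios use 280–560 genes, 16 samples, modules of
60–120 genes, clusters of 3–6 genes; recovery statistics are Monte-Carlo
estimates over 10–20 seeds.  These sizes make every matrix operation exact
and fast while keeping the planted structure at realistic signal-to-noise
(within-module correlations ≈ 0.85–0.9, null correlation sd ≈ 0.26 at 16
samples).  Degenerate inputs are handled explicitly: zero-variance genes
are excluded from networks and pair counts with a warning; an all-constant
module is an error; correlations are clipped to [−1, 1] before the t
transform; the stochastic subsample of the PCC null is seeded and skipped
entirely when the pair count fits in `max_pairs`.

## Known limitations

- The scanner is a geometric stand-in; it will not reproduce the candidate
  sets of HMM-based genome-mining tools on real genomes.
- The non-homology test depends entirely on the quality of the supplied
  protein-family labels.
- The silhouette-selected cut assumes modules are denser than their
  surroundings at some height; heavily nested module hierarchies may be
  merged or split relative to a dynamic-tree-cut reference implementation.
- Cross-species consensus analysis is out of scope; each species is an
  independent invocation.
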