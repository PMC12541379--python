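# Methods

## Representation

A proteome is the unordered multiset (bag) `Phi = {u_1 ... u_m}` of its
proteins' unit embedding vectors. Protein representations are built as
`normalize(mean_pool(residue_matrix))`: mean pooling over residue embeddings,
then scaling to unit norm so conserved proteins with large raw norms do not
dominate the average. Duplicate proteins are kept with multiplicity — family
composition counts weight repeated members. The mean phage representation
(MPR) `phi = (1/m) sum u_i` is *not* re-normalized; its norm is informative
(see below). By the triangle inequality `||phi|| <= 1`, with equality iff all
proteins coincide.

Backends are pluggable objects with a `name`, a fixed `dimension` and
`embed(sequence) -> (L, d)`. The contract requires residue rows only: an
adapter for a transformer pLM must strip begin/end special-token rows before
returning and record that in its metadata (whether a given published pipeline
excluded them is generally not stated, so the choice is surfaced as backend
metadata rather than hidden). The heavy ESM-2 3B adapter (d = 2560, ~24–32 GB
GPU) is loaded on demand only; everything in this repository runs against
deterministic mock backends and the synthetic generator.

Unit-norm postconditions are asserted at 1e-9 in float64; stored data are
float32 on disk (halving storage at d = 2560) and promoted to float64 before
any distance arithmetic, because genus-level MPR distances on real data sit
near 1e-3 — close to float32 resolution after accumulating thousands of
coordinates. Input validation of representations read back from float32
stores uses a correspondingly looser 1e-6.

## Mixture-model theory

The analytic layer treats protein-family memberships as fixed and embeddings
as random with `E[u_i] = alpha_k mu_k`, where `mu_k` is the family direction
and `alpha_k` in [0, 1] its compactness (mean resultant length). Under
independent draws this yields the three expectations quoted in the README:
squared MPR norm (1/m plus a pairwise alignment term), MPR dot product (a
shared-family term `n_k^u n_k^v alpha_k^2` plus a cross-family term damped by
`mu_k' mu_l`), and squared distance via the norm/dot decomposition. The
implementation evaluates the dot product as the bilinear form
`(n_u * alpha)' G (n_v * alpha) / (m_u m_v)` with `G` the direction Gram
matrix — identical to the two-term sum because `mu_k' mu_k = 1`. For `m = 1`
the squared norm is exactly 1 (the pair sum is empty) and is special-cased to
avoid returning `1 + O(1e-16)`.

`alpha_from_kappa` converts a von Mises–Fisher concentration to the
compactness it realizes: `A_d(kappa) = I_{d/2}(kappa) / I_{d/2-1}(kappa)`.
This Bessel ratio is evaluated by a backward continued-fraction recurrence
(`r_nu = 1 / (2 nu / x + r_{nu+1})`, started ~120 orders above
`max(nu, kappa)`), which agrees with direct `scipy.special.ive` evaluation to
1e-12 at moderate dimension and remains finite at d = 2560, where the Bessel
functions themselves underflow. An exact alpha matters: feeding the formulas
a sampled estimate of alpha (1e5 draws gives ~1e-3 noise) introduces a bias
that a 10 000-replicate Monte-Carlo comparison reliably detects. A separate
consistency check (`alpha_empirical`) verifies that the sampler's mean
resultant length matches the analytic value.

`monte_carlo_moments` simulates proteome pairs family-by-family (vectorized
over replicates) and reports formula value, Monte-Carlo mean, standard error
and z-score for each of the three moments. Standard errors are floored at
1e-12 so deterministic quantities compare at float resolution instead of
dividing by ~0.

## Synthetic data generator

The generator reproduces the statistical skeleton the method assumes of real
pLM embeddings — angular protein-family clusters and nested gene-content
sharing — while making no attempt to simulate sequences (it enters the
pipeline at the embedding layer).

* **Families.** K unit directions, drawn uniformly (near-orthogonal in high
  d) or exactly orthogonal on request; the orthogonal regime is where the
  analytic cross-family term vanishes, useful for closed-form tests.
* **Sampling.** von Mises–Fisher via the tangent-normal (Wood) construction:
  the cosine to `mu` by beta-envelope rejection, the tangential part uniform
  in the orthogonal complement. `kappa = 0` reduces to the uniform sphere;
  d = 1 to the two-point distribution. Samples are renormalized to absorb
  rounding.
* **Taxonomy.** Strictly nested family > subfamily > genus labels realized by
  hierarchical sharing of family repertoires: of each genome's
  `repertoire_size` distinct families, fixed fractions are common to its
  family / subfamily / genus (descending, as closer relatives share more gene
  content); remaining slots are private. Proteins are drawn uniformly with
  replacement from the repertoire, so each repertoire entry behaves like a
  functional module represented by several proteins.

Defaults are the documented study conditions: 3 families x 2 subfamilies x
3 genera x 8 genomes (144 genomes), d = 64, K = 200, kappa = 50, seed 11.
The remaining free parameters were fixed once from a small design study and
not revisited: repertoire of 4 family modules per genome, proteome sizes
uniform on [60, 100], shared fractions (0.9, 0.5, 0.25). The rationale:
within-genus MPR noise scales like `sqrt((1 - alpha^2)/m)` while
between-taxon contrast scales like `alpha^2 * (1 - shared)/repertoire`, so a
small repertoire and large proteomes are what give multi-scale structure at
the moderate compactness (`alpha ~ 0.55` at kappa = 50, d = 64) typical of
non-fine-tuned embeddings. Under these conditions mean distances order
strictly as within-genus < within-subfamily < within-family < across-family.

`TaxonomyDesign.separable()` is a deliberately easy regime (kappa = 1e4,
m = 200 fixed, fully genus-shared and cross-family-disjoint repertoires)
whose within/between genus distance distributions have a clean gap; it is the
fixture for threshold-gate tests.

What the generator does **not** emulate: heavy-tailed proteome sizes,
unbalanced taxon sizes, annotation errors (available separately via
`perturb_labels`), anisotropic family clusters, correlated draws within a
genome, or the global anisotropy of real pLM embedding space. Passing tests
therefore demonstrate correctness of the machinery and recoverability under
the stated model, not performance on real phage collections.

## Hierarchy

With `minPts = 2` every point's core distance is its nearest-neighbour
distance, so HDBSCAN's mutual-reachability distance equals the raw distance
and the density hierarchy's merge heights equal single-linkage heights. The
hierarchy is therefore computed with `scipy.cluster.hierarchy.linkage(
method="single")` on the condensed distance matrix; determinism follows from
scipy's stable processing order (ties resolve by condensed position, i.e. by
(distance, lexicographic pair)). Independent oracles — Prim's-MST merge
heights and union-find connected components — are enforced in the test suite
at 1e-12 on hundreds of random instances.

Flat clusters at threshold `eps` are the connected components of the graph of
pairs at distance <= eps (DBSCAN* semantics), obtained as
`fcluster(Z, eps, "distance")`; singleton components are labeled noise,
consistent with the minimum cluster size of 2. Partitions provably coarsen
monotonically in eps, and the tests check it.

`extract_branch` operationalizes reading "the top node of a taxon and all its
successors" off the tree: among all nodes it selects the one whose leaf set
maximizes F1 against the taxon's annotated genome set (ties: smaller node,
then lower height), reporting in-taxon and other leaf counts alongside
precision/recall so other criteria can be recomputed. F1 was chosen over
raw purity or recall because the manual procedure it replaces implicitly
balances both.

## Evaluation

* **Silhouette** `s(i) = (b - a)/max(a, b)` on MPR-space distances (not the
  2-D projection). Sentinel-labeled ("unclassified") genomes are excluded
  entirely; genomes whose label is a singleton score 0 rather than being
  dropped, so every classified genome counts toward the mean. Verified
  against scikit-learn on singleton-free inputs.
* **AMI** via scikit-learn with the arithmetic-mean entropy normalization
  (the standard choice in the AMI literature). An exact hypergeometric
  expected-MI oracle on a 2x2 table pins the adjustment to 1e-12 in the
  tests.
* **AMI-vs-eps profiles** cut the hierarchy at each grid point (default: a
  64-point logarithmic grid spanning the positive distance range), drop
  sentinel-labeled genomes, give each noise point a unique singleton label
  (so stray points are not spuriously merged into one class), and score AMI
  against the rank labels.
* **Threshold analysis** samples 10 000 within-taxon and 10 000 between-taxa
  pairs uniformly with replacement (the sampling rule is otherwise
  unconstrained), scans candidate gates at midpoints between adjacent
  observed distances, and reports the one maximizing Youden's J = TPR − FPR
  together with both histograms and the raw sampled distances, so any other
  criterion can be recomputed from the report.
* **Atlas** projections use UMAP with `n_neighbors = 16`, `min_dist = 0.6`
  and a fixed seed, and are flagged `visualization_only`: they never feed
  back into clustering or distances.

## Query placement

Queries are embedded and averaged exactly like reference genomes, searched by
exact full-scan nearest neighbours (ties broken lexicographically by
accession; approximate indices can be slotted behind the same contract), and
gated: if the nearest distance exceeds the threshold the genome is reported
unclassified. There is deliberately no default threshold — it depends on the
rank of interest and the store's density, and the threshold-analysis report
is the intended calibration source. Placed queries are re-clustered together
with their k nearest neighbours (default k = 50) and returned as a condensed
subtree with the query as a leaf; neighbour annotations are attached for
context but no label is ever asserted for the query. The k-NN ball defines
the neighbourhood; expanding to the enclosing tree branch is a possible
extension, not implemented.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by design: 144-genome
synthetic taxonomies, 10 000-replicate Monte-Carlo comparisons, 50 random
hierarchy instances of up to 200 points. Distance arithmetic is float64
throughout; unit-norm tolerance 1e-9; oracle agreement asserted at 1e-12;
Monte-Carlo agreement at three standard errors. CLI runs derive all
per-stage seeds from one global `--seed` via named substreams, and primary
artifacts contain no timestamps, so reruns are byte-identical.

## Known limitations

* Headline numbers reported for real phage collections (silhouette, AMI
  levels, genus/family distance gates) require the full INPHARED + ESM-2 3B
  embedding store and are out of scope here; the procedures that compute
  them are in scope and tested on synthetic data.
* The bag-of-proteins construction ignores gene order, copy-number biology
  and protein length; a single eps does not correspond to one taxonomic rank
  across lineages (the AMI-vs-eps profile makes this visible per taxon).
* Cross-family embedding correlations in non-fine-tuned pLMs compress
  distance contrasts; the synthetic generator reproduces this only through
  its random (non-orthogonal) family directions.
* Placement quality depends on relatives being present in the store and on
  sound gene calling of the query; the unclassified gate is the only guard.
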