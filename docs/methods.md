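# Methods

This note documents the models, conventions and numerical choices behind
`metaneighbor`, in the spirit of a methods appendix: what each component
computes, which decisions were genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Profiles and distances

A profile collection is a nonnegative samples × features matrix with unique
sample and feature identifiers and optional habitat labels. Counts may be
converted to relative abundances (rows summing to 1 within 1e-9);
operations that require one regime or the other enforce it explicitly
rather than normalizing silently, because several distances are meaningful
in both regimes and the choice changes the geometry (see "Counts versus
relative abundances" below).

Six distances are supported.

* **City block (L1)** and **Euclidean (L2)** are the plain formulas. On
  relative abundances L1 equals twice the Bray–Curtis dissimilarity
  Σ|x−y| / Σ(x+y), since the denominator is then exactly 2; the test suite
  asserts this proportionality against `scipy`'s independent Bray–Curtis
  implementation rather than assuming the two are equal.
* **Standardized Euclidean** divides each dimension by its standard
  deviation. σ is the per-feature sample standard deviation (n−1
  denominator) over the *whole* evaluation collection, query included, and
  is computed once per collection: the retrieval evaluation treats the
  database as fixed, and re-estimating σ for every left-out query would
  make the metric query-dependent. Zero-variance dimensions are skipped —
  they carry no information over the collection and would otherwise
  produce infinities; this mirrors the joint-zero exclusion used for
  Jensen–Shannon.
* **Pearson and Spearman distances** are 1 − ϱ on values and on average
  ranks respectively. They are computed on the vectors as given, with no
  internal normalization; constant vectors are an error (the correlation
  is undefined), reported with the offending sample named.
* **Jensen–Shannon divergence** is ½KL(x‖m) + ½KL(y‖m), m = ½(x+y),
  natural logarithm, defined only for relative abundances (row-sum check
  at 1e-6). Dimensions where both vectors are zero are excluded; zero
  entries contribute nothing to their own KL term (0·ln 0 = 0). After
  joint-zero exclusion m_i > 0 always holds, so no other guard is needed.
  The value is bounded by ln 2.

Scalar functions spell the formulas out in numpy; the pairwise path runs
through `scipy.spatial.distance.pdist` (squaring scipy's `jensenshannon`,
which returns the square root of the divergence). The two routes are
independent enough that the test suite uses the scalar double loop as the
oracle for the vectorized matrix at 1e-12.

## Neighborhood evaluation

Retrieval quality is estimated by leave-one-out cross-validation: each
sample queries the remaining n−1, and its accuracy is the fraction of its
k nearest neighbors (k = 10 by default) sharing its label. Exact distance
ties are broken by ascending sample ID, which makes every result invariant
to storage order. When fewer than k alternatives exist — small habitat
classes are common in curated collections — all n−1 are used and the
denominator is the realized list length, keeping accuracies in [0, 1].

The per-label summary averages per-sample fractions within each label
(the pooled variant — all neighbor slots of a label's queries pooled before
dividing — is available via `label_average="pooled"`; the two differ only
when list lengths vary). The confusion matrix counts neighbor slots by
query label × neighbor label; unrounded rows sum to 100, printed values are
rounded half-up with entries below 0.5 left blank.

## Curation

The filters mirror standard database-construction practice: samples need
at least 1000 total feature hits and hits to at least 400 distinct
features; samples with an externally computed FDU (fraction of domains
unexplained) above 0.6 are dropped. All thresholds follow strict
inequalities — exactly 1000 hits, exactly 400 features, FDU exactly 0.6
are kept. FDU itself is the output of taxonomic mixture-model profiling
and is out of scope here; it is consumed from a two-column table.

Redundancy removal links samples whose Pearson profile correlation exceeds
0.995 and keeps one representative per connected component. Component
semantics (rather than, say, cliques) were chosen because redundant upload
chains are transitive in practice; the representative is the
deepest-sequenced member (largest total count, ties to the smallest ID) as
a proxy for data quality. Labels such as virus-enriched sets can be
exempted from the procedure entirely. Constant profiles, whose correlation
is undefined, are kept as singletons with a warning. The procedure is
idempotent.

## 2D visualization

* **PCA** projects mean-centered profiles onto the top principal axes
  (scikit-learn, full SVD). Sign convention everywhere: the
  largest-magnitude loading of each axis is positive, making outputs
  deterministic.
* **Classical MDS** double-centers −½D² and eigendecomposes. City block
  distance matrices are not Euclidean-realizable, so negative eigenvalues
  are expected; they are clamped to zero and the per-dimension explained
  variance is reported over the positive spectrum only. Eigenvalues below
  1e-12 of the leading one are treated as rank deficiency and set to zero,
  so e.g. collinear configurations embed with an exactly zero second
  coordinate.
* **Sammon mapping** minimizes
  E = (1/Σδ) Σ_{i<j} (δ_ij − d_ij)²/δ_ij, which weights small input
  distances most heavily. The optimizer uses the classic diagonal-Newton
  direction (gradient over the absolute diagonal Hessian) with step
  halving until the stress decreases, so the trace is non-increasing by
  construction; it stops when the relative stress change falls below 1e-9
  or after 500 iterations. It is initialized from classical MDS. Zero
  input distances (duplicate samples) are floored at 1e-12; duplicates
  co-locate.
* **UKR** optimizes latent 2D coordinates X of the Nadaraya–Watson
  regressor f(x) = Σ_j y_j K(x − X_j) / Σ_j K(x − X_j) with the L1 kernel
  K(u) = exp(−‖u‖₁), under the leave-one-out reconstruction objective
  R(X) = Σ_i ‖y_i − f_{−i}(X_i)‖₁ (excluding each sample from its own
  regressor prevents the trivial collapse solution). The reconstruction
  error is measured in L1 to match the kernel family. The subgradient of R
  is computed in closed form and validated against finite differences in
  the test suite. The kernel has no explicit bandwidth: rescaling the
  latent space plays that role, so the initialization (L1-kernel PCA on
  K_ij = exp(−‖y_i − y_j‖₁/s), s the median off-diagonal L1 distance) is
  rescaled over a fixed logarithmic grid of 15 multipliers and the scale
  with the lowest objective starts the descent. Descent uses backtracking
  step halving (monotone trace), capped at 300 iterations, tolerance 1e-9.

All four methods are deterministic: no random initialization or stochastic
optimization anywhere. Maps are scored by the same LOOCV neighborhood
accuracy, on 2D Euclidean distances.

### Counts versus relative abundances

The embedding benchmark runs on **count** profiles. Real collections mix
sequencing depths, and the resulting spread of L1 distances is exactly
what separates the four methods: on counts, a few extreme samples dominate
total variance, so PCA spends its two axes on them and collapses the rest;
classical MDS is similarly dominated by the largest (least meaningful)
distances; Sammon's 1/δ weighting recovers local structure; UKR, which
only ever uses kernel-local neighborhoods, matches the high-dimensional
accuracy almost exactly. On fully normalized profiles L1 distances
saturate near 2, between-habitat structure compresses into a narrow band,
and classical MDS alone already sits near the ceiling — a regime where
Sammon's global stress optimum can even cost neighborhood accuracy. Both
pipelines are exposed (`--normalize relative|none`); the count regime is
the default benchmark because it reflects what profile databases actually
look like before normalization.

## Synthetic collections

The generator emulates a labeled metagenome collection with a
Dirichlet–multinomial hierarchy: a global composition g ~ Dir(1), habitat
base compositions b_h ~ Dir(1), effective compositions
e_h = (1−overlap)·b_h + overlap·g, per-sample compositions
θ ~ Dir(c·e_h) with within-habitat concentration c, and counts
multinomial at a Poisson-distributed depth. Defaults: 5 habitats × 40
samples, 500 features, expected depth 50,000, c = 200, overlap 0.2,
seed 42. The depth is Poisson rather than fixed because real sequencing
depth varies; c = 200 gives within-habitat spread comparable to
between-habitat separation at moderate overlap, so the overlap knob sweeps
accuracy over its full range. At overlap 1 all habitats share one
composition and labels are exchangeable, so retrieval accuracy matches the
label prior.

`generate_confusable_pair` additionally pulls two named habitats toward
their midpoint, reproducing the common situation of one genuinely
overlapping label pair (small skin-like class absorbed by a larger
neighboring class). It shares the generator's exact draw sequence, so a
pair-overlap of 0 is bit-identical to the baseline. `inject_outliers`
appends samples with spiky compositions (Dir(0.05), ten-fold depth),
emulating virus-enriched profiles dominated by a handful of features.

A calibration of 20 independent replicates of the default scenario
(generator seeds 101–120) put the City-block k = 10 retrieval accuracy at
1.0 in every replicate; the end-to-end test therefore requires ≥ 0.99.

**What the generator does not model:** feature correlations (real protein
domains co-occur in operons and pathways), overdispersion beyond
Dirichlet–multinomial, compositional zero-inflation, contamination, or any
specific body-site biology. Passing the end-to-end tests shows the
pipeline is correct and behaves as theory predicts on controlled
compositional data — not that any particular accuracy will be achieved on
real collections.

## Problem sizes and runtime

Test and benchmark sizes were chosen so the full suite runs in seconds on
one core: oracle equivalence uses 25 random collections up to n = 50,
D = 100; the embedding limit checks use n = 100 (MDS recovery) and n = 20
(Sammon convergence); the end-to-end scenarios use the 200-sample default
collection (plus 3 outliers). The quadratic-memory pairwise kernels
(n × n × D intermediates in UKR) are comfortable to roughly n ≈ 2000 on a
laptop, which covers collection sizes typical of curated metagenome
databases.

## Known limitations

* UKR descent is first-order with a per-run latent rescaling; it finds
  good local optima reproducibly but, like all UKR implementations, has no
  global-optimality guarantee.
* Classical MDS explained-variance fractions ignore the clamped negative
  spectrum; with strongly non-Euclidean inputs they overstate the share of
  structure captured.
* k-mer counting is forward-strand only with no reverse-complement
  canonicalization, and any window containing a non-ACGT character is
  skipped entirely. Both conventions are deliberate (deterministic, no
  fractional counts) and recorded here because other toolkits differ.
* The multi-target mapping projection duplicates a source's full count
  into every associated target (association counting); totals are
  conserved only for one-to-one mappings.
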