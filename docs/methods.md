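# Methods

## Model

`stdomain` treats spatial-domain assignment as a two-stage clustering
problem on a chip lattice.

**Spot graph.**  Spots are nodes; edge weights follow a Gaussian kernel
on Euclidean pixel-coordinate distance, A_ij = exp(−d_ij²/2σ²), so every
spot carries a unit self-loop.  σ is not a free parameter: it is solved
(by bisection, exploiting the strict monotonicity of row sums in σ) so
that the mean over spots of Σ_j A_ij − 1 equals `target_rowsum` (default
0.5), i.e. each spot's total affinity to all others averages one half.
The tolerance on that mean is 1e-3.  The graph is dense; at the intended
scale (≤ ~20k spots) an s×s matrix is unproblematic and the kernel
defines no sparsification cut-off.

**AGC pre-clustering.**  The feature matrix F holds the top 50 PC scores
of log-normalized expression (ln(1 + 10⁴·c/total); the +1 keeps zero
counts finite and maps them to exactly 0) restricted to the top 3,000
highly variable genes.  Smoothing applies H_t = (I − L/λ)^t F by repeated
multiplication with λ = 1.5, an upper estimate of the largest eigenvalue
of the normalized Laplacian; larger λ smooths less per step.  At each
order t the similarity H_t H_tᵀ is embedded through its top 26
eigenvectors, **scaled by the square roots of their eigenvalues**
(kernel-PCA scores).  The scale convention matters: with unit-norm
eigenvectors the ~20 low-variance directions carry as much weight as the
informative ones and k-means degrades to near-noise assignments on
moderately sized inputs; the scaled embedding preserves the similarity
geometry and makes the intra-cluster-distance trace meaningful.  k-means
uses k-means++ with 10 restarts and a seed folded with the iteration
index; labels are renamed by first occurrence so runs are reproducible.
The mean intra-cluster distance (per cluster, mean pairwise L2 distance
of its members; singletons contribute 0 since they own no pairs) is
tracked and iteration stops the first time it rises, adopting the
previous assignment.  Comparisons start at t = 2 (the criterion needs two
values); a cap `max_t` = 60 guards non-monotone traces, falling back to
the argmin of the trace.  With n = 1 the assignment is trivial and
returned at t = 1.

**Virtual image.**  The lattice bounding box (max row/col + 1) becomes a
15-channel raster.  Spot pixels carry the top-15 PC scores; every other
pixel carries the projection of the all-zero expression profile through
the same PCA — the representation of a cell-free location.  Pixels are
classified spot / null / background; a non-spot pixel with a spot among
its 8 neighbors is "null" (a stagger gap or hole inside tissue), the rest
are background.  The classification is bookkeeping only: both classes
receive the same imputed value and the losses read spot pixels
exclusively.  Visium spots are placed at their integer array coordinates
(placing them at pixel coordinates would scatter neighbors beyond any
small receptive field); Stereo-seq bins are placed at pixel coordinates
divided by the smallest positive per-axis gap and rounded, with
collisions treated as errors.  Channel order is PC order; no per-channel
standardization is applied.

**Network.**  Two branches of four blocks.  Hidden blocks are
(constrained conv → batch norm → ReLU) at 100 channels; the head is a 1×1
conv to n channels; branch outputs combine as 0.7·O₁ + 0.3·O₂ on Visium
(3×3-dilated branch first) and 0.9·O₁ + 0.1·O₂ on Stereo (undilated
branch first).  Kernel geometry per platform:

| platform | kernel | dilation | zeroed | tie groups |
|---|---|---|---|---|
| visium | 3×3 | 2 | 4 corners | {center}, {4 edge midpoints} |
| visium | 2×2 | 2 (taps at (±1,±1)) | — | {all 4 taps} |
| stereo | 3×3 | 1 | — | {center}, {4 edges}, {4 corners} |
| stereo | 3×3 | 2 | center + 4 corners | {4 edge midpoints} |

The 2×2 dilation-2 kernel is centered by asymmetric padding so its taps
sit on the four diagonal lattice neighbors.  On the staggered lattice the
union of taps reaches exactly a spot's 8 closest spot pixels plus itself
and never touches a null pixel; on the dense grid, the 12 closest plus
itself (the dilated branch's center is zeroed because the undilated
branch already reads it).  Weights are *stored* as one trainable scalar
per tie group and per (out-channel, in-channel) pair and materialized
into dense kernels on demand, so the zero and tying constraints hold
bitwise at every step by construction; a projection operator
(`enforce_constraints`) expresses the same constraint set for dense
kernel tensors and is idempotent.  The ablation variants relax this:
"no_distance" gives every active tap its own parameter, and
"+containing corners" additionally re-activates the corner taps.

Batch normalization runs over all pixels of the single image, including
null/background — empty-pixel statistics therefore leak into the
per-channel scaling.  This is a deliberate simplification (no masking is
specified by the architecture); consequently the receptive-field audit in
the tests is stated for a lone convolution layer, where the locality
claim is exact.  Padding is zero-valued at the canvas border; border
spots see fewer neighbors, and since losses read only spot pixels no
correction is applied.  Parameters initialize fan-in uniform
(±1/√(C_in·k²)) from a seeded generator; biases start at zero.

**Training.**  Differentiation is reverse-mode via `autograd` on numpy
arrays; the optimizer is Adam (β = 0.9/0.999, ε = 1e-8) over the
flattened parameter tree.  Learning rates: 0.05 pre-train / 0.01 train on
Visium, 0.005 / 0.001 on Stereo.  Pre-training minimizes cross-entropy of
softmax(E) against the AGC pseudo-labels for up to 200 iterations.
Training adds the centroid matrix μ (n×n), initialized as per-cluster
means of E under the pseudo-labels — the standard DEC convention matching
the KL objective — and runs up to 400 iterations of: forward → Q
(Student-t kernel) → refresh P on iterations 1, 5, 9, … (so the first
iteration has a defined target) → stop check → loss → step.  P is a
detached constant between refreshes; the high-confidence mask and its
argmax labels are likewise detached within an iteration so gradients flow
only through Q.  Logs carry an ε = 1e-12 guard.  An empty
high-confidence set contributes zero loss rather than an error (early
iterations can be diffuse).  The three degenerate-state stop rules
(unique labels < n; any cluster share < 1%; label-change ratio < 0.1% on
a refresh iteration) apply to both phases, except the change-ratio rule,
which needs P refreshes and is thus training-only.  They are evaluated on
the labels produced at the start of each iteration, so a degenerate state
stops the run before a further step is taken.

**Metrics and SVGs.**  ARI is computed from the contingency table;
silhouette and Davies–Bouldin delegate to scikit-learn.  SVG filters per
domain and gene: two-sided Wilcoxon rank-sum (in-domain vs all other
spots) with Benjamini–Hochberg adjustment (the conventional choice where
only "adjusted p-value" is specified), fold change of back-transformed
(expm1) means > 1.5, in-fraction (share of in-domain spots with nonzero
value; identical whether computed on counts or log-normalized values)
> 0.8, and min over lattice-neighboring domains of the in/out detection
fractions > 1.  Neighboring domains are those sharing at least one
lattice-adjacent spot pair (the same adjacency offsets the continuity
loss uses).

## Synthetic data

The generator emulates the two chip geometries: staggered occupancy
(spots where column parity equals row parity) with an affine pixel map
using a √3 row stretch so all six closest neighbors are equidistant, and
a dense grid.  Domains are planted as row stripes, annuli around a corner
(cortex-layer-like arcs), or Voronoi blobs.  Counts are Gamma–Poisson
(negative binomial) with dispersion 0.5 to mimic UMI overdispersion,
with Bernoulli dropout; markers of a spot's domain have their expected
count multiplied by `marker_lift`.  Defaults — 24×24 staggered lattice
(288 spots), 3 stripes, 200 genes, 10 markers per domain, base rate 0.5,
lift 8, dropout 0.2 — define the standard recovery setting used
throughout the tests.  What the generator does **not** model: gene–gene
correlation beyond the domain blocks, spatially smooth expression
gradients within a domain, library-size variation across spots, and
histology.  Passing tests therefore demonstrate that the machinery
recovers block-marker structure on clean lattices, not performance on
real tissue.

One property of the generator worth knowing: with `marker_lift` = 1 the
expression carries no domain signal, yet agreement with stripe-shaped
truth is *not* near zero — the clusterer is spatial, and smoothing alone
yields contiguous bands that can coincide with stripes.  The honest null
statement, asserted in the tests, is that no-signal recovery is erratic
and systematically below the with-signal recovery.

## Numerical choices and problem sizes

- σ bisection brackets [1e-6·d_max, 10·d_max], widening upward if
  needed; value tolerance 1e-3; errors for s < 2, all-zero distances, or
  unattainable targets.
- PCA uses full SVD with a deterministic sign convention (largest-
  magnitude loading positive); k above the numerical rank is an error.
- HVG ranking: variance/mean dispersion of expm1 values, z-scored within
  20 quantile bins of the mean (singleton or zero-spread bins fall back
  to centred, unscaled scores); stable sort makes ties deterministic.
- Detection filters iterate gene-then-spot rules to a fixed point so
  filtering is idempotent.
- The test suite and the ablation comparison run on reduced lattices
  (8×8 to 16×16, 60–120 genes, iteration caps of 40–200) — sizes chosen
  so each behavioral check isolates one mechanism on the smallest input
  that exercises it; the headline recovery check runs at the full
  288-spot default.

## Known limitations

- Dense s×s graph algebra bounds practical input size (~20k spots).
- Batch-norm statistics include empty pixels (see above).
- The intra-cluster-distance stop can run to the iteration cap on inputs
  whose trace decreases monotonically; the cap then selects the argmin,
  which on strong-signal fixtures is benign but on weak signal may
  over-smooth.
- The Stereo discretization assumes near-regular bin spacing; irregular
  spacing that maps two bins to one pixel is rejected rather than
  resolved.
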