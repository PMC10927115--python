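# stdomain

Spatial-domain clustering for spatial transcriptomics platforms with
regular chip lattices (10x Visium's staggered array, Stereo-seq's dense
bin grid).  Given a spot-by-gene UMI matrix with pixel and array
coordinates and a cluster number *n*, `stdomain` assigns every spot to a
spatially coherent, transcriptionally consistent domain and flags the
spatially variable genes (SVGs) of each domain.  It is aimed at anyone
analysing Visium/Stereo-seq slides who wants domain labels driven jointly
by expression and chip geometry, without histology images.

## Method

The pipeline has two stages.

**1. Adaptive graph convolution (AGC) pre-clustering.**  From pixel
coordinates, a Gaussian-kernel adjacency A<sub>ij</sub> =
exp(−d²<sub>ij</sub>/2σ²) is built, with σ searched so the mean row sum of
A − I equals 0.5.  The top-50 PCA features F of the log-normalized
expression (top 3,000 highly variable genes) are smoothed with the
low-pass filter H<sub>t</sub> = (I − L/λ)<sup>t</sup> F (λ = 1.5, L the
symmetrically normalized Laplacian).  At each order *t* the similarity
H<sub>t</sub>H<sub>t</sub><sup>T</sup> is spectrally embedded (26
components) and clustered with k-means; iteration stops once the mean
intra-cluster distance rises, and the previous assignment becomes the
pseudo-labels C₀.

**2. Constrained dilated convolution network (DCF).**  The chip is
rendered as a 15-channel *virtual image*: each spot pixel carries its
top-15 PC scores, while stagger-gap ("null") and background pixels carry
the projection of an all-zero expression profile.  Two parallel
sub-networks of four blocks (3 × [conv → batch norm → ReLU] at 100
channels, then a 1×1 conv to *n* channels) read this image through
kernels whose taps touch only the closest *spot* pixels — on Visium a
corner-zeroed 3×3 kernel and a 2×2 kernel, both with dilation 2 (self + 8
neighbors); on Stereo-seq an undilated 3×3 plus a center- and
corner-zeroed dilated 3×3 (self + 12 neighbors).  Taps equidistant from
the kernel center share one weight, so neighbor influence depends only on
distance.  The branch outputs combine with weights 0.7/0.3 (Visium) or
0.9/0.1 (Stereo-seq) into a feature image whose spot pixels are the
embeddings E.

The network is pre-trained by cross-entropy of softmax(E) against C₀,
then refined DEC-style: a Student-t soft assignment Q of E to trainable
centroids μ, a sharpened target P (refreshed every 4 iterations), and the
objective

&nbsp;&nbsp;&nbsp;&nbsp;L = 0.78 · KL(P‖Q) + 0.71 · CE<sub>q&gt;0.5</sub> + 1.0 · (0.62 · L<sub>ortho</sub> + 0.58 · L<sub>diag</sub>)

where the cross-entropy counts only spots whose best assignment
probability exceeds 0.5 and the continuity terms are mean embedding
distances between lattice-adjacent spot pairs (diagonal weight 0 on
Stereo-seq).  Training stops when labels degenerate (fewer than *n*
unique labels, a cluster under 1% of spots) or stabilize (<0.1% label
changes on a target-refresh iteration), capped at 200 + 400 iterations.

Clustering quality is scored by the adjusted Rand index; per-domain SVGs
must pass a Wilcoxon rank-sum test (BH-adjusted p < 0.05), fold change
> 1.5, in-fraction > 80%, and an in/out detection-fraction ratio > 1
against every neighboring domain.

## Worked example

Everything is testable offline through the bundled generator, which
plants spatial domains with marker genes on either lattice geometry:

```python
import numpy as np
from stdomain import FixtureSpec, SpatialDomainCluster, ari, simulate_counts

spec = FixtureSpec()  # 288-spot staggered lattice, 3 stripes, 200 genes
data, truth = simulate_counts(spec)

model = SpatialDomainCluster(n_clusters=3, platform="visium", random_state=0)
model.fit(data)

print(f"calibrated sigma      : {model.sigma_:.4f}")
print(f"AGC stop iteration    : {model.agc_stop_t_}")
print(f"pre-clustering ARI    : {ari(truth, model.precluster_labels_):.3f}")
print(f"final ARI             : {ari(truth, model.labels_):.3f}")
print(f"training stop reason  : {model.train_state_.stop_reason}")
```

prints

```
calibrated sigma      : 9.1164
AGC stop iteration    : 60
pre-clustering ARI    : 1.000
final ARI             : 1.000
training stop reason  : label_change_below_tolerance
```

The σ of 9.12 pixel units makes each spot's total affinity to its
neighbors average exactly 0.5; the pre-clustering already recovers the
three planted stripes (ARI 1.0) and training confirms and stabilizes the
assignment, stopping as soon as fewer than 0.1% of labels move.

The same run is available from the shell:

```bash
stdomain make-fixture --out chip.h5ad --truth-out truth.csv
stdomain cluster --input chip.h5ad --n-clusters 3 --truth-labels truth.csv --out-dir out
stdomain svg --input chip.h5ad --labels out/labels.csv --out out/svg.tsv
```

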