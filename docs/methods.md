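# Methods

## Texture amortization maps

The TAM operator forms `TAM(x,y) = T(x,y) · (K ∗ I)(x,y)`: a linear
filter response modulated by a local texture statistic. `T` is computed
from a windowed gray-level co-occurrence matrix (GLCM): the image is
min-max quantized once globally into `L` bins, and at every pixel the
joint frequency `p(i,j)` of quantized pairs at a set of integer offsets
is accumulated over the `W × W` window centered there. Four measures of
that distribution are supported:

| measure     | formula                      | range                 |
|-------------|------------------------------|-----------------------|
| entropy     | `−Σ p log p` (natural log)   | `[0, log L²]`         |
| contrast    | `Σ (i−j)² p(i,j)`            | `[0, (L−1)²]`         |
| homogeneity | `Σ p(i,j) / (1+(i−j)²)`      | `(0, 1]`              |
| energy      | `√(Σ p²)` (ASM in `[1/L²,1]`)| `(0, 1]`              |

Defaults: `L = 8` levels, `W = 7` window, pooled offsets
{(0,1),(1,0),(1,1),(1,−1)} with symmetric counting. These are the
standard GLCM conventions of the texture literature; they match the
entropy/contrast/homogeneity/energy quartet and are small enough that a
7×7 window populates an 8×8 matrix meaningfully. The offset distance
index `n` in the contrast and homogeneity formulas is the gray-level
difference `|i−j|` (Haralick convention).

Numerical choices:

- `0 · log 0 := 0` in the entropy; the GLCM always sums to 1 when the
  window contains at least one valid pair, and construction fails loudly
  when it does not (window smaller than every offset span).
- Texture windows use **reflect** padding (deterministic,
  shape-preserving, no artificial gray level injected); the kernel
  convolution uses **zero** padding with `same` output shape. Both maps
  therefore have exactly the input shape, and the texture map is
  shift-invariant away from the borders.
- Energy defaults to `√ASM`, the standard definition; a literal
  `ASM` mode is available (`energy_as_sqrt=False`) because the two
  conventions coexist in the literature.
- An optional `1/(MN)` factor (`MN` = window pixel count) can be applied
  to the TAM product (`normalize_mn`, default off). Since `p(i,j)` is
  already normalized the factor is a pure rescaling; it is exposed for
  compatibility with formulations that include it, and it never touches
  the reported texture map itself.
- Quantization is global per image (not per window) so that neighboring
  windows see consistent gray levels; a constant image maps to level 0.
- Volumes are processed slice by slice along the third axis — texture is
  a 2-D in-plane notion here; no 3-D GLCM is attempted.

## Geometric classification score

Given points with labels over `K ≥ 2` classes, class `k` is compared
with `B_k`, the union of all other classes. A point `v ∈ C_k` is a
noise point iff

1. at least `min_neighbors` points of `B_k` lie **strictly** within
   radius `r` of `v` (strict inequality is deliberate: it makes the
   `r → 0⁺` limit score exactly 1), and
2. `v` lies inside the convex hull of those neighbors.

`GCS_k = 1 − NS_k/|C_k| ∈ [0, 1]`; the aggregate is the unweighted mean
over classes (class sizes can be very unbalanced in activation samples,
and the per-class scores are the primitive quantity).

**Hull membership as linear feasibility.** `v ∈ conv{u_1..u_m}` iff
`∃ λ ≥ 0, Σλ = 1, Σλᵢuᵢ = v`. We first project onto the affine span of
the neighbors (SVD basis of the centered neighbor matrix): a query point
with an off-span residual above `tolerance × scale` is outside
immediately, and the remaining feasibility program has at most `m`
equality rows regardless of the ambient dimension — essential when the
points are flattened layer activations with thousands of coordinates.
The LP is solved with the HiGHS backend of `scipy.optimize.linprog`.
Boundary points count as inside (a convex combination exists). Default
`tolerance = 1e-9`; `min_neighbors = 2` short-circuits the degenerate
cases (0 or 1 neighbors can never strictly contain a distinct point).

**Radius.** The neighborhood radius is the one real free parameter. The
`auto` rule uses 0.3 × the diameter of the point cloud's bounding box:
large enough that genuinely embedded points collect a neighborhood,
small enough that separated clusters never see each other. It is
deterministic and scale-equivariant (scaling the cloud scales the
radius). Degenerate all-identical clouds are rejected. Min-max
normalization to `[0,1]` per feature is available (and on by default in
the CLI, matching the usual preprocessing of raw tabular data); library
calls default to off so that distances in activation space are left
untouched.

The score as implemented lives in `[0, 1]`. A signed variant (negative
values flagging linearly separable structure) is sometimes discussed
alongside scores of this kind, but no formula for the sign follows from
the definition above, so none is produced.

## Sequential-network backend

The pruning procedure only needs a small, fully deterministic
feed-forward substrate, so the package ships its own NumPy
implementation: conv2d (stride 1, valid), maxpool2d (size = stride,
argmax routing in backward), flatten, dense; ReLU hidden activations and
a terminal softmax trained with cross-entropy via SGD with momentum
(defaults: lr 0.01, momentum 0.9, batch 32, 20 epochs). One seed drives
initialization (He normal), shuffling and sampling; identical seeds give
bit-identical weights and reports on any CPU. Gradients are verified
against central finite differences in the test suite, and parameter
counts against closed-form per-layer formulas.

Activation extraction truncates the forward pass after a given layer and
flattens to vectors. To keep the hull tests tractable the extracted set
is capped (default 2000 points) by seeded stratified sampling — GCS costs
one LP per candidate point per class.

## GCS cut

All hidden layers (everything except the output layer, pooling and
flatten included) are scored on the training data. The cut keeps layers
up to and including the argmax of the profile — ties break toward the
earliest layer, which is the cheapest network — then appends a flatten
(if needed) and a freshly initialized softmax head, and retrains. The
whole cut network is retrained by default; `freeze_retained=True`
restricts training to the new head, which is the transfer-learning
reading of the procedure. Retraining reuses the original training
configuration unless overridden.

A threshold mode (`prune_below_threshold`) additionally emulates
multi-layer removal: every scored layer below a configurable fraction of
the maximum score is dropped, surviving layers keep their weights where
shapes still match, and mismatched layers are re-initialized. The
single-argmax cut remains the canonical, default behavior.

## Synthetic study conditions

The generators define the regimes the score must distinguish; all are
pure functions of their arguments including the seed.

- **Gaussian classes**: isotropic clusters, centers `separation` apart
  on the coordinate axes. "Well separated" in the tests means
  separation 8 at spread 0.5 (no overlap at any plausible radius);
  the label-noise experiments use separation 4 at spread 1 — visibly
  distinct but adjacent clusters, n = 60 per class.
- **Concentric rings**: radii 1 and 2 with radial jitter 0.05 — a
  non-linearly separable problem that is nevertheless perfectly
  classifiable; scored at radius 0.5 (below the inter-ring gap).
- **Label flips**: exactly `⌊fraction·M⌋` points get a different label,
  which directly realizes "a point surrounded by the other class";
  the mean score over 20 seeds decays monotonically through flip
  fractions 0 → 0.3.
- **Motif image set**: 4 classes of 24×24 images (horizontal stripes,
  vertical stripes, disk, checkerboard) of amplitude 2.0 over
  unit-variance Gaussian noise, 150 train / 50 test per class — an
  easily learnable stand-in for a small image-classification task.
- **BOLD-like volume**: truncated-Gaussian activation blobs on Gaussian
  background noise in the 64×64×18 acquisition shape. It reproduces the
  shape and local texture structure the toolkit consumes, *not* the
  hemodynamics, spatial autocorrelation or physiological noise spectra
  of real BOLD data — passing tests show the operators behave correctly
  on volumes of this geometry, nothing about detecting real ERPs.

The pruning demonstration uses an over-parameterized network
(conv 8@3×3 → pool 2 → flatten → three dense-256 layers → softmax,
≈ 0.38 M parameters) on the motif task: the first convolution layer
already yields aggregate GCS 1.0, so the cut keeps it alone and removes
≈ 96 % of the parameters at unchanged test error. These problem sizes
(600 training images, 20 epochs, 240-point activation samples) keep the
full pipeline deterministic and fast on a single CPU while leaving the
qualitative outcome — large reduction, stable error — unambiguous.

## Known limitations

- GCS is O(points × LP) per class; beyond a few thousand activation
  samples the stratified cap, not the full set, is scored.
- The radius is global; strongly anisotropic or multi-scale class
  structure may need a hand-chosen radius rather than the `auto` rule.
- The network backend targets small desk-scale models; there is no GPU
  path, no non-sequential graph, and no recurrent support.
- Texture maps are per-slice; through-plane texture is not measured.
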