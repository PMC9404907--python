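# Methods

## The registration model

`retireg` aligns pairs of fundus photographs with a learned non-rigid
transformation. The model never sees landmarks or ground-truth
deformations: it is trained end to end by maximizing an image-similarity
objective, so the similarity itself plays the role of supervision.

The pipeline has four stages.

**Vessel segmentation.** Registration operates on vessel maps rather
than raw intensities: the vasculature and other stable eye structures
are the anatomy that two visits of the same eye share, while
illumination and color vary freely between acquisitions. Vessels are
extracted with the isotropic undecimated wavelet transform (IUWT), the
à trous scheme with the cubic B3-spline kernel (1,4,6,4,1)/16, dilated
by 2^(j−1) at level j and applied separably with symmetric-reflection
boundaries. Detail plane j is the difference of successive smooths, so
the input is exactly the residual plus the sum of detail planes (this
perfect-reconstruction identity is a test invariant). Vessels are dark,
locally thin structures, so the mid-scale detail planes (levels 2–3 by
default) respond negatively over them; the negated, clipped, rescaled
sum forms the soft map, and the binary view keeps the top
`threshold_fraction` (default 0.15) of pixels. The camera field of view
is estimated from brightness and eroded before thresholding so the
aperture edge — the strongest wavelet edge in any fundus photograph —
is never segmented as structure.

**Correspondence network.** A U-shaped fully convolutional network
takes the two soft maps stacked as channels and emits a dense
displacement field in pixel units. The architecture is an input block
of two 3×3 convolutions, `depth` (default 2) downsampling blocks
(2×2 max pool, two convolutions, filters doubling), matching upsampling
blocks (2×2 stride-2 transposed convolution halving the filters,
concatenation with the encoder block at the same level, two
convolutions), and a 1×1 output convolution with two channels. All
convolutions except the last carry ReLU and batch normalization (batch
statistics while training, running averages with momentum 0.9 at
inference). The output is read as a displacement added to the identity
grid, and the output layer is zero-initialized, so an untrained network
implements exactly the identity transform — a stable starting point.

**Spatial transformer.** The sampler evaluates the moving map at the
displaced coordinates by bilinear interpolation, with
clamp-to-border handling (border clamping avoids injecting artificial
zeros that would bias the correlation objective). The operation is
differentiable in both the image values and the sampling coordinates;
the analytic gradients are verified against central finite differences
(relative agreement ~1e-9 away from the integer-coordinate kinks).
When a full vessel map is warped, the binary view is re-derived from
the warped soft map by the same top-fraction rule used at segmentation,
rather than by interpolating and majority-voting the binary mask:
re-thresholding the interpolated ridge preserves the connectivity of
vessels only one or two pixels wide, which voting severs.

**Objective and training.** The loss is the negated global zero-mean
normalized cross-correlation between the warped and reference soft
maps. Zero-meaning both operands makes the score a true correlation in
[−1, 1], invariant to positive affine intensity changes of either
image. Optimization is plain ADAM (β₁ = 0.9, β₂ = 0.999) over shuffled
mini-batches; the mean per-epoch NCC is recorded as the learning curve.
The learning rate defaults to 1e-4 — displacement fields train
stably there, whereas larger steps can tear the field before the
correlation signal establishes itself. No smoothness penalty is applied
by default: spatial coherence of the field comes from the network's
convolutional inductive bias (an optional penalty exists behind a
config flag, off by default, as an extension). The whole network stack
(layers, gradients, optimizer) is implemented in NumPy; every layer's
backward pass is checked against finite differences in the test suite.

**Refinement.** Non-rigid warping of segmented maps leaves small
spurious clusters. Connected-component analysis labels the warped
binary view (8-adjacency by default — vessels are thin diagonal
structures) and deletes components smaller than `min_size` pixels
(default 20; strict inequality, so a 20-pixel component survives).
The soft map is zeroed exactly on removed pixels, nowhere else. The
morphological comparators (disk-1 opening and closing of the binary
view) exist for the refinement ablation; they are not part of the
default pipeline because they erode or inflate vessel contours.

## Evaluation metrics

MSE and SSIM are image-similarity measures and are computed on the soft
vessel maps; Dice and the gain coefficient are set-overlap measures and
are computed on the binary views, which share one binarization. SSIM
uses the standard windowed form (11×11 Gaussian window, σ = 1.5,
stabilizers c₁ = (0.01 L)², c₂ = (0.03 L)² with dynamic range L = 1);
a whole-image "global" mode is available for the single-statistic
variant. Negative SSIM values are reported as-is. Dice is
2|A∩B|/(|A|+|B|), 1.0 for two empty masks (degenerate perfect
agreement). The gain coefficient |B_ref∩B_warp|/|B_ref∩B_mov| is
undefined (raises) when the pre-registration overlap is empty.

## The synthetic generator

The generator produces everything the pipeline needs without any
dataset download, and its defaults define the study conditions used by
the tests:

- **Anatomy.** Dark recursive branching vessel trees on a bright
  circular retina disc with a weak shared texture (strength 0.03 of the
  dynamic range). At the 64×64 desk scale the suite uses two trees of
  depth 3 with stroke widths 2–4 px, giving a connected vasculature
  covering roughly 10% of the raster — under the segmentation's kept
  fraction, as in real fundus images.
- **Deformation.** Two independent Gaussian-smoothed white-noise
  fields, zero-mean, rescaled so the maximum displacement magnitude
  equals the requested amplitude (suite: 4 px at correlation length
  8 px). The ground-truth grid is returned with each pair.
- **Acquisition.** Each image of a pair receives its own independent
  correlated sensor grain (strength 0.04, correlation length 1.5 px):
  two photographs never share their noise, and the segmentation speckle
  this grain produces is precisely the small-cluster noise the
  refinement stage exists to remove. Every other moving image is
  additionally degraded in the style of a poor acquisition: Gaussian
  blur (σ 0.6), global dimming (×0.85), one smooth occlusion blob, and
  stronger white noise — emulating pairs of one poor and one good
  photograph of the same eye.

What the phantoms do **not** model: pathology, the optic disc as a
distinct anatomical feature, realistic choroidal texture statistics,
chromatic effects, or perspective/rotation extremes. Passing tests
therefore demonstrate that the machinery — segmentation, learned
deformable alignment, refinement, metrics — behaves correctly and that
training recovers smooth synthetic warps; they do not certify accuracy
on clinical images.

## Scaled-down study sizes

The desk-scale experiments train a depth-2, base-8-filter model on 16
synthetic 64×64 pairs for 400 epochs with batch size 4 (production
defaults are 512×512, base 16, batch 8, 5000 epochs). At this size the
whole training study runs in a few minutes on one CPU core. Measured on
the suite, registration raises mean Dice by ≈0.09 and mean NCC by
≈0.15 over the unregistered pairs, the 25-epoch-smoothed learning curve
is non-decreasing (fast early rise, then plateau), size-20
connected-component filtering gives the best mean SSIM among the CCA
refinement variants, and closing degrades it.

One refinement comparator behaves differently at desk scale than at
production scale: disk-1 **opening** slightly *raises* mean SSIM on the
64×64 suite. The warped maps' speckle islands are almost all thinner
than the disk-1 structuring element, so opening acts as an aggressive
speck remover whose gain outweighs its vessel-erosion cost; at 512×512
the erosion cost dominates (on grain-free aligned pairs the
erosion-only effect of opening is ≈−0.006 SSIM here). This is a known
limitation of shrinking the raster while keeping the absolute
structuring-element and component-size thresholds fixed.

## Numerical choices and edge cases

- Intensities are floats in [0, 1] everywhere; 8- and 16-bit rasters
  are rescaled by their bit-depth maximum on load.
- Non-square inputs are stretched anisotropically to the square working
  resolution (no letterboxing); color is converted to gray after
  resizing, using the green channel (highest vessel contrast).
- NCC raises on constant operands (zero denominator) instead of
  returning a value.
- The binary threshold is a quantile, so the kept fraction is honored
  up to value ties; specks below a size floor (10 px at 512², scaled by
  area) are dropped at segmentation time to stabilize training input.
- Training is deterministic given the seed: weight initialization,
  shuffling and batch composition all derive from it; repeated runs
  produce bit-identical curves and outputs.
- Checkpoints are a single `.npz` holding config, weights, batch-norm
  statistics and the learning curve; save/load round-trips bit-exactly.
- The sklearn-style `FundusRegistrar` estimator wraps the library
  (fit = unsupervised training, transform = warp moving maps onto
  references) and composes with sklearn cloning/model selection; the
  module-level functions remain the primitive surface.
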