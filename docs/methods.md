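# Methods

## Problem and pipeline

The toolkit forecasts next-year satellite imagery of a bounded study area
at the pixel level. A yearly archive is modelled per block and per band:
the study area's boundary polygon is rasterized onto the mosaic grid
(pixel centers, even-odd rule, centers on an edge counted inside), an
overlapping block grid is planned over the mask, each block's yearly
frames are scaled to [0, 1], a recurrent conditional generator is trained
to map the j most recent frames to the next one, and predictions are
inverse-scaled, stitched, composited and scored.

## Block-grid planning

Phase 1 slides a window of side `window` (default 128 px) at stride
`stride` across the mosaic in row-major order, keeping only fully
in-bounds windows. The stride defaults to `window/2`: the overlap smooths
stitched predictions while keeping the block count linear in area. Phase 2
discards windows containing no study pixel. Phase 3 covers any study
pixels the lattice missed: for each 4-connected uncovered component, a
window seeded at the component centroid hill-climbs over 8-neighbor
stride-steps maximizing newly covered uncovered pixels (ties toward the
smallest (row_off, col_off)), is emitted at its local maximum, and the
loop repeats until no uncovered study pixel remains. Each emitted window
covers at least one new pixel, so termination is guaranteed; ordinals are
assigned after completion in row-major order, making plans deterministic
and manifests byte-stable. Hill climbing is local: it can emit more
windows than a global greedy set cover, which only costs a few extra
blocks on concave masks.

Windows are never padded: callers supply mosaics that extend beyond the
boundary, so every study pixel can sit inside a full window without
inventing pixel values. Stitching averages all blocks covering a pixel
(uncovered pixels are nodata); where every contribution agrees the common
value is returned bit-exactly, so stitching ground-truth crops reproduces
the source exactly on the covered footprint.

## Scaling and temporal statistics

Scaling is per (block, band): lo/hi are the min/max over all pixels of the
series' training years, and frames map through `(x − lo)/max(hi − lo, eps)`
with `eps = 1e-8` guarding constant blocks (which scale to all zeros and
invert to lo). Fitting on training years only keeps the held-out target
year out of the statistics; target frames are clipped to [0, 1] after
scaling since a drifting scene can exceed the training range slightly.
Per-block scaling (rather than one global range per band) follows from the
per-block statistics the pipeline reports; a global mode can be had by
fitting one ScalingParams over all blocks. Temporal mean/variance use the
population convention (divisor n), and a block's scalar temporal std —
used in the stability report pairing each block's std with its RMSE — is
the pooled std over all pixels and years.

## Forecaster

Architecture fill-ins beyond the three-part design (extractor, recurrent
encoder, generator):

- extractor f: two 3×3 stride-2 valid convolutions (1→8→16 channels),
  ReLU, flatten, linear to `feature_dim` (default 128), ReLU;
- encoder: a standard LSTM cell (hidden 256, forget-gate bias initialized
  to 1) over the j = 3 feature vectors; its final hidden state feeds two
  linear heads giving μ and log σ² of the latent distribution
  (`latent_dim` 64). Training samples z = μ + σ·ε with seeded Gaussian ε;
  inference uses z = μ so predictions are deterministic and repeatable;
- generator G: the condition bits are concatenated to z, then a linear
  layer reshapes to 16×(fs/4)² and two 2×2 stride-2 transposed
  convolutions (non-overlapping, so each latent cell paints a 4×4 patch)
  upsample to frame size, with a sigmoid bounding outputs to [0, 1].

The condition is the block plan ordinal in fixed-width big-endian binary
(width ⌈log₂ n_blocks⌉, min 1); the width is part of the config so
checkpoints are self-describing.

Without a discriminator, the only training signal is reconstruction:
loss = MSE(m̂, m) + `kl_weight`·KL(N(μ, σ²) ‖ N(0, 1)), `kl_weight`
defaulting to 0 (a plain reparameterized bottleneck). The three parameter
groups — extractor, encoder+head, generator — have separate Adam
optimizers stepped in that order after one joint backward pass per
minibatch; separate backward passes per group would triple the cost for
identical gradients. Epoch mean losses are logged; a non-finite loss
raises immediately with the epoch number. All randomness (init, shuffle,
reparameterization noise) flows from one generator seeded by the config,
so train + predict is bit-reproducible.

The network runs on a small reverse-mode autodiff core over numpy written
for this package (broadcast arithmetic, matmul, activations, strided
convolution, non-overlapping transposed convolution); its gradients are
verified against central finite differences in the test suite. At the
problem sizes the package targets (10²–10³ blocks of 128², a few hundred
epochs) CPU throughput is adequate; the core is not a general-purpose
deep-learning framework.

## Evaluation

RMSE and NRMSE = RMSE/σ are computed per (block, band) on inverse-scaled
digital numbers — σ is the population std of the true frame, so NRMSE 1.0
is the score of predicting the block mean, and blocks with constant truth
are excluded (σ = 0 leaves the metric undefined) rather than scored.
Per-band aggregates are the mean and population std of block NRMSEs.
Quartile grouping splits the [min, max] score range into four equal-width
intervals (right edge inclusive on the last; a degenerate range puts all
blocks in Q1); an equal-count mode is available by flag. The segmentation
correct rate counts per-pixel agreement of the predicted and true binary
vegetation masks over the evaluation scope — agreement on both classes,
not vegetation-only recall.

The vegetation rule on the B432 composite (each band min–max rescaled to
8 bit over valid pixels) is red dominance: vegetation iff
red ≥ `r_min` (80) and red ≥ `dominance`·green and ≥ `dominance`·blue
(1.2). Healthy vegetation renders red in a B432 composite because of its
near-infrared reflectance; both thresholds are exposed in config and
recorded in the mask object, since CR values are meaningless without the
rule that produced them.

## Synthetic archive

The generator emulates the *structure* of a yearly Landsat-style archive,
not its radiometry: a smooth latent field (coarse random lattice,
bilinear upsample — chosen over fractal noise so its statistics are
trivially checkable) with a smooth positive trend surface normalized so
the mean drift per year equals `trend_amplitude` exactly; per-band offsets
giving perfectly correlated bands; i.i.d. Gaussian pixel noise
(`noise_sd`, default 2 DN); Poisson-count saturating elliptical cloud
blobs (DN 255, `cloud_rate` 0.2/frame); and with probability `event_rate`
(0.05) an abrupt DN shift of one window-sized patch in the final year —
the unforecastable-change failure mode. The boundary is a random convex
hull covering 30–70% of the extent. Defaults mirror a 21-year, 8-band,
128×128-block archive.

With noise, clouds and events off, the next frame is an exact affine
function of the previous one — a process the model can learn, which the
capacity checks exploit: 16 blocks of 32×32 over 6 years, j = 3, trend
2 DN/yr, training 300 epochs at learning rate 2e-3 on the sliding windows
whose targets lie inside the training span, then scoring the held-out
final year. The trained model reaches mean NRMSE ≈ 0.26 versus ≈ 1.0 for
the temporal-mean baseline. These fixtures omit sensor artifacts
(SLC-off striping, radiometric drift, co-registration error) and
band-specific spectra, so passing them demonstrates mechanism and
correctness of the pipeline, not accuracy on real Landsat archives.

Problem sizes throughout the tests and the acceptance script (32² frames,
16 blocks, ≤ 300 epochs) are scaled-down study conditions chosen so the
whole verification runs on a laptop-class CPU in minutes; the pipeline
itself is size-agnostic.

## Known limitations

- One model per band; no cross-band conditioning (per-band reporting is
  the norm and nothing in the design requires joint modelling).
- Single-step forecasting only; multi-year rollout would compound errors
  and is out of scope.
- The transposed convolutions being non-overlapping can leave faint 4×4
  blockiness in low-loss regimes; overlap-blended stitching hides most of
  it at full-area scale.
- GeoTIFF support covers single-CRS, square-pixel rasters with the
  standard scale/tiepoint tags; reprojection, SLC-off gap-filling and
  scene mosaicking belong to upstream GIS tooling.
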