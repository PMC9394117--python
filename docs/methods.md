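# Methods

This note documents the models, protocols and design choices behind
`segclick`, the parameters that matter, and what the synthetic benchmark
does and does not demonstrate.

## Interaction model

A user annotates one object at a time with positive clicks (inside) and
negative clicks (outside). The segmenter never sees raw coordinates; it
sees per-polarity **guidance maps**. Two encodings are provided:

- **distance**: `u_{x,y} = min over clicks of the Euclidean distance`,
  clipped (default clip 255 px) and scaled to [0, 1] before the backend.
- **gaussian** (default): pointwise maximum of unit-height Gaussians,
  `exp(−d²/2σ²)` with σ = 10 px.

Both are implemented via a single exact Euclidean distance transform to the
click set (valid for the Gaussian because all clicks share one σ, making
the max a monotone function of the minimum distance). The Gaussian is the
default fed to backends because its blank (all-zero) map genuinely encodes
"no clicks here": an all-zero *distance* map would instead read as a click
at every pixel. An empty click set of either polarity is always encoded as
a blank map carrying an explicit empty flag.

Strokes, where needed, are their rasterised pixel sets — each stroke pixel
is one click.

## Semantic prior and channel selection

A semantic prior is a (C+1)-channel per-pixel class-score map from an
offline semantic model (channel 0 = background). Exactly one channel
reaches the backend: scores are summed per class over the positive-click
pixels, the background channel is excluded, ties break to the lowest class
index. Sum aggregation is the simplest order-invariant choice; it equals
the mean for a fixed click count. For a single click the selection is
invariant to any strictly monotone transform of the stored scores, so it
does not matter whether a prior stores probabilities or pre-sigmoid scores;
with several clicks, order preservation holds for positive affine
transforms (a non-affine monotone warp can in principle reorder sums — an
inherent property of any score-aggregating rule). When no prior is
available a blank channel is substituted and backends must behave as
click-only segmenters; "blank" and "all-zero" are defined to be
indistinguishable.

## Simulated user

- **Initial sampling** (used for training): n ~ U[1, budget] positives and
  m = budget − n negatives, total budget 20 by default. The first positive
  is a most-interior object pixel (argmax of the interior distance
  transform, ties broken uniformly); later positives keep ≥ d_step = 10 px
  from all earlier positives. Negatives go first onto other objects
  intersecting a 10 px dilation of the target, then into a background ring
  between the 5 px and 30 px dilations. Shortfalls in one polarity
  reallocate to the other, so the sampler emits exactly the budget whenever
  enough legal pixels exist.
- **Corrective sampling**: mispredicted pixels are split into false-negative
  and false-positive 4-connected components; R ≤ r_max regions are drawn
  without replacement with probability proportional to pixel count, and
  K ∈ [R, k_max] clicks are placed (≥ 1 per selected region, never more
  than the remaining budget). A correction clicks the most interior
  *unclicked* pixel of its region — robust for thin error slivers, and the
  unclicked restriction guarantees the session always makes progress.
  Polarity follows the region kind: positive on missed object pixels,
  negative on spurious prediction pixels.
- **Session**: start from one positive click at the object centre, predict,
  then alternate corrections and re-predictions until IoU ≥ the target
  (0.85) or the 20-click cap. Evaluation uses r_max = k_max = 1 so the
  clicks-to-target statistic has single-click resolution.

4-connectivity defines objects, error regions and phenotype clusters
throughout — one convention everywhere.

## Backends

All backends satisfy one contract: inputs (image, positive guidance,
negative guidance, one possibly-blank prior channel, all spatially aligned,
values in [0, 1]), output a per-pixel object probability; binary masks use
threshold 0.5. Test doubles (ground-truth oracle, constant mask) pin the
protocol's endpoints: the oracle always yields clicks-to-target 1, a
constant-empty backend always caps at 20.

**Prior-threshold baseline** (training-free). For each positive click:
if the prior channel is ≥ 0.5 at the click, add the 4-connected component
of the thresholded prior containing it; otherwise (blank prior, or prior
silent at the click) grow a colour-similarity region from the click on a
σ = 1 px blurred image (Euclidean RGB tolerance 0.2). Each negative click
landing inside the mask carves away the colour-similar region around it.
With a noise-free prior this segments an isolated object *exactly* from a
single click; its known failure mode, shared with the underlying idea, is
touching same-class objects, which one prior component cannot separate.

**Pixel-MLP backend** (trainable reference). The architecture is
deliberately small so that the full training scheme runs on one CPU in
minutes: a fixed multi-scale encoder (each of the six input channels raw
and Gaussian-blurred at σ = 2, 4, 8, plus five prior×colour and
prior×guidance product features; 29 features per pixel) feeding a
one-hidden-layer MLP (24 ReLU units, sigmoid output) trained by
backpropagation with Adam. Larger backbones can register under the same
contract. Training follows the iterative scheme:

1. per sample, draw a small initial click budget (U[1, 6]) and sample
   initial clicks — the remaining budget is reserved for corrections;
2. for up to 3 rounds, predict with the current weights, find error
   regions, add corrective clicks (cap 20), re-encode;
3. with probability 0.3 replace the prior channel with zeros for the whole
   sample (so the model stays usable without a prior);
4. minimise the **bootstrapped cross-entropy**: binary cross-entropy
   averaged over the hardest 25% of pixels (probabilities clamped at 1e-7);
5. learning rate decays exponentially, ×0.9 every 5 epochs, floored.

The reference schedule (initial lr 1e-4, 50 epochs, batch 5, floor 5e-7)
is kept as the documented `TrainConfig` default; desk-scale runs of the
small MLP use 10 epochs at initial lr 0.02, which Adam needs to move this
model's weights meaningfully within 400 gradient steps. Training is
deterministic for a fixed seed on one thread; a non-finite loss aborts with
the offending sample identified.

## Evaluation protocol

- IoU = |Pred ∩ GT| / |Pred ∪ GT|, computed at full frame after window
  restoration (windowing is an acceleration, not a metric change); defined
  as 1 for two empty masks, 0 when exactly one is empty (the convention
  only matters for degenerate inputs — protocol objects are never empty).
- clicks@85%: per object, the first cumulative click count with IoU ≥ 0.85,
  else 20; averaged over objects.
- mIoU-vs-clicks curve: mean IoU at each click count 1..20, carrying each
  session's last observed IoU forward after it stops (the carry-forward
  rule is this package's definition; a session that stops early has, in
  effect, accepted its mask).
- Paired prior-mode comparison: both arms (with prior / blank) run over the
  same objects with per-object random streams derived from (seed, scene
  index, object index), so the arms see identical randomness and the
  difference in means is attributable to the prior.

## Synthetic scenes and prior corruption

Scenes emulate the *structure* of in-vitro tissue-culture images, not their
appearance: a pale background and 1–4 irregular objects (thresholded
smoothed noise, optionally lobed or elongated), each a single 4-connected
region of ≥ 64 px on a 96×96 canvas, one of three classes with distinct
base colours, per-object colour jitter (±0.06) and additive Gaussian pixel
noise (σ = 0.10). Objects keep a 2 px gap by default, so they are isolated.
Priors derive from the ground truth with three independent corruptions
emulating an imperfect offline model: smooth boundary displacement of up to
3 px (errors provably confined to within the jitter radius of class
boundaries), per-pixel winner/other channel swaps at rate 0.05 (isolated
confident mistakes), and temperature softening (τ = 0.25, argmax-preserving).
These defaults are the benchmark's standing conditions.

What passing these tests shows: the protocol machinery is exact (oracle
agreement), the backends honour the contract, the training scheme learns,
and the prior's click-saving direction holds under moderate prior
corruption. What it does not show: performance on real images, where
appearance is not a near-sufficient cue, same-class objects touch, and
prior errors are spatially correlated with object difficulty. The colour
cue in particular makes the click-only (blank-prior) arm stronger here than
it would be on real data, so measured click savings are conservative in
that one respect and optimistic in others (no motion blur, lighting,
occlusion).

## Numerical and degenerate-input choices

- Distance transforms: exact Euclidean (`scipy.ndimage`), no sampling.
- Probability clamp 1e-7 keeps the loss finite at perfect predictions.
- Decision threshold fixed at 0.5; not tuned per backend.
- Ties (object centre, region interior, channel selection) break by the
  seeded rng or, for channels, the lowest index — never by memory layout.
- An object too small for its minimum area, a click outside bounds, a
  window excluding a positive click, an empty record set and an unknown
  mask label are all rejected with explicit errors rather than coerced.

## Known limitations

- Per-pixel classification (even with multi-scale features) has no notion
  of instance connectivity; the trained backend can include distant
  same-class pixels when guidance is ambiguous.
- The baseline's negative-click carving removes colour-connected regions
  and can oscillate when touching same-class objects share one prior
  component.
- The training-free baseline's with-prior advantage is a mean effect over
  scenes; individual seeds can flip its sign, while the trained backend's
  advantage is large and stable (roughly 1.3 vs 2.7 clicks in paired runs).
- The phenotype module assumes one semantic mask per image; week-by-week
  distribution summaries count images, not pixels.
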