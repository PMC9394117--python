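# segclick

Semantic-prior-guided interactive object segmentation, with the simulation
and evaluation machinery needed to measure how many user clicks a segmenter
requires — plus the tissue-trait statistics used downstream in plant
phenotyping.

## The problem

Pixel-accurate training masks are the bottleneck of deep segmentation in
plant biology: tissues such as callus, shoot and stem have curved, irregular
boundaries that are slow to draw by hand. Interactive object segmentation
replaces drawing with a handful of *positive* clicks (inside the object) and
*negative* clicks (outside); a model turns the image plus encoded clicks
into a binary object mask, and the annotator adds corrective clicks until
the mask is right. This package implements and evaluates the variant in
which the model additionally receives one channel of a **semantic prior
map** — a per-class probability map from an offline semantic segmentation
model — selected automatically as the class scoring highest at the positive
click locations. The hypothesis under test: the prior reduces the number of
clicks needed to reach a target mask quality.

## What is implemented

- **Click encoding** (`segclick.encoding`): clicks of either polarity
  encoded as guidance maps, either the clipped minimum Euclidean distance
  `u_{x,y} = min_{(i,j)∈P} √((i−x)² + (j−y)²)` to the click set `P`, or the
  pointwise maximum of unit-height Gaussians `exp(−d²/2σ²)`. An empty click
  set encodes as an all-zero blank map. Bounding-box windowing crops all
  inputs jointly and restores windowed predictions at full frame.
- **Prior channel selection** (`segclick.prior`): per-class sums of the
  prior channels at the positive click pixels; the highest-scoring tissue
  channel (background excluded, ties to the lowest index) is handed to the
  backend; a blank channel stands in when no prior exists.
- **Simulated user** (`segclick.simulate`): initial sampling of n positive
  + m negative clicks up to a 20-click budget (center-first, d_step-spaced
  positives; negatives on nearby objects then in a background ring), and
  corrective sampling that partitions mispredicted pixels into 4-connected
  error regions and clicks the most interior point of regions drawn with
  probability proportional to their size.
- **Backends** (`segclick.backends`): one contract — image, positive and
  negative guidance, prior channel in, per-pixel probability out — behind a
  registry. Ships a ground-truth oracle and a constant mask (test doubles),
  a training-free `prior_threshold` baseline (flood-fill of the thresholded
  prior from the clicks, colour-similarity region growing when the prior is
  blank), and a trainable `pixel_mlp` backend: a per-pixel MLP over
  multi-scale features trained with iterative click simulation, random
  prior reset, bootstrapped cross-entropy and an exponentially decaying
  learning rate (1e-4, ×0.9 every 5 epochs, floored at 5e-7 in the
  reference schedule).
- **Evaluation protocol** (`segclick.evaluation`): IoU, mean clicks to
  reach IoU ≥ 85% (failures counted as the 20-click cap), mean-IoU-vs-click
  curves, and paired with-prior vs blank-prior comparisons using common
  random numbers.
- **Phenotype statistics** (`segclick.phenotype`): per-class pixel area
  `Area_c = Σ_{x,y} 1_c(I_{x,y})`, relative area
  `RArea_c = Area_c / Σ_{c'} Area_{c'}` over tissue classes, per-class image
  fractions and isolated 4-connected cluster counts, with per-image tables
  and dataset/replicate averages.
- **Synthetic scenes** (`segclick.scene`): multi-class instance scenes with
  irregular tissue-like shapes, ground-truth masks, and corruptible priors
  (boundary jitter, channel confusion, score softening) so everything above
  is testable without external data.
- **I/O + CLI** (`segclick.io`, `segclick.cli`): palette PNG label masks
  (by class / by object / nested), 16-bit instance PNGs, multi-channel
  float32 prior TIFFs with JSON sidecars, JSON session records, CSV trait
  tables and curves; subcommands `simulate-data`, `encode`, `train`,
  `evaluate`, `phenotype`.

## Worked example

```python
import numpy as np
import segclick as sg

scenes = sg.generate_scenes(50, sg.SceneConfig(), seed=11)
rng = np.random.default_rng(11)
priors = [sg.make_prior(s, sg.PriorNoise(seed=int(rng.integers(0, 2**31 - 1))))
          for s in scenes]
report = sg.compare_prior_modes(scenes, sg.PriorThresholdBackend(), priors, seed=11)
print(f"mean clicks@85%: with prior {report.mean_clicks_with_prior:.2f}, "
      f"blank {report.mean_clicks_blank:.2f}")
```

prints

```
mean clicks@85%: with prior 2.41, blank 2.92
```

i.e. over the 150 objects of 50 synthetic scenes, the training-free baseline
needs on average 2.41 simulated clicks to reach an IoU of 85% when it
receives a moderately corrupted semantic prior, versus 2.92 clicks when the
prior channel is blank — the prior saves about half a click per object for
this backend, and substantially more for the trained backend (see below).

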