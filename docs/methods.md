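# Methods

`pollenstage` implements a progressive "localization first, then
classification" pipeline for identifying allergenic pollen grains in
whole-slide microscopy images (WSIs), together with a synthetic slide
simulator that exercises the pipeline end to end with exact ground truth.
This note records the model choices, the parameters that matter, what the
simulator does and does not emulate, and the numerical decisions taken
where the design was genuinely open.

## Pipeline model

A slide of L x H pixels is processed in three stages, mirroring how a
palynologist reads a slide:

1. **Preprocessing** — the raster is cut into the non-overlapping grid of
   l x l patches (default l = 512; border strips narrower than l are
   discarded, so M = floor(L/l) * floor(H/l)). A binary CNN scores each
   patch; patches whose foreground (softmax) probability strictly exceeds
   the confidence threshold tau = 0.5 form the candidate set. A probability
   of exactly 0.5 counts as background — the half-open background interval
   [0, 0.5) plus "exceed" for foreground leaves 0.5 ambiguous, and we
   resolve it toward background.
2. **Coarse-grained localization** — an anchor-based single-shot detector
   with a multi-scale feature pyramid proposes boxes in three coarse
   classes (pollen, impurity, bubble); only pollen regions are forwarded.
   The classification head is trained with the focal loss
   FL(p_t) = -(1 - p_t)^gamma log(p_t) (alpha-balanced during training) and
   the box head with smooth-L1 on encoded center/log-size offsets,
   L_loc = sum_i SmoothL1(t_i - v_i) over i in (x, y, w, h).
3. **Fine-grained classification** — detected pollen regions are cropped to
   100 x 100 and passed to a one-vs-rest ensemble: one dedicated binary CNN
   per taxon, each chosen from a menu of architectures by validation
   accuracy (heterogeneous selection), fused at decision level by maximum
   probability. The per-class probability vector is a set of independent
   binary posteriors and does not sum to one; ties break to the lowest
   class index. There is no rejection option at fusion — non-pollen regions
   are the detector's responsibility — though a minimum-probability flag
   exists.

## Desk-scale realization

The package targets a single CPU and minutes of runtime, so the
full-size deep backbones are replaced by small components with the same
structure and training contract:

* **Tiny CNN presets** (`_nn.py`): four convolutional families with
  distinct inductive biases — a wide-kernel shallow net with a dense head
  (`alexnet-tiny`), a deep 3x3 stack (`vgg-tiny`), a residual net
  (`resnet-tiny`), and a densely connected net (`densenet-tiny`) — all on
  32 x 32 inputs, trained by momentum SGD (momentum 0.9, batch 16, at most
  100 epochs, early stopping once the validation loss stops improving).
  The default learning rate is 0.01: the 1e-3 rate customary for large
  pretrained networks converges an order of magnitude too slowly for these
  tiny randomly initialized models. Early stopping is armed only after a
  minimum epoch count (8) and the validation split holds at least 8
  samples; with fewer, the stopping signal is pure noise on small datasets.
* **Patch-filter input**: the patch is downsampled to 32 x 32 and the
  per-patch median color is subtracted. The median estimates the blank
  field, so background maps to ~0 and any object leaves a localized signed
  deviation. Without this normalization the pooled tiny nets cannot find
  the weak global signal of a small object in a large pale patch.
* **Detector backbone**: a fixed descriptor pyramid instead of a learned
  deep stack. Each pyramid level (strides 8/16/32, anchor base sizes
  32/64/128, three aspect ratios, three scale multipliers — the canonical
  single-shot configuration reduced to three levels) carries per-cell RGB
  means/standard deviations, gradient energy, and 3x3 context; with fusion
  enabled the coarser level's features are upsampled and added top-down.
  Disabling fusion leaves a single pyramid level — the "without multi-scale
  fusion" ablation is structurally a single-scale model. Each anchor
  additionally sees pooled box statistics computed from integral images
  (interior color, surround-ring contrast, variance, gradient energy, and
  half-box asymmetries; the asymmetries are what lets a linear map regress
  center offsets). Classification and regression heads share a small
  hidden ReLU trunk (48 units; configurable, 0 gives linear heads).
  Training uses alpha = 0.5 rather than the canonical 0.25: with this
  backbone the 0.25 weighting suppresses positives enough that
  low-contrast taxa fall below any usable operating threshold.
* **Operating points**: anchors score through a sigmoid; the pipeline
  forwards pollen detections above 0.6 after class-wise suppression at
  IoU 0.3. The suppression threshold matches the simulator's overlap cap
  (see below), which makes it lossless there; the module-level defaults
  remain the canonical 0.05/0.5.
* **Stitching**: because tiling is strictly non-overlapping, an object on a
  grid line appears as two (or, at a corner, four) partial detections.
  After mapping detections to slide coordinates, boxes that abut across a
  grid line (within 4 px, perpendicular overlap >= 30%) are unioned, and a
  grid-touching fragment mostly contained in an existing union is absorbed.
  Stitched regions are re-cropped from the slide before classification.
* **OVR training**: negatives default to the full rest-classes pool (the
  module default); the pipeline subsamples them to 3x the positive count
  and augments crops with dihedral transforms (x3) plus 10% box jitter so
  the classifiers see detector-like framing. Without the jitter, grains
  framed by slightly loose detector boxes were systematically mislabeled
  despite perfect accuracy on tight ground-truth crops. Architecture
  selection uses a held-out slice of the full unbalanced pool (15%),
  separate from the trainer's internal early-stopping split.

## Synthetic slide simulator

The generator (`synth.py`) emulates the statistical structure of stained
airborne-pollen WSIs at desk scale (default 4096 x 2048; the full
110,000 x 50,000 geometry is reachable by configuration):

* a pale near-uniform background with smooth low-amplitude mottle, so the
  raster is dominated by foreground-free area;
* pollen grains as regular star-convex shapes in pink tones, eight taxa
  parameterized by (lobe count, boundary jitter, green/blue color
  coordinates, exine texture frequency). Class colors are spread over the
  green-blue plane so that at confusability 0 every pair of taxa is
  separated by a comparable margin; the confusability knob linearly
  interpolates all class vectors toward their mean (1.0 makes the taxa
  indistinguishable). Default per-taxon sampling weights mirror a typical
  aeropalynological collection with Populus and Salix under-represented;
* impurities as irregular random-Fourier blobs in yellow/brown, bubbles as
  colorless circles with a thin gray rim;
* placement is a homogeneous Poisson process (expected counts = density x
  slide area) with rejection of boxes crossing the slide border and a
  pairwise box-IoU cap of 0.3, keeping detection matching unambiguous;
* grain diameters are uniform in [30, 90] px by default — a modeling
  choice consistent with 100 x 100 region crops at 40x magnification.

Exact ground truth (boxes, coarse and fine labels, patch-level
foreground flags) is emitted alongside the pixels; the same (config, seed)
pair reproduces both byte for byte.

What the simulator does **not** emulate: optical blur and focus variation,
staining variability, agglomerated pollen clusters, debris with
pollen-like color, and intra-taxon morphological diversity beyond the
jittered parameters. Passing tests therefore demonstrate that the pipeline
machinery is correct and that its stages compose as designed — not that
the trained desk-scale models would transfer to real micrographs.

## Evaluation

* IoU and the COCO-style AP family: AP is the mean of interpolated average
  precision over IoU thresholds 0.50:0.05:0.95 (101-point all-points
  interpolation; an 11-point switch exists). Matching is greedy by
  descending score, each ground truth claimed once at the threshold.
* End-to-end identification accuracy is grain-level:
  correct / (ground-truth grains + false positives), where a grain is
  correct when an identification matches it (IoU >= 0.5 box-level, or
  center containment for patch-level outputs) with its true taxon, and a
  false positive is an identification matching no grain. The denominator
  includes false positives deliberately: misidentifying impurities or
  blank tiles as pollen is exactly the failure mode the filtering and
  localization stages exist to remove, and a pure-recall definition would
  be blind to it.
* Cross-validation uses stratified ten-fold splitting; classes with fewer
  than ten members are rejected with a hint to augment.

## Reference studies

`experiments.py` packages three study conditions (all seed-derived):

* **identification study** — two dense + two sparse training slides and two
  medium test slides at confusability 0 with equal taxon weights; measures
  end-to-end accuracy, filter accuracy, and detector AP.
* **ablation study** — 2048 x 1024 slides at patch size 128 with grains of
  60–110 px (so classifier-only variants see near-crop framings), test
  slides with as many impurities as grains and a majority of blank tiles;
  runs the four variants (direct sampling vs. filtering) x (localization
  on/off) over five training seeds.
* **fusion study** — grain diameters spanning 24–120 px; compares AP50 of
  the three-level fused detector against the single-level model over five
  training seeds.

Problem sizes were chosen so each study trains and evaluates in minutes on
one CPU; `scripts/acceptance.py` re-runs all three from scratch and writes
the measured quantities as JSON.

## Known limitations

* The descriptor-pyramid backbone is hand-designed; on imagery whose
  foreground/background statistics differ from the simulator's, the fixed
  descriptors may be uninformative where a learned backbone would adapt.
* Probabilities entering max fusion are raw binary posteriors without
  calibration; members trained on very different class balances can be
  mutually overconfident (mitigated here by the shared negative-ratio and
  augmentation policy).
* Stitching assumes at most one object per grid crossing; dense clusters
  straddling a border can merge into a single region.
* The patch-level scoring used by classifier-only ablation variants
  credits one label per tile, so multiple same-class grains in a tile are
  all scored by the same prediction.
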