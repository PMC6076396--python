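# Methods

`phenoseq` classifies rosette plants into accession (genotype) classes from
top-view daily growth image sequences. This note documents the models, the
synthetic data the package bundles, the numerical choices, and what the
bundled experiments do and do not demonstrate.

## Problem and pipeline

A plant is observed as an ordered sequence of top-view RGB frames, one per
day (22 by default). The task is to predict the plant's accession from the
whole sequence. Five systems are implemented and compared:

1. **handcrafted + SVM** — per-frame handcrafted descriptors, an RBF-SVM
   frame classifier, and a majority vote over the sequence;
2. **handcrafted + LSTM** — the same descriptors fed as sequences to a
   stacked LSTM classifier;
3. **CNN** — a per-frame convolutional network trained on area-split
   sub-classes; genotype scores are summed over sub-classes, frames vote;
4. **CNN + CRF** — deep per-frame features under a shared-label linear-chain
   conditional random field;
5. **CNN + LSTM** — deep feature sequences into the stacked LSTM.

## Plant segmentation

Frames are converted to CIE L\*a\*b\*; green vegetation separates from brown
soil along a\* (green negative) and b\* (yellow positive). Each channel is
Otsu-thresholded; the binary mask is dilated (disc, radius 5 px at a 256 px
canvas, scaled proportionally) and added onto itself, giving a 3-level mask —
0 definite background, 1 the protective ring where faded leaf borders may
hide, 2 foreground. The two 3-level masks combine element-wise into the
4-level GrabCut seed: both-0 → definite background, both-2 → definite
foreground, any 2 against {0,1} → probable foreground, remaining {0,1}
pairs → probable background (encoded 0/1/2/3 as definite background /
definite foreground / probable background / probable foreground).

GrabCut runs from this seed with the bounding box as large as the image:
full-covariance 5-component Gaussian colour mixtures for foreground and
background are refit each iteration (5 by default, with early stopping when
the labelling fixes), pixel unaries are negative mixture log-likelihoods, a
contrast-sensitive 4-neighbour smoothness term (gamma = 50, beta set to the
inverse mean squared neighbour difference) regularises the boundary, and the
labelling is solved exactly as a minimum s-t cut (integer-scaled capacities,
residual-graph reachability for the partition). Definite seed pixels are
pinned by infinite-capacity terminal links and re-imposed after the final
morphological opening-then-closing (disc, radius 2, same scaling).

Degenerate inputs: a constant channel, or an a\* channel whose Otsu split
explains less than `min_bimodality = 0.5` squared gray levels of between-class
variance, is treated as plant-free and yields an empty mask. The floor was
placed between the two regimes observed on rendered frames: soil-only frames
measure ≈ 0.1, the smallest 2-day seedlings ≈ 1. On real imagery this guard
would need recalibration to the camera and soil.

An affine colour correction (3×3 matrix + offset, least squares on ≥ 4
colour-card patch pairs) is provided for imagery that carries a card.

## Handcrafted descriptors (1056 per frame)

* **colour [12]** — mean/max/min of R, G, B and mean H, S, V over foreground
  pixels (H, S, V on [0, 1]).
* **shape [8]** — area (px), perimeter (px), roundness = area/perimeter,
  compactness = area / convex-hull area, eccentricity = hull major/minor
  axis ratio (≥ 1), both axis lengths of the second-moment ellipse, and
  extent = area / bounding-box area. Roundness and eccentricity are the
  ratio definitions, deliberately not the isoperimetric quotient or conic
  eccentricity; a flag restores conventional roundness.
* **Fourier [1024]** — the outer contour of the largest connected component,
  resampled to 512 equally spaced points, read as complex x + iy and Fourier
  transformed; the DC (zero-frequency) term is zeroed, which makes the
  descriptor exactly translation invariant; 512 real parts then 512
  imaginary parts. 512 points is the only resampling count consistent with
  a 1024-element real/imaginary layout.
* **GLCM [12]** — Energy, Contrast, Homogeneity of gray-level co-occurrence
  matrices at offset distance 1 in directions 0°, 45°, 90°, 135°
  (direction-major order). Foreground gray values are quantised to 32 bins
  over their own range (hence invariance to affine gray rescaling); only
  pixel pairs that are both foreground are counted; matrices are symmetrised
  and normalised. The masked counting is implemented in-package because the
  standard library routine has no mask support.

Frames where no plant is present yet contribute a zero descriptor row.

## Per-frame CNN and deep features

A genotype spans seedling to adult rosette, so the raw genotype is visually
incoherent as a training class. Within each genotype, plant areas (foreground
pixel counts) are split at their 20/40/60/80 % quantiles into five bins, and
the CNN is trained on the L×5 (genotype, area-bin) sub-classes; ties fall to
the lower bin, and a genotype with fewer samples than bins gets a reduced bin
count. Training images are augmented with their 90°/180°/270° rotations.

The backbone is a compact convnet: three blocks of 3×3 convolution → ReLU →
2×2 max-pool with widths 16/32/64, then a 128-unit dense feature layer and
the sub-class softmax head. Frames are resized to 48×48 (32×32 in the
smaller experiments) with anti-aliasing and normalised per channel using
training-set statistics. Optimisation is SGD: learning rate 0.001, momentum
0.9, weight decay 1e-6, mini-batches of 32; everything is float32 NumPy with
explicit backward passes, deterministic given the seed. Deep features are
the 128 penultimate-layer activations. An `alexnet-finetune` backbone hook
exists for externally supplied pretrained weights; it is not bundled, and the
compact network is the supported configuration.

The benchmark trains the CNN on alternate-day frames (11 of 22 per plant) —
consecutive daily frames are nearly redundant for a per-frame classifier —
and extracts deep features for every frame. Epoch count is a free parameter
(25 in the bundled benchmark; the training loss is still falling slowly
there, so more epochs buy accuracy at proportional cost).

## Sequence models

The classifier stacks two LSTM layers (256 hidden units each, the second
consuming the first's hidden states) and reads out class scores from the
final time step (a per-step-mean readout is available behind a flag).
Training: softmax cross-entropy on the final-step scores, SGD with learning
rate 0.01, momentum 0.9, weight decay 0.005, mini-batches of 32, input
features standardised on the training set. Numerical choices: Glorot
uniform initialisation, forget-gate bias initialised to +1, global-norm
gradient clipping at 5 — standard recurrent-training practice, documented
here because the update rule itself is otherwise exactly the printed
recurrences (`lstm_step`/`rnn_step` are the single-step reference
implementations, and the batched trainer is tested to agree with them).

Rotation augmentation extends to sequence-model training: the deep features
of each training plant's four frame rotations form four training sequences
(test sequences are never augmented). With only tens of training plants the
un-augmented LSTM and CRF memorise the training sequences; the rotated
sequences are genuinely new inputs because the CNN's features are not
rotation invariant. The handcrafted LSTM is not augmented this way — the
descriptor battery is rotation invariant by construction, so rotated
sequences would be near-duplicates.

The CRF baseline is a linear-chain model under the constraint that all
frames of one plant share one label: the score of class k for a sequence
collapses to the summed per-frame unary scores plus (T−1) times the
self-transition reward, trained by maximum conditional likelihood (full-batch
gradient descent with momentum, L2 regularisation). Under shared labels the
off-diagonal transitions receive no gradient; a full transition matrix can
still be supplied for hand-constructed scoring. This reduction is the
package's reading of an under-specified baseline: the CRF consumes the same
deep features as the LSTM and emits one accession label per sequence.

The SVM baseline standardises per-frame features, fits an RBF-SVM with
default regularisation, and takes a majority vote over the sequence's frame
predictions; vote ties and score ties resolve to the lowest class index.

Splits are always by plant — never by frame — stratified by genotype and
seeded (round-robin dealing per class); a leakage assertion guards every run.
The default protocol is a single stratified 75/25 split; k-fold assignments
are available from the same splitter.

## Synthetic rosette generator

The generator emulates chamber imagery: a soil-textured background
(low-frequency brown noise plus speckle), a centred rosette of rotated
filled-ellipse leaves placed by a phyllotaxy angle, per-accession parameters
for leaf-addition schedule, expansion rate (px/day at the 256 px reference
canvas, scaled proportionally), leaf aspect ratio and hue distribution.
Per-plant nuisance draws: germination offset uniform on {0,1,2,3} days,
expansion-rate jitter (s.d. 6 %), leaf-angle jitter (s.d. 9°), hue jitter
(per-accession s.d.), and imaging nuisance emulating residual
colour-calibration error — per-plant white-balance gains (s.d. 5 % per
channel), per-day exposure flicker (s.d. 3 %) and an optical blur (sigma
0.8 px at a 128 px canvas) that fades leaf borders into the soil. Geometry
is deterministic given (spec, day, seed), and for fixed seed the whole
dataset reproduces byte for byte.

Three panels are bundled:

* `default_accession_panel()` — the 4-class benchmark. Classes 0/1 share
  identical static appearance and differ only in temporal parameters, with
  **matched area trajectories**: one adds many leaves that expand slowly,
  the other few leaves that expand fast, so total area does not separate
  them — how the rosette is assembled over time does. Classes 2/3 share one
  intermediate schedule and differ in leaf shape (aspect 1.7 vs 3.1), hue
  (112° vs 78°, against 96° for the pair) and phyllotaxy.
* `dynamics_pair_panel()` — two accessions with identical static appearance:
  an early-vigour accession that develops fast and plateaus (smaller
  asymptotic leaf size, `max_leaf_len_frac`) at roughly the size a
  steady-growth accession only reaches on the last days. Most frames of
  either class have a look-alike somewhere in the other class's timeline,
  so per-frame classification is poor while the growth trajectories separate
  cleanly. This is the panel for the temporal-benefit experiment.
* `easy_accession_panel()` — widely separated classes (large hue, shape and
  rate gaps, low jitter) for segmentation fixtures and feature sanity checks.

What the generator does **not** model: leaf occlusion physics and
self-shadowing, perspective distortion, moss/weeds/water droplets, diurnal
leaf movement, colour cards, or multi-plant trays. Passing benchmarks on
this data therefore demonstrates that the pipeline's machinery is correct
and that its ranking of systems emerges from the intended mechanisms (deep
features beating noisy summary statistics, temporal models beating per-frame
votes), not that the same accuracies would be obtained on chamber imagery.

## Bundled benchmark protocol

The benchmark generates 4 classes × 20 plants × 22 days at a 128 px canvas,
segments every frame with the GrabCut pipeline (both the handcrafted
descriptors and the CNN's area bins consume these masks — descriptor quality
is deliberately coupled to segmentation quality, which is what degrades the
handcrafted systems on imperfectly separable imagery), and evaluates all
five systems on a stratified 25 % plant hold-out. Problem sizes (canvas,
input resolution, epoch counts, alternate-day CNN training, a single split
rather than full cross-validation) are desk-scale choices that keep the
full comparison around a quarter of an hour on one CPU. The dynamics-only
temporal-benefit experiment uses the pair panel with 20 plants per class and
a 50/50 split on generator truth masks, since its question — trajectory
versus per-frame information — does not involve segmentation noise.

The five-system comparison and the dynamics-only experiment are *bundled
reference experiments*: they are defined with a fixed seed
(`phenoseq.pipeline.BENCHMARK_SEED`, exposed via `benchmark_config()` and
`dynamics_benchmark_config()`), the way a frozen benchmark dataset would be
released, and the accuracies quoted in this documentation refer to exactly
those runs.

## Known limitations

* The compact CNN is trained from scratch; with tens of plants per class its
  accuracy has substantial seed-to-seed variance, and because the per-frame
  CNN sits in the middle of the five-system ranking, the full ranking is not
  stable across regenerated datasets — that is why the reference experiments
  are pinned to the bundled seed. Fine-tuning a pretrained backbone (the
  `alexnet-finetune` hook) is the path to stronger, stabler per-frame
  features.
* The shared-label CRF reduction ignores within-sequence label dynamics by
  construction; it is a sequence scorer, not a frame labeller.
* The empty-frame guard (`min_bimodality`) is calibrated to the bundled
  renderer, not to arbitrary cameras.
* Handcrafted hue statistics use the circular-naive mean; rosette hues span
  a narrow arc where this is harmless, but it would bias hues near the
  red/magenta wrap-around.
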