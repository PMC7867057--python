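# Methods

This note documents the models, parameter choices and numerical
decisions behind `multisal`, in the order data flows through the
pipeline.

## Gaze logs and fixation extraction

A gaze log is an ordered stream of binocular samples: timestamp (ms),
left/right gaze position (image pixels, 0-based, x = column), the
device's movement label (fixation / saccade / other), a binary binocular
validity flag, and optional pupil sizes and viewing distance.  The
canonical storage dialect is UTF-8 TSV with one header row; timestamps
are stored to 0.01 ms and positions to 0.01 px, and round trips are
lossless at that precision.  Screen-to-image coordinate mapping (offset
and scale) is applied at import, because display geometry differs
between experiments and the convention must be explicit.

Fixation extraction works on *movement events*, not samples, because a
60 Hz tracker repeats one fixation over many samples.  Runs of samples
sharing a label, a validity flag and a position (to within 0.5 px on
either eye) are coalesced; any change opens a new event, so a validity
dropout in mid-fixation splits it — we treat the device's flags as
authoritative rather than bridging gaps.  Event *i*'s duration is the
difference of start timestamps *i*+1 − *i*; the final event has no
successor and is dropped rather than assigned an arbitrary duration.
Fixation events must pass both filters (label = fixation, validity
positive — the two commute) and their position is the component-wise
mean of the two eyes.  Fixation *detection* from raw traces (I-VT/I-DT)
is out of scope: the device supplies the labels.

## Heat maps

Raw delta maps place impulses of height = duration (s) at the fixation
pixel; coordinates are rounded half-up, sub-pixel splatting was rejected
to keep maps bit-exact and the raw-map/fixation-set correspondence
invertible.  Out-of-bounds fixations are discarded and counted.

The smoothing kernel is an isotropic Gaussian with R = 100 px and
σ = 20 px on a (2R+1)² window, **normalized to unit sum** so that the
filtered map's mass equals total fixation time and intensities are
comparable across observers.  Convolution is linear with zero padding
(scipy's overlap-add method): mass that falls off the image vanishes,
which makes conservation exactly testable for interior fixations
(|error| < 1e−6 asserted; measured ≈ 1e−16).  The continuous FWHM is
2√(2 ln 2)·σ = 47.10 px; the commonly quoted rounded figure is 48 px,
and at 4.26 px/mm display density and 600 mm distance the half-max
extent subtends 2·arctan(48/(2·4.26·600)) = 1.0759° ≈ 1.075° (truncated).
Accumulation is the pixelwise sum of raw maps; accumulate-then-smooth is
canonical and equals smooth-then-accumulate by linearity (asserted to
1e−9).

## Saliency comparison metrics

Maps are compared in ordered pairs (ground truth → test).  Ground-truth
fixations are read off the **raw** delta map — one point per nonzero
pixel, weight = accumulated duration — never off a thresholded filtered
map, which would blur the ground truth.  For dense model-predicted maps
(which have no raw counterpart) the top 1% of pixels serve as a
pseudo-fixation set.

- **NSS** z-scores the test map with its **population** SD; SD below
  1e−12 is treated as a constant map and scores 0 by convention.
  Fixations are unweighted by default (duration weighting is a flag);
  the literature does not weight them.
- **AUC family**: thresholds sweep every distinct score, and the
  trapezoidal ROC area then equals the Mann-Whitney statistic
  P(pos > neg) + ½P(pos = neg) — ties get half credit.  This exhaustive
  sweep is exactly equivalent to strict thresholds placed just below
  each value, and is asserted against a pairwise-enumeration oracle to
  1e−12.  AUC-Judd uses all non-fixation pixels as negatives (an error
  if fixations cover the whole map); AUC-Borji draws |fixations|
  negatives uniformly without replacement per split (default 100 seeded
  splits); the shuffled AUC draws them from a pool of fixations on
  *other* images of the study — within one image there is no natural
  pool, so the study orchestrator pools all other images' accumulated
  fixations.
- **IG** regularizes both maps into probability distributions: every
  pixel receives an extra ε share of the map's total mass (default
  ε = 1/(H·W), i.e. a uniform admixture; configurable), then the mean
  of log₂p_test − log₂p_gt over fixation pixels is reported in bits per
  fixation.  IG(T, T) = 0 identically.  In the per-band analysis the
  sign convention is RGB-minus-band, so positive IG means the RGB map
  is the more informative one.

Chance calibration (seeded Monte-Carlo, asserted in the tests): on
i.i.d. uniform maps with random fixations all AUC variants sit at
0.5 ± 0.05 and NSS and IG at 0 ± 0.05.

## Image complexity metrics

All five are computed from the 8-bit RGB rendering, converted to
grayscale (mean of R, G, B) where a single channel is needed.

- Gradients are central differences.  For G_max (complexity) borders are
  replicated, which keeps M_Co exactly flip-invariant.  For per-section
  HOGs borders are periodic: a texture tiled on the section grid is then
  *exactly* self-similar (M_SeSf = 1), which replicated borders would
  break through seam artifacts.
- HOG: 16 unsigned orientation bins over [0°, 180°), magnitude-weighted,
  L1-normalized; orientation is the **edge** orientation (gradient angle
  + 90°), so a vertical grating loads the 90° bin.  A section with zero
  gradient energy falls back to a flagged uniform histogram, so constant
  images yield M_SeSf = 1 and anisotropy = 0 rather than NaN.  Bin count
  and pyramid depth are configurable.
- Pyramid: level k is a 2^k × 2^k grid (4^k sections), floor division
  with right/bottom remainders discarded; level 3 (64 sections of an
  8×8 grid) is compared against level-2 parents.  The metric is the
  median of the 64 HIK values.
- M_Co is the **mean** of G_max over pixels ("mean norm of the
  gradient"); a printed sum-form of this definition is typographically
  garbled in the source literature, and the mean is the reading
  consistent with its prose.
- M_BLM = M_SeSf / M_Co is undefined (None), not infinite, for a
  gradient-free image.
- Anisotropy pools the bin values of all 64 level-3 histograms and takes
  the population variance (the per-section-scalar alternative is
  ambiguous in the literature; the pooled reading is implemented and
  documented).
- Entropy uses the 256-bin histogram of the 8-bit grayscale image with
  0·log 0 = 0, hence 0 bits for constant and 8 bits for uniform images.

## Multispectral imaging

Cubes are float arrays in [0, 1] (the cameras they model digitize at 12
bits), 8 bands with default centers 425, 482, 530, 570, 615, 680, 770,
833 nm.  Storage is float32 multi-band TIFF plus a JSON sidecar (band
metadata, region masks, provenance) since no standard container exists
for this.  Rendering maps bands 6/4/2 (1-based) to R/G/B; "normalized to
(0, 1)" is read as per-channel min–max (a divide-by-max variant is
available by flag), followed by half-up 8-bit quantization, with no
gamma applied.  PNG is preferred for lossless fixtures; a JPEG writer
exists for fidelity with the original capture format but is excluded
from bit-exact tests.  Subdivision uses floor division and discards
remainders (2058/4 = 514.5 → 514-px tiles), matching the printed tile
sizes of the emulated experiments.

## Synthetic data: what it emulates, and what it does not

Scenes are axis-aligned rectangular regions painted in order (later
regions win), each with an 8-band mean profile and i.i.d. Gaussian
texture noise, clipped to [0, 1]; a "vegetation" region is one whose NIR
bands exceed its visible bands, mimicking the chlorophyll reflectance
rise.  Region rectangles are recorded in metadata so masks are
recoverable.  The generator does **not** model photorealistic structure,
camera noise physics or radiometric calibration.

Gaze is an alternating fixation/saccade timeline sampled at 60 Hz.
Defaults are the emulated study conditions: 6 s display per image, 10
observers, fixation durations uniform in 150–400 ms and saccades in
20–80 ms (typical scene-viewing magnitudes; the uniform law is the
simplest controllable choice), binocular offset SD 2 px drawn once per
event and split symmetrically (so the binocular mean recovers the true
gaze point exactly), validity dropout 5% per fixation sample.
Fixations land on Gaussian attractors chosen by weight; the two tasks
share attractor locations but reverse the weight order, a deterministic
way of shifting emphasis.  Off-screen fixations are only generated when
explicitly configured.  Real gaze has center bias, saccadic
undershoot, smooth pursuit, and drift within fixations — none of which
is modelled, so passing tests demonstrate pipeline correctness, not
behavioural realism.

Everything is seeded: identical seeds reproduce bundles bit for bit
(observer *i* uses the stream (seed, *i*)).

## Validation experiments

Four seeded experiments (in `multisal.validation`) calibrate the whole
chain; the acceptance script re-runs them from scratch:

- **chance calibration** — 20 trials of random 128² maps with 200 random
  fixations each;
- **mass conservation** — 40 interior fixations, relative error of
  filtered mass vs fixation time (≈ 1e−16);
- **attractor recovery** — 100 runs, 5 observers, spread 20 px, dropout
  5%: the accumulated filtered map must peak within 40 px (2σ of the
  kernel) of the planted dominant attractor in ≥ 95% of runs;
- **independence null** — 200 scenes of varying complexity with gaze
  attractors drawn independently of content: every mean r² between
  comparison metrics and complexity metrics stays below 0.05.  The gaze
  stream is seeded separately from the scene stream; sharing one stream
  would silently correlate content with gaze and break the null.

The desk-scale analysis uses 6 scenes × 10 observers (chosen so the full
study runs in seconds while still exercising the 45-pair combinatorics);
the r² values it prints are therefore noisy, and the 200-scene null is
the calibrated check.

## Known limitations

- The saliency predictor is a deterministic local-contrast baseline
  (|gray − wide-Gaussian blur|, min–max normalized) behind a pluggable
  predictor interface; it is not a state-of-the-art saliency model, and
  per-band conclusions drawn from it characterize the harness, not
  human vision.
- Statistics are classical (least squares, Pearson r², one-way ANOVA
  with p from the F distribution, no multiple-testing correction, raw
  p values reported) — appropriate for the table structures produced,
  not for confirmatory inference.
- Correlation tables with few images are descriptive only; degenerate
  fits (constant predictor or response) are flagged and score r² = 0.
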