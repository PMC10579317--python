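# Methods

## Scope and model

`fundusqc` implements a three-stage quality pipeline for infant fundus
photographs: (1) multidimensional assessment — a posterior/peripheral
location decision gating per-aspect binary "poor" classifiers; (2)
comprehensive scoring — IQCS = 1 − Σ wᵢpᵢ with weights summing to one
(equal by default; k = 6 posterior aspects, k = 3 peripheral), graded by a
threshold pair fitted by grid search; (3) targeted enhancement — gamma +
bilateral for poor illumination, CLAHE (red/green) for poor clarity,
discard below the lower threshold, rephotograph advice for poor integrity.
Validation utilities cover ELO-based expert-ranking agreement and the
usual screening statistics (Wilson CIs, DeLong AUC machinery, z/t tests).

Because no public infant-fundus cohort with quality annotations exists,
the package ships a synthetic generator whose defect parameters define
ground truth, and all quantitative claims in the test suite are about this
synthetic population, not about clinical data.

## Synthetic generator

Images are seeded, deterministic functions of their spec: a warm-toned
circular retinal field (radial falloff + Gaussian speckle) on a dark
background; posterior views add a bright elliptical optic disc at 0.45 R
on the nasal side and a darker macula near the centre; sinusoidally
wiggling vessel curves radiate from the disc (posterior) or the nasal
edge (peripheral). ROP features: a bright annular ridge band at 0.75 R
(stage-2-like) or tortuous dilated vessels (plus-like).

Defects and their label thresholds (mechanical surrogates for
human-judged annotation criteria):

| defect | operation | "poor" when | severe (ineligible) when |
|---|---|---|---|
| illumination | region × (1 − s) | s ≥ 0.4 | s ≥ 0.8 |
| clarity | Gaussian blur σ (px) | σ ≥ 1.5 | σ ≥ 3.0 |
| integrity | chord truncation, fraction f | f ≥ 0.15 | f ≥ 0.30 |

Grade: excellent if no aspect is poor, ineligible if any parameter is in
the severe tier (2× the poor threshold), else eligible. Integrity
defects and whole-field darkening apply to peripheral images; posterior
darkening targets one region (macula / optic disc / remaining).

What the generator does **not** emulate: camera optics and vignetting,
pigmentation variation, motion blur anisotropy, real lesion morphology.
Passing tests therefore demonstrate internal consistency of the method,
not clinical performance.

## Classical assessment backend

Deterministic logistic links over hand-crafted features; all constants
are fixed calibration values chosen once so that p = 0.5 falls at each
generator label threshold:

* **Illumination**: p = σ((L0 − mean region luminance)/s), with
  per-region references L0 = 0.6 × the clean region's Rec.-601 luminance
  (macula 49, optic disc 94, remaining 69, whole field 68).
* **Clarity**: sharpness = Var(∇²(G₁ ∗ L)) / (mean L / 100)², i.e. the
  Laplacian variance of mildly pre-smoothed luminance normalised by mean
  luminance. The σ = 1 pre-smoothing makes the feature respond to
  structure-scale blur rather than pixel noise (so denoising does not
  masquerade as blurring); the normalisation decouples blur from
  darkening. The normalising mean is floored at 40: below that, the
  Laplacian is noise-dominated and a near-black region is reported
  unclear. p = σ((V0 − sharpness)/v) with V0 at the blur-threshold value.
* **Integrity** (peripheral): coverage = lit fraction (luminance > 20)
  of the expected circular field; p = σ((0.85 − coverage)/0.03), placing
  p = 0.5 at the 15%-missing label threshold.
* **Location**: posterior iff a disc-sized smoothed-luminance peak
  exceeds 145 (between the clean posterior ≈ 157 and peripheral ≈ 134
  blob values). The decision gates which aspect heads run; a
  `location_override` flag is available since heavily darkened posterior
  images can hide the disc.

## Tiny CNN backend

One binary conv-net per task (1 location + 6 + 3 aspect heads), mirroring
the one-model-per-task design of full-scale systems. Architecture:
3×3 conv (8) → relu → 2×2 max-pool → conv (16) → relu → pool →
conv (32) → relu → concatenated global average + global max pooling →
linear head. The max branch is essential for localized signals (a
darkened optic disc occupies ~1% of the frame; plain average pooling
cannot represent it and heads fail to converge). Training: BCE with
Adam; reduce-on-plateau halves the learning rate after 3 epochs without
validation-accuracy improvement; the checkpoint is the best-validation
parameter set; pixels are normalised to [0, 1]; the train/validation
split is by image id with no overlap. Inputs are resized to a square
`input_size` (minimum 64).

`TrainConfig` defaults (learning rate 0.001, batch 64, 50 epochs,
299-pixel inputs, decay factor 2, patience 3) describe the full-fidelity
recipe for large pretrained backbones; `desk_scale_config()` (64-pixel
inputs, 10 epochs, batch 32, learning rate 0.005) is what the tests and
demos use — the small from-scratch network needs the larger rate to
converge within a desk-scale budget. The `inception_v3` / `densenet`
backbone names are accepted in the config for full-fidelity runs but are
not implemented in this build and raise a clear error. Training is
bit-reproducible given (data, config, seed).

Grad-CAM: with a global-pool linear head, the spatial mean of
∂logit/∂A_k is (w_avg,k + w_max,k)/HW; the heatmap is
relu(Σ_k α_k A_k), bilinearly upsampled to the input size and
max-normalised to [0, 1].

## Scoring and thresholds

IQCS = 1 − Σ wᵢpᵢ; scores within 1e-12 of 0 or 1 are snapped to the exact
bound. Grade boundaries classify upward (score = lower → eligible,
score = upper → excellent); the grid search enumerates the integer-tick
lattice (i/20, j/20) to avoid float drift and breaks accuracy ties to the
lexicographically smallest (lower, upper) pair. One shared threshold pair
is used for both locations, with per-location accuracy obtainable from
the per-image report.

## Enhancement

Operator order when both defect families are present: gamma → bilateral
→ CLAHE (brightening first, then denoising, then contrast equalisation).
The gamma channel assignment is red ← 0.7, green ← 0.9 (configurable);
blue is never transformed. The bilateral filter is the standard
normalised form I′_p = Σ_q G_σs(‖p−q‖) G_σr(|I_p−I_q|) I_q / W_p with a
square window clipped at borders; its stated parameters (radius 10,
σ_s 30, σ_r 40) target clinical-resolution photographs of roughly 1600 px
width, so the dispatcher scales radius and σ_s by `image_width / 1600`
(floor radius 1) while σ_r, an intensity-domain constant, is untouched.
Without this scaling a 21×21 near-uniform kernel on a ~100 px image
destroys all retinal structure and the measured IQCS drops after
"enhancement". CLAHE uses skimage's implementation on the red and green
channels (clip limit 2.0 on the OpenCV scale = 2/256 normalised, 8×8
tiles). All operators round half-up to 8 bits at their output boundary;
enhancement is not idempotent and is never claimed to be.

## Ranking and statistics

ELO uses the conventional chess parameterisation (initial 1500, K = 32,
base-10/400 logistic expectation); a tournament round is a uniform random
perfect matching (odd item sits out), 15 rounds by default. "15 rounds"
is interpreted as 15 matchings of the image set (≈ 15 comparisons per
image). Consensus ranks items by mean rating across raters with
average-rank ties. Simulated raters prefer the truly better image with
probability σ(Δ/τ); τ → 0 is noiseless.

AUC uses Mann–Whitney half-credit ties; its CI and the paired test use
DeLong structural components (midranks). Proportion CIs are Wilson score
(Clopper–Pearson by flag). Two-proportion z pools the variance; a pooled
proportion of exactly 0 or 1 reports p = 1. t-tests are pooled-variance
by default with Welch by flag; two zero-variance samples with equal means
give p = 1, otherwise they are rejected as undefined. All tests
two-sided, α = 0.05.

## Problem sizes used by the test and demo suites

Synthetic images are 64–128 px squares; the enhancement-benefit check
uses 100 eligible-band images at 96 px; ranking recovery uses 30 images,
6 raters, 15 rounds; per-aspect CNN discriminability trains each head on
200 balanced 64-px images and evaluates on 100 held-out images, averaged
over 3 seeds; the ROP raw-vs-enhanced demo uses 60 images per class per
arm over 3 seeds. DeLong null calibration runs 2,000 replicates at n = 60;
Wilson coverage uses 10⁴ draws at n = 50, p = 0.8.

## Known limitations

* All quantitative guarantees are about the synthetic population; the
  classical backend's constants are calibrated to the generator and
  would need re-calibration for any real camera.
* The classical location feature fails on posterior images whose optic
  disc is heavily darkened (by design it keys on the disc blob); use the
  override when location metadata exists.
* Enhancement can lower the score of images far outside the eligible
  band it was designed for; gating by the band is part of the method.
* The tiny CNN is a desk-scale stand-in: no pretraining, 64-px inputs,
  and no claim of clinical-grade discrimination.
* Grad-CAM assumes the positive class is encoded by excitatory evidence;
  heads that encode a class through inhibition (e.g. blur as absence of
  texture activation) can yield flat or even empty heatmaps. Positive
  local evidence (a bright lesion, a dark blob) localises well.
* At desk scale the synthetic ROP discrimination task is easy enough
  that raw and enhanced arms can both saturate; the demo then shows the
  non-inferiority of enhancement rather than a measurable gain.
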