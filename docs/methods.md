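# Methods

`usconf` implements a confidence-aware evaluation framework for CNN
classifiers of high-frequency ultrasound (HFUS) skin images. The framework
couples four ideas: (i) anatomy-anchored preprocessing — the segmented
epidermis defines both a region of interest (ROI) and a *skin layer map*
(SLM) grading every pixel's diagnostic relevance; (ii) Grad-CAM saliency
explaining each classification; (iii) a *classification confidence level*
(CCL) scoring how much of that saliency falls inside relevant anatomy; and
(iv) a *multicriteria model-evaluation measure* that turns per-sample CCLs
into a single model score balancing accuracy, confidence and coverage.

## Skin layer map

Given a binary epidermis mask and the axial pixel size (mm/px), the SLM
`H` assigns 3 on the epidermis; below each column's lowest epidermis pixel
the value decreases twice by 1 every 0.5 mm and then twice by 0.5 every
0.5 mm (bands 2, 1, 0.5, 0 covering the ~2 mm of dermis); deeper pixels,
the probe membrane, residual gel and epidermis-free columns are avoided
(−1); the 30 px of gel directly above each column's highest epidermis
pixel are kept at 0.

Choices where the construction was genuinely open:

- **First band value.** The first 0.5 mm below the epidermis takes value 2,
  so the epidermis is uniquely maximal.
- **Column-wise depth.** Bands follow each column's own epidermis boundary
  (skin layers run roughly parallel to the epidermis), including the gel
  band. ROI cropping, by contrast, is rectangular and uses global extremes.
- **Pixel-center depth with an edge guard.** Row `r` is at depth
  `(r − boundary_row)·axial_res` mm; band edges carry a 1e-9 mm guard so a
  row landing exactly on a 0.5 mm multiple (up to float rounding) falls in
  the shallower band.
- Pixels inside the epidermis vertical span but off the mask (possible
  with ragged predicted masks) take the first dermis value 2; `H = 3`
  remains pixel-exact on the mask.

## ROI extraction

Five rectangular variants: mode 0 is a passthrough; modes 1/3 crop 30 px
above the global epidermis top row, modes 2/4 crop 1 mm above; modes 3/4
additionally crop 2 mm below the global bottom row. mm→px conversion uses
the axial resolution only, rounded to nearest. In modes 1–4 retained
pixels labelled −1 in the SLM are zeroed, removing membrane/gel/muscle
signal; the SLM is the single source of truth for "avoided". Out-of-range
bounds are clamped to the frame and logged. Mode 0 performs no zeroing.

## Grad-CAM

For feature maps `A^k` of the last spatial layer and the pre-softmax score
`y^c` of the predicted class, channel weights are
`α_k = (1/Z)·Σ_ij ∂y^c/∂A^k_ij` and the raw map is `ReLU(Σ_k α_k A^k)`.
The network stack (`usconf.nn`) is a compact numpy implementation with
hand-written backpropagation, so `∂y^c/∂A^k` is directly available and is
validated against a central finite-difference oracle (relative tolerance
1e-3 in the tests; observed agreement ~1e-9).

Normalization is per-image min–max to [0, 1]; an all-constant raw map
(no localized evidence) normalizes to all zeros. Normalization precedes
rescaling — bilinear interpolation cannot leave [0, 1], so the order only
matters at interpolation level. Upsampling to the ROI grid is bilinear
with edge-clamped boundaries; the upsampled strip is placed at the ROI's
row offset on a zero canvas of the original frame so the map aligns
pixel-for-pixel with the SLM, and pixels outside the ROI can never enter
the confidence average.

## Classification confidence level

`G = {L(i,j)·H(i,j) > 0}` and `t = mean(G)`, `M = |G|`. The strict
inequality excludes gel-band pixels (`H = 0`) even when salient. `t`
ranges over [0, 3]. The degenerate case `M = 0` is defined as `t = 0`
("no evidence inside relevant anatomy" = minimal confidence). When an ROI
mode is active the Grad-CAM map is zero outside the ROI by construction,
which restricts the average to the ROI exactly as cropping would.

## Multicriteria measure

For percentiles `p = 1..99` of the pooled CCL values: threshold `t_p`
(linear interpolation between order statistics, implemented directly from
that definition; the method is a knob because the measure is
threshold-sensitive), retained subset `CCL > t_p` (strictly, accepting the
degenerate all-tied case where every subset is empty and `m = 0`), partial
accuracy `a_p` (0 on an empty subset), and
`m_p = a_p · (n_p/N) · t_p`. The model score is `m = max_p m_p`; ties
break toward the smallest `p`, preferring the largest evaluated dataset.
Percentiles are computed over the pooled test predictions of all folds by
default; a per-fold mode would be the leakage-safe alternative but pooled
scoring is the framework's defined behavior.

## Synthetic phantoms

No public HFUS skin dataset accompanies this problem, so the package
ships a seeded phantom generator that emulates the qualitative structure
of HFUS frames: a bright probe-membrane line, dark gel, a bright
epidermis band with a sinusoidal top boundary (so column-wise SLM logic is
non-trivially exercised), class-specific structure — AD: a subepidermal
low-echogenic band (SLEB, default 0.4 mm); psoriasis: epidermis thickened
×1.8 plus a half-thickness SLEB; tumor: a hypoechoic disk in the dermis;
control: none — a speckled dermis and a deep muscle zone. Default frames
are 256×256 at 0.02 mm/px axially, so the 2 mm SLM band structure spans
~100 rows at desk scale. Speckle is multiplicative Rayleigh noise
normalized to unit mean and blended with a scale parameter (default
0.35); real B-mode speckle statistics, beamforming, attenuation and probe
artifacts are *not* modeled. SLEB thickness and band contrasts are
plausible choices, not values calibrated to a clinical cohort. Patients
carry persistent random offsets on depth/thickness so images of one
patient correlate, which is what makes patient-wise cross-validation
meaningful. Consequently, passing phantom tests demonstrates the
correctness and internal consistency of the framework, not clinical
performance.

## Models and training

Both networks are deliberately small, trained from scratch in float64 on
1 CPU; larger pretrained backbones can stand behind the same handles.

- **Segmenter**: 3-level U-Net-style encoder–decoder (channels c, 2c, 4c,
  default c = 8) with skip connections and a 1×1 two-class head. Default
  loss is weighted generalized Dice (weights = inverse squared class
  volume) to absorb the epidermis/background imbalance; cross-entropy and
  unweighted Dice are selectable. The Dice-family losses carry a small
  cross-entropy term (`ce_stabilizer`, default 0.3, the usual Dice+CE
  compound): a pure Dice loss loses its gradient once the softmax
  saturates toward all-background and training can stall in that state,
  while the CE term keeps per-pixel signal alive; with it, training
  converges reliably across seeds. SGD with momentum 0.9, batch 8,
  learning rate 0.05, 10 epochs; augmentation is horizontal reflection
  plus ±10 px translations. Because the net is fully convolutional it is
  trained on random 128×128 crops biased to contain the epidermis band
  and applied to full frames at inference. Post-processing keeps the
  largest connected component (the downstream geometry assumes one band);
  an empty prediction raises, directing the caller to fall back to the
  ground-truth mask or skip the sample, with skips counted.
- **Classifier**: three conv/ReLU blocks (8, 16, 32 channels, two 2×2 max
  pools), global average pooling, linear 4-class head. ROI strips are
  bilinearly resized (aspect-distorting) to 32×32 and shifted to zero
  mean. Cross-entropy, SGD momentum 0.9, batch 8. The config default is
  50 epochs; the shipped experiments use 15, where the phantom task
  saturates. Augmentation `Aug0` = reflection + ±10 px translation;
  `Aug1` adds rotation uniform in ±20° (bilinear, zero fill).

Determinism: all randomness flows from `numpy.random.default_rng` seeds;
two runs with the same config and seed reproduce manifests, folds and
sweeps exactly (model floats to 1e-5 in the tests, exactly in practice on
one machine).

## Cross-validation and reporting

`patientwise_kfold` deals shuffled patients round-robin to folds within
each class (fold class composition balanced to within one patient), then
splits non-test patients 8:1 into train/validation roles. The small
desk-scale networks do not use early stopping, so the validation patients
are folded into training; the split logic is retained (and tested) because
it defines the leakage-free contract. The experiment report contains
per-sample predictions and CCLs, fold accuracies, pooled accuracy and
mean CCL, the full sweep with `m`/`p_opt`, and confusion matrices over
the full test set and over the confidence-limited (`CCL > t_popt`)
subset, in fixed class order (AD, psoriasis, tumor, control).

## Problem sizes

The shipped end-to-end experiment uses 400 phantoms (100 per class, 10
patients per class) with 10-fold patient-wise CV — chosen as the smallest
cohort on which the full protocol (including class-balanced folds with
one patient per class per fold) runs comfortably on a laptop-class CPU.
The segmentation study trains on 50 phantoms and evaluates on 10 held-out
frames.

## Known limitations

- Phantom realism is limited (see above); absolute accuracies and CCLs on
  phantoms do not transfer to clinical imagery.
- The numpy networks are CPU-bound and desk-scale; they demonstrate the
  framework, not state-of-the-art segmentation/classification.
- The strict `>` in both the CCL inclusion set and the percentile sweep
  makes all-tied confidence values degenerate (documented, tested).
- The SLM makes no adjustment inside tumor regions, where skin layers may
  not be parallel; bands are extrapolated as usual.
- CCL is an anatomical-agreement score, not a calibrated probability.
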