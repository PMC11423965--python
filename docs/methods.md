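# Methods

## Problem

During microwave ablation (MWA) of liver tissue, the operator needs to know
how far the lethal heat front has advanced. B-mode ultrasound is the only
monitoring modality routinely at hand, but the bright (hyperechoic)
microbubble cloud it shows systematically overstates the true coagulation
zone. This package implements a texture-based thermometry pipeline: grayscale
texture features of small image patches are regressed against thermocouple
temperatures with a random forest, the fitted model predicts a per-pixel
temperature map, and the area at or above the 54 °C lethal isotherm is the
machine-learning estimate of the coagulation zone. The package also ships a
synthetic ablation simulator so every stage is testable end-to-end without
any imaging hardware or animal tissue.

## Pipeline

1. **Acquisition model.** A thermometer logs 7 thermocouple channels at 2 Hz,
   starting 15 s before the ablation; the scanner films the needle plane at
   12 fps for the 180 s ablation. Trimming the log to the [15 s, 195 s)
   window and re-zeroing yields 360 readings per channel; keeping the first
   and sixth frame of each second thins the video to 360 keyframes; pairing
   each keyframe with the nearest-in-time reading (tolerance 0.25 s, half
   the sampling period) and cutting a 64×64 ROI at each of the 7 marked
   probe points yields 2520 temperature-ROI samples per case.
2. **Features.** Each ROI is described by 104 features in seven families:
   19 first-order, 10 2-D shape, 24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM and
   14 GLDM, following IBSI-style definitions. Matrix families operate on a
   fixed-bin-count quantization (Ng = 32) of the patch; GLCM/GLRLM use
   distance 1 and average feature values over the four principal directions;
   GLSZM zones are 8-connected; GLDM uses distance 1, tolerance α = 0.
3. **Model.** Features are z-scored with training-split statistics, ranked
   by regression-forest impurity-decrease (Gini) importance, the top 10 are
   kept, and the final forest is fitted with hyperparameters chosen on the
   validation split (grid: 200/500 trees × min-leaf 1/5; max_features 1/3).
   One model is trained per power group. Samples are split 4:1:1
   (train:val:test); the default is a per-sample split, with a per-case mode
   available because per-sample splitting mixes frames of one ablation
   across splits and therefore flatters test error.
4. **Thermal map and areas.** The model slides its 64×64 window over a
   target region (reflect padding at frame borders, configurable stride with
   nearest-neighbour upsampling) to produce a heat map; S_p is the area of
   pixels ≥ 54 °C (boundary inclusive; no connected-component filtering by
   default, since the evaluation metric counts every supra-threshold pixel —
   an optional largest-component mode exists). The sonographer's alternative
   estimate is the hyperechoic ellipse S_v = ½·a·b·π with a the major
   diameter and b half the minor diameter. Both are scored against the
   gold-standard area S_r by the error ratio ER = |x − S_r| / S_r, averaged
   per power group.

## Synthetic data generator

The simulator emulates the bench protocol, not tissue physics:

- **Temperature field**: elliptical Gaussian aligned with the needle axis,
  T = baseline + (peak − baseline)·r(t)·exp(−u²/σ_a² − v²/σ_b²), with
  exponential ramp r(t) = 1 − e^(−t/30 s) and σ(t) = σ₀ + g·√t
  (σ_a: 1.5 mm + 0.55·√t, σ_b: 1.0 mm + 0.35·√t). Peaks are 85 °C (15 W)
  and 100 °C (20 W), baseline 37 °C, duration 180 s. This produces a
  fusiform zone with a final 54 °C isotherm area of roughly 160 mm² (15 W) /
  210 mm² (20 W), the right order of magnitude for bench MWA at these
  powers. No bioheat PDE is solved and there is no 3-D structure.
- **B-mode renderer**: mean intensity rises saturatingly with temperature
  (70 → 95 intensity units); multiplicative Rayleigh speckle has a relative
  scale that falls linearly with normalized temperature (0.45 → 0.02), so
  hot tissue is brighter and markedly more uniform. Microbubbles are Poisson
  shot noise (5 blobs/mm² at full ramp, 1 mm smoothing, +30 mean intensity)
  inside the hyperechoic ellipse. These choices reproduce the qualitative
  texture drift the regression relies on: patch minimum and mean rise with
  temperature; variance, mean absolute deviation and GLCM cluster prominence
  fall. The constants were chosen so those monotonicities hold jointly —
  e.g. the mean-intensity gain is modest because a large gain would make the
  absolute speckle variance *rise* with temperature (variance scales with
  the mean under multiplicative noise).
- **Hyperechoic region**: the 54 °C isotherm ellipse with axes scaled by
  s(t) = 1.16 + 0.5·e^(−t/45), so the bright region strictly contains the
  isotherm early, shrinks toward it, and ends ≈ 35% larger in area —
  mimicking the observed bias of hyperechoic-area reading.
- **Probe log**: exact field values at the probe pixels plus N(0, 0.3 °C)
  noise, 2 Hz, preceded by 15 s of baseline preheat readings.
- **What it does not emulate**: attenuation/shadowing, depth-dependent
  resolution, needle reverberation, blood flow, respiration, or any
  acoustic propagation. Passing tests on this generator therefore shows the
  pipeline is correct and self-consistent, not that it would reach the same
  accuracy on clinical images.

## Problem sizes

The default simulated geometry is 480×640 px at 0.1 mm/px. Tests and the
analysis drivers use a compact 256×320 px window at the same 0.1 mm/px
spacing: the spacing (not the grid size) controls feature behaviour, because
a 64-px ROI must stay small relative to the thermal structure, and the
compact window fully contains the zone and all seven ROIs. Training
experiments pool 4 simulated 15 W cases (10 080 samples); heat maps are
evaluated at stride 4 over the hyperechoic bounding box.

## Numerical conventions

- Even-size ROI windows use the half-open span [c − 32, c + 32).
- Quantization of a constant patch maps everything to level 1.
- Degenerate texture values are pinned to finite conventions: GLCM
  correlation and MCC are 1 and IMC1/2 are 0 for a single-level patch;
  NGTDM coarseness is capped at 1e6; GLDM dependence counts include the
  centre pixel (values 1–9) so small-dependence emphases never divide by
  zero; first-order skewness/kurtosis of a constant patch are 0.
- Z-scoring floors the training standard deviation at 1e−12, so features
  constant in training normalize to 0.
- Importance ties break by canonical feature order (stable argsort).
- sklearn normalizes forest importances to sum to 1; only the ranking, not
  the magnitude, is comparable across implementations.
- All randomness flows from explicit seeds; identical configs reproduce
  cases bit-for-bit.

## Known limitations

- The speckle is Rayleigh-type on a mean map, not a coherent interference
  pattern; second-order speckle statistics (autocorrelation length) are not
  matched to any physical transducer.
- Shape features are constant on square ROIs and are retained only to keep
  the full 104-feature battery; they receive ~zero importance.
- The heat-map model reuses the point-trained forest; retraining on pixel
  blocks of the target region is a plausible alternative the pipeline does
  not implement.
- Per-sample splitting leaks temporal structure of an ablation across
  splits; per-case splitting is provided and recommended for honest
  generalization claims.
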