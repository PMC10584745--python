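# Methods

This note documents the models behind `ctfriqa`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic study can and
cannot say about real CT reading.

## CT display preparation

Stored CT pixels are unsigned 16-bit with an additive offset
(`stored = HU + offset`, default offset 32768, matching common unsigned-PNG
CT exports; 0 for plain 8-bit material). Display conversion is the linear
window map `v = 255·(HU − (level − width/2))/width`, clipped to [0, 255]
and rounded half-up. Half-up rounding is a deterministic convention shared
by common display pipelines; the window edges map exactly to 0 and 255 and
the map is monotone in HU. Site default windows: 80/40 HU (head),
1500/−650 HU (chest), 350/40 HU (abdomen).

Background cropping is automated: foreground = pixels ≥ threshold
(optional binary closing), bounding box of the largest connected component,
plus a 2-px margin. The pipeline derives the threshold from the window as
`display(air) + 10`; for head/abdomen windows air maps to 0 so this is the
plain threshold 10, but under a lung window air sits at gray ≈ 68 and a
fixed threshold would never isolate the body. An explicit threshold or crop
box can be supplied instead. The reference's box is applied identically to
the distorted image of every pair, and all-background images fall back to
the full frame with a warning flag.

## Distortion design

Distortions act on the displayed 8-bit image. Noise is i.i.d. Gaussian in
float gray levels, then clip-and-round; its σ is therefore meaningful on
the 8-bit scale. Blur is a normalized Gaussian kernel truncated at
radius ⌈4σ⌉ with reflected borders. When a cell applies both, blur runs
first (system blur precedes detector noise in acquisition); the order is
config (`distortion_order`). Each grid cell gets a deterministic seed
derived from (base seed, reference id, σ_noise, σ_blur) via CRC32, so a
study regenerates bit-identically and changing the base seed changes only
noise realizations, never blur outputs.

Grids: σ_noise ∈ {6, 9, 14, 21, 30} gray levels, σ_blur ∈
{0.6, 0.9, 1.4, 2.1, 3.0} px; each level alone plus all combinations gives
R·(5 + 5 + 25) pairs for R references.

## Metrics

All nine metrics map an equal-shape (reference, distorted) pair to a
scalar, higher = better, and return their ideal value on identical inputs.
Parameters default to the values the original formulations recommend; every
constant is an explicit keyword.

- **PSNR** `10·log10(255²/MSE)`; zero MSE reports the 100 dB cap with a
  flag so downstream regression sees finite numbers (cap value is config).
- **SSIM** 11×11 Gaussian window (σ = 1.5), K1 = 0.01, K2 = 0.03, L = 255,
  mean pooling over the valid region. Matches a brute-force per-window
  oracle to 1e-9 and scikit-image's implementation to ~1e-4 (boundary
  handling differs outside the valid region).
- **MS-SSIM** five dyadic scales (2×2 block-mean downsampling), canonical
  exponents (0.0448, 0.2856, 0.3001, 0.2363, 0.1333); contrast/structure at
  every scale, luminance only at the coarsest. Images too small for five
  scales reduce the scale count (largest L with min(side) ≥ 11·2^(L−1)),
  renormalizing the exponents; the count is reported in the details.
- **IW-SSIM** the MS-SSIM maps pooled with information-content weights
  from a local Gaussian scale-mixture model of band-pass
  (Laplacian-pyramid) coefficients: per-pixel statistics over a 3×3
  neighborhood give a channel gain g and residual variance σ_v², and the
  weight is `log2(1 + g²σ_x²/(σ_v²+σ_n²) + σ_x²/σ_n²)` with σ_n² = 0.4 —
  the information the reference carries plus what survives the distortion
  channel. Uniform weights reduce it exactly to MS-SSIM.
- **FSIM** (grayscale) phase congruency from a log-Gabor bank (4 scales,
  minimum wavelength 6, multiplier 2, σ_onf = 0.55; 4 orientations) as the
  primary feature, Scharr gradient magnitude as the complementary feature;
  similarity constants T1 = 0.85, T2 = 160; pooling weighted by the
  pointwise maximum phase congruency. Inputs larger than ~256 px are
  pre-averaged and decimated as in the original. The measure is symmetric
  in its two arguments.
- **IFC / VIF** Gaussian scale-mixture channel model on a separable
  wavelet decomposition (sym4, 4 levels, all detail subbands; a
  Gaussian-pyramid pixel-domain variant is available via
  `domain="pixel"`). Per-coefficient local statistics (3×3 windows)
  estimate the gain and additive-noise variance of the distortion channel.
  IFC sums `log2(1 + g²σ_x²/σ_v²)` over coefficients (variance floor 1e-6
  standing in for intrinsic neural noise keeps it finite on identical
  images; the score is additive over subbands and grows with image size).
  VIF adds a visual-channel noise σ_n² = 2 to both paths and reports
  retained/total information, exactly 1 on identical images.
- **NQM** a perceptual restoration model: octave-spaced Gaussian band-pass
  pyramid with luminance-normalized local contrast, contrasts below the
  detection threshold (base threshold 0.01 at the peak of a
  Mannos–Sakrison CSF, 32 px/degree assumed display resolution) are
  discarded as invisible, and the score is the dB SNR between the two
  model-restored images. Any rectangular even-sized image is accepted;
  perceptually identical restorations hit the 100 dB cap.
- **VSNR** operates on the error signal: a bior4.4 DWT (≤ 5 levels) gives
  per-octave RMS contrasts relative to mean display luminance; bands are
  tested against CSF-derived detection thresholds and, if none is visible,
  the distortion is imperceptible (cap + flag). Otherwise the score is
  `10·log10(C(I)²/VD²)` with `VD = α·d_pc + (1−α)·d_gp/√2`, α = 0.04,
  where d_pc is the visible-band RMS contrast and d_gp the distance of the
  band-contrast profile from the nearest global-precedence-consistent
  profile — coarse image structure is perceived first, so error energy
  parked in low-frequency bands is the disruptive kind; the consistent
  cone (contrast non-increasing from fine to coarse scales) is reached by
  isotonic projection.

NQM and VSNR are this package's own perceptual models built to those
metrics' published designs (contrast pyramid + CSF thresholding + SNR;
wavelet contrast thresholds + global precedence); they are not ports of
the original authors' code. All nine metrics are monotone non-increasing
along both distortion grids on every phantom site (enforced by tests), and
no table ever contains NaN/Inf — unbounded metrics are capped and flagged.

## Phantoms

`make_phantom` draws site-plausible anatomy on a −1000 HU air background:
head = high-attenuation skull rim around brain-range parenchyma (38 HU)
with CSF ventricles and smooth low-contrast texture; chest = soft-tissue
wall (35 HU) with two −850 HU lung fields carrying bright vessel-like
texture, a heart and a 700 HU spine; abdomen = soft-tissue body with
liver/stomach/kidneys/spine and organ-scale texture. Geometry scales with
matrix size, realizations are deterministic in the seed, and each phantom
ships with region masks (the body mask is the ground truth for crop
tests). The default six-reference design is two phantoms per site.

## Observer model

Latent quality of a grid cell:
`Q = floor + (100 − floor)·exp(−(σ_n/τ_n + σ_b/τ_b))`, floor = 30,
τ_noise = 12 gray levels, τ_blur = 1.2 px; an optional interaction term is
off by default (additive separability is the simplest model consistent
with single-factor quality curves). Q decays strictly in each intensity
with a strictly flattening *rate*. Note that over the widening grids the
raw per-grade decrements are not monotone (9.4, 11.3, 9.6, 6.4 between
successive noise grades) — the grid steps grow faster than the decay
early on — so curve-shape checks are stated on the per-unit-σ slopes
(4.6, 3.1, 2.3, 1.4, 0.7), which do shrink strictly.

Each of the 6 observers draws a persistent bias ~ N(0, bias_sd²) and marks
`clip(Q + bias + ε, 0, 100)` for the distorted image and
`clip(ref_mean + bias + ε′, 0, 100)` for the hidden reference
(ref_mean = 85, ε ~ N(0, mark_sd²), presentation order randomized and
recorded). Defaults mark_sd = bias_sd = 5, a realistic within/between-rater
scatter on a continuous 0–100 scale; the parameter-recovery property
(τ estimates within 15%) is stated at mark_sd ≤ 5.

Because references are marked around ref_mean while Q is anchored at 100,
the double-stimulus subjective score is offset:
`X = (100 − ref_mean) + Q` up to clipping, ≈ Q + 15 at defaults. The
offset affects no rank statistic; the latent-model fit removes it before
recovering (floor, τ_noise, τ_blur), and the single-distortion curve
summaries use only observed grades rather than an X = 100 anchor at σ = 0.

Mean-curve summaries (`mean_single_distortion_curves`) average the
per-grade panel means over 20 replicate simulated studies: the object of
interest is the model's mean behavior, and a single six-observer panel at
mark_sd = 5 can transpose adjacent slope estimates purely by sampling
noise (adjacent slope gaps ≈ 0.9 vs a single-panel SE ≈ 0.5).

### Inter-rater agreement and calibration

ICC(2,1) (two-way random effects, absolute agreement, single measure) is
computed from ANOVA mean squares with the McGraw–Wong F-based 95% CI. The
ratings matrix defaults to per-observer subjective differences
(100 − (mark_ref − mark_dist)) — agreement about perceived quality
difference, the quantity the double-stimulus design elicits — with raw
distorted-image marks as a config alternative. Note the shared observer
bias cancels in difference scores, so bias_sd affects only raw-mark
agreement; with difference ratings the default panel reaches
ICC(2,1) ≈ 0.72. `calibrate_mark_noise` bisects mark_sd until the mean ICC
over replicate studies hits a target (±0.03); targeting 0.68 yields
mark_sd ≈ 5.6. Targets above what the noise-free panel attains raise a
calibration error (reachable only in raw-mark mode, where persistent
biases cap agreement below 1).

## Evaluation harness

Metric scores Y are regressed onto subjective scores X with the
five-parameter logistic
`Y_L = β1(1/2 − 1/(1+exp(β2(Y−β3)))) + β4·Y + β5` before computing PLCC
and RMSE; SROCC uses raw Y (rank correlation is invariant under the
fitted curve's monotone part). The fit exploits that the model is linear
in (β1, β4, β5): those are solved exactly by least squares at every step
(variable projection) while the optimizer searches only (β2, β3), starting
from β2 = 2/SD(Y), β3 = median(Y) after a deterministic 6×5 coarse survey
of (β2 scale, β3 quantile) cells; tolerances 1e-10, ≤ 5000 evaluations,
Levenberg–Marquardt, a fixed 16-point jittered multi-start on
non-convergence, and the exact OLS affine solution always retained as a
candidate — the family nests affine maps, so the fit never does worse than
the best straight line and PLCC after regression is never below |PLCC|
before it. Constant-Y series are flagged degenerate.

SROCC is tie-corrected rank Pearson (capped metrics produce ties); on
tie-free data it equals the classical 1 − 6Σd²/(n(n²−1)) form to 1e-12.
Constant series raise an undefined-correlation error rather than
returning NaN.

Method pairs are compared with a one-tailed F-test at 5% on 5PL residual
variances (mean-centered, n−1 dof each): symbol 1 / − / 0 for
significantly smaller / indistinguishable / significantly larger variance;
no multiple-comparison correction by default (a Bonferroni switch exists).
Codeword matrices concatenate one symbol per subgroup
([noise, blur] or [head, chest, abdomen]); the diagonal is all "−" and
off-diagonal cells are antisymmetric per position by construction.
Subgroups are refit independently (per-subgroup 5PL, config-switchable);
groups smaller than 8 points are skipped with a warning row.

## Orchestration and reproducibility

`run_study` fans one base seed into fixed per-stage offsets (phantoms,
distortions, marks), writes config, manifest, scores, subjective table,
joined records, summaries, significance matrices, ICC report and a run
log, and maintains a STATUS sentinel (`ok` only on full completion).
Tables use stable column order and 6-significant-digit formatting; reruns
are byte-identical.

The benchmark scale used by the test suite and `scripts/acceptance.py` is
128-px phantoms (the generator's default remains 512); at that scale the
full 210-pair study with all nine metrics and the evaluation harness runs
in about a minute on one CPU.

## What the synthetic study does and does not show

Passing tests demonstrate that the pipeline is internally correct:
deterministic distortion design, metrics that are exact (PSNR, SSIM
against oracles) or contractually well-behaved (caps, bounds,
monotonicity), an agreement statistic that matches independent ANOVA
implementations, and a regression/testing harness that recovers known
curves. They do not certify perceptual validity: the observer model's
latent quality depends only on (σ_noise, σ_blur) — every reference and
site with the same distortion intensities receives the same expected
score, in 35 discrete levels, whereas human scores on real slices vary
continuously with image content. Metrics legitimately discriminate
content, so pooled rank correlations against the synthetic subjective
scores are structurally depressed relative to a human study: even the
mathematically exact PSNR tops out near SROCC 0.82 against the noise-free
latent quality, and panel noise at the calibrated ICC ≈ 0.68 level
removes a further ~0.05 through tie-breaking churn. Within-subgroup
correlations (single distortion type, single site) are the meaningful
synthetic-scale readout. Other known limitations: phantoms are
piecewise-smooth with stylized texture (no quantum mottle, no
reconstruction-kernel noise correlation); distortions are spatially
uniform; NQM and VSNR are faithful-shape perceptual models rather than
ports of the original code; and the observer model makes no claim of
psychophysical validation.
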