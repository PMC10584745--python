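# ctfriqa

Benchmarking full-reference image quality assessment (FR-IQA) on CT images.

Objective quality metrics such as PSNR and SSIM were designed for natural
photographs, yet they are routinely used to judge CT reconstruction,
denoising and super-resolution pipelines. `ctfriqa` implements the complete
apparatus needed to test how well such metrics track perceived quality on
CT material:

- **CT display preparation** — site-specific Hounsfield windowing
  (80/40 HU head, 1500/−650 HU chest, 350/40 HU abdomen) to 8-bit display
  images, and automatic background cropping so metrics see only the
  diagnostically relevant region.
- **Distortion grids** — Gaussian noise (σ ∈ {6, 9, 14, 21, 30} gray
  levels), Gaussian blur (σ ∈ {0.6, 0.9, 1.4, 2.1, 3.0} px) and all
  combinations: 35 distorted images per reference, 210 for the standard
  six-reference design.
- **Nine FR-IQA metrics**, implemented from scratch: PSNR, SSIM, FSIM, IFC,
  VIF, NQM, VSNR, MS-SSIM and IW-SSIM. Higher is always better; unbounded
  dB-scaled metrics are capped at 100 dB with an explicit flag.
- **A simulated DSCQS observer study** — CT-like phantom references (head /
  chest / abdomen), a latent-quality model
  `Q = floor + (100 − floor)·exp(−(σ_n/τ_n + σ_b/τ_b))`, and a six-observer
  panel with per-observer bias and mark noise on the continuous 0–100
  double-stimulus scale, calibratable to a target inter-rater ICC(2,1).
- **An evaluation harness** — five-parameter logistic (5PL) regression of
  metric scores onto subjective scores, PLCC / SROCC / RMSE, one-tailed
  residual F-tests at 5%, and pairwise 1/−/0 significance codeword matrices
  over distortion-type and site subgroups.

Subjective scores follow the double-stimulus convention
`X = 100 − DSCQS`, where the DSCQS score is the panel-mean difference
between the marks for the hidden reference and the distorted image.

## Worked example

Run the full synthetic study (six 128-px phantoms, 210 distorted images,
nine metrics, six simulated observers) from Python:

```python
from ctfriqa.study import StudyConfig, run_study
import pandas as pd

out = run_study(StudyConfig(base_seed=1, phantom_size=128, out_dir="demo"))
summary = pd.read_csv(out / "summary.csv")
print(summary[summary.group == "all"][["method", "plcc", "srocc", "rmse"]])
```

prints (seed 1):

```
method     plcc    srocc     rmse
  PSNR 0.828249 0.758841 6.502182
  SSIM 0.853961 0.813972 6.037765
  FSIM 0.887556 0.842314 5.345771
   IFC 0.893168 0.798411 5.218395
   VIF 0.876272 0.754507 5.590789
   NQM 0.858183 0.781695 5.956617
  VSNR 0.777459 0.622575 7.297874
MSSSIM 0.880590 0.822609 5.498677
IWSSIM 0.892757 0.828525 5.227858
```

PLCC and RMSE are computed against the 5PL-regressed metric scores
(prediction accuracy and consistency), SROCC against the raw scores
(prediction monotonicity). The run directory also contains `records.csv`
(one row per distorted image with all metric scores and the subjective
score), `icc.json` (panel agreement: ICC(2,1) ≈ 0.72 for the default
observer model), per-subgroup summaries, and the significance codeword
matrices. Reruns with the same config are byte-identical.

The same pipeline is available from the shell:

```sh
ctfriqa run --seed 1 --out demo          # everything end to end
ctfriqa simulate --out refs --seed 1     # just the phantom references
ctfriqa distort --refs refs --out dist --seed 1
ctfriqa evaluate --records demo/records.csv --out tables
```

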