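# ctbonetex

Opportunistic bone densitometry from CT texture. Chest and abdominal CT
scans acquired for unrelated indications image the trabecular bone of the
L1 vertebra and femoral neck for free; `ctbonetex` estimates Bone Mineral
Content (BMC, g) and Bone Mineral Density (BMD, g/cm²) — and their change
between two scans — from the Hounsfield-unit (HU) texture of a circular
trabecular region on a single axial slice, using DXA measurements as the
regression reference. It is aimed at medical-image-analysis researchers
who want a tested, reproducible implementation of this screening chain,
including a synthetic phantom cohort with planted ground truth so every
stage can be validated without patient data.

## Method

Per scan, the axial slice with the largest trabecular cross-section is
selected by HU-window thresholding (default window [50, 400] HU), and a
circular ROI is inscribed in the trabecular area (radius = 0.9 × the
centroid-to-boundary distance of the thresholded region's convex hull).
From the ROI, 45 features are computed:

* **5 histogram statistics** (k = 1…5): mean, sample SD, skewness,
  kurtosis, Shannon entropy (64-bin, bits) of the in-ROI HU values;
* **40 GLCM statistics**: the ROI is re-quantized to n gray levels over
  its own [min, max]; for each of 2 offset directions (l = 1 horizontal,
  l = 2 vertical; distance 1, asymmetric) and 4 level counts (m = 1…4 ↦
  n = 16, 32, 64, 128), a gray-level co-occurrence matrix
  C(i, j) = #{pixel pairs (p, p+δ) in-ROI with levels i, j} is
  accumulated — eight matrices per ROI — and summarized by contrast,
  correlation, energy, homogeneity and variance (statistic index n = 1…5).

Each feature gets a unique index j ∈ 1…45 (j = k for histogram features,
j = 5 + 20(l−1) + 5(m−1) + n for GLCM features). For longitudinal change,
a subject's two 45-vectors are concatenated into a 90-feature design with
target ΔBMC (or ΔBMD).

Features x_ij and references y_j are z-scored (sample SD); the linear
model ŷ_j = w₀ + Σᵢ wᵢ x_ij is fitted by minimizing Σⱼ (y_j − ŷ_j)² via
the Moore–Penrose pseudoinverse of the normal equations. An L1-penalized
variant minimizes Σⱼ (y_j − ŷ_j)² + λ Σᵢ |wᵢ| by cyclic coordinate
descent with soft thresholding, tracing sparsity/accuracy along a λ grid.
Agreement is reported as Pearson r, MAE, MSE and a two-sided paired
t-test for bias (exactly p = 1 in-sample, since the fitted bias zeroes
the mean residual). A small fully connected network (8–8–2 hidden units,
ReLU) is included as an optional nonlinear baseline.

Estimators follow the scikit-learn protocol (`fit`/`predict`/
`get_params`), so they compose with sklearn pipelines and model
selection; `TextureFeatureExtractor` is the matching transformer from CT
volumes to feature matrices.

## Worked example

```bash
ctbonetex simulate --n-subjects 30 --seed 7 --out cohort --format png
ctbonetex extract  --in cohort/manifest.csv --out features.csv
ctbonetex fit      --features features.csv --target bmc_true --out model_bmc.json
ctbonetex evaluate --model model_bmc.json --features features.csv --out report.json
ctbonetex roi      --in cohort/S01_tp1 --out roi.png
```

prints

```
wrote 60 scans; manifest: cohort/manifest.csv
extracted 60 cases -> features.csv
fitted bmc_true on 60 cases (45 nonzero weights) -> model_bmc.json
cc=0.9971 mae=0.1654 mse=0.0459 t=8.46e-13 p=1 -> report.json
slice 2: circle center=(31.2,32.0) radius=28.4px (2533 px) -> roi.png
```

Reading: the 30-subject synthetic cohort (two timepoints each) carries a
planted BMC signal; the in-sample fit recovers it with r = 0.997 and a
mean absolute error of 0.17 g, and the paired t-test p = 1 shows the
bias-fitted least-squares model is unbiased on its own sample. The `roi`
line reports the selected slice (the central one, where the generator
puts the largest trabecular cross-section) and the fitted circle. A
single command, `ctbonetex run-all --config cfg.yaml --out run/`,
reproduces the whole chain — feature tables, BMC/BMD/ΔBMC/ΔBMD models,
LASSO paths and evaluation reports — deterministically for a given
config and seed.

Library use mirrors the CLI:

```python
from ctbonetex import (SimConfig, generate_cohort, TextureFeatureExtractor,
                       NormalEquationRegressor)

cohort = generate_cohort(SimConfig(n_subjects=30, seed=7))
X = TextureFeatureExtractor().fit_transform([r.volume for r in cohort.records])
y = [r.bmc_true for r in cohort.records]
model = NormalEquationRegressor().fit(X, y)
```

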