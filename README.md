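# rdepth

Radiomic **De**formation and **T**extural **H**eterogeneity (r-DepTH) for
brain-tumor MRI, with LASSO-Cox survival risk stratification.

Aggressive glioblastomas act beyond their visible margins: mass effect
displaces the surrounding normal-appearing parenchyma, and infiltration
changes local tissue texture inside the tumor compartments. `rdepth`
quantifies both phenomena from routine, co-registered MRI:

- **Deformation-heterogeneity features (ℱ_B).** Given a voxel-wise
  displacement field `(δt, δu, δv)` in mm (the inverse mapping of a
  diffeomorphic registration of the subject scan to a healthy atlas), the
  magnitude `D(c) = √(δt² + δu² + δv²)` is summarised over `m` equidistant
  annular bands of brain-around-tumor parenchyma — band `j` holds the
  voxels at physical distance `((j−1)·w, j·w]` from the tumor mask. Five
  first-order statistics (mean, median, SD, skewness, kurtosis) per band;
  with the default 12 bands × 5 mm this is 60 features reaching 60 mm from
  the tumor margin.
- **3D COLLAGE texture (ℱ_T, ℱ_P, ℱ_N).** Per voxel, the dominant local
  gradient orientation ψ is the first right-singular vector of the window's
  stacked gradient vectors; the angles `θ = tan⁻¹(ψ_Y/ψ_X)` and
  `φ = tan⁻¹(ψ_Z/√(ψ_X²+ψ_Y²))` are quantized and co-occurrence matrices
  `M^θ`, `M^φ` accumulated in a local neighbourhood of every voxel. 13
  Haralick statistics per matrix, aggregated over each compartment
  (enhancing lesion T, peritumoral hyperintensity P, necrotic core N) with
  the same five statistics: 13 × 5 × 2 = 130 features per compartment.
- **r-DepTH** is the concatenation `[ℱ_B, ℱ_T, ℱ_P, ℱ_N]` — 450 features
  by default.
- **Survival model.** Features are z-scored and fed to an L1-penalized Cox
  fit (penalty by 5-fold cross-validated partial likelihood). The selected
  features give a risk score `Risc = Σ_g q_g ℱ_g`; the training-median
  threshold stratifies high- vs low-risk groups, evaluated by Kaplan–Meier
  curves, the log-rank test, Harrell's C-index and the hazard ratio.

The package is aimed at quantitative-imaging researchers who already have
skull-stripped scans, compartment segmentations and registration-derived
displacement fields (ANTs/Greedy), and want a tested, deterministic
descriptor + survival pipeline. Registration itself is out of scope.

## Worked example

No patient data ships with the package; a synthetic phantom module
generates cases with known ground truth:

```python
from rdepth import (LassoCoxRiskModel, evaluate, extract_rdepth,
                    risk_score, stratify)
from rdepth.synth import CohortSpec, PhantomSpec, make_cohort, make_phantom

bundle = make_phantom(PhantomSpec(seed=0))   # textured 62^3 phantom case
vec = extract_rdepth(bundle)
print(len(vec), vec.names[0], vec.names[60])
# 450 def_band01_mean collage_T_theta_energy_mean

phantom = PhantomSpec(seed=0)
train = make_cohort(phantom, CohortSpec(n=120, beta=1.5, seed=101))
test = make_cohort(phantom, CohortSpec(n=120, beta=1.5, seed=202))
res = LassoCoxRiskModel(*train).fit()
print(res.summary())
scores = risk_score(res.model, test[0])
report = evaluate(stratify(scores, res.model.threshold), scores, test[1])
print(round(report.c_index, 3), report.logrank_p)
```

The cohort links survival to each subject's deformation amplitude
(log-hazard = β·A, β = 1.5 per mm), so the fit should select deformation
features and separate the held-out risk groups. With the seeds above the
summary reports 9 selected features (4 from the deformation block,
e.g. `def_band01_std`), training C-index 0.862, and the held-out
evaluation prints `0.858 2.33e-18` — a C-index of 0.86 and a decisive
log-rank separation, against a chance level of 0.5.

Equivalent shell workflow: `rdepth synth case`, `rdepth synth cohort`,
`rdepth extract`, `rdepth fit`, `rdepth predict`, `rdepth evaluate`
(`rdepth --help` for options).

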