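# Methods

## Data model and geometric contract

A case is a triple of co-registered lattices sharing one shape, spacing
and affine (checked to 1e-4): a scalar intensity volume, a displacement
field of per-voxel 3-vectors in physical mm, and a segmentation. The
segmentation is a single integer lattice (0 background, 1 enhancing
lesion, 2 peritumoral hyperintensity, 3 necrotic core) — encoding the
compartments in one lattice makes them disjoint by construction — plus a
brain mask that must contain the composite tumor mask. The tumor mask
defaults to the union of labels 1–3 and may be overridden (some protocols
exclude edema from the "tumor" used for band growing). Displacement
fields are accepted in both the plain 4D `(nx,ny,nz,3)` NIfTI layout and
the ITK 5D `(nx,ny,nz,1,3)` layout; components are physical mm (a flag
converts voxel-unit fields via the header spacing). Band statistics are
assumed to be taken in the subject grid, where the masks live.

## Deformation-heterogeneity features

Magnitude is the per-voxel Euclidean norm of the displacement vector.
Bands are built from the **exact Euclidean distance transform** of the
tumor mask computed with physical sampling, not by iterated morphological
dilation: voxel-structuring-element dilation accumulates chamfer error
and becomes anisotropic for anisotropic voxels, while the EDT makes
"5 mm" mean 5 mm in every direction. Band `j` is the shell at distance
`((j−1)w, jw]`, intersected with the brain mask, tumor excluded. Bands
are clipped at the brain boundary — extracranial voxels carry no
parenchymal deformation signal.

First-order statistics are: mean; median; sample standard deviation
(n−1); Fisher moment skewness `m3/m2^1.5` and excess kurtosis
`m4/m2² − 3`, both bias-uncorrected, so a Gaussian sample scores ≈ 0. A
constant sample returns `(v, v, 0, 0, 0)` rather than NaN. A band left
empty (large tumors push distal bands out of the skull) yields NaN for
its five features plus a logged warning rather than a hard failure; the
survival stage imputes NaNs with training medians. Feature names are
`def_band{j:02d}_{stat}`, band-major. The alternative 20-band × 3 mm
layout is a plain configuration (100 features).

## COLLAGE texture

Gradients are central differences (one-sided at borders) scaled by
spacing, so they are intensities per mm. For each voxel, the gradient
vectors of the surrounding `(2r+1)³` window (default 3×3×3, clipped at
image borders) form the matrix F; the dominant direction is the top
eigenvector of the 3×3 matrix FᵀF, computed in closed batch form from
windowed sums of gradient products — algebraically identical to the first
right-singular vector of F, but vectorizable. Because orientations are
axial (ψ and −ψ equivalent), the eigenvector sign is canonicalized
(largest-magnitude component positive) and both angles live in
`(−π/2, π/2]`, with `ψ_X = 0 → θ = π/2` and in-plane ψ → φ = 0. All-zero
windows (constant image patches) are flagged invalid and assigned
θ = φ = 0; they still enter co-occurrence counting, which keeps the
computation deterministic and total.

Angles are quantized into 64 uniform left-open bins (the right edge π/2
belongs to the last bin). Around every compartment voxel, ordered bin
pairs are counted over the 13 unique Chebyshev-distance-1 offset
directions inside a 5×5×5 window, symmetrized by adding the transpose,
and normalized to sum 1. Neighbouring voxels outside the compartment but
inside the image contribute context, matching the local-window character
of the descriptor. The bin count, window radii and offset set follow the
published COLLAGE convention and are configurable. A window with no valid
pair (possible only in degenerate tiny images) falls back to a delta at
the center bin.

The 13 Haralick statistics (energy, contrast, correlation, sum of squares
variance, inverse difference moment, sum average, sum variance, sum
entropy, entropy, difference variance, difference entropy, and the two
information measures of correlation) are evaluated per voxel and per
angle map on 0-based bin indices. Logarithms are guarded as
`log(x + 1e−12)`; correlation with a zero-variance marginal is defined 0;
sum variance is centred on sum average (the common correction of the
original erratum); IMC2 is clamped at 0 before the square root. This
yields 26 per-voxel feature maps, each aggregated over the compartment
with the five first-order statistics: 130 features per compartment,
independent of compartment size, named
`collage_{T|P|N}_{theta|phi}_{haralick}_{stat}`.

The three compartments are treated identically. For efficiency the
computation runs on a bounding box padded by `cooccur_radius +
window_radius + 1` voxels, which provably reproduces the whole-volume
result (verified against a nested-loop reference in the tests).

## Descriptor assembly

`[ℱ_B, ℱ_T, ℱ_P, ℱ_N]` in that fixed order; 60 + 3×130 = 450 features by
default. Block lengths are validated against the active configuration and
names are a pure function of configuration. Tables are CSV with
`subject_id` first; NaN sentinels round-trip as empty cells.

## Survival risk stratification

Features are z-scored with training statistics (constant or all-NaN
columns dropped with a warning; remaining NaNs imputed by training
medians). The LASSO path (50 penalties, `alpha_min_ratio` 0.01) comes
from a coordinate-descent elastic-net Cox solver at `l1_ratio = 1`; the
penalty is chosen by 5-fold cross-validated partial likelihood in the
Verweij–van Houwelingen form `Σ_k [pl(β_{−k}) − pl_{−k}(β_{−k})]`, with
Breslow tie handling and a fixed fold seed. Nonzero coefficients define
the selected set and the risk score is their linear predictor on
standardized features; the stratification threshold is the **median
training score** — the "threshold from the fitted model" is otherwise
underdetermined, and the median is symmetric, reproducible and
configurable. Ties at the threshold go to the low-risk group.

Evaluation: two-sample log-rank with the asymptotic χ² p-value; Harrell's
C with censoring-aware comparable pairs (censored-censored pairs
excluded, score ties 0.5); hazard ratio from a univariate Cox fit on the
group indicator with a Wald 95% CI; Kaplan–Meier curves exportable. With
an empty selected set every score is 0, all subjects fall in one (low)
group, and evaluation degrades gracefully to the C-index alone (0.5).

Train/test separation is structural: the frozen model JSON carries the
selected names, coefficients, scaler, imputation medians, threshold and
penalty, and prediction never re-estimates anything.

## Synthetic phantoms and cohorts

The phantom emulates the data model, not MRI physics: nested ellipsoidal
compartments (necrotic 4 mm ⊂ enhancing 8 mm ⊂ peritumoral 13 mm) inside
a 74 mm ellipsoidal brain on a 62³ lattice of 2.5 mm voxels — sized so
that all 12 default bands (60 mm reach from the composite tumor mask) lie
inside the brain. Texture is a Gaussian random field per compartment
(smoothed white noise rescaled to a target mean/SD, correlation lengths
3–5 mm) so orientation statistics are non-degenerate. The displacement
field points radially outward from the tumor centroid with magnitude
`A·exp(−d/τ)` (default A = 4 mm, τ = 20 mm, mimicking mass effect that
decays over several centimetres), times per-voxel lognormal noise
(σ = 0.15), zero inside the tumor mask.

Cohorts draw per-subject amplitudes `A_i ~ LogNormal(ln 4, 0.35)` and
survival from an exponential law with log-hazard `β(A_i − E[A])` around a
baseline rate of `ln 2 / 400` per day (median ≈ 400 days, in the range of
glioblastoma survival); censoring marks a fixed fraction (default 20%) of
subjects, whose observed time is uniform on (0, T). The default cohort
runs the real extraction per subject on a shared geometry (distance
transform and band labels computed once; fields and textures per
subject); a cases mode materialises full volumes instead. With β = 1.5
the deformation features carry the hazard signal and the texture draws do
not, making the full pipeline a parameter-recovery experiment; β = 0 is
the null.

What passing these tests does **not** show: robustness to registration
error, scanner effects, segmentation variability, non-radial deformation
patterns, or textures with survival signal — the phantoms have none of
these.

## Problem sizes and numerical choices

Tests and the acceptance script use the 62³ default phantom (about 0.5 s
per extraction) and cohorts of 120 train / 120 test subjects, enough for
the stochastic checks (held-out C-index, log-rank, null coverage) to be
stable at their stated tolerances. Geometry comparisons use 1e-4 mm;
oracle equivalence tests assert 1e-8..1e-12 depending on the chain of
floating-point operations involved. Determinism is exact: one seed, one
byte stream.

## Known limitations

- Directional (phase) attributes of the deformation are not modelled —
  only magnitudes.
- The co-occurrence bin count/window/offsets are conventions, not fitted;
  other published COLLAGE variants differ.
- The λ-selection protocol fixes fold structure by seed; a different fold
  seed can select a slightly different feature set (the score is far more
  stable than the support).
- Phantom cohorts share one tumor geometry; anatomical variability across
  subjects is not emulated.
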