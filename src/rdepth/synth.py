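"""Synthetic phantoms and cohorts with known ground truth.

Real glioblastoma cohorts cannot be redistributed, so every stage of the
pipeline is exercised on phantoms: nested ellipsoidal tumor compartments
(necrotic core inside enhancing lesion inside peritumoral hyperintensity)
embedded in an ellipsoidal brain, textured with Gaussian random fields of
compartment-specific mean, variance and correlation length, and deformed by
a radially outward displacement field whose magnitude decays exponentially
with the distance d from the tumor mask:

    |u|(d) = A * exp(-d / tau),   zero inside the tumor mask.

Cohorts link survival to the deformation amplitude A through an exponential
proportional-hazards law, log-hazard = beta * (A_i - E[A]), so that feature
extraction followed by LASSO-Cox fitting can be validated as a
parameter-recovery experiment: for beta > 0 the deformation features carry
the hazard signal while the per-subject textures are survival-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .collage import CollageConfig, collage_descriptor
from .deformation import (BandConfig, build_annular_bands,
                          deformation_descriptor)
from .descriptor import assemble_rdepth, rdepth_feature_names
from .io import (CaseBundle, DisplacementField, SegmentationSet, VolumeGrid,
                 validate_case)

__all__ = ["PhantomSpec", "CohortSpec", "make_phantom", "make_cohort",
           "draw_cohort_survival"]


@dataclass(frozen=True)
class GrfParams:
    """Gaussian-random-field texture law: mean, std and correlation length."""

    mean: float
    std: float
    corr_mm: float


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, texture and deformation law of one phantom case.

    Radii are in mm and nested: necrotic < enhancing < peritumoral; the
    default brain is large enough that all 12 default annular bands (60 mm
    reach from the composite tumor mask) stay inside the brain mask.
    """

    shape: tuple[int, int, int] = (62, 62, 62)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    center_mm: tuple[float, float, float] | None = None
    necrotic_radius_mm: float = 4.0
    enhancing_radius_mm: float = 8.0
    peritumoral_radius_mm: float = 13.0
    brain_semiaxes_mm: tuple[float, float, float] = (74.0, 74.0, 74.0)
    texture: dict = field(default_factory=lambda: {
        "background": GrfParams(100.0, 5.0, 4.0),
        "T": GrfParams(140.0, 20.0, 3.0),
        "P": GrfParams(120.0, 15.0, 5.0),
        "N": GrfParams(60.0, 10.0, 3.0),
    })
    amplitude_mm: float = 4.0
    decay_tau_mm: float = 20.0
    noise_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        r = (self.necrotic_radius_mm, self.enhancing_radius_mm,
             self.peritumoral_radius_mm)
        if not (0 < r[0] < r[1] < r[2]):
            raise ValueError("compartment radii must be positive and nested")
        if self.amplitude_mm < 0 or self.decay_tau_mm <= 0:
            raise ValueError("need amplitude >= 0 and decay tau > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Size, hazard linkage and censoring of a synthetic cohort.

    Per-subject deformation amplitudes are lognormal; survival times are
    exponential with log-hazard beta * (A_i - E[A]) around a baseline rate,
    and a fixed fraction of subjects is independently censored uniformly
    before their event time.
    """

    n: int = 120
    beta: float = 1.5
    baseline_rate: float = np.log(2) / 400.0  # per day; median ~400 d
    censoring_fraction: float = 0.2
    amplitude_log_mean: float = float(np.log(4.0))
    amplitude_log_sigma: float = 0.35
    vary_texture: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort needs n >= 2")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring fraction must lie in [0, 1)")


def _grf(shape, sigma_vox, rng) -> np.ndarray:
    """Unit-variance zero-mean Gaussian random field (smoothed white noise)."""
    noise = rng.standard_normal(shape)
    if np.any(np.asarray(sigma_vox) > 0):
        noise = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def _radius_mm(shape, spacing, center_mm):
    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                         indexing="ij")
    return np.sqrt(sum((c - c0) ** 2 for c, c0 in zip(coords, center_mm)))


def _phantom_masks(spec: PhantomSpec):
    center = spec.center_mm
    if center is None:
        center = tuple((n - 1) * s / 2
                       for n, s in zip(spec.shape, spec.spacing))
    r = _radius_mm(spec.shape, spec.spacing, center)
    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[r <= spec.peritumoral_radius_mm] = 2
    labels[r <= spec.enhancing_radius_mm] = 1
    labels[r <= spec.necrotic_radius_mm] = 3
    # ellipsoidal brain mask
    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(spec.shape,
                                                            spec.spacing)],
                         indexing="ij")
    brain = sum(((c - c0) / a) ** 2 for c, c0, a in
                zip(coords, center, spec.brain_semiaxes_mm)) <= 1.0
    if not np.all(brain[labels > 0]):
        raise ValueError("tumor exceeds the brain extent")
    return labels, brain, center, r


def _texture_volume(spec: PhantomSpec, labels, brain, rng) -> np.ndarray:
    sig = {k: tuple(p.corr_mm / s for s in spec.spacing)
           for k, p in spec.texture.items()}
    bg = spec.texture["background"]
    data = bg.mean + bg.std * _grf(spec.shape, sig["background"], rng)
    for key, lab in (("T", 1), ("P", 2), ("N", 3)):
        p = spec.texture[key]
        mask = labels == lab
        if mask.any():
            data[mask] = (p.mean + p.std
                          * _grf(spec.shape, sig[key], rng)[mask])
    data[~brain] = 0.0
    return data


def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> CaseBundle:
    """Generate a validated phantom case (volume, field, segmentation).

    The displacement field points radially outward from the tumor centroid
    with magnitude A * exp(-d/tau) (d = physical distance from the composite
    tumor mask, zero inside it), times a per-voxel lognormal perturbation of
    sigma ``noise_sigma`` that makes band statistics non-degenerate.
    """
    rng = np.random.default_rng(spec.seed)
    labels, brain, center, _ = _phantom_masks(spec)
    affine = _affine(spec.spacing)
    seg = SegmentationSet(labels=labels, brain_mask=brain, affine=affine)
    data = _texture_volume(spec, labels, brain, rng)
    volume = VolumeGrid(data=data, affine=affine)

    dist = ndimage.distance_transform_edt(~seg.tumor_mask,
                                          sampling=spec.spacing)
    mag = spec.amplitude_mm * np.exp(-dist / spec.decay_tau_mm)
    if spec.noise_sigma > 0:
        mag = mag * np.exp(spec.noise_sigma
                           * rng.standard_normal(spec.shape))
    mag[seg.tumor_mask] = 0.0
    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(spec.shape,
                                                            spec.spacing)],
                         indexing="ij")
    vec = np.stack([c - c0 for c, c0 in zip(coords, center)], axis=-1)
    norm = np.linalg.norm(vec, axis=-1)
    norm[norm == 0] = 1.0
    components = vec / norm[..., None] * mag[..., None]
    fld = DisplacementField(components=components, affine=affine)
    return validate_case(volume, fld, seg)


def _draw_survival(amplitudes: np.ndarray, spec: CohortSpec, rng):
    mean_a = float(np.exp(spec.amplitude_log_mean
                          + spec.amplitude_log_sigma ** 2 / 2))
    rate = spec.baseline_rate * np.exp(spec.beta * (amplitudes - mean_a))
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(len(amplitudes)) < spec.censoring_fraction
    u = rng.uniform(size=len(amplitudes))
    time = np.where(censored, np.maximum(t_event * u, 1e-6), t_event)
    event = (~censored).astype(int)
    return time, event


def draw_cohort_survival(cohort: CohortSpec):
    """Draw per-subject amplitudes and the linked survival table only.

    Useful for validating the hazard linkage and censoring mechanism
    without the cost of image synthesis. Uses the same random stream
    layout as :func:`make_cohort`, so tables match for equal specs.
    """
    root = np.random.default_rng(cohort.seed)
    amplitudes = np.exp(cohort.amplitude_log_mean
                        + cohort.amplitude_log_sigma
                        * root.standard_normal(cohort.n))
    time, event = _draw_survival(amplitudes, cohort, root)
    ids = [f"subj{i:04d}" for i in range(cohort.n)]
    survival = pd.DataFrame({"subject_id": ids, "time": time,
                             "event": event})
    return amplitudes, survival


def make_cohort(
    phantom: PhantomSpec = PhantomSpec(),
    cohort: CohortSpec = CohortSpec(),
    band_cfg: BandConfig = BandConfig(),
    collage_cfg: CollageConfig = CollageConfig(),
    mode: str = "features",
):
    """Generate a cohort and its survival table.

    mode="features" (default) runs the real descriptor extraction per
    subject on a shared phantom geometry — per-subject displacement fields
    and textures are drawn, but the distance transform and band labels are
    computed once. mode="cases" returns full CaseBundles instead (slower;
    intended for small n).

    Returns
    -------
    (features, survival)
        ``features``: DataFrame with ``subject_id`` plus one column per
        r-DepTH feature (features mode), or a list of (subject_id,
        CaseBundle) pairs (cases mode); ``survival``: DataFrame with
        ``subject_id, time, event``.
    """
    if mode not in ("features", "cases"):
        raise ValueError(f"unknown cohort mode {mode!r}")
    root = np.random.default_rng(cohort.seed)
    amplitudes = np.exp(cohort.amplitude_log_mean
                        + cohort.amplitude_log_sigma
                        * root.standard_normal(cohort.n))
    time, event = _draw_survival(amplitudes, cohort, root)
    ids = [f"subj{i:04d}" for i in range(cohort.n)]
    survival = pd.DataFrame({"subject_id": ids, "time": time,
                             "event": event})
    seeds = root.integers(0, 2**31 - 1, size=cohort.n)
    tex_seeds = seeds if cohort.vary_texture else np.full(cohort.n, seeds[0])

    if mode == "cases":
        bundles = []
        for i, sid in enumerate(ids):
            spec_i = replace(phantom, amplitude_mm=float(amplitudes[i]),
                             seed=int(tex_seeds[i]))
            bundles.append((sid, make_phantom(spec_i)))
        return bundles, survival

    # features mode: shared geometry, per-subject fields and textures
    labels, brain, center, _ = _phantom_masks(phantom)
    affine = _affine(phantom.spacing)
    seg = SegmentationSet(labels=labels, brain_mask=brain, affine=affine)
    bands = build_annular_bands(seg, band_cfg, spacing=phantom.spacing)
    dist = ndimage.distance_transform_edt(~seg.tumor_mask,
                                          sampling=phantom.spacing)
    coords = np.meshgrid(*[np.arange(n) * s
                           for n, s in zip(phantom.shape, phantom.spacing)],
                         indexing="ij")
    vec = np.stack([c - c0 for c, c0 in zip(coords, center)], axis=-1)
    norm = np.linalg.norm(vec, axis=-1)
    norm[norm == 0] = 1.0
    unit = vec / norm[..., None]
    base_mag = np.exp(-dist / phantom.decay_tau_mm)

    rows = []
    for i, sid in enumerate(ids):
        rng_i = np.random.default_rng(int(seeds[i]))
        mag = amplitudes[i] * base_mag
        if phantom.noise_sigma > 0:
            mag = mag * np.exp(phantom.noise_sigma
                               * rng_i.standard_normal(phantom.shape))
        mag[seg.tumor_mask] = 0.0
        fld = DisplacementField(components=unit * mag[..., None],
                                affine=affine)
        fB = deformation_descriptor(fld, seg, band_cfg, band_labels=bands)
        tex_rng = np.random.default_rng(int(tex_seeds[i]))
        data = _texture_volume(phantom, labels, brain, tex_rng)
        volume = VolumeGrid(data=data, affine=affine)
        comps = {
            key: collage_descriptor(volume, seg.compartment(key),
                                    collage_cfg, compartment=key)
            for key in ("T", "P", "N")
        }
        vec_i = assemble_rdepth(fB=fB, fT=comps["T"], fP=comps["P"],
                                fN=comps["N"], band_cfg=band_cfg,
                                collage_cfg=collage_cfg)
        rows.append(vec_i.values)
    features = pd.DataFrame(
        rows, columns=rdepth_feature_names(band_cfg, collage_cfg))
    features.insert(0, "subject_id", ids)
    return features, survival
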