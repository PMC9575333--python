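"""Reading, writing and geometric validation of imaging and tabular inputs.

All volumes are NIfTI-1 (optionally gzipped) handled through nibabel.
Displacement fields are per-voxel 3-vectors in physical millimetres, as
written by diffeomorphic registration toolkits (ANTs/Greedy); both the plain
4D ``(nx, ny, nz, 3)`` layout and the ITK-style 5D ``(nx, ny, nz, 1, 3)``
layout are accepted and normalised to one in-memory representation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GeometryError",
    "MaskInvariantError",
    "VolumeGrid",
    "DisplacementField",
    "SegmentationSet",
    "CaseBundle",
    "read_volume",
    "write_volume",
    "read_displacement_field",
    "write_displacement_field",
    "read_segmentation",
    "read_survival_table",
    "write_survival_table",
    "validate_case",
]

#: tolerance (mm) for comparing spacings/affines of co-registered inputs
GEOMETRY_ATOL = 1e-4

# segmentation label encoding fixed by this package (configurable via label_map)
LABEL_ENHANCING = 1
LABEL_PERITUMORAL = 2
LABEL_NECROTIC = 3
DEFAULT_LABEL_MAP = {
    "T": LABEL_ENHANCING,
    "P": LABEL_PERITUMORAL,
    "N": LABEL_NECROTIC,
}


class GeometryError(ValueError):
    """A volume's shape, spacing or affine violates the geometric contract."""


class MaskInvariantError(ValueError):
    """A segmentation mask violates a structural invariant."""


def _voxel_spacing(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(s) for s in nib.affines.voxel_sizes(affine))


@dataclass
class VolumeGrid:
    """A 3D scalar image on a voxel lattice with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities; left untouched on load (no rescale).
    affine : ndarray, shape (4, 4)
        Voxel-index to physical-space (mm) map.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise GeometryError(
                f"expected a 3D volume, got {self.data.ndim}D with shape "
                f"{self.data.shape} (extra axes: {self.data.shape[3:]})"
            )
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise GeometryError("affine is singular")
        if any(s <= 0 or not np.isfinite(s) for s in self.spacing):
            raise GeometryError(f"degenerate voxel spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel size (sx, sy, sz) in mm, derived from the affine."""
        return _voxel_spacing(self.affine)

    def same_geometry(self, other: "VolumeGrid | DisplacementField",
                      atol: float = GEOMETRY_ATOL) -> bool:
        return (
            self.shape == tuple(other.shape[:3])
            and np.allclose(self.affine, other.affine, atol=atol)
        )


@dataclass
class DisplacementField:
    """Per-voxel displacement 3-vectors in physical mm.

    ``components[..., k]`` holds the k-th displacement component on the same
    voxel lattice and geometry as the subject scan.
    """

    components: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.components.ndim != 4 or self.components.shape[-1] != 3:
            raise GeometryError(
                "displacement field must have shape (nx, ny, nz, 3); got "
                f"{self.components.shape} — expected 3 vector components"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[:3]

    @property
    def spacing(self) -> tuple[float, float, float]:
        return _voxel_spacing(self.affine)


@dataclass
class SegmentationSet:
    """Multi-label tumor segmentation plus brain and composite tumor masks.

    Labels: 0 background, 1 enhancing lesion (T), 2 peritumoral
    hyperintensity (P), 3 necrotic core (N). ``tumor_mask`` defaults to the
    union of labels 1–3; ``brain_mask`` must contain it.
    """

    labels: np.ndarray
    brain_mask: np.ndarray
    tumor_mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    label_map: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(np.int32)
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.tumor_mask is None:
            self.tumor_mask = self.labels > 0
        else:
            self.tumor_mask = np.asarray(self.tumor_mask).astype(bool)
        self.validate()

    def validate(self) -> None:
        if self.labels.shape != self.brain_mask.shape:
            raise GeometryError("labels and brain_mask shapes differ")
        if self.labels.shape != self.tumor_mask.shape:
            raise GeometryError("labels and tumor_mask shapes differ")
        present = set(np.unique(self.labels)) - {0}
        allowed = set(self.label_map.values())
        if not present <= allowed:
            raise MaskInvariantError(
                f"unexpected label values {sorted(present - allowed)}")
        # labels are a single integer lattice, so classes 1-3 are disjoint by
        # construction; the containment invariants still need checking
        if np.any((self.labels > 0) & ~self.tumor_mask):
            raise MaskInvariantError(
                "tumor_mask does not contain all labelled tumor voxels")
        if np.any(self.tumor_mask & ~self.brain_mask):
            raise MaskInvariantError("brain_mask does not contain tumor_mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def compartment(self, key: str) -> np.ndarray:
        """Binary mask of compartment 'T', 'P' or 'N'."""
        return self.labels == self.label_map[key]


@dataclass
class CaseBundle:
    """A validated, geometry-consistent (scan, field, segmentation) triple."""

    volume: VolumeGrid
    field: DisplacementField
    segmentation: SegmentationSet

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volume.shape


def read_volume(path: str | os.PathLike) -> VolumeGrid:
    """Load a 3D NIfTI volume; header spacing is preserved, data unrescaled."""
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    return VolumeGrid(data=data, affine=img.affine)


def write_volume(vol: VolumeGrid, path: str | os.PathLike) -> None:
    nib.save(nib.Nifti1Image(vol.data, vol.affine), os.fspath(path))


def read_displacement_field(
    path: str | os.PathLike,
    reference: VolumeGrid | None = None,
    voxel_units: bool = False,
) -> DisplacementField:
    """Load a displacement field in either the 4D or the 5D NIfTI dialect.

    Parameters
    ----------
    reference : VolumeGrid, optional
        If given, the field geometry must match it.
    voxel_units : bool
        Set when the file stores displacements in voxel units; they are
        converted to mm via the header spacing (default: already mm).
    """
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 5:
        # ITK vector-image layout (nx, ny, nz, 1, 3)
        if data.shape[3] != 1:
            raise GeometryError(
                f"5D field must have a singleton 4th axis, got {data.shape}")
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        ncomp = data.shape[-1] if data.ndim >= 4 else data.ndim
        raise GeometryError(
            f"displacement field in {path!s} has {ncomp} components; "
            "expected 3 components per voxel")
    fld = DisplacementField(components=data, affine=img.affine)
    if voxel_units:
        fld.components = fld.components * np.asarray(fld.spacing)
    if reference is not None and not reference.same_geometry(fld):
        raise GeometryError(
            "displacement field geometry does not match the reference volume")
    return fld


def write_displacement_field(
    fld: DisplacementField, path: str | os.PathLike, dialect: str = "4d"
) -> None:
    """Write a field as 4D ``(nx,ny,nz,3)`` or 5D ``(nx,ny,nz,1,3)`` NIfTI."""
    data = fld.components
    if dialect == "5d":
        data = data[:, :, :, None, :]
    elif dialect != "4d":
        raise ValueError(f"unknown field dialect {dialect!r}")
    nib.save(nib.Nifti1Image(data, fld.affine), os.fspath(path))


def read_segmentation(
    labels_path: str | os.PathLike,
    brain_mask_path: str | os.PathLike,
    tumor_mask_path: str | os.PathLike | None = None,
    label_map: dict[str, int] | None = None,
) -> SegmentationSet:
    lab = read_volume(labels_path)
    brain = read_volume(brain_mask_path)
    tumor = None
    if tumor_mask_path is not None:
        tumor = read_volume(tumor_mask_path).data > 0
    kwargs = {}
    if label_map is not None:
        kwargs["label_map"] = label_map
    return SegmentationSet(
        labels=np.rint(lab.data).astype(np.int32),
        brain_mask=brain.data > 0,
        tumor_mask=tumor,
        affine=lab.affine,
        **kwargs,
    )


def read_survival_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a ``subject_id,time,event`` CSV and validate its contract."""
    df = pd.read_csv(path)
    required = {"subject_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns {sorted(missing)}")
    df = df.copy()
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be strictly positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (death)")
    return df


def write_survival_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False)


def validate_case(
    volume: VolumeGrid,
    fld: DisplacementField,
    segmentation: SegmentationSet,
    atol: float = GEOMETRY_ATOL,
) -> CaseBundle:
    """Check the shared-geometry contract and mask invariants of a case.

    Raises
    ------
    GeometryError
        naming the offending input, when shapes/spacings/affines disagree
        beyond `atol`.
    MaskInvariantError
        when the segmentation violates its structural invariants.
    """
    if volume.shape != fld.shape:
        raise GeometryError(
            f"displacement field shape {fld.shape} differs from volume "
            f"shape {volume.shape}")
    if volume.shape != segmentation.shape:
        raise GeometryError(
            f"segmentation shape {segmentation.shape} differs from volume "
            f"shape {volume.shape}")
    if not np.allclose(volume.affine, fld.affine, atol=atol):
        raise GeometryError(
            "displacement field affine/spacing differs from volume geometry")
    if not np.allclose(volume.affine, segmentation.affine, atol=atol):
        raise GeometryError(
            "segmentation affine/spacing differs from volume geometry")
    segmentation.validate()
    if not segmentation.tumor_mask.any():
        raise MaskInvariantError("tumor_mask is empty")
    inside = fld.components[segmentation.brain_mask]
    if not np.all(np.isfinite(inside)):
        raise GeometryError(
            "displacement field has non-finite values inside the brain mask")
    return CaseBundle(volume=volume, field=fld, segmentation=segmentation)
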