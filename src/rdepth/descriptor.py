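"""Assembly of the r-DepTH descriptor and feature-table IO.

The full descriptor concatenates, in canonical order, the banded
deformation block F_B with the three compartment COLLAGE blocks F_T, F_P,
F_N; under the default configuration this is 60 + 3 x 130 = 450 named
features per subject. Feature names are a pure function of the
configuration, so tables from different runs align column-for-column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .collage import CollageConfig, collage_descriptor, collage_feature_names
from .deformation import (BandConfig, build_annular_bands,
                          deformation_descriptor, deformation_feature_names)
from .io import CaseBundle

__all__ = [
    "FeatureVector",
    "SchemaError",
    "assemble_rdepth",
    "rdepth_feature_names",
    "extract_rdepth",
    "write_feature_table",
    "read_feature_table",
]

BLOCK_ORDER = ("B", "T", "P", "N")


class SchemaError(ValueError):
    """A feature block or table does not match the expected schema."""


@dataclass
class FeatureVector:
    """Ordered named feature values with per-feature block provenance."""

    names: list[str]
    values: np.ndarray
    blocks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise SchemaError("names and values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise SchemaError("feature names must be unique")

    def __len__(self) -> int:
        return self.values.size

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def rdepth_feature_names(
    band_cfg: BandConfig = BandConfig(),
    collage_cfg: CollageConfig = CollageConfig(),
) -> list[str]:
    names = deformation_feature_names(band_cfg)
    for comp in ("T", "P", "N"):
        names += collage_feature_names(comp, collage_cfg)
    return names


def assemble_rdepth(
    *,
    fB: np.ndarray,
    fT: np.ndarray,
    fP: np.ndarray,
    fN: np.ndarray,
    band_cfg: BandConfig = BandConfig(),
    collage_cfg: CollageConfig = CollageConfig(),
) -> FeatureVector:
    """Concatenate the four blocks in canonical order B, T, P, N.

    Blocks are keyword-identified, so the call-site ordering of identical
    data cannot change the result. Lengths are validated against the active
    configuration (band block: n_bands x 5; each COLLAGE block: 130).
    """
    blocks = {"B": np.asarray(fB, float), "T": np.asarray(fT, float),
              "P": np.asarray(fP, float), "N": np.asarray(fN, float)}
    expected = {"B": band_cfg.n_bands * 5, "T": 130, "P": 130, "N": 130}
    for key in BLOCK_ORDER:
        if blocks[key] is None:
            raise SchemaError(f"missing feature block {key}")
        if blocks[key].size != expected[key]:
            raise SchemaError(
                f"block {key} has length {blocks[key].size}, expected "
                f"{expected[key]} for the active configuration")
    values = np.concatenate([blocks[k] for k in BLOCK_ORDER])
    names = rdepth_feature_names(band_cfg, collage_cfg)
    tags = [k for k in BLOCK_ORDER for _ in range(expected[k])]
    return FeatureVector(names=names, values=values, blocks=tags)


def extract_rdepth(
    bundle: CaseBundle,
    band_cfg: BandConfig = BandConfig(),
    collage_cfg: CollageConfig = CollageConfig(),
    band_labels: np.ndarray | None = None,
) -> FeatureVector:
    """Run the full descriptor pipeline on one validated case."""
    seg = bundle.segmentation
    if band_labels is None:
        band_labels = build_annular_bands(seg, band_cfg,
                                          spacing=bundle.volume.spacing)
    fB = deformation_descriptor(bundle.field, seg, band_cfg,
                                band_labels=band_labels)
    comps = {
        key: collage_descriptor(bundle.volume, seg.compartment(key),
                                collage_cfg, compartment=key)
        for key in ("T", "P", "N")
    }
    return assemble_rdepth(fB=fB, fT=comps["T"], fP=comps["P"],
                           fN=comps["N"], band_cfg=band_cfg,
                           collage_cfg=collage_cfg)


def write_feature_table(
    vectors: list[tuple[str, FeatureVector]], path
) -> pd.DataFrame:
    """Write one CSV row per subject, ``subject_id`` first.

    All vectors must share one schema; the offending subject is named
    otherwise. Missing-value sentinels (NaN) become empty CSV cells.
    """
    if not vectors:
        raise SchemaError("no feature vectors to write")
    ref_id, ref = vectors[0]
    for sid, vec in vectors[1:]:
        if vec.names != ref.names:
            raise SchemaError(
                f"subject {sid!r} feature schema differs from {ref_id!r}")
    df = pd.DataFrame(
        [vec.values for _, vec in vectors],
        columns=ref.names,
        index=pd.Index([sid for sid, _ in vectors], name="subject_id"),
    )
    df.to_csv(path)
    return df.reset_index()


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise SchemaError("feature table must have a subject_id column")
    return df
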