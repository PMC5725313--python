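"""ICN base-atlas construction, persistence, and summary.

An ICN atlas starts from K co-registered prototype Z-score volumes, one per
intrinsic connectivity network (or artefact component). Construction is
winner-take-all: each voxel whose Z exceeds a threshold T in at least one
component is labelled with the index of the component with the highest
supra-threshold Z; all other voxels are unlabelled (NaN). Alongside the
exclusive label volume the atlas keeps, per component, the thresholded Z
volume (Z where Z > T, NaN elsewhere) and the binary supra-threshold mask,
which is what the overlap metrics intersect with.

Conventions
-----------
* Strict ``Z > T`` everywhere; Z exactly equal to T is excluded.
* Argmax ties are resolved to the lowest component index, deterministically.
* Component labels are 1-based (1..K); NaN marks "belongs to no component".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import GeometryError, GridGeometry

__all__ = [
    "ZMapSet",
    "LabelAtlas",
    "AtlasFormatError",
    "build_atlas",
    "save_atlas",
    "load_atlas",
    "atlas_summary",
]

SCHEMA_KEY = "icnengage_schema"
SCHEMA_VERSION = 1


class AtlasFormatError(ValueError):
    """Raised when a persisted atlas is missing or malformed."""


@dataclass
class ZMapSet:
    """K prototype Z-score volumes on a common grid.

    ``z`` has shape ``(K,) + geometry.shape``. ``artefact_flags[i]`` marks
    noise/artefact components (they are atlased like any other; the flag is
    a reporting annotation only).
    """

    geometry: GridGeometry
    z: np.ndarray
    component_names: list[str]
    artefact_flags: list[bool] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 4 or self.z.shape[1:] != self.geometry.shape:
            raise GeometryError(
                f"z must be (K,)+{self.geometry.shape}, got {self.z.shape}"
            )
        k = self.z.shape[0]
        if k < 1:
            raise ValueError("need at least one component")
        self.component_names = [str(n) for n in self.component_names]
        if len(self.component_names) != k:
            raise ValueError("component_names length must equal K")
        if len(set(self.component_names)) != k:
            raise ValueError("component names must be unique")
        if not self.artefact_flags:
            self.artefact_flags = [False] * k
        if len(self.artefact_flags) != k:
            raise ValueError("artefact_flags length must equal K")

    @property
    def n_components(self) -> int:
        return self.z.shape[0]


@dataclass
class LabelAtlas:
    """Winner-take-all base atlas.

    Attributes
    ----------
    labels : ndarray, float
        1-based component label per voxel, NaN where no component exceeds T.
    z_masked : ndarray, (K,)+shape
        Prototype Z where Z > T, NaN elsewhere.
    binary : ndarray, (K,)+shape, uint8
        Supra-threshold masks (may overlap across components; the label
        volume is their mutually exclusive resolution).
    """

    geometry: GridGeometry
    labels: np.ndarray
    z_masked: np.ndarray
    binary: np.ndarray
    threshold_T: float
    component_names: list[str]
    artefact_flags: list[bool]
    provenance: str = ""

    @property
    def n_components(self) -> int:
        return self.binary.shape[0]

    def label_mask(self, i: int) -> np.ndarray:
        """Boolean mask of voxels exclusively labelled to 1-based component i."""
        return self.labels == i

    def binary_sizes(self) -> np.ndarray:
        """|ICN_i| per component: supra-threshold voxel counts."""
        return self.binary.reshape(self.n_components, -1).sum(axis=1).astype(int)

    def labelled_sizes(self) -> np.ndarray:
        """Exclusive labelled voxel counts per component."""
        flat = self.labels.ravel()
        counts = np.zeros(self.n_components, dtype=int)
        ok = ~np.isnan(flat)
        idx, c = np.unique(flat[ok].astype(int), return_counts=True)
        counts[idx - 1] = c
        return counts


def build_atlas(zmaps: ZMapSet, threshold_T: float = 3.0) -> LabelAtlas:
    """Threshold prototype Z maps and assign winner-take-all labels.

    Each voxel where at least one component's Z strictly exceeds
    ``threshold_T`` receives the (1-based) index of the component with the
    highest supra-threshold Z; ties go to the lowest index. Voxels where no
    component passes are NaN.

    Parameters
    ----------
    zmaps : ZMapSet
    threshold_T : float, default 3.0
        Z threshold for atlas membership (strict inequality).
    """
    if not np.isfinite(threshold_T):
        raise ValueError("threshold_T must be finite")
    z = zmaps.z
    above = z > threshold_T
    z_masked = np.where(above, z, np.nan)
    binary = above.astype(np.uint8)

    any_above = above.any(axis=0)
    # argmax on -inf-filled copy: NaNs never win, ties -> lowest index
    z_for_argmax = np.where(above, z, -np.inf)
    winner = np.argmax(z_for_argmax, axis=0).astype(float) + 1.0
    labels = np.where(any_above, winner, np.nan)

    if not any_above.any():
        warnings.warn(
            "no voxel exceeds the atlas threshold; atlas is empty", stacklevel=2
        )
    return LabelAtlas(
        geometry=zmaps.geometry,
        labels=labels,
        z_masked=z_masked,
        binary=binary,
        threshold_T=float(threshold_T),
        component_names=list(zmaps.component_names),
        artefact_flags=list(zmaps.artefact_flags),
        provenance=zmaps.provenance,
    )


def save_atlas(atlas: LabelAtlas, path: str | Path) -> None:
    """Persist an atlas as NIfTI volumes plus a JSON sidecar.

    Writes ``labels.nii.gz`` (float, NaN = unlabelled), ``zmaps.nii.gz``
    (4-D stack of masked Z volumes) and ``meta.json`` into directory
    ``path`` (created if needed).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    affine = atlas.geometry.affine
    nib.save(
        nib.Nifti1Image(atlas.labels.astype(np.float32), affine),
        path / "labels.nii.gz",
    )
    # 4-D: component axis last, the NIfTI convention
    stack = np.moveaxis(atlas.z_masked, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(stack, affine), path / "zmaps.nii.gz")
    meta = {
        SCHEMA_KEY: SCHEMA_VERSION,
        "component_names": atlas.component_names,
        "artefact_flags": [bool(f) for f in atlas.artefact_flags],
        "threshold_T": atlas.threshold_T,
        "provenance": atlas.provenance,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_atlas(path: str | Path) -> LabelAtlas:
    """Load an atlas saved by :func:`save_atlas`.

    The binary masks are rebuilt from the stored masked Z volumes (a voxel
    is in a component's mask iff its masked Z is finite), so the round trip
    is exact on labels and metadata and float32-exact on Z.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    labels_path = path / "labels.nii.gz"
    z_path = path / "zmaps.nii.gz"
    for p, what in [(labels_path, "label volume"), (z_path, "Z volume stack"),
                    (meta_path, "metadata sidecar")]:
        if not p.exists():
            raise AtlasFormatError(f"atlas at {path} is missing its {what} ({p.name})")
    meta = json.loads(meta_path.read_text())
    for key in (SCHEMA_KEY, "component_names", "threshold_T", "artefact_flags"):
        if key not in meta:
            raise AtlasFormatError(f"atlas metadata is missing field {key!r}")
    labels_img = nib.load(str(labels_path))
    labels = np.asarray(labels_img.dataobj, dtype=float)
    geometry = GridGeometry(shape=labels.shape, affine=labels_img.affine)
    stack = np.asarray(nib.load(str(z_path)).dataobj, dtype=float)
    z_masked = np.moveaxis(stack, -1, 0)
    binary = np.isfinite(z_masked).astype(np.uint8)
    return LabelAtlas(
        geometry=geometry,
        labels=labels,
        z_masked=z_masked,
        binary=binary,
        threshold_T=float(meta["threshold_T"]),
        component_names=list(meta["component_names"]),
        artefact_flags=[bool(f) for f in meta["artefact_flags"]],
        provenance=meta.get("provenance", ""),
    )


def atlas_summary(atlas: LabelAtlas) -> pd.DataFrame:
    """Per-component voxel counts and grid coverage.

    Returns a DataFrame indexed by component name with columns
    ``labelled_voxels`` (exclusive labels), ``binary_voxels``
    (supra-threshold mask size), ``grid_fraction`` (labelled voxels over
    total grid voxels) and ``artefact``.
    """
    labelled = atlas.labelled_sizes()
    binary = atlas.binary_sizes()
    m = atlas.geometry.n_voxels
    return pd.DataFrame(
        {
            "labelled_voxels": labelled,
            "binary_voxels": binary,
            "grid_fraction": labelled / m,
            "artefact": list(atlas.artefact_flags),
        },
        index=pd.Index(atlas.component_names, name="component"),
    )
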