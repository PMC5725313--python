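"""Input statistical maps: loading, grid reconciliation, thresholding.

The metric engine requires the input map to live on the atlas grid. Maps
arriving on a different grid are resampled *to the atlas* (never the
reverse) through the world-space affines of both volumes: trilinear for
continuous statistic volumes, nearest-neighbour for masks/labels. NaN is
the missing-data sentinel throughout and propagates through interpolation.

Thresholding is strict (``value > threshold`` retained) with an optional
SPM-style cluster-extent filter using 26-connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .geometry import GeometryError, GridGeometry

__all__ = ["StatMap", "load_stat_map", "resample_to_atlas", "threshold_map"]


@dataclass
class StatMap:
    """One statistical volume (T, F or Z statistic) on a defined grid.

    NaN marks voxels outside the brain or removed by thresholding. For a
    thresholded map every finite voxel strictly exceeds ``threshold_value``.
    """

    geometry: GridGeometry
    values: np.ndarray
    stat_kind: str = "unknown"  # {"T", "F", "Z", "unknown"}
    thresholded: bool = False
    threshold_value: float | None = None

    def __post_init__(self) -> None:
        self.values = self.geometry.check_volume(
            np.asarray(self.values, dtype=float), "values"
        )
        if self.stat_kind not in {"T", "F", "Z", "unknown"}:
            raise ValueError(f"unknown stat_kind {self.stat_kind!r}")

    @property
    def active_mask(self) -> np.ndarray:
        """Finite, non-zero voxels — the activation set |SPM_t|."""
        return np.isfinite(self.values) & (self.values != 0)


def load_stat_map(
    path: str | Path,
    stat_kind_hint: str | None = None,
    volume_index: int | None = None,
) -> StatMap:
    """Load a NIfTI (.nii/.nii.gz) or Analyze (.hdr/.img) statistic volume.

    Parameters
    ----------
    path : path-like
    stat_kind_hint : {"T", "F", "Z"}, optional
        Statistic type; if omitted, a parseable header ``descrip`` field
        (e.g. "SPM{T_...}") is consulted, else the kind is "unknown".
    volume_index : int, optional
        Required to select one volume from a 4-D file.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        if data.shape[3] == 1:
            data = data[..., 0]
        elif volume_index is None:
            raise ValueError(
                f"{path} is 4-D with {data.shape[3]} volumes; "
                "pass volume_index to select one"
            )
        else:
            data = data[..., int(volume_index)]
    elif data.ndim != 3:
        raise ValueError(f"{path} is {data.ndim}-D; expected a 3-D volume")
    kind = stat_kind_hint or _kind_from_header(img) or "unknown"
    if kind not in {"T", "F", "Z", "unknown"}:
        raise ValueError(f"stat_kind_hint must be T, F or Z, got {kind!r}")
    geometry = GridGeometry(shape=data.shape, affine=img.affine)
    return StatMap(geometry=geometry, values=data, stat_kind=kind)


def _kind_from_header(img) -> str | None:
    try:
        descrip = str(np.asarray(img.header["descrip"]).item(), "ascii", "ignore")
    except (KeyError, TypeError, ValueError):
        return None
    for kind in ("T", "F", "Z"):
        if f"SPM{{{kind}" in descrip or descrip.strip().startswith(f"{kind}-"):
            return kind
    return None


def resample_to_atlas(
    stat_map: StatMap, target: GridGeometry, method: str = "trilinear"
) -> StatMap:
    """Resample a map onto the atlas grid through world coordinates.

    Each target voxel centre is mapped to world space via the target
    affine, then into the source voxel space via the inverse source
    affine, and the source volume is interpolated there. Target voxels
    falling outside the source field of view become NaN, and NaN source
    voxels poison any trilinear interpolation that touches them.

    A map already on the target grid is returned unchanged (identity
    short-circuit, bit-exact values).
    """
    if method not in {"nearest", "trilinear"}:
        raise ValueError(f"method must be 'nearest' or 'trilinear', got {method!r}")
    if stat_map.geometry.matches(target):
        return stat_map

    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in target.shape), indexing="ij")
    world = target.voxel_to_world(np.stack([ii, jj, kk], axis=-1))
    src = stat_map.geometry.world_to_voxel(world)  # fractional source indices

    inside = np.all((src > -0.5) & (src < np.array(stat_map.geometry.shape) - 0.5),
                    axis=-1)
    if not inside.any():
        raise GeometryError(
            "no spatial overlap between the input map and the target grid"
        )

    order = 0 if method == "nearest" else 1
    out = ndimage.map_coordinates(
        stat_map.values,
        np.moveaxis(src, -1, 0),
        order=order,
        mode="constant",
        cval=np.nan,
        prefilter=False,
    )
    out[~inside] = np.nan
    return StatMap(
        geometry=target,
        values=out,
        stat_kind=stat_map.stat_kind,
        thresholded=stat_map.thresholded,
        threshold_value=stat_map.threshold_value,
    )


# 26-neighbour connectivity, SPM's convention for cluster extent
_CONN26 = np.ones((3, 3, 3), dtype=bool)


def threshold_map(
    stat_map: StatMap,
    threshold: float,
    cluster_extent_k: int = 0,
    sign_flip: bool = False,
) -> StatMap:
    """Apply significance thresholding, optionally with a cluster-extent cut.

    Voxels with ``value > threshold`` (strict) are retained; all others
    become NaN. With ``cluster_extent_k > 0``, surviving 26-connected
    clusters smaller than k voxels are also removed. ``sign_flip`` negates
    the map first, for atlasing deactivations.
    """
    if cluster_extent_k < 0:
        raise ValueError("cluster_extent_k must be >= 0")
    if stat_map.thresholded:
        warnings.warn("re-thresholding an already thresholded map", stacklevel=2)
    values = -stat_map.values if sign_flip else stat_map.values
    keep = np.isfinite(values) & (values > threshold)
    if cluster_extent_k > 0:
        lab, n = ndimage.label(keep, structure=_CONN26)
        if n:
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            keep &= sizes[lab] >= cluster_extent_k
    out = np.where(keep, values, np.nan)
    return StatMap(
        geometry=stat_map.geometry,
        values=out,
        stat_kind=stat_map.stat_kind,
        thresholded=True,
        threshold_value=float(threshold),
    )
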