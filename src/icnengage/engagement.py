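"""Engagement metric engine.

Given a statistical map on an atlas grid, the input's active voxels (finite
and non-zero) are labelled by the atlas and a family of engagement metrics
is computed per component plus four global summaries.

Per-component metrics (11)
--------------------------
========  ===========================================================
I         spatial involvement, |SPM ∩ ICN_i| / |ICN_i|
IR        relative spatial involvement, |SPM ∩ ICN_i| / Σ_j |SPM ∩ ICN_j|
OL        spatial overlap, |SPM ∩ ICN_i| / |SPM|
SQ        Sørensen–Dice coefficient, 2|SPM ∩ ICN_i| / (|SPM| + |ICN_i|)
J         Jaccard index, |SPM ∩ ICN_i| / |SPM ∪ ICN_i|
MA        mean activation, Σ v over SPM ∩ ICN_i / |SPM ∩ ICN_i|
MA_N      normalised mean activation, Σ u over SPM ∩ ICN_i / |SPM ∩ ICN_i|
IR_M      relative normalised mean activation, MA_N,i / Σ_j MA_N,j
RA_N      normalised relative activation, U_i / Σ_j U_j
I_M       normalised mean activation density, U_i / |ICN_i|
r         Pearson spatial correlation of the map with the prototype Z
========  ===========================================================

where ``u_n = (v_n − min)/(max − min)`` is the voxel statistic normalised
to the map's (or caller-fixed) bounds and ``U_i = Σ u_n`` over the active
voxels of component i.

Global metrics (4): ``I_T`` (pooled spatial involvement,
Σ_i |SPM ∩ ICN_i| / Σ_i |ICN_i|), ``MA`` and ``MA_N`` (pooled raw and
normalised means over all component-active voxels), and ``I_T_M`` (pooled
normalised density, Σ_i U_i / Σ_i |ICN_i|).

Undefined cells — e.g. MA_N,i where no voxel of component i is active —
are NaN in the table and flagged, never silently zero.

Intersections are computed against the per-component supra-threshold
binary masks by default (``counting="binary"``); a switch selects the
mutually exclusive winner-take-all labels instead (``counting="labels"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import LabelAtlas
from .geometry import GeometryError
from .maps import StatMap, load_stat_map, resample_to_atlas, threshold_map

__all__ = [
    "LabelledActivation",
    "EngagementTable",
    "ICN_METRICS",
    "GLOBAL_METRICS",
    "label_activation",
    "spatial_metrics",
    "activation_metrics",
    "engage",
]

ICN_METRICS = ["I", "IR", "OL", "SQ", "J", "MA", "MA_N", "IR_M", "RA_N", "I_M", "r"]
GLOBAL_METRICS = ["I_T", "MA", "MA_N", "I_T_M"]


class NormalizationError(ValueError):
    """Raised when normalisation bounds are degenerate (max == min)."""


@dataclass
class LabelledActivation:
    """Input map voxels labelled by the atlas, with per-component counts.

    ``L`` holds the atlas label at active input voxels and NaN elsewhere.
    ``counts_binary[i]`` is the binary-mask intersection |SPM ∩ ICN_i|;
    ``counts_label[i]`` the mutually exclusive label-based count.
    ``raw_values``, when present, is the pre-threshold map used for the
    spatial correlation metric.
    """

    L: np.ndarray
    counts_binary: np.ndarray
    counts_label: np.ndarray
    n_active: int
    value_min: float
    value_max: float
    values: np.ndarray
    raw_values: np.ndarray | None = None


@dataclass
class EngagementTable:
    """Per-component and global engagement metrics for one input map."""

    per_icn: pd.DataFrame  # components x ICN_METRICS, NaN = undefined
    global_metrics: dict[str, float]
    meta: dict = field(default_factory=dict)

    @property
    def defined(self) -> pd.DataFrame:
        return self.per_icn.notna()

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: map, basemap, metric, value, defined."""
        rows = self.per_icn.reset_index().melt(
            id_vars="component", var_name="metric", value_name="value"
        )
        rows.insert(0, "map", self.meta.get("input", ""))
        rows = rows.rename(columns={"component": "basemap"})
        g = pd.DataFrame(
            {
                "map": self.meta.get("input", ""),
                "basemap": "_global",
                "metric": list(self.global_metrics),
                "value": list(self.global_metrics.values()),
            }
        )
        out = pd.concat([rows, g], ignore_index=True)
        out["defined"] = out["value"].notna()
        return out

    def to_csv(self, path: str | Path) -> None:
        self.to_tidy().to_csv(path, index=False, float_format="%.12g")

    def to_dict(self) -> dict:
        return {
            "meta": self.meta,
            "global": {
                k: (None if v is None or not np.isfinite(v) else float(v))
                for k, v in self.global_metrics.items()
            },
            "per_icn": {
                name: {
                    m: (None if np.isnan(v) else float(v))
                    for m, v in row.items()
                }
                for name, row in self.per_icn.iterrows()
            },
        }


def label_activation(stat_map: StatMap, atlas: LabelAtlas) -> LabelledActivation:
    """Label the input map's active voxels by the atlas.

    The map must already be on the atlas grid; maps on another grid raise
    a :class:`GeometryError` directing the caller to
    :func:`~icnengage.maps.resample_to_atlas` (no silent resampling).
    """
    if not stat_map.geometry.matches(atlas.geometry):
        raise GeometryError(
            "input map is not on the atlas grid; resample it first with "
            "resample_to_atlas(map, atlas.geometry)"
        )
    active = stat_map.active_mask
    L = np.where(active, atlas.labels, np.nan)
    k = atlas.n_components
    flat_active = active.ravel()
    counts_binary = (
        atlas.binary.reshape(k, -1)[:, flat_active].sum(axis=1).astype(int)
    )
    counts_label = np.zeros(k, dtype=int)
    lab = L.ravel()
    ok = ~np.isnan(lab)
    idx, c = np.unique(lab[ok].astype(int), return_counts=True)
    counts_label[idx - 1] = c
    vals = stat_map.values[active]
    vmin = float(vals.min()) if vals.size else np.nan
    vmax = float(vals.max()) if vals.size else np.nan
    return LabelledActivation(
        L=L,
        counts_binary=counts_binary,
        counts_label=counts_label,
        n_active=int(active.sum()),
        value_min=vmin,
        value_max=vmax,
        values=stat_map.values,
    )


def _masks_sizes(atlas: LabelAtlas, counting: str):
    k = atlas.n_components
    if counting == "binary":
        masks = atlas.binary.astype(bool).reshape(k, -1)
        sizes = atlas.binary_sizes()
    elif counting == "labels":
        flat = atlas.labels.ravel()
        masks = np.stack([flat == i + 1 for i in range(k)])
        sizes = atlas.labelled_sizes()
    else:
        raise ValueError("counting must be 'binary' or 'labels'")
    if (sizes == 0).any():
        bad = [atlas.component_names[i] for i in np.flatnonzero(sizes == 0)]
        raise ValueError(f"atlas integrity: zero-volume component(s) {bad}")
    return masks, sizes


def spatial_metrics(
    la: LabelledActivation, atlas: LabelAtlas, counting: str = "binary"
) -> EngagementTable:
    """Spatial-extent metric family: I, IR, OL, SQ, J per component + I_T."""
    masks, sizes = _masks_sizes(atlas, counting)
    active = np.isfinite(la.values.ravel()) & (la.values.ravel() != 0)
    inter = masks[:, active].sum(axis=1).astype(float)
    n_act = float(la.n_active)
    tot_inter = inter.sum()

    with np.errstate(invalid="ignore", divide="ignore"):
        I = inter / sizes
        IR = inter / tot_inter if tot_inter > 0 else np.full_like(inter, np.nan)
        OL = inter / n_act if n_act > 0 else np.full_like(inter, np.nan)
        SQ = 2.0 * inter / (n_act + sizes)
        union = n_act + sizes - inter
        J = inter / union
    I_T = float(tot_inter / sizes.sum())

    df = pd.DataFrame(
        {"I": I, "IR": IR, "OL": OL, "SQ": SQ, "J": J},
        index=pd.Index(atlas.component_names, name="component"),
    )
    return EngagementTable(
        per_icn=df, global_metrics={"I_T": I_T}, meta={"counting": counting}
    )


def activation_metrics(
    la: LabelledActivation,
    atlas: LabelAtlas,
    bounds: tuple[float, float] | None = None,
    counting: str = "binary",
) -> EngagementTable:
    """Activation-strength metric family.

    Per component: MA, MA_N, IR_M, RA_N, I_M, r; global: MA, MA_N, I_T_M.

    Parameters
    ----------
    bounds : (min, max), optional
        Normalisation bounds for the voxel statistic. Default: the input
        map's own min/max over active voxels. Pass session-wide bounds to
        make normalised metrics comparable across maps of one session.
        Bounds that fail to bracket the data clip with a warning.
    """
    masks, sizes = _masks_sizes(atlas, counting)
    flat = la.values.ravel()
    active = np.isfinite(flat) & (flat != 0)

    if bounds is None:
        vmin, vmax = la.value_min, la.value_max
    else:
        vmin, vmax = float(bounds[0]), float(bounds[1])
        if active.any() and (la.value_min < vmin or la.value_max > vmax):
            warnings.warn(
                "normalisation bounds do not bracket the map values; "
                "normalised statistics are clipped to [0, 1]",
                stacklevel=2,
            )
    if not active.any():
        vmin, vmax = np.nan, np.nan
    elif vmax == vmin:
        raise NormalizationError(
            "map statistic is constant over active voxels (max == min); "
            "normalised activation metrics are undefined — pass explicit bounds"
        )

    v = np.where(active, flat, 0.0)
    u = np.zeros_like(v)
    if active.any():
        u[active] = np.clip((flat[active] - vmin) / (vmax - vmin), 0.0, 1.0)

    counts = masks[:, active].sum(axis=1).astype(float)
    sums = masks @ v          # Σ statistic over active ∩ component
    nums = masks @ u          # Σ normalised statistic, the Eq-style numerator

    with np.errstate(invalid="ignore", divide="ignore"):
        MA = np.where(counts > 0, sums / counts, np.nan)
        MA_N = np.where(counts > 0, nums / counts, np.nan)
        tot_num = nums.sum()
        RA_N = nums / tot_num if tot_num > 0 else np.full_like(nums, np.nan)
        I_M = nums / sizes
        sum_man = np.nansum(MA_N) if np.isfinite(MA_N).any() else np.nan
        IR_M = MA_N / sum_man if sum_man and sum_man > 0 else np.full_like(MA_N, np.nan)

    r = _spatial_correlation(la, atlas, masks)

    tot_counts = counts.sum()
    g = {
        "MA": float(sums.sum() / tot_counts) if tot_counts > 0 else np.nan,
        "MA_N": float(tot_num / tot_counts) if tot_counts > 0 else np.nan,
        "I_T_M": float(tot_num / sizes.sum()),
    }
    df = pd.DataFrame(
        {"MA": MA, "MA_N": MA_N, "IR_M": IR_M, "RA_N": RA_N, "I_M": I_M, "r": r},
        index=pd.Index(atlas.component_names, name="component"),
    )
    return EngagementTable(
        per_icn=df,
        global_metrics=g,
        meta={"bounds": (vmin, vmax), "counting": counting},
    )


def _spatial_correlation(
    la: LabelledActivation, atlas: LabelAtlas, masks: np.ndarray
) -> np.ndarray:
    """Pearson r of the input statistic with each prototype Z volume.

    Computed over the atlas domain (voxels belonging to any component),
    not the whole grid, which would be dominated by out-of-brain zeros.
    Uses the unthresholded input when available. Sub-threshold prototype
    Z is unavailable from a persisted atlas (only masked Z is stored); it
    is treated as 0 there, which only affects domain voxels outside the
    component's own mask.
    """
    domain = masks.any(axis=0)
    x_src = la.raw_values if la.raw_values is not None else la.values
    x = np.nan_to_num(x_src.ravel(), nan=0.0)[domain]
    k = atlas.n_components
    out = np.full(k, np.nan)
    if x.size < 2 or np.std(x) == 0:
        return out
    z = np.nan_to_num(atlas.z_masked.reshape(k, -1), nan=0.0)[:, domain]
    xc = x - x.mean()
    zc = z - z.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(xc) * np.linalg.norm(zc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rr = (zc @ xc) / denom
    out[denom > 0] = rr[denom > 0]
    return out


def engage(
    stat_map: StatMap | str | Path,
    atlas: LabelAtlas,
    input_threshold: float | None = 3.0,
    cluster_k: int = 0,
    bounds: tuple[float, float] | None = None,
    counting: str = "binary",
    resample_method: str = "trilinear",
    stat_kind_hint: str | None = None,
) -> EngagementTable:
    """End-to-end pipeline: load → resample → threshold → label → metrics.

    ``input_threshold=None`` runs in unthresholded ("raw") mode. The
    returned table merges the spatial and activation families plus the
    four global metrics.
    """
    meta_input = ""
    if isinstance(stat_map, (str, Path)):
        meta_input = str(stat_map)
        stat_map = load_stat_map(stat_map, stat_kind_hint)
    if not stat_map.geometry.matches(atlas.geometry):
        stat_map = resample_to_atlas(stat_map, atlas.geometry, resample_method)
    raw = stat_map
    if input_threshold is not None and not stat_map.thresholded:
        stat_map = threshold_map(stat_map, input_threshold, cluster_k)

    la = label_activation(stat_map, atlas)
    la.raw_values = raw.values
    spatial = spatial_metrics(la, atlas, counting)
    activ = activation_metrics(la, atlas, bounds, counting)

    per_icn = pd.concat([spatial.per_icn, activ.per_icn], axis=1)[ICN_METRICS]
    global_metrics = {**spatial.global_metrics, **activ.global_metrics}
    global_metrics = {m: global_metrics[m] for m in GLOBAL_METRICS}
    meta = {
        "input": meta_input,
        "atlas": atlas.provenance,
        "atlas_threshold": atlas.threshold_T,
        "input_threshold": input_threshold,
        "cluster_k": cluster_k,
        "bounds": activ.meta["bounds"],
        "counting": counting,
        "n_active": la.n_active,
    }
    return EngagementTable(per_icn=per_icn, global_metrics=global_metrics, meta=meta)
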