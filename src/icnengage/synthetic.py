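"""Synthetic fixtures with known ground truth.

Everything the toolbox consumes can be generated here at desk scale with
no download: prototype Z-map sets built from smoothed Gaussian blobs
(ground-truth labels computed by an independent per-voxel loop),
activation maps with exactly requested per-component involvement, and
multi-session score sets with known variance components (hence known true
consistency ICC). All generators are deterministic under a fixed seed.

The session model is ``y_st = u_s + b_t + e_st`` with independent
zero-mean normal subject, session, and residual effects. The session
(column) effect exists precisely so that the consistency ICC's
insensitivity to systematic offsets is testable; the true consistency ICC
is sigma_u^2 / (sigma_u^2 + sigma_e^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import LabelAtlas, ZMapSet, build_atlas
from .geometry import GridGeometry
from .maps import StatMap
from .repeatability import SessionScoreSet

__all__ = [
    "SyntheticSpec",
    "default_geometry",
    "make_zmap_set",
    "make_atlas_fixture",
    "make_activation_fixture",
    "make_session_scores",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic world.

    Defaults mirror a small multi-session resting-state study: 25
    subjects scanned in 3 sessions, K=10 atlas components on a coarse
    MNI-like 2 mm grid, atlas and input thresholds of Z = 3.
    """

    shape: tuple[int, int, int] = (28, 28, 28)
    voxel_mm: float = 2.0
    n_components: int = 10
    amplitude_range: tuple[float, float] = (5.0, 9.0)
    blob_radius_vox: float = 4.0
    smooth_fwhm_vox: float = 2.0
    threshold_T: float = 3.0
    n_subjects: int = 25
    n_sessions: int = 3
    sigma_u2: float = 1.0  # subject variance
    sigma_b2: float = 0.25  # session (systematic offset) variance
    sigma_d2: float = 0.0  # subject-specific between-day drift variance
    sigma_e2: float = 1.0  # residual variance
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_u2", "sigma_b2", "sigma_d2", "sigma_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def true_icc(self) -> float:
        denom = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / denom if denom > 0 else np.nan

    def geometry(self) -> GridGeometry:
        return default_geometry(self.shape, self.voxel_mm)


def default_geometry(
    shape: tuple[int, int, int] = (28, 28, 28), voxel_mm: float = 2.0
) -> GridGeometry:
    """An MNI-like grid: isotropic voxels, origin at the grid centre."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    return GridGeometry(shape=tuple(shape), affine=affine)


def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def make_zmap_set(spec: SyntheticSpec) -> ZMapSet:
    """K prototype Z volumes from smoothed Gaussian blobs.

    Each component is a spherical blob with a Gaussian radial profile of
    scale ``blob_radius_vox`` and amplitude drawn from
    ``amplitude_range``, optionally smoothed. Centres are placed by
    greedy farthest-point sampling from a seeded candidate pool (kept a
    blob radius off the grid faces), which spreads components over the
    grid so that supra-threshold regions overlap only moderately — like
    real ICN prototypes, which are spatially segregated but not disjoint.
    """
    rng = np.random.default_rng(spec.seed)
    shape = np.asarray(spec.shape)
    if (spec.blob_radius_vox * 2 >= shape).any():
        raise ValueError("blob radius too large for the grid")
    grid = np.stack(
        np.meshgrid(*(np.arange(s) for s in shape), indexing="ij"), axis=-1
    ).astype(float)
    z = np.empty((spec.n_components, *spec.shape))
    margin = spec.blob_radius_vox
    candidates = rng.uniform(margin, shape - 1 - margin,
                             size=(max(256, 32 * spec.n_components), 3))
    centres = [candidates[0]]
    while len(centres) < spec.n_components:
        d = np.min(
            np.linalg.norm(candidates[:, None] - np.array(centres)[None], axis=-1),
            axis=1,
        )
        centres.append(candidates[int(np.argmax(d))])
    for i in range(spec.n_components):
        centre = centres[i]
        amp = rng.uniform(*spec.amplitude_range)
        d2 = ((grid - centre) ** 2).sum(axis=-1)
        vol = amp * np.exp(-d2 / (2.0 * spec.blob_radius_vox**2))
        if spec.smooth_fwhm_vox > 0:
            vol = ndimage.gaussian_filter(vol, _fwhm_to_sigma(spec.smooth_fwhm_vox))
        z[i] = vol
    names = [f"ICN{i + 1}" for i in range(spec.n_components)]
    return ZMapSet(
        geometry=spec.geometry(),
        z=z,
        component_names=names,
        provenance=f"synthetic blobs (seed={spec.seed})",
    )


def _ground_truth_labels(z: np.ndarray, threshold: float) -> np.ndarray:
    """Per-voxel loop oracle: threshold then argmax, ties to lowest index."""
    k = z.shape[0]
    shape = z.shape[1:]
    labels = np.full(shape, np.nan)
    for idx in np.ndindex(shape):
        best, best_z = None, threshold
        for i in range(k):
            if z[(i, *idx)] > best_z:
                best, best_z = i + 1, z[(i, *idx)]
        if best is not None:
            labels[idx] = best
    return labels


def make_atlas_fixture(spec: SyntheticSpec):
    """Z-map set plus construction ground truth.

    Returns ``(zmaps, truth_labels, truth_sizes)`` where the label volume
    and per-component supra-threshold sizes come from an independent
    per-voxel loop, enabling exact assertions on the atlas builder.
    """
    zmaps = make_zmap_set(spec)
    truth_labels = _ground_truth_labels(zmaps.z, spec.threshold_T)
    truth_sizes = (zmaps.z > spec.threshold_T).reshape(
        spec.n_components, -1
    ).sum(axis=1)
    return zmaps, truth_labels, truth_sizes


def make_activation_fixture(
    atlas: LabelAtlas,
    target_I: np.ndarray,
    amplitude: float = 8.0,
    seed: int = 0,
    n_distractors: int = 0,
    value_floor: float | None = None,
):
    """Activation map achieving exactly floor-quantised involvement targets.

    For each component i, ``floor(target_I[i] * |ICN_i|)`` voxels are
    sampled without replacement from the component's *exclusive*
    supra-threshold region (inside its binary mask and no other), so the
    binary-intersection count — and hence I_i — is exact by construction
    for every component simultaneously. Active voxel values are drawn
    uniformly from ``(value_floor, amplitude]`` with ``value_floor``
    defaulting to the atlas threshold, so the map survives input
    thresholding at the atlas threshold unchanged. Optional distractor
    voxels are placed outside every component mask.

    Returns ``(stat_map, achieved_I)``.
    """
    target_I = np.asarray(target_I, dtype=float)
    k = atlas.n_components
    if target_I.shape != (k,):
        raise ValueError(f"target_I must have length {k}")
    if ((target_I < 0) | (target_I > 1)).any():
        raise ValueError("target_I entries must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sizes = atlas.binary_sizes()
    masks = atlas.binary.astype(bool).reshape(k, -1)
    any_mask = masks.any(axis=0)
    n_other = masks.sum(axis=0)
    values = np.zeros(atlas.geometry.n_voxels)
    lo = atlas.threshold_T if value_floor is None else float(value_floor)
    if amplitude <= lo:
        raise ValueError("amplitude must exceed the value floor")

    achieved = np.zeros(k)
    for i in range(k):
        want = int(np.floor(target_I[i] * sizes[i]))
        exclusive = np.flatnonzero(masks[i] & (n_other == 1))
        if want > exclusive.size:
            raise ValueError(
                f"component {atlas.component_names[i]!r}: requested "
                f"{want} voxels but only {exclusive.size} exclusive "
                "supra-threshold voxels are available"
            )
        chosen = rng.choice(exclusive, size=want, replace=False)
        values[chosen] = rng.uniform(lo + 1e-6, amplitude, size=want)
        achieved[i] = want / sizes[i]

    if n_distractors:
        outside = np.flatnonzero(~any_mask)
        chosen = rng.choice(
            outside, size=min(n_distractors, outside.size), replace=False
        )
        values[chosen] = rng.uniform(lo + 1e-6, amplitude, size=chosen.size)

    stat_map = StatMap(
        geometry=atlas.geometry,
        values=values.reshape(atlas.geometry.shape),
        stat_kind="Z",
    )
    return stat_map, achieved


def make_session_scores(
    spec: SyntheticSpec,
    items: list[tuple] | None = None,
) -> tuple[SessionScoreSet, float]:
    """Multi-subject multi-session scores with a known true ICC.

    One (ic, basemap, metric) item series per entry of ``items`` (default:
    every component of a K-component atlas for metric "I", one IC). Each
    item's scores follow ``y_st = u_s + b_t + d_s·[t ≥ 2] + e_st``: the
    optional drift term d_s (variance ``sigma_d2``, default 0) is a
    subject-specific long-term change shared by the later same-day
    session pair, emulating designs where sessions 2 and 3 are scanned
    months after baseline — it raises within-session agreement above
    between-session agreement. Returns the score set and the true
    consistency ICC sigma_u^2/(sigma_u^2 + sigma_e^2) of the drift-free
    model.
    """
    rng = np.random.default_rng(spec.seed)
    if items is None:
        items = [("IC1", f"ICN{i + 1}", "I") for i in range(spec.n_components)]
    s, t = spec.n_subjects, spec.n_sessions
    rows = []
    for ic, basemap, metric in items:
        u = rng.normal(0.0, np.sqrt(spec.sigma_u2), size=s)
        b = rng.normal(0.0, np.sqrt(spec.sigma_b2), size=t)
        d = rng.normal(0.0, np.sqrt(spec.sigma_d2), size=s)
        e = rng.normal(0.0, np.sqrt(spec.sigma_e2), size=(s, t))
        y = u[:, None] + b[None, :] + e
        y[:, 1:] += d[:, None]
        for si in range(s):
            for ti in range(t):
                rows.append(
                    (si + 1, ti + 1, ic, basemap, metric, y[si, ti])
                )
    scores = pd.DataFrame(
        rows, columns=["subject", "session", "ic", "basemap", "metric", "value"]
    )
    return SessionScoreSet(scores=scores), spec.true_icc


def make_default_atlas(spec: SyntheticSpec | None = None) -> LabelAtlas:
    """Convenience: build the winner-take-all atlas of the synthetic world."""
    spec = spec or SyntheticSpec()
    zmaps = make_zmap_set(spec)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_atlas(zmaps, spec.threshold_T)
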