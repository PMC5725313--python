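"""Test–retest repeatability: intra-class correlation and top-k agreement.

The ICC flavour used throughout is the two-way mixed, consistency-type
coefficient (Shrout–Fleiss ICC(3,1)):

    ICC = (MS_subjects − MS_error) / (MS_subjects + (k − 1) · MS_error)

which by construction does not penalise systematic (additive) differences
between scanning sessions — a constant session offset leaves it unchanged.
An absolute-agreement variant (ICC(2,1)) is available behind a flag for
sensitivity analysis. Estimates can be negative when subject variance is
small relative to noise (minimal or null overlap of a component with the
activation maps typically produces this).

Voxel-wise ICC fields are summarised by their mode: positive values only,
80 equal bins on [0, 1], mode = centre of the argmax bin.

Score sets from a multi-session design are analysed at three collapsing
levels: per item (each IC × base-map × metric separately), per base map
(pooled across ICs), and globally (pooled across ICs and base maps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SessionScoreSet",
    "ICCEstimate",
    "icc_consistency",
    "icc_agreement",
    "voxelwise_icc_mode",
    "collapse_and_estimate",
    "topk_agreement",
]


@dataclass
class SessionScoreSet:
    """Tidy per-subject per-session scores plus the session design.

    ``scores`` columns: subject, session, ic, basemap, metric, value.
    ``within_pair`` names the same-day session pair (e.g. sessions 2 and 3
    scanned 45 min apart); ``between_pairs`` lists (baseline, later)
    session pairs whose rows are stacked for the between-session ICC.
    """

    scores: pd.DataFrame
    within_pair: tuple = (2, 3)
    between_pairs: list[tuple] = field(default_factory=lambda: [(1, 2), (1, 3)])

    REQUIRED = ("subject", "session", "ic", "basemap", "metric", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.scores.columns]
        if missing:
            raise ValueError(f"score table is missing columns {missing}")


@dataclass
class ICCEstimate:
    """One ICC with its provenance (collapsing level, session flavour)."""

    value: float  # NaN when undefined
    level: str  # per_item | per_basemap | global
    flavour: str  # within | between
    ic: object = None
    basemap: object = None
    metric: object = None
    n_rows: int = 0
    n_sessions: int = 0
    undefined_fraction: float = 0.0


def _anova_ms(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way mean squares for a subjects x sessions matrix (no NaN)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_err


def _clean(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D subjects x sessions matrix")
    x = x[~np.isnan(x).any(axis=1)]
    return x


def icc_consistency(x: np.ndarray) -> float:
    """Two-way consistency ICC(3,1) of a subjects x sessions matrix.

    Rows with any NaN are dropped. Returns NaN (undefined) when fewer
    than 2 complete rows remain or total variance is zero.
    """
    x = _clean(x)
    n, k = x.shape
    if n < 2 or k < 2:
        return np.nan
    ms_rows, _, ms_err = _anova_ms(x)
    denom = ms_rows + (k - 1) * ms_err
    if denom <= 0 or not np.isfinite(denom):
        return np.nan
    return float((ms_rows - ms_err) / denom)


def icc_agreement(x: np.ndarray) -> float:
    """Two-way random absolute-agreement ICC(2,1); sensitivity variant."""
    x = _clean(x)
    n, k = x.shape
    if n < 2 or k < 2:
        return np.nan
    ms_rows, ms_cols, ms_err = _anova_ms(x)
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    if denom <= 0 or not np.isfinite(denom):
        return np.nan
    return float((ms_rows - ms_err) / denom)


def voxelwise_icc_mode(
    maps: np.ndarray, flavour_fn=icc_consistency, n_bins: int = 80
) -> float:
    """Mode of the voxel-wise ICC field over positive values.

    Parameters
    ----------
    maps : ndarray, shape (subjects, sessions, *spatial)
        Co-registered per-subject per-session volumes.
    flavour_fn : callable
        ICC estimator applied per voxel.
    n_bins : int, default 80
        Equal-width histogram bins spanning [0, 1].

    Returns the centre of the most populated bin, or NaN when no voxel
    has a positive ICC. ICC values of exactly 1 fall in the last bin.
    """
    maps = np.asarray(maps, dtype=float)
    s, t = maps.shape[:2]
    flat = maps.reshape(s, t, -1)
    vals = np.array([flavour_fn(flat[:, :, v]) for v in range(flat.shape[2])])
    vals = vals[np.isfinite(vals) & (vals > 0)]
    if vals.size == 0:
        return np.nan
    hist, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    b = int(np.argmax(hist))  # ties -> lowest bin
    return float((edges[b] + edges[b + 1]) / 2.0)


def _session_matrix(
    df: pd.DataFrame, row_keys: list[str], flavour: str, ss: SessionScoreSet
) -> tuple[np.ndarray, float]:
    """Pivot tidy scores into a rows x 2-session matrix for one flavour.

    ``within`` pairs the same-day sessions as the two columns; ``between``
    stacks one block of rows per (baseline, later) pair. Each block's
    columns are demeaned before stacking ("mean-free" pairing), so a
    systematic session offset cannot masquerade as subject disagreement —
    the consistency ICC stays invariant to it even across stacked blocks.
    """
    pairs = [ss.within_pair] if flavour == "within" else ss.between_pairs
    blocks = []
    for a, b in pairs:
        wide = (
            df[df["session"].isin([a, b])]
            .pivot_table(index=row_keys, columns="session", values="value",
                         aggfunc="first")
            .reindex(columns=[a, b])
        )
        x = wide.to_numpy()
        if len(pairs) > 1 and x.size:
            x = x - np.nanmean(x, axis=0, keepdims=True)
        blocks.append(x)
    x = np.vstack(blocks) if blocks else np.empty((0, 2))
    n_total = x.shape[0]
    complete = ~np.isnan(x).any(axis=1)
    undef = 1.0 - (complete.sum() / n_total) if n_total else 1.0
    return x, undef


def collapse_and_estimate(
    ss: SessionScoreSet,
    level: str = "per_item",
    flavour: str = "within",
    estimator=icc_consistency,
) -> list[ICCEstimate]:
    """ICC estimates at one of three collapsing levels.

    ``per_item``: one estimate per (ic, basemap, metric) with subjects as
    rows. ``per_basemap``: one per (basemap, metric), pooling subject × IC
    pairs as rows. ``global``: one per metric, pooling subject × IC ×
    basemap. Cells undefined in the engagement tables (NaN values) are
    dropped pairwise with the dropped fraction reported.
    """
    if flavour not in {"within", "between"}:
        raise ValueError("flavour must be 'within' or 'between'")
    grouping = {
        "per_item": ["ic", "basemap", "metric"],
        "per_basemap": ["basemap", "metric"],
        "global": ["metric"],
    }
    if level not in grouping:
        raise ValueError(f"unknown level {level!r}")
    keys = grouping[level]
    row_keys = ["subject"] + [k for k in ["ic", "basemap"] if k not in keys]

    out: list[ICCEstimate] = []
    for group_vals, sub in ss.scores.groupby(keys, sort=True):
        if not isinstance(group_vals, tuple):
            group_vals = (group_vals,)
        info = dict(zip(keys, group_vals))
        x, undef = _session_matrix(sub, row_keys, flavour, ss)
        value = estimator(x) if x.size else np.nan
        out.append(
            ICCEstimate(
                value=value,
                level=level,
                flavour=flavour,
                ic=info.get("ic"),
                basemap=info.get("basemap"),
                metric=info.get("metric"),
                n_rows=int((~np.isnan(x).any(axis=1)).sum()) if x.size else 0,
                n_sessions=2,
                undefined_fraction=float(undef),
            )
        )
    return out


def estimates_to_frame(estimates: list[ICCEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in estimates])


def topk_agreement(
    values_a: pd.Series,
    values_b: pd.Series,
    k: int = 3,
    mapping: dict | None = None,
) -> int:
    """Number of base maps shared by the top-k sets of two score vectors.

    ``values_a``/``values_b`` are one metric's per-component values from
    two engagement tables (indexed by base-map name). ``mapping`` gives
    the correspondence from A's base maps to B's (identity when both come
    from the same atlas). Ties at rank k are broken deterministically by
    index position, lowest first.
    """
    a = pd.Series(values_a)
    b = pd.Series(values_b)
    if k > len(a) or k > len(b):
        raise ValueError(f"k={k} exceeds the number of components")
    if k < 1:
        raise ValueError("k must be >= 1")

    def top(s: pd.Series) -> set:
        order = np.lexsort((np.arange(len(s)), -np.nan_to_num(s.to_numpy(), nan=-np.inf)))
        return set(s.index[order[:k]])

    ta = top(a)
    tb = top(b)
    if mapping is not None:
        ta = {mapping[name] for name in ta}
    return len(ta & tb)
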