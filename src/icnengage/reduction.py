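"""Two-stage metric-set reduction by PCA + exploratory factor analysis.

The 11 per-component engagement metrics are highly redundant (five are
ratios of the same intersection count). To pick a parsimonious subset,
observations (input map × component pairs) are standardised and factored
twice: stage 1 runs principal-axis factoring with a varimax rotation on
all metrics and retains a short list combining the strongest loaders on
the two dominant factors with the highest-uniqueness metric; stage 2
repeats the analysis on the survivors and emits the final selection — the
top loader on each of the two factors plus the survivor with the highest
uniqueness.

:class:`MetricReducer` follows the scikit-learn estimator protocol (fit,
fitted ``_``-suffixed attributes, ``get_params``/``set_params``), so it
composes with sklearn tooling; :func:`reduce_metrics` is a thin
functional wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["MetricReducer", "ReductionReport", "reduce_metrics", "varimax",
           "principal_axis_factoring", "CollinearityError"]


class CollinearityError(ValueError):
    """Raised when the metric correlation matrix is singular."""


def varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Orthogonal varimax rotation (Kaiser, normalised) of a loading matrix."""
    L = np.asarray(loadings, dtype=float).copy()
    p, m = L.shape
    if m < 2:
        return L
    # Kaiser normalisation: rotate rows scaled to unit communality
    h = np.sqrt((L**2).sum(axis=1))
    h[h == 0] = 1.0
    L /= h[:, None]
    R = np.eye(m)
    var_old = 0.0
    for _ in range(max_iter):
        LR = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (LR**3 - LR @ np.diag((LR**2).sum(axis=0)) / p)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return (L @ R) * h[:, None]


def principal_axis_factoring(
    corr: np.ndarray, n_factors: int, tol: float = 1e-6, max_iter: int = 200
) -> np.ndarray:
    """Iterated principal-axis factor extraction from a correlation matrix.

    Communalities start at the squared multiple correlations and are
    iterated to convergence; returns the unrotated p x n_factors loading
    matrix.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise CollinearityError("correlation matrix is singular") from exc
    h2 = 1.0 - 1.0 / np.diag(inv)
    h2 = np.clip(h2, 0.0, 1.0)
    for _ in range(max_iter):
        reduced = corr.copy()
        reduced[np.diag_indices(p)] = h2
        eigval, eigvec = np.linalg.eigh(reduced)
        idx = np.argsort(eigval)[::-1][:n_factors]
        lam = np.clip(eigval[idx], 0.0, None)
        load = eigvec[:, idx] * np.sqrt(lam)
        h2_new = np.clip((load**2).sum(axis=1), 0.0, 1.0)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    return load


def _fit_efa(X: np.ndarray, columns: list[str], n_factors: int) -> pd.DataFrame:
    """Standardise, check collinearity, factor, rotate, and orient.

    Returns a loadings DataFrame (columns F1..Fm ordered by explained
    variance, descending) with a ``uniqueness`` column appended.
    """
    corr = np.corrcoef(X, rowvar=False)
    # name the offending pair rather than failing inside the inversion
    off = np.abs(corr - np.eye(len(columns)))
    ii, jj = np.unravel_index(np.argmax(off), off.shape)
    if off[ii, jj] > 1 - 1e-10 or np.linalg.cond(corr) > 1e10:
        raise CollinearityError(
            f"metric columns {columns[ii]!r} and {columns[jj]!r} are collinear; "
            "drop one before factoring"
        )
    load = principal_axis_factoring(corr, n_factors)
    load = varimax(load)
    # order factors by sum-of-squared loadings, descending
    ssl = (load**2).sum(axis=0)
    order = np.argsort(ssl)[::-1]
    load = load[:, order]
    # sign convention: each factor's largest-|loading| made positive
    for j in range(load.shape[1]):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
    df = pd.DataFrame(
        load, index=columns, columns=[f"F{j+1}" for j in range(load.shape[1])]
    )
    df["uniqueness"] = 1.0 - (load**2).sum(axis=1)
    return df


def _explained_variance(loadings: pd.DataFrame) -> np.ndarray:
    factor_cols = [c for c in loadings.columns if c.startswith("F")]
    ssl = (loadings[factor_cols].to_numpy() ** 2).sum(axis=0)
    return ssl / loadings.shape[0]


@dataclass
class ReductionReport:
    """Loadings, uniqueness and selections from both reduction stages."""

    stage1_loadings: pd.DataFrame
    stage1_retained: list[str]
    stage2_loadings: pd.DataFrame
    explained_variance: np.ndarray  # stage-2 per-factor shares of variance
    selection: list[str]
    rationale: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage1_retained": self.stage1_retained,
            "stage1_loadings": self.stage1_loadings.round(6).to_dict(),
            "stage2_loadings": self.stage2_loadings.round(6).to_dict(),
            "explained_variance": [float(v) for v in self.explained_variance],
            "selection": self.selection,
            "rationale": self.rationale,
        }


class MetricReducer(BaseEstimator):
    """Two-stage PCA + EFA (varimax) metric selector.

    Parameters
    ----------
    n_factors : int, default 2
        Latent factors extracted at each stage.
    n_keep_stage1 : int, default 5
        Metrics retained after stage 1 (strong loaders on the two
        dominant factors, plus the highest-uniqueness metric).
    n_final : int, default 3
        Final selection size: top loader per factor + highest-uniqueness
        survivor.

    Attributes
    ----------
    report_ : ReductionReport
    selection_ : list of str
        The ``n_final`` selected metric names.
    """

    def __init__(self, n_factors: int = 2, n_keep_stage1: int = 5, n_final: int = 3):
        self.n_factors = n_factors
        self.n_keep_stage1 = n_keep_stage1
        self.n_final = n_final

    def fit(self, X, y=None):
        """Fit on an observations x metrics matrix (DataFrame or array).

        Rows containing NaN (undefined metric cells) are dropped; the
        count is recorded in ``n_dropped_rows_``.
        """
        if isinstance(X, pd.DataFrame):
            columns = [str(c) for c in X.columns]
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            columns = [f"m{j}" for j in range(X.shape[1])]
        ok = ~np.isnan(X).any(axis=1)
        self.n_dropped_rows_ = int((~ok).sum())
        X = X[ok]
        if X.shape[0] <= X.shape[1]:
            raise ValueError("need more observations than metrics")
        sd = X.std(axis=0)
        if (sd == 0).any():
            bad = [columns[j] for j in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant metric column(s) after filtering: {bad}")
        Xs = (X - X.mean(axis=0)) / sd

        stage1 = _fit_efa(Xs, columns, self.n_factors)
        retained = self._retain(stage1, self.n_keep_stage1)

        keep_idx = [columns.index(c) for c in retained]
        stage2 = _fit_efa(Xs[:, keep_idx], retained, self.n_factors)
        selection, rationale = self._select_final(stage2)

        self.report_ = ReductionReport(
            stage1_loadings=stage1,
            stage1_retained=retained,
            stage2_loadings=stage2,
            explained_variance=_explained_variance(stage2),
            selection=selection,
            rationale=rationale,
        )
        self.selection_ = selection
        return self

    def _retain(self, loadings: pd.DataFrame, n_keep: int) -> list[str]:
        """Stage-1 shortlist: strongest factor loaders + top uniqueness."""
        factor_cols = [c for c in loadings.columns if c.startswith("F")][:2]
        retained: list[str] = []
        # top-uniqueness metric is always carried forward
        uniq_pick = loadings["uniqueness"].idxmax()
        # alternate between the two dominant factors, strongest |loading| first
        ranked = {
            c: list(loadings[c].abs().sort_values(ascending=False).index)
            for c in factor_cols
        }
        turn = 0
        while len(retained) < n_keep - 1:
            col = factor_cols[turn % len(factor_cols)]
            while ranked[col]:
                cand = ranked[col].pop(0)
                if cand not in retained and cand != uniq_pick:
                    retained.append(cand)
                    break
            turn += 1
            if all(not v for v in ranked.values()):
                break
        retained.append(uniq_pick)
        # preserve the input column order for reproducibility
        order = {name: i for i, name in enumerate(loadings.index)}
        return sorted(retained, key=order.get)

    def _select_final(self, loadings: pd.DataFrame):
        factor_cols = [c for c in loadings.columns if c.startswith("F")][:2]
        selection: list[str] = []
        rationale: dict[str, str] = {}
        for j, col in enumerate(factor_cols, start=1):
            ranked = loadings[col].abs().sort_values(ascending=False).index
            pick = next(m for m in ranked if m not in selection)
            selection.append(pick)
            rationale[pick] = f"high_loading_factor{j}"
        ranked_u = loadings["uniqueness"].sort_values(ascending=False).index
        for m in ranked_u:
            if m not in selection:
                selection.append(m)
                rationale[m] = "high_uniqueness"
                break
        return selection[: self.n_final], rationale


def reduce_metrics(
    metric_matrix: pd.DataFrame,
    n_factors_stage1: int = 2,
    n_keep_stage1: int = 5,
    n_final: int = 3,
) -> ReductionReport:
    """Functional wrapper over :class:`MetricReducer`."""
    reducer = MetricReducer(
        n_factors=n_factors_stage1, n_keep_stage1=n_keep_stage1, n_final=n_final
    )
    reducer.fit(metric_matrix)
    return reducer.report_
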