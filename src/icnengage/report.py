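"""Batch runs, run configuration, and report rendering.

A run is described by a :class:`RunConfig` (serialisable to one JSON
file); every batch writes its resolved config next to its outputs so the
run can be reproduced bit-identically. Numeric outputs (tidy long-format
CSV plus a wide pivot) never depend on the optional bar/polar plots.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import LabelAtlas, load_atlas
from .engagement import EngagementTable, engage
from .maps import load_stat_map

__all__ = ["RunConfig", "run_engage_batch", "bar_chart", "polar_plot"]

log = logging.getLogger("icnengage")


@dataclass
class RunConfig:
    """Resolved configuration of one engagement batch."""

    atlas_path: str
    input_paths: list[str]
    input_threshold: float | None = 3.0
    cluster_k: int = 0
    bounds_policy: str = "per_map"  # per_map | session_matched | fixed
    fixed_bounds: tuple[float, float] | None = None
    counting: str = "binary"
    stat_kind: str | None = None
    make_plots: bool = False
    out_dir: str = "."

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if data.get("fixed_bounds") is not None:
            data["fixed_bounds"] = tuple(data["fixed_bounds"])
        return cls(**data)


def _session_bounds(config: RunConfig) -> tuple[float, float]:
    """Shared min/max over every input map's values (session-matched)."""
    lo, hi = np.inf, -np.inf
    for p in config.input_paths:
        m = load_stat_map(p, config.stat_kind)
        vals = m.values[m.active_mask]
        if vals.size:
            lo = min(lo, float(vals.min()))
            hi = max(hi, float(vals.max()))
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("no active voxels in any input map")
    return lo, hi


def run_engage_batch(
    config: RunConfig, atlas: LabelAtlas | None = None
) -> list[EngagementTable]:
    """Run the engagement pipeline over every input map of a config.

    Writes, under ``config.out_dir``: one tidy CSV per map, a combined
    tidy CSV, a wide pivot for human reading, the resolved config, and
    (optionally) bar and polar plots. Returns the engagement tables.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if atlas is None:
        atlas = load_atlas(config.atlas_path)

    if config.bounds_policy == "fixed":
        if config.fixed_bounds is None:
            raise ValueError("bounds_policy 'fixed' requires fixed_bounds")
        bounds = tuple(config.fixed_bounds)
    elif config.bounds_policy == "session_matched":
        bounds = _session_bounds(config)
        log.info("session-matched bounds: %s", bounds)
    elif config.bounds_policy == "per_map":
        bounds = None
    else:
        raise ValueError(f"unknown bounds_policy {config.bounds_policy!r}")

    tables: list[EngagementTable] = []
    tidies = []
    for p in config.input_paths:
        try:
            table = engage(
                p,
                atlas,
                input_threshold=config.input_threshold,
                cluster_k=config.cluster_k,
                bounds=bounds,
                counting=config.counting,
                stat_kind_hint=config.stat_kind,
            )
        except Exception as exc:
            raise RuntimeError(f"engagement failed for input {p}: {exc}") from exc
        if bounds is not None:
            table.meta["bounds_policy"] = config.bounds_policy
        n_undef = int((~table.defined).to_numpy().sum())
        log.info(
            "%s: %d active voxels, %d undefined metric cells",
            p, table.meta["n_active"], n_undef,
        )
        stem = Path(p).name.split(".")[0]
        table.to_csv(out_dir / f"{stem}_engagement.csv")
        tidies.append(table.to_tidy())
        if config.make_plots:
            bar_chart(table, out_dir / f"{stem}_bar.png")
            polar_plot(table, out_dir / f"{stem}_polar.png")
        tables.append(table)

    combined = pd.concat(tidies, ignore_index=True)
    combined.to_csv(out_dir / "engagement_combined.csv", index=False,
                    float_format="%.12g")
    wide = combined[combined["basemap"] != "_global"].pivot_table(
        index=["map", "basemap"], columns="metric", values="value", sort=False
    )
    wide.to_csv(out_dir / "engagement_wide.csv", float_format="%.12g")
    config.to_json(out_dir / "run_config.json")
    return tables


def bar_chart(table: EngagementTable, path: str | Path,
              metrics: list[str] = ("I", "MA_N", "RA_N")) -> None:
    """Bar chart of selected metrics over base maps."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    metrics = [m for m in metrics if m in table.per_icn.columns]
    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3),
                             squeeze=False)
    for ax, m in zip(axes[0], metrics):
        vals = table.per_icn[m]
        ax.bar(range(len(vals)), vals.fillna(0.0).to_numpy())
        ax.set_xticks(range(len(vals)))
        ax.set_xticklabels(vals.index, rotation=90, fontsize=6)
        ax.set_title(m)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def polar_plot(table: EngagementTable, path: str | Path,
               metrics: list[str] = ("I", "MA_N", "RA_N")) -> None:
    """Polar (radar) plot of selected metrics over base maps."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    metrics = [m for m in metrics if m in table.per_icn.columns]
    n = len(table.per_icn)
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 4),
                             subplot_kw={"projection": "polar"}, squeeze=False)
    for ax, m in zip(axes[0], metrics):
        vals = table.per_icn[m].fillna(0.0).to_numpy()
        closed_t = np.concatenate([theta, theta[:1]])
        closed_v = np.concatenate([vals, vals[:1]])
        ax.plot(closed_t, closed_v)
        ax.fill(closed_t, closed_v, alpha=0.25)
        ax.set_xticks(theta)
        ax.set_xticklabels(table.per_icn.index, fontsize=6)
        ax.set_title(m)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
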