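"""Presentation layer: scatter, volcano and clustered heatmap figures.

Up-regulated outliers are drawn red, down-regulated green, everything else a
neutral grey — the classification always comes in from the detection results
and is never recomputed here. All functions write a figure file and return
its path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .core import DetectionParams
from .io import DOWN, UP, CombinedEntry, OutlierCall, ValidationError


@dataclass(frozen=True)
class PlotStyle:
    up_color: str = "red"
    down_color: str = "green"
    neutral_color: str = "0.6"
    guide_color: str = "0.3"

    def __post_init__(self) -> None:
        if len({self.up_color, self.down_color, self.neutral_color}) < 3:
            raise ValidationError("up/down/neutral colours must be distinct")


def _call_colors(
    probe_ids: Sequence[str], calls: Iterable[OutlierCall], style: PlotStyle
) -> list[str]:
    direction = {c.probe_id: c.direction for c in calls}
    return [
        style.up_color if direction.get(p) == UP
        else style.down_color if direction.get(p) == DOWN
        else style.neutral_color
        for p in probe_ids
    ]


def p_floor(p_values: np.ndarray) -> float:
    """Finite stand-in for p = 0 on a -log10 axis.

    Half the smallest positive p in the vector (1e-300 if none are positive),
    so zero-p probes stay plottable and above every finite point without
    distorting ranks.
    """
    pos = p_values[p_values > 0]
    return float(pos.min() / 2.0) if pos.size else 1e-300


def scatter_plot(
    sample_values: pd.Series,
    control_means: pd.Series,
    calls: Sequence[OutlierCall],
    path: str | Path,
    style: PlotStyle | None = None,
    sample_id: str = "",
) -> Path:
    """Sample expression vs control mean, outliers coloured by direction."""
    style = style or PlotStyle()
    if len(sample_values) != len(control_means):
        raise ValidationError("sample values and control means differ in length")
    colors = _call_colors(list(sample_values.index), calls, style)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(control_means, sample_values, s=6, c=colors, linewidths=0)
    lims = [
        min(control_means.min(), sample_values.min()),
        max(control_means.max(), sample_values.max()),
    ]
    ax.plot(lims, lims, color=style.guide_color, lw=0.8, zorder=0)
    ax.set_xlabel("control group mean (log2)")
    ax.set_ylabel(f"{sample_id or 'sample'} expression (log2)")
    ax.set_title(f"Expression scatter{': ' + sample_id if sample_id else ''}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def volcano_plot(
    fold_changes: pd.Series,
    p_values: pd.Series,
    params: DetectionParams,
    calls: Sequence[OutlierCall],
    path: str | Path,
    style: PlotStyle | None = None,
    sample_id: str = "",
) -> Path:
    """Fold-change vs -log10(p) with threshold guide lines.

    Only probes in ``calls`` are coloured: a probe beyond one guide line but
    not the other stays neutral because both gates are required for a call.
    """
    style = style or PlotStyle()
    if len(fold_changes) != len(p_values):
        raise ValidationError("fold-change and p-value vectors differ in length")
    p = p_values.to_numpy(dtype=float)
    floor = p_floor(p)
    logp = -np.log10(np.maximum(p, floor))
    colors = _call_colors(list(fold_changes.index), calls, style)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(fold_changes, logp, s=6, c=colors, linewidths=0)
    ax.axvline(params.fc_threshold, color=style.guide_color, lw=0.8, ls="--")
    ax.axvline(-params.fc_threshold, color=style.guide_color, lw=0.8, ls="--")
    ax.axhline(-np.log10(params.p_threshold), color=style.guide_color, lw=0.8, ls="--")
    ax.set_xlabel("log2 fold-change")
    ax.set_ylabel("-log10(p)")
    ax.set_title(f"Volcano{': ' + sample_id if sample_id else ''}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def outlier_heatmap(
    values: pd.DataFrame,
    path: str | Path,
    cluster_probes: bool = True,
    cluster_samples: bool = False,
) -> Path:
    """Clustered heatmap of outlier-probe expression.

    Hierarchical clustering uses Euclidean distance with complete linkage.
    The per-individual variant clusters probes only; the combined-cohort
    variant clusters both axes. With a single probe (or sample) on a
    clustered axis, clustering is skipped with a warning and a plain heatmap
    is drawn.
    """
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise ValidationError("heatmap needs at least one probe and one sample")
    row_cluster = cluster_probes
    col_cluster = cluster_samples
    if cluster_probes and values.shape[0] < 2:
        warnings.warn("fewer than 2 probes; probe clustering skipped")
        row_cluster = False
    if cluster_samples and values.shape[1] < 2:
        warnings.warn("fewer than 2 samples; sample clustering skipped")
        col_cluster = False
    if row_cluster or col_cluster:
        grid = sns.clustermap(
            values,
            method="complete",
            metric="euclidean",
            row_cluster=row_cluster,
            col_cluster=col_cluster,
            cmap="RdBu_r",
            center=0,
            figsize=(8, max(4, 0.22 * values.shape[0])),
        )
        grid.savefig(path)
        plt.close(grid.fig)
    else:
        fig, ax = plt.subplots(figsize=(8, max(3, 0.22 * values.shape[0])))
        sns.heatmap(values, cmap="RdBu_r", center=0, ax=ax)
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
    return Path(path)


def combined_heatmap_probes(summary: Sequence[CombinedEntry]) -> list[str]:
    """Probe set of a combined-cohort heatmap: every summarised probe once."""
    seen: dict[str, None] = {}
    for e in summary:
        seen.setdefault(e.probe_id, None)
    return list(seen)
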