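"""ROC/AUC benchmarking of outlier rankings against simulation truth.

Probes are ranked by how many tested individuals were called outliers for
them (separately per direction). Because that score is a small integer, ties
dominate: the ROC curve is therefore built by sweeping the threshold over
distinct score values so tie groups move as blocks, and the trapezoidal area
equals the Mann-Whitney probability with ties counted 1/2. External scorers
(e.g. a GTI implementation) can be benchmarked through the same interface by
supplying any probe -> score mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DetectionParams, call_outliers
from .io import DOWN, UP, CombinedEntry, ValidationError
from .simulate import (
    DEFAULT_SWEEP,
    SimulationConfig,
    simulate_dataset,
    sweep_configs,
)


@dataclass(frozen=True)
class ProbeRanking:
    """Scores over all probes of a matrix, ordered non-increasingly.

    ``scores`` is indexed by probe ID, sorted by decreasing score with the
    original probe order preserved inside tie groups (no arbitrary within-tie
    order is materialised: consumers must treat equal scores as one block).
    """

    scores: pd.Series
    direction: str | None = None


def rank_probes(
    summary: Sequence[CombinedEntry],
    all_probes: Sequence[str],
    direction: str,
) -> ProbeRanking:
    """Rank every probe by its outlier-sample count in one direction.

    Probes called in ``direction`` score their count; all other probes
    (including those called only in the opposite direction) score 0.
    """
    if direction not in (UP, DOWN):
        raise ValidationError(f"direction must be up/down, got {direction!r}")
    scores = pd.Series(0, index=pd.Index(all_probes, name="ProbeID"), dtype=int)
    for e in summary:
        if e.direction == direction:
            scores.loc[e.probe_id] = e.count
    scores = scores.sort_values(ascending=False, kind="mergesort")
    return ProbeRanking(scores=scores, direction=direction)


@dataclass(frozen=True)
class RocResult:
    """ROC points from (0,0) to (1,1) plus the trapezoidal area."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(ranking: ProbeRanking, positives: Iterable[str]) -> RocResult:
    """ROC curve and AUC of a probe ranking against a truth set.

    The threshold sweeps the distinct score values in decreasing order, so
    probes with equal scores enter the confusion matrix together; the
    trapezoidal area then equals the Mann-Whitney statistic
    P(score_pos > score_neg) + P(tie)/2.
    """
    pos = set(positives)
    index = ranking.scores.index
    unknown = pos - set(index)
    if unknown:
        raise ValidationError(f"positives not in ranking: {sorted(unknown)[:5]}")
    n_pos = len(pos)
    n_neg = len(index) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            "ROC needs a non-empty, non-exhaustive positive set "
            f"(got {n_pos} positives of {len(index)} probes)"
        )
    scores = ranking.scores.to_numpy()
    labels = index.isin(pos)

    fpr = [0.0]
    tpr = [0.0]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:  # scores already sorted descending; consume one tie block
        j = i
        while j < n and scores[j] == scores[i]:
            j += 1
        tp += int(labels[i:j].sum())
        fp += (j - i) - int(labels[i:j].sum())
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
        i = j
    fpr_arr = np.asarray(fpr)
    tpr_arr = np.asarray(tpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return RocResult(fpr=fpr_arr, tpr=tpr_arr, auc=auc)


def scores_from_mapping(
    score_by_probe: Mapping[str, float], all_probes: Sequence[str]
) -> ProbeRanking:
    """Adapt an external scorer (probe -> score) to the ranking interface.

    Probes absent from the mapping score 0. This is the plug-in point for
    third-party outlier scores such as GTI.
    """
    scores = pd.Series(
        [float(score_by_probe.get(p, 0.0)) for p in all_probes],
        index=pd.Index(all_probes, name="ProbeID"),
    )
    scores = scores.sort_values(ascending=False, kind="mergesort")
    return ProbeRanking(scores=scores)


def run_benchmark(
    configs: Sequence[SimulationConfig] | None = None,
    params: DetectionParams | None = None,
    seed: int = 0,
    sweep: tuple[int, ...] = DEFAULT_SWEEP,
    base_config: SimulationConfig | None = None,
    roc_out: dict | None = None,
) -> pd.DataFrame:
    """Simulate, detect, rank and score one dataset per outlier-count level.

    Detection defaults follow the published benchmark settings: raw p < 0.01
    and |log2 fc| > 0.5, each experimental sample tested against the control
    group. Returns a tidy table with one row per (dataset, direction) holding
    the AUC; pass ``roc_out`` (a dict) to also capture the ROC points keyed
    by (n_outlier_genes, direction).
    """
    if configs is None:
        configs = sweep_configs(base_config, sweep=sweep, seed=seed)
    params = params or DetectionParams(p_threshold=0.01, fc_threshold=0.5,
                                       correction="raw", mode="test_vs_control")
    rows = []
    for cfg in configs:
        matrix, design, truth = simulate_dataset(cfg)
        _, summary = call_outliers(matrix, design, params)
        for direction in (UP, DOWN):
            ranking = rank_probes(summary, matrix.probe_ids, direction)
            roc = roc_auc(ranking, truth.probes(direction))
            if roc_out is not None:
                roc_out[(cfg.n_outlier_genes, direction)] = roc
            rows.append({
                "n_outlier_genes": cfg.n_outlier_genes,
                "seed": cfg.seed,
                "direction": direction,
                "n_positives": len(truth.probes(direction)),
                "auc": roc.auc,
            })
    return pd.DataFrame(rows)


def summarize_benchmark(report: pd.DataFrame) -> pd.Series:
    """Mean AUC per direction across the datasets of a benchmark report."""
    return report.groupby("direction")["auc"].mean()
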