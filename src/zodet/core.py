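"""Per-sample z-score outlier statistics.

For each tested individual and each probe, the deviation of the sample's
log2 expression from a reference cohort is standardised,

    z = (E_sample - mu) / sigma,

where mu and sigma are the mean and sample standard deviation of the
reference (control) group for that probe. Two-sided p-values come from the
standard normal; a probe is called an outlier in that individual only when
the (optionally multiplicity-corrected) p-value falls below the p threshold
AND the absolute log2 fold-change |E_sample - mu| exceeds the fold-change
threshold. The sign of the fold-change sets the direction (up/down).

Five comparison modes choose which samples are tested and which serve as the
reference; whenever the tested sample belongs to the reference set it is
removed from the reference statistics (leave-one-out) so it cannot dilute
its own null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    DOWN,
    UP,
    CombinedEntry,
    ExpressionMatrix,
    OutlierCall,
    SampleDesign,
    ValidationError,
    combine_calls,
)

CORRECTIONS = ("raw", "bonferroni", "qvalue")

#: mode name -> (tested side, reference side); "all" = both groups
MODES = {
    "test_vs_control": (("experimental",), ("control",)),
    "test_vs_all": (("experimental",), ("control", "experimental")),
    "test_vs_test": (("experimental",), ("experimental",)),
    "control_vs_control": (("control",), ("control",)),
    "control_vs_all": (("control",), ("control", "experimental")),
}


@dataclass(frozen=True)
class ControlStats:
    """Per-probe mean/sd of the reference group (sample sd, ddof=1)."""

    mu: pd.Series
    sigma: pd.Series
    n_controls: int


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds and mode for an outlier-detection run.

    Defaults follow the method's published settings: p-value threshold 0.01,
    log2 fold-change threshold 1, uncorrected p-values, each experimental
    individual tested against the control group. Both threshold comparisons
    are strict (p < p_threshold, |fc| > fc_threshold).
    """

    p_threshold: float = 0.01
    fc_threshold: float = 1.0
    correction: str = "raw"
    mode: str = "test_vs_control"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValidationError(
                f"p-threshold must be in (0, 1], got {self.p_threshold}"
            )
        if self.fc_threshold < 0:
            raise ValidationError(
                f"fc-threshold must be >= 0, got {self.fc_threshold}"
            )
        if self.correction not in CORRECTIONS:
            raise ValidationError(
                f"unknown correction {self.correction!r}; "
                f"accepted: {', '.join(CORRECTIONS)}"
            )
        if self.mode not in MODES:
            raise ValidationError(
                f"unknown mode {self.mode!r}; accepted: {', '.join(MODES)}"
            )


def control_stats(
    matrix: ExpressionMatrix,
    control_ids: Sequence[str],
    exclude: str | None = None,
) -> ControlStats:
    """Per-probe mean and sample standard deviation of the reference group.

    ``exclude`` removes one sample from the reference iff it is a member
    (leave-one-out for self-referential modes); excluding a non-member is a
    no-op. At least two reference samples must remain.
    """
    ids = [s for s in control_ids if s != exclude]
    unknown = [s for s in ids if s not in matrix.values.columns]
    if unknown:
        raise ValidationError(f"reference samples not in matrix: {unknown}")
    if len(ids) < 2:
        raise ValidationError(
            f"need at least 2 reference samples, have {len(ids)}"
        )
    sub = matrix.values[ids]
    return ControlStats(
        mu=sub.mean(axis=1),
        sigma=sub.std(axis=1, ddof=1),
        n_controls=len(ids),
    )


def zscore(e_sample, mu, sigma):
    """Standardised deviation (E_sample - mu) / sigma, elementwise.

    Degenerate sigma = 0 yields z = 0 when the sample equals the reference
    mean and a signed infinity otherwise (p maps to 0), so constant probes
    never crash a run.
    """
    e = np.asarray(e_sample, dtype=float)
    m = np.asarray(mu, dtype=float)
    s = np.asarray(sigma, dtype=float)
    diff = e - m
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / s
    sentinel = np.where(diff == 0, 0.0, np.where(diff > 0, np.inf, -np.inf))
    z = np.where(s == 0, sentinel, z)
    if np.isscalar(e_sample) or z.ndim == 0:
        return float(z)
    return z


def z_to_p(z):
    """Two-sided standard-normal tail probability, p = 2 * (1 - Phi(|z|))."""
    p = 2.0 * stats.norm.sf(np.abs(np.asarray(z, dtype=float)))
    p = np.minimum(p, 1.0)
    if np.isscalar(z) or p.ndim == 0:
        return float(p)
    return p


def fold_change(e_sample, mu):
    """Log2 fold-change: difference of log2 expressions, E_sample - mu.

    Inputs are already log2, so a value of 1 is a 2-fold linear change.
    """
    fc = np.asarray(e_sample, dtype=float) - np.asarray(mu, dtype=float)
    if np.isscalar(e_sample) or fc.ndim == 0:
        return float(fc)
    return fc


def _storey_pi0(p: np.ndarray) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the grid
    lambda = 0.05, 0.10, ..., 0.95, smoothed with a cubic fit and read off at
    the largest lambda. A degenerate fit (non-finite or <= 0) falls back to
    pi0 = 1, which reduces the q-values to Benjamini-Hochberg.
    """
    m = p.size
    lam = np.arange(0.05, 0.951, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    try:
        coeffs = np.polyfit(lam, pi0_lam, 3)
        pi0 = float(np.polyval(coeffs, lam.max()))
    except Exception:
        pi0 = 1.0
    if not np.isfinite(pi0) or pi0 <= 0:
        pi0 = 1.0
    return min(pi0, 1.0)


def storey_qvalues(p_values) -> np.ndarray:
    """Storey q-values for a vector of p-values (monotone in sorted order)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    pi0 = _storey_pi0(p)
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def adjust_p(p_values, method: str, m: int | None = None) -> np.ndarray:
    """Multiple-testing adjustment across the probes of one tested sample.

    ``raw`` is the identity, ``bonferroni`` is min(1, p*m) with m the number
    of probes, ``qvalue`` is Storey's FDR-based q-value.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if method == "raw":
        return p.copy()
    if method == "bonferroni":
        m = p.size if m is None else m
        return np.minimum(1.0, p * m)
    if method == "qvalue":
        return storey_qvalues(p)
    raise ValidationError(
        f"unknown correction {method!r}; accepted: {', '.join(CORRECTIONS)}"
    )


def _mode_sides(design: SampleDesign, mode: str) -> tuple[list[str], list[str]]:
    if mode not in MODES:
        raise ValidationError(
            f"unknown mode {mode!r}; accepted: {', '.join(MODES)}"
        )
    test_side, ref_side = MODES[mode]
    groups = {"control": design.control_ids, "experimental": design.experimental_ids}
    tested = [s for g in test_side for s in groups[g]]
    reference = [s for g in ref_side for s in groups[g]]
    return tested, reference


def call_outliers(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    params: DetectionParams | None = None,
    target: str | None = None,
) -> tuple[list[OutlierCall], list[CombinedEntry]]:
    """Call per-individual outlier probes under the dual threshold.

    Each sample on the mode's test side (or the single ``target``) is scored
    against the mode's reference group; the tested sample is left out of the
    reference statistics whenever it is a member. A probe is called iff the
    adjusted p-value is below ``p_threshold`` and the absolute log2
    fold-change exceeds ``fc_threshold``; the fold-change sign gives the
    direction. Returns the individual calls plus the combined summary.
    """
    params = params or DetectionParams()
    design.validate_against(matrix)
    tested, reference = _mode_sides(design, params.mode)
    if target is not None:
        if target not in tested:
            raise ValidationError(
                f"sample {target!r} is not on the test side of mode {params.mode!r}"
            )
        tested = [target]
    if not tested:
        raise ValidationError(f"mode {params.mode!r} has no samples to test")

    ref_set = set(reference)
    probe_ids = matrix.probe_ids
    calls: list[OutlierCall] = []
    shared_stats: ControlStats | None = None

    for sid in tested:
        if sid in ref_set:
            st = control_stats(matrix, reference, exclude=sid)
        else:
            if shared_stats is None:
                shared_stats = control_stats(matrix, reference)
            st = shared_stats
        e = matrix.values[sid].to_numpy()
        mu = st.mu.to_numpy()
        sigma = st.sigma.to_numpy()
        z = zscore(e, mu, sigma)
        p_raw = z_to_p(z)
        p_adj = adjust_p(p_raw, params.correction)
        fc = fold_change(e, mu)
        hit = (p_adj < params.p_threshold) & (np.abs(fc) > params.fc_threshold)
        for i in np.flatnonzero(hit):
            calls.append(OutlierCall(
                probe_id=probe_ids[i],
                sample_id=sid,
                z=float(z[i]),
                p_raw=float(p_raw[i]),
                p_adj=float(p_adj[i]),
                fold_change=float(fc[i]),
                direction=UP if fc[i] > 0 else DOWN,
                sigma_zero=bool(sigma[i] == 0),
            ))
    return calls, combine_calls(calls)


def normality_screen(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Lilliefors normality screen across all samples, probe by probe.

    Each probe's values over all samples are tested with the Lilliefors
    variant of the Kolmogorov-Smirnov test (mean and sd estimated from the
    data); a probe is flagged non-normal iff its corrected p-value is below
    ``alpha``. Constant probes are degenerate distributions: flagged
    non-normal with p reported as 0. Requires at least 4 samples.

    Returns a DataFrame indexed by probe with columns ``statistic``,
    ``p_value``, ``p_adjusted`` and boolean ``normal``.
    """
    from statsmodels.stats.diagnostic import lilliefors

    if not (0.0 < alpha <= 1.0):
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    n = matrix.shape[1]
    if n < 4:
        raise ValidationError(
            f"normality screen needs at least 4 samples, have {n}"
        )
    stat = np.empty(matrix.shape[0])
    pval = np.empty(matrix.shape[0])
    vals = matrix.values.to_numpy()
    for i in range(matrix.shape[0]):
        row = vals[i]
        if np.ptp(row) == 0.0:
            stat[i] = np.inf
            pval[i] = 0.0
        else:
            s, p = lilliefors(row, dist="norm", pvalmethod="approx")
            stat[i] = s
            pval[i] = min(max(float(p), 0.0), 1.0)
    padj = adjust_p(pval, correction)
    return pd.DataFrame(
        {
            "statistic": stat,
            "p_value": pval,
            "p_adjusted": padj,
            "normal": ~(padj < alpha),
        },
        index=pd.Index(matrix.probe_ids, name="ProbeID"),
    )
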