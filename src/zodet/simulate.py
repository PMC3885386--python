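"""Spiked-outlier expression simulation.

Generates the benchmark datasets used to validate the detector: a probes ×
samples grid of i.i.d. standard-normal "log2 expression" values split into a
control and an experimental group, with a chosen number of probes spiked per
direction. Each spiked probe gets 5-10 affected experimental samples whose
values are replaced by quantiles of the standard normal chosen so that their
two-sided tail probability against the true N(0,1) null lies between 0.05
and 1e-6 — i.e. the injected value *is* the population z-score of the
outlier. The ground truth (which probes, which samples, which direction, at
what target p) is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    DOWN,
    UP,
    CONTROL,
    EXPERIMENTAL,
    ExpressionMatrix,
    SampleDesign,
    ValidationError,
)

#: the published sweep of spiked-gene counts per direction
DEFAULT_SWEEP = (20, 50, 100, 250, 500, 1000)

P_SAMPLERS = ("log-uniform", "uniform")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults are the published simulation: 20,000 probes, 100 samples split
    50 control / 50 experimental, ``n_outlier_genes`` probes spiked per
    direction with 5-10 affected experimental samples each, and spike
    magnitudes mapped from target tail p-values in [1e-6, 0.05]. Target
    p-values are drawn log-uniformly by default so effect sizes cover the
    4.7 decades of the range evenly (``p_sampler="uniform"`` is available).
    """

    n_genes: int = 20_000
    n_controls: int = 50
    n_experimental: int = 50
    n_outlier_genes: int = 100
    samples_per_gene: tuple[int, int] = (5, 10)
    p_range: tuple[float, float] = (1e-6, 0.05)
    p_sampler: str = "log-uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if self.n_controls < 2 or self.n_experimental < 2:
            raise ValidationError("both groups need at least 2 samples")
        if self.n_outlier_genes < 0:
            raise ValidationError("n_outlier_genes must be >= 0")
        if 2 * self.n_outlier_genes > self.n_genes:
            raise ValidationError(
                "2 * n_outlier_genes exceeds n_genes "
                f"({2 * self.n_outlier_genes} > {self.n_genes})"
            )
        lo, hi = self.samples_per_gene
        if not (1 <= lo <= hi <= self.n_experimental):
            raise ValidationError(
                f"samples_per_gene range {self.samples_per_gene} invalid for "
                f"{self.n_experimental} experimental samples"
            )
        plo, phi = self.p_range
        if not (0.0 < plo <= phi <= 1.0):
            raise ValidationError(f"p_range {self.p_range} must satisfy 0 < lo <= hi <= 1")
        if self.p_sampler not in P_SAMPLERS:
            raise ValidationError(
                f"unknown p_sampler {self.p_sampler!r}; accepted: {', '.join(P_SAMPLERS)}"
            )


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a simulated dataset: one row per spiked cell.

    ``table`` has columns probe_id, direction, sample_id, p_target,
    injected_value.
    """

    table: pd.DataFrame

    @property
    def up_probes(self) -> set[str]:
        t = self.table
        return set(t.loc[t["direction"] == UP, "probe_id"])

    @property
    def down_probes(self) -> set[str]:
        t = self.table
        return set(t.loc[t["direction"] == DOWN, "probe_id"])

    def probes(self, direction: str) -> set[str]:
        return self.up_probes if direction == UP else self.down_probes

    def spiked_cells(self) -> set[tuple[str, str]]:
        return set(zip(self.table["probe_id"], self.table["sample_id"]))


def injected_magnitude(p_target, p_range: tuple[float, float] = (1e-6, 0.05)):
    """Spike magnitude |z*| for a target two-sided tail probability.

    |z*| = Phi^-1(1 - p/2): the absolute value a standard-normal observation
    must take for its two-sided tail probability to equal ``p_target``.
    Monotone decreasing in p. Targets outside ``p_range`` are rejected.
    """
    p = np.asarray(p_target, dtype=float)
    lo, hi = p_range
    if np.any((p < lo) | (p > hi)):
        raise ValidationError(
            f"target p outside the allowed range [{lo:g}, {hi:g}]"
        )
    mag = stats.norm.isf(p / 2.0)
    if np.isscalar(p_target) or mag.ndim == 0:
        return float(mag)
    return mag


def _draw_p_targets(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    lo, hi = cfg.p_range
    if cfg.p_sampler == "uniform":
        return rng.uniform(lo, hi, size=n)
    return 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)


def simulate_dataset(
    config: SimulationConfig | None = None,
) -> tuple[ExpressionMatrix, SampleDesign, SimulationTruth]:
    """Generate one simulated dataset with known spiked outliers.

    A single seeded generator drives, in fixed order: the background grid,
    the spiked-probe selection (up first, then down, disjoint), then per
    spiked probe the affected-sample count, the affected samples and the
    target p-values. Spiked values replace the background draw. Bit-identical
    output for identical configs.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    n_samples = cfg.n_controls + cfg.n_experimental
    width = max(2, len(str(cfg.n_genes)))
    probe_ids = [f"g{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]
    ctl_ids = [f"ctl{i:02d}" for i in range(1, cfg.n_controls + 1)]
    exp_ids = [f"exp{i:02d}" for i in range(1, cfg.n_experimental + 1)]

    values = rng.standard_normal((cfg.n_genes, n_samples))

    k = cfg.n_outlier_genes
    spiked = rng.choice(cfg.n_genes, size=2 * k, replace=False)
    directions = {UP: spiked[:k], DOWN: spiked[k:]}

    lo, hi = cfg.samples_per_gene
    exp_offset = cfg.n_controls
    rows = []
    for direction in (UP, DOWN):
        sign = 1.0 if direction == UP else -1.0
        for gi in directions[direction]:
            n_aff = int(rng.integers(lo, hi + 1))
            cols = rng.choice(cfg.n_experimental, size=n_aff, replace=False)
            p_t = _draw_p_targets(rng, n_aff, cfg)
            mags = injected_magnitude(p_t, cfg.p_range)
            for c, p, m in zip(cols, p_t, np.atleast_1d(mags)):
                values[gi, exp_offset + c] = sign * m
                rows.append((probe_ids[gi], direction, exp_ids[c], p, sign * m))

    matrix = ExpressionMatrix(pd.DataFrame(
        values,
        index=pd.Index(probe_ids, name="ProbeID"),
        columns=ctl_ids + exp_ids,
    ))
    design = SampleDesign(
        {**{s: CONTROL for s in ctl_ids}, **{s: EXPERIMENTAL for s in exp_ids}}
    )
    truth = SimulationTruth(pd.DataFrame(
        rows,
        columns=["probe_id", "direction", "sample_id", "p_target", "injected_value"],
    ))
    return matrix, design, truth


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> SimulationTruth:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "sample_id": str})
    return SimulationTruth(df)


def sweep_configs(
    base: SimulationConfig | None = None,
    sweep: tuple[int, ...] = DEFAULT_SWEEP,
    seed: int | None = None,
) -> list[SimulationConfig]:
    """One config per outlier-count level, with independent derived seeds."""
    base = base or SimulationConfig()
    root = base.seed if seed is None else seed
    child = np.random.default_rng(root).integers(2**31, size=len(sweep))
    return [
        replace(base, n_outlier_genes=k, seed=int(s))
        for k, s in zip(sweep, child)
    ]
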