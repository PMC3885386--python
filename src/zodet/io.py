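"""Core data containers and tab-delimited file I/O.

Expression data are probes × samples grids of normalised log2 intensities.
All files are plain TSV (UTF-8): an expression file with a ``ProbeID`` first
column and one column per sample; a two-column design file assigning each
sample to the ``control`` or ``experimental`` group; an optional annotation
table mapping probes to gene symbols.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
EXPERIMENTAL = "experimental"
GROUP_LABELS = (CONTROL, EXPERIMENTAL)

UP = "up"
DOWN = "down"

#: fixed numeric formats for result tables — reproducible diffs
P_FMT = "{:.3e}"      # 4 significant digits, scientific
NUM_FMT = "{:.4f}"    # z and fold-change


class ZodetError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ZodetError):
    """Invalid data, parameters or file contents."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probes × samples grid of normalised log2 expression values.

    ``values`` is a float DataFrame indexed by probe ID with sample IDs as
    columns. Probe and sample identifiers must be unique and every cell must
    be a finite number; missing values are rejected at construction.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise ValidationError("expression matrix must be non-empty")
        _check_unique(list(v.index.astype(str)), "probe ID")
        _check_unique(list(v.columns.astype(str)), "sample ID")
        if not np.isfinite(v.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(v.to_numpy()))[0]
            raise ValidationError(
                "non-finite expression value at probe "
                f"{v.index[bad[0]]!r}, sample {v.columns[bad[1]]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class SampleDesign:
    """Assignment of each sample to the control or experimental group."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        for sid, grp in self.assignments.items():
            if grp not in GROUP_LABELS:
                raise ValidationError(
                    f"unknown group {grp!r} for sample {sid!r}; "
                    f"accepted labels: {', '.join(GROUP_LABELS)}"
                )
        if len(self.control_ids) < 2:
            raise ValidationError(
                "at least 2 control samples are required "
                "(standard deviation must be estimable)"
            )

    @property
    def control_ids(self) -> list[str]:
        return [s for s, g in self.assignments.items() if g == CONTROL]

    @property
    def experimental_ids(self) -> list[str]:
        return [s for s, g in self.assignments.items() if g == EXPERIMENTAL]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Require an exact one-to-one match of sample IDs with the matrix."""
        mat = set(matrix.sample_ids)
        des = set(self.assignments)
        missing = sorted(des - mat)
        if missing:
            raise ValidationError(
                f"samples in design but not in expression matrix: {missing}"
            )
        uncovered = sorted(mat - des)
        if uncovered:
            raise ValidationError(
                f"samples in expression matrix but not in design: {uncovered}"
            )


@dataclass(frozen=True)
class Annotation:
    """Optional probe → (gene symbol, description) lookup."""

    table: dict[str, tuple[str, str]] = field(default_factory=dict)

    def symbol(self, probe_id: str) -> str:
        return self.table.get(probe_id, ("", ""))[0]

    def description(self, probe_id: str) -> str:
        return self.table.get(probe_id, ("", ""))[1]


@dataclass(frozen=True)
class OutlierCall:
    """One (probe, tested sample) outlier event.

    ``z`` is the standardised deviation from the reference-group mean,
    ``fold_change`` the difference of log2 expressions (sample − reference
    mean). ``sigma_zero`` flags calls made on probes whose reference standard
    deviation was exactly zero (z reported as ±inf, p as 0).
    """

    probe_id: str
    sample_id: str
    z: float
    p_raw: float
    p_adj: float
    fold_change: float
    direction: str
    sigma_zero: bool = False

    def __post_init__(self) -> None:
        if self.direction not in (UP, DOWN):
            raise ValidationError(f"direction must be up/down, got {self.direction!r}")


@dataclass(frozen=True)
class CombinedEntry:
    """Per-probe, per-direction aggregation across tested samples."""

    probe_id: str
    direction: str
    samples: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.samples)


def combine_calls(calls: Iterable[OutlierCall]) -> list[CombinedEntry]:
    """Aggregate calls into the combined summary (Table-1 style).

    Rows are keyed by (probe, direction); ordering is up before down, then
    decreasing count, then probe ID — so the most recurrent outliers lead.
    """
    groups: dict[tuple[str, str], list[str]] = defaultdict(list)
    for c in calls:
        groups[(c.probe_id, c.direction)].append(c.sample_id)
    entries = [
        CombinedEntry(probe_id=p, direction=d, samples=tuple(s))
        for (p, d), s in groups.items()
    ]
    entries.sort(key=lambda e: (e.direction != UP, -e.count, e.probe_id))
    return entries


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression file (first column probe IDs, header sample IDs)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    _check_unique(list(raw.index), f"probe ID in {path.name}")
    _check_unique(list(raw.columns), f"sample ID in {path.name}")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cells = raw[col]
        try:
            # float() is correctly rounded, so written values read back bit-exact
            parsed = np.array([float(x) for x in cells], dtype=float)
        except (TypeError, ValueError):
            parsed = np.full(len(cells), np.nan)
            for i, x in enumerate(cells):
                try:
                    parsed[i] = float(x)
                except (TypeError, ValueError):
                    pass
        bad = cells.index[~np.isfinite(parsed)]
        if len(bad):
            raise ValidationError(
                f"non-numeric or missing value in {path.name} at probe "
                f"{bad[0]!r}, sample {col!r}"
            )
        values[col] = parsed
    return ExpressionMatrix(values)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a TSV expression file; floats use a bit-exact %.17g format."""
    out = matrix.values.copy()
    out.index.name = "ProbeID"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_design(path: str | Path) -> SampleDesign:
    """Read a two-column TSV design file (SampleID, Group).

    Group labels are matched case-insensitively against ``control`` /
    ``experimental``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path.name}: expected two columns SampleID, Group")
    assignments: dict[str, str] = {}
    for _, row in df.iterrows():
        sid = str(row.iloc[0]).strip()
        grp = str(row.iloc[1]).strip().lower()
        if grp not in GROUP_LABELS:
            raise ValidationError(
                f"{path.name}: unknown group {row.iloc[1]!r} for sample {sid!r}; "
                f"accepted labels: {', '.join(GROUP_LABELS)}"
            )
        if sid in assignments:
            raise ValidationError(f"{path.name}: duplicate sample ID {sid!r}")
        assignments[sid] = grp
    return SampleDesign(assignments)


def write_design(design: SampleDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("SampleID\tGroup\n")
        for sid, grp in design.assignments.items():
            fh.write(f"{sid}\t{grp}\n")


def read_annotation(path: str | Path) -> Annotation:
    """Read a TSV annotation table (ProbeID, Symbol, optional Description)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.shape[1] < 2:
        raise ValidationError(f"{path.name}: expected columns ProbeID, Symbol")
    table: dict[str, tuple[str, str]] = {}
    for _, row in df.iterrows():
        pid = str(row.iloc[0]).strip()
        if pid in table:
            raise ValidationError(f"{path.name}: duplicate probe ID {pid!r}")
        desc = str(row.iloc[2]).strip() if df.shape[1] > 2 else ""
        table[pid] = (str(row.iloc[1]).strip(), desc)
    return Annotation(table)


_CALL_COLUMNS = [
    "ProbeID", "Symbol", "Description", "Expression", "Z",
    "PRaw", "PAdj", "FoldChange", "Direction", "SigmaZero",
]
_SUMMARY_COLUMNS = ["ProbeID", "Symbol", "Direction", "Count", "Samples"]


def write_results(
    calls: Sequence[OutlierCall],
    summary: Sequence[CombinedEntry],
    annotation: Annotation | None,
    out_dir: str | Path,
    matrix: ExpressionMatrix | None = None,
    tested_samples: Sequence[str] | None = None,
) -> list[Path]:
    """Write one per-sample gene-list table plus the combined summary table.

    Per-sample tables are named ``outliers_<sample>.tsv``; the cohort-level
    table is ``combined_summary.tsv``. Probes without an annotation entry get
    an empty gene symbol. ``tested_samples`` forces a (possibly header-only)
    table for every tested sample, called or not. Returns the paths written
    (combined table last).
    """
    ann = annotation or Annotation()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    per_sample: dict[str, list[OutlierCall]] = defaultdict(list)
    for sid in tested_samples or ():
        per_sample[sid] = []
    for c in calls:
        per_sample[c.sample_id].append(c)

    written: list[Path] = []
    for sid in sorted(per_sample):
        path = out_dir / f"outliers_{sid}.tsv"
        with open(path, "w") as fh:
            fh.write("\t".join(_CALL_COLUMNS) + "\n")
            for c in per_sample[sid]:
                expr = ""
                if matrix is not None:
                    expr = NUM_FMT.format(matrix.values.at[c.probe_id, sid])
                fh.write("\t".join([
                    c.probe_id,
                    ann.symbol(c.probe_id),
                    ann.description(c.probe_id),
                    expr,
                    NUM_FMT.format(c.z),
                    P_FMT.format(c.p_raw),
                    P_FMT.format(c.p_adj),
                    NUM_FMT.format(c.fold_change),
                    c.direction,
                    str(int(c.sigma_zero)),
                ]) + "\n")
        written.append(path)

    combined = out_dir / "combined_summary.tsv"
    with open(combined, "w") as fh:
        fh.write("\t".join(_SUMMARY_COLUMNS) + "\n")
        for e in summary:
            fh.write("\t".join([
                e.probe_id,
                ann.symbol(e.probe_id),
                e.direction,
                str(e.count),
                ",".join(e.samples),
            ]) + "\n")
    written.append(combined)
    return written
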