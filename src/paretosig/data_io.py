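"""Reading and writing expression matrices, phenotype tables and pipeline outputs.

All tabular I/O is plain TSV: expression matrices are genes x samples with a
header row of sample IDs and gene IDs in the first column (the layout Xena-style
matrices use); phenotype tables are two columns (sample_id, label). Recognized
missing-value tokens are "NA", "NaN" and the empty string, case-insensitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ValueScale = Literal["counts", "logcpm", "zscore", "other"]

_NA_TOKENS = {"na", "nan", ""}

#: decimal places written by :func:`write_expression`; round-trips are exact
#: to this precision.
FLOAT_PRECISION = 10


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric matrix with unique identifiers on both axes.

    ``values`` is a float array of shape (G, S); missing entries are NaN.
    ``value_scale`` records what the numbers mean: raw ``counts`` (>= 0),
    ``logcpm`` (log2 counts-per-million), gene-wise ``zscore``, or ``other``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_scale: ValueScale = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g, s = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (g, s):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{g} genes x {s} samples"
            )
        if g < 1 or s < 2:
            raise ValueError("need at least 1 gene and 2 samples")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} ID: {dup!r}")
        if self.value_scale == "counts":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and finite.min() < 0:
                raise ValueError("value_scale='counts' requires all entries >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Row subset in the given order; unknown genes are an error."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            idx = [pos[g] for g in genes]
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"gene {e.args[0]!r} not in matrix") from None
        return ExpressionMatrix(
            list(genes), list(self.sample_ids), self.values[idx], self.value_scale
        )

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in samples]
        return ExpressionMatrix(
            list(self.gene_ids), list(samples), self.values[:, idx], self.value_scale
        )


@dataclass
class GroupLabels:
    """Sample -> {control, case} assignment for a two-group contrast.

    ``positive_group`` names the group treated as positive/diseased when
    computing classification metrics (default: case).
    """

    mapping: dict[str, str]
    positive_group: str = "case"

    def __post_init__(self) -> None:
        bad = {g for g in self.mapping.values() if g not in ("control", "case")}
        if bad:
            raise ValueError(f"group labels must be 'control'/'case', got {sorted(bad)}")
        if self.positive_group not in ("control", "case"):
            raise ValueError("positive_group must be 'control' or 'case'")

    @property
    def control_samples(self) -> list[str]:
        return [s for s, g in self.mapping.items() if g == "control"]

    @property
    def case_samples(self) -> list[str]:
        return [s for s, g in self.mapping.items() if g == "case"]

    def require_both_groups(self) -> None:
        if not self.control_samples or not self.case_samples:
            raise ValueError("both control and case groups must be non-empty")

    def labels_for(self, sample_ids: list[str]) -> np.ndarray:
        """0/1 array (control=0, case=1) aligned to ``sample_ids``."""
        return np.array(
            [1 if self.mapping[s] == "case" else 0 for s in sample_ids], dtype=int
        )


def _first_duplicate(ids) -> str | None:
    seen = set()
    for i in ids:
        if i in seen:
            return i
        seen.add(i)
    return None


def read_expression(path: str | Path, value_scale: ValueScale = "counts") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene IDs, header sample IDs).

    NA tokens become NaN. Duplicated gene or sample IDs and non-numeric cells
    are hard errors naming the offender.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, na_values=[]
    )
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    for name, ids in (("gene", gene_ids), ("sample", sample_ids)):
        dup = _first_duplicate(ids)
        if dup is not None:
            raise ValueError(f"{path}: duplicate {name} ID: {dup!r}")
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            if cell.lower() in _NA_TOKENS:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at gene "
                        f"{gene_ids[i]!r}, sample {sample_ids[j]!r}"
                    ) from None
    mat = ExpressionMatrix(gene_ids, sample_ids, values, value_scale)
    logger.info("read %d genes x %d samples from %s", mat.n_genes, mat.n_samples, path)
    return mat


def write_expression(X: ExpressionMatrix, path: str | Path) -> None:
    df = X.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=f"%.{FLOAT_PRECISION}g", na_rep="NA")


def read_groups(
    path: str | Path,
    control_label: str,
    case_label: str,
    positive_group: str = "case",
) -> GroupLabels:
    """Read a two-column TSV (sample_id, label) into a two-group assignment.

    Rows whose label matches neither ``control_label`` nor ``case_label`` are a
    hard error listing the offending rows, as is an empty group.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, label)")
    sample_col, label_col = df.columns[0], df.columns[1]
    dup = _first_duplicate(df[sample_col].tolist())
    if dup is not None:
        raise ValueError(f"{path}: duplicate sample ID: {dup!r}")
    mapping: dict[str, str] = {}
    bad_rows = []
    for row_num, (sid, lab) in enumerate(zip(df[sample_col], df[label_col]), start=2):
        if lab == control_label:
            mapping[sid] = "control"
        elif lab == case_label:
            mapping[sid] = "case"
        else:
            bad_rows.append(f"line {row_num}: {sid!r} -> {lab!r}")
    if bad_rows:
        raise ValueError(
            f"{path}: labels matching neither {control_label!r} nor "
            f"{case_label!r}:\n  " + "\n  ".join(bad_rows)
        )
    groups = GroupLabels(mapping, positive_group=positive_group)
    n_ctrl, n_case = len(groups.control_samples), len(groups.case_samples)
    if n_ctrl == 0:
        raise ValueError(f"{path}: no samples labelled {control_label!r} (control)")
    if n_case == 0:
        raise ValueError(f"{path}: no samples labelled {case_label!r} (case)")
    logger.info("read groups from %s: %d control, %d case", path, n_ctrl, n_case)
    return groups


def write_groups(
    groups: GroupLabels, path: str | Path, control_label: str = "control",
    case_label: str = "case",
) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, g in groups.mapping.items():
            fh.write(f"{sid}\t{control_label if g == 'control' else case_label}\n")


def align_samples(X: ExpressionMatrix, groups: GroupLabels) -> tuple[ExpressionMatrix, GroupLabels]:
    """Intersect matrix samples with phenotype samples by ID.

    Gene order is never touched; samples absent from either side are dropped
    with a logged count. Matrix column order is preserved for the survivors.
    """
    keep = [s for s in X.sample_ids if s in groups.mapping]
    n_dropped_x = X.n_samples - len(keep)
    n_dropped_g = len(groups.mapping) - len(keep)
    if n_dropped_x or n_dropped_g:
        logger.info(
            "sample alignment dropped %d matrix columns and %d phenotype rows",
            n_dropped_x, n_dropped_g,
        )
    if len(keep) < 2:
        raise ValueError("fewer than 2 samples shared between matrix and phenotype table")
    sub = X.subset_samples(keep)
    gl = GroupLabels({s: groups.mapping[s] for s in keep}, groups.positive_group)
    return sub, gl
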