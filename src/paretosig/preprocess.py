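"""Gene pre-filtering, gene-wise standardization, log-CPM and voom-style weights.

The differential-expression stage consumes log2 counts-per-million (optionally
with voom-style precision weights); the clustering stages downstream consume the
gene-wise standardized (z-score) matrix.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data_io import ExpressionMatrix, GroupLabels

logger = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """Gene counts before/after each pre-filtering step."""

    n_input_genes: int = 0
    n_dropped_all_zero: int = 0
    n_dropped_na: int = 0
    n_dropped_constant: int = 0
    n_output_genes: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        dropped = self.n_dropped_all_zero + self.n_dropped_na + self.n_dropped_constant
        if self.n_output_genes != self.n_input_genes - dropped:
            raise ValueError("inconsistent PreprocessReport counts")


def prefilter(
    X: ExpressionMatrix,
    drop_na_policy: Literal["drop_gene", "impute_zero"] = "drop_gene",
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Remove all-zero genes and handle genes with missing values.

    Missing values are handled per ``drop_na_policy``: ``drop_gene`` removes
    any gene with a missing entry; ``impute_zero`` replaces missing entries
    with 0 (the gene is then still subject to the all-zero filter).
    """
    report = PreprocessReport(n_input_genes=X.n_genes)
    values = X.values.copy()
    has_na = np.isnan(values).any(axis=1)

    if drop_na_policy == "impute_zero":
        values[np.isnan(values)] = 0.0
        keep_na = np.ones(X.n_genes, dtype=bool)
    elif drop_na_policy == "drop_gene":
        keep_na = ~has_na
        report.n_dropped_na = int(has_na.sum())
    else:
        raise ValueError(f"unknown drop_na_policy {drop_na_policy!r}")

    with np.errstate(invalid="ignore"):
        all_zero = np.nansum(np.abs(values), axis=1) == 0
    # only count a gene once: NA-dropped genes are not also counted as all-zero
    report.n_dropped_all_zero = int((all_zero & keep_na).sum())
    keep = keep_na & ~all_zero
    report.n_output_genes = int(keep.sum())
    report.validate()
    if report.n_output_genes == 0:
        raise ValueError("empty matrix after prefilter")
    out = ExpressionMatrix(
        [g for g, k in zip(X.gene_ids, keep) if k],
        list(X.sample_ids),
        values[keep],
        X.value_scale,
    )
    logger.info(
        "prefilter: %d -> %d genes (%d all-zero, %d with NA dropped)",
        report.n_input_genes, report.n_output_genes,
        report.n_dropped_all_zero, report.n_dropped_na,
    )
    return out, report


def standardize_genes(
    X: ExpressionMatrix, report: PreprocessReport | None = None
) -> ExpressionMatrix:
    """Z-score each gene: (x - row mean) / row sd, sample sd (ddof=1).

    Zero-variance rows cannot be standardized and are dropped with a logged
    count (recorded as ``n_dropped_constant`` when a report is passed in).
    """
    if X.n_samples < 2:
        raise ValueError("standardization needs >= 2 samples per gene")
    mean = X.values.mean(axis=1, keepdims=True)
    sd = X.values.std(axis=1, ddof=1, keepdims=True)
    keep = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    n_const = int((~keep).sum())
    if n_const:
        logger.info("standardize_genes: dropped %d constant gene(s)", n_const)
    if report is not None:
        report.n_dropped_constant += n_const
        report.n_output_genes -= n_const
        report.validate()
    if not keep.any():
        raise ValueError("empty matrix after dropping constant genes")
    z = (X.values[keep] - mean[keep]) / sd[keep]
    return ExpressionMatrix(
        [g for g, k in zip(X.gene_ids, keep) if k], list(X.sample_ids), z, "zscore"
    )


def log_cpm(X: ExpressionMatrix, prior_count: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million: log2((c + prior) / (L + 1) * 1e6).

    L is the per-sample library size (column sum). The +prior/+1 offsets keep
    zero counts finite, following the standard voom/limma transformation.
    """
    if X.value_scale != "counts":
        raise ValueError(f"log_cpm expects counts, got value_scale={X.value_scale!r}")
    lib = np.nansum(X.values, axis=0)
    zero = np.where(lib == 0)[0]
    if zero.size:
        raise ValueError(f"library size 0 for sample {X.sample_ids[zero[0]]!r}")
    y = np.log2((X.values + prior_count) / (lib[None, :] + 1.0) * 1e6)
    return ExpressionMatrix(list(X.gene_ids), list(X.sample_ids), y, "logcpm")


def voom_weights(
    Y: ExpressionMatrix,
    groups: GroupLabels,
    lowess_span: float = 0.5,
) -> np.ndarray:
    """Voom-style precision weights from the mean-variance trend of log-CPM.

    Fits a lowess trend of sqrt(residual sd) against mean log-CPM across
    genes (residuals from the two group means), predicts the sqrt-sd at each
    observation's fitted value (clamped to the trend's x-range), and returns
    weight = predicted**-4. All weights are finite and strictly positive.
    """
    if Y.n_genes < 10:
        raise ValueError(
            "voom_weights needs at least 10 genes to estimate the "
            "mean-variance trend; got %d" % Y.n_genes
        )
    y01 = groups.labels_for(Y.sample_ids)
    V = Y.values
    fitted = np.empty_like(V)
    for g01 in (0, 1):
        cols = y01 == g01
        if cols.sum() < 2:
            raise ValueError("each group needs >= 2 samples for the trend fit")
        fitted[:, cols] = V[:, cols].mean(axis=1, keepdims=True)
    resid = V - fitted
    df = V.shape[1] - 2
    sd = np.sqrt((resid ** 2).sum(axis=1) / df)
    sx = V.mean(axis=1)
    sy = np.sqrt(sd)
    trend = lowess(sy, sx, frac=lowess_span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    # guard against a degenerate (non-positive) lowess prediction
    floor = max(1e-8, float(np.min(sy[sy > 0], initial=1e-4)) * 1e-3)
    ty = np.maximum(ty, floor)
    pred = np.interp(np.clip(fitted, tx[0], tx[-1]), tx, ty)
    w = pred ** -4.0
    if not np.all(np.isfinite(w)) or not np.all(w > 0):  # pragma: no cover
        raise RuntimeError("voom weights must be finite and positive")
    return w
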