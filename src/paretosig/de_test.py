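"""Two-group empirical-Bayes moderated t-test and volcano bi-filtering.

Per-gene ordinary least squares (optionally weighted) on a two-group design,
variance moderation by the empirical-Bayes shrinkage of Smyth (scaled inverse
chi-square prior fitted by method of moments on log variances), and the
volcano rule: up-regulated means p < alpha and fold change > fc_hi,
down-regulated means p < alpha and fold change < fc_lo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .data_io import ExpressionMatrix, GroupLabels

logger = logging.getLogger(__name__)

DE_COLUMNS = [
    "gene_id", "mean_control", "mean_case", "log2fc", "fold_change",
    "s2", "s2_tilde", "t_mod", "p", "q_bh", "status",
]


@dataclass
class EBayesPrior:
    """Scaled inverse chi-square prior on gene variances.

    d0 is the prior degrees of freedom (may be +inf when the observed
    variances show no excess spread); s0_sq the prior variance.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive")
        if not (np.isfinite(self.s0_sq) and self.s0_sq > 0):
            raise ValueError("s0_sq must be finite and positive")


def fit_two_group(
    Y: ExpressionMatrix,
    groups: GroupLabels,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene (weighted) group means, log2 fold change and residual variance.

    Returns a frame indexed by gene with columns mean_control, mean_case,
    log2fc (case minus control), s2 and df_residual (= S - 2). Weighted fits
    use per-observation precision weights; unit weights reproduce the
    unweighted fit exactly.
    """
    groups.require_both_groups()
    y01 = groups.labels_for(Y.sample_ids)
    n_ctrl, n_case = int((y01 == 0).sum()), int((y01 == 1).sum())
    if n_ctrl < 2 or n_case < 2:
        raise ValueError(
            f"each group needs >= 2 samples (control={n_ctrl}, case={n_case})"
        )
    V = Y.values
    if weights is None:
        W = np.ones_like(V)
    else:
        W = np.asarray(weights, dtype=float)
        if W.shape != V.shape:
            raise ValueError("weights must match the expression matrix shape")
        if not np.all(W > 0):
            raise ValueError("weights must be strictly positive")

    means = {}
    sw = {}
    rss = np.zeros(V.shape[0])
    for g01, name in ((0, "control"), (1, "case")):
        cols = y01 == g01
        wg = W[:, cols]
        sw[name] = wg.sum(axis=1)
        means[name] = (wg * V[:, cols]).sum(axis=1) / sw[name]
        rss += (wg * (V[:, cols] - means[name][:, None]) ** 2).sum(axis=1)

    df_resid = V.shape[1] - 2
    s2 = rss / df_resid
    out = pd.DataFrame(
        {
            "mean_control": means["control"],
            "mean_case": means["case"],
            "log2fc": means["case"] - means["control"],
            "s2": s2,
            "df_residual": df_resid,
            # variance factor of the group-difference contrast
            "v_contrast": 1.0 / sw["control"] + 1.0 / sw["case"],
        },
        index=pd.Index(Y.gene_ids, name="gene_id"),
    )
    return out


def _trigamma_inverse(x: float, max_iter: int = 100, tol: float = 1e-8) -> float | None:
    """Solve trigamma(y) = x by Newton iteration; None on non-convergence."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < tol * y:
            return float(y)
    return None


def ebayes_moderate(
    s2: np.ndarray, df: int
) -> tuple[EBayesPrior, np.ndarray]:
    """Moderate per-gene variances toward a fitted prior.

    The prior (d0, s0_sq) is estimated by method of moments on log variances
    (closed forms via digamma/trigamma inversion). Posterior variances are
    s2_tilde = (d0*s0_sq + df*s2) / (d0 + df); with d0 = +inf every gene gets
    s0_sq (the all-variances-identical branch), with d0 -> 0 no shrinkage.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if int(pos.sum()) < 10:
        raise ValueError("ebayes_moderate needs >= 10 genes with positive variance")
    z = np.log(s2[pos])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))

    d0 = np.inf
    if evar > 0:
        inv = _trigamma_inverse(evar)
        if inv is not None:
            d0 = 2.0 * inv
    if np.isfinite(d0):
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        s0_sq = float(np.exp(emean))
        s2_tilde = np.full_like(s2, s0_sq)
    return EBayesPrior(d0=d0, s0_sq=s0_sq), s2_tilde


def moderated_test(
    Y: ExpressionMatrix,
    groups: GroupLabels,
    weights: np.ndarray | None = None,
    alpha: float = 0.05,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
) -> tuple[pd.DataFrame, EBayesPrior]:
    """Full DE table: fit, moderate, test and volcano-classify each gene.

    p-values are two-sided from a t distribution with d0 + df_residual
    degrees of freedom. BH-adjusted q-values are reported alongside but the
    up/down status uses the raw p-value, matching the stated filtering rule.
    """
    fit = fit_two_group(Y, groups, weights=weights)
    df_resid = int(fit["df_residual"].iloc[0])
    prior, s2_tilde = ebayes_moderate(fit["s2"].to_numpy(), df_resid)
    se = np.sqrt(s2_tilde * fit["v_contrast"].to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = fit["log2fc"].to_numpy() / se
    df_total = prior.d0 + df_resid
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    p = np.where(np.isnan(t_mod), 1.0, p)  # zero-variance, zero-fc genes

    de = fit.drop(columns=["df_residual", "v_contrast"]).copy()
    de["s2_tilde"] = s2_tilde
    de["fold_change"] = 2.0 ** de["log2fc"]
    de["t_mod"] = t_mod
    de["p"] = p
    de["q_bh"] = _bh_adjust(p)
    de["status"] = _classify(de["p"], de["fold_change"], alpha, fc_hi, fc_lo)
    de = de.reset_index()[DE_COLUMNS]
    return de, prior


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def _classify(p, fold_change, alpha, fc_hi, fc_lo) -> np.ndarray:
    p = np.asarray(p)
    fc = np.asarray(fold_change)
    return np.where(
        (p < alpha) & (fc > fc_hi), "up",
        np.where((p < alpha) & (fc < fc_lo), "down", "ns"),
    ).astype(object)


def volcano_filter(
    de: pd.DataFrame,
    alpha: float = 0.05,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Split a DE table into up- and down-regulated gene lists (input order).

    up: p < alpha and fold change > fc_hi; down: p < alpha and fold change
    < fc_lo; everything else is non-significant. The three sets partition the
    genes.
    """
    status = _classify(de["p"], de["fold_change"], alpha, fc_hi, fc_lo)
    genes = de["gene_id"].to_numpy()
    up = [g for g, s in zip(genes, status) if s == "up"]
    down = [g for g, s in zip(genes, status) if s == "down"]
    logger.info("volcano filter: %d up, %d down of %d genes", len(up), len(down), len(genes))
    return up, down
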