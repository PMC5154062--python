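"""Panel correlation QC and the per-sample composite IFN score.

The IFN score of a sample is the arithmetic mean of its log2 relative
expression over a fixed panel of interferon response genes (IRGs).
Averaging is justified when the panel genes move together; the QC here
reports the fraction of gene pairs whose pairwise correlation clears a
threshold (r >= 0.7 at p <= 0.002 in the original assay) and warns — but
never filters — when the panel looks less coherent than that.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["CorrelationSummary", "correlation_qc", "compute_ifn_score"]


@dataclass
class CorrelationSummary:
    """All pairwise panel correlations plus the pass-fraction headline.

    ``pairs`` has one row per unordered gene pair with columns
    gene_i, gene_j, n, r, p, passing. Pairs undefined because a gene has
    zero variance (or too few complete observations) carry NaN r and are
    excluded from the pass-fraction denominator.
    """

    n_genes: int
    n_pairs: int
    threshold_r: float
    threshold_p: float
    fraction_pairs_passing: float
    pairs: pd.DataFrame

    def summary_line(self) -> str:
        return (
            f"{self.n_genes} genes, {self.n_pairs} pairs: "
            f"{self.fraction_pairs_passing:.1%} with r >= {self.threshold_r} "
            f"and p <= {self.threshold_p}"
        )


def correlation_qc(
    expr: ExpressionMatrix,
    threshold_r: float = 0.7,
    threshold_p: float = 0.002,
    method: str = "pearson",
) -> CorrelationSummary:
    """Pairwise-complete correlation of every panel gene pair.

    Parameters
    ----------
    expr : ExpressionMatrix
        Log2 expression, >= 2 genes and >= 4 samples.
    threshold_r, threshold_p : float
        A pair "passes" when r >= threshold_r and p <= threshold_p
        (two-sided p from the t approximation with n-2 df).
    method : {"pearson", "spearman"}
        Correlation flavor; Pearson on log2 values is the default.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    genes = list(expr.values.columns)
    if len(genes) < 2:
        raise ValueError("correlation QC needs at least 2 panel genes")
    if len(expr.values) < 4:
        raise ValueError("correlation QC needs at least 4 samples")

    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    n_undefined = 0
    X = expr.values
    for i, gi in enumerate(genes):
        for gj in genes[i + 1 :]:
            sub = X[[gi, gj]].dropna()
            n = len(sub)
            a, b = sub[gi].to_numpy(), sub[gj].to_numpy()
            if n < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
                rows.append((gi, gj, n, np.nan, np.nan, False))
                n_undefined += 1
                continue
            r, p = corr_fn(a, b)
            passing = bool(r >= threshold_r and p <= threshold_p)
            rows.append((gi, gj, n, float(r), float(p), passing))
    pairs = pd.DataFrame(
        rows, columns=["gene_i", "gene_j", "n", "r", "p", "passing"]
    )
    if n_undefined:
        warnings.warn(
            f"{n_undefined} gene pair(s) had undefined correlation "
            "(zero variance or too few complete observations); excluded from "
            "the pass-fraction denominator",
            stacklevel=2,
        )
    defined = pairs["r"].notna()
    fraction = float(pairs.loc[defined, "passing"].mean()) if defined.any() else np.nan
    summary = CorrelationSummary(
        n_genes=len(genes),
        n_pairs=len(pairs),
        threshold_r=threshold_r,
        threshold_p=threshold_p,
        fraction_pairs_passing=fraction,
        pairs=pairs,
    )
    if np.isfinite(fraction) and fraction < 0.9:
        warnings.warn(
            "panel coherence below the reference level: " + summary.summary_line(),
            stacklevel=2,
        )
    return summary


def compute_ifn_score(
    expr: ExpressionMatrix,
    panel: list[str] | None = None,
    min_fraction: float = 1.0,
) -> pd.Series:
    """Per-sample mean of log2 expression over the panel genes.

    Parameters
    ----------
    expr : ExpressionMatrix
    panel : list of gene ids, optional
        Defaults to every column of the matrix. Must be non-empty and a
        subset of the matrix genes.
    min_fraction : float in (0, 1]
        Minimum fraction of non-missing panel genes a sample needs for its
        score to be defined; samples below it are omitted (and logged).
        Default 1.0: every panel gene required.

    Returns
    -------
    pandas.Series
        sample_id -> IFN score, named ``"ifn_score"``.
    """
    if panel is None:
        panel = list(expr.values.columns)
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    absent = [g for g in panel if g not in expr.values.columns]
    if absent:
        raise KeyError(f"panel gene(s) absent from expression matrix: {absent}")
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")

    sub = expr.values[list(panel)]
    frac_present = sub.notna().mean(axis=1)
    keep = frac_present >= min_fraction
    if (~keep).any():
        logger.info(
            "omitting %d sample(s) with < %.0f%% of panel genes measured: %s",
            int((~keep).sum()), 100 * min_fraction, list(sub.index[~keep]),
        )
    scores = sub.loc[keep].mean(axis=1, skipna=True)
    scores.name = "ifn_score"
    scores.index.name = "sample_id"
    return scores
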