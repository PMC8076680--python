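"""Risk-group comparison of immune scores and gene/checkpoint correlations.

Immune-cell enrichment scores are compared between high- and low-risk
groups with the two-sided Mann-Whitney U test, labelled with the usual
significance stars.  Candidate target genes are correlated (Spearman)
against immune-cell scores and checkpoint genes (PD-L1 is addressed by its
gene symbol CD274; CTLA4 by CTLA4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import SsgseaResult
from .errors import ValidationError

__all__ = [
    "CHECKPOINT_ALIASES",
    "CorrelationMatrixResult",
    "mannwhitney_compare",
    "spearman_matrix",
    "star_label",
]

# common protein names -> gene symbols used in expression matrices
CHECKPOINT_ALIASES = {"PD-L1": "CD274", "PDL1": "CD274", "B7-H1": "CD274",
                      "CD152": "CTLA4"}

_STAR_STEPS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def star_label(p: float) -> str:
    """Significance stars: NS if p>0.05, then * / ** / *** / **** at
    p <= 0.05 / 0.01 / 0.001 / 0.0001."""
    for thresh, label in _STAR_STEPS:
        if p <= thresh:
            return label
    return "NS"


def mannwhitney_compare(
    scores: SsgseaResult | pd.DataFrame,
    groups: pd.Series,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Mann-Whitney comparison of each score row between risk groups.

    Uses exact enumeration when both groups have at most ``exact_max_n``
    samples (and no ties), otherwise the tie-corrected normal approximation.
    Returns one row per cell type: group medians and means, U, p, stars.
    """
    mat = scores.nes if isinstance(scores, SsgseaResult) else scores
    groups = pd.Series(groups).reindex(mat.columns)
    high = mat.columns[(groups == "high").to_numpy()]
    low = mat.columns[(groups == "low").to_numpy()]
    if len(high) == 0 or len(low) == 0:
        raise ValidationError("both risk groups must contain at least one sample")
    rows = []
    for cell in mat.index:
        x = mat.loc[cell, high].to_numpy(dtype=float)
        y = mat.loc[cell, low].to_numpy(dtype=float)
        method = "exact" if max(len(x), len(y)) <= exact_max_n else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        p = float(res.pvalue)
        rows.append(
            {
                "cell_type": cell,
                "median_high": float(np.median(x)),
                "median_low": float(np.median(y)),
                "mean_high": float(x.mean()),
                "mean_low": float(y.mean()),
                "U": float(res.statistic),
                "p": p,
                "label": star_label(p),
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")


@dataclass
class CorrelationMatrixResult:
    """Spearman correlations of genes against immune-cell scores and
    checkpoint genes, with raw-threshold significance flags."""

    rho: pd.DataFrame  # genes x (cell types + checkpoints)
    p: pd.DataFrame
    flags: pd.DataFrame  # "" / "*" (p<0.05) / "**" (p<0.01)


def _flag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def spearman_matrix(
    expr: pd.DataFrame,
    gene_rows,
    cell_scores: SsgseaResult | pd.DataFrame | None = None,
    checkpoint_genes=("CD274", "CTLA4"),
) -> CorrelationMatrixResult:
    """Spearman correlation of selected genes vs immune scores & checkpoints.

    Ranks use average ties; p-values come from the t approximation with
    n - 2 degrees of freedom (perfect correlations report the smallest
    representable positive p).  Samples are aligned on the expression
    matrix columns.
    """
    gene_rows = [str(g).upper() for g in gene_rows]
    checkpoints = [CHECKPOINT_ALIASES.get(str(g).upper(), str(g).upper())
                   for g in checkpoint_genes]
    missing = sorted((set(gene_rows) | set(checkpoints)) - set(expr.index))
    if missing:
        raise ValidationError("genes missing from expression matrix: "
                              + ", ".join(missing))
    samples = list(expr.columns)
    if len(samples) < 4:
        raise ValidationError("too few samples for correlation (need >= 4)")
    cols: dict[str, np.ndarray] = {}
    if cell_scores is not None:
        mat = cell_scores.nes if isinstance(cell_scores, SsgseaResult) else cell_scores
        mat = mat[samples]
        for cell in mat.index:
            cols[str(cell)] = mat.loc[cell].to_numpy(dtype=float)
    for g in checkpoints:
        cols[g] = expr.loc[g, samples].to_numpy(dtype=float)
    rho = pd.DataFrame(index=gene_rows, columns=list(cols), dtype=float)
    pmat = pd.DataFrame(index=gene_rows, columns=list(cols), dtype=float)
    tiny = np.finfo(float).tiny
    for g in gene_rows:
        x = expr.loc[g, samples].to_numpy(dtype=float)
        for name, y in cols.items():
            r, p = stats.spearmanr(x, y)
            rho.loc[g, name] = float(r)
            pmat.loc[g, name] = float(max(p, tiny))
    flags = pmat.map(_flag)
    return CorrelationMatrixResult(rho=rho, p=pmat, flags=flags)
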