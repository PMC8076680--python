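"""Single-sample and preranked gene-set enrichment.

ssGSEA scores one sample at a time: genes are ranked by expression and the
enrichment score for a set is the integrated difference between the
weighted in-set rank CDF and the uniform out-of-set CDF.  Because only
within-sample ranks enter, the scores share the platform invariance of the
gene-pair features.

Preranked GSEA walks a weighted Kolmogorov-Smirnov running sum down a
ranked gene list; significance comes from a seeded gene-label permutation
null, normalised within the sign of the observed score, with
Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "SsgseaResult",
    "GseaResult",
    "ssgsea_scores",
    "log2fc_ranking",
    "gsea",
    "bh_adjust",
]


@dataclass
class SsgseaResult:
    """ssGSEA enrichment scores, raw and range-normalised.

    ``nes`` = ``scores`` divided by (max - min) over the whole matrix, the
    usual cross-set normalisation for single-sample scores.
    """

    scores: pd.DataFrame  # sets x samples, raw ES
    norm_constant: float
    nes: pd.DataFrame


def ssgsea_scores(expr: pd.DataFrame, sets, tau: float = 0.25) -> SsgseaResult:
    """Per-sample gene-set enrichment (ssGSEA).

    For each sample, genes are ranked by expression (rank N for the highest,
    average ranks on ties).  Walking down the ranking, the in-set CDF is
    weighted by rank**tau and the out-of-set CDF is uniform; the enrichment
    score is the sum of their differences over all positions.

    Parameters
    ----------
    expr
        Expression matrix (genes x samples).
    sets
        Mapping name -> list of gene symbols (a GeneSetCollection works).
    tau
        Rank-weighting exponent, >= 0 (0 gives the unweighted KS form).

    Notes
    -----
    Sets with no gene in ``expr`` are dropped with a warning; a set covering
    every gene has no outside CDF and is rejected.  When the score matrix is
    a single value, range normalisation is degenerate and raw scores are
    returned with a warning.
    """
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    set_items = dict(getattr(sets, "sets", sets))
    genes = expr.index
    n_genes = len(genes)
    members: dict[str, np.ndarray] = {}
    for name, syms in set_items.items():
        mask = np.asarray(genes.isin([str(s).upper() for s in syms]))
        k = int(mask.sum())
        if k == 0:
            warnings.warn(f"gene set {name!r} has no gene in the expression matrix; "
                          "excluded", RuntimeWarning, stacklevel=2)
            continue
        if k == n_genes:
            raise ValidationError(
                f"gene set {name!r} covers every gene; no outside distribution"
            )
        members[name] = mask
    if not members:
        raise ValidationError("no gene set overlaps the expression matrix")

    values = expr.to_numpy(dtype=float)
    n_samples = values.shape[1]
    es = np.empty((len(members), n_samples))
    for j in range(n_samples):
        col = values[:, j]
        ranks = stats.rankdata(col, method="average")  # N for the highest
        order = np.argsort(-col, kind="stable")  # descending positions
        r_desc = ranks[order] ** tau
        for i, mask in enumerate(members.values()):
            hit = mask[order]
            w = r_desc * hit
            denom_in = w.sum()
            p_in = np.cumsum(w) / denom_in
            p_out = np.cumsum(~hit) / (n_genes - hit.sum())
            es[i, j] = float(np.sum(p_in - p_out))
    scores = pd.DataFrame(es, index=list(members), columns=expr.columns)
    spread = float(es.max() - es.min())
    if spread <= 0:
        warnings.warn(
            "degenerate range normalisation (all enrichment scores equal); "
            "returning raw scores",
            RuntimeWarning,
            stacklevel=2,
        )
        return SsgseaResult(scores=scores, norm_constant=1.0, nes=scores.copy())
    return SsgseaResult(scores=scores, norm_constant=spread, nes=scores / spread)


def log2fc_ranking(
    expr: pd.DataFrame, groups: pd.Series, pseudocount: float = 0.01
) -> pd.Series:
    """Rank genes by log2 fold change of mean expression, high vs low group.

    ``groups`` maps sample -> "high"/"low".  Returns a Series of scores
    sorted descending; ties break deterministically by gene symbol.
    """
    groups = pd.Series(groups)
    high = groups.index[groups == "high"]
    low = groups.index[groups == "low"]
    if len(high) == 0 or len(low) == 0:
        raise ValidationError("both risk groups must be non-empty")
    mean_high = expr[high].mean(axis=1)
    mean_low = expr[low].mean(axis=1)
    denom = mean_low + pseudocount
    if (denom <= 0).any():
        raise ValidationError(
            "zero denominator in fold change; set a positive pseudocount"
        )
    score = np.log2((mean_high + pseudocount) / denom)
    df = pd.DataFrame({"score": score, "gene": score.index})
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    return pd.Series(df["score"].to_numpy(), index=df["gene"], name="log2fc")


def _running_es(weights: np.ndarray, hits: np.ndarray) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    ``weights`` are |score|**p in list order; ``hits`` is a boolean mask of
    set membership.  Ties between the positive and negative extreme resolve
    to the positive one.
    """
    n_hit = hits.sum()
    w_hit = weights * hits
    denom = w_hit.sum()
    if denom <= 0:  # all hit scores zero: fall back to unweighted steps
        w_hit = hits.astype(float)
        denom = float(n_hit)
    run = np.cumsum(w_hit / denom - (~hits) / (len(hits) - n_hit))
    hi, lo = run.max(), run.min()
    return float(hi if hi >= -lo else lo)


def _null_es(weights: np.ndarray, n: int, k: int, n_perm: int, rng) -> np.ndarray:
    """Null ES distribution for random k-subsets of the list (vectorised)."""
    ridx = rng.random((n_perm, n)).argsort(axis=1, kind="stable")[:, :k]
    hits = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hits, ridx, True, axis=1)
    wh = hits * weights
    denom = wh.sum(axis=1, keepdims=True)
    zero = denom[:, 0] <= 0
    if zero.any():  # all-zero hit weights: unweighted steps for those rows
        wh[zero] = hits[zero].astype(float)
        denom = wh.sum(axis=1, keepdims=True)
    run = np.cumsum(wh / denom - (~hits) / (n - k), axis=1)
    hi = run.max(axis=1)
    lo = run.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


@dataclass
class GseaResult:
    """Per-set preranked GSEA statistics.

    ``table`` columns: size, es, nes, p, p_adj, leading_edge (comma-joined
    gene symbols).
    """

    table: pd.DataFrame
    n_perm: int


def gsea(
    ranked: pd.Series,
    sets,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> GseaResult:
    """Preranked GSEA with a gene-label permutation null.

    Parameters
    ----------
    ranked
        Scores indexed by gene symbol, sorted descending (e.g. the output
        of :func:`log2fc_ranking`).
    sets
        Mapping name -> gene list; genes absent from ``ranked`` are ignored,
        a set with no overlap is skipped with a warning, and a set covering
        the whole list is rejected.
    n_perm
        Number of permutations (>= 1).
    weight
        Exponent on |score| for hit increments (1 = classic weighting).

    Notes
    -----
    The normalised score divides the observed ES by the mean |null ES| of
    matching sign, and the nominal p-value is computed among same-sign null
    scores with the +1 correction; Benjamini-Hochberg adjusts across sets.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    ranked = pd.Series(ranked)
    ranked.index = ranked.index.astype(str).str.upper()
    order = np.argsort(-ranked.to_numpy(), kind="stable")
    scores = ranked.to_numpy()[order]
    gene_list = ranked.index.to_numpy()[order]
    n = len(gene_list)
    weights = np.abs(scores) ** weight
    rng = np.random.default_rng(seed)
    pos = {g: i for i, g in enumerate(gene_list)}

    set_items = dict(getattr(sets, "sets", sets))
    rows = []
    for name, syms in set_items.items():
        idx = np.array(sorted({pos[str(s).upper()] for s in syms if str(s).upper() in pos}),
                       dtype=int)
        k = len(idx)
        if k == 0:
            warnings.warn(f"gene set {name!r} has no gene in the ranked list; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        if k >= n:
            raise ValidationError(f"gene set {name!r} is as large as the ranked list")
        hits = np.zeros(n, dtype=bool)
        hits[idx] = True
        es = _running_es(weights, hits)

        null = _null_es(weights, n, k, n_perm, rng)
        same = null >= 0 if es >= 0 else null < 0
        n_same = int(same.sum())
        if n_same:
            nes = es / max(np.abs(null[same]).mean(), np.finfo(float).tiny)
            p = (1 + int(np.sum(np.abs(null[same]) >= abs(es)))) / (n_same + 1)
        else:
            nes = np.nan
            p = 1.0 / (n_perm + 1)

        # leading edge: set genes up to (or after) the running-sum extremum
        run = np.cumsum(
            np.where(hits, weights / max(weights[hits].sum(), np.finfo(float).tiny),
                     -1.0 / (n - k))
        )
        if es >= 0:
            edge_idx = idx[idx <= int(np.argmax(run))]
        else:
            edge_idx = idx[idx >= int(np.argmin(run))]
        rows.append(
            {
                "set": name,
                "size": k,
                "es": es,
                "nes": nes,
                "p": p,
                "leading_edge": ",".join(gene_list[edge_idx]),
            }
        )
    if not rows:
        raise ValidationError("no gene set overlaps the ranked list")
    table = pd.DataFrame(rows).set_index("set")
    table["p_adj"] = bh_adjust(table["p"].to_list())
    table = table[["size", "es", "nes", "p", "p_adj", "leading_edge"]]
    return GseaResult(table=table, n_perm=n_perm)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
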