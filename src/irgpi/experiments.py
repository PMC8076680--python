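"""Replicated simulation studies of the pipeline's operating characteristics.

Each function runs one replicate (or one batch) of a self-contained
experiment on synthetic cohorts: recovery of a planted pair signature and
its transfer to an independently distorted validation cohort, type-I
calibration of the univariate screen and of the validation log-rank under a
null signature, and calibration of the preranked-GSEA permutation p-value.
These back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import enrichment, pairs, simulate, survival
from .errors import ValidationError

__all__ = [
    "recovery_planted_pairs",
    "signature_recovery_replicate",
    "null_signature_replicate",
    "gsea_null_batch",
]


def recovery_planted_pairs() -> list[tuple[str, str, float]]:
    """Planted pairs for the recovery study: five disjoint pairs with
    coefficient magnitudes spanning 0.35-0.55 and mixed sign."""
    coefs = [0.5, -0.4, 0.45, -0.55, 0.35]
    return [(f"G{2*k+1:04d}", f"G{2*k+2:04d}", coefs[k]) for k in range(5)]


def _panel_pair_matrix(
    expr: pd.DataFrame,
    planted: list[tuple[str, str, float]],
    n_noise_pairs: int,
    panel_size: int = 50,
) -> pairs.PairScoreMatrix:
    """Pair matrix holding the planted pairs plus ``n_noise_pairs`` others."""
    panel = [f"G{k+1:04d}" for k in range(panel_size)]
    pm = pairs.build_pairs(expr, panel)
    planted_set = {(a, b) for a, b, _ in planted}
    planted_genes = {g for a, b, _ in planted for g in (a, b)}
    keep, noise = [], 0
    for k, p in enumerate(pm.pairs):
        if p in planted_set or (p[1], p[0]) in planted_set:
            keep.append(k)
        elif not planted_genes & set(p) and noise < n_noise_pairs:
            # noise features share no gene with the planted signature, so
            # they carry no indirect signal
            keep.append(k)
            noise += 1
    return pm.subset(keep)


def _spec_pair(seed: int, planted, n_discovery: int, n_validation: int,
               panel_size: int = 50):
    spec_d = simulate.CohortSpec(
        n_samples=n_discovery,
        n_genes=panel_size,
        planted_pairs=planted,
        platform_distortion="none",
        seed=2 * seed,
        sample_prefix="D",
    )
    spec_v = simulate.CohortSpec(
        n_samples=n_validation,
        n_genes=panel_size,
        planted_pairs=planted,
        platform_distortion="log-affine",
        seed=2 * seed + 1,
        sample_prefix="V",
    )
    return simulate.make_two_cohorts(spec_d, spec_v)


def signature_recovery_replicate(
    seed: int,
    n_discovery: int = 300,
    n_validation: int = 374,
    n_noise_pairs: int = 200,
    alpha: float = 0.05,
    k_folds: int = 10,
) -> dict:
    """One replicate of the planted-signature recovery study.

    Simulates a discovery cohort driven by five planted pairs among
    ``n_noise_pairs`` noise pairs, selects a signature by cross-validated
    lasso Cox over the candidate pair features, picks the ROC cutoff on
    discovery, then scores an independently (log-affine) distorted
    validation cohort with the fitted signature.

    Returns per-replicate outcomes: number of planted pairs selected with
    the planted coefficient sign, signature size, and the validation
    log-rank p-value (NaN when no signature was selected or one risk group
    is empty).
    """
    planted = recovery_planted_pairs()
    (expr_d, clin_d, _), (expr_v, clin_v, _) = _spec_pair(
        seed, planted, n_discovery, n_validation
    )
    pm = _panel_pair_matrix(expr_d, planted, n_noise_pairs)
    t, e = clin_d["time"].to_numpy(float), clin_d["event"].to_numpy(int)
    out = {
        "n_candidate_pairs": len(pm.pairs),
        "n_recovered_sign_consistent": 0,
        "n_selected": 0,
        "validation_logrank_p": np.nan,
    }
    try:
        _, sig = survival.lasso_cox_select(pm, t, e, k_folds=k_folds, seed=seed)
    except ValidationError:
        return out
    fitted = {(p.gene_a, p.gene_b): p.coefficient for p in sig.pairs}
    recovered = 0
    for a, b, coef in planted:
        if (a, b) in fitted and np.sign(fitted[(a, b)]) == np.sign(coef):
            recovered += 1
        elif (b, a) in fitted and np.sign(fitted[(b, a)]) == -np.sign(coef):
            recovered += 1
    out["n_recovered_sign_consistent"] = recovered
    out["n_selected"] = len(sig.pairs)
    roc = survival.td_roc(pairs.score_signature(expr_d, sig), t, e, t_eval=365.0)
    groups_v = pairs.assign_risk(pairs.score_signature(expr_v, sig), roc.cutoff)
    if groups_v.nunique() == 2:
        lr = survival.logrank_test(
            clin_v["time"].to_numpy(float),
            clin_v["event"].to_numpy(int),
            groups_v.to_numpy(),
        )
        out["validation_logrank_p"] = lr.p
    return out


def null_signature_replicate(
    seed: int,
    n_discovery: int = 300,
    n_validation: int = 374,
    n_noise_pairs: int = 200,
    alpha: float = 0.05,
    k_folds: int = 10,
) -> dict:
    """One replicate of the null study: planted coefficients all zero.

    Returns the univariate-screen retention fraction over the candidate
    pairs and whether the full fitted pipeline (when it selects anything at
    all) rejects on the validation cohort at the 0.05 level — under the
    null, finding no signature counts as a correct non-rejection.
    """
    planted = [(a, b, 0.0) for a, b, _ in recovery_planted_pairs()]
    (expr_d, clin_d, _), (expr_v, clin_v, _) = _spec_pair(
        seed, planted, n_discovery, n_validation
    )
    pm = _panel_pair_matrix(expr_d, planted, n_noise_pairs)
    t, e = clin_d["time"].to_numpy(float), clin_d["event"].to_numpy(int)
    out = {"n_pairs_tested": len(pm.pairs), "retained": 0, "validation_reject": False}
    try:
        _, table = survival.univariate_screen(pm, t, e, alpha=alpha)
        out["retained"] = int(table["kept"].sum())
    except ValidationError:
        pass  # zero pairs retained is a legitimate null outcome
    try:
        _, sig = survival.lasso_cox_select(pm, t, e, k_folds=k_folds, seed=seed)
        roc = survival.td_roc(pairs.score_signature(expr_d, sig), t, e, t_eval=365.0)
        groups_v = pairs.assign_risk(pairs.score_signature(expr_v, sig), roc.cutoff)
        if groups_v.nunique() == 2:
            lr = survival.logrank_test(
                clin_v["time"].to_numpy(float),
                clin_v["event"].to_numpy(int),
                groups_v.to_numpy(),
            )
            out["validation_reject"] = bool(lr.p < 0.05)
    except ValidationError:
        pass  # no signature selected: correct non-rejection under the null
    return out


def gsea_null_batch(
    seed: int,
    n_lists: int = 100,
    n_sets_per_list: int = 10,
    n_genes: int = 100,
    set_size: int = 15,
    n_perm: int = 200,
) -> dict:
    """Type-I calibration of the preranked-GSEA permutation p-value.

    For each replicate list, gene scores are i.i.d. normal and the sets are
    random draws, so every nominal p should be uniform.  Returns the
    fraction of set-level p-values below 0.05.
    """
    rng = np.random.default_rng(seed)
    n_sig = 0
    n_total = 0
    pvals = []
    for rep in range(n_lists):
        scores = pd.Series(
            rng.normal(size=n_genes),
            index=[f"N{rep}_{i}" for i in range(n_genes)],
        )
        genes = scores.index.to_numpy()
        sets = {
            f"R{j}": list(rng.choice(genes, size=set_size, replace=False))
            for j in range(n_sets_per_list)
        }
        res = enrichment.gsea(
            scores, sets, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        pvals.extend(res.table["p"].to_list())
        n_sig += int((res.table["p"] < 0.05).sum())
        n_total += len(res.table)
    return {
        "n_tests": n_total,
        "rate_p_below_05": n_sig / n_total,
        "pvals": np.asarray(pvals),
    }
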