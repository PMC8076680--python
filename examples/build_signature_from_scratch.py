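"""Fit a gene-pair prognostic signature on a simulated discovery cohort.

Pipeline: variable-gene filter (scaled MAD > 0.5) -> all immune gene pairs
-> univariate screen (Cox Wald and log-rank, both p < 0.05) -> lasso-Cox
with 10-fold cross-validation -> one-year time-dependent ROC to pick the
risk cutoff (Youden index) -> validation on a second, distorted cohort.
"""

from irgpi import (
    CohortSpec,
    assign_risk,
    build_pairs,
    lasso_cox_select,
    logrank_test,
    mad_filter,
    make_two_cohorts,
    score_signature,
    td_roc,
    univariate_screen,
)

spec_d = CohortSpec(n_samples=300, n_genes=50, seed=8)
spec_v = CohortSpec(n_samples=374, n_genes=50, seed=9,
                    platform_distortion="log-affine")
(expr_d, clin_d, _), (expr_v, clin_v, _) = make_two_cohorts(spec_d, spec_v)
t, e = clin_d["time"].to_numpy(), clin_d["event"].to_numpy()

filtered = mad_filter(expr_d, threshold=0.5)
pm = build_pairs(filtered, filtered.index)
print(f"{filtered.shape[0]} variable genes -> {len(pm.pairs)} candidate pairs")

screened, _ = univariate_screen(pm, t, e, alpha=0.05)
print(f"{len(screened.pairs)} pairs pass the univariate screen")

path, sig = lasso_cox_select(screened, t, e, k_folds=10, seed=8)
print(f"lasso keeps {len(sig.pairs)} pairs at lambda.min={path.alpha_min:.4f}:")
for p in sig.pairs:
    print(f"  {p.gene_a}>{p.gene_b}: {p.coefficient:+.3f}")

roc = td_roc(score_signature(expr_d, sig), t, e, t_eval=365.0)
sig.cutoff = roc.cutoff
print(f"one-year ROC AUC {roc.auc:.3f}; Youden cutoff {roc.cutoff:.3f}")

groups_v = assign_risk(score_signature(expr_v, sig), sig.cutoff)
lr = logrank_test(clin_v["time"], clin_v["event"], groups_v)
print(
    f"validation cohort: {int((groups_v == 'high').sum())} high / "
    f"{int((groups_v == 'low').sum())} low risk, "
    f"log-rank chi2={lr.chi2:.1f}, p={lr.p:.2e}"
)
print("A small p confirms the discovery-fitted signature stratifies survival "
      "on a cohort measured on a different platform.")
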