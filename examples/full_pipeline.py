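"""Run the complete pipeline on synthetic two-cohort data.

Simulates a 149-sample discovery and 374-sample validation cohort (with a
log-affine cross-platform distortion), fits and validates a pair
signature, and writes every table — risk scores, Cox tables, ssGSEA
comparisons, GSEA, correlations — to ``irgpi_demo/``.
"""

import yaml

from irgpi import PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="irgpi_demo", seed=1, synthetic=True, n_perm=500)
outdir = run_pipeline(cfg)

log = yaml.safe_load((outdir / "run_log.yaml").read_text())
print(f"outputs in {outdir}/")
print(f"  variable genes:        {log['genes_after_mad']}")
print(f"  candidate pairs:       {log['candidate_pairs']}")
print(f"  pairs after screen:    {log['screened_pairs']}")
print(f"  pairs in signature:    {log['selected_pairs']}")
print(f"  one-year ROC AUC:      {log['roc_auc']:.3f}")
print(f"  risk cutoff:           {log['cutoff']:.3f}")
print(f"  discovery log-rank:    chi2={log['discovery_logrank_chi2']:.1f}, "
      f"p={log['discovery_logrank_p']:.2e}")
print(f"  validation log-rank:   chi2={log['validation_logrank_chi2']:.1f}, "
      f"p={log['validation_logrank_p']:.2e}")
print(f"  cell types differing:  {log['discovery_significant_cell_types']}/30 "
      "(discovery, p<=0.05)")
print(
    "\nThe validation line is the key readout: the signature and cutoff "
    "fitted on discovery stratify survival in an independently distorted "
    "cohort.  At this discovery size (n=149) transfer strength varies "
    "between simulations; see the replicated experiments in "
    "irgpi.experiments for operating characteristics."
)
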