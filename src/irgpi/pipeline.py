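"""End-to-end orchestration: from expression + clinical tables (or a
synthetic two-cohort simulation) to signature, risk groups, survival
statistics, immune-infiltration comparison, pathway enrichment and
correlation tables, all written as TSV into an output directory.

Every stochastic stage draws from the single configured seed; rerunning
with the same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare, enrichment, io, pairs, simulate, survival
from .errors import IrgpiError, PipelineError, ValidationError

__all__ = ["PipelineConfig", "run_pipeline", "synthetic_inputs"]


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run.

    File inputs are ignored when ``synthetic`` is true; then two cohorts are
    generated (discovery/validation sample sizes below) with the planted
    five-pair signature and planted immune-set signal.
    """

    outdir: str = "irgpi_out"
    seed: int = 0
    synthetic: bool = False
    # file inputs (discovery required unless synthetic)
    expression: str | None = None
    clinical: str | None = None
    validation_expression: str | None = None
    validation_clinical: str | None = None
    immune_gene_list: str | None = None  # default: packaged list
    cell_sets: str | None = None  # GMT for ssGSEA; default: packaged panel
    pathway_sets: str | None = None  # GMT for GSEA; default: same as cell_sets
    # synthetic-cohort conditions
    n_discovery: int = 149
    n_validation: int = 374
    n_genes: int = 400
    n_pair_panel: int = 80  # synthetic immune genes eligible for pairing
    discovery_distortion: str = "none"
    validation_distortion: str = "log-affine"
    censor_rate: float = 0.3
    immune_effect: float = 1.0
    # method parameters
    mad_threshold: float = 0.5
    min_minor_freq: float = 0.2
    screen_alpha: float = 0.05
    k_folds: int = 10
    lambda_selection: str = "min"
    ties: str = "efron"
    t_eval: float = 365.0
    tau: float = 0.25
    n_perm: int = 1000
    gsea_weight: float = 1.0
    pseudocount: float = 0.01
    target_genes: list[str] = field(default_factory=list)
    checkpoint_genes: list[str] = field(default_factory=lambda: ["CD274", "CTLA4"])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**raw)


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except (IrgpiError, FileNotFoundError, OSError, ValueError) as exc:
        raise PipelineError(f"stage[{name}]: {exc}") from exc


def synthetic_inputs(cfg: PipelineConfig) -> dict:
    """Generate discovery and validation cohorts plus gene-set inputs.

    Thirty immune cell-type sets of six genes each are planted on genes not
    used by the pair signature, alternating positive and negative
    association with risk; the same collection doubles as the pathway
    collection for GSEA.  Two member genes of the first positively
    associated set stand in for checkpoint genes, and the first three for
    correlation target genes.
    """
    planted = simulate.default_planted_pairs(5)
    n_sets, set_size = 30, 10
    first = cfg.n_pair_panel + 1  # immune sets never overlap the pair panel
    need = first - 1 + n_sets * set_size
    if cfg.n_genes < need:
        raise ValidationError(
            f"synthetic mode needs at least {need} genes, got {cfg.n_genes}"
        )
    if cfg.n_pair_panel < 11:
        raise ValidationError("pair panel must cover the ten planted-pair genes")
    sets, signs = {}, {}
    for i in range(n_sets):
        name = f"Immune set {i + 1:02d}"
        start = first + i * set_size
        sets[name] = [f"G{start + j:04d}" for j in range(set_size)]
        signs[name] = 1 if i % 2 == 0 else -1
    spec_d = simulate.CohortSpec(
        n_samples=cfg.n_discovery,
        n_genes=cfg.n_genes,
        planted_pairs=planted,
        censor_rate=cfg.censor_rate,
        platform_distortion=cfg.discovery_distortion,
        immune_sets=sets,
        immune_set_signs=signs,
        immune_effect=cfg.immune_effect,
        seed=cfg.seed,
        sample_prefix="D",
    )
    spec_v = replace(
        spec_d,
        n_samples=cfg.n_validation,
        platform_distortion=cfg.validation_distortion,
        seed=cfg.seed + 1,
        sample_prefix="V",
    )
    disc, val = simulate.make_two_cohorts(spec_d, spec_v)
    collection = io.GeneSetCollection(
        sets=dict(sets), descriptions={k: ("up" if signs[k] > 0 else "down") for k in sets}
    )
    pos_set = sets["Immune set 01"]
    return {
        "discovery": disc,
        "validation": val,
        "immune_genes": pd.Series("Synthetic", index=pd.Index(
            spec_d.gene_names()[: cfg.n_pair_panel], name="gene"), name="category"),
        "cell_sets": collection,
        "pathway_sets": collection,
        "target_genes": pos_set[:3],
        "checkpoint_genes": pos_set[3:5],
        "planted_pairs": planted,
    }


def _cox_tables(clinical: pd.DataFrame, groups: pd.Series, ties: str):
    """Univariate and multivariate Cox tables over the standard factors."""
    covs = {}
    if "age" in clinical.columns:
        covs["Age"] = pd.to_numeric(clinical["age"]).to_numpy(dtype=float)
    if "gender" in clinical.columns:
        covs["Gender"] = (
            clinical["gender"].astype(str).str.lower() == "male"
        ).to_numpy(dtype=float)
    for col, label in (("radiotherapy", "Radiotherapy"), ("chemotherapy", "Chemotherapy")):
        if col in clinical.columns:
            covs[label] = pd.to_numeric(clinical[col]).to_numpy(dtype=float)
    covs["Risk"] = (groups.reindex(clinical.index) == "high").to_numpy(dtype=float)
    time = clinical["time"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=int)
    uni_rows = []
    for label, x in covs.items():
        fit = survival.cox_fit(time, event, x[:, None], names=[label], ties=ties)
        uni_rows.append(fit.summary)
    uni = pd.concat(uni_rows)
    X = pd.DataFrame(covs, index=clinical.index)
    multi = survival.cox_fit(time, event, X, ties=ties).summary
    return uni, multi


def _format_cox(table: pd.DataFrame) -> pd.DataFrame:
    """Publication-style layout: Factor, HR(95%CI), P-value."""
    out = pd.DataFrame(index=table.index)
    out["HR(95%CI)"] = [
        f"{r.hr:.2f}({r.ci_lower:.2f}-{r.ci_upper:.2f})" for r in table.itertuples()
    ]
    out["P-value"] = [f"{p:.3g}" for p in table["p"]]
    return out


def _survival_block(name, expr, clinical, sig, cutoff, cfg, outdir, log):
    """Score, stratify and test one cohort; returns risk groups."""
    samples = io.check_sample_alignment(expr, clinical)
    expr = expr[samples]
    clinical = clinical.loc[samples]
    scores = pairs.score_signature(expr, sig)
    groups = pairs.assign_risk(scores, cutoff)
    risk = pd.DataFrame(
        {"risk_score": scores, "risk_group": groups,
         "time": clinical["time"], "event": clinical["event"]}
    )
    risk.to_csv(outdir / f"risk_{name}.tsv", sep="\t", index_label="sample")
    if groups.nunique() < 2:
        raise ValidationError(
            f"{name}: risk cutoff {cutoff:.4g} puts every sample in one group"
        )
    lr = survival.logrank_test(
        clinical["time"].to_numpy(float), clinical["event"].to_numpy(int), groups.to_numpy()
    )
    log[f"{name}_logrank_chi2"] = round(float(lr.chi2), 6)
    log[f"{name}_logrank_p"] = float(lr.p)
    uni, multi = _cox_tables(clinical, groups, cfg.ties)
    _format_cox(uni).to_csv(outdir / f"cox_univariate_{name}.tsv", sep="\t",
                            index_label="Factor")
    _format_cox(multi).to_csv(outdir / f"cox_multivariate_{name}.tsv", sep="\t",
                              index_label="Factor")
    uni.to_csv(outdir / f"cox_univariate_{name}_full.tsv", sep="\t")
    multi.to_csv(outdir / f"cox_multivariate_{name}_full.tsv", sep="\t")
    km = survival.km_curve(clinical["time"].to_numpy(float),
                           clinical["event"].to_numpy(int))
    km.to_csv(outdir / f"km_{name}.tsv", sep="\t")
    return expr, clinical, groups


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and write the output directory; returns its path.

    Stages: input loading (or simulation), MAD gene filter, pair
    construction, univariate screening, lasso-Cox selection, ROC cutoff,
    risk stratification and survival testing on discovery and validation,
    ssGSEA + group comparison, preranked GSEA, and gene/checkpoint
    correlations.  Any failure aborts with a stage-labelled message.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": {k: v for k, v in asdict(cfg).items()}}

    with _stage("inputs"):
        if cfg.synthetic:
            inputs = synthetic_inputs(cfg)
            (expr_d, clin_d, truth_d) = inputs["discovery"]
            (expr_v, clin_v, truth_v) = inputs["validation"]
            immune_genes = inputs["immune_genes"]
            cell_sets = inputs["cell_sets"]
            pathway_sets = inputs["pathway_sets"]
            target_genes = cfg.target_genes or inputs["target_genes"]
            checkpoint_genes = inputs["checkpoint_genes"]
            io.write_expression(expr_d, outdir / "expression_discovery.tsv")
            io.write_expression(expr_v, outdir / "expression_validation.tsv")
            clin_d.to_csv(outdir / "clinical_discovery.tsv", sep="\t",
                          index_label="sample")
            clin_v.to_csv(outdir / "clinical_validation.tsv", sep="\t",
                          index_label="sample")
            truth_d.to_csv(outdir / "truth_discovery.tsv", sep="\t")
            truth_v.to_csv(outdir / "truth_validation.tsv", sep="\t")
        else:
            if cfg.expression is None:
                raise ValidationError("expression matrix required")
            if cfg.clinical is None:
                raise ValidationError("survival table required")
            expr_d = io.load_expression(cfg.expression)
            clin_d = io.load_clinical(cfg.clinical)
            expr_v = clin_v = None
            if cfg.validation_expression is not None:
                if cfg.validation_clinical is None:
                    raise ValidationError("survival table required for validation cohort")
                expr_v = io.load_expression(cfg.validation_expression)
                clin_v = io.load_clinical(cfg.validation_clinical)
            immune_genes = (
                io.load_immune_gene_list(cfg.immune_gene_list)
                if cfg.immune_gene_list
                else io.packaged_immune_gene_list()
            )
            cell_sets = (
                io.load_gmt(cfg.cell_sets) if cfg.cell_sets
                else io.packaged_immune_cell_sets()
            )
            pathway_sets = io.load_gmt(cfg.pathway_sets) if cfg.pathway_sets else cell_sets
            target_genes = cfg.target_genes
            checkpoint_genes = cfg.checkpoint_genes
        samples = io.check_sample_alignment(expr_d, clin_d)
        expr_d, clin_d = expr_d[samples], clin_d.loc[samples]

    with _stage("mad_filter"):
        filtered = pairs.mad_filter(expr_d, threshold=cfg.mad_threshold)
        log["genes_after_mad"] = int(filtered.shape[0])

    with _stage("pairs"):
        pair_matrix = pairs.build_pairs(
            filtered, immune_genes.index, min_minor_freq=cfg.min_minor_freq
        )
        log["candidate_pairs"] = len(pair_matrix.pairs)

    with _stage("screen"):
        screened, screen_table = survival.univariate_screen(
            pair_matrix,
            clin_d["time"].to_numpy(float),
            clin_d["event"].to_numpy(int),
            alpha=cfg.screen_alpha,
        )
        screen_table.to_csv(outdir / "screening.tsv", sep="\t")
        log["screened_pairs"] = len(screened.pairs)

    with _stage("lasso"):
        path, sig = survival.lasso_cox_select(
            screened,
            clin_d["time"].to_numpy(float),
            clin_d["event"].to_numpy(int),
            k_folds=cfg.k_folds,
            seed=cfg.seed,
            selection=cfg.lambda_selection,
        )
        pd.DataFrame(
            {"alpha": path.alphas, "cv_deviance": path.cv_mean, "cv_se": path.cv_se,
             "n_nonzero": (path.coefs != 0).sum(axis=0)}
        ).to_csv(outdir / "lasso_path.tsv", sep="\t", index=False)
        log["selected_pairs"] = len(sig.pairs)
        log["lasso_alpha"] = float(path.selected_alpha)

    with _stage("cutoff"):
        scores_d = pairs.score_signature(expr_d, sig)
        roc = survival.td_roc(
            scores_d,
            clin_d["time"].to_numpy(float),
            clin_d["event"].to_numpy(int),
            t_eval=cfg.t_eval,
        )
        sig.cutoff = roc.cutoff
        roc.curve.to_csv(outdir / "roc_curve.tsv", sep="\t", index=False)
        io.save_signature(sig, outdir / "signature.json")
        log["roc_auc"] = round(float(roc.auc), 6)
        log["cutoff"] = float(roc.cutoff)

    with _stage("survival_discovery"):
        expr_d, clin_d, groups_d = _survival_block(
            "discovery", expr_d, clin_d, sig, sig.cutoff, cfg, outdir, log
        )

    groups_v = None
    if expr_v is not None:
        with _stage("survival_validation"):
            expr_v, clin_v, groups_v = _survival_block(
                "validation", expr_v, clin_v, sig, sig.cutoff, cfg, outdir, log
            )

    cohorts = [("discovery", expr_d, groups_d)]
    if groups_v is not None:
        cohorts.append(("validation", expr_v, groups_v))

    cell_scores = {}
    for name, expr, groups in cohorts:
        with _stage(f"infiltration_{name}"):
            ss = enrichment.ssgsea_scores(expr, cell_sets, tau=cfg.tau)
            ss.nes.to_csv(outdir / f"ssgsea_nes_{name}.tsv", sep="\t",
                          index_label="cell_type")
            comp = compare.mannwhitney_compare(ss, groups)
            comp.to_csv(outdir / f"immune_comparison_{name}.tsv", sep="\t")
            cell_scores[name] = ss
            log[f"{name}_significant_cell_types"] = int((comp["p"] <= 0.05).sum())

    for name, expr, groups in cohorts:
        with _stage(f"gsea_{name}"):
            ranked = enrichment.log2fc_ranking(expr, groups, pseudocount=cfg.pseudocount)
            res = enrichment.gsea(
                ranked, pathway_sets, n_perm=cfg.n_perm,
                weight=cfg.gsea_weight, seed=cfg.seed,
            )
            table = res.table.sort_values("nes", ascending=False)
            table.to_csv(outdir / f"gsea_{name}.tsv", sep="\t")
            log[f"{name}_significant_pathways"] = int((table["p_adj"] < 0.05).sum())

    if target_genes:
        for name, expr, groups in cohorts:
            with _stage(f"correlate_{name}"):
                corr = compare.spearman_matrix(
                    expr, target_genes, cell_scores[name],
                    checkpoint_genes=checkpoint_genes,
                )
                corr.rho.to_csv(outdir / f"correlation_rho_{name}.tsv", sep="\t",
                                index_label="gene")
                corr.p.to_csv(outdir / f"correlation_p_{name}.tsv", sep="\t",
                              index_label="gene")
                corr.flags.to_csv(outdir / f"correlation_flags_{name}.tsv", sep="\t",
                                  index_label="gene")

    with _stage("run_log"):
        log["signature"] = sig.to_dict()
        (outdir / "run_log.yaml").write_text(
            yaml.safe_dump(log, sort_keys=True), encoding="utf-8"
        )
    return outdir
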