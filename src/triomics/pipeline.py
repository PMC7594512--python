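"""End-to-end pipeline: preprocess -> correlated-gene selection -> prognostic
filtering -> single-omic and integrated clustering -> subgroup survival ->
subgroup-specific genes -> downstream summaries.

Every run writes its artifacts into one config-addressed directory (no
timestamps) together with a manifest holding the config hash, the seed and a
hash over all numeric outputs, plus a JSON-lines stage log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import downstream, genecor, perturbation, subgroup_genes, survival
from .io_preprocess import (
    MatchedCohort,
    cohort_manifest,
    preprocess_cohort,
    read_clinical,
    read_omics_matrix,
)


@dataclass
class PipelineConfig:
    """All knobs of a full run; hashable to address the output directory."""

    mrna_path: str
    cna_path: str
    met_path: str
    clinical_path: str
    out_dir: str
    alpha_correlation: float = 0.05
    alpha_cox: float = 0.05
    alpha_q: float = 0.05
    alpha_anova: float = 0.05
    sign_constraint: str = "any"
    k_min: int = 2
    k_max: int = 10
    n_perturb: int = perturbation.DEFAULT_N_PERTURB
    noise_scale: float = perturbation.DEFAULT_NOISE_SCALE
    kmeans_restarts: int = perturbation.DEFAULT_KMEANS_RESTARTS
    linkage: str = perturbation.DEFAULT_LINKAGE
    age_threshold: float = 65.0
    burden_threshold: float = 0.3
    max_missing_frac: float = 0.5
    knn_k: int = 10
    truncate_months: float | None = None
    filter_mrna_by_cox: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.alpha_correlation, self.alpha_cox, self.alpha_q, self.alpha_anova):
            if not 0.0 < a < 1.0:
                raise ValueError("alpha thresholds must lie in (0, 1)")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("invalid k range")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", **kw)


class _StageLog:
    def __init__(self, path: Path) -> None:
        self.path = path
        self.path.write_text("")

    def record(self, stage: str, **info) -> None:
        entry = {"stage": stage, **info}
        with self.path.open("a") as fh:
            fh.write(json.dumps(entry, default=str) + "\n")


def run_pipeline(config: PipelineConfig, cohort: MatchedCohort | None = None) -> Path:
    """Execute the full protocol; returns the run directory.

    ``cohort`` may be supplied directly (already preprocessed or raw matrices
    read from the configured paths otherwise). Inputs are never mutated; all
    outputs land under ``<out_dir>/run-<config hash>``.
    """
    run_dir = Path(config.out_dir) / f"run-{config.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    log = _StageLog(run_dir / "log.jsonl")
    t0 = _time.time()

    # --- preprocess ---------------------------------------------------------
    if cohort is None:
        mrna = read_omics_matrix(config.mrna_path, "mRNA")
        cna = read_omics_matrix(config.cna_path, "CNA")
        met = read_omics_matrix(config.met_path, "MET")
        clinical = read_clinical(config.clinical_path)
        cohort = preprocess_cohort(
            mrna, cna, met, clinical,
            max_missing_frac=config.max_missing_frac,
            knn_k=config.knn_k,
            truncate_months=config.truncate_months,
        )
    _write_tsv(cohort_manifest(cohort), run_dir / "cohort_manifest.tsv")
    log.record("preprocess", n_samples=cohort.n_samples,
               shapes={k: m.shape for k, m in cohort.omics().items()},
               elapsed=_time.time() - t0)

    # --- correlated-gene selection -----------------------------------------
    t = _time.time()
    cna_recs = genecor.pairwise_gene_correlation(cohort.cna, cohort.mrna)
    met_recs = genecor.pairwise_gene_correlation(cohort.met, cohort.mrna)
    cna_sel = genecor.select_correlated_genes(cna_recs, config.alpha_correlation, config.sign_constraint)
    met_sel = genecor.select_correlated_genes(met_recs, config.alpha_correlation, config.sign_constraint)
    _write_tsv(cna_sel.to_frame(), run_dir / "correlation_cna_mrna.tsv")
    _write_tsv(met_sel.to_frame(), run_dir / "correlation_met_mrna.tsv")
    shared_full, n_shared_full = genecor.intersect_gene_sets(cna_sel.selected, met_sel.selected)
    summary = {
        "cna": {"n_selected": len(cna_sel.selected), "skewness": cna_sel.skewness, "skew_p": cna_sel.skew_p},
        "met": {"n_selected": len(met_sel.selected), "skewness": met_sel.skewness, "skew_p": met_sel.skew_p},
        "intersection_full": n_shared_full,
    }
    log.record("genecor", **summary, elapsed=_time.time() - t)

    # --- prognostic gene filter (score test on omics values) ---------------
    t = _time.time()
    cnacor = survival.cox_feature_select(
        cohort.cna.select_genes(cna_sel.selected), cohort.clinical, config.alpha_cox
    ) if cna_sel.selected else []
    metcor = survival.cox_feature_select(
        cohort.met.select_genes(met_sel.selected), cohort.clinical, config.alpha_cox
    ) if met_sel.selected else []
    shared_prog, n_shared_prog = genecor.intersect_gene_sets(cnacor, metcor)
    summary["cnacor_prognostic"] = len(cnacor)
    summary["metcor_prognostic"] = len(metcor)
    summary["intersection_prognostic"] = n_shared_prog
    (run_dir / "genecor_summary.json").write_text(json.dumps(summary, indent=1))
    pd.DataFrame({"gene": sorted(cnacor)}).to_csv(run_dir / "cnacor_genes.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": sorted(metcor)}).to_csv(run_dir / "metcor_genes.tsv", sep="\t", index=False)
    log.record("cox_filter", n_cnacor=len(cnacor), n_metcor=len(metcor), elapsed=_time.time() - t)
    if not cnacor or not metcor:
        raise RuntimeError("cox_filter: empty prognostic gene set, cannot cluster")

    # --- clustering ---------------------------------------------------------
    t = _time.time()
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(3)]
    k_range = range(config.k_min, config.k_max + 1)
    cna_mat = cohort.cna.select_genes(cnacor).values.to_numpy().T  # samples x genes
    met_mat = cohort.met.select_genes(metcor).values.to_numpy().T
    kw = dict(
        k_range=k_range, n_perturb=config.n_perturb, noise_scale=config.noise_scale,
        n_restarts=config.kmeans_restarts, linkage_method=config.linkage,
    )
    single_cna = perturbation.single_subtype(cna_mat, cohort.sample_ids, seed=stage_seeds[0], **kw)
    single_met = perturbation.single_subtype(met_mat, cohort.sample_ids, seed=stage_seeds[1], **kw)

    mrna_for_integration = cohort.mrna
    if config.filter_mrna_by_cox:
        keep = survival.cox_feature_select(cohort.mrna, cohort.clinical, config.alpha_cox)
        mrna_for_integration = cohort.mrna.select_genes(keep)
    integrated = perturbation.integrate_subtype(
        [mrna_for_integration.values.to_numpy().T, cna_mat, met_mat],
        cohort.sample_ids, seed=stage_seeds[2], **kw,
    )
    for name, res in (("cna", single_cna), ("met", single_met), ("integrated", integrated)):
        _write_tsv(res.labels_frame(), run_dir / f"labels_{name}.tsv")
        _write_tsv(res.trace.to_frame(), run_dir / f"trace_{name}.tsv")
        pd.DataFrame(
            res.connectivity.values,
            index=res.connectivity.sample_ids,
            columns=res.connectivity.sample_ids,
        ).to_csv(run_dir / f"connectivity_{name}.tsv", sep="\t", float_format="%.10g")
    log.record(
        "clustering",
        k_star={"cna": single_cna.k_star, "met": single_met.k_star, "integrated": integrated.k_star},
        auc_max={n: max(r.trace.auc) for n, r in
                 (("cna", single_cna), ("met", single_met), ("integrated", integrated))},
        elapsed=_time.time() - t,
    )

    # --- subgroup survival and overlap tests --------------------------------
    t = _time.time()
    labels = integrated.labels
    lr_stat, lr_p = survival.logrank_test(labels, cohort.clinical)
    curves = survival.km_curve(labels, cohort.clinical)
    km_rows = [
        {"group": grp, "time": ti, "survival": si, "at_risk": ri}
        for grp, curve in curves.items()
        for ti, si, ri in zip(curve.times, curve.survival, curve.at_risk)
    ]
    _write_tsv(pd.DataFrame(km_rows), run_dir / "km_integrated.tsv")
    overlaps = {}
    for name, res in (("cna", single_cna), ("met", single_met)):
        try:
            chi2, p = perturbation.overlap_chi2(labels, res.labels)
            overlaps[name] = {"chi2": chi2, "p": p}
        except ValueError as exc:
            overlaps[name] = {"error": str(exc)}
    # subgroup hazard ratio from a Cox fit on the subgroup indicator
    subgroup_hr = None
    if len(np.unique(labels)) == 2:
        from lifelines import CoxPHFitter

        df = pd.DataFrame({
            "time": cohort.clinical.data["os_time"].to_numpy(float),
            "event": np.where(
                pd.isna(cohort.clinical.data["os_event"].to_numpy()), False,
                cohort.clinical.data["os_event"].to_numpy(),
            ).astype(int),
            "grp": (labels == np.unique(labels)[1]).astype(float),
        })
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        coef = float(cph.params_["grp"]); se = float(cph.standard_errors_["grp"])
        subgroup_hr = {
            "hr": float(np.exp(coef)),
            "ci_low": float(np.exp(coef - 1.959963984540054 * se)),
            "ci_high": float(np.exp(coef + 1.959963984540054 * se)),
        }
    log.record("subgroup_survival", logrank_p=lr_p, overlaps=overlaps, elapsed=_time.time() - t)

    # --- median-split univariate Cox on the prognostic panels ---------------
    t = _time.time()
    cox_tables = {}
    for name, genes in (("cnacor", cnacor), ("metcor", metcor)):
        recs = survival.univariate_cox_median(
            cohort.mrna.select_genes([g for g in genes if g in set(cohort.mrna.gene_ids)]),
            cohort.clinical, alpha=config.alpha_cox, q_alpha=config.alpha_q,
        ) if genes else []
        frame = survival.survival_records_frame(recs)
        _write_tsv(frame, run_dir / f"cox_median_{name}.tsv")
        cox_tables[name] = int(frame["significant"].sum()) if len(frame) else 0
    log.record("cox_median", n_significant=cox_tables, elapsed=_time.time() - t)

    # --- subgroup-specific genes --------------------------------------------
    t = _time.time()
    specific_counts = {}
    panels = (
        ("expression", cohort.mrna, None),
        ("cna", cohort.cna, cnacor),
        ("met", cohort.met, metcor),
    )
    for name, matrix, candidates in panels:
        recs = subgroup_genes.assign_specific_genes(
            matrix, labels, alpha=config.alpha_anova, candidate_genes=candidates
        )
        frame = subgroup_genes.specific_genes_frame(recs)
        _write_tsv(frame, run_dir / f"specific_genes_{name}.tsv")
        sig = frame[frame["significant"]]
        specific_counts[name] = sig.groupby("assigned_subgroup").size().to_dict()
    log.record("specific_genes", counts=specific_counts, elapsed=_time.time() - t)

    # --- downstream characterization ----------------------------------------
    t = _time.time()
    summaries = downstream.summarize_subgroups(cohort.clinical, labels)
    _write_tsv(downstream.summaries_frame(summaries), run_dir / "subgroup_summary.tsv")
    age_split = downstream.age_split_survival(cohort.clinical, labels, config.age_threshold)
    burden = downstream.cna_burden(cohort.cna, config.burden_threshold)
    report: dict = {
        "n_samples": cohort.n_samples,
        "k_star": int(integrated.k_star),
        "subgroup_sizes": {int(s.subgroup): s.n for s in summaries},
        "logrank": {"statistic": lr_stat, "p": lr_p},
        "subgroup_hr": subgroup_hr,
        "overlap_chi2": overlaps,
        "age_split_logrank": {str(k): v for k, v in age_split.items()},
        "specific_gene_counts": {k: {str(kk): int(vv) for kk, vv in v.items()}
                                 for k, v in specific_counts.items()},
        "genecor_summary": summary,
        "cox_median_significant": cox_tables,
    }
    if len(np.unique(labels)) == 2:
        cmp = downstream.compare_burden(burden, labels)
        report["cna_burden"] = {"group_means": {str(k): v for k, v in cmp.group_means.items()},
                                "t": cmp.t_stat, "p": cmp.p}
        try:
            reg = downstream.subgroup_omics_regression(
                labels, burden.to_numpy(), cohort.met.values.mean(axis=0).to_numpy()
            )
            report["regression"] = {"coefficients": reg.coefficients, "p_values": reg.p_values,
                                    "note": reg.note}
        except ValueError as exc:
            report["regression"] = {"error": str(exc)}
    try:
        ct = downstream.crosstab_pam50(labels, cohort.clinical)
        ct.to_csv(run_dir / "pam50_crosstab.tsv", sep="\t", float_format="%.10g")
        report["pam50_crosstab"] = {str(i): row.to_dict() for i, row in ct.iterrows()}
    except ValueError:
        report["pam50_crosstab"] = None
    burden.to_frame().reset_index(names="sample_id").to_csv(
        run_dir / "cna_burden.tsv", sep="\t", index=False, float_format="%.10g"
    )
    log.record("downstream", elapsed=_time.time() - t)

    (run_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True, default=float))

    numeric_outputs = sorted(p for p in run_dir.glob("*.tsv"))
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": {p.name: _hash_file(p) for p in numeric_outputs},
        "report_hash": _hash_file(run_dir / "report.json"),
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    log.record("done", elapsed=_time.time() - t0)
    return run_dir
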