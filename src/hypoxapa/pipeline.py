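"""End-to-end orchestration of the hypoxia-APA analysis.

Stage order: synthetic data (optional) -> PDUI quantification -> enrichment
scoring -> hypoxic/normoxic classification -> differential screen -> HSS
model -> miRNA competition -> survival/drug association (-> single-cell
mode).  Every stage writes its table under the output directory; a metrics
JSON collects the headline numbers and a manifest records the full config,
the seed fan-out and per-stage row counts, sufficient to re-run any stage
in isolation.

Module thresholds default to the published analysis parameters: <60%
missing / <40% constant informativeness, mean expression >= 1, nominal
P < 0.010 with |log2FC| > 0.050, |R| > 0.1, 10 CV folds, >20 cells.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
import zlib

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .apa_quant import filter_expressed_genes, filter_informative_events, pdui_matrix
from .diff_screen import differential_table, screen_candidates
from .enrichment import GeneSet, score_matrix
from .hss_model import associate_hss, compute_hss, evaluate_auc, fit_hss
from .hypoxia_class import classify_samples
from .mirna_competition import find_competing_genes, shared_mirna_overlap, sites_lost
from .sc_apa import compare_group_pdui, filter_sc_events, per_cell_pdui, pseudobulk_breakpoints
from .surv_drug import drug_association, logrank_test, treatment_stratified_survival
from .syndata import SimConfig, simulate_cohort, simulate_single_cells

log = logging.getLogger("hypoxapa")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (stage-name hashed) below 2**31."""
    return (seed ^ zlib.crc32(stage.encode())) % (2**31)


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    # input paths (ignored under simulate)
    coverage_dir: str | None = None
    utr_bed: str | None = None
    expression: str | None = None
    signatures_gmt: str | None = None
    hypoxia_gmt: str | None = None
    clinical: str | None = None
    ic50: str | None = None
    mirna_sites: str | None = None
    mirna_targets: str | None = None
    # module parameters (published defaults)
    max_missing_frac: float = 0.60
    max_constant_frac: float = 0.40
    min_mean_expression: float = 1.0
    min_total_reads: float = 30.0
    p_max: float = 0.010
    lfc_min: float = 0.050
    r_min: float = 0.1
    n_folds: int = 10
    freq_min: float = 0.5
    nmf_k: int = 2
    nmf_restarts: int = 10
    sc_min_cells: int = 20
    sc_min_reads: float = 5.0
    single_cell: bool = True
    # simulation conditions
    sim: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {exc}")
        self.stage = stage


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def run_pipeline(config: PipelineConfig, out_dir: str, simulate: bool = False) -> dict:
    """Run every stage; returns the metrics dict (also written as JSON)."""
    os.makedirs(out_dir, exist_ok=True)
    metrics: dict = {}
    manifest: dict = {
        "version": __version__, "config": config.to_dict(),
        "simulate": simulate, "stages": {},
    }
    t0 = time.time()
    stage = "syndata"
    try:
        if simulate:
            sim_kwargs = dict(config.sim)
            sim_kwargs.setdefault("seed", stage_seed(config.seed, "syndata"))
            sim_kwargs.setdefault("make_coverage", True)
            cohort = simulate_cohort(SimConfig(**sim_kwargs))
            expr = cohort.expression
            labels_true = cohort.labels_true
            survival = cohort.survival
            ic50 = cohort.ic50
            utrs = cohort.utrs
            coverage = cohort.coverage
            sites = cohort.mirna_sites
            targets = cohort.mirna_targets
            signatures = {n: cohort.gene_sets[n] for n in ("WINTER", "BUFFA", "RAGNUM")}
            hypoxia_set = GeneSet.from_iterable("HYPOXIA", cohort.gene_sets["HYPOXIA"])
            validation_sets = {n: cohort.gene_sets[n] for n in ("HYPOXIA", "EMT", "GLYCOLYSIS")}
            io.write_matrix(expr, os.path.join(out_dir, "expression.tsv"))
            io.write_bed6(utrs.values(), os.path.join(out_dir, "utrs.bed"))
            io.write_gmt(cohort.gene_sets, os.path.join(out_dir, "gene_sets.gmt"))
            survival.to_csv(os.path.join(out_dir, "clinical.tsv"), sep="\t")
            sites.to_csv(os.path.join(out_dir, "mirna_sites.tsv"), sep="\t", index=False)
        else:
            required = {"coverage_dir": config.coverage_dir, "utr_bed": config.utr_bed,
                        "expression": config.expression,
                        "signatures_gmt": config.signatures_gmt,
                        "hypoxia_gmt": config.hypoxia_gmt, "clinical": config.clinical}
            missing = [k for k, v in required.items() if not v]
            if missing:
                raise FileNotFoundError(
                    f"missing required inputs {missing}; provide paths in the "
                    "config or run with --simulate"
                )
            cohort = None
            utrs = io.read_bed6(config.utr_bed)
            coverage = io.read_coverage_dir(config.coverage_dir, utrs)
            expr = io.read_matrix(config.expression)
            signatures = io.read_gmt(config.signatures_gmt)
            hyp_sets = io.read_gmt(config.hypoxia_gmt)
            hypoxia_set = GeneSet.from_iterable(*next(iter(hyp_sets.items())))
            validation_sets = hyp_sets
            clin = pd.read_csv(config.clinical, sep="\t", index_col=0)
            survival = clin
            labels_true = None
            ic50 = (pd.read_csv(config.ic50, sep="\t", index_col=0).iloc[:, 0]
                    if config.ic50 else None)
            sites = io.read_sites_table(config.mirna_sites) if config.mirna_sites else None
            targets = io.read_targets_table(config.mirna_targets) if config.mirna_targets else None
        manifest["stages"][stage] = {"n_samples": expr.shape[1], "n_utrs": len(utrs)}
        log.info("[%s] %d samples, %d UTRs", stage, expr.shape[1], len(utrs))

        stage = "apa_quant"
        pdui, breakpoints = pdui_matrix(coverage, utrs, config.min_total_reads)
        pdui_inf = filter_informative_events(
            pdui, config.max_missing_frac, config.max_constant_frac
        )
        expr_f = filter_expressed_genes(expr, config.min_mean_expression)
        io.write_matrix(pdui_inf, os.path.join(out_dir, "pdui.tsv"))
        metrics["n_events_total"] = int(pdui.shape[0])
        metrics["n_events_informative"] = int(pdui_inf.shape[0])
        metrics["n_genes_expressed"] = int(expr_f.shape[0])
        manifest["stages"][stage] = {"rows": int(pdui_inf.shape[0])}
        log.info("[%s] %d/%d informative events", stage, pdui_inf.shape[0], pdui.shape[0])

        stage = "enrichment"
        enr = score_matrix(expr_f, validation_sets)
        io.write_matrix(enr, os.path.join(out_dir, "enrichment.tsv"))
        manifest["stages"][stage] = {"rows": int(enr.shape[0])}

        stage = "hypoxia_class"
        nmf_expr = np.log2(expr_f + 1.0)
        labels_df = classify_samples(
            expr_f, signatures, hypoxia_set,
            k=config.nmf_k, restarts=config.nmf_restarts,
            seed=stage_seed(config.seed, "nmf"), nmf_expr=nmf_expr,
            hypoxia_scores=enr.loc["HYPOXIA"] if "HYPOXIA" in enr.index else None,
        )
        labels_df.to_csv(os.path.join(out_dir, "labels.tsv"), sep="\t")
        labels = labels_df["consensus_label"]
        metrics["n_hypoxic"] = int((labels == "hypoxic").sum())
        metrics["n_normoxic"] = int((labels == "normoxic").sum())
        metrics["n_mixed"] = int((labels == "mixed").sum())
        if labels_true is not None:
            non_mixed = labels.isin(["hypoxic", "normoxic"])
            acc = float((labels[non_mixed] == labels_true[non_mixed]).mean())
            metrics["label_accuracy_non_mixed"] = acc
        manifest["stages"][stage] = dict(metrics_subset=["n_hypoxic", "n_normoxic", "n_mixed"])
        log.info("[%s] %d hypoxic / %d normoxic / %d mixed", stage,
                 metrics["n_hypoxic"], metrics["n_normoxic"], metrics["n_mixed"])

        stage = "diff_screen"
        diff = differential_table(pdui_inf, labels, config.p_max, config.lfc_min)
        diff.to_csv(os.path.join(out_dir, "diff_pdui.tsv"), sep="\t")
        metrics["n_diff_down"] = diff.attrs["n_down"]
        metrics["n_diff_up"] = diff.attrs["n_up"]
        cand = screen_candidates(diff, expr_f, pdui_inf, hypoxia_set,
                                 config.r_min, config.p_max)
        cand.to_csv(os.path.join(out_dir, "candidates.tsv"), sep="\t")
        metrics["n_candidates"] = int(cand.shape[0])
        manifest["stages"][stage] = {"rows": int(diff.shape[0]),
                                     "candidates": int(cand.shape[0])}
        log.info("[%s] %d down / %d up, %d candidates", stage,
                 metrics["n_diff_down"], metrics["n_diff_up"], metrics["n_candidates"])

        stage = "hss_model"
        if metrics["n_candidates"] >= 2:
            model = fit_hss(pdui_inf.loc[cand.index], labels,
                            n_folds=config.n_folds,
                            seed=stage_seed(config.seed, "hss"),
                            freq_min=config.freq_min)
            model.to_json(os.path.join(out_dir, "hss_model.json"))
            hss = compute_hss(model, pdui_inf)
            hss.to_csv(os.path.join(out_dir, "hss.tsv"), sep="\t")
            non_mixed = labels.isin(["hypoxic", "normoxic"])
            metrics["hss_n_events"] = len(model.events)
            metrics["hss_cv_auc_valid"] = model.cv_auc_valid[0]
            metrics["hss_auc_consensus"] = evaluate_auc(
                hss[non_mixed], labels[non_mixed]
            )
            assoc = associate_hss(hss, survival,
                                  stage=survival.get("stage"), enrichment=enr)
            metrics["hss_survival_logrank_p"] = assoc.get("survival", {}).get("logrank_p")
        else:
            model, hss = None, None
            log.warning("[%s] <2 candidate events; HSS skipped", stage)
        manifest["stages"][stage] = {"events": metrics.get("hss_n_events", 0)}

        stage = "mirna_competition"
        if sites is not None and cohort is not None:
            target_utr = utrs[cohort.target_event.split("|")[0]]
            ev_bp = breakpoints.get(cohort.target_event, target_utr.breakpoint)
            lost = sites_lost(sites, target_utr, breakpoint=ev_bp)
            comp = find_competing_genes(
                expr_f, cohort.target_gene,
                pdui.loc[cohort.target_event] if cohort.target_event in pdui.index
                else cohort.pdui_observed.loc[cohort.target_event],
                config.r_min, config.p_max,
            )
            comp.to_csv(os.path.join(out_dir, "competing_genes.tsv"), sep="\t")
            overlap = shared_mirna_overlap(lost, targets, cohort.competitor_gene)
            metrics["n_mirnas_lost"] = overlap.n_lost
            metrics["n_mirnas_shared"] = overlap.n_shared
            metrics["mirna_overlap_pct"] = overlap.pct
            metrics["n_competing_genes"] = int(comp.shape[0])
            metrics["competitor_recovered"] = bool(cohort.competitor_gene in comp.index)
        manifest["stages"][stage] = {"lost": metrics.get("n_mirnas_lost", 0)}

        stage = "surv_drug"
        hyp_mask = (labels == "hypoxic").reindex(survival.index, fill_value=False)
        norm_mask = (labels == "normoxic").reindex(survival.index, fill_value=False)
        if hyp_mask.sum() and norm_mask.sum():
            chi2, p = logrank_test(survival.loc[hyp_mask.to_numpy()],
                                   survival.loc[norm_mask.to_numpy()])
            metrics["survival_hyp_vs_norm_logrank_p"] = p
        if ic50 is not None and cohort is not None:
            gene_expr = expr.loc[cohort.target_gene]
            da = drug_association(gene_expr, ic50)
            metrics["ic50_expression_r"] = da["r"]
            ev = cohort.target_event
            ev_pdui = (pdui.loc[ev] if ev in pdui.index
                       else cohort.pdui_observed.loc[ev])
            da2 = drug_association(ev_pdui, ic50)
            metrics["ic50_pdui_r"] = da2["r"]
            strat = treatment_stratified_survival(survival, ev_pdui)
            if strat.get("treated"):
                metrics["treated_logrank_p"] = strat["treated"]["logrank_p"]
        manifest["stages"][stage] = {"done": True}

        stage = "sc_apa"
        if config.single_cell and simulate:
            sc_kwargs = dict(config.sim)
            sc_kwargs.setdefault("seed", stage_seed(config.seed, "sc"))
            sc_kwargs.setdefault("dropout", 0.6)
            sc_kwargs.pop("make_coverage", None)
            cells = simulate_single_cells(SimConfig(**sc_kwargs, make_coverage=False))
            bps = pseudobulk_breakpoints(cells.coverage, cells.utrs)
            cell_mat = per_cell_pdui(cells.coverage, cells.utrs, bps, config.sc_min_reads)
            retained = filter_sc_events(cell_mat, cells.labels, config.sc_min_cells)
            sc_cmp = compare_group_pdui(retained, cells.labels)
            sc_cmp.to_csv(os.path.join(out_dir, "sc_events.tsv"), sep="\t")
            metrics["sc_n_events_retained"] = int(retained.shape[0])
            metrics["sc_mean_pdui_hypoxic"] = float(np.nanmean(sc_cmp["mean_hypoxic"]))
            metrics["sc_mean_pdui_normoxic"] = float(np.nanmean(sc_cmp["mean_normoxic"]))
            manifest["stages"][stage] = {"rows": int(sc_cmp.shape[0])}
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        manifest["failed_stage"] = stage
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=_json_default, sort_keys=True)
        raise StageError(stage, exc) from exc

    manifest["runtime_s"] = round(time.time() - t0, 2)
    with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=2, default=_json_default, sort_keys=True)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default, sort_keys=True)
    log.info("pipeline complete in %.1fs", manifest["runtime_s"])
    return metrics
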