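"""End-to-end orchestration: simulate/load -> preprocess -> differential
methylation -> CIMP -> regulation screens -> specificity cascade ->
progressive diagnostic model.

A single :class:`PipelineConfig` (YAML-serializable) drives the run; the
manifest records every artifact path, per-stage counts, the config hash
and all seeds, and re-running the same config reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from methylmark import cimp as cimp_mod
from methylmark import diagnostic, diffmeth, io, markers, preprocess, regulation, simulate

log = logging.getLogger("methylmark")

DEFAULT_THRESHOLDS = {
    "delta_beta": 0.2,
    "site_fdr": 0.01,
    "deg_log2fc": 1.0,
    "deg_fdr": 0.01,
    "correlation_alpha": 0.05,
    "cimp_sd": 0.2,
    "cimp_normal_mean": 0.05,
}


@dataclass
class PipelineConfig:
    """Either a simulation block or real-data paths, plus thresholds and seeds."""

    target_cohort: str = "BRCA"
    simulation: simulate.SimulationConfig | None = None
    beta_path: str | None = None
    annotation_path: str | None = None
    sheet_path: str | None = None
    counts_path: str | None = None
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    k_range: list = field(default_factory=lambda: [2, 3, 4, 5, 6])
    seed: int = 0
    test_fraction: float = 0.3
    consensus_resamples: int = 50

    def validate(self) -> None:
        real = [self.beta_path, self.annotation_path, self.sheet_path]
        if self.simulation is not None and any(p is not None for p in real):
            raise ValueError("config must give either a simulation block or "
                             "real-data paths, not both")
        if self.simulation is None and not all(p is not None for p in real):
            raise ValueError("real-data mode needs beta, annotation and sheet paths")
        thr = {**DEFAULT_THRESHOLDS, **self.thresholds}
        for key in ("delta_beta", "site_fdr", "deg_fdr", "correlation_alpha",
                    "cimp_sd", "cimp_normal_mean"):
            if not 0 < thr[key] <= 1:
                raise ValueError(f"threshold {key} must be in (0, 1], got {thr[key]}")
        if thr["deg_log2fc"] <= 0:
            raise ValueError("deg_log2fc must be positive")
        self.thresholds = thr

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = simulate.SimulationConfig.from_dict(sim)
        return cfg

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "simulation"}
        d["simulation"] = self.simulation.to_dict() if self.simulation else None
        return d


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest: dict = {"config_hash": _config_hash(config), "seed": config.seed,
                      "target_cohort": config.target_cohort,
                      "artifacts": {}, "counts": {}}

    def save(name, writer, *args):
        path = out / name
        writer(*args, path)
        manifest["artifacts"][name.split(".")[0]] = str(path)
        return path

    # ---- inputs -----------------------------------------------------------
    if config.simulation is not None:
        sim = config.simulation
        log.info("simulating cohorts (seed=%d, %d probes)", sim.seed, sim.n_probes)
        annot = simulate.simulate_annotation(sim.n_probes, sim.seed,
                                             snp_frac=sim.snp_frac,
                                             sex_frac=sim.sex_frac,
                                             n_genes=sim.n_genes)
        beta, sheet, truth = simulate.simulate_cohorts(sim, annot)
        counts = simulate.simulate_expression(beta, sheet, annot, truth, sim)
        save("annotation.tsv", io.write_annotation, annot)
        save("beta.tsv", lambda df, p: io.write_matrix(df, p), beta)
        save("sheet.tsv", io.write_sheet, sheet)
        save("counts.tsv", lambda df, p: io.write_matrix(df, p, "gene"), counts)
        save("truth.json", io.write_json, truth.to_dict())
    else:
        beta = io.read_matrix(config.beta_path)
        annot = io.read_annotation(config.annotation_path)
        sheet = io.read_sheet(config.sheet_path)
        counts = io.read_matrix(config.counts_path) if config.counts_path else None
        truth = None

    # ---- preprocess -------------------------------------------------------
    beta, report = preprocess.filter_probes(beta, annot)
    save("filter_report.json", io.write_json, report)
    manifest["counts"]["probes_retained"] = report["n_retained"]

    # ---- differential methylation ----------------------------------------
    target = config.target_cohort
    dmcs_paired = diffmeth.call_dmcs(beta, sheet, mode="paired", cohort=target,
                                     delta_min=thr["delta_beta"],
                                     fdr_max=thr["site_fdr"])
    dmcs_unpaired = diffmeth.call_dmcs(beta, sheet, mode="unpaired", cohort=target,
                                       delta_min=thr["delta_beta"],
                                       fdr_max=thr["site_fdr"])
    save("dmcs_paired.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), dmcs_paired)
    save("dmcs_unpaired.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), dmcs_unpaired)
    hyper = dmcs_paired.index[dmcs_paired["direction"] == "hyper"]
    hypo = dmcs_paired.index[dmcs_paired["direction"] == "hypo"]
    manifest["counts"].update({
        "dmcs_paired": int((dmcs_paired["direction"] != "ns").sum()),
        "dmcs_unpaired": int((dmcs_unpaired["direction"] != "ns").sum()),
        "hyper": len(hyper), "hypo": len(hypo),
    })
    if len(hyper) and len(hypo):
        enr = diffmeth.feature_enrichment(hyper, hypo, annot, "Island")
        save("enrichment_island.json", io.write_json, {
            "feature": enr.feature, "table": list(enr.table),
            "odds_ratio": enr.odds_ratio, "ci95": list(enr.ci95),
            "p_value": enr.p_value})

    # ---- CIMP -------------------------------------------------------------
    t_ids = sheet.index[(sheet["cohort"] == target) & (sheet["tissue"] == "tumor")]
    n_ids = sheet.index[(sheet["cohort"] == target) & (sheet["tissue"] == "adjacent_normal")]
    selected = cimp_mod.select_variable_cpgs(beta[list(t_ids)], beta[list(n_ids)],
                                             sd_min=thr["cimp_sd"],
                                             normal_mean_max=thr["cimp_normal_mean"])
    manifest["counts"]["cimp_selected_cpgs"] = len(selected)
    if len(selected) >= 2:
        subset = beta.loc[selected, list(t_ids)]
        profile = cimp_mod.consensus_cluster(subset, config.k_range,
                                             n_resamples=config.consensus_resamples,
                                             seed=config.seed)
        assignment = cimp_mod.kmeans_cluster(subset, profile.chosen_k, seed=config.seed)
        result = cimp_mod.call_cimp(assignment, subset)
        cimp_table = pd.DataFrame({"sample_id": assignment.index,
                                   "cluster": assignment.to_numpy(),
                                   "cimp": result.cimp_flags.to_numpy()})
        save("cimp.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), cimp_table)
        save("consensus.json", io.write_json, {
            "k_range": profile.k_range, "pac": profile.pac,
            "mean_consensus": profile.mean_consensus, "chosen_k": profile.chosen_k})
        manifest["counts"]["cimp_k"] = profile.chosen_k
        manifest["counts"]["cimp_samples"] = int(result.cimp_flags.sum())
        surv = sheet.loc[t_ids]
        if surv["os_days"].notna().all():
            groups = result.cimp_flags.map({True: "CIMP", False: "non-CIMP"})
            _, stat, p = cimp_mod.km_logrank(surv, groups)
            manifest["counts"]["cimp_logrank_p"] = p

    # ---- regulation -------------------------------------------------------
    if counts is not None:
        target_sheet = sheet[sheet["cohort"] == target]
        degs = regulation.call_degs(counts, target_sheet,
                                    log2fc_min=thr["deg_log2fc"],
                                    fdr_max=thr["deg_fdr"])
        save("degs.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), degs)
        expr = regulation.log2_cpm(counts)
        cis = regulation.cis_correlation(beta, expr, annot, dmcs_paired,
                                         alpha=thr["correlation_alpha"])
        trans = regulation.trans_correlation(beta, expr, annot, dmcs_paired, degs,
                                             alpha=thr["correlation_alpha"],
                                             max_pairs=20000, seed=config.seed)
        save("correlations_cis.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), cis)
        save("correlations_trans.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), trans)
        both = pd.concat([cis, trans], ignore_index=True)
        if len(both):
            bias = regulation.bias_summary(both, dmcs_paired["direction"],
                                           degs["direction"])
            save("bias_summary.json", io.write_json, bias.to_dict(orient="records"))
        manifest["counts"].update({
            "degs": int((degs["direction"] != "ns").sum()),
            "cis_pairs": len(cis), "trans_pairs": len(trans),
        })

    # ---- specificity cascade ---------------------------------------------
    panel = markers.cascade_filter(beta, sheet, target,
                                   delta_min=thr["delta_beta"],
                                   fdr_max=thr["site_fdr"])
    save("marker_panel.tsv", lambda df, p: df.to_csv(p, sep="\t", index_label="probe_id"),
         panel.flags)
    (out / "markers.txt").write_text("\n".join(panel.final) + "\n")
    manifest["artifacts"]["markers"] = str(out / "markers.txt")
    manifest["counts"]["cascade"] = panel.stage_counts
    manifest["counts"]["final_markers"] = len(panel.final)

    # ---- diagnostic model -------------------------------------------------
    if len(panel.final) >= 1:
        X = beta.loc[panel.final, list(t_ids) + list(n_ids)].T
        y = pd.Series(np.r_[np.ones(len(t_ids)), np.zeros(len(n_ids))], index=X.index)
        idx_tr, idx_te = train_test_split(np.arange(len(X)),
                                          test_size=config.test_fraction,
                                          random_state=config.seed, stratify=y)
        X_tr, y_tr = X.iloc[idx_tr], y.iloc[idx_tr]
        X_te, y_te = X.iloc[idx_te], y.iloc[idx_te]
        ranking = diagnostic.rank_features(beta.loc[panel.final, X_tr.index], y_tr)
        save("feature_ranking.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False),
             ranking)
        progression = diagnostic.progressive_evaluation(
            ranking["probe_id"].tolist(), (X_tr, y_tr), (X_te, y_te),
            k_max=len(panel.final))
        save("progressive_auc.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), progression)
        model = diagnostic.fit_logistic(X_tr[ranking["probe_id"].tolist()], y_tr)
        model.ranked_probes = list(zip(ranking["probe_id"], ranking["ig"]))
        model.to_json(out / "model.json")
        manifest["artifacts"]["model"] = str(out / "model.json")
        cohort_betas = {}
        for cohort, grp in sheet.groupby("cohort"):
            if cohort == target:
                continue
            cohort_betas[cohort] = {
                tissue: beta.loc[panel.final, ids.index].T
                for tissue, ids in grp.groupby("tissue") if len(ids)
            }
        if cohort_betas:
            mis = diagnostic.cross_cohort_misclassification(model, cohort_betas)
            save("misclassification.tsv",
                 lambda df, p: df.to_csv(p, sep="\t", index=False), mis)
        manifest["counts"]["auc_by_k"] = dict(
            zip(progression["k"].astype(int), progression["auc"].round(6)))
        if truth is not None:
            planted = set(truth.marker_probe_ids)
            found = set(panel.final)
            manifest["counts"]["marker_recovery"] = {
                "planted": len(planted),
                "recovered": len(planted & found),
                "false_positives": len(found - planted),
            }

    io.write_json(manifest, out / "manifest.json")
    return manifest
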