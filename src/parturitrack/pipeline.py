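"""End-to-end orchestration: simulate/ingest -> normalize -> QC -> DE ->
OSC-PLS transfer -> clustering -> cross-species comparison.

The stages always run in this fixed order; every intermediate can be
persisted as TSV/JSON and the whole run is a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusterprof, counts as counts_mod, de, mva, qc, simdata, xspecies

log = logging.getLogger("parturitrack")

MODEL_CONTRASTS = {
    "term": [("E16", "E18"), ("E16", "LAB"), ("E18", "LAB")],
    "ru486": [("6h_RU486", "18h_RU486"), ("6h_RU486", "LAB_RU486"),
              ("18h_RU486", "LAB_RU486")],
    "lps": [("2h_LPS", "6h_LPS"), ("2h_LPS", "LAB_LPS"), ("6h_LPS", "LAB_LPS")],
}

VEHICLE_CONTRASTS = {
    "ru486": [("6h_DMSO", "6h_RU486")],
    "lps": [("2h_PBS", "2h_LPS")],
}

MODELS = ("term", "ru486", "lps")


@dataclass
class PipelineConfig:
    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    counts_path: str | None = None          # ingest instead of simulating
    sample_sheet_path: str | None = None
    fdr_cutoff: float = 0.001
    wave_fdr_cutoff: float = 0.01
    qc_alpha: float = 0.01                  # <= 0 disables outlier exclusion
    n_osc: int = 1
    k_range: tuple = (2, 10)
    loading_k_range: tuple = (2, 12)
    run_clustering: bool = True
    run_human: bool = True
    human_frac_core: float = 1.0
    human_frac_lps: float = 0.7
    human_frac_ru486: float = 0.2
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for cut in (self.fdr_cutoff, self.wave_fdr_cutoff):
            if not 0.0 < cut < 1.0:
                raise ValueError("FDR cutoffs must lie in (0, 1)")


def _treated_ids(cm: counts_mod.CountMatrix, model: str) -> list[str]:
    s = cm.samples
    mask = (s["model"] == model) & (s["treatment"].isin(["none", "RU486", "LPS"]))
    return list(s.index[mask])


def mouse_analysis(cm: counts_mod.CountMatrix, config: PipelineConfig) -> dict:
    """Normalization, QC, DE, trajectory models and transfer matrix for the
    three mouse parturition models."""
    cm = counts_mod.drop_zero_genes(cm)

    # QC: per-model centroid-distance outliers on log-CPM
    nf0 = counts_mod.tmm_factors(cm)
    em0 = counts_mod.log_cpm(cm, nf0)
    excluded: list[str] = []
    qc_report = None
    if config.qc_alpha > 0:
        qc_report = qc.centroid_outliers(em0, cm.samples["model"], alpha=config.qc_alpha)
        excluded = list(qc_report.index[qc_report["flagged"]])
        if excluded:
            log.info("QC excluded samples: %s", excluded)
            cm = cm.subset_samples([s for s in cm.sample_ids if s not in excluded])
            cm = counts_mod.drop_zero_genes(cm)
    nf = counts_mod.tmm_factors(cm)
    em = counts_mod.log_cpm(cm, nf)

    contrasts: dict[str, de.ContrastResult] = {}
    unions: dict[str, de.DEGSet] = {}
    for model in MODELS:
        ids = list(cm.samples.index[cm.samples["model"] == model])
        sub = cm.subset_samples(ids)
        disp = de.estimate_dispersion(sub, sub.samples["group"],
                                      nf=None)
        model_results = []
        for ga, gb in MODEL_CONTRASTS[model]:
            res = de.exact_test(sub, counts_mod.NormFactors(
                nf.factors.loc[ids] / np.exp(np.mean(np.log(nf.factors.loc[ids]))),
                sub.lib_sizes), disp, ga, gb)
            contrasts[res.label] = res
            model_results.append(res)
        unions[model] = de.model_deg_union(model_results, model, config.fdr_cutoff)

    venn = de.overlap_partition([unions[m] for m in MODELS])
    union_genes = sorted(set().union(*[unions[m].genes for m in MODELS]))

    models: dict[str, mva.OscPlsModel] = {}
    data: dict[str, tuple[pd.DataFrame, np.ndarray]] = {}
    transfer = None
    if union_genes:
        for model in MODELS:
            ids = _treated_ids(cm, model)
            sub_em = em.loc[union_genes, ids]
            y = cm.samples.loc[ids, "pseudotime"].to_numpy(float)
            data[model] = (sub_em, y)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                models[model] = mva.fit_oscpls(sub_em, y, n_osc=config.n_osc, label=model)
        transfer = mva.pairwise_transfer_matrix(models, data)

    clusters: dict[str, clusterprof.ClusterResult] = {}
    if config.run_clustering and union_genes:
        for model in MODELS:
            genes = sorted(unions[model].genes)
            if len(genes) <= config.k_range[1]:
                continue
            ids = _treated_ids(cm, model)
            groups = cm.samples.loc[ids, "group"]
            order = list(dict.fromkeys(groups))
            means = pd.DataFrame(
                {g: em.loc[genes, groups.index[groups == g]].mean(axis=1) for g in order})
            try:
                clusters[model] = clusterprof.ward_cluster(
                    means, k_range=range(config.k_range[0], config.k_range[1] + 1))
            except clusterprof.DegenerateInputError:
                log.warning("degenerate cluster input for model %s", model)

    return {"counts": cm, "norm": nf, "expr": em, "qc": qc_report,
            "excluded": excluded, "contrasts": contrasts, "unions": unions,
            "venn": venn, "union_genes": union_genes, "models": models,
            "model_data": data, "transfer": transfer, "clusters": clusters}


def human_analysis(mouse_result: dict, human_cm: counts_mod.CountMatrix,
                   omap: xspecies.OrthologMap, config: PipelineConfig) -> dict:
    """Human DE, shared ortholog set, cross-species transfer and loading
    clusters."""
    human_cm = counts_mod.drop_zero_genes(human_cm)
    nf = counts_mod.tmm_factors(human_cm)
    em = counts_mod.log_cpm(human_cm, nf)
    disp = de.estimate_dispersion(human_cm, human_cm.samples["group"])
    res = de.exact_test(human_cm, nf, disp, "NIL", "IL")
    human_degs = res.deg_set(config.fdr_cutoff)

    shared = xspecies.shared_degs(mouse_result["union_genes"], human_degs.genes, omap)
    out = {"human_contrast": res, "human_degs": human_degs, "shared": shared,
           "transfers": None, "loadings": None, "loading_clusters": None}
    if shared.empty:
        return out
    y = xspecies.harmonize_pseudotime(human_cm.samples["group"]).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        transfers, loadings = xspecies.human_transfer(
            mouse_result["model_data"], em, y, shared, n_osc=config.n_osc)
    out["transfers"] = transfers
    out["loadings"] = loadings
    if config.run_clustering and loadings.shape[0] > config.loading_k_range[1]:
        try:
            out["loading_clusters"] = xspecies.loading_clusters(
                loadings, k_range=range(config.loading_k_range[0],
                                        config.loading_k_range[1] + 1))
        except clusterprof.DegenerateInputError:
            log.warning("degenerate loading-cluster input")
    return out


def early_late_waves(contrasts: dict[str, de.ContrastResult],
                     fdr: float = 0.01) -> dict:
    """Early/late gene waves shared between term gestation and the RU486
    6h->18h window.

    early = DEGs(E16 vs E18) ∩ DEGs(6h vs 18h RU486);
    late  = DEGs(E18 vs LAB) ∩ DEGs(6h vs 18h RU486);
    fractions are relative to the term-contrast set sizes.
    """
    needed = ["E16_vs_E18", "E18_vs_LAB", "6h_RU486_vs_18h_RU486"]
    missing = [k for k in needed if k not in contrasts]
    if missing:
        raise KeyError(f"missing contrasts: {missing}")
    sets = {k: contrasts[k].deg_set(fdr).genes for k in needed}
    early = sets["E16_vs_E18"] & sets["6h_RU486_vs_18h_RU486"]
    late = sets["E18_vs_LAB"] & sets["6h_RU486_vs_18h_RU486"]
    return {
        "early": early, "late": late,
        "early_fraction": len(early) / len(sets["E16_vs_E18"]) if sets["E16_vs_E18"] else 0.0,
        "late_fraction": len(late) / len(sets["E18_vs_LAB"]) if sets["E18_vs_LAB"] else 0.0,
        "term_early_size": len(sets["E16_vs_E18"]),
        "term_late_size": len(sets["E18_vs_LAB"]),
    }


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return a machine-readable report."""
    if config.counts_path is not None:
        cm = counts_mod.read_counts(config.counts_path, config.sample_sheet_path)
        truth = None
    else:
        cm, truth = simdata.simulate_mouse_models(config.sim)
    log.info("stage simulate/ingest: %d genes x %d samples", *cm.counts.shape)

    mouse = mouse_analysis(cm, config)
    log.info("stage mouse analysis: %d union DEGs, %d samples excluded",
             len(mouse["union_genes"]), len(mouse["excluded"]))

    human = None
    if config.run_human and truth is not None:
        hcm, omap_df, _ = simdata.simulate_human_labor(
            config.sim, truth, frac_core=config.human_frac_core,
            frac_lps=config.human_frac_lps, frac_ru486=config.human_frac_ru486)
        human = human_analysis(mouse, hcm, xspecies.OrthologMap(omap_df), config)
        log.info("stage human analysis: %d shared orthologs", len(human["shared"]))

    waves = None
    try:
        waves = early_late_waves(mouse["contrasts"], config.wave_fdr_cutoff)
    except KeyError:
        pass

    report = {
        "n_genes": int(mouse["counts"].counts.shape[0]),
        "n_samples": int(mouse["counts"].counts.shape[1]),
        "excluded_samples": mouse["excluded"],
        "deg_counts": {label: int((r.table["fdr"] < config.fdr_cutoff).sum())
                       for label, r in mouse["contrasts"].items()},
        "model_union_sizes": {m: len(mouse["unions"][m].genes) for m in MODELS},
        "venn_cells": dict(sorted(mouse["venn"]["cells"].items())),
        "core_up": len(mouse["venn"]["core_up"]),
        "core_down": len(mouse["venn"]["core_down"]),
        "transfer": (None if mouse["transfer"] is None
                     else mouse["transfer"].round(6).to_dict(orient="records")),
        "cluster_k": {m: c.k for m, c in mouse["clusters"].items()},
    }
    if waves is not None:
        report["early_fraction"] = round(waves["early_fraction"], 6)
        report["late_fraction"] = round(waves["late_fraction"], 6)
    if human is not None:
        report["human_deg_count"] = len(human["human_degs"].genes)
        report["shared_ortholog_count"] = int(len(human["shared"]))
        if human["transfers"]:
            ranking = sorted(human["transfers"], key=lambda t: -t.r)
            report["human_transfer"] = {t.train_label: round(t.r, 6)
                                        for t in human["transfers"]}
            report["human_best_training_model"] = ranking[0].train_label
        if human["loading_clusters"] is not None:
            report["loading_cluster_k"] = human["loading_clusters"].k

    if config.out_dir:
        _persist(config, mouse, human, report)
    return {"report": report, "mouse": mouse, "human": human, "waves": waves}


def _persist(config: PipelineConfig, mouse: dict, human: dict | None,
             report: dict) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts_mod.write_counts(mouse["counts"], out / "counts.tsv", out / "samples.tsv")
    mouse["expr"].to_csv(out / "log_cpm.tsv", sep="\t")
    if mouse["qc"] is not None:
        mouse["qc"].to_csv(out / "qc_report.tsv", sep="\t")
    for label, res in mouse["contrasts"].items():
        res.table.to_csv(out / f"contrast_{label}.tsv", sep="\t", index_label="gene_id")
    if mouse["transfer"] is not None:
        mouse["transfer"].to_csv(out / "transfer_matrix.tsv", sep="\t", index=False)
    for model, m in mouse["models"].items():
        (out / f"oscpls_{model}.json").write_text(json.dumps(m.to_dict()))
    if human is not None and human["loadings"] is not None:
        human["loadings"].to_csv(out / "human_loadings.tsv", sep="\t",
                                 index_label="gene_id")
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
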