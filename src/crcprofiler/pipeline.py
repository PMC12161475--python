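"""Umbrella orchestration: simulate -> score -> purity/ploidy -> cohort ->
activities -> cluster -> baskets -> report.

Each stage reads and writes plain TSV/GMT/YAML files in the run directory,
so stages can also be run individually from the command line. A manifest
records the stages executed, the seed, the configuration hash and the main
output files; a rerun with the same configuration and seed reproduces every
output byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, activity, cnaploidy, cohort, io, strat, synth, varscore
from .config import PipelineConfig

log = logging.getLogger("crcprofiler")

STAGES = ("simulate", "score", "purity_ploidy", "cohort", "activities",
          "cluster", "baskets")


def setup_logging(outdir: Path | None = None, verbose: bool = True) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(outdir / "run.log", mode="a"))
    logging.basicConfig(level=logging.INFO if verbose else logging.WARNING,
                        format="%(asctime)s %(levelname)s %(message)s",
                        handlers=handlers, force=True)


def stage_simulate(cfg: PipelineConfig, outdir: Path,
                   n_patients: int = 30, msi_fraction: float = 0.25) -> dict:
    """Generate the synthetic cohort and write every input table."""
    data = synth.gen_cohort(n_patients=n_patients, msi_fraction=msi_fraction,
                            seed=cfg.seed)
    h = cfg.config_hash()
    io.write_table(data["variants"], outdir / "variants.tsv", h)
    io.write_table(data["patients"], outdir / "patients.tsv", h)
    io.write_matrix(data["counts"], outdir / "counts.tsv", h)
    io.write_table(data["network"], outdir / "network.tsv", h)
    io.write_matrix(data["pathway_weights"], outdir / "pathway_weights.tsv", h)
    fx = data["fixtures"]
    io.write_table(fx["knowledgebase"], outdir / "knowledgebase.tsv", h)
    io.write_table(fx["basket_map"], outdir / "basket_map.tsv", h)
    (outdir / "drivers.txt").write_text("\n".join(fx["drivers"]) + "\n")
    io.write_table(fx["mane"], outdir / "mane.tsv", h)
    io.write_gmt(fx["gene_sets"], outdir / "gene_sets.gmt")
    segdir = outdir / "segments"
    segdir.mkdir(parents=True, exist_ok=True)
    for pid in data["segments"]:
        io.write_table(data["segments"][pid], segdir / f"{pid}.segments.tsv", h)
        io.write_table(data["snps"][pid], segdir / f"{pid}.snps.tsv", h)
    truth = {
        "planted": {k: float(v) for k, v in data["planted"].items()},
        "patients": [
            {"patient_id": t.patient_id, "msi_status_true": t.msi_status_true,
             "tcc_true": t.tcc_true, "ploidy_true": t.ploidy_true,
             "n_mutations_true": t.n_mutations_true}
            for t in data["truths"]],
    }
    (outdir / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))
    log.info("simulate: %d patients, %d variants", n_patients,
             len(data["variants"]))
    return data


def stage_score(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Confidence-filter, recompute expression evidence, score, prioritize."""
    variants = io.read_table(outdir / "variants.tsv")
    counts = io.read_matrix(outdir / "counts.tsv")
    h = cfg.config_hash()
    confident = varscore.filter_confidence(variants, cfg.min_confidence)
    expressed = ((counts >= cfg.expr_min_count).sum(axis=1)
                 >= cfg.expr_min_samples)
    confident = confident.copy()
    confident["ev_expression"] = (
        confident["gene"].map(expressed).fillna(False).astype(float))
    scored = varscore.score_table(confident, cfg.evidence_weights)
    prioritized = varscore.prioritize(scored, cfg.svracas_cutoff)
    io.write_table(scored, outdir / "variants_scored.tsv", h)
    io.write_table(prioritized, outdir / "variants_prioritized.tsv", h)
    drivers = set((outdir / "drivers.txt").read_text().split())
    mutated_drivers = varscore.map_drivers(set(prioritized["gene"]), drivers)
    (outdir / "drivers_mutated.txt").write_text(
        "\n".join(mutated_drivers) + "\n")
    log.info("score: %d confident, %d prioritized, %d driver genes",
             len(confident), len(prioritized), len(mutated_drivers))
    return prioritized


def stage_purity_ploidy(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Per-patient purity/ploidy grid search on the segment tables."""
    segdir = outdir / "segments"
    rows = []
    seg_states = []
    for seg_path in sorted(segdir.glob("*.segments.tsv")):
        pid = seg_path.name.split(".")[0]
        seg_df = io.read_table(seg_path)
        snp_df = io.read_table(segdir / f"{pid}.snps.tsv")
        segments = cnaploidy.segments_from_tables(seg_df, snp_df)
        solutions = cnaploidy.estimate_purity_ploidy(
            segments, grid=cfg.grid, n_min=cfg.min_het_snps, max_solutions=5)
        for rank, sol in enumerate(solutions, start=1):
            rows.append((pid, rank, sol.tcc, sol.ploidy, sol.distance))
        top = solutions[0].per_segment.copy()
        top.insert(0, "patient_id", pid)
        seg_states.append(top)
    out = pd.DataFrame(rows, columns=["patient_id", "rank", "tcc", "ploidy",
                                      "distance"])
    h = cfg.config_hash()
    io.write_table(out, outdir / "purity_ploidy.tsv", h)
    io.write_table(pd.concat(seg_states, ignore_index=True),
                   outdir / "segment_states.tsv", h)
    log.info("purity_ploidy: %d patients fitted", out["patient_id"].nunique())
    return out


def stage_cohort(cfg: PipelineConfig, outdir: Path) -> dict:
    """MSI calls, TMB, substitution spectrum, Fisher comparison, ORA."""
    patients = io.read_table(outdir / "patients.tsv")
    variants = io.read_table(outdir / "variants_scored.tsv")
    prioritized = io.read_table(outdir / "variants_prioritized.tsv")
    gene_sets = io.read_gmt(outdir / "gene_sets.gmt")
    h = cfg.config_hash()
    patients = patients.copy()
    patients["msi_status"] = [
        cohort.classify_msi_mantis(s, cfg.mantis_msi, cfg.mantis_mss)
        for s in patients["mantis_score"]]
    roster = list(patients["patient_id"])
    tmb = cohort.compute_tmb(variants, cfg.capture_mb, patients=roster)
    patients = patients.merge(tmb, on="patient_id")
    io.write_table(patients, outdir / "cohort_status.tsv", h)
    spectrum = cohort.substitution_spectrum(variants)
    io.write_table(spectrum.reset_index(), outdir / "spectrum.tsv", h)
    # binary mutation matrix from prioritized variants
    determined = patients.loc[patients["msi_status"] != cohort.UNDETERMINED]
    groups = pd.Series(determined["msi_status"].to_numpy(),
                       index=determined["patient_id"])
    matrix = (prioritized.assign(v=1)
              .pivot_table(index="gene", columns="patient_id", values="v",
                           aggfunc="max", fill_value=0)
              .reindex(columns=roster, fill_value=0))
    fisher = cohort.compare_mutation_freq(matrix, groups,
                                          p_adj_max=cfg.p_adj_max,
                                          min_mutated=cfg.min_mutated)
    io.write_table(fisher, outdir / "mutation_freq_compare.tsv", h)
    hits = set(fisher.loc[fisher["significant"], "gene"]) \
        if len(fisher) else set()
    universe = set(matrix.index)
    ora = cohort.ora_hypergeom(hits & universe, universe, gene_sets,
                               p_adj_max=cfg.p_adj_max) \
        if hits else pd.DataFrame()
    io.write_table(ora, outdir / "ora.tsv", h)
    log.info("cohort: %d MSI / %d MSS, %d genes tested, %d enriched sets",
             (patients["msi_status"] == "MSI").sum(),
             (patients["msi_status"] == "MSS").sum(), len(fisher),
             int(ora["significant"].sum()) if len(ora) else 0)
    return {"patients": patients, "fisher": fisher, "ora": ora}


def stage_activities(cfg: PipelineConfig, outdir: Path) -> dict:
    """Contrast and per-sample footprint activities plus ssGSEA projection."""
    counts = io.read_matrix(outdir / "counts.tsv")
    network = io.read_table(outdir / "network.tsv")
    pathway_w = io.read_matrix(outdir / "pathway_weights.tsv")
    status = io.read_table(outdir / "cohort_status.tsv")
    gene_sets = io.read_gmt(outdir / "gene_sets.gmt")
    h = cfg.config_hash()
    network = activity.filter_kinase_network(network)
    expr = activity.filter_normalize(counts, cfg.expr_min_count,
                                     cfg.expr_min_samples)
    determined = status.loc[status["msi_status"] != cohort.UNDETERMINED]
    groups = pd.Series(determined["msi_status"].to_numpy(),
                       index=determined["patient_id"])
    stat = activity.contrast_statistic(expr[groups.index], groups)
    tf_contrast = activity.norm_wmean(stat, network, n_perm=cfg.n_perm,
                                      seed=cfg.seed,
                                      min_size=cfg.min_regulon_size)
    pw_contrast = activity.pathway_scores(stat, pathway_w, top_n=100,
                                          n_perm=cfg.n_perm, seed=cfg.seed,
                                          min_size=cfg.min_regulon_size)
    io.write_table(tf_contrast, outdir / "tf_contrast_nes.tsv", h)
    io.write_table(pw_contrast, outdir / "pathway_contrast_nes.tsv", h)
    tf_nes, _ = activity.per_sample_activities(
        expr, network, n_perm=cfg.n_perm, seed=cfg.seed,
        min_size=cfg.min_regulon_size, nes_threshold=cfg.nes_threshold)
    pw_edges = pathway_topn_edges(pathway_w, top_n=100)
    pw_nes, _ = activity.per_sample_activities(
        expr, pw_edges, n_perm=cfg.n_perm, seed=cfg.seed,
        min_size=cfg.min_regulon_size, nes_threshold=cfg.nes_threshold)
    nes_matrix = pd.concat([tf_nes, pw_nes])
    io.write_matrix(nes_matrix, outdir / "per_sample_nes.tsv", h)
    scores, pvals = activity.ssgsea(
        expr, gene_sets,
        activity.SsgseaParams(alpha=cfg.ssgsea_alpha, n_perm=cfg.n_perm,
                              min_size=cfg.ssgsea_min_size),
        seed=cfg.seed)
    io.write_matrix(scores, outdir / "ssgsea_scores.tsv", h)
    io.write_matrix(pvals, outdir / "ssgsea_p.tsv", h)
    log.info("activities: %d TFs, %d pathways, %d gene sets scored",
             len(tf_nes), len(pw_nes), len(scores))
    return {"nes_matrix": nes_matrix, "tf_contrast": tf_contrast,
            "pw_contrast": pw_contrast, "ssgsea": scores}


def pathway_topn_edges(pathway_w: pd.DataFrame, top_n: int = 100) -> pd.DataFrame:
    """Edge list of each pathway's top-|weight| responsive genes."""
    rows = []
    W = pathway_w.to_numpy()
    for i, pth in enumerate(pathway_w.index):
        idx = np.argsort(-np.abs(W[i]))[:top_n]
        for j in idx:
            rows.append((pth, pathway_w.columns[j], float(W[i, j])))
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


def stage_cluster(cfg: PipelineConfig, outdir: Path) -> pd.Series:
    """HCPC-style clustering of the per-sample activity profiles."""
    nes = io.read_matrix(outdir / "per_sample_nes.tsv")
    labels, n_comp = strat.hcpc_cluster(
        nes.T, var_threshold=cfg.var_threshold, max_k=cfg.max_clusters,
        consolidate=cfg.consolidate, seed=cfg.seed)
    out = labels.rename_axis("patient_id").reset_index()
    io.write_table(out, outdir / "clusters.tsv", cfg.config_hash())
    log.info("cluster: %d clusters on %d components",
             labels.nunique(), n_comp)
    return labels


def stage_baskets(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Actionability filtering and interventional basket assignment."""
    prioritized = io.read_table(outdir / "variants_prioritized.tsv")
    kb = io.read_table(outdir / "knowledgebase.tsv")
    basket_map = io.read_table(outdir / "basket_map.tsv")
    status = io.read_table(outdir / "cohort_status.tsv")
    clusters = io.read_table(outdir / "clusters.tsv").set_index("patient_id")
    nes = io.read_matrix(outdir / "per_sample_nes.tsv")
    h = cfg.config_hash()
    actionable = strat.actionable_filter(prioritized, kb)
    io.write_table(actionable, outdir / "variants_actionable.tsv", h)
    rows = []
    reports = []
    for _, pat in status.iterrows():
        pid = pat["patient_id"]
        mine = actionable.loc[actionable["patient_id"] == pid] \
            if len(actionable) else actionable
        genes = set(mine["gene"]) if len(mine) else set()
        baskets = strat.assign_baskets(genes, basket_map,
                                       pat["msi_status"], pat["tmb"],
                                       tmb_high=cfg.tmb_high)
        profile = strat.PatientProfile(
            patient_id=pid, msi_status=pat["msi_status"], tmb=pat["tmb"],
            cluster_id=int(clusters.loc[pid, "cluster_id"])
            if pid in clusters.index else 0,
            mutated_genes=genes, baskets=baskets)
        rows.append((pid, pat["msi_status"], pat["tmb"], profile.cluster_id,
                     ";".join(sorted(genes)), ";".join(sorted(baskets))))
        reports.append(strat.patient_report(
            profile, actionable,
            nes[pid] if pid in nes.columns else None,
            nes_threshold=cfg.nes_threshold))
    profiles = pd.DataFrame(rows, columns=["patient_id", "msi_status", "tmb",
                                           "cluster_id", "actionable_genes",
                                           "baskets"])
    io.write_table(profiles, outdir / "patient_profiles.tsv", h)
    (outdir / "patient_reports.txt").write_text("\n\n".join(reports) + "\n")
    log.info("baskets: %d/%d patients assigned to >= 1 basket",
             (profiles["baskets"] != "").sum(), len(profiles))
    return profiles


def run_pipeline(cfg: PipelineConfig, outdir: str | Path,
                 n_patients: int = 30, msi_fraction: float = 0.25,
                 simulate: bool = True) -> Path:
    """Execute all stages and write a machine-readable run manifest."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    setup_logging(outdir)
    cfg.save(outdir / "config.yaml")
    completed = []
    try:
        if simulate:
            stage_simulate(cfg, outdir, n_patients, msi_fraction)
        completed.append("simulate")
        stage_score(cfg, outdir)
        completed.append("score")
        stage_purity_ploidy(cfg, outdir)
        completed.append("purity_ploidy")
        stage_cohort(cfg, outdir)
        completed.append("cohort")
        stage_activities(cfg, outdir)
        completed.append("activities")
        stage_cluster(cfg, outdir)
        completed.append("cluster")
        stage_baskets(cfg, outdir)
        completed.append("baskets")
    finally:
        manifest = {"tool": "crcprofiler", "version": __version__,
                    "seed": cfg.seed, "config_hash": cfg.config_hash(),
                    "stages": completed,
                    "complete": len(completed) == len(STAGES)}
        (outdir / "manifest.yaml").write_text(
            yaml.safe_dump(manifest, sort_keys=True))
    return outdir
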