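"""End-to-end workflow: preprocess -> network -> summary -> preservation
(-> eqtl -> enrichment), with TSV/JSON reports and a seeded run log."""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import pandas as pd

import netpres
from netpres import io as npio
from netpres import preprocess
from netpres.eqtl import fit_eqtl, trans_set_enrichment
from netpres.enrichment import hypergeom_enrichment
from netpres.module_summary import summarize_modules
from netpres.network import (
    adjacency,
    bicor_matrix,
    cut_modules,
    merge_similar_modules,
    pick_soft_threshold,
    tom_similarity,
)
from netpres.preservation import (
    align_test_to_ref,
    preservation_report,
    project_assignment,
)
from netpres.synthetic_data import SimConfig, generate_paired_study

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},  # SimConfig overrides; set to None to read input files
    "input_dir": None,
    "outlier_z_cut": 3.0,
    "correlation": "bicor",
    "power": None,  # null = pick automatically
    "min_module_size": 50,
    "deep_split": 3,
    "merge_cut_height": 0.15,
    "n_permutations": 10000,
    "preservation_p_cut": 1e-4,
    "run_eqtl": False,
    "eqtl_p_cut": 0.01,
    "run_enrichment": False,
    "gene_sets_gmt": None,
}


def run_pipeline(config: dict | None = None, outdir: str | Path = "netpres_run") -> dict:
    """Execute the full workflow; returns paths of all emitted reports."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    paths: dict[str, str] = {}

    # ---- inputs -----------------------------------------------------------
    if cfg.get("simulate") is not None:
        sim_cfg = SimConfig(**{**cfg["simulate"], "seed": seed})
        study = generate_paired_study(sim_cfg)
        ref_probes, test_probes = study.ref_probes, study.test_probes
        om = study.ortholog_map
        dosages, covariates = study.dosages, study.covariates
        snp_pos, gene_pos = study.snp_positions, study.gene_positions
        cfg["simulate"] = asdict(sim_cfg)
    else:
        indir = Path(cfg["input_dir"])
        ref_probes = npio.read_probe_matrix(
            indir / "ref_probes.tsv", indir / "ref_probe_map.tsv", species="ref"
        )
        test_probes = npio.read_probe_matrix(
            indir / "test_probes.tsv", indir / "test_probe_map.tsv", species="test"
        )
        om = npio.read_ortholog_tsv(indir / "orthologs.tsv")
        dosages = covariates = snp_pos = gene_pos = None
        if (indir / "dosages.tsv").exists():
            dosages = npio.read_dosage_tsv(indir / "dosages.tsv")
            snp_pos = npio.read_positions_tsv(indir / "snp_positions.tsv")
            gene_pos = npio.read_positions_tsv(indir / "gene_positions.tsv")
        if (indir / "covariates.tsv").exists():
            covariates = npio.read_covariates_tsv(indir / "covariates.tsv")

    # ---- preprocess -------------------------------------------------------
    ref_em, _ = preprocess.collapse_probes(ref_probes)
    test_em, _ = preprocess.collapse_probes(test_probes)
    reports = {}
    for tag, em in (("ref", ref_em), ("test", test_em)):
        rep = preprocess.outlier_report(em, z_cut=float(cfg["outlier_z_cut"]))
        reports[tag] = rep
        rep.to_csv(outdir / f"outliers_{tag}.tsv", sep="\t", index=False)
        paths[f"outliers_{tag}"] = str(outdir / f"outliers_{tag}.tsv")
    ref_em = ref_em.drop_samples(reports["ref"].loc[reports["ref"]["flagged"], "sample"])
    test_em = test_em.drop_samples(reports["test"].loc[reports["test"]["flagged"], "sample"])
    ref_em, test_em, pairs = preprocess.harmonize_orthologs(ref_em, test_em, om)
    test_em = align_test_to_ref(test_em, pairs)

    # ---- network ----------------------------------------------------------
    cm = bicor_matrix(ref_em, method=cfg["correlation"])
    if cfg["power"] is None:
        power, diag = pick_soft_threshold(cm)
    else:
        power = float(cfg["power"])
        from netpres.network import soft_threshold_table

        diag = soft_threshold_table(cm)
    diag.to_csv(outdir / "soft_threshold.tsv", sep="\t", index=False)
    paths["soft_threshold"] = str(outdir / "soft_threshold.tsv")

    am = adjacency(cm, power=power)
    tom = tom_similarity(am)
    ma = cut_modules(
        tom.dissimilarity(),
        min_module_size=int(cfg["min_module_size"]),
        deep_split=int(cfg["deep_split"]),
    )
    ref_summary = summarize_modules(ref_em, ma, method=cfg["correlation"])
    if float(cfg["merge_cut_height"]) > 0 and len(ma.module_ids) > 1:
        ma = merge_similar_modules(ref_summary, ma, cut_height=float(cfg["merge_cut_height"]))
        ref_summary = summarize_modules(ref_em, ma, method=cfg["correlation"])

    assignment_out = pd.DataFrame({"gene": ma.genes, "module": ma.labels.values})
    assignment_out.to_csv(outdir / "modules.tsv", sep="\t", index=False)
    paths["modules"] = str(outdir / "modules.tsv")
    ref_summary.eigengenes.to_csv(outdir / "eigengenes_ref.tsv", sep="\t")
    ref_summary.kme.to_csv(outdir / "kme_ref.tsv", sep="\t")
    paths["eigengenes_ref"] = str(outdir / "eigengenes_ref.tsv")
    paths["kme_ref"] = str(outdir / "kme_ref.tsv")

    # ---- preservation -----------------------------------------------------
    if ma.module_ids:
        test_summary = project_assignment(test_em, ma, method=cfg["correlation"])
        pres = preservation_report(
            ref_summary,
            test_summary,
            ma,
            n_perm=int(cfg["n_permutations"]),
            seed=seed,
            p_cut=float(cfg["preservation_p_cut"]),
        )
        pres_table = pres.table
    else:
        warnings.warn("no modules found; preservation skipped")
        pres_table = pd.DataFrame()
    pres_table.to_csv(outdir / "preservation.tsv", sep="\t", index=False)
    paths["preservation"] = str(outdir / "preservation.tsv")

    # Table-1-shaped module report
    module_rows = []
    for mod in ma.module_ids:
        row = {
            "module": f"M{mod}",
            "size": int(len(ma.members(mod))),
            "me_pct": round(100 * float(ref_summary.variance_explained[mod]), 1),
        }
        if len(pres_table):
            prow = pres_table[pres_table["module"] == mod].iloc[0]
            row["consistent_frac"] = round(float(prow["fraction"]), 2)
            row["preservation_p"] = float(prow["p"])
        module_rows.append(row)
    module_table = pd.DataFrame(module_rows)
    module_table.to_csv(outdir / "module_table.tsv", sep="\t", index=False)
    paths["module_table"] = str(outdir / "module_table.tsv")

    # ---- optional eQTL ----------------------------------------------------
    if cfg["run_eqtl"] and dosages is not None:
        records = fit_eqtl(
            dosages,
            ref_em,
            covariates=covariates,
            snp_positions=snp_pos,
            gene_positions=gene_pos,
        )
        records.to_csv(outdir / "eqtl_records.tsv", sep="\t", index=False)
        paths["eqtl_records"] = str(outdir / "eqtl_records.tsv")
        enrich_rows = []
        for mod in ma.module_ids:
            targets = set(ma.members(mod))
            for snp in dosages.snps:
                sub = records[records["snp"] == snp]
                res = trans_set_enrichment(sub, targets, p_cut=float(cfg["eqtl_p_cut"]))
                enrich_rows.append(
                    {
                        "snp": snp,
                        "module": mod,
                        "prop_target": res["prop_target"],
                        "prop_background": res["prop_background"],
                        "odds_ratio": res["odds_ratio"],
                        "p": res["p"],
                    }
                )
        pd.DataFrame(enrich_rows).to_csv(
            outdir / "trans_enrichment.tsv", sep="\t", index=False
        )
        paths["trans_enrichment"] = str(outdir / "trans_enrichment.tsv")

    # ---- optional gene-set enrichment ------------------------------------
    if cfg["run_enrichment"] and cfg.get("gene_sets_gmt"):
        gene_sets = npio.read_gmt(cfg["gene_sets_gmt"])
        universe = set(ref_em.genes)
        enr_frames = []
        for mod in ma.module_ids:
            members = set(ma.members(mod))
            if len(pres_table):
                prow = pres_table[pres_table["module"] == mod].iloc[0]
                if not bool(prow["preserved"]):
                    continue
                # enrichment runs on the consistent genes of preserved modules
                kr = ref_summary.kme[mod]
                kt = test_summary.kme[mod]
                sign_ok = (kr.loc[list(members)] * kt.loc[list(members)]) > 0
                members = set(sign_ok.index[sign_ok])
            res = hypergeom_enrichment(members, gene_sets, universe)
            res.insert(0, "module", mod)
            enr_frames.append(res)
        enr = pd.concat(enr_frames) if enr_frames else pd.DataFrame()
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        paths["enrichment"] = str(outdir / "enrichment.tsv")

    log = {
        "version": netpres.__version__,
        "seed": seed,
        "power": float(power),
        "config": _jsonable(cfg),
        "outputs": paths,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    paths["run_log"] = str(outdir / "run_log.json")
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "item"):
        return obj.item()
    return obj
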