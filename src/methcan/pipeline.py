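"""End-to-end orchestration of the analysis on a simulated compendium.

Stages: simulate -> preprocess -> constitutive -> dm -> correlate ->
signals -> predict -> dhs.  Every stage writes plain-text exports into the
bundle directory, and a manifest records the configuration, master seed and
content hashes so a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import chromatin, constitutive, predict, signals as sigmod, synthetic, tissue_independence as ti
from .genome import promoter_window, write_annotation, write_bed, write_manifest
from .preprocess import (
    aggregate_region_beta,
    fit_sample_thresholds,
    preprocess_cohort,
    svd_phenotype_check,
    write_beta_matrix,
)

log = logging.getLogger("methcan")

DEFAULT_PARAMS = {
    "coverage_min_frac": 0.7,
    "knn_k": 5,
    "knn_max_donors": 2000,
    "mixture_subsample": 4000,
    "dm_top_n": 300,
    "dm_set_size": 1000,
    "split_fractions": (0.5, 0.2, 0.3),
    "promoter_window": 300,
    "bivalent_quantile": 0.75,
    "floor_total_reads_millions": 39,
    "floor_read_threshold": 10,
    "floor_mean_gene_kb": 1,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _save_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(
    cfg: synthetic.SyntheticConfig,
    outdir: str | Path,
    params: dict | None = None,
) -> dict:
    """Run every stage on a freshly simulated dataset; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = {**DEFAULT_PARAMS, **(params or {})}
    manifest: dict = {"seed": cfg.seed, "config": asdict(cfg), "params": {
        k: list(v) if isinstance(v, tuple) else v for k, v in p.items()
    }, "stages": {}}
    state: dict = {}

    all_stages = [
        ("simulate", _stage_simulate),
        ("preprocess", _stage_preprocess),
        ("constitutive", _stage_constitutive),
        ("dm", _stage_dm),
        ("correlate", _stage_correlate),
        ("signals", _stage_signals),
        ("predict", _stage_predict),
        ("dhs", _stage_dhs),
    ]
    selected = p.get("stages")
    stages = [s for s in all_stages if selected is None or s[0] in selected]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            fn(cfg, p, outdir, state)
        except Exception as exc:
            _save_json(manifest, outdir / "manifest.json")
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        log.info("stage %s done in %.2fs", name, manifest["stages"][name]["seconds"])

    manifest["outputs"] = {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(outdir.glob("*"))
        if f.is_file() and f.name != "manifest.json"
    }
    # exclude wall-clock timings from the hashable manifest content
    hashable = {k: v for k, v in manifest.items() if k != "stages"}
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(hashable, sort_keys=True).encode()
    ).hexdigest()
    _save_json(manifest, outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, p, outdir, state):
    ds = synthetic.generate_all(cfg)
    state["ds"] = ds
    write_annotation(ds.genes, outdir / "genes.tsv")
    write_manifest(ds.manifest, outdir / "probe_manifest.tsv")
    ds.cgis.to_csv(outdir / "cgis.tsv", sep="\t", index=False)
    write_beta_matrix(ds.betas, outdir / "betas.tsv")
    ds.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    ds.expression.to_frame().to_csv(outdir / "expression_rpkm.tsv", sep="\t", float_format="%.6g")
    truth = pd.DataFrame(
        {"u": ds.truth.u, "promoter_state": ds.truth.promoter_state, "body_state": ds.truth.body_state}
    )
    truth.to_csv(outdir / "truth_genes.tsv", sep="\t", float_format="%.6g")
    for source, marks in ds.tracks.items():
        for mark, track in marks.items():
            sigmod.write_bedgraph(track, outdir / f"track_{source}_{mark}.bedGraph")
    for tissue, ivs in ds.dhs.items():
        write_bed(ivs, outdir / f"dhs_{tissue}.bed")


def _stage_preprocess(cfg, p, outdir, state):
    ds = state["ds"]
    # each cohort (fetal compendium; per-tissue normal+cancer) is filtered
    # and imputed on its own, then joined over the shared retained probes
    cohorts = {"fetal": ds.samples("fetal")}
    for tissue in cfg.tissues:
        cohorts[tissue] = ds.samples("normal", tissue) + ds.samples("cancer", tissue)
    processed = [
        preprocess_cohort(
            ds.betas[ids], p["coverage_min_frac"], p["knn_k"], p["knn_max_donors"]
        )
        for ids in cohorts.values()
    ]
    betas = pd.concat(processed, axis=1, join="inner")
    state["betas"] = betas
    for region_class in ("promoter", "gene_body", "cgi"):
        agg = aggregate_region_beta(betas, ds.manifest, region_class)
        state[f"region_{region_class}"] = agg
        write_beta_matrix(agg, outdir / f"region_{region_class}.tsv")
    fetal = ds.samples("fetal")
    state["fits"] = fit_sample_thresholds(
        betas[fetal], seed=cfg.seed, subsample=p["mixture_subsample"]
    )
    _save_json({s: f.to_dict() for s, f in state["fits"].items()}, outdir / "mixture_fits.json")
    svd_rows = []
    for tissue in cfg.tissues:
        ids = ds.samples("normal", tissue) + ds.samples("cancer", tissue)
        labels = pd.Series(
            ["cancer" if s.startswith("cancer") else "normal" for s in ids], index=ids
        )
        chk = svd_phenotype_check(state["region_promoter"][ids], labels)
        svd_rows.append({"tissue": tissue, "r": chk["r"], "passed": chk["passed"]})
    pd.DataFrame(svd_rows).to_csv(outdir / "svd_check.tsv", sep="\t", index=False, float_format="%.6g")


def _stage_constitutive(cfg, p, outdir, state):
    ds = state["ds"]
    fetal = ds.samples("fetal")
    for kind, region_class in (("cu_GP", "promoter"), ("cu_CGI", "cgi"), ("cm_GB", "gene_body")):
        cs = constitutive.constitutive_set(
            state[f"region_{region_class}"][fetal], state["fits"], kind
        )
        state[kind] = cs
        constitutive.write_constitutive_set(cs, outdir / f"{kind.lower().replace('_', '-')}.txt")


def _stage_dm(cfg, p, outdir, state):
    ds = state["ds"]
    dm = {}
    for tissue in cfg.tissues:
        normal, cancer = ds.samples("normal", tissue), ds.samples("cancer", tissue)
        prom = state["region_promoter"].loc[
            state["region_promoter"].index.intersection(state["cu_GP"].members)
        ]
        body = state["region_gene_body"].loc[
            state["region_gene_body"].index.intersection(state["cm_GB"].members)
        ]
        t_prom = ti.dm_t_test(prom, normal, cancer)
        t_body = ti.dm_t_test(body, normal, cancer)
        n_prom = min(p["dm_top_n"], len(t_prom) // 2)
        n_body = min(p["dm_top_n"], len(t_body) // 2)
        if min(n_prom, n_body) < p["dm_top_n"]:
            log.info("dm_top_n capped to %d/%d by region counts", n_prom, n_body)
        dm[tissue] = {
            "promoter_t": t_prom,
            "body_t": t_body,
            "promoter_labels": ti.rank_and_label(t_prom["t"], N=n_prom, direction="hyper"),
            "body_labels": ti.rank_and_label(t_body["t"], N=n_body, direction="hypo"),
        }
        dm[tissue]["promoter_labels"].to_csv(
            outdir / f"dm_promoter_{tissue}.tsv", sep="\t", float_format="%.6g"
        )
    state["dm"] = dm


def _stage_correlate(cfg, p, outdir, state):
    ds = state["ds"]
    cu = state["region_promoter"].index.intersection(state["cu_GP"].members)
    cancer_profiles = {
        t: ti.phenotype_mean_profile(state["region_promoter"].loc[cu], ds.samples("cancer", t))
        for t in cfg.tissues
    }
    normal_profiles = {
        t: ti.phenotype_mean_profile(state["region_promoter"].loc[cu], ds.samples("normal", t))
        for t in cfg.tissues
    }
    r2, mean_off = ti.pairwise_r2(cancer_profiles)
    r2.to_csv(outdir / "r2_cancer_cancer.tsv", sep="\t", float_format="%.6g")
    cn = pd.DataFrame(
        {
            tn: {
                tc: float(np.corrcoef(cancer_profiles[tc], normal_profiles[tn])[0, 1]) ** 2
                for tc in cfg.tissues
            }
            for tn in cfg.tissues
        }
    )  # rows = cancers, cols = normals
    cn.to_csv(outdir / "r2_cancer_normal.tsv", sep="\t", float_format="%.6g")
    if cfg.n_tissues >= 3:
        t_stat, p_val = ti.own_vs_other_normal_test(cn)
    else:
        log.info("own-vs-other-normal test skipped: <3 tissues")
        t_stat = p_val = float("nan")
    _save_json(
        {"mean_offdiag_r2": mean_off, "own_vs_other_t": t_stat, "own_vs_other_p": p_val},
        outdir / "correlation_summary.json",
    )
    top = ti.top_ranked_matrix(cancer_profiles, cfg.tissues[0], n=min(1500, len(cu)))
    top.to_csv(outdir / "top_ranked_regions.tsv", sep="\t", float_format="%.6g")
    state["cancer_profiles"] = cancer_profiles


def _stage_signals(cfg, p, outdir, state):
    ds = state["ds"]
    per_source: dict[str, pd.DataFrame] = {}
    for source, marks in ds.tracks.items():
        cols = {}
        for mark, track in marks.items():
            if mark == "H3K36me3":
                cols[mark] = sigmod.gene_body_signal(track, ds.genes, "with_introns")
            else:
                cols[mark] = sigmod.promoter_signal_matrix(track, ds.genes, p["promoter_window"])
        per_source[source] = pd.DataFrame(cols)
        per_source[source].to_csv(
            outdir / f"gene_signals_{source}.tsv", sep="\t", float_format="%.6g"
        )
    state["gene_signals"] = per_source
    expr = sigmod.floor_expression(
        ds.expression,
        total_reads_millions=p["floor_total_reads_millions"],
        read_threshold=p["floor_read_threshold"],
        mean_gene_kb=p["floor_mean_gene_kb"],
    )
    state["expression_log2"] = expr
    chosen_w, profile = sigmod.tune_window(
        ds.tracks["hESC"]["H3K4me3"], ds.tracks["hESC"]["H3K27me3"], expr, ds.genes
    )
    profile.to_csv(outdir / "window_tuning.tsv", sep="\t", index=False, float_format="%.6g")
    _save_json({"chosen_window": chosen_w}, outdir / "window_choice.json")


def _stage_predict(cfg, p, outdir, state):
    ds = state["ds"]
    if "gene_signals" not in state:
        log.warning("prediction stage skipped: no histone signals available")
        return
    auc_rows = []
    for tissue in cfg.tissues:
        for direction, labels_key, region in (
            ("hyper", "promoter_labels", "promoter"),
            ("hypo", "body_labels", "gene_body"),
        ):
            labels = state["dm"][tissue][labels_key]["label"]
            for source_name, source in (("normal", tissue), ("hesc", "hESC")):
                gs = {
                    (mark, source_name): state["gene_signals"][source][mark]
                    for mark in predict.MARKS
                }
                table = predict.predict_dm_auc(gs, labels, direction=direction)
                table.insert(0, "tissue", tissue)
                auc_rows.append(table)
    aucs = pd.concat(auc_rows, ignore_index=True)
    aucs.to_csv(outdir / "auc_table.tsv", sep="\t", index=False, float_format="%.6g")
    state["aucs"] = aucs

    # paired Wilcoxon per mark across tissues (promoter hypermethylation)
    wilcoxon = {}
    hyper = aucs[aucs["direction"] == "hyper"]
    for mark in predict.MARKS:
        pairs = hyper[hyper["mark"] == mark].pivot(index="tissue", columns="source", values="auc")
        wilcoxon[mark] = predict.paired_wilcoxon_auc(pairs)
    bivalent_pairs = hyper[hyper["mark"].isin(["H3K4me3", "H3K27me3"])].pivot_table(
        index=["tissue", "mark"], columns="source", values="auc"
    )
    wilcoxon["bivalent_pooled"] = predict.paired_wilcoxon_auc(bivalent_pairs)
    _save_json(wilcoxon, outdir / "wilcoxon_normal_vs_hesc.json")

    # multivariate model selection on the first tissue's hypermethylation set,
    # ranked over all gene promoters (the 1000+1000 design needs >=2000 genes)
    tissue = cfg.tissues[0]
    tstats = ti.dm_t_test(
        state["region_promoter"], ds.samples("normal", tissue), ds.samples("cancer", tissue)
    )["t"]
    if len(tstats) >= 2000:
        dm_set = predict.build_dm_gene_set(tstats)
        split = predict.stratified_split(dm_set["label"], tuple(p["split_fractions"]), seed=cfg.seed)
        best, report = predict.model_selection(
            state["gene_signals"][tissue], dm_set["label"], split
        )
        report.to_csv(outdir / "model_selection.tsv", sep="\t", index=False, float_format="%.6g")
        _save_json(
            {"predictors": list(best.predictors), "z": best.z.to_dict(),
             "test_auc": best.test_auc},
            outdir / "best_model.json",
        )
    else:
        log.info("model selection skipped: %d < 2000 labelled regions", len(tstats))


def _stage_dhs(cfg, p, outdir, state):
    ds = state["ds"]
    windows = {g.gene_id: promoter_window(g, p["promoter_window"], "symmetric") for g in ds.genes}
    rows = []
    have_signals = "gene_signals" in state
    if not have_signals:
        log.warning("bivalency stratification skipped: no histone signals available")
    for tissue in cfg.tissues:
        dhs = chromatin.dhs_stratify(windows, ds.dhs[tissue])
        table = chromatin.stratified_normal_cancer_t(
            state["region_promoter"],
            ds.samples("normal", tissue),
            ds.samples("cancer", tissue),
            chromatin.partition_strata(dhs),
        )
        table.insert(0, "tissue", tissue)
        rows.append(table)
        if have_signals:
            k4 = state["gene_signals"][tissue]["H3K4me3"]
            k27 = state["gene_signals"][tissue]["H3K27me3"]
            bivalent = chromatin.call_bivalent(k4, k27, p["bivalent_quantile"])
            table_biv = chromatin.stratified_normal_cancer_t(
                state["region_promoter"],
                ds.samples("normal", tissue),
                ds.samples("cancer", tissue),
                chromatin.partition_strata(dhs, bivalent),
            )
            table_biv.insert(0, "tissue", tissue)
            rows.append(table_biv)
    pd.concat(rows, ignore_index=True).to_csv(
        outdir / "dhs_strata.tsv", sep="\t", index=False, float_format="%.6g"
    )
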