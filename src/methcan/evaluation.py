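"""Study-condition experiments: end-to-end checks of the analysis machinery.

Each function runs one experiment from scratch on freshly simulated data at
the generator's default conditions and returns the measured quantities.
They are shared by the acceptance script and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import predict as pm
from . import tissue_independence as ti
from .chromatin import dhs_stratify, partition_strata, stratified_normal_cancer_t
from .constitutive import constitutive_set
from .genome import promoter_window
from .preprocess import (
    aggregate_region_beta,
    fit_beta_mixture,
    fit_sample_thresholds,
    preprocess_cohort,
)
from .signals import floor_expression, gene_body_signal, promoter_signal_matrix
from .synthetic import (
    SyntheticConfig,
    generate_all,
    generate_annotation,
    generate_histone_tracks,
    generate_methylation,
)

MIXTURE_TRUTH = ((2, 18), (10, 10), (18, 2))  # component means 0.1, 0.5, 0.9


def _seed_list(seed: int, n: int) -> list[int]:
    """n well-separated child seeds below 2**31."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# 1. expression floor derivation
# ---------------------------------------------------------------------------

def expression_floor_derivation(
    total_reads_millions: float = 39, read_threshold: float = 10, mean_gene_kb: float = 1
) -> dict:
    """The analytic low-expression threshold: log2(10 / (39 x 1)) -> -2."""
    raw = float(np.log2(read_threshold / (total_reads_millions * mean_gene_kb)))
    floored = float(round(raw))
    # confirm floor_expression applies exactly this floor
    demo = floor_expression(
        pd.Series([8.0, 0.1, 0.0]),
        total_reads_millions=total_reads_millions,
        read_threshold=read_threshold,
        mean_gene_kb=mean_gene_kb,
    )
    assert demo.min() == floored
    return {"log2_threshold_raw": raw, "log2_threshold_rounded": floored}


# ---------------------------------------------------------------------------
# 2. trapezoid ROC AUC vs Mann-Whitney pairwise AUC
# ---------------------------------------------------------------------------

def auc_equivalence(seed: int = 0, n_instances: int = 500) -> dict:
    """Max |trapezoid AUC - pairwise AUC| over random instances (with ties)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(10, 120))
        if rng.random() < 0.5:
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
        else:
            x = rng.normal(size=n)
        labels = np.where(rng.random(n) < rng.uniform(0.2, 0.8), "DM", "nonDM")
        if len(set(labels)) < 2:
            continue
        signal = pd.Series(x)
        lab = pd.Series(labels)
        worst = max(worst, abs(pm.roc_curve(signal, lab).auc - pm.auc_from_labels(signal, lab)))
    return {"max_abs_auc_difference": worst}


# ---------------------------------------------------------------------------
# 3. three-state beta-mixture recovery
# ---------------------------------------------------------------------------

def mixture_recovery(seed: int = 0, n_seeds: int = 20, n: int = 5000, tol: float = 0.05) -> dict:
    """Fraction of runs recovering all three component means within +/-tol."""
    truth_means = np.array([a / (a + b) for a, b in MIXTURE_TRUTH])
    ok = 0
    max_err = 0.0
    for s in _seed_list(seed, n_seeds):
        rng = np.random.default_rng(s)
        comps = rng.integers(0, 3, size=n)
        x = np.concatenate(
            [rng.beta(*MIXTURE_TRUTH[k], size=int((comps == k).sum())) for k in range(3)]
        )
        fit = fit_beta_mixture(x, seed=s)
        err = float(np.abs(fit.means - truth_means).max())
        max_err = max(max_err, err)
        ok += err <= tol
    return {"recovery_rate": ok / n_seeds, "max_mean_error": max_err}


# ---------------------------------------------------------------------------
# 4. shared-fraction recovery through the full pipeline
# ---------------------------------------------------------------------------

def _recovered_cu_gp(cfg, betas_fetal, manifest, seed):
    """Constitutive unmethylated promoters from fetal samples via EM thresholds."""
    fetal_prom = aggregate_region_beta(betas_fetal, manifest, "promoter")
    fits = fit_sample_thresholds(betas_fetal, seed=seed, subsample=4000)
    return constitutive_set(fetal_prom, fits, "cu_GP")


def shared_fraction_recovery(
    seed: int = 0, n_seeds: int = 20, f: float = 0.6, n_genes: int = 2000
) -> dict:
    """Mean cross-cancer R^2 over cu-GPs at generator shared_fraction f.

    Runs the preprocessing, constitutive-set and correlation stages from
    scratch for every seed.
    """
    means = []
    for s in _seed_list(seed, n_seeds):
        cfg = SyntheticConfig(n_genes=n_genes, shared_fraction=f, seed=s)
        genes, manifest, cgis = generate_annotation(cfg)
        betas, sheet, truth = generate_methylation(cfg, genes, manifest, cgis)

        def ids(kind, tissue=None):
            sel = sheet["phenotype"] == kind
            if tissue is not None:
                sel &= sheet["tissue"] == tissue
            return sheet.loc[sel, "sample"].tolist()

        fetal = preprocess_cohort(betas[ids("fetal")], max_donors=1500)
        cu = _recovered_cu_gp(cfg, fetal, manifest, s)
        profiles = {}
        for tissue in cfg.tissues:
            cancer = preprocess_cohort(betas[ids("cancer", tissue)], max_donors=1500)
            prom = aggregate_region_beta(cancer, manifest, "promoter")
            sub = prom.index.intersection(cu.members)
            profiles[tissue] = ti.phenotype_mean_profile(prom.loc[sub], list(prom.columns))
        common = profiles[cfg.tissues[0]].index
        for v in profiles.values():
            common = common.intersection(v.index)
        profiles = {k: v.loc[common] for k, v in profiles.items()}
        _, mean_off = ti.pairwise_r2(profiles)
        means.append(mean_off)
    return {"mean_cross_cancer_r2": float(np.mean(means)), "per_seed": means}


# ---------------------------------------------------------------------------
# 5. logistic sign recovery (K27 +, K4 -, K36 -)
# ---------------------------------------------------------------------------

def _one_tissue_dataset(seed: int, n_genes: int = 2000):
    cfg = SyntheticConfig(n_genes=n_genes, n_tissues=1, seed=seed)
    genes, manifest, cgis = generate_annotation(cfg)
    betas, sheet, truth = generate_methylation(cfg, genes, manifest, cgis)
    tracks, targets = generate_histone_tracks(cfg, truth, genes)
    return cfg, genes, manifest, betas, sheet, truth, tracks


def _tissue_signals(tracks, genes, source, w=300):
    return pd.DataFrame(
        {
            "H3K4me3": promoter_signal_matrix(tracks[source]["H3K4me3"], genes, w),
            "H3K27me3": promoter_signal_matrix(tracks[source]["H3K27me3"], genes, w),
            "H3K36me3": gene_body_signal(tracks[source]["H3K36me3"], genes, "with_introns"),
        }
    )


def sign_recovery(seed: int = 0, n_seeds: int = 20) -> dict:
    """Fraction of seeds where the 3-predictor logistic z pattern is (+,-,-)."""
    ok = 0
    for s in _seed_list(seed, n_seeds):
        cfg, genes, manifest, betas, sheet, truth, tracks = _one_tissue_dataset(s)
        tissue = cfg.tissues[0]
        cohort = preprocess_cohort(
            betas[sheet.loc[sheet["phenotype"] != "fetal", "sample"]], max_donors=1500
        )
        prom = aggregate_region_beta(cohort, manifest, "promoter")
        normal = [c for c in prom.columns if c.startswith("normal")]
        cancer = [c for c in prom.columns if c.startswith("cancer")]
        tstats = ti.dm_t_test(prom, normal, cancer)["t"]
        dm_set = pm.build_dm_gene_set(tstats)
        design = _tissue_signals(tracks, genes, tissue)
        fit = pm.fit_logistic(design.loc[dm_set.index], dm_set["label"])
        z = fit.z
        ok += (z["H3K27me3"] > 0) and (z["H3K4me3"] < 0) and (z["H3K36me3"] < 0)
    return {"sign_recovery_rate": ok / n_seeds}


# ---------------------------------------------------------------------------
# 6. normal-tissue vs hESC prediction and the paired Wilcoxon
# ---------------------------------------------------------------------------

def source_comparison(seed: int = 0, n_seeds: int = 20, top_n: int = 300) -> dict:
    """Normal-vs-hESC AUC gap for the bivalent marks, plus the exact Wilcoxon.

    Per seed a one-tissue dataset is simulated, cancer hypermethylation
    labels (top/bottom N=300 by t over ground-state-unmethylated promoters)
    are computed, and the K4/K27 AUCs from the normal-tissue and hESC tracks
    compared.  A final 6-tissue run feeds the paired Wilcoxon.
    """
    wins = 0
    for s in _seed_list(seed, n_seeds):
        cfg, genes, manifest, betas, sheet, truth, tracks = _one_tissue_dataset(s)
        tissue = cfg.tissues[0]
        cohort = preprocess_cohort(
            betas[sheet.loc[sheet["phenotype"] != "fetal", "sample"]], max_donors=1500
        )
        prom = aggregate_region_beta(cohort, manifest, "promoter")
        unmeth = truth.promoter_state.index[truth.promoter_state == 0]
        prom = prom.loc[prom.index.intersection(unmeth)]
        normal = [c for c in prom.columns if c.startswith("normal")]
        cancer = [c for c in prom.columns if c.startswith("cancer")]
        labels = ti.rank_and_label(
            ti.dm_t_test(prom, normal, cancer)["t"], N=top_n, direction="hyper"
        )["label"]
        sig_norm = _tissue_signals(tracks, genes, tissue)
        sig_hesc = _tissue_signals(tracks, genes, "hESC")
        win = True
        for mark in ("H3K4me3", "H3K27me3"):
            auc_n = pm.roc_curve(sig_norm[mark], labels).auc
            auc_h = pm.roc_curve(sig_hesc[mark], labels).auc
            win &= auc_n > auc_h
        wins += win

    # six-tissue run for the paired signed-rank test
    cfg = SyntheticConfig(n_genes=2000, n_tissues=6, seed=_seed_list(seed, n_seeds + 1)[-1])
    genes, manifest, cgis = generate_annotation(cfg)
    betas, sheet, truth = generate_methylation(cfg, genes, manifest, cgis)
    tracks, _ = generate_histone_tracks(cfg, truth, genes)
    unmeth = truth.promoter_state.index[truth.promoter_state == 0]
    rows = []
    sig_hesc = _tissue_signals(tracks, genes, "hESC")
    for tissue in cfg.tissues:
        ids_n = sheet.loc[(sheet["phenotype"] == "normal") & (sheet["tissue"] == tissue), "sample"]
        ids_c = sheet.loc[(sheet["phenotype"] == "cancer") & (sheet["tissue"] == tissue), "sample"]
        cohort = preprocess_cohort(betas[list(ids_n) + list(ids_c)], max_donors=1500)
        prom = aggregate_region_beta(cohort, manifest, "promoter")
        prom = prom.loc[prom.index.intersection(unmeth)]
        labels = ti.rank_and_label(
            ti.dm_t_test(prom, list(ids_n), list(ids_c))["t"], N=top_n, direction="hyper"
        )["label"]
        sig_norm = _tissue_signals(tracks, genes, tissue)
        rows.append(
            {
                "tissue": tissue,
                "normal": pm.roc_curve(sig_norm["H3K27me3"], labels).auc,
                "hesc": pm.roc_curve(sig_hesc["H3K27me3"], labels).auc,
            }
        )
    pairs = pd.DataFrame(rows).set_index("tissue")
    return {
        "normal_beats_hesc_rate": wins / n_seeds,
        "wilcoxon_p_six_tissues": pm.paired_wilcoxon_auc(pairs),
        "n_positive_differences": int((pairs["normal"] > pairs["hesc"]).sum()),
    }


# ---------------------------------------------------------------------------
# 7. DHS structure
# ---------------------------------------------------------------------------

def dhs_structure(seed: int = 0, n_genes: int = 2000) -> dict:
    """In-DHS promoters: lower normal beta and stronger cancer differential."""
    cfg = SyntheticConfig(n_genes=n_genes, n_tissues=1, seed=seed)
    ds = generate_all(cfg)
    tissue = cfg.tissues[0]
    cohort = preprocess_cohort(
        ds.betas[ds.samples("normal", tissue) + ds.samples("cancer", tissue)], max_donors=1500
    )
    prom = aggregate_region_beta(cohort, ds.manifest, "promoter")
    windows = {g.gene_id: promoter_window(g, 300, "symmetric") for g in ds.genes}
    strat = dhs_stratify(windows, ds.dhs[tissue]).reindex(prom.index)
    normal = ds.samples("normal", tissue)
    cancer = ds.samples("cancer", tissue)
    normal_means = prom[normal].mean(axis=1)
    res = stats.ttest_ind(
        normal_means[strat == "in"], normal_means[strat == "out"], equal_var=False
    )
    table = stratified_normal_cancer_t(prom, normal, cancer, partition_strata(strat))
    t_by = table.set_index("stratum")["t"]
    return {
        "normal_beta_in_minus_out": float(
            normal_means[strat == "in"].mean() - normal_means[strat == "out"].mean()
        ),
        "normal_beta_ttest_p": float(res.pvalue),
        "t_in": float(t_by["dhs_in"]),
        "t_out": float(t_by["dhs_out"]),
    }


# ---------------------------------------------------------------------------
# 8. constitutive-set soundness
# ---------------------------------------------------------------------------

def cu_soundness(seed: int = 0, n_genes: int = 2000) -> dict:
    """Recall of ground-state-unmethylated promoters in the recovered cu-GP set
    and contamination by ground-state-methylated promoters."""
    cfg = SyntheticConfig(n_genes=n_genes, seed=seed)
    genes, manifest, cgis = generate_annotation(cfg)
    betas, sheet, truth = generate_methylation(cfg, genes, manifest, cgis)
    fetal_ids = sheet.loc[sheet["phenotype"] == "fetal", "sample"].tolist()
    fetal = preprocess_cohort(betas[fetal_ids], max_donors=1500)
    cu = _recovered_cu_gp(cfg, fetal, manifest, seed)
    members = set(cu.members)
    unmeth = set(truth.promoter_state.index[truth.promoter_state == 0])
    meth = set(truth.promoter_state.index[truth.promoter_state == 2])
    return {
        "cu_gp_recall": len(members & unmeth) / len(unmeth),
        "cu_gp_methylated_contamination": len(members & meth),
        "cu_gp_size": len(members),
    }
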