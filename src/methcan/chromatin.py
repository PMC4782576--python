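"""Promoter stratification by chromatin accessibility and bivalency.

Promoters are split by whether their window overlaps a DNase hypersensitive
site in the matched normal tissue and by bivalent status (high H3K4me3 and
H3K27me3 together), and the normal-vs-cancer differential methylation is
compared between strata.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from .genome import GenomicInterval, IntervalSet


def dhs_stratify(
    promoter_windows: dict[str, GenomicInterval], dhs_set: IntervalSet
) -> pd.Series:
    """'in' / 'out' per gene according to promoter window overlap with DHSs."""
    return pd.Series(
        {g: "in" if dhs_set.overlaps(iv) else "out" for g, iv in promoter_windows.items()},
        name="dhs",
    )


def call_bivalent(
    k4_signals: pd.Series, k27_signals: pd.Series, quantile: float = 0.75
) -> pd.Index:
    """Genes whose promoter exceeds the quantile cutoff in both bivalent marks.

    Genes missing either mark are excluded.  Raising the quantile can only
    shrink the set.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    common = k4_signals.dropna().index.intersection(k27_signals.dropna().index)
    n_dropped = len(k4_signals.index.union(k27_signals.index)) - len(common)
    if n_dropped:
        warnings.warn(f"{n_dropped} gene(s) missing a mark excluded from bivalency", stacklevel=2)
    k4, k27 = k4_signals[common], k27_signals[common]
    cut4, cut27 = k4.quantile(quantile), k27.quantile(quantile)
    return common[(k4 > cut4) & (k27 > cut27)]


def stratified_normal_cancer_t(
    region_betas: pd.DataFrame,
    normal_ids: list[str],
    cancer_ids: list[str],
    strata: pd.Series,
    unit: str = "genes",
) -> pd.DataFrame:
    """Cancer-vs-normal t statistic within each promoter stratum.

    ``strata`` maps gene -> stratum name.  With unit='genes' (default) the
    t-test compares the per-gene cancer-mean betas against the per-gene
    normal-mean betas across the stratum's genes; unit='samples' pools all
    sample-level region values instead.  Strata with <3 genes are skipped.
    """
    if len(normal_ids) < 2 or len(cancer_ids) < 2:
        raise ValueError("need >=2 samples per phenotype")
    strata = strata.reindex(region_betas.index).dropna()
    rows = []
    for stratum in sorted(strata.unique()):
        genes = strata.index[strata == stratum]
        if len(genes) < 3:
            warnings.warn(f"stratum {stratum!r} has <3 genes; skipped", stacklevel=2)
            continue
        sub = region_betas.loc[genes]
        normal_means = sub[normal_ids].mean(axis=1)
        cancer_means = sub[cancer_ids].mean(axis=1)
        if unit == "genes":
            res = stats.ttest_ind(cancer_means, normal_means, equal_var=False)
        elif unit == "samples":
            res = stats.ttest_ind(
                sub[cancer_ids].to_numpy().ravel(),
                sub[normal_ids].to_numpy().ravel(),
                equal_var=False,
            )
        else:
            raise ValueError("unit must be 'genes' or 'samples'")
        rows.append(
            {
                "stratum": stratum,
                "n_genes": len(genes),
                "mean_beta_normal": float(normal_means.mean()),
                "mean_beta_cancer": float(cancer_means.mean()),
                "t": float(res.statistic),
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)


def partition_strata(dhs: pd.Series, bivalent: pd.Index | None = None) -> pd.Series:
    """Combine DHS membership and bivalency into one partition label per gene."""
    if bivalent is None:
        return dhs.map(lambda v: f"dhs_{v}")
    out = {}
    for gene, v in dhs.items():
        biv = "bivalent" if gene in bivalent else "nonbivalent"
        out[gene] = f"dhs_{v}|{biv}"
    return pd.Series(out, name="stratum")
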