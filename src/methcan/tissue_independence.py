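"""Differential methylation and cross-cancer correlation analysis.

Per-region Welch t-tests between normal and cancer cohorts, rank-based
DM/nonDM labelling (top/bottom N by t), phenotype-mean profiles, pairwise
R^2 matrices across cancer types, and the test of whether a cancer
correlates more with its own normal tissue than with other tissues' normals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_TOP_N = 300


def dm_t_test(
    region_betas: pd.DataFrame,
    normal_ids: list[str],
    cancer_ids: list[str],
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-region two-sample t (positive = higher in cancer) and two-tailed p.

    Welch's unequal-variance form by default; regions with zero variance in
    both groups are excluded (t undefined).
    """
    if len(normal_ids) < 2 or len(cancer_ids) < 2:
        raise ValueError("need >=2 samples in each group")
    a = region_betas[cancer_ids].to_numpy(dtype=float)
    b = region_betas[normal_ids].to_numpy(dtype=float)
    degenerate = (a == a[:, :1]).all(axis=1) & (b == b[:, :1]).all(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    out = pd.DataFrame(
        {"t": res.statistic, "p": res.pvalue}, index=region_betas.index
    )
    out.loc[degenerate, ["t", "p"]] = np.nan  # t undefined with no variance anywhere
    dropped = out.index[out["t"].isna()]
    if len(dropped):
        warnings.warn(f"{len(dropped)} region(s) with undefined t excluded", stacklevel=2)
        out = out.drop(index=dropped)
    return out


def rank_and_label(tstats: pd.Series, N: int = DEFAULT_TOP_N, direction: str = "hyper") -> pd.DataFrame:
    """Label the top N regions DM and bottom N nonDM by t statistic.

    direction='hyper' sorts t descending (hypermethylation first);
    'hypo' ascending.  Ties break by region id.  Returns a frame with
    columns t, rank, label over all regions.
    """
    if direction not in {"hyper", "hypo"}:
        raise ValueError("direction must be 'hyper' or 'hypo'")
    if 2 * N > len(tstats):
        raise ValueError(f"2N = {2 * N} exceeds number of regions {len(tstats)}")
    ascending = direction == "hypo"
    frame = tstats.rename("t").to_frame()
    frame["_id"] = frame.index.astype(str)
    frame = frame.sort_values(["t", "_id"], ascending=[ascending, True], kind="stable")
    frame["rank"] = np.arange(1, len(frame) + 1)
    labels = np.array(["unlabeled"] * len(frame), dtype=object)
    labels[:N] = "DM"
    labels[-N:] = "nonDM"
    frame["label"] = labels
    return frame.drop(columns="_id")


def phenotype_mean_profile(region_betas: pd.DataFrame, sample_ids: list[str]) -> pd.Series:
    """Per-region mean beta over a sample group."""
    if not sample_ids:
        raise ValueError("empty sample group")
    return region_betas[sample_ids].mean(axis=1)


def pairwise_r2(
    profiles: dict[str, pd.Series], region_subset=None
) -> tuple[pd.DataFrame, float]:
    """Symmetric R^2 (squared Pearson) matrix over phenotype-mean profiles.

    Returns the matrix and the mean off-diagonal R^2.  A zero-variance
    profile yields NaN entries for its pairs (flagged by warning).
    """
    names = list(profiles)
    if region_subset is not None:
        profiles = {k: v.loc[region_subset] for k, v in profiles.items()}
    lengths = {len(v) for v in profiles.values()}
    if len(lengths) != 1:
        raise ValueError("profiles must cover the same region subset")
    if lengths.pop() < 3:
        raise ValueError("need >=3 regions")
    mat = np.column_stack([profiles[n].to_numpy(dtype=float) for n in names])
    sd = mat.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("zero-variance profile: its pairwise entries are NaN", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(mat, rowvar=False)
    r2 = r**2
    np.fill_diagonal(r2, 1.0)
    r2[sd == 0, :] = np.nan
    r2[:, sd == 0] = np.nan
    np.fill_diagonal(r2, 1.0)
    frame = pd.DataFrame(r2, index=names, columns=names)
    off = r2[~np.eye(len(names), dtype=bool)]
    return frame, float(np.nanmean(off)) if len(off) else float("nan")


def own_vs_other_normal_test(r2_matrix: pd.DataFrame, per_cancer_mean: bool = False) -> tuple[float, float]:
    """Two-sample t of diagonal (own-normal) vs off-diagonal R^2 entries.

    Rows are cancers, columns normals.  Positive t means a cancer resembles
    its own normal tissue more than other tissues' normals.  With
    ``per_cancer_mean`` the off-diagonal entries are first averaged within
    each cancer (row) before testing.
    """
    if r2_matrix.shape[0] != r2_matrix.shape[1]:
        raise ValueError("R^2 matrix must be square (cancers x normals)")
    n = r2_matrix.shape[0]
    if n < 3:
        raise ValueError("need >=3 tissues")
    vals = r2_matrix.to_numpy(dtype=float)
    diag = np.diag(vals)
    offmask = ~np.eye(n, dtype=bool)
    if per_cancer_mean:
        off = np.array([vals[i, offmask[i]].mean() for i in range(n)])
    else:
        off = vals[offmask]
    res = stats.ttest_ind(diag, off, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def top_ranked_matrix(
    profiles: dict[str, pd.Series], reference: str, n: int = 1500
) -> pd.DataFrame:
    """Regions sorted by the reference phenotype's mean beta, truncated to n.

    All phenotype columns are carried along, ready for heatmap export.
    Ties break by region id.
    """
    if reference not in profiles:
        raise ValueError(f"unknown reference phenotype {reference!r}")
    frame = pd.DataFrame(profiles)
    if n > len(frame):
        raise ValueError(f"n = {n} exceeds number of regions {len(frame)}")
    frame["_id"] = frame.index.astype(str)
    frame = frame.sort_values([reference, "_id"], ascending=[False, True], kind="stable")
    return frame.drop(columns="_id").head(n)
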