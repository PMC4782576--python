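"""ROC/AUC prediction of cancer differential methylation from histone signals.

A threshold sweep over the signal defines occupancy (signal >= threshold) at
each gene; sensitivity / 1-specificity over the sweep give the ROC curve and
its trapezoid AUC, which equals the Mann-Whitney concordance probability
with half credit for ties.  Also: the paired Wilcoxon comparison of
normal-tissue vs hESC AUCs, the 1000+1000 DM gene set, the stratified
train/validation/test split, logistic fits with Wald z and AIC, and
selection among the seven predictor subsets of {K4, K27, K36}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .tissue_independence import rank_and_label

MARKS = ("H3K4me3", "H3K27me3", "H3K36me3")


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    points: np.ndarray          # (n, 2) of (1-specificity, sensitivity), sorted
    auc: float
    n_pos: int
    n_neg: int
    n_excluded: int = 0


def _clean_signal_labels(signal: pd.Series, labels: pd.Series):
    labels = labels.reindex(signal.index).dropna()
    signal = signal.reindex(labels.index)
    keep = signal.notna()
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} gene(s) with missing signal excluded", stacklevel=3)
    signal, labels = signal[keep], labels[keep]
    y = labels == "DM"
    if y.all() or (~y).all():
        raise ValueError("need at least one gene in each of DM and nonDM")
    return signal.to_numpy(dtype=float), y.to_numpy(), n_excluded


def roc_curve(signal: pd.Series, labels: pd.Series) -> ROCResult:
    """ROC from the occupancy threshold sweep; AUC by trapezoid.

    ``labels`` holds 'DM' (positive class) and 'nonDM'; other labels are
    ignored.  Occupancy at a threshold is signal >= threshold; thresholds
    are the unique signal values.
    """
    x, y, n_excluded = _clean_signal_labels(signal, labels[labels.isin(["DM", "nonDM"])])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    pts = [(0.0, 0.0)]
    for thr in np.unique(x)[::-1]:
        occupied = x >= thr
        tp = int((occupied & y).sum())
        fp = int((occupied & ~y).sum())
        pts.append((fp / n_neg, tp / n_pos))
    pts.append((1.0, 1.0))
    points = np.array(sorted(set(pts)))
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return ROCResult(points=points, auc=auc, n_pos=n_pos, n_neg=n_neg, n_excluded=n_excluded)


def auc_from_labels(signal: pd.Series, labels: pd.Series) -> float:
    """Mann-Whitney AUC: (concordant + 0.5 * tied) / (n_DM * n_nonDM)."""
    x, y, _ = _clean_signal_labels(signal, labels[labels.isin(["DM", "nonDM"])])
    pos, neg = x[y], x[~y]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def predict_dm_auc(
    gene_signals: dict[tuple[str, str], pd.Series],
    dm_labels: pd.Series,
    direction: str = "hyper",
) -> pd.DataFrame:
    """AUC per (mark, source) for one tissue's DM labels.

    ``gene_signals`` maps (mark, source) -> per-gene <S>; ``dm_labels`` is a
    rank_and_label output column restricted to the analysed region set.
    Missing combinations are skipped with a warning.
    """
    rows = []
    for (mark, source), signal in gene_signals.items():
        if signal is None or signal.dropna().empty:
            warnings.warn(f"no signal for ({mark}, {source}); skipped", stacklevel=2)
            continue
        roc = roc_curve(signal, dm_labels)
        rows.append(
            {"mark": mark, "source": source, "direction": direction,
             "auc": roc.auc, "n_pos": roc.n_pos, "n_neg": roc.n_neg}
        )
    return pd.DataFrame(rows)


def auc_over_n_grid(
    signal: pd.Series, tstats: pd.Series, n_grid, direction: str = "hyper"
) -> pd.DataFrame:
    """Robustness of the AUC to the DM set size N."""
    rows = []
    for n in n_grid:
        labels = rank_and_label(tstats, N=int(n), direction=direction)["label"]
        rows.append({"N": int(n), "auc": roc_curve(signal, labels).auc})
    return pd.DataFrame(rows)


def paired_wilcoxon_auc(auc_pairs: pd.DataFrame, alternative: str = "greater") -> float:
    """One-tailed paired Wilcoxon signed-rank p for normal-vs-hESC AUCs.

    ``auc_pairs`` has columns 'normal' and 'hesc', one row per tissue (or
    tissue x mark when pooling marks into a single test).  Zero differences
    are dropped; the exact distribution is used up to 25 pairs, a normal
    approximation with continuity correction beyond.
    """
    diffs = (auc_pairs["normal"] - auc_pairs["hesc"]).to_numpy(dtype=float)
    nz = diffs[diffs != 0]
    if nz.size == 0:
        warnings.warn("all AUC differences are zero; p = 1", stacklevel=2)
        return 1.0
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(
        nz, alternative=alternative, zero_method="wilcox", correction=True, method=method
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# DM gene set, split, logistic models
# ---------------------------------------------------------------------------

def build_dm_gene_set(tstats: pd.Series, direction: str = "hyper") -> pd.DataFrame:
    """Top 1000 + bottom 1000 genes by t, labelled DM / nonDM."""
    if len(tstats) < 2000:
        raise ValueError(f"need >=2000 genes, got {len(tstats)}")
    frame = rank_and_label(tstats, N=1000, direction=direction)
    return frame[frame["label"] != "unlabeled"]


def stratified_split(
    labels: pd.Series,
    fractions: tuple[float, float, float] = (0.5, 0.2, 0.3),
    seed: int = 0,
) -> pd.Series:
    """Assign genes to train/validation/test preserving DM/nonDM balance.

    Within each label class genes are shuffled with the seed and allocated
    by largest-remainder rounding of the fractions.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    parts = ("train", "validation", "test")
    rng = np.random.default_rng(seed)
    assignment = pd.Series(index=labels.index, dtype=object, name="split")
    for cls in sorted(labels.unique()):
        ids = labels.index[labels == cls].to_numpy()
        ids = ids[np.argsort([str(i) for i in ids], kind="stable")]
        rng.shuffle(ids)
        n = len(ids)
        raw = np.array(fractions) * n
        counts = np.floor(raw).astype(int)
        for i in np.argsort(-(raw - counts), kind="stable")[: n - counts.sum()]:
            counts[i] += 1
        if np.any(counts == 0):
            raise ValueError(f"class {cls!r} would leave a split part empty")
        edges = np.concatenate([[0], np.cumsum(counts)])
        for part, lo, hi in zip(parts, edges[:-1], edges[1:]):
            assignment[ids[lo:hi]] = part
    return assignment


@dataclass
class ModelFit:
    predictors: tuple[str, ...]
    coefficients: pd.Series           # includes the intercept ('const')
    z: pd.Series
    loglik: float
    aic: float
    separation_flag: bool = False
    train_auc: float | None = None
    validation_auc: float | None = None
    test_auc: float | None = None
    scaler: tuple[pd.Series, pd.Series] | None = None  # (mean, sd) on training data

    def decision(self, design: pd.DataFrame) -> pd.Series:
        """Linear predictor on standardized inputs (monotone in P(DM))."""
        x = design[list(self.predictors)].astype(float)
        if self.scaler is not None:
            mean, sd = self.scaler
            x = (x - mean[list(self.predictors)]) / sd[list(self.predictors)]
        lin = self.coefficients["const"] + x.to_numpy() @ self.coefficients[
            list(self.predictors)
        ].to_numpy()
        return pd.Series(lin, index=design.index)


def fit_logistic(design: pd.DataFrame, labels: pd.Series, standardize: bool = True) -> ModelFit:
    """Maximum-likelihood logistic fit of DM status on histone signals.

    Genes with any missing predictor are dropped; predictors are
    standardized (mean 0, sd 1 on the fitting data) so coefficients are
    comparable across marks — the Wald z statistics are scale-invariant
    either way.  AIC = 2k - 2 lnL with k counting the intercept.
    """
    labels = labels.reindex(design.index).dropna()
    x = design.loc[labels.index].astype(float).dropna()
    n_dropped = len(labels) - len(x)
    if n_dropped:
        warnings.warn(f"{n_dropped} gene(s) dropped for missing predictors", stacklevel=2)
    y = (labels.loc[x.index] == "DM").astype(float)
    if y.nunique() < 2:
        raise ValueError("labels are single-class after filtering")
    scaler = None
    if standardize:
        mean, sd = x.mean(), x.std(ddof=0)
        if (sd == 0).any():
            raise ValueError("constant predictor cannot be standardized")
        x = (x - mean) / sd
        scaler = (mean, sd)
    exog = sm.add_constant(x, has_constant="add")
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 50:
            separation = True
    except Exception:
        # perfect separation: fall back to IRLS capped at the iteration limit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, exog, family=sm.families.Binomial()).fit(maxiter=100)
        separation = True
    coefs = pd.Series(res.params, index=exog.columns)
    zstats = pd.Series(res.params / res.bse, index=exog.columns)
    return ModelFit(
        predictors=tuple(design.columns),
        coefficients=coefs,
        z=zstats,
        loglik=float(res.llf),
        aic=float(2 * len(coefs) - 2 * res.llf),
        separation_flag=separation,
        scaler=scaler,
    )


def model_selection(
    signals: pd.DataFrame,
    labels: pd.Series,
    split: pd.Series,
    predictors: tuple[str, ...] = MARKS,
) -> tuple[ModelFit, pd.DataFrame]:
    """Fit all 7 predictor subsets on train; choose by validation AUC.

    Ties prefer fewer predictors, then lower AIC.  The winning model's AUC
    on the blind test part is recorded; the report covers every model.
    """
    labels = labels.reindex(signals.index).dropna()
    split = split.reindex(labels.index)
    parts = {p: split.index[split == p] for p in ("train", "validation", "test")}
    subsets = [
        combo
        for r in (1, 2, 3)
        for combo in combinations(predictors, r)
    ]
    fits: list[ModelFit] = []
    rows = []
    for subset in subsets:
        design = signals.loc[labels.index, list(subset)]
        try:
            fit = fit_logistic(design.loc[parts["train"]], labels.loc[parts["train"]])
        except Exception as exc:  # report and move on
            warnings.warn(f"model {subset} failed to fit: {exc}", stacklevel=2)
            continue
        for part in ("train", "validation"):
            score = fit.decision(design.loc[parts[part]])
            auc = roc_curve(score, labels.loc[parts[part]]).auc
            if part == "train":
                fit.train_auc = auc
            else:
                fit.validation_auc = auc
        fits.append(fit)
        rows.append(
            {"predictors": "+".join(subset), "n_predictors": len(subset),
             "train_auc": fit.train_auc, "validation_auc": fit.validation_auc,
             "aic": fit.aic, "separation": fit.separation_flag}
        )
    if not fits:
        raise ValueError("no model could be fitted")
    order = sorted(
        range(len(fits)),
        key=lambda i: (-fits[i].validation_auc, len(fits[i].predictors), fits[i].aic),
    )
    best = fits[order[0]]
    test_design = signals.loc[labels.index, list(best.predictors)].loc[parts["test"]]
    best.test_auc = roc_curve(best.decision(test_design), labels.loc[parts["test"]]).auc
    report = pd.DataFrame(rows)
    report["selected"] = [i == order[0] for i in range(len(fits))]
    report.loc[report["selected"], "test_auc"] = best.test_auc
    return best, report
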