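"""450k-style beta-value preprocessing.

Probe coverage filtering, kNN imputation, a per-sample three-state
(unmethylated / half- / fully methylated) beta-mixture model fitted by EM
with posterior-crossing state thresholds, region-level aggregation, an SVD
sanity check that the leading axis of variation tracks normal/cancer status,
and probe-density statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .genome import ProbeManifest

EPS_BOUNDARY = 1e-6  # nudge applied to beta values at exactly 0 or 1


# ---------------------------------------------------------------------------
# Coverage filter and kNN imputation
# ---------------------------------------------------------------------------

def filter_probes_by_coverage(m: pd.DataFrame, min_frac: float = 0.7) -> pd.DataFrame:
    """Remove probes observed in fewer than ``min_frac`` of samples.

    The filter is strict at the boundary: a probe with coverage exactly
    ``min_frac`` is retained.  Probe order is preserved.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    frac = m.notna().mean(axis=1)
    keep = frac >= min_frac
    if not keep.any():
        raise ValueError("coverage filter removed every probe")
    return m.loc[keep]


def impute_knn(m: pd.DataFrame, k: int = 5, max_donors: int | None = None) -> pd.DataFrame:
    """Impute missing entries from the k nearest probes (rows).

    Distance between two probes is the root mean squared difference over the
    samples where both are observed (pairwise-complete, count-normalised);
    probe pairs with no shared observed sample are non-neighbours.  A missing
    entry (probe i, sample j) becomes the mean over sample j of the k nearest
    probes that are observed at j, ties broken by probe row order.  Observed
    values are never altered.

    ``max_donors`` optionally caps the donor pool to that many probes —
    those with the most observed values, ties by row order — which keeps the
    distance computation tractable on large matrices; with the default
    ``None`` every probe is a candidate neighbour.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = m.to_numpy(dtype=float)
    mask = np.isfinite(values)
    if not mask.any(axis=1).all():
        bad = m.index[~mask.any(axis=1)].tolist()
        raise ValueError(f"probes with no observed value cannot be imputed: {bad[:5]}")
    out = values.copy()
    target_rows = np.flatnonzero(~mask.all(axis=1))
    if target_rows.size == 0:
        return m.copy()

    n = values.shape[0]
    if max_donors is not None and n > max_donors:
        obs_counts = mask.sum(axis=1)
        donor_rows = np.sort(np.argsort(-obs_counts, kind="stable")[:max_donors])
    else:
        donor_rows = np.arange(n)

    x = np.where(mask, values, 0.0)
    mk = mask.astype(float)
    d_x, d_m = x[donor_rows], mk[donor_rows]
    t_x, t_m = x[target_rows], mk[target_rows]
    # squared distances via masked matrix products
    sq = (t_x**2) @ d_m.T + t_m @ (d_x**2).T - 2.0 * (t_x @ d_x.T)
    counts = t_m @ d_m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(np.maximum(sq, 0.0) / counts)
    dist[counts == 0] = np.inf

    # a target must not be its own donor
    donor_pos = {int(r): c for c, r in enumerate(donor_rows)}
    for ti, i in enumerate(target_rows):
        if i in donor_pos:
            dist[ti, donor_pos[i]] = np.inf

    # neighbour order per target: ascending distance, distance ties resolved
    # by donor position (= probe row order, donor_rows being sorted).  Only
    # the nearest K0 candidates are ordered via argpartition; rows where the
    # K0-boundary is ambiguous (tied or non-finite) use a full stable sort,
    # so the result is identical to sorting every donor.
    n_d = donor_rows.size
    K0 = min(n_d, k + 64)
    if K0 < n_d:
        cand_pos = np.sort(np.argpartition(dist, K0 - 1, axis=1)[:, :K0], axis=1)
        d_cand = np.take_along_axis(dist, cand_pos, axis=1)
        d_bound = d_cand.max(axis=1)
        with np.errstate(invalid="ignore"):
            ambiguous = (dist <= d_bound[:, None]).sum(axis=1) != K0
        ambiguous |= ~np.isfinite(d_bound)
        rows = np.flatnonzero(ambiguous)
        if rows.size:
            full = np.argsort(dist[rows], axis=1, kind="stable")[:, :K0]
            cand_pos[rows] = full
            d_cand[rows] = np.take_along_axis(dist[rows], full, axis=1)
        sub = np.argsort(d_cand, axis=1, kind="stable")
        order = np.take_along_axis(cand_pos, sub, axis=1)
    else:
        order = np.argsort(dist, axis=1, kind="stable")
    usable_sorted = np.isfinite(np.take_along_axis(dist, order, axis=1))
    cand_rows = donor_rows[order]

    def _exact_entry(t_idx: int, j: int) -> float:
        """Full-sort fallback for an entry needing more than K0 candidates."""
        full_order = np.argsort(dist[t_idx], kind="stable")
        usable = np.isfinite(dist[t_idx][full_order])
        donors = donor_rows[full_order[usable]]
        donors = donors[mask[donors, j]]
        if donors.size == 0:
            raise ValueError(
                f"no donor probe observed at sample {m.columns[j]!r} "
                f"for probe {m.index[target_rows[t_idx]]!r}"
            )
        if donors.size < k:
            warnings.warn(
                f"fewer than k={k} candidate neighbours available; using all",
                stacklevel=3,
            )
        return float(values[donors[:k], j].mean())

    ent_t, ent_j = np.nonzero(~mask[target_rows])  # positions / columns of gaps
    warned = False
    chunk = 2000
    for lo in range(0, ent_t.size, chunk):
        t_idx = ent_t[lo:lo + chunk]
        cols = ent_j[lo:lo + chunk]
        cand = cand_rows[t_idx]                      # (c, width) candidate rows
        ok = mask[cand, cols[:, None]] & usable_sorted[t_idx]
        rank = np.cumsum(ok, axis=1)
        pick = ok & (rank <= k)
        n_found = pick.sum(axis=1)
        short = n_found < k
        sums = np.where(pick, values[cand, cols[:, None]], 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            filled = sums / n_found
        for e in np.flatnonzero(short):
            if K0 < n_d:
                filled[e] = _exact_entry(int(t_idx[e]), int(cols[e]))
            elif n_found[e] == 0:
                raise ValueError(
                    f"no donor probe observed at sample {m.columns[cols[e]]!r} "
                    f"for probe {m.index[target_rows[t_idx[e]]]!r}"
                )
            elif not warned:
                warnings.warn(
                    f"fewer than k={k} candidate neighbours available; using all",
                    stacklevel=2,
                )
                warned = True
        out[target_rows[t_idx], cols] = filled
    return pd.DataFrame(out, index=m.index, columns=m.columns)


# ---------------------------------------------------------------------------
# Three-state beta mixture
# ---------------------------------------------------------------------------

@dataclass
class BetaMixtureFit:
    """Per-sample K-component beta mixture with derived state thresholds.

    Components are sorted by mean, so index 0 is the unmethylated state and
    index K-1 the fully methylated state.  ``lower`` / ``upper`` are the
    posterior-crossing thresholds L and U used for state calling; they are
    filled in by :func:`state_thresholds`.
    """

    weights: np.ndarray
    a: np.ndarray
    b: np.ndarray
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True
    degenerate: bool = False
    lower: float | None = None
    upper: float | None = None

    @property
    def means(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    def component_logpdf(self, x: np.ndarray) -> np.ndarray:
        """(K, n) matrix of log component densities."""
        x = np.asarray(x, dtype=float)
        return np.vstack(
            [stats.beta.logpdf(x, self.a[k], self.b[k]) for k in range(len(self.a))]
        )

    def posterior(self, x: np.ndarray) -> np.ndarray:
        lp = self.component_logpdf(x) + np.log(self.weights)[:, None]
        lp -= special.logsumexp(lp, axis=0, keepdims=True)
        return np.exp(lp)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "degenerate": bool(self.degenerate),
            "lower": None if self.lower is None else float(self.lower),
            "upper": None if self.upper is None else float(self.upper),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BetaMixtureFit":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            a=np.asarray(d["a"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            loglik=float(d["loglik"]),
            converged=bool(d.get("converged", True)),
            degenerate=bool(d.get("degenerate", False)),
            lower=d.get("lower"),
            upper=d.get("upper"),
        )


def _weighted_beta_mle(
    a0: float, b0: float, sw: float, slx: float, sl1x: float
) -> tuple[float, float]:
    """Maximise sw*[(a-1)m_lx + (b-1)m_l1x - ln B(a,b)] starting from (a0, b0).

    m_lx = slx/sw etc. are the weighted means of log(x) and log(1-x).  The
    optimiser is started at the current parameters so the EM step can never
    decrease the objective (generalised EM).
    """
    m_lx, m_l1x = slx / sw, sl1x / sw

    def neg(params):
        a, b = params
        val = (a - 1) * m_lx + (b - 1) * m_l1x - special.betaln(a, b)
        da = m_lx - special.digamma(a) + special.digamma(a + b)
        db = m_l1x - special.digamma(b) + special.digamma(a + b)
        return -val, -np.array([da, db])

    res = optimize.minimize(
        neg,
        x0=np.array([a0, b0]),
        jac=True,
        method="L-BFGS-B",
        bounds=[(1e-3, 1e6), (1e-3, 1e6)],
    )
    if res.fun <= neg(np.array([a0, b0]))[0]:
        return float(res.x[0]), float(res.x[1])
    return a0, b0


def _moment_init(x: np.ndarray, quantiles: tuple[float, ...], kappa0: float = 10.0):
    means = np.quantile(x, quantiles)
    means = np.clip(means, 0.02, 0.98)
    a = means * kappa0
    b = (1 - means) * kappa0
    w = np.full(len(quantiles), 1.0 / len(quantiles))
    return w, a, b


def fit_beta_mixture(
    sample_betas: np.ndarray | pd.Series,
    K: int = 3,
    tol: float = 1e-5,
    max_iter: int = 200,
    seed: int = 0,
) -> BetaMixtureFit:
    """Fit a K-component beta mixture to one sample's beta values by EM.

    Values at exactly 0/1 are nudged inward by 1e-6.  Initialisation is
    quantile-based (10th/50th/90th percentile for K=3), which is
    deterministic for a given seed; the seed is only consulted if a
    component degenerates and a jittered re-initialisation is needed.
    The M-step starts each component's optimiser at its current shape
    parameters, so the observed log-likelihood is non-decreasing.
    """
    x = np.asarray(sample_betas, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValueError(f"need >=100 finite beta values, got {x.size}")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    x = np.clip(x, EPS_BOUNDARY, 1 - EPS_BOUNDARY)
    lx, l1x = np.log(x), np.log1p(-x)

    quantiles = tuple(np.linspace(0.1, 0.9, K))
    w, a, b = _moment_init(x, quantiles)

    def run_em(w, a, b):
        trace: list[float] = []
        converged = False
        for _ in range(max_iter):
            # beta log-density from precomputed log(x), log(1-x)
            lp = (
                (a - 1)[:, None] * lx[None, :]
                + (b - 1)[:, None] * l1x[None, :]
                - special.betaln(a, b)[:, None]
            )
            lp += np.log(w)[:, None]
            norm = special.logsumexp(lp, axis=0)
            ll = float(norm.sum())
            resp = np.exp(lp - norm)
            trace.append(ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * (abs(trace[-2]) + 1):
                converged = True
                break
            sw = resp.sum(axis=1)
            if np.any(sw < 1e-12):
                return w, a, b, trace, converged, True
            for k in range(K):
                a[k], b[k] = _weighted_beta_mle(
                    a[k], b[k], sw[k], float(resp[k] @ lx), float(resp[k] @ l1x)
                )
            w = sw / x.size
        return w, a, b, trace, converged, False

    w, a, b, trace, converged, collapsed = run_em(w, a, b)
    degenerate = collapsed or bool(np.any(w < 1e-4))
    if degenerate:
        rng = np.random.default_rng(seed)
        w2, a2, b2 = _moment_init(x, quantiles)
        a2 = a2 * rng.uniform(0.8, 1.25, size=K)
        b2 = b2 * rng.uniform(0.8, 1.25, size=K)
        w, a, b, trace, converged, collapsed = run_em(w2, a2, b2)
        degenerate = collapsed or bool(np.any(w < 1e-4))
    if not converged:
        warnings.warn("beta-mixture EM did not converge; returning best fit", stacklevel=2)

    order = np.argsort(a / (a + b))
    fit = BetaMixtureFit(
        weights=np.asarray(w)[order],
        a=np.asarray(a)[order],
        b=np.asarray(b)[order],
        loglik=trace[-1],
        loglik_trace=trace,
        converged=converged,
        degenerate=degenerate,
    )
    return fit


def state_thresholds(fit: BetaMixtureFit, resolution: float = 1e-4) -> tuple[float, float]:
    """Posterior-crossing thresholds (L, U) of a three-state fit.

    L is the smallest grid beta in (mean1, mean2) where the half-methylated
    state is at least as probable a posteriori as the unmethylated state; U
    likewise between the half and fully methylated states.  The thresholds
    are stored on the fit and returned.
    """
    means = fit.means
    if len(means) != 3:
        raise ValueError("state thresholds require a three-component fit")
    if not (means[0] < means[1] < means[2]):
        raise ValueError("component means must be strictly increasing")

    def crossing(lo: float, hi: float, k_from: int, k_to: int) -> float:
        grid = np.arange(lo + resolution, hi, resolution)
        if grid.size == 0:
            raise ValueError(f"empty grid between components {k_from} and {k_to}")
        post = fit.posterior(grid)
        hit = np.flatnonzero(post[k_to] >= post[k_from])
        if hit.size == 0:
            raise ValueError(
                f"no posterior crossing between components {k_from} and {k_to}"
            )
        return float(grid[hit[0]])

    lower = crossing(means[0], means[1], 0, 1)
    upper = crossing(means[1], means[2], 1, 2)
    fit.lower, fit.upper = lower, upper
    return lower, upper


def fit_sample_thresholds(
    m: pd.DataFrame,
    seed: int = 0,
    subsample: int | None = None,
    **fit_kwargs,
) -> dict[str, BetaMixtureFit]:
    """Fit the three-state mixture and thresholds for every sample (column).

    ``subsample`` caps the number of probes used per fit (seeded draw); the
    mixture is a three-mode density and is stable under subsampling.
    """
    fits: dict[str, BetaMixtureFit] = {}
    for idx, sample in enumerate(m.columns):
        vals = m[sample].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if subsample is not None and vals.size > subsample:
            rng = np.random.default_rng([seed, idx])
            vals = rng.choice(vals, size=subsample, replace=False)
        fit = fit_beta_mixture(vals, seed=seed + idx, **fit_kwargs)
        state_thresholds(fit)
        fits[sample] = fit
    return fits


def preprocess_cohort(
    m: pd.DataFrame,
    min_frac: float = 0.7,
    k: int = 5,
    max_donors: int | None = None,
) -> pd.DataFrame:
    """Coverage filter then kNN imputation for one cohort's columns.

    Cohorts (the fetal compendium, and each tissue's normal+cancer set) are
    processed independently, so a probe's coverage is judged against the
    samples it was measured with.
    """
    return impute_knn(filter_probes_by_coverage(m, min_frac), k=k, max_donors=max_donors)


# ---------------------------------------------------------------------------
# Region aggregation, SVD check, probe density
# ---------------------------------------------------------------------------

def aggregate_region_beta(
    m: pd.DataFrame, manifest: ProbeManifest, region_class: str
) -> pd.DataFrame:
    """Average member-probe beta values per region (promoter / gene_body / cgi).

    Regions with no member probe present in the matrix are dropped.
    """
    members = manifest.region_members(region_class)
    pairs = members.explode()
    pairs = pairs[pairs.isin(m.index)]
    agg = m.loc[pairs.to_numpy()].groupby(pairs.index.to_numpy()).mean()
    agg = agg.reindex([r for r in members.index if r in agg.index])
    agg.index.name = "region_id"
    n_dropped = len(members) - len(agg)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} {region_class} region(s) had no probes in the matrix",
            stacklevel=2,
        )
    return agg


def svd_phenotype_check(
    m: pd.DataFrame, labels: pd.Series, threshold: float = 0.5
) -> dict:
    """Check that the leading axis of sample variation tracks the phenotype.

    Each probe (row) is centred, the top right-singular vector of the
    centred matrix is correlated with the binary label vector, and the check
    passes when |r| exceeds ``threshold``.
    """
    labels = labels.reindex(m.columns)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 label classes, got {classes}")
    if labels.value_counts().min() < 2:
        raise ValueError("need >=2 samples per label class")
    y = (labels == classes[1]).astype(float).to_numpy()
    centred = m.to_numpy(dtype=float) - m.to_numpy(dtype=float).mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    v1 = vt[0]
    r = float(np.corrcoef(v1, y)[0, 1])
    return {
        "r": r,
        "singular_values": s,
        "top_right_vector": v1,
        "passed": bool(abs(r) > threshold),
    }


def probe_density(
    manifest: ProbeManifest, cgis: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region probe densities and pairwise t-tests between region classes.

    Gene regions (TSS200, Body) use n_probes / max pairwise probe distance
    and need >=2 probes; regions with fewer are skipped.  CGI density uses
    n_probes / (end - start), which requires a ``cgis`` table with columns
    cgi_id, start, end.
    """
    records = []
    t = manifest.table
    for region_class in ("TSS200", "Body"):
        sub = t[t["region_class"] == region_class]
        for gene_id, grp in sub.groupby("gene_id"):
            if len(grp) < 2:
                continue
            span = grp["pos"].max() - grp["pos"].min()
            if span <= 0:
                continue
            records.append(
                {"region_class": region_class, "region_id": gene_id,
                 "density": len(grp) / span}
            )
    if cgis is not None:
        counts = t[t["cgi_id"] != ""].groupby("cgi_id").size()
        for row in cgis.itertuples(index=False):
            n = int(counts.get(row.cgi_id, 0))
            length = int(row.end) - int(row.start)
            if n == 0 or length <= 0:
                continue
            records.append({"region_class": "CGI", "region_id": row.cgi_id,
                            "density": n / length})
    densities = pd.DataFrame(records)
    tests = []
    classes = densities["region_class"].unique().tolist() if len(densities) else []
    for i, ci in enumerate(classes):
        for cj in classes[i + 1:]:
            xi = densities.loc[densities["region_class"] == ci, "density"]
            xj = densities.loc[densities["region_class"] == cj, "density"]
            tt = stats.ttest_ind(xi, xj, equal_var=False)
            tests.append({"class_a": ci, "class_b": cj,
                          "t": float(tt.statistic), "p": float(tt.pvalue)})
    return densities, pd.DataFrame(tests)


# ---------------------------------------------------------------------------
# Tab-separated matrix I/O
# ---------------------------------------------------------------------------

def write_beta_matrix(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", index_label="id", float_format="%.6g")


def read_beta_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
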