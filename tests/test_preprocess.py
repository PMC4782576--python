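import numpy as np
import pandas as pd
import pytest

from methcan.preprocess import (
    aggregate_region_beta,
    filter_probes_by_coverage,
    fit_beta_mixture,
    impute_knn,
    probe_density,
    state_thresholds,
    svd_phenotype_check,
)
from methcan.genome import ProbeManifest
from methcan.preprocess import BetaMixtureFit


def knn_oracle(m: pd.DataFrame, k: int) -> np.ndarray:
    """Exhaustive-search kNN imputation (pairwise-complete RMS distance)."""
    M = np.isfinite(m.to_numpy())
    V = m.to_numpy()
    out = V.copy()
    n = len(m)
    for i in range(n):
        for j in range(m.shape[1]):
            if M[i, j]:
                continue
            ds = []
            for r in range(n):
                if r == i:
                    continue
                shared = M[i] & M[r]
                if not shared.any():
                    continue
                ds.append((np.sqrt(((V[i, shared] - V[r, shared]) ** 2).mean()), r))
            ds.sort(key=lambda t: (t[0], t[1]))
            donors = [r for _, r in ds if M[r, j]][:k]
            out[i, j] = np.mean(V[donors, j])
    return out


class TestCoverageFilter:
    def test_strict_boundary(self):
        m = pd.DataFrame(np.ones((2, 10)))
        m.iloc[0, :4] = np.nan  # 6/10 present -> removed
        m.iloc[1, :3] = np.nan  # 7/10 present -> retained
        out = filter_probes_by_coverage(m, 0.7)
        assert list(out.index) == [1]

    def test_fully_observed_identity(self):
        m = pd.DataFrame(np.random.default_rng(0).random((5, 4)))
        pd.testing.assert_frame_equal(filter_probes_by_coverage(m), m)

    def test_all_removed_is_error(self):
        m = pd.DataFrame(np.full((3, 4), np.nan))
        m.iloc[:, 0] = 0.5
        with pytest.raises(ValueError, match="every probe"):
            filter_probes_by_coverage(m, 0.7)


class TestImputeKnn:
    def test_uniform_neighbours(self):
        m = pd.DataFrame(np.full((7, 3), 0.4))
        m += np.arange(7)[:, None] * 1e-4  # distinct but close probes
        m.iloc[0, 1] = np.nan
        out = impute_knn(m, k=5)
        assert out.iloc[0, 1] == pytest.approx(m.iloc[1:6, 1].mean())

    def test_no_missing_identity(self, rng):
        m = pd.DataFrame(rng.random((10, 5)))
        pd.testing.assert_frame_equal(impute_knn(m), m)

    def test_matches_bruteforce_oracle(self, rng):
        """30-probe fixture equals the exhaustive-search kNN oracle."""
        for _ in range(5):
            vals = rng.random((30, 8))
            miss = rng.random((30, 8)) < 0.25
            miss[miss.all(axis=1)] = False
            m = pd.DataFrame(np.where(miss, np.nan, vals))
            k = int(rng.integers(1, 7))
            got = impute_knn(m, k=k)
            assert np.allclose(got.to_numpy(), knn_oracle(m, k), atol=1e-12)

    def test_max_donors_matches_restricted_oracle(self, rng):
        vals = rng.random((40, 6))
        miss = rng.random((40, 6)) < 0.2
        miss[miss.all(axis=1)] = False
        m = pd.DataFrame(np.where(miss, np.nan, vals))
        got = impute_knn(m, k=3, max_donors=15)
        pool = np.sort(np.argsort(-np.isfinite(m.to_numpy()).sum(1), kind="stable")[:15])
        restricted = knn_oracle(m.iloc[list(pool)].reindex(m.index), 3)  # placeholder
        # direct restricted oracle
        M = np.isfinite(m.to_numpy())
        V = m.to_numpy()
        exp = V.copy()
        for i in range(40):
            for j in range(6):
                if M[i, j]:
                    continue
                ds = []
                for r in pool:
                    if r == i:
                        continue
                    shared = M[i] & M[r]
                    if not shared.any():
                        continue
                    ds.append((np.sqrt(((V[i, shared] - V[r, shared]) ** 2).mean()), r))
                ds.sort(key=lambda t: (t[0], t[1]))
                donors = [r for _, r in ds if M[r, j]][:3]
                exp[i, j] = np.mean(V[donors, j])
        assert np.allclose(got.to_numpy(), exp, atol=1e-12)

    def test_exact_ties_resolved_by_row_order(self, rng):
        base = rng.random(6)
        m = pd.DataFrame([base] * 4 + [base + 0.5])  # rows 1-3 at distance exactly 0
        m.iloc[0, 2] = np.nan
        out = impute_knn(m, k=2)
        assert out.iloc[0, 2] == base[2]

    def test_observed_values_untouched_and_range_preserved(self, rng):
        vals = rng.random((25, 6))
        miss = rng.random((25, 6)) < 0.2
        miss[miss.all(axis=1)] = False
        m = pd.DataFrame(np.where(miss, np.nan, vals))
        out = impute_knn(m, k=4)
        obs = m.notna().to_numpy()
        assert np.array_equal(out.to_numpy()[obs], m.to_numpy()[obs])
        # imputed values are means of observed donors, hence inside their range
        assert out.to_numpy().min() >= np.nanmin(m.to_numpy())
        assert out.to_numpy().max() <= np.nanmax(m.to_numpy())

    def test_filter_impute_idempotent(self, rng):
        vals = rng.random((20, 10))
        miss = rng.random((20, 10)) < 0.15
        m = pd.DataFrame(np.where(miss, np.nan, vals))
        once = impute_knn(filter_probes_by_coverage(m), k=3)
        twice = impute_knn(filter_probes_by_coverage(once), k=3)
        pd.testing.assert_frame_equal(once, twice)


class TestBetaMixture:
    @pytest.fixture(scope="class")
    def well_separated_fit(self):
        rng = np.random.default_rng(7)
        x = np.concatenate(
            [rng.beta(2, 18, 1700), rng.beta(10, 10, 1600), rng.beta(18, 2, 1700)]
        )
        fit = fit_beta_mixture(x, seed=7)
        state_thresholds(fit)
        return fit

    def test_recovers_component_means(self, well_separated_fit):
        assert np.allclose(well_separated_fit.means, [0.1, 0.5, 0.9], atol=0.05)

    def test_loglik_monotone(self, well_separated_fit):
        trace = np.array(well_separated_fit.loglik_trace)
        assert (np.diff(trace) >= -1e-8 * np.abs(trace[:-1])).all()

    def test_single_component_data_stays_in_middle(self):
        """Unimodal mid-range data must not spawn extreme-state components.

        The maximum-likelihood fit may share the central hump between
        near-identical components, so the check is on where the weight sits,
        not on a single component's share.
        """
        rng = np.random.default_rng(3)
        fit = fit_beta_mixture(rng.beta(5, 5, 4000), seed=3)
        central = (fit.means > 0.35) & (fit.means < 0.65)
        assert fit.weights[central].sum() >= 0.9

    def test_thresholds_between_means(self, well_separated_fit):
        L, U = well_separated_fit.lower, well_separated_fit.upper
        assert 0.1 < L < 0.5 < U < 0.9

    def test_thresholds_match_posterior_grid_oracle(self, well_separated_fit):
        fit = well_separated_fit
        grid = np.arange(fit.means[0] + 1e-4, fit.means[1], 1e-4)
        post = fit.posterior(grid)
        expected_L = grid[np.flatnonzero(post[1] >= post[0])[0]]
        assert fit.lower == pytest.approx(expected_L, abs=1e-9)

    def test_symmetric_fit_thresholds_mirror(self):
        fit = BetaMixtureFit(
            weights=np.array([1 / 3, 1 / 3, 1 / 3]),
            a=np.array([2.0, 10.0, 18.0]),
            b=np.array([18.0, 10.0, 2.0]),
            loglik=0.0,
        )
        L, U = state_thresholds(fit)
        assert L + U == pytest.approx(1.0, abs=1e-3)

    def test_raising_first_weight_moves_lower_threshold_right(self):
        def fit_with_w1(w1):
            w = np.array([w1, (1 - w1) / 2, (1 - w1) / 2])
            f = BetaMixtureFit(
                weights=w, a=np.array([2.0, 10.0, 18.0]), b=np.array([18.0, 10.0, 2.0]), loglik=0.0
            )
            return state_thresholds(f)[0]

        assert fit_with_w1(0.6) > fit_with_w1(0.2)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">=100"):
            fit_beta_mixture(np.linspace(0.1, 0.9, 50))


def tiny_manifest():
    rows = []
    for g in range(4):
        for j in range(3):
            rows.append((f"g{g}_p{j}", "chr1", 1000 * g + j * 50, f"g{g}", "TSS200", ""))
        for j in range(2):
            rows.append((f"g{g}_b{j}", "chr1", 1000 * g + 500 + j * 100, f"g{g}", "Body", ""))
    rows.append(("c0_0", "chr1", 10, "", "", "cgi0"))
    rows.append(("c0_1", "chr1", 20, "", "", "cgi0"))
    return ProbeManifest(
        pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "gene_id", "region_class", "cgi_id"])
    )


class TestAggregation:
    def test_mean_of_member_probes(self):
        mani = tiny_manifest()
        m = pd.DataFrame(
            {"s1": [0.2, 0.4, 0.6]},
            index=["g0_p0", "g0_p1", "g0_p2"],
        )
        out = aggregate_region_beta(m, mani, "promoter")
        assert out.loc["g0", "s1"] == pytest.approx(0.4)

    def test_constant_probes_identity(self, rng):
        mani = tiny_manifest()
        ids = mani.table["probe_id"]
        m = pd.DataFrame(0.37, index=ids, columns=["s1", "s2"])
        for rc in ("promoter", "gene_body", "cgi"):
            out = aggregate_region_beta(m, mani, rc)
            assert np.allclose(out.to_numpy(), 0.37)

    def test_matches_direct_mean_oracle(self, rng):
        mani = tiny_manifest()
        ids = mani.table["probe_id"]
        m = pd.DataFrame(rng.random((len(ids), 5)), index=ids, columns=list("abcde"))
        out = aggregate_region_beta(m, mani, "promoter")
        for g in ("g0", "g1", "g2", "g3"):
            probes = [f"{g}_p{j}" for j in range(3)]
            assert np.allclose(out.loc[g], m.loc[probes].mean(axis=0))

    def test_commutes_with_sample_subsetting(self, rng):
        mani = tiny_manifest()
        ids = mani.table["probe_id"]
        m = pd.DataFrame(rng.random((len(ids), 6)), index=ids, columns=list("abcdef"))
        sub = ["b", "d"]
        left = aggregate_region_beta(m, mani, "gene_body")[sub]
        right = aggregate_region_beta(m[sub], mani, "gene_body")
        pd.testing.assert_frame_equal(left, right)

    def test_unknown_region_class(self):
        with pytest.raises(ValueError):
            aggregate_region_beta(pd.DataFrame(), tiny_manifest(), "enhancer")


class TestSvdCheck:
    def test_group_shift_detected(self, rng):
        base = rng.random(200)
        cols = {}
        for i in range(6):
            cols[f"n{i}"] = base + rng.normal(0, 0.01, 200)
        for i in range(6):
            cols[f"c{i}"] = base + 0.5 + rng.normal(0, 0.01, 200)
        m = pd.DataFrame(cols)
        labels = pd.Series(["normal"] * 6 + ["cancer"] * 6, index=m.columns)
        res = svd_phenotype_check(m, labels)
        assert abs(res["r"]) > 0.9 and res["passed"]

    def test_noise_rarely_passes(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            m = pd.DataFrame(r.random((100, 12)))
            labels = pd.Series(["a"] * 6 + ["b"] * 6, index=m.columns)
            hits += svd_phenotype_check(m, labels)["passed"]
        assert hits <= 1

    def test_label_permutation_leaves_singular_values(self, rng):
        m = pd.DataFrame(rng.random((50, 8)))
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=m.columns)
        s1 = svd_phenotype_check(m, labels)["singular_values"]
        s2 = svd_phenotype_check(m, labels.sample(frac=1, random_state=1))["singular_values"]
        assert np.allclose(s1, s2)

    def test_single_label_error(self, rng):
        m = pd.DataFrame(rng.random((10, 4)))
        labels = pd.Series(["a"] * 4, index=m.columns)
        with pytest.raises(ValueError):
            svd_phenotype_check(m, labels)


class TestProbeDensity:
    def test_gene_span_density(self):
        rows = [(f"p{j}", "chr1", pos, "g0", "TSS200", "") for j, pos in enumerate([0, 250, 500, 750, 1000])]
        mani = ProbeManifest(pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "gene_id", "region_class", "cgi_id"]))
        dens, _ = probe_density(mani)
        assert dens.loc[dens["region_id"] == "g0", "density"].item() == pytest.approx(0.005)

    def test_cgi_density_uses_interval_length(self):
        rows = [(f"p{j}", "chr1", j * 10, "", "", "cgi0") for j in range(10)]
        mani = ProbeManifest(pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "gene_id", "region_class", "cgi_id"]))
        cgis = pd.DataFrame({"cgi_id": ["cgi0"], "start": [0], "end": [500]})
        dens, _ = probe_density(mani, cgis)
        assert dens.loc[dens["region_class"] == "CGI", "density"].item() == pytest.approx(0.02)
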