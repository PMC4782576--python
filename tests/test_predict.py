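import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from methcan.predict import (
    auc_from_labels,
    build_dm_gene_set,
    fit_logistic,
    model_selection,
    paired_wilcoxon_auc,
    predict_dm_auc,
    roc_curve,
    stratified_split,
)


def series(vals, labels):
    idx = [f"g{i}" for i in range(len(vals))]
    return pd.Series(vals, index=idx, dtype=float), pd.Series(labels, index=idx)


class TestRoc:
    def test_perfect_separation(self):
        s, l = series([0.9, 0.8, 0.2, 0.1], ["DM", "DM", "nonDM", "nonDM"])
        assert roc_curve(s, l).auc == 1.0

    def test_half_concordant(self):
        # concordant pairs = 2 of 4 -> AUC 0.5
        s, l = series([0.1, 0.9, 0.2, 0.8], ["DM", "DM", "nonDM", "nonDM"])
        assert roc_curve(s, l).auc == pytest.approx(0.5)

    def test_label_flip_symmetry(self, rng):
        s, l = series(rng.random(50), rng.choice(["DM", "nonDM"], 50, p=[0.4, 0.6]))
        flipped = l.map({"DM": "nonDM", "nonDM": "DM"})
        assert roc_curve(s, flipped).auc == pytest.approx(1 - roc_curve(s, l).auc)

    def test_points_monotone_and_anchored(self, rng):
        s, l = series(rng.integers(0, 5, 60).astype(float), rng.choice(["DM", "nonDM"], 60))
        pts = roc_curve(s, l).points
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        s, l = series([1.0, 2.0], ["DM", "DM"])
        with pytest.raises(ValueError):
            roc_curve(s, l)


class TestAucOracle:
    def test_matches_trapezoid_on_random_instances(self, rng):
        """Trapezoid over the threshold sweep == Mann-Whitney pairwise count."""
        for _ in range(200):
            n = int(rng.integers(6, 80))
            vals = rng.integers(0, 8, n).astype(float) if rng.random() < 0.5 else rng.normal(size=n)
            labels = rng.choice(["DM", "nonDM"], n)
            if len(set(labels)) < 2:
                continue
            s, l = series(vals, labels)
            assert roc_curve(s, l).auc == pytest.approx(auc_from_labels(s, l), abs=1e-12)

    def test_all_tied_signal(self):
        s, l = series([1.0] * 6, ["DM"] * 3 + ["nonDM"] * 3)
        assert auc_from_labels(s, l) == 0.5

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(size=40)
        s, l = series(vals, rng.choice(["DM", "nonDM"], 40))
        s2 = pd.Series(np.exp(2 * s) + 7, index=s.index)
        assert roc_curve(s2, l).auc == pytest.approx(roc_curve(s, l).auc, abs=1e-12)

    def test_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        vals = rng.normal(size=120)
        s, l = series(vals, rng.choice(["DM", "nonDM"], 120))
        assert roc_curve(s, l).auc == pytest.approx(
            roc_auc_score((l == "DM").astype(int), s), abs=1e-12
        )

    def test_permutation_null_centred(self, rng):
        vals = rng.normal(size=600)
        labels = np.array(["DM"] * 300 + ["nonDM"] * 300)
        aucs = []
        for _ in range(100):
            rng.shuffle(labels)
            s, l = series(vals, labels)
            aucs.append(auc_from_labels(s, l))
        assert 0.47 <= np.mean(aucs) <= 0.53


class TestPairedWilcoxon:
    def test_six_uniform_positives_exact(self):
        pairs = pd.DataFrame({"normal": [0.8, 0.82, 0.9, 0.7, 0.75, 0.85],
                              "hesc": [0.7, 0.72, 0.8, 0.6, 0.65, 0.75]})
        assert paired_wilcoxon_auc(pairs) == pytest.approx(1 / 64)

    def test_symmetric_null_near_half(self, rng):
        d = rng.normal(0, 0.05, 12)
        pairs = pd.DataFrame({"normal": 0.7 + d, "hesc": np.full(12, 0.7)})
        p = paired_wilcoxon_auc(pairs)
        assert 0.05 < p < 0.95

    def test_swapping_order_complements_tail(self):
        rng = np.random.default_rng(5)
        pairs = pd.DataFrame({"normal": 0.8 + rng.normal(0, 0.05, 8), "hesc": np.full(8, 0.75)})
        p_greater = paired_wilcoxon_auc(pairs, "greater")
        swapped = pairs.rename(columns={"normal": "hesc", "hesc": "normal"})
        p_swapped = paired_wilcoxon_auc(swapped, "greater")
        assert p_greater < 0.5 < p_swapped

    def test_all_zero_differences(self):
        pairs = pd.DataFrame({"normal": [0.5, 0.5], "hesc": [0.5, 0.5]})
        with pytest.warns(UserWarning):
            assert paired_wilcoxon_auc(pairs) == 1.0


class TestDmSetAndSplit:
    def test_build_dm_gene_set_counts(self, rng):
        t = pd.Series(rng.normal(size=2500), index=[f"g{i}" for i in range(2500)])
        dm = build_dm_gene_set(t)
        counts = dm["label"].value_counts()
        assert counts["DM"] == 1000 and counts["nonDM"] == 1000
        assert not (set(dm.index[dm["label"] == "DM"]) & set(dm.index[dm["label"] == "nonDM"]))

    def test_too_few_genes(self, rng):
        with pytest.raises(ValueError):
            build_dm_gene_set(pd.Series(rng.normal(size=1500)))

    def test_split_fractions_and_balance(self, rng):
        labels = pd.Series(["DM"] * 1000 + ["nonDM"] * 1000,
                           index=[f"g{i}" for i in range(2000)])
        split = stratified_split(labels, seed=3)
        sizes = split.value_counts()
        assert sizes["train"] == 1000 and sizes["validation"] == 400 and sizes["test"] == 600
        for part, n in (("train", 500), ("validation", 200), ("test", 300)):
            sub = labels[split == part]
            assert (sub == "DM").sum() == n

    def test_split_deterministic_and_partition(self, rng):
        labels = pd.Series(rng.choice(["DM", "nonDM"], 300), index=[f"g{i}" for i in range(300)])
        s1 = stratified_split(labels, seed=9)
        s2 = stratified_split(labels, seed=9)
        assert s1.equals(s2)
        assert set(s1.index) == set(labels.index)
        assert s1.notna().all()


def logit_oracle(x, y):
    """Generic-optimizer maximum-likelihood logistic fit (with intercept)."""
    X = np.column_stack([np.ones(len(x)), x])

    def nll(beta):
        eta = X @ beta
        return -(y * eta - np.logaddexp(0, eta)).sum()

    res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS")
    return res.x, -res.fun


class TestLogistic:
    def test_null_model_closed_form(self):
        n = 200
        labels = pd.Series(["DM"] * 100 + ["nonDM"] * 100, index=[f"g{i}" for i in range(n)])
        rng = np.random.default_rng(0)
        design = pd.DataFrame({"x": rng.normal(size=n)}, index=labels.index)
        # independent predictor: intercept ~ 0, lnL ~ n*ln(1/2)
        fit = fit_logistic(design, labels)
        assert abs(fit.coefficients["const"]) < 0.2
        assert fit.loglik == pytest.approx(n * np.log(0.5), rel=0.02)

    def test_aic_formula(self):
        rng = np.random.default_rng(1)
        n = 300
        x = rng.normal(size=n)
        y = rng.random(n) < special.expit(x)
        labels = pd.Series(np.where(y, "DM", "nonDM"), index=[f"g{i}" for i in range(n)])
        design = pd.DataFrame({"x": x}, index=labels.index)
        fit = fit_logistic(design, labels)
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik, abs=1e-9)

    def test_matches_generic_optimizer(self):
        rng = np.random.default_rng(2)
        n = 500
        x = rng.normal(size=n)
        y = (rng.random(n) < special.expit(0.8 * x - 0.3)).astype(float)
        labels = pd.Series(np.where(y == 1, "DM", "nonDM"), index=[f"g{i}" for i in range(n)])
        design = pd.DataFrame({"x": x}, index=labels.index)
        fit = fit_logistic(design, labels, standardize=False)
        beta_hat, llf = logit_oracle(x, y)
        assert np.allclose(
            [fit.coefficients["const"], fit.coefficients["x"]], beta_hat, atol=1e-6
        )
        assert fit.loglik == pytest.approx(llf, abs=1e-6)

    def test_perfect_separation_flagged(self):
        labels = pd.Series(["DM"] * 50 + ["nonDM"] * 50, index=[f"g{i}" for i in range(100)])
        design = pd.DataFrame({"x": np.r_[np.ones(50), np.zeros(50)]}, index=labels.index)
        fit = fit_logistic(design, labels)
        assert fit.separation_flag


def simulate_signal_data(seed, couplings=(1.2, -1.0, -1.0), n=2000, bivalent=1.5, noise=0.8):
    """Light-weight generator of (signals, labels) with the study's sign structure."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=n)
    eps = rng.normal(0, noise, (n, 3))
    k27_core = couplings[0] * u + eps[:, 0]
    s27 = np.logaddexp(0, k27_core)
    s4 = np.logaddexp(0, bivalent * k27_core + couplings[1] * u + 2 + eps[:, 1])
    s36 = np.logaddexp(0, couplings[2] * u + 2 + eps[:, 2])
    idx = [f"g{i}" for i in range(n)]
    order = np.argsort(-u)
    labels = pd.Series("unlabeled", index=idx, dtype=object)
    labels.iloc[order[: n // 2]] = "DM"
    labels.iloc[order[n // 2:]] = "nonDM"
    signals = pd.DataFrame({"H3K4me3": s4, "H3K27me3": s27, "H3K36me3": s36}, index=idx)
    return signals, labels


class TestModelSelection:
    def test_three_predictor_model_wins_when_all_informative(self):
        wins = 0
        for seed in range(20):
            signals, labels = simulate_signal_data(seed)
            split = stratified_split(labels, seed=seed)
            best, report = model_selection(signals, labels, split)
            wins += len(best.predictors) == 3
        assert wins >= 16  # >= 80 % of seeds

    def test_single_driver_noise_predictors_add_nothing(self):
        """With K27 the only informative mark, AIC prefers K27-only over the
        full model, and the extra marks leave the validation AUC unchanged."""
        wins = 0
        auc_gaps = []
        aic_gaps = []
        for seed in range(20):
            rng = np.random.default_rng(seed + 100)
            n = 2000
            u = rng.normal(size=n)
            s27 = np.logaddexp(0, 1.5 * u + rng.normal(0, 0.6, n))
            idx = [f"g{i}" for i in range(n)]
            signals = pd.DataFrame(
                {
                    "H3K4me3": rng.random(n) * 3,
                    "H3K27me3": s27,
                    "H3K36me3": rng.random(n) * 3,
                },
                index=idx,
            )
            labels = pd.Series(np.where(u > np.median(u), "DM", "nonDM"), index=idx)
            split = stratified_split(labels, seed=seed)
            _, report = model_selection(signals, labels, split)
            by = report.set_index("predictors")
            aic_gap = by.loc["H3K27me3", "aic"] - by.loc["H3K4me3+H3K27me3+H3K36me3", "aic"]
            wins += aic_gap < 0
            aic_gaps.append(aic_gap)
            auc_gaps.append(
                by.loc["H3K4me3+H3K27me3+H3K36me3", "validation_auc"]
                - by.loc["H3K27me3", "validation_auc"]
            )
        # two noise parameters raise AIC by 4 - chi^2_2 (mean +2); the
        # per-seed win rate is Binomial(20, P(chi^2_2 < 4) = 0.865)
        assert wins >= 14
        assert np.mean(aic_gaps) < 0
        assert abs(np.mean(auc_gaps)) < 0.01

    def test_test_auc_tracks_validation_auc(self):
        for seed in (0, 1, 2):
            signals, labels = simulate_signal_data(seed)
            split = stratified_split(labels, seed=seed)
            best, _ = model_selection(signals, labels, split)
            assert abs(best.test_auc - best.validation_auc) < 0.1

    def test_z_sign_pattern_recovered(self):
        ok = 0
        for seed in range(20):
            signals, labels = simulate_signal_data(seed)
            fit = fit_logistic(signals, labels[labels != "unlabeled"])
            ok += (fit.z["H3K27me3"] > 0) and (fit.z["H3K4me3"] < 0) and (fit.z["H3K36me3"] < 0)
        assert ok >= 19


def test_predict_dm_auc_table(rng):
    n = 400
    u = rng.normal(size=n)
    idx = [f"g{i}" for i in range(n)]
    labels = pd.Series(np.where(u > np.median(u), "DM", "nonDM"), index=idx)
    signals = {
        ("H3K27me3", "normal"): pd.Series(np.logaddexp(0, u + rng.normal(0, 0.5, n)), index=idx),
        ("H3K27me3", "hesc"): pd.Series(np.logaddexp(0, 0.3 * u + rng.normal(0, 0.5, n)), index=idx),
    }
    table = predict_dm_auc(signals, labels)
    by = table.set_index("source")["auc"]
    assert by["normal"] > 0.5 and by["normal"] > by["hesc"]
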