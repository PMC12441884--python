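"""Group tests, logistic ROC/AUC, bootstrap CIs and table-shaped reports."""

import numpy as np
import pandas as pd
import pytest

from mrcyt.cohort_stats import (
    FEATURE_SETS,
    auc_midrank,
    ihc_report,
    kruskal_wallis,
    logistic_roc,
    mann_whitney,
    roc_points,
    subtype_report,
)
from mrcyt.errors import DataError


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        r = mann_whitney([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert r.p_value == 1.0
        assert r.all_tied

    def test_disjoint_small_samples_exact(self):
        """All 20 rank assignments of {1,2,3} vs {4,5,6}: U=0, p = 2/20."""
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1)

    def test_asymptotic_close_to_exact_at_n8(self, rng):
        for _ in range(5):
            a = rng.normal(size=8)
            b = rng.normal(0.8, 1, size=8)
            import scipy.stats as sps

            exact = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            approx = sps.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic")
            assert approx.pvalue == pytest.approx(exact.pvalue, rel=0.05, abs=0.01)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0], [2.0, 3.0])


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        r = kruskal_wallis([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_matches_permutation_null(self, rng):
        """H for {1,2},{3,4},{5,6} is maximal; its permutation p-value is
        exactly 3! / (6! / 2!^3) = 1/15, recovered within Monte-Carlo error."""
        groups = [np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([5.0, 6.0])]
        r = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        n_perm = 20_000
        count = 0
        for _ in range(n_perm):
            p = rng.permutation(pooled)
            h = kruskal_wallis([p[:2], p[2:4], p[4:]]).statistic
            count += h >= r.statistic - 1e-12
        assert count / n_perm == pytest.approx(1.0 / 15.0, abs=0.01)

    def test_group_order_invariance(self, rng):
        groups = [rng.normal(size=6), rng.normal(1, 1, size=5), rng.normal(2, 1, 7)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis(groups[::-1]).statistic
        assert h1 == pytest.approx(h2, rel=1e-12)


class TestAUC:
    def test_auc_equals_pairwise_enumeration(self, rng):
        """Apparent single-feature AUC equals P(x+ > x-) + P(=)/2 (oriented
        by the fitted slope sign), enumerated over all pairs at n <= 20."""
        for trial in range(20):
            n = int(rng.integers(8, 21))
            x = np.round(rng.normal(size=n), 1)  # rounding induces ties
            y = (rng.random(n) < 0.5).astype(int)
            if y.sum() < 2 or n - y.sum() < 2:
                continue
            rep = logistic_roc(x, y, n_boot=0)
            pos, neg = x[y == 1], x[y == 0]
            A = np.mean([
                1.0 if a > b else (0.5 if a == b else 0.0)
                for a in pos for b in neg
            ])
            slope = rep.coefficients[1]
            expected = A if slope > 0 else (1 - A if slope < 0 else 0.5)
            assert rep.auc == pytest.approx(expected, abs=1e-12)

    def test_perfectly_ordered_feature(self):
        x = np.arange(20.0)
        y = (x >= 10).astype(int)
        rep = logistic_roc(x, y, n_boot=0)
        assert rep.auc == 1.0
        assert rep.separation

    def test_null_feature_auc_near_half(self, rng):
        aucs = []
        for _ in range(60):
            x = rng.normal(size=200)
            y = (rng.random(200) < 0.5).astype(int)
            aucs.append(logistic_roc(x, y, n_boot=0).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_midrank_tie_convention(self):
        scores = np.array([0.1, 0.5, 0.5, 0.9])
        y = np.array([0, 0, 1, 1])
        # pairs: (0.5,0.1)=1, (0.5,0.5)=0.5, (0.9,0.1)=1, (0.9,0.5)=1 -> 3.5/4
        assert auc_midrank(scores, y) == pytest.approx(3.5 / 4)

    def test_roc_points_bracket_unit_square(self, rng):
        x = rng.normal(size=30)
        y = (rng.random(30) < 0.4).astype(int)
        pts = roc_points(x, y)
        assert pts.iloc[0]["fpr"] == 0 and pts.iloc[0]["tpr"] == 0
        assert pts.iloc[-1]["fpr"] == 1 and pts.iloc[-1]["tpr"] == 1
        assert (pts["fpr"].diff().dropna() >= 0).all()


class TestLogisticROC:
    def test_ci_brackets_auc(self, rng):
        x = np.r_[rng.normal(size=40), rng.normal(1.0, 1, 40)]
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        rep = logistic_roc(x, y, n_boot=300, seed=2)
        assert rep.ci_low <= rep.auc <= rep.ci_high
        assert 0.5 < rep.auc < 1.0
        assert rep.p_value < 0.01

    def test_combined_model_reports_lr_p(self, rng):
        X = rng.normal(size=(80, 3))
        y = (X[:, 0] + 0.5 * rng.normal(size=80) > 0).astype(int)
        rep = logistic_roc(X, y, n_boot=100, seed=0)
        assert rep.p_value == rep.p_lr
        assert rep.auc > 0.7

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            logistic_roc(np.arange(10.0), np.ones(10, int), n_boot=0)

    def test_newton_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        from mrcyt.cohort_stats import _newton_logistic, _standardize

        X = rng.normal(size=(120, 2))
        y = (X[:, 0] - 0.4 * X[:, 1] + rng.normal(size=120) > 0).astype(int)
        Xd = sm.add_constant(_standardize(X))
        beta_sm = sm.Logit(y, Xd).fit(disp=0).params
        beta_nt = _newton_logistic(Xd, y)
        np.testing.assert_allclose(beta_nt, beta_sm, atol=1e-5)


def _synthetic_table(rng, n=60, d_shift_target="HER2"):
    """Metric table where only the diameter separates one subtype."""
    subtypes = np.array(
        ["LuminalA"] * 20 + ["LuminalB"] * 20 + ["TNBC"] * 12 + ["HER2"] * 8
    )
    rows = {}
    for m, cols in FEATURE_SETS.items():
        for c in cols:
            rows[c] = rng.normal(1.0, 0.1, size=n)
    for c in ("impulsed_d", "joint_d", "exchange_d"):
        rows[c] = np.where(subtypes == d_shift_target, 16.0, 14.0) + rng.normal(
            0, 0.4, size=n
        )
    df = pd.DataFrame(rows)
    df["subtype"] = subtypes
    df["ER"] = (subtypes != "TNBC").astype(int) * (subtypes != "HER2").astype(int)
    df["PR"] = df["ER"]
    df["HER2"] = (subtypes == "HER2").astype(int)
    df["Ki67"] = (rng.random(n) < 0.5).astype(int)
    # need both classes everywhere
    df.loc[0, "Ki67"] = 0
    df.loc[1, "Ki67"] = 1
    return df


class TestReports:
    def test_ihc_report_shape_and_best_metric(self, rng):
        table = _synthetic_table(rng)
        rep = ihc_report(table, n_boot=50, seed=0)
        # 4 targets x (19 single-metric + 4 combined) rows
        assert len(rep) == 4 * (19 + 4)
        assert set(rep["target"]) == {"ER", "PR", "HER2", "Ki67"}
        her2 = rep[(rep["target"] == "HER2") & (rep["parameter"] != "combined")]
        best = her2.sort_values("auc").iloc[-1]
        assert best["parameter"] == "d"  # only d was made discriminative
        assert (rep["ci_low"] <= rep["auc"]).all()
        assert (rep["auc"] <= rep["ci_high"]).all()

    def test_combined_auc_oriented(self, rng):
        table = _synthetic_table(rng)
        rep = ihc_report(table, n_boot=0)
        assert (rep.loc[rep["parameter"] == "combined", "auc"] >= 0.5).all()

    def test_subtype_report_shape_and_kruskal(self, rng):
        table = _synthetic_table(rng)
        rep = subtype_report(table, n_boot=50, seed=0)
        assert len(rep.auc_table) == 4 * (19 + 4)
        assert set(rep.auc_table["target"]) == {
            "TNBC", "HER2", "LuminalA", "LuminalB",
        }
        kw = rep.kruskal_table
        assert len(kw) == 19
        d_p = kw.loc[(kw["model"] == "EXCHANGE") & (kw["parameter"] == "d"), "kw_p"]
        assert float(d_p.iloc[0]) < 0.05  # diameter separates the subtypes

    def test_shuffled_labels_cover_half(self, rng):
        """Permuted labels: bootstrap CIs should cover AUC = 0.5 most of the time."""
        table = _synthetic_table(rng)
        covered = 0
        reps = 20
        for i in range(reps):
            y = rng.permutation(table["HER2"].to_numpy())
            rep = logistic_roc(table["exchange_d"].to_numpy(), y,
                               n_boot=200, seed=i)
            covered += rep.ci_low <= 0.5 <= rep.ci_high
        assert covered >= 0.8 * reps

    def test_missing_metric_rejected(self, rng):
        table = _synthetic_table(rng).drop(columns=["exchange_d"])
        with pytest.raises(DataError):
            ihc_report(table, n_boot=0)

    def test_lesion_order_invariance(self, rng):
        table = _synthetic_table(rng)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = mann_whitney(
            table.loc[table["HER2"] == 1, "exchange_d"],
            table.loc[table["HER2"] == 0, "exchange_d"],
        )
        b = mann_whitney(
            shuffled.loc[shuffled["HER2"] == 1, "exchange_d"],
            shuffled.loc[shuffled["HER2"] == 0, "exchange_d"],
        )
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
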