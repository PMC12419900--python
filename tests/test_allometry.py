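"""OLS/PGLS allometry, AICc, and the dual-convention outlier protocol."""

import numpy as np
import pandas as pd
import pytest

import stylocom as sc
from stylocom.allometry import (
    AllometricModel,
    TraitTable,
    aicc,
    fit_suite,
    flag_outliers,
    quartiles,
)
from stylocom.phylo import brownian_vcv


def table_from_xy(x, y, taxa=None, transformed=True, ratite=None):
    n = len(x)
    taxa = taxa or [f"t{i + 1}" for i in range(n)]
    data = pd.DataFrame(
        {
            "taxon": taxa,
            "clade": "mammal",
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
            "ratite": ratite if ratite is not None else False,
        }
    )
    return TraitTable(data, predictor="C_index", transformed=transformed)


class TestOlsFit:
    def test_perfect_line(self):
        x = np.arange(5.0)
        fit = sc.ols_fit(table_from_xy(x, 2 * x + 1))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.adj_R2 == pytest.approx(1.0)
        assert fit.residuals.abs().max() < 1e-12

    def test_hand_computed_least_squares(self):
        # Sxy = 3, Sxx = 2 -> slope 1.5; intercept = mean(y) - 1.5 mean(x) = -1/6
        fit = sc.ols_fit(table_from_xy([0, 1, 2], [0, 1, 3]))
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(-1 / 6)
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-12)

    def test_matches_identity_covariance_gls_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = 0.8 * x + rng.normal(scale=0.3, size=12)
        fit = sc.ols_fit(table_from_xy(x, y))
        X = np.column_stack([np.ones(12), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            sc.ols_fit(table_from_xy([1, 1, 1], [0, 1, 2]))

    def test_log10_transform_applied_once(self):
        raw = table_from_xy([1.0, 10.0, 100.0], [1.0, 10.0, 100.0], transformed=False)
        fit = sc.ols_fit(raw)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_values_cannot_transform(self):
        with pytest.raises(ValueError, match="non-positive"):
            table_from_xy([1.0, -2.0, 3.0], [1, 2, 3], transformed=False).log10()


class TestAicc:
    @pytest.mark.parametrize(
        "loglik, k, n, expected",
        [
            (0.0, 3, 10, 10.0),  # 2k + 2k(k+1)/(n-k-1) = 6 + 4
            (-5.0, 3, 7, 24.0),  # 10 + 6 + 8
            (2.5, 2, 8, -5 + 4 + 12 / 5),
        ],
    )
    def test_formula(self, loglik, k, n, expected):
        assert aicc(loglik, k, n) == pytest.approx(expected)

    def test_large_n_limit_is_plain_aic(self):
        assert aicc(0.0, 3, 10**7) == pytest.approx(6.0, abs=1e-4)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="AICc undefined"):
            aicc(0.0, 3, 4)


class TestPglsFit:
    def test_star_tree_equals_ols(self):
        n = 8
        newick = "(" + ",".join(f"t{i + 1}:2.0" for i in range(n)) + ");"
        tree = sc.parse_newick(newick)
        rng = np.random.default_rng(1)
        x = rng.normal(size=n)
        y = 1.2 * x + rng.normal(scale=0.2, size=n)
        table = table_from_xy(x, y)
        ols = sc.ols_fit(table)
        pgls = sc.pgls_fit(table, tree)
        assert pgls.slope == pytest.approx(ols.slope, abs=1e-10)
        assert pgls.intercept == pytest.approx(ols.intercept, abs=1e-10)
        assert pgls.slope_p == pytest.approx(ols.slope_p, abs=1e-10)

    def test_three_taxon_dense_gls_oracle(self):
        tree = sc.parse_newick("((A:1,B:1):1,C:2);")
        x = np.array([0.1, 0.3, -0.2])
        y = np.array([0.05, 0.4, -0.3])
        fit = sc.pgls_fit(table_from_xy(x, y, taxa=["A", "B", "C"]), tree)
        C = brownian_vcv(tree, taxa=["A", "B", "C"]).matrix
        X = np.column_stack([np.ones(3), x])
        Ci = np.linalg.inv(C)
        beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_tree_dense_gls_oracle(self, seed):
        tree = sc.simulate_tree(10, seed=seed)
        rng = np.random.default_rng(seed + 100)
        x = rng.normal(size=10)
        y = 0.9 * x + rng.normal(scale=0.3, size=10)
        taxa = tree.tips
        fit = sc.pgls_fit(table_from_xy(x, y, taxa=taxa), tree)
        C = brownian_vcv(tree, taxa=taxa).matrix
        X = np.column_stack([np.ones(10), x])
        Ci = np.linalg.inv(C)
        beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        # ML log-likelihood from the dense form
        resid = y - X @ beta
        sigma2 = resid @ Ci @ resid / 10
        loglik = -0.5 * (10 * np.log(2 * np.pi * sigma2) + np.linalg.slogdet(C)[1] + 10)
        assert fit.loglik == pytest.approx(loglik, abs=1e-8)

    def test_parameter_recovery_under_brownian_residuals(self):
        """Mean PGLS slope over replicates within 2 SE of the truth (1.24)."""
        true_slope = 1.24
        tree = sc.simulate_tree(40, seed=21)
        depth = max(tree.depths().values())
        rng = np.random.default_rng(42)
        estimates = []
        for _ in range(100):
            lx = sc.simulate_brownian(tree, rate=0.02, seed=rng)
            resid = sc.simulate_brownian(tree, rate=0.06**2 / depth, seed=rng)
            taxa = tree.tips
            x = np.array([lx[t] for t in taxa])
            y = true_slope * x - 0.355 + np.array([resid[t] for t in taxa])
            estimates.append(sc.pgls_fit(table_from_xy(x, y, taxa=taxa), tree).slope)
        estimates = np.asarray(estimates)
        sem = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - true_slope) < 2 * sem


class TestQuartileConventions:
    @staticmethod
    def quartiles_bruteforce(values, convention):
        """Direct halved-list construction, written independently."""
        v = sorted(values)
        n = len(v)
        med = lambda s: (s[len(s) // 2] if len(s) % 2 else (s[len(s) // 2 - 1] + s[len(s) // 2]) / 2)
        if n % 2 == 0:
            lower, upper = v[: n // 2], v[n // 2:]
        elif convention == "inclusive":
            lower, upper = v[: n // 2 + 1], v[n // 2:]
        else:
            lower, upper = v[: n // 2], v[n // 2 + 1:]
        return med(lower), med(upper)

    @pytest.mark.parametrize("n", [5, 6, 7, 8, 9, 11])
    @pytest.mark.parametrize("convention", ["inclusive", "exclusive"])
    def test_matches_bruteforce_on_random_sets(self, n, convention):
        rng = np.random.default_rng(n)
        for _ in range(20):
            values = rng.normal(size=n)
            expected = self.quartiles_bruteforce(values, convention)
            assert quartiles(values, convention) == pytest.approx(expected)

    def test_conventions_agree_for_even_n(self):
        values = [1.0, 2.0, 4.0, 8.0, 16.0, 32.0]
        assert quartiles(values, "inclusive") == quartiles(values, "exclusive")


def fit_with_residuals(residuals, taxa=None):
    """Build a minimal AllometricFit carrying the given residuals."""
    n = len(residuals)
    taxa = taxa or [f"t{i}" for i in range(n)]
    fit = sc.ols_fit(table_from_xy(np.arange(n, dtype=float), np.arange(n, dtype=float)))
    fit.residuals = pd.Series(residuals, index=taxa, dtype=float)
    return fit


class TestFlagOutliers:
    def test_benign_residuals_unflagged(self):
        report = flag_outliers(fit_with_residuals([-1.0, -0.5, 0.0, 0.5, 1.0, -0.3, 0.3]))
        assert report.flagged == []

    def test_extreme_residual_flagged_under_both_conventions(self):
        resid = [-0.1, -0.05, 0.0, 0.05, 0.1, 3.0]
        report = flag_outliers(fit_with_residuals(resid))
        assert report.flagged == ["t5"]
        assert report.flagged_by["inclusive"] == ["t5"]
        assert report.flagged_by["exclusive"] == ["t5"]

    def test_single_convention_flag_not_enough(self):
        """A residual set found by brute-force search where the conventions
        disagree: flagged under one set of fences only -> not an outlier."""
        found = None
        for extreme in np.arange(0.5, 4.0, 0.025):
            resid = np.array([-0.4, -0.1, 0.0, 0.1, 0.2, 0.3, extreme])
            flags = {}
            for conv in ("inclusive", "exclusive"):
                q1, q3 = quartiles(resid, conv)
                iqr = q3 - q1
                flags[conv] = bool((resid > q3 + 1.5 * iqr).any() | (resid < q1 - 1.5 * iqr).any())
            if flags["inclusive"] != flags["exclusive"]:
                found = resid
                break
        assert found is not None, "search failed to construct a disagreement case"
        report = flag_outliers(fit_with_residuals(found))
        assert report.flagged == []
        assert report.flagged_by["inclusive"] != [] or report.flagged_by["exclusive"] != []

    def test_exclusive_fences_contain_inclusive_fences(self):
        """Excluding the median pushes both hinges outward, so the exclusive
        fences are always at least as wide: taxa flagged under exclusive
        quartiles are a subset of those flagged under inclusive ones."""
        rng = np.random.default_rng(13)
        for n in (5, 7, 9, 11, 15):
            for _ in range(50):
                resid = rng.normal(size=n)
                q1i, q3i = quartiles(resid, "inclusive")
                q1e, q3e = quartiles(resid, "exclusive")
                assert q1e <= q1i + 1e-12 and q3e >= q3i - 1e-12
                report = flag_outliers(fit_with_residuals(resid))
                assert set(report.flagged_by["exclusive"]) <= set(report.flagged_by["inclusive"])
                assert set(report.flagged) == set(report.flagged_by["exclusive"])

    def test_small_n_returns_empty_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            report = flag_outliers(fit_with_residuals([0.0, 1.0, -1.0, 5.0]))
        assert report.flagged == []


class TestFitSuite:
    def test_combinatorial_count_primary_fits(self, study_fixture):
        suite = fit_suite(study_fixture.extant_frame, tree=study_fixture.tree)
        primary = [f for f in suite.fits if f.variant == "all"]
        # 3 clades x 4 indices x 2 methods
        assert len(primary) == 24

    def test_injected_outlier_triggers_refit_excluding_it(self, study_fixture):
        df = study_fixture.extant_frame.copy()
        mask = df["clade"] == "mammal"
        victim = df.loc[mask, "taxon"].iloc[0]
        df.loc[df["taxon"] == victim, "relative_com"] *= 3.0  # huge residual
        suite = fit_suite(
            df[mask], predictors=("W1_index",), methods=("ols",)
        )
        report = suite.outliers[("mammal", "W1_index", "ols")]
        assert victim in report.flagged
        refit = suite.get(variant="outliers_removed")
        assert len(refit) == 1
        assert victim not in refit[0].residuals.index
        assert refit[0].n == mask.sum() - len(report.flagged)

    def test_ratite_variant_reduces_n_by_flag_count(self, study_fixture):
        df = study_fixture.extant_frame
        n_ratites = int(df["ratite"].sum())
        assert n_ratites > 0
        suite = fit_suite(df, predictors=("C_index",), methods=("ols",))
        full = suite.get(subset="bird", variant="all")[0]
        reduced = suite.get(subset="bird", variant="ratites_removed")[0]
        assert reduced.n == full.n - n_ratites

    def test_tiny_subset_skipped_with_warning(self):
        df = pd.DataFrame(
            {
                "taxon": ["a", "b"],
                "clade": "mammal",
                "C_index": [1.0, 1.1],
                "relative_com": [0.5, 0.55],
                "ratite": False,
            }
        )
        with pytest.warns(UserWarning, match="skipped"):
            suite = fit_suite(df, predictors=("C_index",), methods=("ols",))
        assert suite.fits == []


def test_type_i_error_calibration():
    """Under a zero-slope null the slope test rejects at ~5%."""
    rng = np.random.default_rng(321)
    n, reps = 20, 1000
    rejections = 0
    for _ in range(reps):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if sc.ols_fit(table_from_xy(x, y)).slope_p < 0.05:
            rejections += 1
    assert 0.03 < rejections / reps < 0.07


def test_slope_ci_coverage_at_low_noise():
    """95% CI covers the true slope >= 90% of the time at n = 10, noise
    SD at the well-constrained (mammal-like) level."""
    rng = np.random.default_rng(99)
    true_slope, covered, reps = 0.866, 0, 500
    for _ in range(reps):
        x = rng.normal(0.0, 0.1, size=10)
        y = true_slope * x - 0.294 + rng.normal(0.0, 0.02, size=10)
        fit = sc.ols_fit(table_from_xy(x, y))
        lo, hi = fit.slope_ci95
        covered += lo <= true_slope <= hi
    assert covered / reps >= 0.90


def test_summary_mentions_key_statistics(study_fixture):
    suite = fit_suite(
        study_fixture.extant_frame, predictors=("W1_index",), methods=("ols",)
    )
    text = suite.get(subset="mammal", variant="all")[0].summary()
    assert "slope" in text and "AICc" in text and "n = 10" in text
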