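"""Reliability statistics against independent definitional oracles."""

import numpy as np
import pandas as pd
import pytest

from audiocog import (
    InsufficientDataError,
    InvalidParameterError,
    StandardizationError,
    ValidationError,
    bootstrap_corr_diff,
    chi_square_2x2,
    icc_two_way,
    partial_corr,
    pearson_with_ci,
    preprocess,
    residualize,
    steiger_dependent_corr,
)


class TestPreprocess:
    def test_log_identity(self):
        df = pd.DataFrame({"AUM_F": [1.0, np.e, np.e**2]})
        out = preprocess(df, log_columns=["AUM_F"], z_columns=[])
        assert np.allclose(out["AUM_F"], [0.0, 1.0, 2.0])

    def test_z_scoring_contract(self, rng):
        df = pd.DataFrame({"x": rng.normal(5, 3, 50)})
        out = preprocess(df, z_columns=["x"])
        assert abs(out["x"].mean()) < 1e-12
        assert abs(out["x"].std(ddof=1) - 1) < 1e-12

    def test_pearson_invariant_under_z(self, rng):
        df = pd.DataFrame({"x": rng.normal(0, 2, 40), "y": rng.normal(1, 5, 40)})
        raw_r = np.corrcoef(df.x, df.y)[0, 1]
        out = preprocess(df, z_columns=["x", "y"])
        assert np.corrcoef(out.x, out.y)[0, 1] == pytest.approx(raw_r, abs=1e-12)

    def test_missingness_preserved_never_imputed(self, rng):
        df = pd.DataFrame({"AUM_F": [1.0, np.nan, 2.0, np.nan], "x": [1, 2, np.nan, 4]})
        out = preprocess(df, log_columns=["AUM_F"], z_columns=["x"])
        assert out["AUM_F"].isna().tolist() == [False, True, False, True]
        assert out["x"].isna().tolist() == [False, False, True, False]

    def test_zero_variance_names_column(self):
        df = pd.DataFrame({"flat": [3.0, 3.0, 3.0]})
        with pytest.raises(StandardizationError, match="flat"):
            preprocess(df, z_columns=["flat"])

    def test_nonpositive_precision_rejected(self):
        df = pd.DataFrame({"AUM_F": [1.0, 0.0]})
        with pytest.raises(ValidationError):
            preprocess(df, log_columns=["AUM_F"], z_columns=[])


class TestPearson:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        res = pearson_with_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = pearson_with_ci([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.r == pytest.approx(0.8, abs=1e-12)

    def test_definitional_oracle_on_random_table(self, rng):
        x, y = rng.normal(size=(2, 10))
        res = pearson_with_ci(x, y)
        # brute-force sums-of-squares definition
        xm, ym = x - x.mean(), y - y.mean()
        r_oracle = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert res.r == pytest.approx(r_oracle, abs=1e-10)

    def test_fisher_ci_contains_estimate_and_shrinks(self, rng):
        rho = 0.6
        for n_small, n_big in [(20, 200)]:
            widths = []
            for n in (n_small, n_big):
                x = rng.normal(size=n)
                y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
                res = pearson_with_ci(x, y)
                assert res.ci_low <= res.r <= res.ci_high
                widths.append(res.ci_high - res.ci_low)
            assert widths[1] < widths[0]

    def test_degenerate_inputs(self):
        with pytest.raises(InvalidParameterError):
            pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(InsufficientDataError):
            pearson_with_ci([1, 2, 3], [1, 2, 3])

    def test_incomplete_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 3.0, np.nan, 5.0, 6.0]
        res = pearson_with_ci(x, y)
        assert res.n == 4


class TestIcc:
    def test_perfect_agreement(self):
        pairs = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc_two_way(pairs).icc == pytest.approx(1.0)

    def test_mean_squares_oracle_five_subjects(self):
        """ICC(2,1) equals an independent variance-components computation."""
        x = np.array([[1, 1], [2, 2], [3, 3], [4, 4], [5, 6]], dtype=float)
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (((x - grand) ** 2).sum() - msr * (n - 1) - msc * (k - 1)) / ((n - 1) * (k - 1))
        oracle = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_two_way(x).icc == pytest.approx(oracle, abs=1e-12)

    def test_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        vals = rng.normal(size=(12, 2))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile(["a", "b"], 12),
                "score": vals.reshape(-1),
            }
        )
        table = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        assert icc_two_way(vals, kind="agreement").icc == pytest.approx(
            table.loc["ICC(A,1)", "ICC"], abs=1e-8
        )
        assert icc_two_way(vals, kind="consistency").icc == pytest.approx(
            table.loc["ICC(C,1)", "ICC"], abs=1e-8
        )

    def test_independent_columns_near_zero(self, rng):
        vals = rng.normal(size=(10_000, 2))
        assert abs(icc_two_way(vals).icc) < 0.03

    def test_missing_cells_rejected(self):
        x = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 2.0], [1.0, 1.0], [0.0, 4.0]])
        with pytest.raises(ValidationError):
            icc_two_way(x)


class TestSteiger:
    def test_equal_correlations_give_zero(self):
        res = steiger_dependent_corr(0.5, 0.5, 0.3, 58)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_williams_formula_oracle(self):
        """Step-by-step evaluation of the Williams t frozen as the expected value."""
        r_jk, r_jh, r_kh, n = 0.5, 0.3, 0.6, 58
        det = 1 - r_jk**2 - r_jh**2 - r_kh**2 + 2 * r_jk * r_jh * r_kh
        rbar = (r_jk + r_jh) / 2
        t_oracle = (r_jk - r_jh) * np.sqrt(
            (n - 1) * (1 + r_kh) / (2 * det * (n - 1) / (n - 3) + rbar**2 * (1 - r_kh) ** 3)
        )
        res = steiger_dependent_corr(r_jk, r_jh, r_kh, n)
        assert res.statistic == pytest.approx(t_oracle, abs=1e-12)
        assert res.statistic == pytest.approx(1.90508, abs=1e-4)  # frozen oracle value
        assert res.df == 55

    def test_antisymmetric_in_compared_correlations(self):
        a = steiger_dependent_corr(0.5, 0.3, 0.6, 58)
        b = steiger_dependent_corr(0.3, 0.5, 0.6, 58)
        assert a.statistic == pytest.approx(-b.statistic)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(InvalidParameterError):
            steiger_dependent_corr(0.9, -0.9, 0.9, 58)


class TestBootstrap:
    def _table(self, rng, n=58):
        z = rng.normal(size=(n, 4))
        return pd.DataFrame(z, columns=list("abcd"))

    def test_self_comparison_degenerate_at_zero(self, rng):
        df = self._table(rng)
        res = bootstrap_corr_diff(df, ("a", "b"), ("a", "b"), B=200, rng=rng)
        assert res.mean_diff == 0.0
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)
        assert not res.significant

    def test_deterministic_under_seed(self, rng):
        df = self._table(rng)
        r1 = bootstrap_corr_diff(df, ("a", "b"), ("c", "d"), B=300, rng=np.random.default_rng(9))
        r2 = bootstrap_corr_diff(df, ("a", "b"), ("c", "d"), B=300, rng=np.random.default_rng(9))
        assert (r1.ci_low, r1.ci_high, r1.mean_diff) == (r2.ci_low, r2.ci_high, r2.mean_diff)

    def test_recovers_population_difference(self):
        """Paired correlations 0.75 vs 0.44 at n=58: mean bootstrap diff near 0.31."""
        rng = np.random.default_rng(11)
        diffs = []
        for _ in range(40):
            n = 58
            x1 = rng.normal(size=n)
            y1 = 0.75 * x1 + np.sqrt(1 - 0.75**2) * rng.normal(size=n)
            x2 = rng.normal(size=n)
            y2 = 0.44 * x2 + np.sqrt(1 - 0.44**2) * rng.normal(size=n)
            df = pd.DataFrame({"a": x1, "b": y1, "c": x2, "d": y2})
            diffs.append(
                bootstrap_corr_diff(df, ("a", "b"), ("c", "d"), B=200, rng=rng).mean_diff
            )
        assert np.mean(diffs) == pytest.approx(0.31, abs=0.05)


class TestChiSquare:
    def test_identical_proportions_zero(self):
        assert chi_square_2x2([[10, 10], [10, 10]]).statistic == 0.0

    def test_closed_form_oracle(self):
        """Pearson statistic equals N(ad-bc)^2 / product of margins."""
        a, b, c, d = 30, 10, 15, 25
        n = a + b + c + d
        oracle = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        res = chi_square_2x2([[a, b], [c, d]])
        assert res.statistic == pytest.approx(oracle, abs=1e-10)
        assert res.statistic == pytest.approx(11.4286, abs=1e-3)
        assert res.df == 1

    def test_swap_symmetry(self):
        base = chi_square_2x2([[30, 10], [15, 25]]).statistic
        swapped = chi_square_2x2([[25, 15], [10, 30]]).statistic
        assert base == pytest.approx(swapped)

    def test_yates_flag_reduces_statistic(self):
        plain = chi_square_2x2([[30, 10], [15, 25]]).statistic
        yates = chi_square_2x2([[30, 10], [15, 25]], yates=True).statistic
        assert yates < plain

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestResidualize:
    def test_orthogonal_covariate_returns_centered_y(self, rng):
        y = rng.normal(size=50)
        cov = rng.normal(size=50)
        cov = cov - cov.mean()
        cov -= (cov @ (y - y.mean())) / ((y - y.mean()) @ (y - y.mean())) * (y - y.mean())
        resid = residualize(y, cov)
        assert np.allclose(resid, y - y.mean(), atol=1e-10)

    def test_perfect_fit_gives_zero_residuals(self, rng):
        age = rng.uniform(50, 86, 30)
        resid = residualize(3 * age, age)
        assert np.max(np.abs(resid)) < 1e-10

    def test_partial_correlation_matches_textbook_formula(self, rng):
        z = rng.normal(size=200)
        x = 0.5 * z + rng.normal(size=200)
        y = -0.3 * z + 0.4 * x + rng.normal(size=200)
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        formula = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        res = partial_corr(x, y, z)
        assert res.r == pytest.approx(formula, abs=1e-10)

    def test_rank_deficient_design_rejected(self, rng):
        y = rng.normal(size=20)
        x = rng.normal(size=20)
        with pytest.raises(ValidationError):
            residualize(y, np.column_stack([x, 2 * x]))
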