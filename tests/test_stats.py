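"""Statistics layer, cross-checked against independent oracles
(textbook formulas, brute-force decompositions, pingouin, statsmodels,
Monte-Carlo simulation)."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from stoperp.errors import AnalysisError, ContractError
from stoperp.stats import (
    bonferroni,
    cohens_d_av,
    ks_normality,
    ols_regression_standardized,
    paired_t,
    partial_eta_sq,
    pearson_r,
    power_paired_t,
    rm_anova_2x2,
    steiger_z,
)


class TestPairedT:
    def test_identical_samples(self):
        r = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == 1.0 and r.d_av == 0.0 and r.d_z == 0.0

    def test_textbook_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 6.0])
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(3))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), 2)
        r = paired_t(x, y)
        assert r.t == pytest.approx(t_oracle, abs=1e-12)
        assert r.p == pytest.approx(p_oracle, abs=1e-12)
        assert r.df == 2
        # cross-check against scipy's implementation
        sp_res = sps.ttest_rel(x, y)
        assert r.t == pytest.approx(sp_res.statistic)
        assert r.p == pytest.approx(sp_res.pvalue)

    def test_d_av_from_printed_ssrt_statistics(self):
        """SSRT 203.3 (23.3) vs 217.3 (23.3): d_av = 14/23.3 = 0.6."""
        assert cohens_d_av(217.3 - 203.3, 23.3, 23.3) == pytest.approx(0.6, abs=0.005)

    def test_length_contracts(self):
        with pytest.raises(ContractError):
            paired_t([1.0], [1.0])
        with pytest.raises(ContractError):
            paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestRmAnova:
    @staticmethod
    def _brute_force(values):
        """Independent oracle: explicit loop-based SS decomposition."""
        n = values.shape[0]
        grand = values.mean()
        ss = {}
        a_m = [values[:, i, :].mean() for i in range(2)]
        b_m = [values[:, :, j].mean() for j in range(2)]
        s_m = [values[k].mean() for k in range(n)]
        ss["A"] = 2 * n * sum((m - grand) ** 2 for m in a_m)
        ss["B"] = 2 * n * sum((m - grand) ** 2 for m in b_m)
        ss["AB"] = n * sum(
            (values[:, i, j].mean() - a_m[i] - b_m[j] + grand) ** 2
            for i in range(2) for j in range(2)
        )
        ss["AS"] = 2 * sum(
            (values[k, i, :].mean() - a_m[i] - s_m[k] + grand) ** 2
            for k in range(n) for i in range(2)
        )
        ss["BS"] = 2 * sum(
            (values[k, :, j].mean() - b_m[j] - s_m[k] + grand) ** 2
            for k in range(n) for j in range(2)
        )
        ss["ABS"] = sum(
            (
                values[k, i, j]
                - values[:, i, j].mean()
                - values[k, i, :].mean()
                - values[k, :, j].mean()
                + a_m[i] + b_m[j] + s_m[k] - grand
            ) ** 2
            for k in range(n) for i in range(2) for j in range(2)
        )
        df = n - 1
        return {
            "A": (ss["A"] / (ss["AS"] / df)),
            "B": (ss["B"] / (ss["BS"] / df)),
            "AB": (ss["AB"] / (ss["ABS"] / df)),
        }

    def test_all_cells_identical(self):
        values = np.ones((5, 2, 2)) * 3.0
        res = rm_anova_2x2(values)
        for eff in (res.factor_a, res.factor_b, res.interaction):
            assert eff.F == 0.0 and eff.partial_eta_sq == 0.0

    def test_brute_force_oracle_four_subjects(self):
        rng = np.random.default_rng(5)
        values = rng.normal(10.0, 3.0, size=(4, 2, 2))
        res = rm_anova_2x2(values)
        oracle = self._brute_force(values)
        assert res.factor_a.F == pytest.approx(oracle["A"], abs=1e-10)
        assert res.factor_b.F == pytest.approx(oracle["B"], abs=1e-10)
        assert res.interaction.F == pytest.approx(oracle["AB"], abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        values = rng.normal(0.0, 1.0, size=(12, 2, 2))
        res = rm_anova_2x2(values)
        rows = [
            {"subject": s, "A": a, "B": b, "y": values[s, a, b]}
            for s in range(12) for a in range(2) for b in range(2)
        ]
        table = pg.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["A", "B"],
            subject="subject", detailed=True,
        )
        by_source = table.set_index("Source")
        assert res.factor_a.F == pytest.approx(by_source.loc["A", "F"], rel=1e-9)
        assert res.factor_b.F == pytest.approx(by_source.loc["B", "F"], rel=1e-9)
        assert res.interaction.F == pytest.approx(by_source.loc["A * B", "F"],
                                                  rel=1e-9)

    def test_one_df_effects_equal_squared_paired_t(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(10, 2, 2))
        res = rm_anova_2x2(values)
        a_contrast_x = values[:, 0, :].mean(axis=1)
        a_contrast_y = values[:, 1, :].mean(axis=1)
        t_a = paired_t(a_contrast_x, a_contrast_y)
        assert res.factor_a.F == pytest.approx(t_a.t**2, abs=1e-10)
        inter_x = values[:, 0, 0] - values[:, 0, 1]
        inter_y = values[:, 1, 0] - values[:, 1, 1]
        t_ab = paired_t(inter_x, inter_y)
        assert res.interaction.F == pytest.approx(t_ab.t**2, abs=1e-10)


class TestPartialEtaSq:
    @pytest.mark.parametrize(
        "F,expected",
        [(5.20, 0.14), (71.81, 0.70), (0.0, 0.0)],
    )
    def test_printed_values(self, F, expected):
        assert round(partial_eta_sq(F, 1, 31), 2) == expected

    def test_negative_f_rejected(self):
        with pytest.raises(ContractError):
            partial_eta_sq(-1.0, 1, 31)


class TestRegression:
    def test_exact_dependence(self):
        rng = np.random.default_rng(0)
        x1 = rng.standard_normal(30)
        x2 = rng.standard_normal(30)
        res = ols_regression_standardized(x1, {"x1": x1, "x2": x2})
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.betas[0] == pytest.approx(1.0, abs=1e-10)
        assert res.betas[1] == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_predictors_r2_identity(self):
        """With exactly orthogonal standardized predictors,
        R^2 = r(y,x1)^2 + r(y,x2)^2."""
        rng = np.random.default_rng(4)
        x1 = rng.standard_normal(40)
        x2 = rng.standard_normal(40)
        # orthogonalize and standardize
        x2 = x2 - np.polyval(np.polyfit(x1, x2, 1), x1)
        y = 0.5 * x1 + 0.3 * x2 + rng.standard_normal(40)
        res = ols_regression_standardized(y, {"x1": x1, "x2": x2})
        expected = pearson_r(y, x1).r ** 2 + pearson_r(y, x2).r ** 2
        assert res.r_squared == pytest.approx(expected, abs=1e-10)

    def test_normal_equations_oracle(self):
        """Six-point dataset: betas match (Z'Z)^-1 Z'y to 1e-10."""
        y = np.array([3.1, 4.9, 1.2, 7.4, 5.5, 2.8])
        x1 = np.array([1.0, 2.0, 0.5, 3.5, 2.5, 1.2])
        x2 = np.array([0.3, -1.2, 0.8, 0.1, -0.4, 1.1])
        res = ols_regression_standardized(y, {"x1": x1, "x2": x2})
        Z = np.column_stack([
            (v - v.mean()) / v.std(ddof=1) for v in (x1, x2)
        ])
        zy = (y - y.mean()) / y.std(ddof=1)
        oracle = np.linalg.solve(Z.T @ Z, Z.T @ zy)
        np.testing.assert_allclose(res.betas, oracle, atol=1e-10)

    def test_collinearity_names_offender(self):
        x1 = np.arange(10.0)
        with pytest.raises(AnalysisError, match="x1|x2"):
            ols_regression_standardized(
                np.random.default_rng(0).standard_normal(10),
                {"x1": x1, "x2": 2.0 * x1},
            )


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        assert pearson_r(x, x).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_covariance_formula_oracle(self):
        x = np.array([2.0, 4.0, 6.0, 9.0, 1.0])
        y = np.array([1.5, 3.1, 2.2, 6.0, 0.4])
        r_oracle = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert pearson_r(x, y).r == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(AnalysisError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSteigerZ:
    def test_equal_correlations_give_zero(self):
        for variant in ("updated", "classic"):
            res = steiger_z(0.5, 0.5, 0.3, 32, variant)
            assert res.Z == 0.0
            assert res.p == pytest.approx(1.0)

    def test_sign_convention(self):
        assert steiger_z(0.6, 0.2, 0.3, 32).Z > 0
        assert steiger_z(0.2, 0.6, 0.3, 32).Z < 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ContractError):
            steiger_z(1.0, 0.5, 0.3, 32)
        with pytest.raises(ContractError):
            steiger_z(0.5, 0.4, 0.3, 3)


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        for tails in (1, 2):
            assert power_paired_t(32, 0.0, 0.05, tails) == pytest.approx(0.05,
                                                                         abs=1e-9)

    def test_monotone_in_n(self):
        powers = [power_paired_t(n, 0.5, 0.05, 2) for n in (8, 16, 32, 64)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_against_statsmodels(self):
        smp = pytest.importorskip("statsmodels.stats.power")
        ours = power_paired_t(32, 0.5, 0.05, 1)
        theirs = smp.TTestPower().power(effect_size=0.5, nobs=32, alpha=0.05,
                                        alternative="larger")
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_monte_carlo_oracle(self):
        """Analytic power at n=32, dz=0.5, one-tailed ~ 0.87; a
        100,000-replicate simulation agrees within 0.01."""
        analytic = power_paired_t(32, 0.5, 0.05, 1)
        rng = np.random.default_rng(6)
        diffs = rng.standard_normal((100_000, 32)) + 0.5
        t = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / math.sqrt(32))
        sim = float(np.mean(t > sps.t.ppf(0.95, 31)))
        assert analytic == pytest.approx(sim, abs=0.01)
        assert analytic > 0.80


class TestNormalityAndBonferroni:
    def test_uniform_sample_rejected(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(size=500)
        D, p = ks_normality(x)
        assert p < 0.05

    def test_normal_sample_retained(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(200)
        _, p = ks_normality(x)
        assert p > 0.05

    def test_classic_flag(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        D_l, _ = ks_normality(x, estimated=True)
        D_c, _ = ks_normality(x, estimated=False)
        assert D_l == pytest.approx(D_c, abs=1e-12)  # same distance statistic

    def test_bonferroni_scaling_and_cap(self):
        np.testing.assert_allclose(bonferroni([0.03], m=2), [0.06])
        np.testing.assert_allclose(bonferroni([0.9], m=3), [1.0])
        np.testing.assert_allclose(bonferroni([0.01, 0.02]), [0.02, 0.04])
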