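"""Tests for the per-gene exposure regression machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from conftest import brute_force_bh
from expotrans import regression, simulate
from expotrans.errors import DesignError, InputDataError
from expotrans.regression import DesignSpec


def _y_from(cohort, fn):
    return pd.Series(fn(cohort), index=cohort["sample_id"])


class TestFitGeneModel:
    def test_exact_linear_relation(self, small_cohort):
        y = _y_from(small_cohort, lambda c: 0.1 * c["pm10"].to_numpy())
        fit = regression.fit_gene_model(y, small_cohort, DesignSpec(stratum="M"))
        assert fit.slope == pytest.approx(0.1, abs=1e-10)
        assert fit.p < 1e-12

    def test_constant_response_degenerate(self, small_cohort):
        y = _y_from(small_cohort, lambda c: np.full(len(c), 7.0))
        fit = regression.fit_gene_model(y, small_cohort, DesignSpec(stratum="F"))
        assert fit.slope == 0.0 and fit.p == 1.0 and fit.degenerate

    def test_matches_normal_equations_on_hand_dataset(self):
        """12-point dataset, one covariate: slope/se from (X'X)^-1 X'y."""
        rng = np.random.default_rng(4)
        n = 12
        pm = np.linspace(18, 32, n)
        age = rng.uniform(50, 65, n)
        y = 5.0 + 0.07 * pm + 0.01 * age + rng.normal(0, 0.2, n)
        cohort = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "sex": "M",
                "age": age,
                "bmi": 26.0,
                "ses": "low",
                "smoking": "never",
                "season": "cold",
                "daytime": "<1200",
                "leukocytes": np.nan,
                "neutrophils": np.nan,
                "pm10": pm,
                "pm25": pm / 1.5,
            }
        )
        design = DesignSpec(stratum="M", covariates=("age",), outlier_threshold=np.inf)
        fit = regression.fit_gene_model(
            pd.Series(y, index=cohort["sample_id"]), cohort, design
        )
        X = np.column_stack([np.ones(n), pm, age])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (n - 3)
        cov = s2 * np.linalg.inv(X.T @ X)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        assert fit.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)

    def test_gross_outlier_removed_once(self, small_cohort):
        rng = np.random.default_rng(8)
        men = small_cohort[small_cohort["sex"] == "M"]
        y = 0.05 * men["pm10"].to_numpy() + rng.normal(0, 0.1, len(men))
        y[0] += 25.0  # gross outlier
        fit = regression.fit_gene_model(
            pd.Series(y, index=men["sample_id"]), small_cohort, DesignSpec(stratum="M")
        )
        assert fit.outliers_removed == 1
        assert fit.slope == pytest.approx(0.05, abs=0.03)

    def test_rank_deficient_design_names_columns(self, small_cohort):
        cohort = small_cohort.copy()
        cohort["bmi"] = cohort["age"]  # perfectly collinear
        y = _y_from(cohort, lambda c: c["pm10"].to_numpy())
        with pytest.raises(DesignError, match="collinear"):
            regression.fit_gene_model(y, cohort, DesignSpec(stratum="M"))


class TestFcPerIncrement:
    def test_zero_slope_gives_unit_fold_change(self):
        fc, (lo, hi) = regression.fc_per_increment(0.0, 0.02, df=40)
        assert fc == 1.0
        assert lo * hi == pytest.approx(1.0)  # CI symmetric about 1 on log scale

    def test_slope_point_two_doubles_expression(self):
        fc, _ = regression.fc_per_increment(0.2, 0.0, df=40)
        assert fc == pytest.approx(2.0)

    def test_printed_discovery_estimate_inverts(self):
        slope = np.log2(1.36) / 5.0
        fc, _ = regression.fc_per_increment(slope, 0.0, df=40)
        assert fc == pytest.approx(1.36, abs=1e-12)

    def test_unit_rescaling_equivariance(self, small_cohort):
        """Exposure in units of c ug/m3 divides the slope by c but leaves the
        fold change per rescaled increment unchanged."""
        rng = np.random.default_rng(3)
        y = _y_from(
            small_cohort,
            lambda c: 0.04 * c["pm10"].to_numpy() + rng.normal(0, 0.2, len(c)),
        )
        fit = regression.fit_gene_model(y, small_cohort, DesignSpec(stratum="F"))
        scaled = small_cohort.copy()
        scaled["pm10"] = scaled["pm10"] * 10.0
        fit_scaled = regression.fit_gene_model(y, scaled, DesignSpec(stratum="F"))
        assert fit_scaled.slope == pytest.approx(fit.slope / 10.0, rel=1e-9)
        fc, _ = regression.fc_per_increment(fit.slope, fit.se, fit.df_resid, 5.0)
        fc_scaled, _ = regression.fc_per_increment(
            fit_scaled.slope, fit_scaled.se, fit_scaled.df_resid, 50.0
        )
        assert fc_scaled == pytest.approx(fc, rel=1e-9)


class TestBhAdjust:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            regression.bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_p_unchanged(self):
        assert regression.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(regression.bh_adjust([0.3] * 5), [0.3] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputDataError):
            regression.bh_adjust([0.5, 1.2])

    def test_matches_statsmodels(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(regression.bh_adjust(p), expected, atol=1e-12)

    def test_matches_brute_force_definition(self, rng):
        p = rng.uniform(size=25)
        np.testing.assert_allclose(regression.bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=15),
        st.data(),
    )
    def test_monotone_in_each_p(self, pvals, data):
        """Increasing any single p never decreases any q."""
        i = data.draw(st.integers(min_value=0, max_value=len(pvals) - 1))
        bumped = list(pvals)
        bumped[i] = min(1.0, bumped[i] + data.draw(st.floats(0.0, 0.5)))
        q0 = regression.bh_adjust(pvals)
        q1 = regression.bh_adjust(bumped)
        assert (q1 >= q0 - 1e-12).all()


class TestRankGenes:
    def test_rank_follows_p(self):
        df = pd.DataFrame({"gene": ["a", "b", "c"], "p": [0.5, 0.001, 0.02]})
        out = regression.rank_genes(df)
        assert dict(zip(out["gene"], out["rank"])) == {"b": 1, "c": 2, "a": 3}

    def test_ties_broken_lexicographically(self):
        df = pd.DataFrame({"gene": ["zz", "aa"], "p": [0.01, 0.01]})
        out = regression.rank_genes(df)
        assert list(out["gene"]) == ["aa", "zz"]

    def test_matches_sort_oracle(self, rng):
        p = rng.uniform(size=1000)
        df = pd.DataFrame({"gene": [f"g{i:04d}" for i in range(1000)], "p": p})
        out = regression.rank_genes(df)
        oracle = sorted(range(1000), key=lambda i: (p[i], f"g{i:04d}"))
        assert list(out["gene"]) == [f"g{i:04d}" for i in oracle]


class TestInteractionScan:
    def _expr(self, cohort, slopes_by_sex, noise, seed=0):
        rng = np.random.default_rng(seed)
        pm = cohort["pm10"].to_numpy()
        is_m = (cohort["sex"] == "M").to_numpy()
        y = np.where(is_m, slopes_by_sex["M"], slopes_by_sex["F"]) * pm
        y = y + rng.normal(0, noise, len(pm))
        return pd.DataFrame([y], index=["g1"], columns=cohort["sample_id"])

    def test_opposite_slopes_detected(self):
        cfg = simulate.SimulationConfig(n_men=100, n_women=100, seed=5)
        cohort = simulate.generate_cohort(cfg)
        expr = self._expr(cohort, {"M": 0.1, "F": -0.1}, noise=0.05)
        p = regression.interaction_scan(expr, cohort, DesignSpec())
        assert p["g1"] < 1e-6

    def test_constant_exposure_rejected(self, small_cohort):
        cohort = small_cohort.copy()
        cohort["pm10"] = 25.0
        expr = pd.DataFrame(
            [np.ones(len(cohort))], index=["g1"], columns=cohort["sample_id"]
        )
        with pytest.raises(DesignError, match="constant"):
            regression.interaction_scan(expr, cohort, DesignSpec())

    def test_single_sex_rejected(self, small_cohort):
        men = small_cohort[small_cohort["sex"] == "M"]
        expr = pd.DataFrame([np.ones(len(men))], index=["g1"], columns=men["sample_id"])
        with pytest.raises(DesignError, match="both sexes"):
            regression.interaction_scan(expr, men, DesignSpec())

    def test_null_interaction_p_uniform(self):
        """Equal slopes in both sexes: interaction p is uniform over sims."""
        pvals = []
        for seed in range(250):
            cfg = simulate.SimulationConfig(n_men=30, n_women=30, seed=1000 + seed)
            cohort = simulate.generate_cohort(cfg)
            expr = self._expr(cohort, {"M": 0.05, "F": 0.05}, noise=0.3, seed=seed)
            pvals.append(regression.interaction_scan(expr, cohort, DesignSpec())["g1"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
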