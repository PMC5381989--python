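"""Tests of the synthetic cohort / expression / Cq generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from expotrans import preprocess, qpcr, regression, simulate
from expotrans.errors import ConfigurationError
from expotrans.regression import DesignSpec, DISCOVERY_COVARIATES


def _noiseless_config(**kwargs):
    defaults = dict(
        n_men=24,
        n_women=24,
        residual_sd=0.0,
        probe_sd=0.0,
        flag_probability=0.0,
        covariate_effects={},
        n_null_genes=5,
        seed=11,
    )
    defaults.update(kwargs)
    return simulate.SimulationConfig(**defaults)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        cfg = simulate.SimulationConfig(seed=42)
        a = simulate.generate_cohort(cfg)
        b = simulate.generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        cfg = simulate.SimulationConfig(seed=42)
        a = simulate.generate_cohort(cfg)
        b = simulate.generate_cohort(cfg, rng_seed=43)
        assert not np.allclose(a["pm10"], b["pm10"])

    def test_exposure_mean_calibration(self):
        """48 men at the discovery PM10 settings: sample mean near 25.8."""
        cfg = simulate.SimulationConfig(
            n_men=48, n_women=2, pm10_mean=25.8, pm10_sd=2.7, seed=5
        )
        cohort = simulate.generate_cohort(cfg)
        men = cohort[cohort["sex"] == "M"]
        assert abs(men["pm10"].mean() - 25.8) < 1.2  # ~3 standard errors

    def test_zero_sd_degenerates_to_point_mass(self):
        cfg = simulate.SimulationConfig(pm10_sd=0.0, seed=1)
        cohort = simulate.generate_cohort(cfg)
        np.testing.assert_allclose(cohort["pm10"], 25.9)

    def test_pm_correlation_recovered(self):
        cfg = simulate.SimulationConfig(
            n_men=5000, n_women=5000, pm_correlation=0.8, season_exposure_shift=0.0, seed=9
        )
        cohort = simulate.generate_cohort(cfg)
        r = np.corrcoef(cohort["pm10"], cohort["pm25"])[0, 1]
        assert abs(r - 0.8) < 0.02

    def test_structure_and_invariants(self):
        disc = simulate.generate_cohort(simulate.SimulationConfig(seed=2))
        assert (disc["smoking"] == "never").all()  # smokers excluded at discovery
        assert disc["leukocytes"].isna().all()
        val = simulate.generate_cohort(
            simulate.SimulationConfig(cohort_kind="validation", seed=2)
        )
        assert set(val["ses"]) <= {"low", "medium", "high"}
        assert set(val["daytime"]) <= set(simulate.DAYTIME_LEVELS)
        assert (val["pm10"] > 0).all() and (val["pm25"] > 0).all()
        assert val["leukocytes"].notna().all()

    @pytest.mark.parametrize(
        "field,value,fragment",
        [
            ("n_men", 0, "n_men"),
            ("pm_correlation", 1.0, "pm_correlation"),
            ("flag_probability", 1.0, "flag_probability"),
            ("residual_sd", -0.1, "residual_sd"),
            ("efficiencies", {"HPRT": 1.5}, "efficiencies"),
        ],
    )
    def test_invalid_config_names_field(self, field, value, fragment):
        cfg = simulate.SimulationConfig(**{field: value})
        with pytest.raises(ConfigurationError, match=fragment):
            cfg.validate()


class TestGenerateExpression:
    def test_zero_noise_null_constant_after_preprocessing(self):
        cfg = _noiseless_config()
        cohort = simulate.generate_cohort(cfg)
        raw = simulate.generate_expression(cohort, cfg)
        ann = simulate.annotation_frame(cfg.resolved_probe_map())
        expr, _ = preprocess.run_preprocessing(
            raw, ann, preprocess.PreprocessParams(flat_rms_threshold=0.0)
        )
        spread = expr.max(axis=1) - expr.min(axis=1)
        assert (spread < 1e-9).all()

    def test_unknown_effect_gene_rejected(self):
        cfg = _noiseless_config(effect_table=(simulate.EffectSpec("NOPE", "M", 0.1),))
        cfg.probe_map = {"OTHER": ("OTHER|p1|s1",)}
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_embedded_fold_change_recovered_by_fit(self):
        """FC 1.36 per 5 ug/m3 embedded in men comes back from the model."""
        cfg = simulate.SimulationConfig(
            n_men=48,
            n_women=2,
            effect_table=(simulate.EffectSpec("DNAJB5", "M", float(np.log2(1.36))),),
            residual_sd=0.05,
            seed=21,
        )
        cohort = simulate.generate_cohort(cfg)
        expr = simulate.simulate_gene_matrix(cohort, cfg)
        fit = regression.fit_gene_model(
            expr.loc["DNAJB5"], cohort, DesignSpec(stratum="M")
        )
        fc, _ = regression.fc_per_increment(fit.slope, fit.se, fit.df_resid)
        assert fc == pytest.approx(1.36, abs=0.05)

    def test_noiseless_pipeline_recovers_slopes_exactly(self):
        """With all noise off the chain (QN disabled) returns embedded slopes
        to better than six significant digits."""
        effects = (
            simulate.EffectSpec("GENEA", "M", 0.30),
            simulate.EffectSpec("GENEB", "F", -0.22),
        )
        cfg = _noiseless_config(effect_table=effects, n_null_genes=10)
        cohort = simulate.generate_cohort(cfg)
        raw = simulate.generate_expression(cohort, cfg)
        ann = simulate.annotation_frame(cfg.resolved_probe_map())
        params = preprocess.PreprocessParams(
            quantile_normalization=False, flat_rms_threshold=0.0
        )
        expr, _ = preprocess.run_preprocessing(raw, ann, params)
        for gene, sex, log2fc in [("GENEA", "M", 0.30), ("GENEB", "F", -0.22)]:
            design = DesignSpec(stratum=sex, covariates=DISCOVERY_COVARIATES,
                                outlier_threshold=np.inf)
            fit = regression.fit_gene_model(expr.loc[gene], cohort, design)
            assert fit.slope == pytest.approx(log2fc / 5.0, rel=1e-7)

    def test_null_gene_slopes_centred_on_zero(self):
        cfg = simulate.SimulationConfig(n_men=50, n_women=2, n_null_genes=400, seed=3)
        cohort = simulate.generate_cohort(cfg)
        expr = simulate.simulate_gene_matrix(cohort, cfg)
        design = DesignSpec(stratum="M")
        slopes = [
            regression.fit_gene_model(expr.loc[g], cohort, design).slope
            for g in expr.index
        ]
        se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 3 * se + 1e-4


class TestGenerateCq:
    def test_doubled_expression_is_one_cycle_lower(self):
        """E = 2: a twofold quantity difference is exactly one Cq cycle."""
        cfg = _noiseless_config(
            cq_replicate_sd=0.0,
            cq_outlier_probability=0.0,
            effect_table=(simulate.EffectSpec("TGT", "M", 5.0),),  # slope 1 per ug
            pm10_sd=0.0,
        )
        cfg.probe_map = {}
        cfg.n_null_genes = 0
        cohort = simulate.generate_cohort(cfg)
        # doubling expression = +1 in log2Q; engineer via pm shift of 1 ug/m3
        cohort.loc[cohort.index[0], "pm10"] = cohort["pm10"].iloc[1] + 1.0
        cq = simulate.generate_cq(cohort, cfg)
        tgt = cq[cq["assay_id"] == "TGT"].set_index("sample_id")
        s0, s1 = cohort["sample_id"].iloc[0], cohort["sample_id"].iloc[1]
        assert tgt.loc[s0, "rep1"] == pytest.approx(tgt.loc[s1, "rep1"] - 1.0)

    def test_zero_noise_triplicates_identical(self):
        cfg = _noiseless_config(cq_replicate_sd=0.0, cq_outlier_probability=0.0)
        cohort = simulate.generate_cohort(cfg)
        cq = simulate.generate_cq(cohort, cfg, assays=["NULL0000"])
        np.testing.assert_allclose(cq["rep1"], cq["rep2"])
        np.testing.assert_allclose(cq["rep1"], cq["rep3"])

    def test_reference_gene_with_effect_rejected(self):
        cfg = _noiseless_config(
            effect_table=(simulate.EffectSpec("HPRT", "F", 0.2),), probe_map={}
        )
        cfg.probe_map = {}
        cohort = simulate.generate_cohort(cfg)
        with pytest.raises(ConfigurationError, match="reference"):
            simulate.generate_cq(cohort, cfg)

    def test_qpcr_chain_recovers_embedded_fold_change(self):
        """Embedded log2 FC -0.3 per 5 ug/m3 in 94 women survives the full
        Cq -> NRQ -> regression chain (FC near 0.812)."""
        cfg = simulate.SimulationConfig(
            n_men=4,
            n_women=94,
            cohort_kind="validation",
            effect_table=(simulate.EffectSpec("TGT", "F", -0.3),),
            residual_sd=0.05,
            cq_replicate_sd=0.02,
            cq_outlier_probability=0.0,
            seed=13,
        )
        cohort = simulate.generate_cohort(cfg)
        cq = simulate.generate_cq(cohort, cfg)
        processed = qpcr.process_cq_table(cq, cfg.reference_genes)
        nrq = qpcr.nrq_matrix(processed)
        design = DesignSpec(
            stratum="F", covariates=regression.VALIDATION_COVARIATES
        )
        fit = regression.fit_gene_model(nrq.loc["TGT"], cohort, design)
        fc, _ = regression.fc_per_increment(fit.slope, fit.se, fit.df_resid)
        assert fc == pytest.approx(2 ** -0.3, abs=0.05)


def test_probe_matrix_roundtrip(tmp_path):
    cfg = simulate.SimulationConfig(n_men=3, n_women=3, n_null_genes=4, seed=8)
    cohort = simulate.generate_cohort(cfg)
    raw = simulate.generate_expression(cohort, cfg)
    raw.write(tmp_path / "raw.tsv")
    back = simulate.ProbeIntensityMatrix.read(tmp_path / "raw.tsv")
    np.testing.assert_allclose(back.foreground, raw.foreground, rtol=1e-9)
    pd.testing.assert_frame_equal(back.flags, raw.flags, check_names=False)


def test_expression_generation_deterministic():
    cfg = simulate.SimulationConfig(n_men=5, n_women=5, n_null_genes=6, seed=99)
    cohort = simulate.generate_cohort(cfg)
    a = simulate.generate_expression(cohort, cfg)
    b = simulate.generate_expression(cohort, cfg)
    pd.testing.assert_frame_equal(a.foreground, b.foreground)
    cq_a = simulate.generate_cq(cohort, cfg, assays=["NULL0000"])
    cq_b = simulate.generate_cq(cohort, cfg, assays=["NULL0000"])
    pd.testing.assert_frame_equal(cq_a, cq_b)
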