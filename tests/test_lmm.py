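import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from mctkit.datamodel import GrowthCurve, MCTDataset
from mctkit.lmm import (
    LMMSpec,
    biomarker_scan,
    fit_lmm,
    interpret_gene_effects,
    naive_correlation_scan,
    tgi_by_model,
)
from mctkit.simulate import SimConfig, biomarker_preset, generate_expression, generate_mct

from conftest import make_dataset


def rescaled(ds, factor):
    curves = [
        GrowthCurve(c.mouse_id, c.model_id, c.arm, c.days,
                    tuple(factor * v for v in c.volumes))
        for c in ds.curves
    ]
    return MCTDataset(curves=curves, model_covariates=ds.model_covariates)


def arm_swapped(ds):
    flip = {"vehicle": "treatment", "treatment": "vehicle"}
    curves = [
        GrowthCurve(c.mouse_id, c.model_id, flip[c.arm], c.days, c.volumes)
        for c in ds.curves
    ]
    return MCTDataset(curves=curves, model_covariates=ds.model_covariates)


@pytest.fixture(scope="module")
def trial():
    cfg = SimConfig(n_models=15, n_mice_per_arm=3)
    ds, truth = generate_mct(cfg, seed=101)
    return cfg, ds, truth


class TestFitLmm:
    def test_near_noiseless_recovery(self):
        cfg = SimConfig(
            n_models=6, n_mice_per_arm=2,
            model_sd_intercept=0, model_sd_slope=0,
            mouse_sd_intercept=0, mouse_sd_slope=0,
            residual_sd=1e-6, beta1=0.06, beta2=-0.012,
            initial_volume_range=(150.0, 150.0),
        )
        ds, _ = generate_mct(cfg, seed=1)
        fit = fit_lmm(ds)
        assert fit.coef("Day") == pytest.approx(0.06, abs=1e-5)
        assert fit.coef("Day:Treatment") == pytest.approx(-0.012, abs=1e-5)
        assert fit.coef("Intercept") == pytest.approx(math.log(150), abs=1e-4)
        for level in ("model", "mouse"):
            assert np.all(np.abs(fit.random_effect_cov[level]) < 1e-8)

    def test_recovers_variance_components_at_scale(self):
        cfg = SimConfig(n_models=150, n_mice_per_arm=3)
        ds, _ = generate_mct(cfg, seed=77)
        fit = fit_lmm(ds)
        assert fit.coef("Day") == pytest.approx(cfg.beta1, abs=3 * fit.se("Day"))
        assert fit.coef("Day:Treatment") == pytest.approx(
            cfg.beta2, abs=3 * fit.se("Day:Treatment")
        )
        assert fit.random_effect_cov["model"][1, 1] == pytest.approx(
            cfg.model_sd_slope**2, rel=0.5
        )
        assert fit.random_effect_cov["mouse"][1, 1] == pytest.approx(
            cfg.mouse_sd_slope**2, rel=0.3
        )
        assert fit.residual_sd == pytest.approx(cfg.residual_sd, rel=0.1)

    def test_volume_rescaling_shifts_only_intercept(self, trial):
        _, ds, _ = trial
        f1 = fit_lmm(ds)
        f2 = fit_lmm(rescaled(ds, 10.0))
        assert f2.coef("Intercept") == pytest.approx(
            f1.coef("Intercept") + math.log(10), abs=1e-5
        )
        for term in ("Day", "Day:Treatment"):
            assert f2.coef(term) == pytest.approx(f1.coef(term), abs=1e-7)
            assert f2.pvalue(term) == pytest.approx(f1.pvalue(term), rel=1e-3)
        np.testing.assert_allclose(
            f2.random_effect_cov["mouse"][1, 1],
            f1.random_effect_cov["mouse"][1, 1],
            rtol=1e-4,
        )

    def test_arm_swap_negates_treatment_slope(self, trial):
        """In a balanced design, relabeling arms flips the sign of the
        treatment effect and adds it to the time slope."""
        _, ds, _ = trial
        f1 = fit_lmm(ds)
        f2 = fit_lmm(arm_swapped(ds))
        b2 = f1.coef("Day:Treatment")
        assert f2.coef("Day:Treatment") == pytest.approx(-b2, abs=1e-6)
        assert f2.coef("Day") == pytest.approx(f1.coef("Day") + b2, abs=1e-6)

    def test_matches_two_level_oracle_without_clustering(self):
        """With model-level variances 0, the three-level fit agrees with an
        independent two-level (mouse-only) mixed model from statsmodels."""
        import statsmodels.formula.api as smf

        cfg = SimConfig(n_models=30, n_mice_per_arm=2,
                        model_sd_intercept=0.0, model_sd_slope=0.0)
        ds, _ = generate_mct(cfg, seed=13)
        fit = fit_lmm(ds)

        df = ds.to_long()
        df["logv"] = np.log(df["volume_mm3"])
        df["treat"] = (df["arm"] == "treatment").astype(float)
        df["day_treat"] = df["day"] * df["treat"]
        md = smf.mixedlm(
            "logv ~ day + day_treat", df, groups=df["mouse_id"],
            re_formula="~day",
        ).fit(reml=True)
        assert fit.coef("Day") == pytest.approx(
            md.params["day"], abs=2 * md.bse["day"]
        )
        assert fit.coef("Day:Treatment") == pytest.approx(
            md.params["day_treat"], abs=2 * md.bse["day_treat"]
        )
        # with no true model-level heterogeneity the estimates are near-equal
        assert fit.coef("Day:Treatment") == pytest.approx(
            md.params["day_treat"], abs=1e-3
        )

    def test_categorical_covariate_expansion(self):
        cfg = SimConfig(n_models=12, n_mice_per_arm=2)
        ds, _ = generate_mct(cfg, seed=3)
        for i, m in enumerate(ds.model_ids):
            ds.model_covariates[m]["cancer_type"] = ["ES", "GA", "LU"][i % 3]
        spec = LMMSpec(
            model_covariates=("cancer_type",),
            include_treatment=True,
            include_covariate_by_treatment=True,
            reference_level="ES",
        )
        fit = fit_lmm(ds, spec)
        terms = set(fit.fixed_effects)
        assert terms == {
            "Intercept", "Day", "Day:cancer_type[GA]", "Day:cancer_type[LU]",
            "Day:Treatment", "Day:cancer_type[GA]:Treatment",
            "Day:cancer_type[LU]:Treatment",
        }

    def test_zero_volume_observations_dropped(self, trial):
        _, ds, _ = trial
        curves = list(ds.curves)
        c = curves[0]
        curves[0] = GrowthCurve(
            c.mouse_id, c.model_id, c.arm, c.days,
            (*c.volumes[:-1], 0.0),
        )
        ds2 = MCTDataset(curves=curves, model_covariates=ds.model_covariates)
        fit = fit_lmm(ds2)
        assert fit.n_zero_volume_dropped == 1
        total = sum(len(c) for c in ds2.curves)
        assert fit.n_observations == total - 1


class TestBiomarkerScan:
    @pytest.fixture(scope="class")
    def scan_world(self):
        cfg = replace(biomarker_preset(n_genes=30), n_models=20)
        ds, truth = generate_mct(cfg, seed=55)
        expr = generate_expression(cfg, truth, seed=56)
        return cfg, ds, truth, expr

    def test_causal_gene_tops_ranking(self, scan_world):
        _, ds, truth, expr = scan_world
        table = biomarker_scan(ds, expr)
        assert table.index[0] == truth["causal_gene"]
        assert table.loc["G_causal", "rank"] == 1
        assert table.loc["G_causal", "p_adj"] <= table.loc["G_causal", "p_value"] * 30

    def test_constant_gene_skipped(self, scan_world):
        _, ds, _, expr = scan_world
        expr2 = expr.copy()
        expr2.loc["G0001"] = 1.0
        table = biomarker_scan(ds, expr2)
        assert bool(table.loc["G0001", "skipped"])
        assert np.isnan(table.loc["G0001", "p_value"])

    def test_naive_scan_monotone_extremes(self, scan_world):
        _, ds, _, expr = scan_world
        t = tgi_by_model(ds)
        models = list(t)
        vals = np.array([t[m] for m in models])
        expr2 = pd.DataFrame(
            [vals, -vals, np.zeros(len(models))],
            index=["mono", "anti", "flat"], columns=models,
        )
        table = naive_correlation_scan(expr2, t)
        assert table.loc["mono", "rho"] == pytest.approx(1.0)
        assert table.loc["anti", "rho"] == pytest.approx(-1.0)
        assert np.isnan(table.loc["flat", "rho"])


class TestInterpretGeneEffects:
    def _fit_with(self, b2, b4):
        cfg = replace(
            biomarker_preset(n_genes=5), n_models=25, n_mice_per_arm=2,
            gene_growth_effect=b2, gene_treatment_effect=b4,
            residual_sd=0.02, mouse_sd_slope=0.002, model_sd_slope=0.002,
        )
        ds, truth = generate_mct(cfg, seed=8)
        gv = truth["gene_value"]
        spec = LMMSpec(model_covariates=("Gene",), include_treatment=True,
                       include_covariate_by_treatment=True)
        return fit_lmm(ds, spec, extra_covariates={"Gene": gv})

    def test_opposite_signs_narrative(self):
        fit = self._fit_with(-0.02, 0.02)
        report = interpret_gene_effects(fit)
        assert report["growth_effect"][0] < 0
        assert report["treatment_modification"][0] > 0
        assert "slower" in report["narrative"]
        assert "smaller" in report["narrative"]
        assert "opposite directions" in report["narrative"]
        # Fig-style mean curves: high-expression vehicle grows slower,
        # but gains less from treatment
        s = report["mean_growth_slopes"]
        assert s[(1.0, "vehicle")] < s[(-1.0, "vehicle")]
        benefit_hi = s[(1.0, "vehicle")] - s[(1.0, "treatment")]
        benefit_lo = s[(-1.0, "vehicle")] - s[(-1.0, "treatment")]
        assert benefit_hi < benefit_lo

    def test_null_and_single_effect_reports(self):
        fit = self._fit_with(-0.02, 0.02)
        # synthetic edits: force exact zeros to exercise the report branches
        fit.fixed_effects["Day:Gene"] = (0.0, 1.0, 1.0)
        fit.fixed_effects["Day:Gene:Treatment"] = (0.0, 1.0, 1.0)
        assert "No detectable" in interpret_gene_effects(fit)["narrative"]
        fit.fixed_effects["Day:Gene:Treatment"] = (-0.01, 0.001, 1e-6)
        assert "Purely predictive" in interpret_gene_effects(fit)["narrative"]
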