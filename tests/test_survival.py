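import math
from dataclasses import replace

import numpy as np
import pytest

from mctkit.exceptions import InsufficientDataError
from mctkit.simulate import SimConfig, generate_mct, generate_survival
from mctkit.survival import (
    SurvivalRecord,
    _FrailtyData,
    _gh_grid,
    _marginal_loglik,
    derive_survival,
    fit_cox,
    fit_frailty,
    frailty_growth_correlation,
    records_to_frame,
    vehicle_growth_rates,
)

from conftest import exp_curve, make_curve, make_dataset


def no_frailty_config(**kw):
    base = dict(n_models=50, n_mice_per_arm=3, frailty_sigma2=0.0,
                frailty_tau2=0.0)
    base.update(kw)
    return SimConfig(**base)


class TestDeriveSurvival:
    def test_tripling_time_closed_form(self):
        k = math.log(3) / 10
        ds = make_dataset([exp_curve(k, tuple(range(0, 22, 1)))])
        recs = derive_survival(ds, "tripling")
        assert recs[0].event
        assert recs[0].time == pytest.approx(10.0, abs=0.05)

    def test_shrinking_tumor_censored(self):
        ds = make_dataset([make_curve([100, 80, 60])])
        recs = derive_survival(ds, "doubling")
        assert not recs[0].event and recs[0].time == 14

    def test_mixed_cohort_and_zero_baseline_skip(self):
        curves = [
            exp_curve(0.2, (0, 7, 14), mouse_id="fast"),
            make_curve([100, 90, 80], mouse_id="resp"),
            make_curve([0, 10, 20], mouse_id="zero"),
        ]
        with pytest.warns(UserWarning, match="zero baseline"):
            recs = derive_survival(make_dataset(curves), "doubling")
        assert len(recs) == 2
        assert {r.event for r in recs} == {True, False}


class TestFitCox:
    def test_recovers_true_hazard_ratio(self):
        cfg = no_frailty_config(n_models=250, n_mice_per_arm=2, log_hr=math.log(0.5))
        recs, _ = generate_survival(cfg, seed=17)
        out = fit_cox(recs)
        assert 0.4 < out["hazard_ratio"] < 0.6
        lo, hi = out["ci_95"]
        assert lo < out["hazard_ratio"] < hi

    def test_null_ci_covers_one(self):
        cfg = no_frailty_config(log_hr=0.0)
        recs, _ = generate_survival(cfg, seed=23)
        lo, hi = fit_cox(recs)["ci_95"]
        assert lo < 1.0 < hi

    def test_arm_swap_negates_log_hr(self):
        cfg = no_frailty_config(log_hr=math.log(0.6))
        recs, _ = generate_survival(cfg, seed=29)
        swapped = [
            SurvivalRecord(r.model_id, r.mouse_id, 1 - r.treatment, r.time,
                           r.event, r.covariates)
            for r in recs
        ]
        assert fit_cox(swapped)["log_hr"] == pytest.approx(
            -fit_cox(recs)["log_hr"], abs=1e-6
        )

    def test_no_events_rejected(self):
        recs = [
            SurvivalRecord("M0", f"m{i}", i % 2, 10.0, False) for i in range(10)
        ]
        with pytest.raises(InsufficientDataError):
            fit_cox(recs)


class TestFitFrailty:
    @pytest.fixture(scope="class")
    def clustered_world(self):
        cfg = SimConfig(n_models=80, n_mice_per_arm=3, frailty_sigma2=0.5,
                        frailty_tau2=0.2, frailty_rho=0.0, log_hr=math.log(0.5))
        recs, truth = generate_survival(cfg, seed=31)
        return cfg, recs, truth

    def test_reduces_to_cox_without_frailty(self):
        cfg = no_frailty_config(n_models=60, log_hr=math.log(0.5))
        recs, _ = generate_survival(cfg, seed=37)
        cox = fit_cox(recs)
        fr = fit_frailty(recs, fix_rho=0.0)
        assert fr.w == pytest.approx(cox["log_hr"], abs=2 * cox["se"])
        assert fr.sigma2 < 0.1 and fr.tau2 < 0.1

    def test_recovers_generator_parameters(self, clustered_world):
        cfg, recs, _ = clustered_world
        fit = fit_frailty(recs, fix_rho=0.0)
        assert fit.converged
        assert fit.w == pytest.approx(cfg.log_hr, abs=3 * fit.se_w)
        assert fit.sigma2 == pytest.approx(0.5, rel=0.6)
        assert fit.tau2 == pytest.approx(0.2, rel=0.9)
        assert fit.weibull_shape == pytest.approx(cfg.weibull_shape, rel=0.2)
        assert fit.weibull_scale == pytest.approx(cfg.weibull_scale, rel=0.2)
        assert fit.p_sigma2 < 0.05  # frailty variance detectably > 0
        lo, hi = fit.hazard_ratio_ci
        assert lo < fit.hazard_ratio < hi

    def test_marginal_likelihood_gradient_vanishes(self, clustered_world):
        _, recs, _ = clustered_world
        fit = fit_frailty(recs, fix_rho=0.0)
        data = _FrailtyData(recs)
        nodes, logw = _gh_grid(9)

        def ll(w, shape, scale, s2, t2):
            Sigma = np.array([[s2, 0.0], [0.0, t2]])
            return _marginal_loglik(
                data, w, np.zeros(0), shape, scale, Sigma, nodes, logw
            )[0]

        args = [fit.w, fit.weibull_shape, fit.weibull_scale, fit.sigma2, fit.tau2]
        f0 = ll(*args)
        for i in range(len(args)):
            h = 1e-5 * max(1.0, abs(args[i]))
            up = args.copy(); up[i] += h
            dn = args.copy(); dn[i] -= h
            grad = (ll(*up) - ll(*dn)) / (2 * h)
            curv = abs(ll(*up) - 2 * f0 + ll(*dn)) / h**2
            assert abs(grad) < 1e-3 * max(curv * h, 1.0) + 0.05

    def test_quadrature_convergence(self, clustered_world):
        """Marginal log-likelihood stable under 9 -> 15 nodes per dimension."""
        _, recs, _ = clustered_world
        fit = fit_frailty(recs, fix_rho=0.0)
        data = _FrailtyData(recs)
        Sigma = np.array([[fit.sigma2, 0.0], [0.0, fit.tau2]])
        lls = []
        for nq in (9, 15):
            nodes, logw = _gh_grid(nq)
            lls.append(
                _marginal_loglik(data, fit.w, np.zeros(0), fit.weibull_shape,
                                 fit.weibull_scale, Sigma, nodes, logw)[0]
            )
        assert abs(lls[1] - lls[0]) < 1e-4

    def test_time_rescaling_equivariance(self, clustered_world):
        _, recs, _ = clustered_world
        c = 3.0
        scaled = [
            SurvivalRecord(r.model_id, r.mouse_id, r.treatment, c * r.time,
                           r.event, r.covariates)
            for r in recs
        ]
        f1 = fit_frailty(recs, fix_rho=0.0)
        f2 = fit_frailty(scaled, fix_rho=0.0)
        assert f2.weibull_scale == pytest.approx(c * f1.weibull_scale, rel=1e-3)
        assert f2.w == pytest.approx(f1.w, abs=1e-3)
        assert f2.sigma2 == pytest.approx(f1.sigma2, rel=1e-2)
        assert f2.tau2 == pytest.approx(f1.tau2, rel=5e-2)
        assert f2.weibull_shape == pytest.approx(f1.weibull_shape, rel=1e-3)

    def test_weibull_ph_limit_with_singleton_clusters(self):
        """Clusters of size 1 with tau^2 fixed at 0: w approaches the
        Weibull proportional-hazards estimate (lifelines AFT oracle)."""
        from lifelines import WeibullAFTFitter

        cfg = no_frailty_config(n_models=400, n_mice_per_arm=1, log_hr=math.log(0.6))
        recs, _ = generate_survival(cfg, seed=41)
        singles = [
            SurvivalRecord(f"C{i}", r.mouse_id, r.treatment, r.time, r.event)
            for i, r in enumerate(recs)
        ]
        fit = fit_frailty(singles, fix_tau2=0.0, fix_rho=0.0)
        df = records_to_frame(recs)[["time", "event", "treatment"]]
        aft = WeibullAFTFitter().fit(df, duration_col="time", event_col="event")
        rho_ = float(aft.summary.loc[("rho_", "Intercept"), "coef"])
        shape = math.exp(rho_)
        log_hr_ph = -float(
            aft.summary.loc[("lambda_", "treatment"), "coef"]
        ) * shape
        assert fit.w == pytest.approx(log_hr_ph, abs=0.05)
        assert fit.sigma2 < 0.05  # singleton frailty collapses

    def test_boundary_variance_flagged(self):
        cfg = no_frailty_config(n_models=30, n_mice_per_arm=2)
        recs, _ = generate_survival(cfg, seed=43)
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_frailty(recs, fix_rho=0.0)
        assert fit.boundary
        assert fit.p_sigma2 == 1.0 or fit.p_tau2 == 1.0

    def test_too_few_clusters_rejected(self):
        recs = [
            SurvivalRecord(f"M{i%3}", f"m{i}", i % 2, 5.0 + i, True)
            for i in range(12)
        ]
        with pytest.raises(InsufficientDataError):
            fit_frailty(recs)


class TestFrailtyGrowthCorrelation:
    def test_frailty_tracks_growth_rate(self):
        """Models generated with faster vehicle growth have larger baseline
        frailty: u_i and k_c are positively correlated."""
        rng = np.random.default_rng(3)
        n_clusters = 50
        curves, recs = [], []
        for j in range(n_clusters):
            kc = rng.uniform(0.04, 0.16)
            model = f"M{j:03d}"
            for i in range(3):
                curves.append(
                    exp_curve(kc, (0, 3, 6, 9, 12, 15, 18, 21), tv0=150,
                              mouse_id=f"{model}v{i}", model_id=model,
                              arm="vehicle")
                )
            # event times from a hazard whose frailty is driven by kc
            u = (kc - 0.10) * 10.0
            for i in range(3):
                t = 12.0 * (rng.exponential() * math.exp(-u)) ** 0.5
                recs.append(
                    SurvivalRecord(model, f"{model}t{i}", 1, min(t, 60.0),
                                   t <= 60.0)
                )
                tv = 12.0 * (rng.exponential() * math.exp(-u)) ** 0.5
                recs.append(
                    SurvivalRecord(model, f"{model}vv{i}", 0, min(tv, 60.0),
                                   tv <= 60.0)
                )
        ds = make_dataset(curves)
        fit = fit_frailty(recs, fix_rho=0.0)
        rates = vehicle_growth_rates(ds)
        rep = frailty_growth_correlation(fit, rates)
        assert rep["pearson_r"] > 0
        assert rep["r_squared"] > 0.5

        # permuting cluster labels collapses the correlation
        perm = rng.permutation(list(rates))
        shuffled = dict(zip(perm, [rates[c] for c in sorted(rates)]))
        rep_perm = frailty_growth_correlation(fit, shuffled)
        assert rep_perm["r_squared"] < rep["r_squared"] / 2

    def test_needs_three_clusters(self):
        recs = [
            SurvivalRecord(f"M{i}", f"m{i}a", 0, 5.0, True) for i in range(5)
        ] + [SurvivalRecord(f"M{i}", f"m{i}b", 1, 7.0, True) for i in range(5)]
        fit = fit_frailty(recs, fix_rho=0.0)
        with pytest.raises(InsufficientDataError):
            frailty_growth_correlation(fit, {"M0": 0.05, "M1": 0.06})
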