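"""Survival analysis on clustered event times: Cox vs additive frailty.

Event times (volume tripling, the mouse-study stand-in for overall
survival) are simulated with real between-model heterogeneity in both
baseline hazard and drug response.  The naive Cox model ignores the
clustering and attenuates the hazard ratio toward 1; the additive frailty
model recovers the conditional treatment effect and flags both frailty
variances as significantly positive.
"""

import math

from mctkit import SimConfig, fit_cox, fit_frailty, generate_survival

config = SimConfig(
    n_models=80, n_mice_per_arm=3,
    frailty_sigma2=0.5, frailty_tau2=0.2, log_hr=math.log(0.5),
)
records, truth = generate_survival(config, seed=11)
events = sum(r.event for r in records)
print(f"{len(records)} mice, {events} events (tripling before day "
      f"{config.censor_horizon:.0f})")

cox = fit_cox(records)
print(f"\nCox (ignores clustering):   HR = {cox['hazard_ratio']:.3f} "
      f"(95% CI {cox['ci_95'][0]:.3f}-{cox['ci_95'][1]:.3f})")

fit = fit_frailty(records, fix_rho=0.0)
lo, hi = fit.hazard_ratio_ci
print(f"additive frailty:           HR = {fit.hazard_ratio:.3f} "
      f"(95% CI {lo:.3f}-{hi:.3f})")
print(f"  baseline frailty variance sigma^2 = {fit.sigma2:.3f} "
      f"(p = {fit.p_sigma2:.2e})")
print(f"  response frailty variance tau^2   = {fit.tau2:.3f} "
      f"(p = {fit.p_tau2:.2e})")
print(f"  Weibull baseline: shape {fit.weibull_shape:.2f}, "
      f"scale {fit.weibull_scale:.2f} days")
print(
    f"\nGenerator truth: HR = 0.5, sigma^2 = 0.5, tau^2 = 0.2. The Cox HR "
    f"sits closer\nto 1 than the frailty HR — the attenuation that motivates "
    f"frailty modeling."
)
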