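"""Compute the continuous efficacy endpoints for one model's two arms.

PFS (doubling time) is per mouse; RTV ratio and TGI are day-specific group
contrasts; growth-rate and AUC ratios use whole trajectories and do not
depend on the evaluation day — the printout shows TGI drifting with day
while the trajectory-based endpoints stay put.
"""

from dataclasses import replace

from mctkit import (
    SimConfig,
    auc_ratio,
    generate_mct,
    growth_rate_ratio,
    pfs,
    rtv_ratio,
    tgi,
)

# a potent drug (2/3 growth-rate reduction) makes the day-dependence visible
config = replace(SimConfig(n_models=5, n_mice_per_arm=3), beta2=-0.04)
dataset, _ = generate_mct(config, seed=7)
model = dataset.model_ids[0]
treated = dataset.curves_for(model, "treatment")
vehicle = dataset.curves_for(model, "vehicle")

for mouse in treated:
    res = pfs(mouse)
    label = (
        f"doubles at day {res['time']:.1f}"
        if res["event"]
        else f"censored at day {res['censored_at']:.0f}"
    )
    print(f"  {mouse.mouse_id}: {label}")

for day in (7, 14, 21):
    print(
        f"day {day:2d}: RTV ratio = {rtv_ratio(treated, vehicle, day):.3f}, "
        f"TGI = {tgi(treated, vehicle, day):.3f}"
    )
print(f"growth-rate ratio k_t/k_c = {growth_rate_ratio(treated, vehicle):.3f}")
print(f"AUC ratio               = {auc_ratio(treated, vehicle):.3f}")
print(
    "\nTGI drifts with the chosen day; the two trajectory-based ratios are "
    "day-free.\nThey coincide exactly for noise-free exponential growth and "
    "differ here only\nthrough measurement noise and per-mouse heterogeneity."
)
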