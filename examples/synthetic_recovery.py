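"""Closed-loop recovery of regeneration parameters from synthetic CT data.

Generates noiseless volumetry from the dog-2 scenario with a known partial
growth phase (half the organ initially active, joining at 54% of the final
volume), then runs the full analysis pipeline: time-scale calibration and
joining-point detection on the normal-growth curve, followed by the
alternating (A, p) fit.
"""

import dataclasses

import numpy as np

from livergrowth import (calibrate_and_detect, fit_partial_growth,
                         generate_observations, integrate_normal_growth,
                         preset_scenarios)

scenario = dataclasses.replace(
    preset_scenarios()["dog2"], noise_cv=0.0,
    observation_times=np.arange(1.0, 30.001, 1.0))
truth = scenario.partial
obs = generate_observations(scenario)

shape, cfg = scenario.shape, scenario.config
normal = integrate_normal_growth(shape, cfg).scale_volume(shape.volume_scale)
scale, joining = calibrate_and_detect(normal, obs)

print("joining detection (truth: fraction 0.54, 4.0 days per model unit)")
print(f"  joining day        : {joining.time:6.1f}")
print(f"  volume fraction    : {joining.volume_fraction:6.4f}")
print(f"  time scale (d/unit): {scale:6.4f}")

v_j = joining.volume_fraction * shape.final_state().volume
fit = fit_partial_growth(obs, shape, cfg, v_j)
print(f"fit (truth: A=0.5, p=0.83)")
print(f"  A_hat = {fit.A_hat:.4f}   p_hat = {fit.p_hat:.4f}   "
      f"objective = {fit.objective:.2e}")
print(f"  converged after {fit.iterations} rounds")

# The detected joining fraction and the fitted initially-active fraction
# quantify, from volumetry alone, when the transplant resumed normal growth
# and how much of it proliferated from the start.
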