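"""Growth curve of a whole transplanted dog liver (torus model).

Builds the dog-1 geometry (tube radius growing 1 -> 1.291 with d/r = 1.25
fixed, 2/3 of the torus ring, initial volume 374.28 cm^3), integrates the
growth equation, and prints the volume trajectory in model time.
"""

import numpy as np

from livergrowth import GrowthConfig, TorusLiverShape, integrate_normal_growth

shape = TorusLiverShape.with_initial_volume(
    r_b=1.0, r_e=1.291, d_b=1.25, P=2 / 3, initial_volume_cm3=374.28)
curve = integrate_normal_growth(shape, GrowthConfig()).scale_volume(
    shape.volume_scale)

print(f"initial volume : {curve.v_b:8.2f} cm^3")
print(f"maximum volume : {curve.v_max:8.2f} cm^3 "
      f"(relative growth {curve.v_max / curve.v_b:.4f})")
print()
print(" t(model)   V (cm^3)   V/Vmax     G")
for frac in (0.47, 0.54, 0.6, 0.7, 0.8, 0.9, 0.95):
    v = frac * curve.v_max
    t = np.interp(v, curve.volume, curve.time)
    g = np.interp(v, curve.volume, curve.growth_ratio)
    print(f"{t:9.3f} {v:10.2f} {frac:8.2f} {g:8.4f}")

# The growth ratio G is the fraction of nutrient influx left for biomass
# production; it falls to zero as the liver approaches its maximum size,
# which is why the trajectory flattens.  Model time becomes days once the
# curve is scaled to data (see examples/synthetic_recovery.py).
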