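"""Why left-lobe liver remnants regrow faster than right-lobe remnants.

Compares the growth ratio of the two human liver lobes (cut-prism model,
published proportions) at equal relative volumes.  The thin left lobe keeps
a larger relative surface while it regrows, so a larger fraction of the
nutrient influx is available for biomass production.
"""

import numpy as np

from livergrowth import (PrismLiverShape, graft_length_from_fraction,
                         growth_ratio, relative_surface_volume)

shapes = {
    lobe: PrismLiverShape.from_width_units(
        width=1.2, small_base=1.0, large_base=3.5, length=2.9,
        lobe=lobe, F=0.596)
    for lobe in ("left", "right")
}

print(" V/Vwhole    G_left   G_right   ratio")
for F in np.linspace(0.596, 0.86, 10):
    g = {}
    for lobe, shape in shapes.items():
        ell = graft_length_from_fraction(shape, F)
        s, v = relative_surface_volume(shape.state(ell), shape.final_state())
        g[lobe] = growth_ratio(s, v)
    print(f"{F:9.3f} {g['left']:9.4f} {g['right']:9.4f} "
          f"{g['left'] / g['right']:7.2f}")

# G_left > G_right at every matched volume: with the same nutrient supply
# the growing left lobe produces more biomass per unit time, which matches
# the clinical observation that right-lobe donors (left remnants) show the
# fastest regeneration.
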