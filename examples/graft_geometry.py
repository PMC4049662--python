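"""Graft geometry: from a recorded volume fraction to a cut plane.

Transplant records state the graft as a fraction of the donor liver volume.
The cut-prism model inverts that fraction to a boundary-plane position in
closed form, for either lobe.
"""

import math

from livergrowth import PrismLiverShape, graft_length_from_fraction, \
    prism_volume

shape = PrismLiverShape.from_width_units(
    width=1.2, small_base=1.0, large_base=3.5, length=2.9, lobe="left",
    F=0.485)

print(f"whole-liver volume  : {shape.whole_volume:.4f} (model units^3)")
print(f"prism base angle    : {math.degrees(shape.alpha):.2f} degrees")
print()
print(" lobe   fraction   graft length   roundtrip fraction")
for lobe in ("left", "right"):
    s = PrismLiverShape.from_width_units(1.2, 1.0, 3.5, 2.9, lobe=lobe)
    for F in (0.3, 0.485, 0.596, 1.0):
        ell = graft_length_from_fraction(s, F)
        back = prism_volume(s, ell) / s.whole_volume
        print(f" {lobe:5s} {F:9.3f} {ell:13.4f} {back:17.10f}")

# The roundtrip fraction reproduces the requested fraction to 1e-10: the
# quadratic volume formula is inverted exactly, not numerically.
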