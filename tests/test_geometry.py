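"""Geometry: closed-form solids, growth ratio, and their oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from livergrowth.errors import DomainError
from livergrowth.geometry import (PrismLiverShape, TorusLiverShape,
                                  graft_length_from_fraction, growth_ratio,
                                  prism_base_angle, prism_surface,
                                  prism_volume, relative_surface_volume,
                                  torus_surface, torus_volume)

from .conftest import make_prism
from ._oracles import mc_prism_volume, mc_torus_volume, mesh_torus_surface


class TestTorus:
    def test_dog1_relative_volume_matches_table(self):
        """The capped sliced 2/3 torus reproduces the dog-1 published
        volume ratio 2.1509 at the printed dimensions."""
        ratio = torus_volume(1.291, 1.613, 2 / 3) / torus_volume(1, 1.25, 2 / 3)
        assert ratio == pytest.approx(2.1509, abs=1e-3)
        assert round(ratio, 4) == 2.1509

    def test_dog2_geometric_ratio(self):
        """Dog 2's geometric evaluation gives 3.0486; the published table
        prints 3.0453 (= 1049.963/344.778), a known small discrepancy of
        the printed dimensions."""
        ratio = torus_volume(1.45, 1.8125, 2 / 3) / torus_volume(1, 1.25, 2 / 3)
        assert ratio == pytest.approx(3.0486, abs=1e-3)

    @given(s=st.floats(0.1, 10.0))
    def test_dilation_scaling(self, s):
        v1 = torus_volume(1.0, 1.25, 2 / 3)
        s1 = torus_surface(1.0, 1.25, 2 / 3)
        assert torus_volume(s, 1.25 * s, 2 / 3) == pytest.approx(s**3 * v1,
                                                                 rel=1e-12)
        assert torus_surface(s, 1.25 * s, 2 / 3) == pytest.approx(s**2 * s1,
                                                                  rel=1e-12)

    def test_monotonicity_in_radius(self):
        r = np.linspace(1.0, 1.45, 50)
        v = torus_volume(r, 1.25 * r, 2 / 3)
        s = torus_surface(r, 1.25 * r, 2 / 3)
        assert np.all(np.diff(v) > 0)
        assert np.all(np.diff(s) > 0)
        assert torus_surface(1.45, 1.8125, 2 / 3) > torus_surface(1, 1.25, 2 / 3)

    def test_monte_carlo_volume_oracle(self):
        v = mc_torus_volume(1.0, 1.25, 2 / 3, n=4 * 10**6)
        assert v == pytest.approx(torus_volume(1.0, 1.25, 2 / 3), rel=1e-3)

    def test_mesh_surface_oracle(self):
        s = mesh_torus_surface(1.0, 1.25, 2 / 3, n=600)
        assert s == pytest.approx(torus_surface(1.0, 1.25, 2 / 3), rel=5e-3)

    @pytest.mark.parametrize("args", [
        (-1.0, 1.25, 2 / 3), (1.0, 0.9, 2 / 3), (1.0, 1.25, 1.5),
        (1.0, 1.25, 0.0),
    ])
    def test_invalid_dimensions_rejected(self, args):
        with pytest.raises(DomainError):
            torus_volume(*args)
        with pytest.raises(DomainError):
            torus_surface(*args)

    def test_shape_invariants(self):
        with pytest.raises(DomainError):
            TorusLiverShape(r_b=1.0, r_e=0.9, d_b=1.25, P=2 / 3)
        with pytest.raises(DomainError):
            TorusLiverShape(r_b=1.0, r_e=1.3, d_b=0.8, P=2 / 3)
        shape = TorusLiverShape(1.0, 1.291, 1.25, 2 / 3)
        assert shape.kappa == pytest.approx(1.25)


class TestPrism:
    def test_base_angle(self, left_prism):
        a = prism_base_angle(left_prism)
        assert 0 < a < math.pi / 2
        # degenerate limit: cut face vanishes into a rectangular box
        near = PrismLiverShape(W=1.2, B=1.2, B_X=1.2 + 1e-9, L_full=3.48)
        assert prism_base_angle(near) == pytest.approx(math.pi / 2, abs=1e-6)
        doubled = PrismLiverShape(W=2.4, B=2.4, B_X=8.4, L_full=6.96)
        assert prism_base_angle(doubled) == pytest.approx(a, rel=1e-12)
        from types import SimpleNamespace
        with pytest.raises(DomainError):
            prism_base_angle(SimpleNamespace(B=1.0, B_X=1.0, L_full=2.0))

    def test_left_right_agree_at_full_length(self, left_prism):
        right = make_prism("right", 0.596)
        v_left = prism_volume(left_prism, left_prism.L_full)
        v_right = prism_volume(right, right.L_full)
        assert v_left == pytest.approx(v_right, rel=1e-10)
        assert v_left == pytest.approx(left_prism.whole_volume, rel=1e-12)

    @given(s=st.floats(0.2, 5.0))
    def test_dilation_scaling(self, s):
        base = make_prism("left", 0.5)
        scaled = PrismLiverShape(W=base.W * s, B=base.B * s, B_X=base.B_X * s,
                                 L_full=base.L_full * s, lobe="left", F=0.5)
        ell = 0.6 * base.L_full
        assert prism_volume(scaled, s * ell) == pytest.approx(
            s**3 * prism_volume(base, ell), rel=1e-12)
        assert prism_surface(scaled, s * ell) == pytest.approx(
            s**2 * prism_surface(base, ell), rel=1e-12)

    def test_monte_carlo_volume_oracle(self, left_prism):
        v = mc_prism_volume(left_prism, left_prism.L_full, n=4 * 10**6)
        assert v == pytest.approx(left_prism.whole_volume, rel=1e-3)

    def test_surface_matches_face_decomposition(self, left_prism):
        """Independent face-by-face area computation from vertex geometry
        (two trapezoid sides, bottom, slant, boundary face)."""
        ell = 2.0
        c = left_prism.cot_alpha
        h = left_prism.B + c * ell
        trap = ell * (left_prism.B + h) / 2.0
        slant = left_prism.W * math.hypot(ell, c * ell)
        expect = 2 * trap + left_prism.W * ell + slant + left_prism.W * h
        assert prism_surface(left_prism, ell) == pytest.approx(expect,
                                                               rel=1e-12)

    @given(F=st.floats(0.05, 1.0))
    def test_graft_length_roundtrip(self, F):
        for lobe in ("left", "right"):
            shape = make_prism(lobe, 0.5)
            ell = graft_length_from_fraction(shape, F)
            frac = prism_volume(shape, ell) / shape.whole_volume
            assert frac == pytest.approx(F, rel=1e-10, abs=1e-12)

    def test_graft_length_limits(self, left_prism):
        assert graft_length_from_fraction(left_prism, 1.0) == pytest.approx(
            left_prism.L_full, rel=1e-12)
        assert graft_length_from_fraction(left_prism, 1e-9) < 1e-3
        with pytest.raises(DomainError):
            graft_length_from_fraction(left_prism, 1.2)

    def test_male_remnant_fraction(self):
        shape = make_prism("left", 0.485)
        ell = shape.initial_length
        assert prism_volume(shape, ell) / shape.whole_volume == pytest.approx(
            0.485, rel=1e-10)

    def test_volume_monotone_in_length(self, left_prism):
        for lobe in ("left", "right"):
            shape = make_prism(lobe, 0.5)
            ell = np.linspace(0.1, shape.L_full, 80)
            assert np.all(np.diff(prism_volume(shape, ell)) > 0)


class TestGrowthRatio:
    def test_relative_pair_definition(self, dog1_shape):
        final = dog1_shape.final_state()
        s, v = relative_surface_volume(final, final)
        assert (s, v) == (pytest.approx(1.0), pytest.approx(1.0))
        s0, v0 = relative_surface_volume(dog1_shape.initial_state(), final)
        assert v0 == pytest.approx(1 / 2.1509, abs=1e-3)
        with pytest.raises(DomainError):
            relative_surface_volume(final, dog1_shape.initial_state())

    def test_unit_scale_invariance(self):
        a = TorusLiverShape(1.0, 1.291, 1.25, 2 / 3, unit_scale=1.0)
        b = TorusLiverShape(1.0, 1.291, 1.25, 2 / 3, unit_scale=3.31)
        for r in (1.0, 1.1, 1.25):
            sa = relative_surface_volume(a.state(r), a.final_state())
            sb = relative_surface_volume(b.state(r), b.final_state())
            assert sa == pytest.approx(sb, rel=1e-12)

    def test_scale_free(self):
        assert growth_ratio(0.8, 0.6) == pytest.approx(0.8 / 0.6 - 1.0)
        with pytest.raises(DomainError):
            growth_ratio(1.2, 0.5)
        with pytest.raises(DomainError):
            growth_ratio(0.5, 0.0)

    def test_vanishes_at_maximum_size(self, dog1_shape):
        """No nutrients remain for biomass production at the fully grown
        size: G(1, 1) = 0 and G decreases monotonically along growth."""
        final = dog1_shape.final_state()
        rs = np.linspace(dog1_shape.r_b, dog1_shape.r_e, 30)
        gs = [growth_ratio(*relative_surface_volume(dog1_shape.state(r), final))
              for r in rs]
        assert gs[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(gs) < 0)

    def test_left_lobe_ratio_exceeds_right_at_equal_relative_volume(self):
        """The thin left lobe keeps a larger relative surface while it
        regrows than the thick right lobe does, so its growth ratio is
        higher at every shared relative volume."""
        left = make_prism("left", 0.596)
        right = make_prism("right", 0.596)
        for F in np.linspace(0.596, 0.87, 40):
            g = {}
            for shape in (left, right):
                ell = graft_length_from_fraction(shape, F)
                s, v = relative_surface_volume(shape.state(ell),
                                               shape.final_state())
                g[shape.lobe] = growth_ratio(s, v)
            assert g["left"] > g["right"]
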