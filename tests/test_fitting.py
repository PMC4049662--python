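"""Calibration, joining detection and the alternating (A, p) fit."""

import dataclasses

import numpy as np
import pytest

from livergrowth.errors import DomainError
from livergrowth.fitting import (Observations, calibrate_and_detect,
                                 calibrate_time_scale, detect_joining_point,
                                 fit_partial_growth, objective,
                                 partial_growth_objective)
from livergrowth.growth import GrowthConfig, integrate_normal_growth, \
    time_rescale
from livergrowth.synthetic import generate_observations

from .conftest import noiseless


@pytest.fixture(scope="module")
def dog2_normal(presets):
    sc = presets["dog2"]
    curve = integrate_normal_growth(sc.shape, sc.config)
    return time_rescale(curve.scale_volume(sc.shape.volume_scale),
                        sc.time_scale_truth)


@pytest.fixture(scope="module")
def dog2_obs(presets):
    return generate_observations(noiseless(presets["dog2"]))


class TestObjective:
    def test_zero_on_interpolating_data(self, dog2_normal):
        sc_times = np.linspace(3.0, 60.0, 9)
        vols = np.interp(sc_times, dog2_normal.time, dog2_normal.volume)
        obs = Observations(sc_times, vols)
        assert objective(dog2_normal, obs) == pytest.approx(0.0, abs=1e-14)

    def test_uniform_inflation(self, dog2_normal):
        """A constant 10% inflation of all observations gives exactly 0.10
        (deviations are measured relative to the model volume)."""
        t = np.linspace(3.0, 60.0, 9)
        vols = 1.1 * np.interp(t, dog2_normal.time, dog2_normal.volume)
        obs = Observations(t, vols)
        assert objective(dog2_normal, obs) == pytest.approx(0.10, abs=1e-12)

    def test_reorder_invariance(self, dog2_normal):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(3.0, 60.0, 12))
        v = np.interp(t, dog2_normal.time, dog2_normal.volume) \
            * rng.uniform(0.9, 1.1, 12)
        a = objective(dog2_normal, Observations(t, v))
        # reversed record order (times must stay sorted, so rebuild sorted
        # from a shuffled pairing — the mean is symmetric in the records)
        idx = rng.permutation(12)
        t2, v2 = t[idx], v[idx]
        order = np.argsort(t2, kind="stable")
        b = objective(dog2_normal, Observations(t2[order], v2[order]))
        assert a == pytest.approx(b, rel=1e-12)


class TestCalibration:
    def test_self_calibration(self, dog2_normal):
        t = np.linspace(3.0, 60.0, 12)
        obs = Observations(t, np.interp(t, dog2_normal.time,
                                        dog2_normal.volume))
        assert calibrate_time_scale(dog2_normal, obs) == pytest.approx(
            1.0, abs=1e-4)

    def test_doubled_times(self, dog2_normal):
        t = np.linspace(3.0, 60.0, 12)
        v = np.interp(t, dog2_normal.time, dog2_normal.volume)
        obs = Observations(2.0 * t, v)
        assert calibrate_time_scale(dog2_normal, obs) == pytest.approx(
            2.0, rel=1e-4)

    def test_noisy_recovery_across_seeds(self, presets):
        """With 5% noise the recovered factor is unbiased: its mean over 20
        seeds stays within 2% of the truth."""
        sc = presets["dog2"]
        curve = integrate_normal_growth(sc.shape, sc.config)
        curve = curve.scale_volume(sc.shape.volume_scale)
        normal_sc = dataclasses.replace(sc, partial=None)
        factors = []
        for seed in range(20):
            obs = generate_observations(normal_sc.with_seed(seed))
            factors.append(calibrate_time_scale(curve, obs))
        assert np.mean(factors) == pytest.approx(sc.time_scale_truth,
                                                 rel=0.02)

    def test_flat_observations_warn(self, dog2_normal):
        obs = Observations(np.array([5.0, 10.0, 20.0]),
                           np.array([700.0, 700.0, 700.0]))
        with pytest.warns(UserWarning):
            assert calibrate_time_scale(dog2_normal, obs) == 1.0


class TestDetectJoining:
    def test_agreeing_data_joins_at_first_observation(self, dog2_normal):
        t = np.linspace(3.0, 60.0, 10)
        obs = Observations(t, np.interp(t, dog2_normal.time,
                                        dog2_normal.volume))
        res = detect_joining_point(dog2_normal, obs, tol=0.05)
        assert res.found and res.index == 0 and res.time == t[0]

    def test_infinite_tolerance_vacuous(self, dog2_normal, dog2_obs):
        res = detect_joining_point(dog2_normal, dog2_obs, tol=np.inf)
        assert res.found and res.index == 0

    def test_monotone_in_tolerance(self, dog2_normal, presets):
        obs = generate_observations(presets["dog2"].with_seed(5))
        prev_index = None
        for tol in (0.02, 0.05, 0.1, 0.3, 1.0):
            res = detect_joining_point(dog2_normal, obs, tol=tol)
            if prev_index is not None and res.found:
                assert res.index <= prev_index
            if res.found:
                prev_index = res.index

    def test_no_joining_flagged(self, dog2_normal, dog2_obs):
        res = detect_joining_point(dog2_normal, dog2_obs, tol=1e-9)
        assert not res.found

    def test_closed_loop_recovery_noiseless(self, presets):
        """Partial-growth data (A = 0.5, p = 0.83, joining at 54% of final
        volume) localize the joining fraction within 3% and the time scale
        to 4 digits on noiseless dog-2-like data."""
        sc = noiseless(presets["dog2"], times=np.arange(1.0, 30.001, 1.0))
        obs = generate_observations(sc)
        normal = integrate_normal_growth(sc.shape, sc.config)
        normal = normal.scale_volume(sc.shape.volume_scale)
        factor, res = calibrate_and_detect(normal, obs)
        assert res.found
        assert res.volume_fraction == pytest.approx(0.54, rel=0.03)
        assert factor == pytest.approx(sc.time_scale_truth, rel=1e-3)


class TestFit:
    def test_noiseless_parameter_recovery(self, presets):
        """From dense noiseless dog-1-like data the alternating fit recovers
        the generating (A, p) within optimizer tolerance."""
        sc = noiseless(presets["dog1"], times=np.arange(0.5, 30.001, 0.5))
        obs = generate_observations(sc)
        v_j = sc.partial.V_j
        res = fit_partial_growth(obs, sc.shape, sc.config, v_j)
        assert res.converged
        assert abs(res.A_hat - 0.5) < 0.01
        assert abs(res.p_hat - 0.85) < 0.05
        assert res.time_scale == pytest.approx(5.0, rel=1e-3)
        assert res.joining_volume_fraction == pytest.approx(0.54, rel=1e-9)

    def test_sensitivity_asymmetry(self, presets):
        """The initially active fraction dominates the fit: a 5% change of
        A moves the objective several-fold more than a 5% change of p."""
        sc = noiseless(presets["dog2"], times=np.arange(1.0, 30.001, 1.0))
        obs = generate_observations(sc)
        v_j = sc.partial.V_j
        o0, _, _ = partial_growth_objective(obs, sc.shape, sc.config, v_j,
                                            0.5, 0.83)
        oA, _, _ = partial_growth_objective(obs, sc.shape, sc.config, v_j,
                                            0.5 * 1.05, 0.83)
        op, _, _ = partial_growth_objective(obs, sc.shape, sc.config, v_j,
                                            0.5, 0.83 * 1.05)
        assert o0 < 1e-10
        assert (oA - o0) > 3.0 * (op - o0) > 0

    def test_p_underdetermined_with_sparse_prefix(self, presets):
        """With the every-2-days schedule only two observations precede the
        dog-1 joining point, so p is flagged underdetermined while A is
        still fitted."""
        sc = noiseless(presets["dog1"])
        obs = generate_observations(sc)
        res = fit_partial_growth(obs, sc.shape, sc.config, sc.partial.V_j)
        assert res.p_underdetermined
        assert 0.05 <= res.A_hat <= 1.0

    def test_too_few_observations_rejected(self, presets):
        sc = presets["dog1"]
        obs = Observations(np.array([2.0, 4.0]), np.array([400.0, 420.0]))
        with pytest.raises(DomainError):
            fit_partial_growth(obs, sc.shape, sc.config, sc.partial.V_j)
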