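"""Circular-statistics tests against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depthgait.circstats import (MULTIMODAL, UNIFORM, UNIMODAL, CircSample,
                                 CircTestResult, bonferroni,
                                 circular_dispersion, circular_mean_variance,
                                 classify_distribution, dispersion_compare,
                                 hermans_rasson_statistic,
                                 hermans_rasson_test, rayleigh_test,
                                 vonmises_check, watson_williams)


def hr_oracle(deg):
    """Literal double-loop transcription of the corrected HR statistic."""
    r = np.radians(deg)
    n = len(r)
    total = 0.0
    for i in range(n):
        for j in range(n):
            d = r[i] - r[j]
            total += abs(abs(d) - np.pi) - np.pi / 2
            total -= 2.895 * (abs(np.sin(d)) - 2 / np.pi)
    return total / n


class TestHermansRasson:
    def test_statistic_matches_double_loop_oracle(self, rng):
        for n in (5, 12, 25):
            x = rng.uniform(0, 360, n)
            assert hermans_rasson_statistic(x) == pytest.approx(
                hr_oracle(x), abs=1e-9)

    def test_statistic_rotation_invariant(self, rng):
        x = rng.uniform(0, 360, 15)
        for shift in (10.0, 123.4, 301.0):
            assert hermans_rasson_statistic((x + shift) % 360) == \
                pytest.approx(hermans_rasson_statistic(x), abs=1e-9)

    def test_identical_angles_are_nonuniform(self):
        _, p = hermans_rasson_test(np.full(20, 77.0), n_mc=999, seed=0)
        assert p <= 0.05

    def test_uniform_grid_is_uniform(self):
        grid = np.arange(20) * 18.0
        _, p = hermans_rasson_test(grid, n_mc=999, seed=0)
        assert p > 0.05

    def test_antipodal_bimodal_detected(self):
        x = np.concatenate([np.zeros(20), np.full(20, 180.0)])
        _, p = hermans_rasson_test(x, n_mc=999, seed=0)
        assert p <= 0.05

    def test_deterministic_under_seed(self, rng):
        x = rng.uniform(0, 360, 12)
        a = hermans_rasson_test(x, n_mc=999, seed=42)
        b = hermans_rasson_test(x, n_mc=999, seed=42)
        assert a == b

    def test_preconditions(self):
        with pytest.raises(ValueError):
            hermans_rasson_test(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            hermans_rasson_test(np.arange(10.0), n_mc=10)


class TestRayleigh:
    def test_identical_angles(self):
        rbar, p = rayleigh_test(np.full(20, 45.0))
        assert rbar == pytest.approx(1.0)
        assert p < 1e-6

    def test_balanced_antipodal_cancels(self):
        rbar, p = rayleigh_test(np.array([0.0, 180.0] * 10))
        assert rbar == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_rbar_matches_complex_sum_oracle(self, rng):
        for _ in range(5):
            x = rng.uniform(0, 360, 50)
            rbar, _ = rayleigh_test(x)
            oracle = np.abs(np.exp(1j * np.radians(x)).mean())
            assert rbar == pytest.approx(oracle, abs=1e-12)

    def test_p_close_to_reference_implementation(self, rng):
        pg = pytest.importorskip("pingouin")
        for kappa in (0.5, 2.0):
            x = rng.vonmises(0.0, kappa, 40)
            _, p = rayleigh_test(np.degrees(x) % 360)
            _, p_ref = pg.circ_rayleigh(x)
            assert p == pytest.approx(p_ref, abs=0.01)

    def test_needs_three(self):
        with pytest.raises(ValueError):
            rayleigh_test(np.array([0.0, 90.0]))


class TestVonMisesCheck:
    def test_von_mises_sample_accepted_in_most_replicates(self, rng):
        accepted = 0
        for _ in range(20):
            x = np.degrees(rng.vonmises(1.0, 3.0, 100)) % 360
            ok, _ = vonmises_check(x, n_boot=100, seed=rng)
            accepted += ok
        assert accepted >= 18

    def test_antipodal_mixture_rejected_in_most_replicates(self, rng):
        rejected = 0
        for _ in range(20):
            x = np.degrees(np.concatenate([rng.vonmises(0, 10, 50),
                                           rng.vonmises(np.pi, 10, 50)])) % 360
            ok, _ = vonmises_check(x, n_boot=100, seed=rng)
            rejected += not ok
        assert rejected >= 18

    def test_small_sample_raises(self):
        with pytest.raises(ValueError):
            vonmises_check(np.array([0.0, 10.0, 20.0, 30.0]))


class TestClassify:
    def test_tight_cluster_is_unimodal_with_mean(self):
        x = np.degrees(
            np.random.default_rng(7).vonmises(np.pi, 10.0, 30)) % 360
        res = classify_distribution(x, n_mc=999, n_boot=100, seed=1)
        assert res.classification == UNIMODAL
        assert res.circular_mean_deg == pytest.approx(180.0, abs=15.0)
        assert 0 <= res.angular_variance <= 1

    def test_antipodal_mixture_is_multimodal_without_mean(self, rng):
        x = np.degrees(np.concatenate([rng.vonmises(0, 20, 25),
                                       rng.vonmises(np.pi, 20, 25)])) % 360
        res = classify_distribution(x, n_mc=999, n_boot=100, seed=1)
        assert res.classification == MULTIMODAL
        assert res.circular_mean_deg is None
        assert res.angular_variance is None

    def test_uniform_sample_classified_uniform(self):
        x = np.random.default_rng(21).uniform(0, 360, 100)
        res = classify_distribution(x, n_mc=999, seed=1)
        assert res.classification == UNIFORM
        assert res.circular_mean_deg is None

    def test_result_invariant_enforced(self):
        with pytest.raises(ValueError):
            CircTestResult(n=10, classification=UNIFORM,
                           circular_mean_deg=10.0)

    def test_skip_hr_screening_path(self, rng):
        x = np.degrees(rng.vonmises(0.0, 20.0, 10)) % 360
        res = classify_distribution(x, n_boot=100, seed=2, skip_hr=True)
        assert res.hr_p is None
        assert res.classification == UNIMODAL

    def test_needs_five(self):
        with pytest.raises(ValueError):
            classify_distribution(np.array([0.0, 1.0, 2.0, 3.0]))


class TestMeanVariance:
    def test_degenerate_point_mass(self):
        mean, var = circular_mean_variance([90.0, 90.0, 90.0])
        assert mean == pytest.approx(90.0)
        assert var == pytest.approx(0.0, abs=1e-12)

    def test_wraparound_pair(self):
        mean, var = circular_mean_variance([350.0, 10.0])
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert var == pytest.approx(1 - np.cos(np.radians(10.0)))

    def test_antipodal_pair_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            circular_mean_variance([0.0, 180.0])

    @given(st.lists(st.floats(0, 359.99), min_size=3, max_size=30),
           st.floats(1.0, 359.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rotation_equivariance(self, angles, shift):
        x = np.asarray(angles)
        try:
            m0, v0 = circular_mean_variance(x)
        except ValueError:
            return  # zero resultant
        m1, v1 = circular_mean_variance((x + shift) % 360)
        assert v1 == pytest.approx(v0, abs=1e-9)
        assert (m1 - m0 - shift) % 360 == pytest.approx(0.0, abs=1e-6) or \
            (m1 - m0 - shift) % 360 == pytest.approx(360.0, abs=1e-6)


class TestWatsonWilliams:
    def test_duplicated_group_gives_near_zero_F(self, rng):
        g = np.degrees(rng.vonmises(1.0, 4.0, 30)) % 360
        F, p = watson_williams([g, g.copy()])
        assert F == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    def test_separated_means_detected(self, rng):
        a = np.degrees(rng.vonmises(0.0, 4.0, 30)) % 360
        b = np.degrees(rng.vonmises(np.pi / 2, 4.0, 30)) % 360
        F, p = watson_williams([a, b])
        assert p < 0.05

    def test_type_i_error_near_nominal(self, rng):
        rej = 0
        reps = 400
        for _ in range(reps):
            a = np.degrees(rng.vonmises(0.0, 4.0, 20)) % 360
            b = np.degrees(rng.vonmises(0.0, 4.0, 20)) % 360
            _, p = watson_williams([a, b])
            rej += p < 0.05
        # 95% binomial interval around 0.05 at 400 reps
        assert 0.028 <= rej / reps <= 0.078

    def test_undefined_mean_raises(self):
        with pytest.raises(ValueError):
            watson_williams([[0.0, 180.0] * 5, [0.0] * 10])


class TestDispersion:
    def test_single_observation_at_mean_has_zero_dispersion(self):
        assert circular_dispersion([42.0])[0] == pytest.approx(0.0)

    def test_dispersion_bounded_by_180(self, rng):
        x = rng.uniform(0, 360, 50)
        d = circular_dispersion(x)
        assert np.all((d >= 0) & (d <= 180))

    def test_different_concentrations_detected(self, rng):
        a = np.degrees(rng.vonmises(0.0, 1.0, 40)) % 360
        b = np.degrees(rng.vonmises(0.0, 20.0, 40)) % 360
        H, p, table = dispersion_compare([a, b])
        assert p < 0.05
        assert set(table.columns) >= {"group_i", "group_j", "p_raw", "p_adj"}


class TestBonferroni:
    def test_scales_and_caps(self):
        assert bonferroni([0.01], 5) == [0.05]
        assert bonferroni([0.5], 3) == [1.0]
        assert bonferroni([0.2], 1) == [0.2]

    def test_rejects_bad_pvalues(self):
        with pytest.raises(ValueError):
            bonferroni([1.5], 2)
        with pytest.raises(ValueError):
            bonferroni([0.5], 0)


def test_circsample_wraps_and_validates():
    s = CircSample(angles_deg=np.array([370.0, -10.0]))
    assert np.allclose(s.angles_deg, [10.0, 350.0])
    with pytest.raises(ValueError):
        CircSample(angles_deg=np.array([np.nan]))
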