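"""Univariate K / L statistics, envelopes, standardization and L_max."""

import numpy as np
import pytest

from nanospat import (
    InsufficientPointsError,
    PointPattern,
    RadialCurve,
    StudyRegion,
    ValidationError,
    csr_envelope,
    gen_csr,
    k_univariate,
    l_transform,
    lmax,
    standardize,
)
from nanospat.edge import EdgeCorrectionRangeWarning

from oracles import k_univariate_oracle


class TestKUnivariate:
    def test_two_point_pattern_step_function(self):
        # two interior points at distance 50: K jumps from 0 to A * n^-2 * 2
        region = StudyRegion(10000.0, 10000.0)
        p = PointPattern([[5000.0, 5000.0], [5050.0, 5000.0]], region)
        radii = np.array([10.0, 49.0, 50.0, 60.0])
        k = k_univariate(p, radii)
        expected = region.area / 4.0 * 2.0
        np.testing.assert_allclose(k.values, [0.0, 0.0, expected, expected])

    def test_matches_bruteforce_oracle_small_patterns(self, region, short_radii):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(3, 11)
            pts = rng.uniform(0, 1000, size=(n, 2))
            ours = k_univariate(PointPattern(pts, region), short_radii).values
            oracle = k_univariate_oracle(pts, 1000.0, 1000.0, short_radii)
            np.testing.assert_allclose(ours, oracle, rtol=1e-9, atol=1e-9)

    def test_unbiased_normalization_option(self, region, short_radii):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1000, size=(6, 2))
        p = PointPattern(pts, region)
        biased = k_univariate(p, short_radii).values
        unbiased = k_univariate(p, short_radii, unbiased=True).values
        np.testing.assert_allclose(unbiased, biased * 36 / 30, rtol=1e-12)

    def test_monotone_nondecreasing(self, region):
        p = gen_csr(80, region, seed=5)
        k = k_univariate(p)
        assert np.all(np.diff(k.values) >= 0)

    def test_insufficient_points(self, region):
        with pytest.raises(InsufficientPointsError):
            k_univariate(PointPattern([[1.0, 1.0]], region))

    def test_warns_beyond_validity_range(self):
        region = StudyRegion(400.0, 400.0)
        p = gen_csr(30, region, seed=1)
        with pytest.warns(EdgeCorrectionRangeWarning):
            k_univariate(p, np.arange(1.0, 201.0))

    def test_scale_invariance(self, short_radii):
        # scaling coordinates and window by s scales K by s^2 on the scaled grid
        rng = np.random.default_rng(21)
        pts = rng.uniform(0, 1000, size=(40, 2))
        s = 2.5
        k1 = k_univariate(PointPattern(pts, StudyRegion(1000, 1000)), short_radii).values
        k2 = k_univariate(
            PointPattern(pts * s, StudyRegion(1000 * s, 1000 * s)), short_radii * s
        ).values
        np.testing.assert_allclose(k2, k1 * s**2, rtol=1e-10)

    def test_translation_invariance_in_interior(self, short_radii):
        # a compact pattern far from every edge has all weights 1, so K is
        # unchanged by translation
        region = StudyRegion(10000.0, 10000.0)
        rng = np.random.default_rng(8)
        pts = 4000.0 + rng.uniform(0, 500, size=(25, 2))
        k1 = k_univariate(PointPattern(pts, region), short_radii).values
        k2 = k_univariate(PointPattern(pts + 800.0, region), short_radii).values
        np.testing.assert_allclose(k1, k2, rtol=1e-12)

    def test_mean_over_csr_matches_poisson_closed_form(self, region):
        # E[K(r)] ~ pi r^2 under CSR (up to the (n-1)/n factor of the n^-2
        # normalization); checked within Monte Carlo error of the mean
        radii = np.arange(5.0, 125.0, 5.0)
        n, n_sim = 100, 150
        sims = np.vstack(
            [k_univariate(gen_csr(n, region, seed=1000 + s), radii).values for s in range(n_sim)]
        )
        target = np.pi * radii**2 * (n - 1) / n
        se = sims.std(axis=0, ddof=1) / np.sqrt(n_sim)
        assert np.all(np.abs(sims.mean(axis=0) - target) < 4.0 * se + 1e-9)


class TestLTransform:
    def test_csr_closed_form_maps_to_zero(self):
        radii = np.arange(1.0, 241.0)
        k = RadialCurve(radii, np.pi * radii**2, "K")
        np.testing.assert_allclose(l_transform(k).values, 0.0, atol=1e-10)

    def test_zero_k_maps_to_minus_r(self):
        radii = np.arange(1.0, 11.0)
        k = RadialCurve(radii, np.zeros_like(radii), "K")
        np.testing.assert_allclose(l_transform(k).values, -radii)

    def test_arithmetic_identity_at_unit_radius(self):
        k = RadialCurve([1.0], [4.0 * np.pi], "K")
        assert l_transform(k).values[0] == pytest.approx(1.0)

    def test_negative_k_rejected(self):
        k = RadialCurve([1.0, 2.0], [1.0, 1.0], "K")
        k.values[1] = -1.0
        with pytest.raises(ValidationError):
            l_transform(k)


class TestEnvelope:
    def test_seeded_determinism(self, region, short_radii):
        e1 = csr_envelope(50, region, short_radii, n_sim=40, seed=123)
        e2 = csr_envelope(50, region, short_radii, n_sim=40, seed=123)
        np.testing.assert_array_equal(e1.bound, e2.bound)

    def test_bound_strictly_positive_after_clamp(self, region, short_radii):
        env = csr_envelope(5, region, short_radii, n_sim=10, seed=1, floor=1e-6)
        assert np.all(env.bound >= 1e-6)
        # clamped radii are flagged
        assert env.clamped.dtype == bool and env.clamped.shape == short_radii.shape

    def test_higher_level_gives_higher_bound(self, region, short_radii):
        e90 = csr_envelope(60, region, short_radii, level=0.90, n_sim=200, seed=9)
        e99 = csr_envelope(60, region, short_radii, level=0.99, n_sim=200, seed=9)
        assert np.all(e99.bound >= e90.bound)

    def test_pointwise_exceedance_rate_near_nominal(self, region):
        # calibration at one radius: fresh CSR sheets exceed the 99% bound
        # about 1% of the time
        radii = np.array([50.0])
        n = 120
        env = csr_envelope(n, region, radii, level=0.99, n_sim=500, seed=42)
        fresh = np.array(
            [
                l_transform(k_univariate(gen_csr(n, region, seed=90000 + s), radii)).values[0]
                for s in range(400)
            ]
        )
        rate = float(np.mean(fresh > env.bound[0]))
        assert rate < 0.04  # 1% nominal; generous binomial slack at 400 draws


class TestStandardizeAndLmax:
    def test_envelope_standardizes_to_one(self, region, short_radii):
        env = csr_envelope(80, region, short_radii, n_sim=50, seed=2)
        std = standardize(env.as_curve(), env)
        assert np.all(std.values[~env.clamped] == 1.0)

    def test_zero_curve_standardizes_to_zero(self, region, short_radii):
        env = csr_envelope(80, region, short_radii, n_sim=50, seed=2)
        zero = RadialCurve(short_radii, np.zeros_like(short_radii), "L_minus_r")
        np.testing.assert_array_equal(standardize(zero, env).values, 0.0)

    def test_linearity(self, region, short_radii):
        env = csr_envelope(80, region, short_radii, n_sim=50, seed=2)
        double = RadialCurve(short_radii, 2.0 * env.bound, "L_minus_r")
        np.testing.assert_allclose(standardize(double, env).values, 2.0)

    def test_grid_mismatch_rejected(self, region, short_radii):
        env = csr_envelope(80, region, short_radii, n_sim=20, seed=2)
        other = RadialCurve(short_radii + 1.0, np.ones_like(short_radii), "L_minus_r")
        with pytest.raises(ValidationError):
            standardize(other, env)

    def test_lmax_constant_curve_ties_to_smallest_radius(self, short_radii):
        std = RadialCurve(short_radii, np.ones_like(short_radii), "standardized")
        peak = lmax(std)
        assert peak.value == 1.0 and peak.radius == short_radii[0]

    def test_lmax_single_peak(self, short_radii):
        values = np.zeros_like(short_radii)
        values[short_radii == 30.0] = 2.5
        peak = lmax(RadialCurve(short_radii, values, "standardized"))
        assert peak.value == 2.5 and peak.radius == 30.0
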