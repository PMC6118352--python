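"""Bivariate cross-K statistics, toroidal-shift envelopes and the LBI."""

import numpy as np
import pytest

from nanospat import (
    BivariatePattern,
    BivariateSpec,
    ClusterProcessSpec,
    InsufficientPointsError,
    PointPattern,
    RadialCurve,
    StudyRegion,
    ValidationError,
    bivariate_envelope,
    gen_bivariate,
    k_bivariate,
    l_biv_transform,
    lbi,
    standardize,
)

from oracles import k_bivariate_oracle


def _bp(big_pts, small_pts, region):
    return BivariatePattern(
        PointPattern(big_pts, region), PointPattern(small_pts, region)
    )


class TestKBivariate:
    def test_single_pair_step_function(self):
        # one big and one small point at distance 30 in a huge window:
        # K_bs = K_sb = K_biv = 0 below 30 and = A at/above 30 (w = 1)
        region = StudyRegion(10000.0, 10000.0)
        bp = _bp([[5000.0, 5000.0]], [[5030.0, 5000.0]], region)
        radii = np.array([10.0, 29.0, 30.0, 40.0])
        curves = k_bivariate(bp, radii)
        step = [0.0, 0.0, region.area, region.area]
        for c in (curves.k_bs, curves.k_sb, curves.k_biv):
            np.testing.assert_allclose(c.values, step)

    def test_matches_bruteforce_oracle_small_patterns(self, region, short_radii):
        rng = np.random.default_rng(17)
        for _ in range(15):
            n_b, n_s = rng.integers(1, 6, size=2)
            big = rng.uniform(0, 1000, size=(n_b, 2))
            small = rng.uniform(0, 1000, size=(n_s, 2))
            curves = k_bivariate(_bp(big, small, region), short_radii)
            o_bs, o_sb, o_biv = k_bivariate_oracle(big, small, 1000.0, 1000.0, short_radii)
            np.testing.assert_allclose(curves.k_bs.values, o_bs, rtol=1e-9, atol=1e-9)
            np.testing.assert_allclose(curves.k_sb.values, o_sb, rtol=1e-9, atol=1e-9)
            np.testing.assert_allclose(curves.k_biv.values, o_biv, rtol=1e-9, atol=1e-9)

    def test_channel_swap_leaves_k_biv_unchanged(self, region, short_radii):
        rng = np.random.default_rng(23)
        big = rng.uniform(0, 1000, size=(12, 2))
        small = rng.uniform(0, 1000, size=(7, 2))
        fwd = k_bivariate(_bp(big, small, region), short_radii)
        rev = k_bivariate(_bp(small, big, region), short_radii)
        np.testing.assert_allclose(fwd.k_biv.values, rev.k_biv.values, rtol=1e-12)
        # the directed components swap roles
        np.testing.assert_allclose(fwd.k_bs.values, rev.k_sb.values, rtol=1e-12)

    def test_empty_channel_rejected(self, region):
        with pytest.raises(InsufficientPointsError):
            k_bivariate(_bp([[1.0, 1.0]], np.empty((0, 2)), region))


class TestLBivTransform:
    def test_independence_closed_form_maps_to_zero(self):
        radii = np.arange(1.0, 241.0)
        k = RadialCurve(radii, np.pi * radii**2, "K")
        np.testing.assert_allclose(l_biv_transform(k).values, 0.0, atol=1e-10)

    def test_zero_maps_to_minus_r(self):
        radii = np.arange(1.0, 11.0)
        np.testing.assert_allclose(
            l_biv_transform(RadialCurve(radii, np.zeros_like(radii), "K")).values, -radii
        )

    def test_four_pi_r_squared_maps_to_r(self):
        radii = np.arange(1.0, 11.0)
        k = RadialCurve(radii, 4.0 * np.pi * radii**2, "K")
        np.testing.assert_allclose(l_biv_transform(k).values, radii, rtol=1e-12)


class TestBivariateEnvelope:
    def test_seeded_determinism(self, region, short_radii):
        bt = gen_bivariate(BivariateSpec(), region, seed=5)
        e1 = bivariate_envelope(bt.pattern, short_radii, n_sim=30, seed=77)
        e2 = bivariate_envelope(bt.pattern, short_radii, n_sim=30, seed=77)
        np.testing.assert_array_equal(e1.bound, e2.bound)

    def test_shift_channel_validation(self, region, short_radii):
        bt = gen_bivariate(BivariateSpec(), region, seed=5)
        with pytest.raises(ValidationError):
            bivariate_envelope(bt.pattern, short_radii, n_sim=5, shift_channel="medium")

    def test_independent_channels_fluctuate_about_zero(self, region):
        # standardized curves of independent channels should mostly sit below 1
        radii = np.arange(5.0, 121.0, 5.0)
        below = 0
        for s in range(6):
            bt = gen_bivariate(
                BivariateSpec(shared_fraction=0.0), region, seed=500 + s
            )
            curves = k_bivariate(bt.pattern, radii)
            env = bivariate_envelope(bt.pattern, radii, n_sim=200, seed=900 + s)
            std = standardize(l_biv_transform(curves.k_biv), env)
            below += int(np.max(std.values) < 1.0)
        assert below >= 4  # 95% pointwise bound; most sheets stay below


class TestLBI:
    def _std(self, values, radii=None):
        radii = np.arange(1.0, 241.0) if radii is None else radii
        return RadialCurve(radii, np.full_like(radii, values), "standardized")

    def test_unit_curve_integrates_to_interval_length(self):
        assert lbi(self._std(1.0)).lbi == pytest.approx(100.0)

    def test_zero_curve_integrates_to_zero(self):
        assert lbi(self._std(0.0)).lbi == 0.0

    def test_linearity(self):
        assert lbi(self._std(2.0)).lbi == pytest.approx(200.0)

    def test_threshold_flag(self):
        assert not lbi(self._std(1.0)).co_localized
        assert lbi(self._std(1.1)).co_localized

    def test_bounds_outside_grid_rejected(self):
        with pytest.raises(ValidationError):
            lbi(self._std(1.0, np.arange(20.0, 241.0)), bounds=(10.0, 110.0))

    def test_custom_bounds(self):
        assert lbi(self._std(1.0), bounds=(20.0, 60.0)).lbi == pytest.approx(40.0)


class TestCoClusteringDetection:
    def test_shared_parents_yield_high_lbi_monotone_in_strength(self, region):
        # LBI should grow with the shared-parent fraction
        radii = np.arange(2.0, 161.0, 2.0)
        means = []
        for frac in (0.0, 0.5, 1.0):
            scores = []
            for s in range(4):
                bt = gen_bivariate(
                    BivariateSpec(shared_fraction=frac), region, seed=3000 + 17 * s
                )
                curves = k_bivariate(bt.pattern, radii)
                env = bivariate_envelope(bt.pattern, radii, n_sim=150, seed=4000 + s)
                std = standardize(l_biv_transform(curves.k_biv), env)
                scores.append(lbi(std, bounds=(10.0, 110.0)).lbi)
            means.append(np.mean(scores))
        assert means[0] < 100.0 < means[2]
        assert means[0] < means[1] < means[2]
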