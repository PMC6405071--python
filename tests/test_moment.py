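"""Moment-distance family: examples, oracle equivalence and identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdshape import (
    HyperCube,
    PivotPair,
    SpectralCurve,
    md_cube,
    md_metrics,
    md_sweep,
    moment_distance_lp,
    moment_distance_rp,
)


def oracle_md(reflectance, abscissa, lp, rp):
    """Independent term-by-term summation of both moment distances."""
    md_lp = md_rp = 0.0
    for rho, x in zip(reflectance, abscissa):
        if lp <= x <= rp:
            md_lp += np.hypot(rho, x - lp)
            md_rp += np.hypot(rho, rp - x)
    return md_lp, md_rp


def curve(refl, absc=None):
    refl = np.asarray(refl, dtype=float)
    if absc is None:
        absc = np.arange(refl.size, dtype=float)
    return SpectralCurve(refl, np.asarray(absc, dtype=float))


positive_curves = st.lists(
    st.floats(1e-6, 1.0), min_size=2, max_size=200
).map(curve)


class TestPivotSums:
    def test_zero_reflectance_sums_abscissa_legs(self):
        c = curve([0, 0, 0, 0])
        p = PivotPair(0, 3)
        assert moment_distance_lp(c, p) == pytest.approx(6.0)
        assert moment_distance_rp(c, p) == pytest.approx(6.0)

    def test_single_sample_degenerate_window(self):
        c = curve([0.7], [0.0])
        p = PivotPair(0, 0)
        assert moment_distance_lp(c, p) == pytest.approx(0.7)
        assert moment_distance_rp(c, p) == pytest.approx(0.7)

    def test_three_point_hand_sum(self):
        c = curve([0.1, 0.5, 0.2])
        p = PivotPair(0, 2)
        expect_lp = 0.1 + np.sqrt(0.5**2 + 1) + np.sqrt(0.2**2 + 4)
        expect_rp = 0.2 + np.sqrt(0.5**2 + 1) + np.sqrt(0.1**2 + 4)
        assert moment_distance_lp(c, p) == pytest.approx(expect_lp, rel=1e-12)
        assert moment_distance_rp(c, p) == pytest.approx(expect_rp, rel=1e-12)

    def test_symmetric_curve_equal_pivot_sums(self):
        c = curve([0.2, 0.8, 0.8, 0.2])
        p = PivotPair(0, 3)
        assert moment_distance_lp(c, p) == pytest.approx(moment_distance_rp(c, p))

    def test_empty_window_raises(self):
        c = curve([0.1, 0.2], [0.0, 10.0])
        with pytest.raises(ValueError, match="window"):
            moment_distance_lp(c, PivotPair(3.0, 4.0))

    def test_nan_policy_fail_fast_then_skip(self):
        c = curve([0.1, np.nan, 0.3])
        p = PivotPair(0, 2)
        with pytest.raises(ValueError, match="NaN"):
            moment_distance_lp(c, p)
        got = moment_distance_lp(c, p, skip_nan=True)
        assert got == pytest.approx(0.1 + np.sqrt(0.3**2 + 4))
        assert md_metrics(c, p, skip_nan=True).n_used == 2

    def test_window_growth_is_monotone(self, rng):
        refl = rng.uniform(0, 1, 30)
        c = curve(refl)
        prev_lp = prev_rp = 0.0
        for rp in range(0, 30):
            p = PivotPair(0, rp)
            lp_v = moment_distance_lp(c, p)
            rp_v = moment_distance_rp(c, p)
            assert lp_v >= prev_lp - 1e-12
            # widening on the right moves RP, so only MD_LP is nested
            prev_lp = lp_v


class TestMetricsIdentities:
    def test_symmetric_curve_neutral_metrics(self):
        res = md_metrics(curve([0.3, 0.9, 0.3]))
        assert res.mdi == pytest.approx(0.0, abs=1e-14)
        assert res.mdin == pytest.approx(0.0, abs=1e-14)
        assert res.mdrlr == pytest.approx(1.0)
        assert res.mdrrl == pytest.approx(1.0)

    def test_three_point_mdi_value(self):
        res = md_metrics(curve([0.1, 0.5, 0.2]))
        expect = (0.2 + np.sqrt(1.25) + np.sqrt(4.01)) - (
            0.1 + np.sqrt(1.25) + np.sqrt(4.04)
        )
        assert res.mdi == pytest.approx(expect, rel=1e-12)

    def test_zero_curve_ratios_undefined(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            res = md_metrics(curve([0.0], [0.0]), PivotPair(0, 0))
        assert np.isnan(res.mdrlr) and np.isnan(res.mdrrl) and np.isnan(res.mdin)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(positive_curves)
    def test_oracle_equivalence_and_identities(self, c):
        res = md_metrics(c)
        lp, rp = oracle_md(c.reflectance, c.abscissa, c.abscissa[0], c.abscissa[-1])
        assert res.md_lp == pytest.approx(lp, rel=1e-10)
        assert res.md_rp == pytest.approx(rp, rel=1e-10)
        assert res.mdrlr * res.mdrrl == pytest.approx(1.0, rel=1e-10)
        assert res.mdin == pytest.approx((res.mdrrl - 1) / (res.mdrrl + 1), rel=1e-7, abs=1e-10)
        assert res.mdi == pytest.approx(res.md_lp * (res.mdrrl - 1), rel=1e-7, abs=1e-8)
        assert -1.0 < res.mdin < 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(positive_curves)
    def test_reversal_antisymmetry(self, c):
        fwd = md_metrics(c)
        rev = md_metrics(c.reversed())
        assert rev.md_lp == pytest.approx(fwd.md_rp, rel=1e-10)
        assert rev.md_rp == pytest.approx(fwd.md_lp, rel=1e-10)
        assert rev.mdi == pytest.approx(-fwd.mdi, rel=1e-9, abs=1e-10)
        assert rev.mdin == pytest.approx(-fwd.mdin, rel=1e-9, abs=1e-12)
        assert rev.mdrlr == pytest.approx(fwd.mdrrl, rel=1e-10)
        assert rev.mdrrl == pytest.approx(fwd.mdrlr, rel=1e-10)


class TestCube:
    def test_constant_cube_spatially_invariant(self):
        refl = np.array([0.2, 0.6, 0.3, 0.1])
        data = np.broadcast_to(refl[:, None, None], (4, 3, 5)).copy()
        cube = HyperCube(data, [400, 500, 600, 700])
        res = md_metrics(SpectralCurve(refl, np.arange(4.0)))
        out = md_cube(cube, metric="mdi")
        assert np.allclose(out, res.mdi)

    def test_zero_cube_gives_zero_mdi(self):
        cube = HyperCube(np.zeros((3, 2, 2)), [400, 500, 600])
        assert np.all(md_cube(cube, metric="mdi") == 0.0)

    def test_pixelwise_matches_per_curve_metrics(self, rng):
        data = rng.uniform(0, 1, size=(8, 2, 2))
        cube = HyperCube(data, np.linspace(400, 900, 8))
        for metric in ("mdi", "mdin", "mdrlr", "mdrrl"):
            out = md_cube(cube, metric=metric)
            for r in range(2):
                for c_ in range(2):
                    want = md_metrics(cube.pixel_curve(r, c_)).get(metric)
                    assert out[r, c_] == pytest.approx(want, rel=1e-12)

    def test_band_mask_excluded_and_reindexed(self, rng):
        data = rng.uniform(0, 1, size=(6, 2, 2))
        mask = np.array([True, False, True, True, False, True])
        cube = HyperCube(data, np.arange(400, 1000, 100), band_mask=mask)
        out = md_cube(cube, metric="mdi")
        kept = data[mask]
        want = md_metrics(SpectralCurve(kept[:, 0, 0], np.arange(4.0))).mdi
        assert out[0, 0] == pytest.approx(want, rel=1e-12)

    def test_reflectance_scale_matches_scaled_curve(self, rng):
        data = rng.uniform(0, 1, size=(10, 2, 2))
        cube = HyperCube(data, np.linspace(400, 900, 10))
        out = md_cube(cube, metric="mdrrl", reflectance_scale=1e4)
        want = md_metrics(
            SpectralCurve(data[:, 1, 1] * 1e4, np.arange(10.0))
        ).mdrrl
        assert out[1, 1] == pytest.approx(want, rel=1e-12)

    def test_pivot_outside_range_names_valid_range(self):
        cube = HyperCube(np.zeros((4, 2, 2)) + 0.5, [400, 500, 600, 700])
        with pytest.raises(ValueError, match=r"\[0\.0, 3\.0\]"):
            md_cube(cube, PivotPair(0, 10))


class TestSweep:
    def test_zero_curve_cumulative_legs(self):
        got = md_sweep(curve([0, 0, 0, 0]), fixed="LP")
        assert np.allclose(got, [0, 1, 3, 6])
        got_rp = md_sweep(curve([0, 0, 0, 0]), fixed="RP")
        assert np.allclose(got_rp, [0, 1, 3, 6])

    def test_final_element_equals_full_window_md(self, rng):
        refl = rng.uniform(0, 1, 17)
        c = curve(refl)
        p = PivotPair(0, 16)
        assert md_sweep(c, "LP")[-1] == pytest.approx(moment_distance_lp(c, p))
        assert md_sweep(c, "RP")[-1] == pytest.approx(moment_distance_rp(c, p))

    def test_running_sum_oracle(self):
        c = curve([0.1, 0.5, 0.2])
        terms = [0.1, np.sqrt(0.25 + 1), np.sqrt(0.04 + 4)]
        assert np.allclose(md_sweep(c, "LP"), np.cumsum(terms))
        terms_rp = [0.2, np.sqrt(0.25 + 1), np.sqrt(0.01 + 4)]
        assert np.allclose(md_sweep(c, "RP"), np.cumsum(terms_rp))

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            md_sweep(curve([0.5], [0.0]))
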