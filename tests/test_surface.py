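"""Unit and property tests for the ISO 25178 texture parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteotex.heightmap import DegenerateSurfaceError, HeightMap
from osteotex import surface as sf

from .conftest import random_rough_surface
from . import oracles


def grid(n=64, d=1.0):
    yy, xx = np.mgrid[0:n, 0:n] * d
    return yy, xx


# ---------------------------------------------------------------------------
# Sa
# ---------------------------------------------------------------------------

class TestSa:
    def test_constant_surface_is_zero(self):
        hm = HeightMap.from_array(np.full((16, 16), 5.0))
        assert sf.compute_sa(hm) == 0.0

    def test_sinusoid_matches_mean_abs_sine(self, sinusoid_surface):
        assert sf.compute_sa(sinusoid_surface) == pytest.approx(2 / np.pi, rel=1e-2)

    def test_translation_invariance(self):
        hm = random_rough_surface(0)
        shifted = hm.with_heights(hm.heights + 10.0)
        assert sf.compute_sa(shifted) == pytest.approx(sf.compute_sa(hm), rel=1e-12)

    def test_linear_height_scaling(self):
        hm = random_rough_surface(1)
        doubled = hm.with_heights(2.0 * hm.heights)
        assert sf.compute_sa(doubled) == pytest.approx(2 * sf.compute_sa(hm), rel=1e-12)

    def test_mask_robustness_one_percent(self):
        hm = random_rough_surface(2, n=128)
        rng = np.random.default_rng(3)
        mask = hm.mask.copy()
        drop = rng.choice(mask.size, size=mask.size // 100, replace=False)
        mask.ravel()[drop] = False
        masked = HeightMap(hm.heights, mask, hm.dx, hm.dy)
        assert sf.compute_sa(masked) == pytest.approx(sf.compute_sa(hm), rel=1e-2)

    def test_all_nonmeasured_raises(self):
        z = np.full((8, 8), np.nan)
        with pytest.raises(DegenerateSurfaceError):
            sf.compute_sa(HeightMap.from_array(z))


# ---------------------------------------------------------------------------
# ACF and Sal
# ---------------------------------------------------------------------------

class TestAcf:
    def test_lag_zero_is_one_and_symmetric(self):
        hm = random_rough_surface(4)
        g = sf.compute_acf(hm)
        cy, cx = g.center
        assert g.acf[cy, cx] == pytest.approx(1.0)
        np.testing.assert_allclose(g.acf, g.acf[::-1, ::-1], atol=1e-12)

    def test_matches_direct_estimator_on_full_mask(self):
        from scipy.signal import correlate2d

        hm = random_rough_surface(5, n=24)
        z = hm.heights - hm.heights.mean()
        direct = correlate2d(z, z, mode="full")
        direct /= direct[hm.shape[0] - 1, hm.shape[1] - 1]
        np.testing.assert_allclose(sf.compute_acf(hm).acf, direct, atol=1e-10)

    def test_sinusoid_acf_is_cosine(self, sinusoid_surface):
        g = sf.compute_acf(sinusoid_surface)
        cy, cx = g.center
        lag = int(round(25.0 / sinusoid_surface.dx))  # quarter period
        assert g.acf[cy, cx + lag] == pytest.approx(0.0, abs=0.02)

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(6)
        hm = HeightMap.from_array(rng.standard_normal((128, 128)))
        g = sf.compute_acf(hm)
        cy, cx = g.center
        assert abs(g.acf[cy, cx + 1]) < 4 / 128  # O(1/sqrt(N)) bound

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateSurfaceError):
            sf.compute_acf(HeightMap.from_array(np.zeros((8, 8))))


class TestSal:
    def test_white_noise_gives_one_sample_spacing(self):
        rng = np.random.default_rng(0)
        hm = HeightMap.from_array(rng.standard_normal((128, 128)), dx=1.5625)
        assert sf.compute_sal(hm) == pytest.approx(1.5625)

    def test_sinusoid_inverts_cosine(self, sinusoid_surface):
        expected = 100.0 / (2 * np.pi) * np.arccos(0.2)
        assert sf.compute_sal(sinusoid_surface) == pytest.approx(expected, rel=0.02)

    def test_rotation_and_height_scaling_invariance(self):
        hm = random_rough_surface(7)
        rot = HeightMap(np.rot90(hm.heights).copy(), np.rot90(hm.mask).copy(), 1.0, 1.0)
        assert sf.compute_sal(rot) == pytest.approx(sf.compute_sal(hm), rel=1e-9)
        scaled = hm.with_heights(3.0 * hm.heights)
        assert sf.compute_sal(scaled) == pytest.approx(sf.compute_sal(hm), rel=1e-12)

    def test_no_decay_warns_and_returns_max_lag(self):
        # a threshold below the ACF minimum is unreachable on any grid
        hm = random_rough_surface(20, n=16)
        with pytest.warns(sf.SalDecayWarning):
            out = sf.compute_sal(hm, s=-1.5)
        assert out == pytest.approx(sf.compute_acf(hm).lag_distances().max())


# ---------------------------------------------------------------------------
# Material ratio curve and Smr1
# ---------------------------------------------------------------------------

class TestMaterialRatio:
    def test_endpoints(self):
        hm = random_rough_surface(8)
        curve = sf.compute_material_ratio_curve(hm)
        n = hm.n_measured
        assert curve.ratios[0] >= 100.0 / n
        assert curve.ratios[-1] == pytest.approx(100.0)

    def test_linear_ramp_gives_straight_line(self):
        ramp = np.tile(np.linspace(0, 10, 512), (8, 1))
        curve = sf.compute_material_ratio_curve(HeightMap.from_array(ramp))
        # uniform heights: smr(c) is linear in c
        fit = np.polyval(np.polyfit(curve.heights, curve.ratios, 1), curve.heights)
        assert np.max(np.abs(fit - curve.ratios)) < 0.5  # grid tolerance, %

    def test_translation_shifts_heights_only(self):
        hm = random_rough_surface(9)
        c0 = sf.compute_material_ratio_curve(hm)
        c1 = sf.compute_material_ratio_curve(hm.with_heights(hm.heights + 5.0))
        np.testing.assert_allclose(c1.heights, c0.heights + 5.0, atol=1e-9)
        np.testing.assert_array_equal(c1.ratios, c0.ratios)


class TestSmr1:
    def test_linear_ramp_is_zero(self):
        ramp = np.tile(np.linspace(0, 10, 256), (16, 1))
        assert sf.compute_smr1(HeightMap.from_array(ramp)) == 0.0

    def test_plateau_and_pit_surface_below_five_percent(self):
        rng = np.random.default_rng(10)
        z = np.zeros((64, 64))
        idx = rng.choice(z.size, size=int(0.05 * z.size), replace=False)
        z.ravel()[idx] = -10.0
        assert sf.compute_smr1(HeightMap.from_array(z)) < 5.0

    def test_translation_invariance(self):
        hm = random_rough_surface(11)
        shifted = hm.with_heights(hm.heights - 3.0)
        assert sf.compute_smr1(shifted) == pytest.approx(sf.compute_smr1(hm), abs=1e-9)

    def test_constant_surface_raises(self):
        with pytest.raises(DegenerateSurfaceError):
            sf.compute_smr1(HeightMap.from_array(np.ones((8, 8))))


# ---------------------------------------------------------------------------
# Peaks and Spc
# ---------------------------------------------------------------------------

def paraboloid(n=64, R=50.0, x0=None, y0=None, h=10.0):
    yy, xx = grid(n)
    x0 = n // 2 if x0 is None else x0
    y0 = n // 2 if y0 is None else y0
    return np.maximum(h - ((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * R), 0.0)


class TestPeaks:
    def test_single_bump_gives_one_peak_at_apex(self):
        hm = HeightMap.from_array(paraboloid())
        peaks = sf.find_significant_peaks(hm)
        assert len(peaks) == 1
        assert tuple(peaks.locations[0]) == (32, 32)

    def test_two_bumps_give_two_peaks(self):
        z = np.maximum(paraboloid(x0=16), paraboloid(x0=48))
        peaks = sf.find_significant_peaks(HeightMap.from_array(z))
        assert len(peaks) == 2

    def test_small_ripple_is_pruned(self):
        z = paraboloid(R=100.0)
        yy, xx = grid(64)
        sz = z.max() - z.min()
        z = z + 0.02 * sz * np.sin(2 * np.pi * xx / 9)  # amplitude < 5% of Sz
        peaks = sf.find_significant_peaks(HeightMap.from_array(z))
        assert len(peaks) == 1

    def test_spc_of_paraboloid_is_inverse_radius(self):
        R = 50.0
        hm = HeightMap.from_array(paraboloid(R=R))
        peaks = sf.find_significant_peaks(hm)
        assert sf.compute_spc(hm, peaks) == pytest.approx(1.0 / R, rel=0.02)

    def test_spc_mean_of_identical_peaks_and_scaling(self):
        z1 = paraboloid(x0=16)
        z2 = np.maximum(z1, paraboloid(x0=48))
        hm1, hm2 = HeightMap.from_array(z1), HeightMap.from_array(z2)
        spc1 = sf.compute_spc(hm1)
        assert sf.compute_spc(hm2) == pytest.approx(spc1, rel=1e-9)
        assert sf.compute_spc(hm1.with_heights(2 * z1)) == pytest.approx(2 * spc1, rel=1e-9)

    def test_empty_peaks_error(self):
        hm = HeightMap.from_array(paraboloid())
        empty = sf.PeakSet(np.empty((0, 2), int), np.empty(0), 0.0)
        with pytest.raises(DegenerateSurfaceError):
            sf.compute_spc(hm, empty)


# ---------------------------------------------------------------------------
# Composition and 180° symmetry
# ---------------------------------------------------------------------------

def test_compute_all_params_matches_components():
    hm = random_rough_surface(12)
    tp = sf.compute_all_params(hm)
    assert tp.sa == sf.compute_sa(hm)
    assert tp.sal == sf.compute_sal(hm)
    assert tp.spc == sf.compute_spc(hm)
    assert tp.smr1 == sf.compute_smr1(hm)
    assert all(v > 0 for v in (tp.sa, tp.sal, tp.spc)) and tp.smr1 >= 0


def test_sal_and_spc_invariant_under_180_rotation():
    hm = random_rough_surface(13)
    rot = HeightMap(hm.heights[::-1, ::-1].copy(), hm.mask[::-1, ::-1].copy(), 1.0, 1.0)
    assert sf.compute_sal(rot) == pytest.approx(sf.compute_sal(hm), rel=1e-12)
    assert sf.compute_spc(rot) == pytest.approx(sf.compute_spc(hm), rel=1e-12)


# ---------------------------------------------------------------------------
# Brute-force oracle agreement (small sample; the full 50-surface sweep is
# exercised in the acceptance suite)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("with_mask", [False, True])
def test_oracle_agreement(seed, with_mask):
    hm = random_rough_surface(seed, with_mask=with_mask)
    assert sf.compute_sal(hm) == oracles.brute_force_sal(hm)
    assert sf.compute_smr1(hm) == pytest.approx(oracles.brute_force_smr1(hm), abs=1e-9)
    got = sorted(map(tuple, sf.find_significant_peaks(hm).locations))
    assert got == oracles.brute_force_peaks(hm)


# ---------------------------------------------------------------------------
# Hypothesis property tests
# ---------------------------------------------------------------------------

@given(
    seed=st.integers(0, 10_000),
    offset=st.floats(-50, 50, allow_nan=False),
    scale=st.floats(0.1, 10, allow_nan=False),
)
@settings(max_examples=20, deadline=None, derandomize=True)
def test_sa_affine_response(seed, offset, scale):
    """Sa is translation-invariant and exactly linear in height scaling."""
    hm = random_rough_surface(seed, n=24)
    sa = sf.compute_sa(hm)
    out = sf.compute_sa(hm.with_heights(scale * hm.heights + offset))
    assert out == pytest.approx(scale * sa, rel=1e-9)


@given(seed=st.integers(0, 10_000), offset=st.floats(-20, 20, allow_nan=False))
@settings(max_examples=10, deadline=None, derandomize=True)
def test_smr1_translation_invariant(seed, offset):
    hm = random_rough_surface(seed, n=32)
    assert sf.compute_smr1(hm.with_heights(hm.heights + offset)) == pytest.approx(
        sf.compute_smr1(hm), abs=1e-8
    )
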