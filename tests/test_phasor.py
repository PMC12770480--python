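"""Spectral phasor transform, two-cursor analysis, fluidity statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coacwet import phasor, synth
from coacwet.phasor import (
    CursorPair,
    HyperspectralStack,
    PhasorPoint,
    fluidity_histogram,
    linear_combination_check,
    phasor_transform,
    segment_membrane_regions,
    two_cursor_fraction,
)


def stack_with_channels(intensity, channels, lo=400.0, hi=700.0):
    return HyperspectralStack(intensity=np.asarray(intensity, float),
                              lambda_min=lo, lambda_max=hi,
                              channels=np.asarray(channels, float))


class TestTransform:
    def test_delta_at_lambda_min(self):
        ch = np.linspace(400, 700, 31)
        spec = np.zeros((1, 31))
        spec[0, 0] = 5.0
        G, S = phasor_transform(stack_with_channels(spec, ch))
        assert (G[0], S[0]) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_delta_at_quarter_period(self):
        ch = np.linspace(400, 700, 13)  # includes 475 = lo + range/4
        spec = np.zeros((1, 13))
        spec[0, np.argmin(np.abs(ch - 475.0))] = 2.0
        G, S = phasor_transform(stack_with_channels(spec, ch))
        assert G[0] == pytest.approx(0.0, abs=1e-12)
        assert S[0] == pytest.approx(1.0, abs=1e-12)

    def test_uniform_spectrum_at_origin(self):
        ch = synth.default_channels(30, 400.0, 700.0)  # midpoint grid
        spec = np.ones((1, 30))
        G, S = phasor_transform(stack_with_channels(spec, ch))
        assert G[0] == pytest.approx(0.0, abs=1e-12)
        assert S[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_pixels_masked_not_error(self):
        ch = synth.default_channels(30, 400.0, 700.0)
        spec = np.zeros((2, 30))
        spec[1, 3] = 1.0
        G, S = phasor_transform(stack_with_channels(spec, ch))
        assert np.isnan(G[0]) and np.isfinite(G[1])

    def test_negative_intensity_rejected(self):
        ch = synth.default_channels(30, 400.0, 700.0)
        with pytest.raises(ValueError):
            stack_with_channels(-np.ones((1, 30)), ch)

    def test_intensity_scaling_invariance(self, rng):
        ch = synth.default_channels(30, 400.0, 700.0)
        spec = rng.uniform(0, 1, size=(5, 30))
        G1, S1 = phasor_transform(stack_with_channels(spec, ch))
        G2, S2 = phasor_transform(stack_with_channels(7.3 * spec, ch))
        assert np.allclose(G1, G2) and np.allclose(S1, S2)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_unit_modulus_bound(self, seed):
        r = np.random.default_rng(seed)
        ch = synth.default_channels(20, 400.0, 700.0)
        spec = r.uniform(0, 10, size=(3, 20))
        G, S = phasor_transform(stack_with_channels(spec, ch))
        ok = np.isfinite(G)
        assert np.all(np.hypot(G[ok], S[ok]) <= 1.0 + 1e-12)


class TestLinearCombination:
    def test_endpoints_exact(self, rng):
        ch = synth.default_channels(30, 400.0, 700.0)
        meta = stack_with_channels(np.ones((1, 30)), ch)
        a, b = rng.uniform(0, 1, 30), rng.uniform(0, 1, 30)
        assert linear_combination_check(a, b, 0.0, meta) < 1e-12
        assert linear_combination_check(a, b, 1.0, meta) < 1e-12

    def test_equal_integral_midpoint(self, rng):
        ch = synth.default_channels(30, 400.0, 700.0)
        meta = stack_with_channels(np.ones((1, 30)), ch)
        a = rng.uniform(0, 1, 30)
        b = rng.uniform(0, 1, 30)
        b *= a.sum() / b.sum()
        from coacwet.phasor import phasor_of_spectrum

        mix = 0.5 * a + 0.5 * b
        pm = phasor_of_spectrum(mix, meta).as_array()
        midpoint = 0.5 * (phasor_of_spectrum(a, meta).as_array()
                          + phasor_of_spectrum(b, meta).as_array())
        assert np.allclose(pm, midpoint, atol=1e-12)

    def test_random_mixtures_numerically_exact(self, rng):
        ch = synth.default_channels(30, 400.0, 700.0)
        meta = stack_with_channels(np.ones((1, 30)), ch)
        for alpha in rng.uniform(0, 1, 10):
            a, b = rng.uniform(0, 2, 30), rng.uniform(0, 2, 30)
            assert linear_combination_check(a, b, float(alpha), meta) < 1e-12


class TestTwoCursor:
    cursors = CursorPair(PhasorPoint(0.2, 0.1), PhasorPoint(0.8, 0.5))

    def test_cursor_endpoints(self):
        f = two_cursor_fraction(np.array([0.2, 0.8]), np.array([0.1, 0.5]),
                                self.cursors)
        assert f[0] == 0.0 and f[1] == pytest.approx(1.0)

    def test_midpoint(self):
        f = two_cursor_fraction(np.array([0.5]), np.array([0.3]), self.cursors)
        assert f[0] == pytest.approx(0.5)

    def test_off_segment_perpendicular_foot(self):
        p1 = np.array([0.0, 0.0])
        p2 = np.array([1.0, 0.0])
        c = CursorPair(PhasorPoint(*p1), PhasorPoint(*p2))
        f = two_cursor_fraction(np.array([0.3]), np.array([0.4]), c)
        assert f[0] == pytest.approx(0.3)

    def test_clamping(self):
        c = CursorPair(PhasorPoint(0.0, 0.0), PhasorPoint(1.0, 0.0))
        f = two_cursor_fraction(np.array([-0.5, 1.5]), np.array([0.0, 0.0]), c)
        assert f[0] == 0.0 and f[1] == 1.0

    def test_degenerate_cursors_rejected(self):
        with pytest.raises(ValueError):
            CursorPair(PhasorPoint(0.1, 0.1), PhasorPoint(0.1, 0.1))


class TestFluidityHistogram:
    def test_point_mass(self):
        h = fluidity_histogram(np.full(100, 0.3), n_bins=100)
        assert h.cm == pytest.approx(0.3, abs=0.01)  # half-bin discretization
        assert h.counts.sum() == pytest.approx(1.0)

    def test_symmetric_split(self):
        h = fluidity_histogram(np.r_[np.zeros(50), np.ones(50)])
        assert h.cm == pytest.approx(0.5, abs=0.01)

    def test_two_gaussian_mixture_mean(self, rng):
        x = np.r_[rng.normal(0.3, 0.05, 6000), rng.normal(0.6, 0.05, 4000)]
        x = np.clip(x, 0, 1)
        h = fluidity_histogram(x)
        assert h.cm == pytest.approx(x.mean(), abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fluidity_histogram(np.array([np.nan]))


class TestRegionSegmentation:
    def _cursors_from_bases(self):
        ch = synth.default_channels()
        packed, fluid = synth.basis_spectra(ch)
        meta = HyperspectralStack(intensity=np.ones((1, len(ch))),
                                  lambda_min=synth.LAMBDA_MIN,
                                  lambda_max=synth.LAMBDA_MAX, channels=ch)
        from coacwet.phasor import phasor_of_spectrum

        return CursorPair(phasor_of_spectrum(fluid, meta),
                          phasor_of_spectrum(packed, meta))

    def test_packed_region_has_lower_fluidity_cm(self):
        stack, m, masks, _ = synth.gen_hyperspectral(
            shape=(32, 32), mixing="two-region", m_values=(0.8, 0.2), seed=1)
        hists = segment_membrane_regions(stack, self._cursors_from_bases(), masks)
        assert hists["wetted"].cm < hists["bare"].cm

    def test_identical_regions_identical_cm(self):
        stack, m, _, _ = synth.gen_hyperspectral(
            shape=(16, 16), mixing="constant", m_values=(0.5, 0.5), seed=2)
        masks = {"wetted": np.zeros((16, 16), bool), "bare": np.zeros((16, 16), bool)}
        masks["wetted"][:, :8] = True
        masks["bare"][:, 8:] = True
        hists = segment_membrane_regions(stack, self._cursors_from_bases(), masks)
        assert hists["wetted"].cm == pytest.approx(hists["bare"].cm, abs=0.01)

    def test_single_pixel_region(self):
        stack, m, _, _ = synth.gen_hyperspectral(
            shape=(8, 8), mixing="constant", m_values=(0.4, 0.4), seed=3)
        mask = np.zeros((8, 8), bool)
        mask[0, 0] = True
        hists = segment_membrane_regions(stack, self._cursors_from_bases(),
                                         {"one": mask})
        G, S = phasor_transform(stack)
        frac = phasor.fluidity_fraction(G, S, self._cursors_from_bases())[0, 0]
        assert hists["one"].cm == pytest.approx(frac, abs=0.01)

    def test_overlapping_masks_rejected(self):
        stack, *_ = synth.gen_hyperspectral(shape=(8, 8), seed=4)
        m = np.ones((8, 8), bool)
        with pytest.raises(ValueError):
            segment_membrane_regions(stack, self._cursors_from_bases(),
                                     {"a": m, "b": m})

    def test_mixture_recovery_correlation(self):
        """Two-cursor fractions track the generating mixing field."""
        stack, m, _, _ = synth.gen_hyperspectral(
            shape=(24, 24), mixing="gradient", m_values=(0.1, 0.9), seed=5)
        G, S = phasor_transform(stack)
        frac = two_cursor_fraction(G, S, self._cursors_from_bases())
        r = np.corrcoef(frac.ravel(), m.ravel())[0, 1]
        assert r > 0.99
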