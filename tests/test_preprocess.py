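"""Baseline correction, normalization, derivative and region selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sersdx.spectra import Spectrum
from sersdx.preprocess import (
    PreprocessConfig,
    class_mean,
    difference_spectrum,
    lower_convex_hull_indices,
    mean_center,
    normalize,
    preprocess_set,
    rubberband_baseline,
    select_region,
    sg_second_derivative,
)


def brute_force_lower_hull(x, y):
    """O(n^3) oracle: a point pair (i, j) is a lower-hull edge iff every
    other point lies on or above the line through them; hull vertices are
    the endpoints of the chain of such edges."""
    n = len(x)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = True
            for k in range(n):
                if k in (i, j):
                    continue
                # signed area: negative when k is below line i-j
                cross = (x[j] - x[i]) * (y[k] - y[i]) - (y[j] - y[i]) * (x[k] - x[i])
                if cross < -1e-12 * max(1.0, abs(x[j] - x[i])):
                    ok = False
                    break
            if ok:
                edges.append((i, j))
    verts = {0, n - 1}
    # chain from the left: follow edges with maximal reach
    cur = 0
    while cur != n - 1:
        nxt = max(j for (i, j) in edges if i == cur)
        verts.add(nxt)
        cur = nxt
    return np.array(sorted(verts))


class TestRubberband:
    def test_straight_line_corrects_to_zero(self):
        wn = np.linspace(0, 10, 11)
        s = Spectrum(wn, 2.0 * wn + 5.0)
        baseline, corrected = rubberband_baseline(s)
        np.testing.assert_allclose(corrected.intensities, 0.0, atol=1e-12)
        np.testing.assert_allclose(baseline.intensities, s.intensities)

    def test_single_peak_flat_baseline(self):
        wn = np.linspace(0, 10, 101)
        peak = np.exp(-0.5 * ((wn - 5) / 0.5) ** 2)
        s = Spectrum(wn, 1.0 + peak)
        baseline, corrected = rubberband_baseline(s)
        np.testing.assert_allclose(baseline.intensities, 1.0, atol=1e-9)
        np.testing.assert_allclose(corrected.intensities, peak, atol=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        """Monotone-chain hull vertices equal the exhaustive pairwise
        lower-hull oracle on random small spectra."""
        for _ in range(200):
            n = rng.integers(3, 13)
            x = np.sort(rng.uniform(0, 100, size=n))
            while np.any(np.diff(x) <= 1e-6):
                x = np.sort(rng.uniform(0, 100, size=n))
            y = rng.normal(size=n)
            got = lower_convex_hull_indices(x, y)
            expected = brute_force_lower_hull(x, y)
            np.testing.assert_array_equal(got, expected)

    def test_nonnegative_and_zero_at_anchors(self, rng):
        x = np.sort(rng.uniform(0, 50, 30))
        s = Spectrum(x, rng.normal(size=30))
        _, corrected = rubberband_baseline(s)
        assert np.all(corrected.intensities >= 0)
        # at least the two endpoints are hull vertices with zero residue
        assert corrected.intensities[0] == 0.0
        assert corrected.intensities[-1] == 0.0
        assert np.sum(np.isclose(corrected.intensities, 0.0, atol=1e-12)) >= 2


class TestNormalize:
    def test_vector_idempotent(self, toy_spectrum):
        once = normalize(toy_spectrum, "vector")
        twice = normalize(once, "vector")
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-12)
        assert np.isclose(np.linalg.norm(once.intensities), 1.0)

    def test_three_four_five(self):
        s = Spectrum([0.0, 1.0, 2.0], [3.0, 4.0, 0.0])
        out = normalize(s, "vector")
        np.testing.assert_allclose(out.intensities, [0.6, 0.8, 0.0])

    def test_area_rectangle(self):
        # unit-height rectangle of width w=6 -> heights 1/6
        s = Spectrum([0.0, 2.0, 4.0, 6.0], np.ones(4))
        out = normalize(s, "area")
        np.testing.assert_allclose(out.intensities, 1.0 / 6.0)

    def test_max_method(self, toy_spectrum):
        out = normalize(toy_spectrum, "max")
        assert np.isclose(out.intensities.max(), 1.0)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(ValueError, match="norm"):
            normalize(Spectrum([0.0, 1.0, 2.0], [0.0, 0.0, 0.0]), "vector")


class TestSGDerivative:
    def test_constant_gives_zero(self):
        s = Spectrum(np.arange(50.0), np.full(50, 7.0))
        out = sg_second_derivative(s, 11, 3)
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-10)
        assert len(out) == 50 - 10  # edges truncated

    @pytest.mark.parametrize("a", [1.0, -2.5])
    def test_quadratic_second_derivative(self, a):
        """d2/dx2 of a x^2 is 2a on interior points, cross-checked against
        an explicit per-window polynomial refit."""
        x = 600.0 + 2.0 * np.arange(60)
        s = Spectrum(x, a * x**2)
        out = sg_second_derivative(s, 11, 3)
        np.testing.assert_allclose(out.intensities, 2 * a, rtol=1e-8)
        # oracle: refit the centered window polynomial at one point
        i = 30
        xi = x[i - 5 : i + 6] - x[i]
        coef = np.polynomial.polynomial.polyfit(xi, s.intensities[i - 5 : i + 6], 3)
        assert np.isclose(out.intensities[i - 5], 2 * coef[2], rtol=1e-8)

    def test_linearity(self, rng):
        x = np.arange(40.0)
        y = rng.normal(size=40)
        s = Spectrum(x, y)
        alpha = 3.7
        a = sg_second_derivative(s.with_intensities(alpha * y), 9, 2)
        b = sg_second_derivative(s, 9, 2)
        np.testing.assert_allclose(a.intensities, alpha * b.intensities, atol=1e-12)

    @given(deg=st.integers(0, 3), seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_polynomial_reproduction(self, deg, seed):
        """SG(order 3) reproduces the analytic 2nd derivative of any
        polynomial of degree <= 3 on interior points (degree <= 1: zero)."""
        rng = np.random.default_rng(seed)
        coeffs = rng.uniform(-1, 1, size=deg + 1)
        x = np.linspace(-1.0, 1.0, 41)
        y = np.polynomial.polynomial.polyval(x, coeffs)
        out = sg_second_derivative(Spectrum(x, y), 9, 3)
        d2 = np.polynomial.polynomial.polyval(
            out.wavenumbers, np.polynomial.polynomial.polyder(coeffs, 2)
        )
        np.testing.assert_allclose(out.intensities, d2, atol=1e-8)

    def test_nonuniform_grid_rejected(self):
        s = Spectrum([0.0, 1.0, 3.0, 4.0, 5.0, 6.0, 7.0], np.zeros(7))
        with pytest.raises(ValueError, match="uniform"):
            sg_second_derivative(s, 5, 2)


class TestSelectRegion:
    def test_full_axis_identity(self, toy_spectrum):
        out = select_region(toy_spectrum, 0.0, 1e4)
        np.testing.assert_array_equal(out.intensities, toy_spectrum.intensities)

    def test_fingerprint_region_point_count(self):
        grid = np.arange(600.0, 2302.0, 2.0)
        s = Spectrum(grid, np.zeros(grid.size))
        out = select_region(s, 750.0, 1750.0)
        assert len(out) == 501  # (1750 - 750) / 2 + 1

    def test_degenerate_selection_too_short_downstream(self):
        grid = np.arange(600.0, 700.0, 2.0)
        s = Spectrum(grid, np.zeros(grid.size))
        with pytest.raises(ValueError):
            # single-point selection violates the >= 3-point invariant
            select_region(s, 650.0, 650.0)

    def test_empty_selection_rejected(self, toy_spectrum):
        with pytest.raises(ValueError, match="no grid points"):
            select_region(toy_spectrum, 5000.0, 6000.0)


class TestMeanCenter:
    def test_columns_centered(self, rng):
        X = rng.normal(size=(11, 7))
        Xc, means = mean_center(X)
        np.testing.assert_allclose(Xc.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xc + means, X, atol=1e-12)

    def test_identical_rows_zero(self):
        X = np.tile([1.0, 2.0, 3.0], (4, 1))
        Xc, means = mean_center(X)
        np.testing.assert_allclose(Xc, 0.0, atol=1e-15)
        np.testing.assert_allclose(means, [1.0, 2.0, 3.0])

    def test_simple_column(self):
        Xc, means = mean_center(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(Xc.ravel(), [-1.0, 1.0])
        assert means[0] == 2.0


class TestDifferenceSpectrum:
    def test_self_difference_zero(self, toy_spectrum):
        d = difference_spectrum(toy_spectrum, toy_spectrum)
        np.testing.assert_allclose(d.intensities, 0.0)

    def test_antisymmetry(self, rng):
        wn = np.arange(10.0)
        a = Spectrum(wn, rng.normal(size=10))
        b = Spectrum(wn, rng.normal(size=10))
        np.testing.assert_allclose(
            difference_spectrum(a, b).intensities,
            -difference_spectrum(b, a).intensities,
        )

    def test_grid_mismatch_rejected(self, toy_spectrum):
        other = Spectrum(
            toy_spectrum.wavenumbers + 1.0, toy_spectrum.intensities
        )
        with pytest.raises(ValueError, match="shared grid"):
            difference_spectrum(toy_spectrum, other)


class TestPipeline:
    def test_deterministic(self, small_cohort):
        cfg = PreprocessConfig()
        a = preprocess_set(small_cohort, cfg)
        b = preprocess_set(small_cohort, cfg)
        np.testing.assert_array_equal(a.X, b.X)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(sg_window=24)
        with pytest.raises(ValueError):
            PreprocessConfig(region_lo=1000.0, region_hi=900.0)
        with pytest.raises(ValueError):
            PreprocessConfig(normalization="median")

    def test_output_shape_and_region(self, small_cohort):
        out = preprocess_set(small_cohort, PreprocessConfig())
        assert len(out) == 37  # replicate-averaged samples
        # region 750-1750 minus 12 SG edge points per side at 2 cm^-1
        assert out.grid[0] == 750.0 + 24.0
        assert out.grid[-1] == 1750.0 - 24.0

    def test_class_mean_labels(self, small_cohort):
        m = class_mean(small_cohort, "FM")
        assert m.label == "FM"
        with pytest.raises(ValueError, match="labelled"):
            class_mean(small_cohort.select_labels("FM"), "NC")
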