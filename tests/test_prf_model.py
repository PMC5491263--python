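"""CSS forward model: Gaussian fields, overlap responses, HRF, contralateral."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prfclust import (
    ApertureSequence,
    FieldSpec,
    HRFSpec,
    PRFParams,
    contralateral_prediction,
    convolve_hrf,
    css_neural_response,
    css_prediction,
    effective_size,
    gaussian_field,
    generate_bar_sequence,
    linear_prediction,
)
from prfclust.prf_model import contralateral_regressor, overlap_series


def _bar_mask(field: FieldSpec, x_lo: float, x_hi: float) -> np.ndarray:
    x = field.pixel_centers()
    m = np.zeros((1, field.n_pixels, field.n_pixels), dtype=np.uint8)
    m[0, :, (x >= x_lo) & (x < x_hi)] = 1
    return m


def _seq(field: FieldSpec, masks: np.ndarray) -> ApertureSequence:
    return ApertureSequence(masks, field, 1.6, 1.0, "left-right")


class TestGaussianField:
    def test_peak_is_one_at_center(self, field):
        g = gaussian_field(PRFParams(2.0, -1.0, 1.5), field)
        # peak sampled at the nearest pixel center, a half-pixel off at worst
        assert g.max() == pytest.approx(1.0, abs=0.01)

    def test_value_at_one_sigma(self, field):
        params = PRFParams(0.0, 0.0, 2.0)
        g = gaussian_field(params, field)
        x = field.pixel_centers()
        row = np.argmin(np.abs(x))  # pixel nearest y = 0
        col = np.argmin(np.abs(x - 2.0))  # pixel nearest x = sigma
        expected = np.exp(
            -((x[col]) ** 2 + (x[row]) ** 2) / (2 * 2.0**2)
        )
        assert g[row, col] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(np.exp(-0.5), rel=0.1)

    def test_reflection_symmetry_about_center(self, field):
        g = gaussian_field(PRFParams(0.0, 0.0, 1.0), field)
        np.testing.assert_allclose(g, g[::-1, :], atol=1e-12)
        np.testing.assert_allclose(g, g[:, ::-1], atol=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            PRFParams(0, 0, 0.0)


class TestCSSResponse:
    def test_zero_mask_gives_zero(self, field):
        seq = _seq(field, np.zeros((3, field.n_pixels, field.n_pixels), np.uint8))
        np.testing.assert_array_equal(
            css_neural_response(seq, PRFParams(0, 0, 2, 0.5)), 0.0
        )

    @pytest.mark.parametrize("n", [0.25, 0.5, 1.0])
    def test_full_field_normalized_returns_beta(self, field, n):
        seq = _seq(field, np.ones((2, field.n_pixels, field.n_pixels), np.uint8))
        r = css_neural_response(seq, PRFParams(1, -2, 3, n, beta=2.0))
        np.testing.assert_allclose(r, 2.0, rtol=1e-12)

    def test_quarter_overlap_square_root(self, field):
        # half-field mask over a pRF centered on the dividing line has
        # overlap 1/2; engineered 1/4 via exponent arithmetic instead:
        seq = _seq(field, _bar_mask(field, 0.0, 12.0))
        params = PRFParams(0.0, 0.0, 2.0, 1.0)
        ov = overlap_series(seq, params)[0]
        assert ov == pytest.approx(0.5, abs=0.01)
        r = css_neural_response(seq, PRFParams(0.0, 0.0, 2.0, 0.5))
        assert r[0] == pytest.approx(np.sqrt(ov), rel=1e-12)

    def test_mismatched_geometry_rejected(self, field):
        other = FieldSpec(resolution=8)
        seq = _seq(field, np.ones((1, field.n_pixels, field.n_pixels), np.uint8))
        params = PRFParams(0, 0, 1)
        with pytest.raises((ValueError, IndexError)):
            # Gaussian built on a different raster cannot combine with masks
            g = gaussian_field(params, other)
            _ = seq.masks.reshape(len(seq), -1) @ g.ravel()

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        split=st.floats(-6, 6),
        n=st.sampled_from([0.25, 0.5, 0.75]),
        x0=st.floats(-4, 4),
    )
    def test_subadditivity_on_disjoint_masks(self, field, split, n, x0):
        # response(A u B) <= response(A) + response(B) for n < 1
        a = _bar_mask(field, -10.0, split)
        b = _bar_mask(field, split, 10.0)
        both = (a | b).astype(np.uint8)
        p = PRFParams(x0, 0.0, 2.0, n)
        ra = css_neural_response(_seq(field, a), p)[0]
        rb = css_neural_response(_seq(field, b), p)[0]
        rab = css_neural_response(_seq(field, both), p)[0]
        assert rab <= ra + rb + 1e-12

    def test_additivity_at_n_equal_one(self, field):
        a = _bar_mask(field, -10.0, 0.0)
        b = _bar_mask(field, 0.0, 10.0)
        p = PRFParams(1.0, 0.0, 2.0, 1.0)
        ra = css_neural_response(_seq(field, a), p)[0]
        rb = css_neural_response(_seq(field, b), p)[0]
        rab = css_neural_response(_seq(field, (a | b).astype(np.uint8)), p)[0]
        assert rab == pytest.approx(ra + rb, rel=1e-10)

    def test_resolution_convergence(self):
        # predictions at the default 5 samples/deg agree with a raster twice
        # as fine within 2% RMS (the default pixel divides step and widths
        # exactly, so doubling changes only the Gaussian sampling)
        for sigma in (0.5, 1.0, 3.0):
            rs = []
            for res in (5, 10):
                f = FieldSpec(resolution=res)
                seq = generate_bar_sequence(f, 2.0, "left-right")
                rs.append(css_neural_response(seq, PRFParams(1.5, -0.5, sigma, 0.5)))
            rms = np.sqrt(np.mean((rs[0] - rs[1]) ** 2)) / (
                np.sqrt(np.mean(rs[1] ** 2))
            )
            assert rms < 0.02

    def test_translation_invariance(self, field):
        seq0 = _seq(field, _bar_mask(field, -1.0, 1.0))
        seq1 = _seq(field, _bar_mask(field, 2.0, 4.0))  # shifted by 3 deg
        r0 = css_neural_response(seq0, PRFParams(0.0, 0.0, 1.5, 0.5))
        r1 = css_neural_response(seq1, PRFParams(3.0, 0.0, 1.5, 0.5))
        assert r1[0] == pytest.approx(r0[0], rel=1e-6)


class TestHRF:
    def test_zero_in_zero_out(self):
        hrf = HRFSpec()
        np.testing.assert_array_equal(convolve_hrf(np.zeros(20), hrf), 0.0)

    def test_impulse_reproduces_kernel(self):
        hrf = HRFSpec()
        x = np.zeros(17)
        x[0] = 1.0
        np.testing.assert_allclose(convolve_hrf(x, hrf), hrf.kernel()[:17])

    def test_linearity(self):
        hrf = HRFSpec()
        rng = np.random.default_rng(0)
        a, b = rng.random(30), rng.random(30)
        np.testing.assert_allclose(
            convolve_hrf(a + b, hrf), convolve_hrf(a, hrf) + convolve_hrf(b, hrf)
        )

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            convolve_hrf(np.array([]), HRFSpec())

    def test_kernel_peaks_early_and_undershoots(self):
        k = HRFSpec(dt_s=1.0).kernel()
        assert 3 <= np.argmax(k) <= 7  # peak near 5 s
        assert k.min() < 0  # undershoot present
        assert k.sum() == pytest.approx(1.0)


class TestLinearAndContralateral:
    def test_linear_is_css_with_unit_exponent(self, field):
        seq = generate_bar_sequence(field, 2.0, "left-right")
        p = PRFParams(1.0, 2.0, 1.5, 0.25, beta=1.3)
        lin = linear_prediction(seq, p)
        unit = css_prediction(seq, PRFParams(1.0, 2.0, 1.5, 1.0, 1.3))
        np.testing.assert_allclose(lin, unit)

    def test_beta_scales_linear_prediction(self, field):
        seq = generate_bar_sequence(field, 2.0, "left-right")
        one = linear_prediction(seq, PRFParams(0, 0, 2, 1.0, 1.0))
        two = linear_prediction(seq, PRFParams(0, 0, 2, 1.0, 2.0))
        np.testing.assert_allclose(two, 2 * one)

    def test_full_field_css_equals_linear(self, field):
        seq = _seq(field, np.ones((4, field.n_pixels, field.n_pixels), np.uint8))
        p = PRFParams(0, 0, 2, 0.25, beta=1.7)
        np.testing.assert_allclose(
            css_prediction(seq, p), linear_prediction(seq, p)
        )

    def test_contralateral_rule(self, field):
        right_bar = _seq(field, _bar_mask(field, 3.0, 4.0))
        left_bar = _seq(field, _bar_mask(field, -4.0, -3.0))
        straddle = _seq(field, _bar_mask(field, -0.5, 0.5))
        assert contralateral_regressor(right_bar, "left")[0] == 1.0
        assert contralateral_regressor(left_bar, "left")[0] == 0.0
        assert contralateral_regressor(right_bar, "right")[0] == 0.0
        assert contralateral_regressor(straddle, "left")[0] == 1.0
        assert contralateral_regressor(straddle, "right")[0] == 1.0

    def test_unknown_hemisphere_rejected(self, field):
        seq = _seq(field, _bar_mask(field, 0.0, 1.0))
        with pytest.raises(ValueError, match="hemisphere"):
            contralateral_prediction(seq, "dorsal")


class TestEffectiveSize:
    @pytest.mark.parametrize(
        "sigma,n,expected", [(3.0, 0.25, 12.0), (2.0, 1.0, 2.0), (1.0, 0.5, 2.0)]
    )
    def test_ratio(self, sigma, n, expected):
        assert effective_size(PRFParams(0, 0, sigma, n)) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(sigma=st.floats(0.1, 12.0), n=st.sampled_from([0.25, 0.5, 0.75, 1.0]))
    def test_never_smaller_than_sigma(self, sigma, n):
        assert effective_size(PRFParams(0, 0, sigma, n)) >= sigma
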