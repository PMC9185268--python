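import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from podnirs import (MathTreatment, SpectralSet, WavelengthGrid,
                     apply_treatment, detrend, gap_segment_derivative,
                     parse_math_treatment, snv)
from podnirs.treatments import treated_grid


class TestParseCode:
    @pytest.mark.parametrize("code, expected", [
        ("2,5,5,2", (2, 5, 5, 2, "none")),
        ("1,4,4,1", (1, 4, 4, 1, "none")),
        ("0,0,1,1", (0, 1, 1, 1, "none")),
        ("2,5,5,2 snv_dt", (2, 5, 5, 2, "snv_dt")),
    ])
    def test_four_integer_codes(self, code, expected):
        t = parse_math_treatment(code)
        assert (t.derivative_order, t.gap, t.smooth1, t.smooth2,
                t.scatter) == expected

    def test_identity_code(self):
        assert parse_math_treatment("0,0,1,1").is_identity

    @pytest.mark.parametrize("bad", ["2,5,5", "1,2,3,4,5", "a,b,c,d",
                                     "-1,4,4,1", "1,4,4,1 msc"])
    def test_malformed_codes_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_math_treatment(bad)

    def test_code_round_trip(self):
        for code in ("2,5,5,2 snv_dt", "1,4,4,1"):
            assert parse_math_treatment(code).code == code


class TestSNV:
    def test_simple_vector(self):
        np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0])),
                                   [-1.0, 0.0, 1.0])

    def test_output_standardized(self, rng):
        x = rng.random(200)
        out = snv(x)
        assert out.mean() == pytest.approx(0.0, abs=1e-10)
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.floats(0.1, 100.0), b=st.floats(-50.0, 50.0),
           seed=st.integers(0, 1000))
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).random(50)
        np.testing.assert_allclose(snv(a * x + b), snv(x), atol=1e-8)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError):
            snv(np.ones(10))


class TestDetrend:
    def test_annihilates_quadratic_baseline(self, short_grid):
        wl = short_grid.wavelengths
        x = 3.0 - 0.002 * wl + 1e-6 * wl ** 2
        np.testing.assert_allclose(detrend(x, short_grid), 0.0, atol=1e-9)

    def test_annihilates_constant(self, short_grid):
        np.testing.assert_allclose(
            detrend(np.full(short_grid.n_points, 5.0), short_grid), 0.0,
            atol=1e-12)

    def test_matches_independent_least_squares_fit(self, short_grid, rng):
        wl = short_grid.wavelengths
        band = np.exp(-0.5 * ((wl - 1100) / 15.0) ** 2)
        x = 1.0 + 0.001 * wl + band
        # oracle: monomial least squares via polyfit
        coef = np.polyfit(wl, x, 2)
        expected = x - np.polyval(coef, wl)
        np.testing.assert_allclose(detrend(x, short_grid), expected,
                                   atol=1e-9)

    def test_residual_orthogonal_to_polynomial_basis(self, short_grid, rng):
        x = rng.random(short_grid.n_points)
        res = detrend(x, short_grid)
        wl = short_grid.wavelengths
        for deg in range(3):
            basis = (wl - wl.mean()) ** deg
            assert abs(res @ basis) / np.linalg.norm(basis) < 1e-8

    def test_degree_too_high_rejected(self):
        g = WavelengthGrid(400.0, 404.0, 2.0)
        with pytest.raises(ValueError):
            detrend(np.ones(3), g, degree=3)


class TestGapSegmentDerivative:
    def test_constant_spectrum_maps_to_zero(self):
        t = parse_math_treatment("1,4,4,1")
        out = gap_segment_derivative(np.full(100, 2.5), t)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)
        assert out.size == 100 - t.window_loss

    @pytest.mark.parametrize("gap", [1, 3, 5])
    def test_ramp_gives_closed_form_constant(self, gap):
        # first gap difference of a + b*i is exactly b*gap
        b = 0.37
        x = 1.2 + b * np.arange(80)
        t = MathTreatment(1, gap, 1, 1)
        np.testing.assert_allclose(gap_segment_derivative(x, t), b * gap,
                                   atol=1e-12)

    def test_smoothing_preserves_ramp_slope(self):
        b = -0.2
        x = 5.0 + b * np.arange(100)
        t = parse_math_treatment("1,4,4,1")
        np.testing.assert_allclose(gap_segment_derivative(x, t), b * 4,
                                   atol=1e-12)

    def test_second_derivative_equals_naive_double_gap_difference(self, rng):
        x = rng.random(60)
        g = 3
        # oracle: two explicit gap-difference loops
        d1 = np.array([x[i + g] - x[i] for i in range(x.size - g)])
        d2 = np.array([d1[i + g] - d1[i] for i in range(d1.size - g)])
        out = gap_segment_derivative(x, MathTreatment(2, g, 1, 1))
        np.testing.assert_allclose(out, d2, atol=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 500), alpha=st.floats(-3.0, 3.0),
           beta=st.floats(-3.0, 3.0))
    def test_operator_is_linear(self, seed, alpha, beta):
        r = np.random.default_rng(seed)
        x, y = r.random(50), r.random(50)
        t = parse_math_treatment("2,3,3,2")
        lhs = gap_segment_derivative(alpha * x + beta * y, t)
        rhs = (alpha * gap_segment_derivative(x, t)
               + beta * gap_segment_derivative(y, t))
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_window_longer_than_spectrum_rejected(self):
        with pytest.raises(ValueError):
            gap_segment_derivative(np.ones(10), MathTreatment(2, 5, 5, 2))


class TestApplyTreatment:
    def test_identity_treatment_is_noop(self, small_dataset):
        spectra, _ = small_dataset
        out = apply_treatment(spectra, parse_math_treatment("0,0,1,1"))
        np.testing.assert_array_equal(out.absorbance, spectra.absorbance)

    def test_shape_contract_and_grid_trim(self, small_dataset):
        spectra, _ = small_dataset
        t = parse_math_treatment("2,5,5,2 snv_dt")
        out = apply_treatment(spectra, t)
        assert out.n_samples == spectra.n_samples
        assert out.grid.n_points == spectra.grid.n_points - t.window_loss
        assert out.grid.step_nm == spectra.grid.step_nm
        expected = treated_grid(spectra.grid, t)
        assert out.grid == expected

    def test_scatter_correction_restores_similarity(self, rng):
        # same chemistry, different per-sample gain/offset/slope artifacts
        grid = WavelengthGrid(1000.0, 1398.0, 2.0)
        wl = grid.wavelengths
        clean = np.exp(-0.5 * ((wl - 1200) / 30.0) ** 2)
        n = 12
        u = (wl - wl.mean()) / 200.0
        mat = np.stack([
            (1 + 0.3 * rng.standard_normal()) * clean
            + 0.2 * rng.standard_normal()
            + 0.1 * rng.standard_normal() * u
            for _ in range(n)])
        s = SpectralSet(grid, mat, [f"s{i}" for i in range(n)])
        treated = apply_treatment(s, MathTreatment(scatter="snv_dt"))

        def mean_corr(m):
            c = np.corrcoef(m)
            return c[np.triu_indices(n, 1)].mean()

        assert mean_corr(treated.absorbance) > mean_corr(s.absorbance)
        assert mean_corr(treated.absorbance) > 0.99

    def test_snv_dt_recovers_clean_treated_spectrum_as_noise_vanishes(self):
        grid = WavelengthGrid(1000.0, 1398.0, 2.0)
        wl = grid.wavelengths
        clean = 0.5 + np.exp(-0.5 * ((wl - 1200) / 30.0) ** 2)
        u = (wl - wl.mean()) / 200.0
        t = MathTreatment(scatter="snv_dt")
        ref = apply_treatment(SpectralSet(grid, clean[None], ["c"]), t)
        resid = []
        for eps in (1e-1, 1e-2, 1e-3, 0.0):
            corrupted = (1 + eps) * clean + eps + eps * u + eps * u ** 2
            out = apply_treatment(SpectralSet(grid, corrupted[None], ["c"]), t)
            resid.append(np.abs(out.absorbance - ref.absorbance).max())
        assert resid[0] > resid[1] > resid[2]
        assert resid[3] == pytest.approx(0.0, abs=1e-10)
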