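"""Scatter corrections and gap-segment derivative treatments against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mircoag.data_model import Spectra, WavenumberAxis
from mircoag.preprocess import (
    MATH_GRID,
    MSC,
    SNV,
    Detrend,
    GapSegmentDerivative,
    PreprocessSpec,
    apply_preprocess,
    detrend,
    math_treatment,
    snv,
    snv_detrend,
)


def _axis(n, lo=1000.0, hi=1500.0):
    return WavenumberAxis(np.linspace(lo, hi, n))


# ---------------------------------------------------------------------------
# oracles, written as plain loops independent of the implementation
# ---------------------------------------------------------------------------

def running_mean_oracle(row, window):
    out = []
    for i in range(len(row) - window + 1):
        out.append(sum(row[i:i + window]) / window)
    return np.array(out)


def gap_difference_oracle(row, gap):
    return np.array([row[i + gap] - row[i] for i in range(len(row) - gap)])


def math_treatment_oracle(row, code):
    d, gap, s1, s2 = code
    z = running_mean_oracle(row, s1)
    for _ in range(d):
        z = gap_difference_oracle(z, gap)
    return running_mean_oracle(z, s2)


def detrend_oracle(row, w):
    """Degree-2 polynomial regression residual via the normal equations."""
    V = np.vander((w - w.mean()) / w.std(), 3, increasing=True)
    beta = np.linalg.solve(V.T @ V, V.T @ row)
    return row - V @ beta


# ---------------------------------------------------------------------------
# SNV
# ---------------------------------------------------------------------------

class TestSNV:
    def test_three_point_example(self):
        out = SNV().fit_transform(np.array([[1.0, 2.0, 3.0]]))
        assert np.allclose(out, [[-1.0, 0.0, 1.0]])

    def test_output_rows_have_unit_sd(self, rng):
        out = SNV().fit_transform(rng.standard_normal((20, 60)) * 3 + 5)
        assert np.abs(out.std(axis=1, ddof=1) - 1.0).max() < 1e-10
        assert np.abs(out.mean(axis=1)).max() < 1e-10

    def test_constant_row_raises_with_row_index(self):
        X = np.ones((3, 10))
        X[0] += np.arange(10)
        X[2] += np.arange(10)
        with pytest.raises(ValueError, match="row 1"):
            SNV().fit_transform(X)

    @settings(max_examples=30, derandomize=True)
    @given(
        alpha=st.floats(0.01, 100.0),
        beta=st.floats(-50.0, 50.0),
        seed=st.integers(0, 2**16),
    )
    def test_affine_invariance(self, alpha, beta, seed):
        row = np.random.default_rng(seed).standard_normal((1, 30))
        assert np.allclose(SNV().fit_transform(alpha * row + beta),
                           SNV().fit_transform(row), atol=1e-8)


# ---------------------------------------------------------------------------
# Detrend
# ---------------------------------------------------------------------------

class TestDetrend:
    def test_annihilates_quadratic(self):
        w = np.linspace(1000, 1500, 80)
        row = 2.0 - 0.003 * w + 1.5e-6 * w**2
        out = Detrend(wavenumbers=w).fit_transform(row[None, :])
        assert np.abs(out).max() < 1e-8 * max(1.0, np.abs(row).max())

    def test_residual_orthogonal_to_basis(self, rng):
        w = np.linspace(1000, 1500, 60)
        X = rng.standard_normal((4, 60))
        out = Detrend(wavenumbers=w).fit_transform(X)
        for basis in (np.ones_like(w), w, w**2):
            b = (basis - basis.mean()) / (basis.std() or 1.0)
            assert np.abs(out @ b).max() < 1e-7

    def test_matches_normal_equations_oracle(self, rng):
        w = np.linspace(900, 3000, 120)
        row = rng.standard_normal(120)
        out = Detrend(wavenumbers=w).fit_transform(row[None, :])[0]
        assert np.abs(out - detrend_oracle(row, w)).max() < 1e-8

    def test_idempotent(self, rng):
        w = np.linspace(1000, 1500, 50)
        X = rng.standard_normal((3, 50))
        t = Detrend(wavenumbers=w)
        once = t.fit_transform(X)
        assert np.abs(t.fit_transform(once) - once).max() < 1e-10

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3 points"):
            Detrend().fit_transform(np.ones((1, 2)))


class TestSNVDetrend:
    def test_equals_explicit_composition(self, small_spectra):
        combined = snv_detrend(small_spectra)
        explicit = detrend(snv(small_spectra))
        assert np.abs(combined.absorbance - explicit.absorbance).max() < 1e-12

    def test_order_matters_in_general(self, rng):
        w = np.linspace(1000, 1500, 40)
        row = 0.5 * ((w - 1200) / 100) ** 2 + rng.standard_normal(40)
        spectra = Spectra(WavenumberAxis(w), row[None, :], ["x"])
        a = detrend(snv(spectra)).absorbance
        b = snv(detrend(spectra)).absorbance
        assert np.abs(a - b).max() > 1e-3


# ---------------------------------------------------------------------------
# MSC
# ---------------------------------------------------------------------------

class TestMSC:
    def test_reference_row_unchanged(self, rng):
        ref = rng.standard_normal(50) + 2.0
        out = MSC(reference=ref).fit_transform(ref[None, :])
        assert np.abs(out - ref).max() < 1e-10

    def test_inverts_affine_distortion(self, rng):
        ref = rng.standard_normal(50) + 2.0
        out = MSC(reference=ref).fit_transform((2.0 * ref + 5.0)[None, :])
        assert np.abs(out - ref).max() < 1e-10

    def test_regression_matches_closed_form(self, rng):
        ref = rng.standard_normal(80) + 1.0
        row = 1.5 * ref + 2.0 + 0.3 * rng.standard_normal(80)
        # simple-linear-regression closed form for x ~ a + b*ref
        b = np.cov(row, ref, ddof=1)[0, 1] / np.var(ref, ddof=1)
        a = row.mean() - b * ref.mean()
        out = MSC(reference=ref).fit_transform(row[None, :])[0]
        assert np.abs(out - (row - a) / b).max() < 1e-10

    def test_affine_family_collapses_to_mean_shape(self, rng):
        # rows are affine distortions of one shape; MSC must restore them all,
        # so the corrected mean equals the learned (mean-derived) reference
        shape = rng.standard_normal(40) + 3.0
        b = rng.uniform(0.5, 2.0, 10)
        a = rng.uniform(-1.0, 1.0, 10)
        X = a[:, None] + b[:, None] * shape
        t = MSC().fit(X)
        corrected = t.transform(X)
        assert np.abs(corrected - t.reference_).max() < 1e-8
        assert np.abs(corrected.mean(axis=0) - t.reference_).max() < 1e-8

    def test_near_zero_slope_raises(self, rng):
        ref = np.linspace(0.0, 1.0, 30)
        flat = np.full((1, 30), 0.7) + 1e-12 * np.arange(30)
        with pytest.raises(ValueError, match="slope"):
            MSC(reference=ref).fit_transform(flat)


# ---------------------------------------------------------------------------
# math treatments
# ---------------------------------------------------------------------------

class TestMathTreatment:
    def test_identity_code(self, small_spectra):
        out = math_treatment(small_spectra, (0, 0, 1, 1))
        assert np.array_equal(out.absorbance, small_spectra.absorbance)
        assert np.array_equal(out.axis.values, small_spectra.axis.values)

    def test_first_difference_of_linear_is_constant(self):
        row = 0.5 * np.arange(40.0) + 3.0
        out = GapSegmentDerivative(1, 4, 4, 1).fit_transform(row[None, :])[0]
        assert np.abs(out - out[0]).max() < 1e-10
        assert out[0] == pytest.approx(0.5 * 4)  # gap of 4 index steps

    def test_second_difference_of_linear_is_zero(self):
        row = -1.2 * np.arange(50.0) + 7.0
        out = GapSegmentDerivative(2, 5, 5, 1).fit_transform(row[None, :])[0]
        assert np.abs(out).max() < 1e-10

    @pytest.mark.parametrize("code", MATH_GRID)
    def test_matches_loop_oracle(self, code, rng):
        row = rng.standard_normal(80)
        expected = math_treatment_oracle(row, code)
        d, gap, s1, s2 = code
        out = GapSegmentDerivative(d, gap, s1, s2).fit_transform(row[None, :])[0]
        assert out.shape == expected.shape
        assert np.abs(out - expected).max() < 1e-10

    def test_linearity(self, rng):
        x, y = rng.standard_normal(60), rng.standard_normal(60)
        t = GapSegmentDerivative(2, 5, 5, 1)
        combined = t.fit_transform((2.5 * x - 1.5 * y)[None, :])
        parts = 2.5 * t.fit_transform(x[None, :]) - 1.5 * t.fit_transform(y[None, :])
        assert np.abs(combined - parts).max() < 1e-10

    def test_axis_shrinks_consistently(self, small_spectra):
        out = math_treatment(small_spectra, (1, 4, 4, 1))
        assert len(out.axis) == out.absorbance.shape[1]
        assert out.absorbance.shape[1] == small_spectra.n_points - (4 - 1) - 4
        # trimmed axis stays inside the original span
        assert out.axis.values[0] >= small_spectra.axis.values[0]
        assert out.axis.values[-1] <= small_spectra.axis.values[-1]

    def test_window_exceeding_row_raises(self):
        with pytest.raises(ValueError, match="window|gap"):
            GapSegmentDerivative(0, 0, 50, 1).fit_transform(np.ones((1, 10)))


# ---------------------------------------------------------------------------
# combined spec application
# ---------------------------------------------------------------------------

class TestApplyPreprocess:
    def test_none_identity(self, small_spectra):
        out = apply_preprocess(small_spectra, PreprocessSpec("none", (0, 0, 1, 1)))
        assert np.array_equal(out.absorbance, small_spectra.absorbance)

    def test_equals_manual_composition(self, small_spectra):
        spec = PreprocessSpec("snv", (1, 4, 4, 1))
        out = apply_preprocess(small_spectra, spec)
        manual = math_treatment(snv(small_spectra), (1, 4, 4, 1))
        assert np.array_equal(out.absorbance, manual.absorbance)

    def test_msc_requires_reference(self, small_spectra):
        with pytest.raises(ValueError, match="reference"):
            apply_preprocess(small_spectra, PreprocessSpec("msc", (0, 0, 1, 1)))

    @pytest.mark.parametrize("scatter,math_code", [
        ("snv", "1,4,4,1"), ("d", "0,0,1,1"), ("snv", "0,0,1,1"),
    ])
    def test_reported_best_specs_are_representable(self, scatter, math_code):
        spec = PreprocessSpec.parse(scatter, math_code)
        assert spec.math in MATH_GRID

    @pytest.mark.parametrize("scatter,math", [
        ("bogus", (0, 0, 1, 1)),
        ("snv", (0, 2, 1, 1)),     # zero derivative with nonzero gap
        ("snv", (1, 0, 1, 1)),     # derivative without a gap
        ("snv", (3, 1, 1, 1)),     # unsupported derivative order
        ("snv", (0, 0, 0, 1)),     # smoothing window < 1
    ])
    def test_invalid_specs_rejected(self, scatter, math):
        with pytest.raises(ValueError):
            PreprocessSpec(scatter, math)
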