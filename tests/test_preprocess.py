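"""Preprocessing: rubber-band baseline, SG derivatives, VN, pipeline composition."""

import numpy as np
import pytest

from ftirfp import (
    PipelineSpec,
    Spectrum,
    apply_pipeline,
    extract_window,
    gaussian_band,
    rubberband_correct,
    savgol_derivative,
    vector_normalize,
)
from ftirfp.preprocess import (
    GridError,
    NormalizationError,
    rubberband_baseline,
)
from ftirfp.spectra import FINGERPRINT

from conftest import make_set


# ---------------------------------------------------------------------------
# Rubber-band baseline
# ---------------------------------------------------------------------------

def recursive_rubberband_oracle(x, y):
    """Independent O(n^2) baseline: recursively find the point furthest below the chord."""

    def recurse(i, j, out):
        if j - i < 2:
            return
        chord = y[i] + (y[j] - y[i]) * (x[i:j + 1] - x[i]) / (x[j] - x[i])
        below = y[i:j + 1] - chord
        k = int(np.argmin(below))
        if below[k] < -1e-15:
            k += i
            out.add(k)
            recurse(i, k, out)
            recurse(k, j, out)

    vertices = {0, x.size - 1}
    recurse(0, x.size - 1, vertices)
    idx = np.array(sorted(vertices))
    return np.interp(x, x[idx], y[idx])


def test_rubberband_straight_line_gives_zero():
    x = np.arange(0.0, 100.0, 2.0)
    s = Spectrum(x, 3.0 + 0.5 * x, donor_id="T")
    assert np.allclose(rubberband_correct(s).absorbance, 0.0, atol=1e-12)


def test_rubberband_peak_with_zero_endpoints_unchanged():
    x = np.arange(0.0, 200.0, 1.0)
    y = gaussian_band(x, 100.0, 5.0, 1.0)  # tails are exactly zero at the ends
    s = Spectrum(x, y, donor_id="T")
    assert np.allclose(rubberband_correct(s).absorbance, y, atol=1e-12)


def test_rubberband_matches_brute_force_hull_oracle():
    rng = np.random.default_rng(8)
    x = np.arange(0.0, 300.0, 2.0)
    for _ in range(10):
        y = (
            gaussian_band(x, rng.uniform(80, 220), rng.uniform(10, 40), rng.uniform(0.5, 2))
            + rng.uniform(-0.01, 0.01) * x
            + rng.uniform(0, 1)
            + 1e-4 * rng.normal(size=x.size)
        )
        assert np.allclose(
            rubberband_baseline(x, y), recursive_rubberband_oracle(x, y), atol=1e-10
        )


def test_rubberband_output_nonnegative_guard_and_idempotent():
    rng = np.random.default_rng(1)
    x = np.arange(0.0, 200.0, 2.0)
    y = gaussian_band(x, 90.0, 30.0, 1.0) + 0.002 * x + rng.normal(0, 0.01, x.size)
    once = rubberband_correct(Spectrum(x, y, donor_id="T"))
    assert once.absorbance.min() >= -1e-12
    twice = rubberband_correct(once)
    assert np.allclose(once.absorbance, twice.absorbance, atol=1e-12)


# ---------------------------------------------------------------------------
# Savitzky–Golay derivatives
# ---------------------------------------------------------------------------

def test_savgol_constant_is_zero_both_orders():
    x = np.arange(0.0, 100.0, 2.0)
    s = Spectrum(x, np.full(x.size, 2.5), donor_id="T")
    for order in (1, 2):
        out = savgol_derivative(s, order)
        assert np.allclose(out.absorbance, 0.0, atol=1e-12)
        assert out.n_points == s.n_points - 14  # 7 points trimmed per edge


def test_savgol_second_derivative_exact_on_quadratic():
    x = np.arange(900.0, 1200.0, 2.0)
    s = Spectrum(x, x**2, donor_id="T")
    out = savgol_derivative(s, 2)
    assert np.allclose(out.absorbance, 2.0, atol=1e-9)


def test_savgol_first_derivative_matches_polyfit_oracle():
    """SG output equals an independent per-window quadratic least-squares fit."""
    x = np.arange(0.0, 400.0, 2.0)
    y = np.sin(0.05 * x)
    out = savgol_derivative(Spectrum(x, y, donor_id="T"), 1)
    half = 7
    oracle = []
    for c in range(half, x.size - half):
        xi = x[c - half : c + half + 1]
        coeffs = np.polyfit(xi - x[c], y[c - half : c + half + 1], 2)
        oracle.append(coeffs[1])  # derivative of the local fit at the center
    oracle = np.array(oracle)
    assert np.allclose(out.absorbance, oracle, atol=1e-10)
    # and the smoothed derivative tracks the analytic one
    truth = 0.05 * np.cos(0.05 * out.wavenumbers)
    bound = np.max(np.abs(oracle - 0.05 * np.cos(0.05 * x[half:-half]))) + 1e-12
    assert np.max(np.abs(out.absorbance - truth)) <= bound


def test_savgol_rejects_nonuniform_grid_and_long_window():
    x = np.array([0.0, 1.0, 2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0, 13.0, 14.0])
    with pytest.raises(GridError):
        savgol_derivative(Spectrum(x, np.zeros(15), donor_id="T"), 1)
    short = Spectrum(np.arange(10.0), np.zeros(10), donor_id="T")
    with pytest.raises(ValueError, match="exceeds"):
        savgol_derivative(short, 1)


# ---------------------------------------------------------------------------
# Vector normalization
# ---------------------------------------------------------------------------

def test_vector_normalize_closed_form_and_scale_invariance():
    s = Spectrum(np.array([0.0, 1.0]), np.array([3.0, 4.0]), donor_id="T")
    assert np.allclose(vector_normalize(s).absorbance, [0.6, 0.8])
    scaled = Spectrum(s.wavenumbers, 17.0 * s.absorbance, donor_id="T")
    assert np.allclose(
        vector_normalize(s).absorbance, vector_normalize(scaled).absorbance
    )


def test_vector_normalize_unit_norm_on_random_spectra():
    rng = np.random.default_rng(0)
    x = np.arange(0.0, 100.0)
    for _ in range(100):
        s = Spectrum(x, rng.normal(size=x.size), donor_id="T")
        assert np.linalg.norm(vector_normalize(s).absorbance) == pytest.approx(
            1.0, abs=1e-12
        )


def test_vector_normalize_zero_vector_rejected():
    s = Spectrum(np.arange(4.0), np.zeros(4), donor_id="T")
    with pytest.raises(NormalizationError):
        vector_normalize(s)


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------

def test_pipeline_names_cover_the_evaluation_ladder():
    for name in ("bc", "vn", "d1", "d1+vn", "d2", "d2+fcbf"):
        spec = PipelineSpec.from_name(name, "fingerprint")
        assert spec.name == name
    assert PipelineSpec.from_name("d2+fcbf", "fingerprint").fcbf
    with pytest.raises(ValueError):
        PipelineSpec.from_name("pca", "fingerprint")
    with pytest.raises(ValueError):
        PipelineSpec(region="fingerprint", steps=("sg_deriv_1", "sg_deriv_2"))


def test_pipeline_vn_identity_on_unit_norm_rows():
    grid = 900.0 + 2.0 * np.arange(451)
    rng = np.random.default_rng(0)
    m = rng.normal(size=(3, 451))
    m /= np.linalg.norm(m, axis=1, keepdims=True)
    s = make_set(grid, m)
    out = apply_pipeline(s, PipelineSpec.from_name("vn", "fingerprint"))
    assert np.allclose(out.matrix, m, atol=1e-12)


def test_pipeline_derivative_edge_trim_without_margin():
    grid = 900.0 + 2.0 * np.arange(451)  # no room for a margin
    s = make_set(grid, np.random.default_rng(1).normal(size=(2, 451)))
    out = apply_pipeline(s, PipelineSpec.from_name("d2", "fingerprint"))
    assert out.n_points == 451 - 14


def test_pipeline_derivative_margin_preserves_window(donor_set):
    out = apply_pipeline(donor_set, PipelineSpec.from_name("d2", "fingerprint"))
    assert out.grid[0] == 900.0 and out.grid[-1] == 1800.0
    assert out.n_points == 451


def test_pipeline_composition_matches_sequential_ops(donor_set):
    combined = apply_pipeline(donor_set, PipelineSpec.from_name("d1+vn", "fingerprint"))
    manual = apply_pipeline(donor_set, PipelineSpec.from_name("d1", "fingerprint"))
    manual_rows = np.array(
        [vector_normalize(manual.row(i)).absorbance for i in range(manual.n_spectra)]
    )
    assert np.allclose(combined.matrix, manual_rows, atol=1e-12)


def test_pipeline_row_order_invariance(donor_set):
    perm = np.random.default_rng(3).permutation(donor_set.n_spectra)
    spec = PipelineSpec.from_name("d2", "fingerprint")
    a = apply_pipeline(donor_set, spec)
    b = apply_pipeline(donor_set.subset(perm), spec)
    assert np.allclose(a.matrix[perm], b.matrix)


def test_pipeline_ending_in_vn_removes_multiplicative_scaling(donor_set):
    scaled = make_set(
        donor_set.grid,
        donor_set.matrix * np.linspace(0.5, 2.0, donor_set.n_spectra)[:, None],
        donors=donor_set.meta["donor_id"].tolist(),
        groups=[g.value for g in donor_set.meta["group"]],
    )
    spec = PipelineSpec.from_name("d1+vn", "fingerprint")
    assert np.allclose(
        apply_pipeline(donor_set, spec).matrix,
        apply_pipeline(scaled, spec).matrix,
        atol=1e-10,
    )
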