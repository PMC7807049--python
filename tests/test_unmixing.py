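import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import lsq_linear

from senequant.library import SpectralLibrary
from senequant.spectra import Spectrum
from senequant.unmixing import (
    SpectralUnmixer,
    preprocess,
    summarize_cells,
    unmix,
)


def _spectrum(grid, values, **meta):
    return Spectrum(grid, values, meta)


# -- preprocess -------------------------------------------------------------


def test_preprocess_self_subtraction_gives_zero(grid):
    vals = 1.0 + np.sin(grid / 30.0) ** 2
    cell = _spectrum(grid, vals, role="cell")
    bg = _spectrum(grid, vals.copy(), role="background")
    out = preprocess(cell, [bg])
    np.testing.assert_allclose(out.intensities, 0.0, atol=1e-12)
    assert out.meta["preprocessed"] is True


def test_preprocess_crops_to_working_range():
    wl = np.arange(350.0, 901.0)
    cell = _spectrum(wl, np.ones_like(wl))
    bg = _spectrum(wl, np.zeros_like(wl))
    out = preprocess(cell, [bg])
    assert out.wavelengths_nm[0] >= 400.0
    assert out.wavelengths_nm[-1] <= 850.0


def test_preprocess_output_never_negative(grid):
    rng = np.random.default_rng(0)
    cell = _spectrum(grid, rng.normal(0.0, 1.0, grid.size))
    bg = _spectrum(grid, np.full_like(grid, 0.5))
    out = preprocess(cell, [bg])
    assert (out.intensities >= 0).all()


def test_preprocess_requires_backgrounds_and_coverage(grid):
    cell = _spectrum(grid, np.ones_like(grid))
    with pytest.raises(ValueError, match="background"):
        preprocess(cell, [])
    narrow = _spectrum(np.arange(450.0, 700.0), np.ones(250))
    bg = _spectrum(np.arange(450.0, 700.0), np.zeros(250))
    with pytest.raises(ValueError, match="span"):
        preprocess(narrow, [bg])


# -- unmix ------------------------------------------------------------------


def test_unmix_single_component_identity(truth_library, grid):
    fad = truth_library["FAD"].evaluate(grid)
    result = unmix(_spectrum(grid, 2.0 * fad), truth_library)
    np.testing.assert_allclose(result.coefficients, [0.0, 0.0, 2.0, 0.0], atol=1e-9)
    assert result.residual_l2 == pytest.approx(0.0, abs=1e-9)
    assert result.r_squared == pytest.approx(1.0)


def test_unmix_zero_spectrum(truth_library, grid):
    result = unmix(_spectrum(grid, np.zeros_like(grid)), truth_library)
    np.testing.assert_array_equal(result.coefficients, 0.0)
    assert result.total_autofluorescence == 0.0


def test_unmix_underdetermined_error(truth_library):
    tiny = _spectrum(np.array([500.0, 600.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError, match="underdetermined"):
        unmix(tiny, truth_library)


def test_unmix_matches_bounded_lsq_oracle_and_truth(truth_library, grid):
    """NNLS agrees with an independent bounded least-squares solver, and
    recovers the generating coefficients from 1%-noise mixtures."""
    rng = np.random.default_rng(11)
    D = truth_library.design_matrix(grid)
    a_true = np.array([0.5, 1.0, 1.5, 2.0])
    clean = D @ a_true
    for _ in range(5):
        noisy = clean + rng.normal(0.0, 0.01 * clean.max(), grid.size)
        result = unmix(_spectrum(grid, noisy), truth_library)
        oracle = lsq_linear(D, noisy, bounds=(0.0, np.inf), method="bvls")
        np.testing.assert_allclose(result.coefficients, oracle.x, atol=1e-6)
        np.testing.assert_allclose(result.coefficients, a_true, rtol=0.05)
        assert (result.coefficients >= 0).all()


def test_unmix_linearity(truth_library, grid):
    D = truth_library.design_matrix(grid)
    mix = D @ np.array([0.3, 0.7, 1.1, 0.9])
    r1 = unmix(_spectrum(grid, mix), truth_library)
    r3 = unmix(_spectrum(grid, 3.0 * mix), truth_library)
    np.testing.assert_allclose(r3.coefficients, 3.0 * r1.coefficients, rtol=1e-8)
    np.testing.assert_allclose(
        r3.total_autofluorescence, 3.0 * r1.total_autofluorescence, rtol=1e-12
    )


def test_unmix_component_order_independence(truth_library, grid):
    D = truth_library.design_matrix(grid)
    mix = D @ np.array([0.3, 0.7, 1.1, 0.9])
    permuted = SpectralLibrary(
        [truth_library[n] for n in ("lipopigment", "FAD", "NADH_free", "NADH_bound")],
        truth_library.domain,
    )
    r = unmix(_spectrum(grid, mix), truth_library)
    rp = unmix(_spectrum(grid, mix), permuted)
    for name in truth_library.names:
        assert rp.coefficient(name) == pytest.approx(r.coefficient(name), abs=1e-9)
        assert rp.integral(name) == pytest.approx(r.integral(name), rel=1e-9)


def test_integrated_intensities_bounded_by_total(truth_library, grid):
    """Sum of component integrals stays within a small tolerance of the
    total autofluorescence for noiseless mixtures (exact decomposition)."""
    D = truth_library.design_matrix(grid)
    mix = D @ np.array([0.5, 0.6, 0.7, 0.8])
    r = unmix(_spectrum(grid, mix), truth_library)
    assert r.integrated_intensity.sum() == pytest.approx(
        r.total_autofluorescence, rel=1e-9
    )


# -- summaries --------------------------------------------------------------


def test_summarize_cells_basic(truth_library, grid):
    D = truth_library.design_matrix(grid)
    results = [
        unmix(_spectrum(grid, D @ np.array([0.0, 0.0, 0.0, float(k)])), truth_library)
        for k in (1, 2, 3)
    ]
    lipo_int = truth_library["lipopigment"].evaluate(grid)
    unit = float(np.trapezoid(lipo_int, grid))
    mean, sd, n = summarize_cells(results, metric="coefficient:lipopigment")
    assert (mean, sd, n) == (pytest.approx(2.0), pytest.approx(1.0), 3)
    mean_i, _, _ = summarize_cells(results, metric="integral:lipopigment")
    assert mean_i == pytest.approx(2.0 * unit, rel=1e-9)


def test_summarize_single_cell_sd_zero(truth_library, grid):
    r = unmix(_spectrum(grid, truth_library.design_matrix(grid) @ np.ones(4)), truth_library)
    mean, sd, n = summarize_cells([r], metric="total_af")
    assert sd == 0.0 and n == 1 and mean == pytest.approx(r.total_autofluorescence)


def test_summarize_zero_component_propagates(truth_library, grid):
    fad_only = truth_library.design_matrix(grid) @ np.array([0.0, 0.0, 1.0, 0.0])
    results = [unmix(_spectrum(grid, fad_only), truth_library) for _ in range(3)]
    mean, sd, _ = summarize_cells(results, metric="integral:lipopigment")
    assert mean == pytest.approx(0.0, abs=1e-9)


def test_summarize_empty_errors():
    with pytest.raises(ValueError):
        summarize_cells([])


# -- sklearn-style transformer ---------------------------------------------


def test_spectral_unmixer_transformer(truth_library, grid):
    A = np.abs(np.random.default_rng(5).normal(1.0, 0.3, size=(6, 4)))
    X = A @ truth_library.design_matrix(grid).T
    est = SpectralUnmixer(truth_library).fit(X, wavelengths_nm=grid)
    coeffs = est.transform(X)
    np.testing.assert_allclose(coeffs, A, atol=1e-8)
    assert est.component_names_ == truth_library.names


def test_spectral_unmixer_sklearn_compatible(truth_library, grid):
    from sklearn.base import clone

    est = SpectralUnmixer(truth_library)
    cloned = clone(est)
    assert cloned.get_params()["library"].names == truth_library.names
    with pytest.raises(ValueError, match="not fitted"):
        cloned.transform(np.ones((1, grid.size)))


@given(scale=st.floats(min_value=0.1, max_value=50.0))
def test_unmixer_scale_equivariance(scale):
    """transform(c*X) = c*transform(X) for c >= 0 (noiseless linearity)."""
    from senequant import make_default_library_truth
    from senequant.simulate import default_grid

    lib = make_default_library_truth()
    grid = default_grid()
    X = (np.ones((1, 4)) @ lib.design_matrix(grid).T)
    est = SpectralUnmixer(lib).fit(X, wavelengths_nm=grid)
    np.testing.assert_allclose(
        est.transform(scale * X), scale * est.transform(X), rtol=1e-6, atol=1e-9
    )
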