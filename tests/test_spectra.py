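import numpy as np
import pytest

from omicblup import (
    SpectraMatrix,
    mi_kernel,
    nir_kernel,
    normalize_columns,
    savgol_first_derivative,
)


def make_spectra(values, kind="MI", axis=None):
    values = np.asarray(values, float)
    if axis is None:
        axis = np.arange(values.shape[1], dtype=float)
    return SpectraMatrix(
        [f"p{i}" for i in range(values.shape[0])], axis, values, kind
    )


class TestNormalize:
    def test_simple_column(self):
        sp = normalize_columns(make_spectra([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(sp.values[:, 0], [-1, 0, 1])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        sp = normalize_columns(make_spectra(rng.normal(size=(20, 10))))
        again = normalize_columns(sp)
        np.testing.assert_allclose(again.values, sp.values, atol=1e-12)

    def test_columnwise_moments_match_oracle(self):
        rng = np.random.default_rng(1)
        sp = normalize_columns(make_spectra(rng.normal(2, 3, size=(20, 10))))
        np.testing.assert_allclose(sp.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(sp.values.std(axis=0, ddof=1), 1.0)

    def test_zero_variance_columns_dropped(self):
        vals = np.column_stack([np.ones(5), np.arange(5.0)])
        sp = normalize_columns(make_spectra(vals))
        assert sp.n_features == 1

    def test_all_constant_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            normalize_columns(make_spectra(np.ones((5, 3))))


class TestSavgolDerivative:
    def test_linear_spectrum_exact_slope(self):
        k = np.arange(30.0)
        sp = make_spectra((3 + 2 * k)[None, :].repeat(3, axis=0), kind="NIR")
        out = savgol_first_derivative(sp, window=7, polyorder=2)
        np.testing.assert_allclose(out.values, 2.0, atol=1e-10)

    def test_constant_spectrum_zero(self):
        sp = make_spectra(np.full((2, 25), 5.0), kind="NIR")
        out = savgol_first_derivative(sp, window=5, polyorder=2)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_quadratic_interior_derivative(self):
        k = np.arange(40.0)
        sp = make_spectra((k**2)[None, :], kind="NIR")
        out = savgol_first_derivative(sp, window=5, polyorder=2)
        # exact polynomial reproduction, including the fitted edges
        np.testing.assert_allclose(out.values[0], 2 * k, atol=1e-8)

    def test_parameter_validation(self):
        sp = make_spectra(np.zeros((2, 20)), kind="NIR")
        with pytest.raises(ValueError):
            savgol_first_derivative(sp, window=6, polyorder=2)
        with pytest.raises(ValueError):
            savgol_first_derivative(sp, window=31, polyorder=2)
        with pytest.raises(ValueError, match="NIR"):
            savgol_first_derivative(make_spectra(np.zeros((2, 20))), 5, 2)


class TestMiKernel:
    def test_single_feature_outer_product(self):
        sp = normalize_columns(make_spectra([[1.0], [2.0], [3.0]]))
        k = mi_kernel(sp)
        np.testing.assert_allclose(
            k.values, [[1, 0, -1], [0, 0, 0], [-1, 0, 1]], atol=1e-12
        )

    def test_trace_is_n_minus_one(self):
        rng = np.random.default_rng(3)
        sp = normalize_columns(make_spectra(rng.normal(size=(15, 40))))
        k = mi_kernel(sp)
        assert np.trace(k.values) == pytest.approx(14.0)

    def test_matches_cross_product_oracle(self):
        rng = np.random.default_rng(4)
        sp = normalize_columns(make_spectra(rng.normal(size=(15, 40))))
        k = mi_kernel(sp)
        m = sp.values
        np.testing.assert_allclose(k.values, m @ m.T / 40, atol=1e-12)

    def test_requires_normalisation(self):
        with pytest.raises(ValueError, match="normalis"):
            mi_kernel(make_spectra(np.random.default_rng(0).normal(size=(5, 4))))


class TestNirKernel:
    def test_rank_one_spectra_single_component(self):
        rng = np.random.default_rng(5)
        curve = rng.normal(size=30)
        coefs = rng.normal(size=10)
        sp = normalize_columns(make_spectra(np.outer(coefs, curve), kind="NIR"))
        k = nir_kernel(sp)
        assert k.meta["t_components"] == 1
        assert k.meta["explained_variance"][0] == pytest.approx(1.0)

    def test_var_target_one_keeps_full_rank(self):
        rng = np.random.default_rng(6)
        sp = normalize_columns(make_spectra(rng.normal(size=(12, 30)), kind="NIR"))
        k = nir_kernel(sp, var_target=1.0)
        assert k.meta["t_components"] == 11  # rank of a centred 12-row matrix

    def test_low_rank_eight_detected_and_matches_eigen_oracle(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=(40, 8)) * np.linspace(4, 1.5, 8)
        load = rng.normal(size=(8, 50))
        vals = scores @ load + 1e-6 * rng.normal(size=(40, 50))
        sp = normalize_columns(make_spectra(vals, kind="NIR"))
        k = nir_kernel(sp, var_target=0.99)
        assert k.meta["t_components"] == 8
        x = sp.values - sp.values.mean(axis=0)
        w, u = np.linalg.eigh(x @ x.T)
        w, u = w[::-1], u[:, ::-1]
        m = u[:, :8] * np.sqrt(np.clip(w[:8], 0, None))
        np.testing.assert_allclose(k.values, m @ m.T / 8, atol=1e-7)

    def test_truncation_converges_to_full_kernel(self):
        rng = np.random.default_rng(8)
        sp = normalize_columns(make_spectra(rng.normal(size=(15, 25)), kind="NIR"))
        x = sp.values - sp.values.mean(axis=0)
        full = nir_kernel(sp, var_target=1.0)
        t_full = full.meta["t_components"]
        dists = []
        for target in (0.6, 0.8, 0.95, 1.0):
            k = nir_kernel(sp, var_target=target)
            t = k.meta["t_components"]
            dists.append(
                np.linalg.norm(k.values * t - full.values * t_full)
            )
        assert all(a >= b - 1e-9 for a, b in zip(dists, dists[1:]))

    def test_var_target_validation(self):
        rng = np.random.default_rng(9)
        sp = normalize_columns(make_spectra(rng.normal(size=(5, 6)), kind="NIR"))
        with pytest.raises(ValueError):
            nir_kernel(sp, var_target=0.0)


def test_kernels_invariant_to_plot_permutation():
    rng = np.random.default_rng(10)
    vals = rng.normal(size=(12, 20))
    sp = normalize_columns(make_spectra(vals))
    k1 = mi_kernel(sp)
    perm = rng.permutation(12)
    sp2 = normalize_columns(
        SpectraMatrix(
            [f"p{i}" for i in perm], sp.feature_axis, vals[perm], "MI"
        )
    )
    k2 = mi_kernel(sp2).reindex(k1.entity_ids)
    np.testing.assert_allclose(k2.values, k1.values, atol=1e-12)
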