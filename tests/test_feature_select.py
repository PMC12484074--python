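"""Correlation analysis, PCA summarisation and RFE band selection."""

import numpy as np
import pytest

from stresskit import (
    SpectralLibrary,
    correlation_matrix,
    generate_band_recovery_library,
    pca_fit,
    pca_transform,
    prune_redundant,
    rfe_select,
    write_spectral_library,
    read_spectral_library,
)
from stresskit.errors import ContractError, InsufficientDataError, ParameterError
from stresskit.feature_select import LinearMarginImportance


def library_from(matrix, wavelengths=None, labels=None):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    wl = (
        np.asarray(wavelengths, dtype=float)
        if wavelengths is not None
        else np.arange(matrix.shape[1], dtype=float) * 10 + 437
    )
    return SpectralLibrary(wavelengths=wl, reflectance=matrix, labels=labels)


def pearson_naive(x, y):
    xm, ym = x.mean(), y.mean()
    num = ((x - xm) * (y - ym)).sum()
    den = np.sqrt(((x - xm) ** 2).sum()) * np.sqrt(((y - ym) ** 2).sum())
    return num / den


class TestCorrelation:
    def test_perfect_linear_dependence(self, rng):
        x = rng.random(20)
        lib = library_from(np.column_stack([x, 2 * x, -x + 1]))
        cm = correlation_matrix(lib)
        assert cm.r[0, 1] == pytest.approx(1.0)
        assert cm.r[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(cm.r, cm.r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(cm.r), 1.0, atol=1e-12)

    def test_matches_naive_double_loop(self, rng):
        x = rng.random((20, 5))
        cm = correlation_matrix(library_from(x))
        for i in range(5):
            for j in range(5):
                assert cm.r[i, j] == pytest.approx(pearson_naive(x[:, i], x[:, j]), abs=1e-12)

    def test_insufficient_samples(self):
        with pytest.raises(InsufficientDataError):
            correlation_matrix(library_from([[0.1, 0.2]]))


class TestPrune:
    def test_duplicate_band_dropped(self, rng):
        x = rng.random(30)
        lib = library_from(np.column_stack([x, x + 1e-9, rng.random(30)]))
        retained = prune_redundant(correlation_matrix(lib), 0.95)
        assert len(retained) == 2 and retained[0] == 437.0

    def test_uncorrelated_bands_all_retained(self, rng):
        lib = library_from(rng.random((200, 6)))
        retained = prune_redundant(correlation_matrix(lib), 0.95)
        assert len(retained) == 6

    def test_no_retained_pair_exceeds_threshold(self, rng):
        base = rng.random((50, 4))
        mix = base @ rng.random((4, 12)) + 0.05 * rng.random((50, 12))
        cm = correlation_matrix(library_from(mix))
        retained = prune_redundant(cm, 0.9)
        idx = [np.argmin(np.abs(cm.wavelengths - w)) for w in retained]
        for a in idx:
            for b in idx:
                if a != b:
                    assert abs(cm.r[a, b]) <= 0.9

    def test_threshold_validation(self, rng):
        cm = correlation_matrix(library_from(rng.random((10, 3))))
        with pytest.raises(ParameterError):
            prune_redundant(cm, 1.5)


class TestPCA:
    def test_planar_data_fully_explained_by_two_components(self, rng):
        t = rng.normal(size=(40, 2))
        basis = rng.normal(size=(2, 8))
        lib = library_from(t @ basis + 0.5)
        model = pca_fit(lib, k=2)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_full_rank_reconstruction(self, rng):
        x = rng.random((15, 6))
        lib = library_from(x)
        model = pca_fit(lib, k=6)
        z = pca_transform(model, lib)
        np.testing.assert_allclose(z @ model.loadings.T + model.mean, x, atol=1e-9)
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(6), atol=1e-9
        )

    def test_pc1_variance_matches_eigendecomposition(self, small_library):
        model = pca_fit(small_library, k=3)
        x = small_library.reflectance
        cov = np.cov(x, rowvar=False, ddof=1)
        top = np.linalg.eigvalsh(cov).max()
        pc1_var = model.explained_variance_ratio[0] * np.trace(cov)
        assert pc1_var == pytest.approx(top, rel=1e-9)

    def test_scores_centred(self, small_library):
        model = pca_fit(small_library, k=4)
        z = pca_transform(model, small_library)
        assert np.abs(z.mean(axis=0)).max() < 1e-9

    def test_k_too_large(self, small_library):
        with pytest.raises(ParameterError):
            pca_fit(small_library, k=small_library.n_samples + 1)


class TestRFE:
    def test_identity_selection_when_k_equals_n_bands(self, rng):
        lib, _ = generate_band_recovery_library(n_per_class=5, n_bands=8, seed=0)
        ranking = rfe_select(lib, k=8, seed=0)
        assert sorted(ranking.wavelengths) == sorted(lib.wavelengths)
        assert ranking.elimination_order == []

    def test_elimination_order_length(self):
        lib, _ = generate_band_recovery_library(n_per_class=5, n_bands=10, seed=1)
        ranking = rfe_select(lib, k=4, seed=1)
        assert len(ranking.elimination_order) == 6
        assert len(ranking.wavelengths) == 4

    def test_informative_band_recovery_single_seed(self):
        lib, info = generate_band_recovery_library(n_per_class=30, n_bands=20, seed=7)
        ranking = rfe_select(lib, k=3, seed=7)
        assert sorted(ranking.wavelengths) == sorted(info)

    def test_linear_estimator_also_recovers(self):
        lib, info = generate_band_recovery_library(n_per_class=30, n_bands=15, seed=3)
        ranking = rfe_select(lib, estimator="linear", k=3, seed=3)
        assert sorted(ranking.wavelengths) == sorted(info)

    def test_reproducible_for_fixed_seed(self):
        lib, _ = generate_band_recovery_library(n_per_class=10, n_bands=10, seed=2)
        a = rfe_select(lib, k=3, seed=5)
        b = rfe_select(lib, k=3, seed=5)
        np.testing.assert_array_equal(a.wavelengths, b.wavelengths)
        assert a.elimination_order == b.elimination_order

    def test_selection_invariant_to_csv_column_order(self, tmp_path, rng):
        lib, _ = generate_band_recovery_library(n_per_class=10, n_bands=8, seed=4)
        path = tmp_path / "lib.csv"
        write_spectral_library(lib, path)
        # shuffle the spectral columns in the file
        lines = path.read_text().strip().splitlines()
        header = lines[0].split(",")
        order = rng.permutation(len(header))
        shuffled = [",".join(line.split(",")[i] for i in order) for line in lines]
        shuffled_path = tmp_path / "shuffled.csv"
        shuffled_path.write_text("\n".join(shuffled) + "\n")
        a = rfe_select(read_spectral_library(path), k=3, seed=9)
        b = rfe_select(read_spectral_library(shuffled_path), k=3, seed=9)
        np.testing.assert_array_equal(np.sort(a.wavelengths), np.sort(b.wavelengths))

    def test_wavelength_tie_break_drops_longest(self):
        # all-identical noise bands: importances tie, longest wavelengths go first
        class ZeroImportance:
            def fit(self, X, y):
                self._n = X.shape[1]

            def importances(self):
                return np.zeros(self._n)

        rng = np.random.default_rng(0)
        lib = library_from(rng.random((30, 5)), labels=rng.integers(0, 2, 30))
        ranking = rfe_select(lib, estimator=ZeroImportance(), k=2)
        assert ranking.elimination_order == [477.0, 467.0, 457.0]
        assert sorted(ranking.wavelengths) == [437.0, 447.0]

    def test_estimator_contract_enforced(self, small_library):
        with pytest.raises(ContractError):
            rfe_select(small_library, estimator=object(), k=3)

    def test_unlabeled_library_rejected(self, rng):
        lib = library_from(rng.random((10, 4)))
        with pytest.raises(ContractError):
            rfe_select(lib, k=2)

    def test_linear_margin_importance_shape(self, rng):
        est = LinearMarginImportance(seed=0)
        est.fit(rng.random((40, 6)), rng.integers(0, 3, 40))
        imp = est.importances()
        assert imp.shape == (6,) and np.all(imp >= 0)
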