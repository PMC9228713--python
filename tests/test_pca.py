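"""PCA fitting, projection, component identification, ellipses."""

import numpy as np
import pytest
from scipy import stats

from igg_orient.pca import (
    PCSelection,
    confidence_ellipse,
    fit_pca,
    fit_pca_on_table,
    load_model,
    project,
    save_model,
    select_pcs,
)
from igg_orient.spectra_io import mean_center, normalize_to_selected_sum

from .conftest import make_table


def centered(matrix):
    return mean_center(np.asarray(matrix, dtype=float))[0]


class TestFit:
    def test_matches_brute_force_covariance_eigensolve(self):
        X = centered([[1.0, 2.0], [3.0, 3.0], [2.0, 5.0], [6.0, 4.0]])
        model = fit_pca(X, 2)
        cov = X.T @ X / (X.shape[0] - 1)
        w, v = np.linalg.eigh(cov)      # independent route on the 2x2
        order = np.argsort(w)[::-1]
        np.testing.assert_allclose(model.eigenvalues, w[order], atol=1e-10)
        for j in range(2):
            direction = v[:, order[j]]
            cos = abs(direction @ model.loadings[:, j])
            assert cos == pytest.approx(1.0, abs=1e-10)

    def test_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(3)
        X = centered(rng.random((12, 6)))
        model = fit_pca(X, 4)
        ref = sklearn.PCA(n_components=4).fit(X)
        np.testing.assert_allclose(
            model.eigenvalues, ref.explained_variance_, rtol=1e-9
        )
        for j in range(4):
            cos = abs(ref.components_[j] @ model.loadings[:, j])
            assert cos == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_matrix_has_single_variance_fraction(self):
        base = np.array([1.0, 2.0, 2.0])
        X = centered(np.outer([1.0, 2.0, 4.0], base))
        model = fit_pca(X, 2)
        np.testing.assert_allclose(model.variance_fractions, [1.0, 0.0], atol=1e-10)

    def test_orthonormal_loadings_and_variance_conservation(self):
        rng = np.random.default_rng(7)
        X = centered(rng.random((10, 5)))
        model = fit_pca(X, 5)
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(5), atol=1e-8
        )
        total = np.var(X, axis=0, ddof=1).sum()
        assert model.eigenvalues.sum() == pytest.approx(total, abs=1e-8)
        # full-rank reconstruction
        np.testing.assert_allclose(
            model.training_scores @ model.loadings.T, X, atol=1e-8
        )
        # scores uncorrelated across components
        score_cov = np.cov(model.training_scores, rowvar=False)
        np.testing.assert_allclose(
            score_cov - np.diag(np.diag(score_cov)), 0.0, atol=1e-8
        )

    def test_component_count_beyond_rank_rejected(self):
        X = centered(np.random.default_rng(0).random((3, 5)))
        with pytest.raises(ValueError, match="rank"):
            fit_pca(X, 3)

    def test_uncentered_input_rejected(self):
        with pytest.raises(ValueError, match="centred"):
            fit_pca(np.array([[1.0, 2.0], [3.0, 4.0]]), 1)


class TestProject:
    def test_training_table_reproduces_training_scores(self):
        rng = np.random.default_rng(5)
        t = make_table(rng.random((8, 4)))
        norm = normalize_to_selected_sum(t)
        model = fit_pca_on_table(norm, 3)
        np.testing.assert_allclose(
            project(model, norm), model.training_scores, atol=1e-10
        )

    def test_mean_row_projects_to_zero(self):
        rng = np.random.default_rng(6)
        t = normalize_to_selected_sum(make_table(rng.random((6, 4))))
        model = fit_pca_on_table(t, 2)
        mean_row = make_table(model.mean_vector[None, :], peaks=t.peaks,
                              normalized=True)
        np.testing.assert_allclose(project(model, mean_row), 0.0, atol=1e-12)

    def test_two_peak_hand_arithmetic(self):
        X = np.array([[0.4, 0.6], [0.6, 0.4]])
        t = make_table(X, normalized=True)
        model = fit_pca_on_table(t, 1)
        # loading along (1,-1)/sqrt2 with positive first entry; score of row 0
        # is (0.4-0.5, 0.6-0.5).(1,-1)/sqrt2 = -0.1*sqrt2
        s = project(model, t)
        assert s[0, 0] == pytest.approx(-0.1 * np.sqrt(2), abs=1e-12)
        assert s[1, 0] == pytest.approx(+0.1 * np.sqrt(2), abs=1e-12)

    def test_peak_mismatch_lists_difference(self):
        rng = np.random.default_rng(1)
        t = normalize_to_selected_sum(make_table(rng.random((5, 3))))
        model = fit_pca_on_table(t, 2)
        other = make_table(rng.random((2, 3)), peaks=["P0+", "P1+", "Q9+"])
        with pytest.raises(ValueError, match="Q9"):
            project(model, other)


class TestSelectPCs:
    def _fixture(self, sep_component=1, fc_sign=+1):
        """Training scores separating classes only along one component."""
        rng = np.random.default_rng(2)
        n_per = 5
        labels = ["bare"] * n_per + ["fc_ref"] * n_per + ["fab2_ref"] * n_per
        scores = rng.normal(0.0, 0.01, size=(3 * n_per, 3))
        scores[:n_per, 0] -= 5.0           # coverage separates on comp 0
        scores[n_per:2 * n_per, sep_component] += fc_sign * 3.0
        scores[2 * n_per:, sep_component] -= fc_sign * 3.0
        from igg_orient.pca import PCAModel

        return PCAModel(
            mean_vector=np.zeros(3),
            loadings=np.eye(3),
            eigenvalues=np.array([3.0, 2.0, 1.0]),
            variance_fractions=np.array([0.5, 0.3, 0.2]),
            training_scores=scores,
            training_labels=labels,
            peaks=["a", "b", "c"],
        )

    def test_orientation_pc_found_by_separation(self):
        sel = select_pcs(self._fixture(sep_component=1))
        assert sel.coverage_pc == 0
        assert sel.orientation_pc == 1
        assert sel.orientation_sign == +1

    def test_sign_convention_flips_for_negative_fc(self):
        sel = select_pcs(self._fixture(sep_component=2, fc_sign=-1))
        assert sel.orientation_pc == 2
        assert sel.orientation_sign == -1

    def test_missing_reference_class_rejected(self):
        model = self._fixture()
        model.training_labels = ["bare"] * 15
        with pytest.raises(ValueError, match="fc_ref"):
            select_pcs(model)

    def test_same_component_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            PCSelection(coverage_pc=1, orientation_pc=1, orientation_sign=1)


class TestConfidenceEllipse:
    def test_isotropic_cloud_gives_chi2_radius(self):
        # construct scores with exactly identity sample covariance
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 2))
        X -= X.mean(axis=0)
        cov = np.cov(X, rowvar=False)
        X = X @ np.linalg.inv(np.linalg.cholesky(cov)).T
        _, axes, _ = confidence_ellipse(X, level=0.95)
        expected = np.sqrt(stats.chi2.ppf(0.95, 2))  # ~2.4477
        np.testing.assert_allclose(axes, expected, rtol=1e-9)
        assert expected == pytest.approx(2.4477, abs=5e-5)

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 2))
        _, axes1, _ = confidence_ellipse(X)
        _, axes3, _ = confidence_ellipse(3.0 * X)
        np.testing.assert_allclose(axes3, 3.0 * axes1, rtol=1e-9)

    def test_anisotropic_axes_match_eigensolve(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(500, 2)) * [3.0, 0.5]
        _, axes, _ = confidence_ellipse(X, level=0.9)
        evals = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        np.testing.assert_allclose(
            axes, np.sqrt(stats.chi2.ppf(0.9, 2) * evals), rtol=1e-9
        )

    def test_degenerate_scores_rejected(self):
        X = np.array([[1.0, 2.0]] * 5)
        with pytest.raises(ValueError, match="degenerate"):
            confidence_ellipse(X)


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        t = normalize_to_selected_sum(make_table(rng.random((6, 4))))
        model = fit_pca_on_table(t, 3)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_allclose(back.loadings, model.loadings)
        np.testing.assert_allclose(back.mean_vector, model.mean_vector)
        np.testing.assert_allclose(
            project(back, t), project(model, t), atol=1e-12
        )
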