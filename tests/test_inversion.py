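import numpy as np
import pytest

from shiftsense.inversion import (
    ShiftDelta,
    fit_inverse_model,
    fit_pca,
    predict_bond_deltas,
    pseudoinverse_predict,
    read_shift_delta,
    write_shift_delta,
)
from shiftsense.sensitivity import SensitivityMatrix, build_sensitivity_matrix
from shiftsense.synthetic import default_model_spec, simulate_state_pair, simulate_trajectory
from shiftsense.trajectory_io import BondSeries, ShiftSeries


def _shift_series(X, atoms=None):
    n, k = X.shape
    return ShiftSeries(tuple(atoms or [f"A{i}" for i in range(k)]),
                       np.arange(n, dtype=float), X)


class TestFitPCA:
    def test_two_feature_line_geometry(self, rng):
        t = rng.normal(size=300)
        X = np.column_stack([t, t]) + 100.0
        X[:, 1] += rng.normal(0, 1e-6, 300)
        p = fit_pca(_shift_series(X))
        first = p.loadings[0]
        assert abs(first @ np.array([1, 1]) / np.sqrt(2)) == pytest.approx(1.0, abs=1e-6)
        assert p.explained_variance[1] == pytest.approx(0.0, abs=1e-9)

    def test_explained_variance_conserves_total(self):
        spec = default_model_spec("square", seed=21)
        _, shift_series, _ = simulate_trajectory(spec, 400)
        p = fit_pca(shift_series)
        total = shift_series.shifts.var(axis=0, ddof=1).sum()
        assert p.explained_variance.sum() == pytest.approx(total, rel=1e-10)

    def test_loadings_match_covariance_eigendecomposition(self):
        """Independent oracle: eigh of the sample covariance, up to sign."""
        spec = default_model_spec("square", seed=22)
        _, shift_series, _ = simulate_trajectory(spec, 500)
        p = fit_pca(shift_series)
        X = shift_series.shifts
        cov = np.cov(X, rowvar=False)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        np.testing.assert_allclose(p.explained_variance, w, rtol=1e-8)
        for i in range(p.n_components):
            dot = abs(p.loadings[i] @ v[:, i])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_rows_orthonormal(self):
        spec = default_model_spec("square", seed=23)
        _, shift_series, _ = simulate_trajectory(spec, 300)
        p = fit_pca(shift_series)
        np.testing.assert_allclose(p.loadings @ p.loadings.T,
                                   np.eye(p.n_components), atol=1e-8)

    def test_constant_column_rejected_by_name(self, rng):
        X = rng.normal(size=(100, 3))
        X[:, 1] = 42.0
        with pytest.raises(ValueError, match="'A1'"):
            fit_pca(_shift_series(X))

    def test_too_few_frames_rejected(self, rng):
        X = rng.normal(size=(5, 6))
        with pytest.raises(ValueError, match="frames"):
            fit_pca(_shift_series(X))


class TestInverseModel:
    def test_noiseless_in_sample_prediction_exact(self, square_noiseless_pair):
        ds = square_noiseless_pair
        p = fit_pca(ds.shift_series)
        m = fit_inverse_model(p, ds.shift_series, ds.bond_series)
        scores = (ds.shift_series.shifts - p.feature_means) @ p.loadings.T
        pred = scores @ m.coefficients.T + m.intercepts
        np.testing.assert_allclose(pred, ds.bond_series.lengths, atol=1e-8)

    def test_coefficients_equal_rotated_direct_regression(self, square_noisy_pair):
        """Algebraic identity: regressing on scores == regressing on centred
        shifts then rotating the coefficients by the loadings."""
        ds = square_noisy_pair
        p = fit_pca(ds.shift_series)
        m = fit_inverse_model(p, ds.shift_series, ds.bond_series)
        X = ds.shift_series.shifts
        Xc = X - X.mean(axis=0)
        Dc = ds.bond_series.lengths - ds.bond_series.lengths.mean(axis=0)
        direct = np.linalg.lstsq(Xc, Dc, rcond=None)[0].T  # bonds x features
        np.testing.assert_allclose(m.coefficients @ p.loadings, direct, atol=1e-8)

    def test_frame_permutation_invariance(self, square_noisy_pair):
        ds = square_noisy_pair
        p = fit_pca(ds.shift_series)
        m1 = fit_inverse_model(p, ds.shift_series, ds.bond_series)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.shift_series.n_frames)
        t = np.arange(len(perm), dtype=float)
        s2 = ShiftSeries(ds.shift_series.atom_labels, t, ds.shift_series.shifts[perm])
        b2 = BondSeries(ds.bond_series.bond_labels, t.copy(), ds.bond_series.lengths[perm])
        p2 = fit_pca(s2)
        m2 = fit_inverse_model(p2, s2, b2)
        np.testing.assert_allclose(m2.coefficients @ p2.loadings,
                                   m1.coefficients @ p.loadings, atol=1e-8)


class TestPredict:
    def test_zero_delta_predicts_zero(self, square_noiseless_pair):
        ds = square_noiseless_pair
        p = fit_pca(ds.shift_series)
        m = fit_inverse_model(p, ds.shift_series, ds.bond_series)
        zero = ShiftDelta("null", ds.spec.atom_labels, np.zeros(6))
        pred = predict_bond_deltas(m, zero, n_boot=0)
        np.testing.assert_allclose(pred.delta_pm, 0.0, atol=1e-12)

    def test_noiseless_truth_recovered(self, square_noiseless_pair):
        ds = square_noiseless_pair
        p = fit_pca(ds.shift_series)
        m = fit_inverse_model(p, ds.shift_series, ds.bond_series)
        pred = predict_bond_deltas(m, ds.observed_delta, n_boot=0)
        np.testing.assert_allclose(pred.delta_pm, ds.delta_d_true_pm, atol=0.01)

    def test_homogeneity_doubling_delta(self, square_noisy_pair):
        ds = square_noisy_pair
        p = fit_pca(ds.shift_series)
        m = fit_inverse_model(p, ds.shift_series, ds.bond_series)
        one = predict_bond_deltas(m, ds.observed_delta, n_boot=0)
        doubled = ShiftDelta("x2", ds.observed_delta.atom_labels,
                             ds.observed_delta.delta_ppm * 2.0)
        two = predict_bond_deltas(m, doubled, n_boot=0)
        np.testing.assert_allclose(two.delta_pm, one.delta_pm * 2.0, atol=1e-9)

    def test_missing_atom_rejected(self, square_noiseless_pair):
        ds = square_noiseless_pair
        p = fit_pca(ds.shift_series)
        m = fit_inverse_model(p, ds.shift_series, ds.bond_series)
        exp = ShiftDelta("partial", ds.spec.atom_labels[:-1], np.zeros(5))
        with pytest.raises(ValueError, match="missing atom"):
            predict_bond_deltas(m, exp, n_boot=0)

    def test_pca_is_a_pure_rotation_of_the_regression(self, square_noisy_pair):
        """Predictions are identical whether the regression runs on PC scores
        or directly on centred shifts — PCA does not reduce dimension."""
        ds = square_noisy_pair
        p = fit_pca(ds.shift_series)
        m = fit_inverse_model(p, ds.shift_series, ds.bond_series)
        pred_pca = predict_bond_deltas(m, ds.observed_delta, n_boot=0)
        X = ds.shift_series.shifts
        Xc = X - X.mean(axis=0)
        Dc = ds.bond_series.lengths - ds.bond_series.lengths.mean(axis=0)
        direct = np.linalg.lstsq(Xc, Dc, rcond=None)[0].T
        direct_pred_pm = 100.0 * (direct @ ds.observed_delta.delta_ppm)
        np.testing.assert_allclose(pred_pca.delta_pm, direct_pred_pm, atol=1e-8)

    def test_bootstrap_uncertainty_positive_and_seeded(self, square_noisy_pair):
        ds = square_noisy_pair
        p = fit_pca(ds.shift_series)
        m = fit_inverse_model(p, ds.shift_series, ds.bond_series)
        a = predict_bond_deltas(m, ds.observed_delta, n_boot=40, seed=7)
        b = predict_bond_deltas(m, ds.observed_delta, n_boot=40, seed=7)
        np.testing.assert_array_equal(a.uncertainty_pm, b.uncertainty_pm)
        assert np.all(a.uncertainty_pm > 0)

    def test_bootstrap_uncertainty_shrinks_with_frames(self):
        dd = dict(zip(default_model_spec("square").bond_labels,
                      (-17.0, 5.0, -14.0, 0.0, 2.0, 16.0)))
        uncs = []
        for n in (1000, 4000):
            spec = default_model_spec("square", seed=30, sigma_d_A=0.02,
                                      sigma_shift_ppm=0.5)
            ds = simulate_state_pair(spec, dd, n)
            p = fit_pca(ds.shift_series)
            m = fit_inverse_model(p, ds.shift_series, ds.bond_series)
            pred = predict_bond_deltas(m, ds.observed_delta, n_boot=60, seed=1)
            uncs.append(pred.uncertainty_pm.mean())
        assert uncs[1] < uncs[0]


class TestPseudoinverse:
    @staticmethod
    def _matrix(slopes):
        slopes = np.asarray(slopes, float)
        mask = slopes != 0
        na, nb = slopes.shape
        return SensitivityMatrix(
            tuple(f"A{i}" for i in range(na)), tuple(f"B{j}" for j in range(nb)),
            slopes, mask, 0.05, "none", slopes.copy(),
            np.zeros_like(slopes), np.zeros_like(slopes), 100)

    def test_identity_matrix_unit_conversion(self):
        m = self._matrix(np.eye(6))
        exp = ShiftDelta("t", tuple(f"A{i}" for i in range(6)), np.ones(6))
        pred = pseudoinverse_predict(m, exp)
        np.testing.assert_allclose(pred.delta_pm, 100.0, atol=1e-9)
        assert pred.method == "pseudoinverse"

    def test_square_invertible_solves_exactly(self, rng):
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        m = self._matrix(A)
        dd = np.array([0.01, -0.02, 0.005, 0.0])
        exp = ShiftDelta("t", m.atom_labels, A @ dd)
        pred = pseudoinverse_predict(m, exp)
        np.testing.assert_allclose(pred.delta_pm, dd * 100.0, atol=1e-8)

    def test_no_significant_entries_rejected(self):
        slopes = np.zeros((2, 2))
        m = SensitivityMatrix(("A0", "A1"), ("B0", "B1"), slopes,
                              np.zeros((2, 2), bool), 0.05, "none",
                              slopes.copy(), slopes.copy(), np.ones((2, 2)), 10)
        exp = ShiftDelta("t", ("A0", "A1"), np.ones(2))
        with pytest.raises(ValueError, match="no significant"):
            pseudoinverse_predict(m, exp)

    def test_two_route_agreement_noiseless(self, square_noiseless_pair):
        """PC regression and pseudoinverse inversion agree on the noiseless
        square fixture to well below 0.1 pm."""
        ds = square_noiseless_pair
        p = fit_pca(ds.shift_series)
        model = fit_inverse_model(p, ds.shift_series, ds.bond_series)
        pred_a = predict_bond_deltas(model, ds.observed_delta, n_boot=0)
        matrix = build_sensitivity_matrix(ds.shift_series, ds.bond_series)
        pred_b = pseudoinverse_predict(matrix, ds.observed_delta)
        np.testing.assert_allclose(pred_a.delta_pm, pred_b.delta_pm, atol=0.1)


class TestShiftDeltaIO:
    def test_json_round_trip(self, tmp_path):
        d = ShiftDelta("Pr->Pg", ("C13", "C14"), np.array([-3.2, 1.1]), "lit")
        write_shift_delta(tmp_path / "d.json", d)
        back = read_shift_delta(tmp_path / "d.json")
        assert back.transition_name == "Pr->Pg"
        assert back.atom_labels == d.atom_labels
        np.testing.assert_allclose(back.delta_ppm, d.delta_ppm)

    def test_csv_reader(self, tmp_path):
        (tmp_path / "d.csv").write_text("atom,delta_ppm\nC13,-3.2\nC14,1.1\n")
        back = read_shift_delta(tmp_path / "d.csv")
        assert back.atom_labels == ("C13", "C14")
        np.testing.assert_allclose(back.delta_ppm, [-3.2, 1.1])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ShiftDelta("x", ("C13", "C13"), np.zeros(2))
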