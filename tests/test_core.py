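import numpy as np
import pytest

from emmcup.basis import build_polynomial_basis
from emmcup.core import (
    BiasCoefficients,
    CorrectionState,
    ImageGrid,
    MembershipMap,
    SolverConfig,
    TissueMeans,
    auto_mask,
    evaluate_energy,
    initialize_state,
    run_correction,
    update_coefficients,
    update_means,
    update_membership,
)
from emmcup.errors import DegenerateInputError
from tests.conftest import random_instance


def make_state(grid, basis, means, coeffs):
    membership = update_membership(grid, basis, TissueMeans(means), BiasCoefficients(coeffs))
    return CorrectionState(
        membership=membership,
        means=TissueMeans(means),
        coefficients=BiasCoefficients(coeffs),
    )


class TestEnergy:
    def test_perfect_piecewise_fit_is_zero(self):
        data = np.where(np.arange(36).reshape(6, 6) < 18, 2.0, 5.0)
        grid = ImageGrid.from_array(data)
        basis = build_polynomial_basis(grid, 1)
        state = make_state(grid, basis, [2.0, 5.0], np.zeros(3))
        assert evaluate_energy(grid, basis, state) == 0.0

    def test_unit_residual_everywhere(self):
        grid = ImageGrid.from_array(np.zeros((5, 7)))
        basis = build_polynomial_basis(grid, 0)
        state = make_state(grid, basis, [1.0], [0.0])
        assert evaluate_energy(grid, basis, state) == pytest.approx(35.0)

    def test_matches_pixel_loop_oracle(self, rng):
        grid, basis, state = random_instance(rng, shape=(8, 8), degree=2)
        total = 0.0
        for r in range(8):
            for c in range(8):
                if not grid.mask[r, c]:
                    continue
                label = state.membership.labels[r, c]
                fs = float(state.coefficients.values @ basis.functions[:, r, c])
                total += (grid.intensities[r, c] - state.means.values[label - 1] - fs) ** 2
        assert evaluate_energy(grid, basis, state) == pytest.approx(total, rel=1e-12)


class TestCoefficientUpdate:
    def test_zero_residual_gives_zero_coefficients(self):
        data = np.full((6, 6), 3.0)
        grid = ImageGrid.from_array(data)
        basis = build_polynomial_basis(grid, 2)
        membership = MembershipMap(np.ones((6, 6), dtype=np.int32), count=1)
        w = update_coefficients(grid, basis, membership, TissueMeans([3.0]))
        np.testing.assert_allclose(w.values, 0.0, atol=1e-12)

    def test_constant_basis_gives_mean_residual(self, rng):
        data = rng.uniform(size=(7, 7))
        grid = ImageGrid.from_array(data)
        basis = build_polynomial_basis(grid, 0)
        membership = MembershipMap(np.ones((7, 7), dtype=np.int32), count=1)
        w = update_coefficients(grid, basis, membership, TissueMeans([0.2]))
        assert w.values[0] == pytest.approx((data - 0.2).mean(), rel=1e-12)

    def test_matches_generic_least_squares_oracle(self, rng):
        grid, basis, state = random_instance(rng, shape=(10, 10), degree=2)
        w = update_coefficients(grid, basis, state.membership, state.means)
        # independent route: dense overdetermined pixel system
        mask = grid.mask
        design = basis.functions[:, mask].T
        target = grid.intensities[mask] - state.means.values[
            state.membership.labels[mask] - 1
        ]
        expected, *_ = np.linalg.lstsq(design, target, rcond=None)
        np.testing.assert_allclose(w.values, expected, atol=1e-8)

    def test_is_energy_minimizer_in_w(self, rng):
        grid, basis, state = random_instance(rng, shape=(9, 9), degree=1)
        w = update_coefficients(grid, basis, state.membership, state.means)
        best = CorrectionState(state.membership, state.means, w)
        e_best = evaluate_energy(grid, basis, best)
        for _ in range(10):
            other = BiasCoefficients(w.values + rng.normal(0, 0.05, basis.count))
            alt = CorrectionState(state.membership, state.means, other)
            assert evaluate_energy(grid, basis, alt) >= e_best - 1e-12


class TestMeansUpdate:
    def test_constant_class_with_zero_bias(self):
        data = np.full((5, 5), 7.0)
        grid = ImageGrid.from_array(data)
        basis = build_polynomial_basis(grid, 0)
        membership = MembershipMap(np.ones((5, 5), dtype=np.int32), count=1)
        c = update_means(grid, basis, membership, BiasCoefficients([0.0]))
        assert c.values[0] == pytest.approx(7.0)

    def test_bias_subtracted_before_mean(self):
        data = np.array([[2.0, 4.0]])
        grid = ImageGrid.from_array(data)
        basis = build_polynomial_basis(grid, 0)
        membership = MembershipMap(np.ones((1, 2), dtype=np.int32), count=1)
        c = update_means(grid, basis, membership, BiasCoefficients([1.0]))
        assert c.values[0] == pytest.approx(2.0)  # mean of {1, 3}

    def test_matches_per_class_loop_oracle(self, rng):
        grid, basis, state = random_instance(rng, shape=(12, 12), n_tissues=3)
        c = update_means(grid, basis, state.membership, state.coefficients)
        fs = np.einsum("k,kij->ij", state.coefficients.values, basis.functions)
        for i in range(1, 4):
            sel = (state.membership.labels == i) & grid.mask
            if sel.any():
                expected = (grid.intensities[sel] - fs[sel]).mean()
                assert c.values[i - 1] == pytest.approx(expected, rel=1e-12)

    def test_empty_class_keeps_previous_value(self):
        data = np.full((4, 4), 1.0)
        grid = ImageGrid.from_array(data)
        basis = build_polynomial_basis(grid, 0)
        labels = np.ones((4, 4), dtype=np.int32)  # class 2 empty
        membership = MembershipMap(labels, count=2)
        prev = TissueMeans([0.5, 9.0])
        c = update_means(grid, basis, membership, BiasCoefficients([0.0]), previous=prev)
        assert c.values[1] == 9.0

    def test_empty_class_without_previous_raises(self):
        grid = ImageGrid.from_array(np.ones((4, 4)))
        basis = build_polynomial_basis(grid, 0)
        membership = MembershipMap(np.ones((4, 4), dtype=np.int32), count=2)
        with pytest.raises(DegenerateInputError):
            update_means(grid, basis, membership, BiasCoefficients([0.0]))


class TestMembershipUpdate:
    def test_nearest_mean_wins(self):
        grid = ImageGrid.from_array(np.full((3, 3), 10.0))
        basis = build_polynomial_basis(grid, 0)
        m = update_membership(grid, basis, TissueMeans([9.0, 20.0]), BiasCoefficients([0.0]))
        assert np.all(m.labels == 1)

    def test_tie_breaks_to_smallest_index(self):
        grid = ImageGrid.from_array(np.full((3, 3), 5.0))
        basis = build_polynomial_basis(grid, 0)
        m = update_membership(grid, basis, TissueMeans([4.0, 6.0]), BiasCoefficients([0.0]))
        assert np.all(m.labels == 1)

    def test_matches_exhaustive_argmin_oracle(self, rng):
        grid, basis, state = random_instance(rng, shape=(10, 10), n_tissues=3, degree=2)
        m = update_membership(grid, basis, state.means, state.coefficients)
        for r in range(10):
            for c in range(10):
                if not grid.mask[r, c]:
                    assert m.labels[r, c] == 0
                    continue
                fs = float(state.coefficients.values @ basis.functions[:, r, c])
                resid = [
                    (grid.intensities[r, c] - ci - fs) ** 2
                    for ci in state.means.values
                ]
                assert m.labels[r, c] == int(np.argmin(resid)) + 1

    def test_partition_covers_mask(self, rng):
        grid, basis, state = random_instance(rng, mask_fraction=0.6, n_tissues=2)
        m = update_membership(grid, basis, state.means, state.coefficients)
        assert np.all((m.labels > 0) == grid.mask)


class TestInitialize:
    def test_single_tissue_constant_image(self):
        grid = ImageGrid.from_array(np.full((6, 6), 4.0))
        basis = build_polynomial_basis(grid, 1)
        state = initialize_state(grid, basis, 1, method="quantile")
        assert state.means.values[0] == pytest.approx(4.0)
        np.testing.assert_array_equal(state.coefficients.values, 0.0)
        assert state.energy_trace[0] == pytest.approx(0.0)

    def test_two_tissue_quantiles(self):
        data = np.linspace(0.0, 1.0, 10000).reshape(100, 100)
        grid = ImageGrid.from_array(data)
        basis = build_polynomial_basis(grid, 0)
        state = initialize_state(grid, basis, 2, method="quantile")
        np.testing.assert_allclose(state.means.values, [0.25, 0.75], atol=1e-3)

    def test_deterministic(self, rng):
        data = rng.uniform(size=(12, 12))
        grid = ImageGrid.from_array(data)
        basis = build_polynomial_basis(grid, 1)
        a = initialize_state(grid, basis, 2, seed=7, method="kmeans")
        b = initialize_state(grid, basis, 2, seed=7, method="kmeans")
        np.testing.assert_array_equal(a.means.values, b.means.values)
        np.testing.assert_array_equal(a.membership.labels, b.membership.labels)
        assert a.energy_trace == b.energy_trace

    def test_too_many_tissues_raises(self):
        grid = ImageGrid.from_array(np.full((5, 5), 2.0))
        basis = build_polynomial_basis(grid, 0)
        with pytest.raises(DegenerateInputError):
            initialize_state(grid, basis, 2)


def model_matched_grid(shape=(32, 32), seed=0, noise_sd=0.0):
    """f = piecewise constant + degree-2 polynomial field (+ noise)."""
    rng = np.random.default_rng(seed)
    rows, cols = shape
    labels = 1 + (np.add.outer(np.arange(rows), np.arange(cols)) > rows).astype(int)
    c_true = np.array([0.3, 0.7])
    y, x = np.meshgrid(
        np.linspace(-1, 1, rows), np.linspace(-1, 1, cols), indexing="ij"
    )
    fs_true = 0.15 * (x**2 + y**2) - 0.1 * x
    f = c_true[labels - 1] + fs_true + rng.normal(0, noise_sd, shape)
    return ImageGrid.from_array(f), fs_true, labels


class TestRunCorrection:
    def test_noiseless_model_matched_recovery(self):
        grid, fs_true, _ = model_matched_grid()
        cfg = SolverConfig(n_tissues=2, degree=3, eps=1e-10, max_iter=300)
        result = run_correction(grid, cfg)
        assert result.final_energy < 1e-10 * result.energy_trace[0]
        mask = grid.mask
        est = result.bias_field[mask]
        true = fs_true[mask] - fs_true[mask].mean()
        lo, hi = grid.intensity_scale
        rmse = np.sqrt(np.mean((est - true) ** 2)) / (hi - lo)
        assert rmse < 1e-6

    def test_huge_eps_stops_after_one_iteration(self):
        grid, _, _ = model_matched_grid()
        result = run_correction(grid, SolverConfig(n_tissues=2, eps=10.0))
        assert result.converged and result.iterations == 1

    def test_energy_trace_non_increasing(self):
        grid, _, _ = model_matched_grid(noise_sd=0.02, seed=3)
        result = run_correction(grid, SolverConfig(n_tissues=2))
        trace = np.array(result.energy_trace)
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1e-30))

    def test_energy_non_increasing_after_each_sub_update(self, rng):
        grid, basis, state = random_instance(rng, shape=(14, 14), n_tissues=3, degree=2)
        energy = evaluate_energy(grid, basis, state)
        for _ in range(4):
            w = update_coefficients(grid, basis, state.membership, state.means)
            state = CorrectionState(state.membership, state.means, w)
            e = evaluate_energy(grid, basis, state)
            assert e <= energy * (1 + 1e-9) + 1e-15
            energy = e
            c = update_means(grid, basis, state.membership, w, previous=state.means)
            state = CorrectionState(state.membership, c, w)
            e = evaluate_energy(grid, basis, state)
            assert e <= energy * (1 + 1e-9) + 1e-15
            energy = e
            u = update_membership(grid, basis, c, w)
            state = CorrectionState(u, c, w)
            e = evaluate_energy(grid, basis, state)
            assert e <= energy * (1 + 1e-9) + 1e-15
            energy = e

    def test_reconstruction_identity(self):
        grid, _, _ = model_matched_grid(noise_sd=0.01, seed=5)
        result = run_correction(grid, SolverConfig(n_tissues=2))
        np.testing.assert_allclose(
            result.corrected + result.bias_field, grid.intensities, atol=1e-12
        )

    def test_bias_field_zero_mean_over_mask(self):
        grid, _, _ = model_matched_grid(noise_sd=0.01, seed=6)
        result = run_correction(grid, SolverConfig(n_tissues=2))
        assert abs(result.bias_field[result.mask].mean()) < 1e-10

    def test_intensity_equivariance(self):
        grid, _, _ = model_matched_grid(noise_sd=0.01, seed=7)
        cfg = SolverConfig(n_tissues=2)
        r1 = run_correction(grid, cfg)
        scaled = ImageGrid.from_array(3.0 * grid.intensities, mask=grid.mask)
        r2 = run_correction(scaled, cfg)
        np.testing.assert_allclose(r2.bias_field, 3.0 * r1.bias_field, atol=1e-9)

    def test_label_permutation_invariance(self, rng):
        grid, _, _ = model_matched_grid(noise_sd=0.01, seed=8)
        basis = build_polynomial_basis(grid.normalized(), 3)
        ngrid = grid.normalized()

        def iterate(means):
            c = TissueMeans(means)
            w = BiasCoefficients(np.zeros(basis.count))
            u = update_membership(ngrid, basis, c, w)
            for _ in range(12):
                w = update_coefficients(ngrid, basis, u, c)
                c = update_means(ngrid, basis, u, w, previous=c)
                u = update_membership(ngrid, basis, c, w)
            return np.einsum("k,kij->ij", w.values, basis.functions)

        fs_a = iterate([0.3, 0.8])
        # permuted ordering: same set of starting means, reversed
        c0 = TissueMeans([0.8, 0.3])
        w0 = BiasCoefficients(np.zeros(basis.count))
        u0 = update_membership(ngrid, basis, TissueMeans([0.3, 0.8]), w0)
        # labels under the permuted means are the permutation of the originals
        u_perm = update_membership(ngrid, basis, c0, w0)
        assert np.array_equal((u0.labels == 1), (u_perm.labels == 2))
        c, w, u = c0, w0, u_perm
        for _ in range(12):
            w = update_coefficients(ngrid, basis, u, c)
            c = update_means(ngrid, basis, u, w, previous=c)
            u = update_membership(ngrid, basis, c, w)
        fs_b = np.einsum("k,kij->ij", w.values, basis.functions)
        np.testing.assert_allclose(fs_a, fs_b, atol=1e-10)


class TestAutoMask:
    def test_disk_recovered(self):
        rows, cols = 64, 64
        rr, cc = np.ogrid[:rows, :cols]
        disk = (rr - 32) ** 2 + (cc - 32) ** 2 <= 20**2
        image = np.where(disk, 1.0, 0.0)
        mask = auto_mask(image)
        assert (mask == disk).mean() > 0.99

    def test_constant_image_falls_back_to_full(self):
        assert auto_mask(np.full((8, 8), 3.0)).all()
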