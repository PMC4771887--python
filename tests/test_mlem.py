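"""MLEM deconvolution tests.

The convolution oracle is an explicit double-loop spatial convolution,
independent of the FFT path used by the implementation.
"""

import warnings

import numpy as np
import pytest

from cbctscatter import (
    CorrectionConfig,
    MLEMState,
    log_likelihood,
    mlem_update,
    run_scatter_correction,
    scatter_convolve,
)

FLAT = 1.0e4


def direct_convolve_same(image, kernel):
    """Brute-force 'same' linear convolution by explicit loops."""
    n, m = image.shape
    kn, km = kernel.shape
    pn, pm = kn // 2, km // 2
    out = np.zeros_like(image)
    for i in range(n):
        for j in range(m):
            acc = 0.0
            for a in range(kn):
                for b in range(km):
                    ii, jj = i - (a - pn), j - (b - pm)
                    if 0 <= ii < n and 0 <= jj < m:
                        acc += image[ii, jj] * kernel[a, b]
            out[i, j] = acc
    return out


class TestScatterConvolve:
    def test_zero_subprojections_give_zero(self):
        subs = np.zeros((3, 8, 8))
        kernels = [np.full((5, 5), 0.1)] * 3
        np.testing.assert_array_equal(scatter_convolve(subs, kernels), 0.0)

    def test_delta_image_reproduces_kernel(self):
        subs = np.zeros((1, 9, 9))
        subs[0, 4, 4] = 1.0
        k = np.arange(25, dtype=float).reshape(5, 5) / 100.0
        out = scatter_convolve(subs, [k])
        np.testing.assert_allclose(out[2:7, 2:7], k, atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        img = rng.uniform(0.0, 100.0, (16, 16))
        k1 = rng.uniform(0.0, 0.1, (5, 5))
        k2 = rng.uniform(0.0, 0.1, (5, 5))
        subs = np.stack([img, img[::-1]])
        got = scatter_convolve(subs, [k1, k2])
        want = direct_convolve_same(img, k1) + direct_convolve_same(img[::-1], k2)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_kernel_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="one kernel per group"):
            scatter_convolve(np.zeros((2, 4, 4)), [np.ones((3, 3))])


class TestLogLikelihood:
    def test_all_ones_image_gives_minus_n(self):
        img = np.ones((8, 8))
        assert log_likelihood(img, img) == pytest.approx(-64.0)

    def test_maximized_at_the_measurement(self, rng):
        m = rng.uniform(10.0, 100.0, (16, 16))
        assert log_likelihood(m, m) > log_likelihood(m, 0.5 * m)
        assert log_likelihood(m, m) > log_likelihood(m, 1.5 * m)

    def test_nonpositive_estimate_on_support_rejected(self):
        m = np.ones((2, 2))
        est = np.array([[1.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="strictly positive"):
            log_likelihood(m, est)


class TestMLEMUpdate:
    def test_zero_kernels_return_measurement_bit_exactly(
            self, small_cylinder_projections, small_kernel_db):
        _, _, _, measured = small_cylinder_projections
        config = CorrectionConfig(kernels=small_kernel_db.zero_like(), max_iterations=1)
        state = MLEMState(estimate=measured.intensities[0].copy())
        new = mlem_update(state, measured.intensities[0], FLAT, config)
        np.testing.assert_array_equal(new.estimate, measured.intensities[0])
        assert new.n == 1
        assert len(new.log_likelihood_history) == 2  # initial + one update

    def test_positivity_preserved_on_support(
            self, small_cylinder_projections, small_kernel_db):
        _, _, _, measured = small_cylinder_projections
        config = CorrectionConfig(kernels=small_kernel_db)
        m = measured.intensities[0]
        state = MLEMState(estimate=m.copy())
        for _ in range(3):
            state = mlem_update(state, m, FLAT, config)
            assert np.all(state.estimate[m > 0] > 0)

    def test_converged_estimate_is_a_fixed_point(
            self, small_cylinder_projections, small_kernel_db):
        _, _, _, measured = small_cylinder_projections
        config = CorrectionConfig(kernels=small_kernel_db, max_iterations=40,
                                  tolerance=1e-13)
        m = measured.intensities[0]
        state = MLEMState(estimate=m.copy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(40):
                state = mlem_update(state, m, FLAT, config)
        before = state.estimate.copy()
        after = mlem_update(state, m, FLAT, config).estimate
        assert np.abs(after - before).max() < 1e-6 * FLAT


class TestRunScatterCorrection:
    def test_scatter_free_input_unchanged_after_one_iteration(
            self, small_cylinder_projections, small_kernel_db):
        _, _, primary, _ = small_cylinder_projections
        config = CorrectionConfig(kernels=small_kernel_db.zero_like(), max_iterations=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corrected, states, _ = run_scatter_correction(primary, config)
        np.testing.assert_array_equal(corrected.intensities, primary.intensities)
        assert all(s.n == 1 for s in states)

    def test_small_fixture_recovery_and_history_shape(
            self, small_cylinder_projections, small_kernel_db):
        _, _, primary, measured = small_cylinder_projections
        config = CorrectionConfig(kernels=small_kernel_db, max_iterations=8,
                                  tolerance=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corrected, states, _ = run_scatter_correction(measured, config)
        rmse = np.sqrt(np.mean((corrected.intensities - primary.intensities) ** 2))
        assert rmse < 0.02 * FLAT
        for s in states:
            assert len(s.log_likelihood_history) == s.n + 1

    def test_zero_iterations_return_input(
            self, small_cylinder_projections, small_kernel_db):
        _, _, _, measured = small_cylinder_projections
        config = CorrectionConfig(kernels=small_kernel_db, max_iterations=0)
        corrected, states, _ = run_scatter_correction(measured, config)
        np.testing.assert_array_equal(corrected.intensities, measured.intensities)
        assert all(s.n == 0 for s in states)

    def test_iterating_past_convergence_changes_little(
            self, small_cylinder_projections, small_kernel_db):
        from cbctscatter import ProjectionSet
        _, _, _, measured = small_cylinder_projections
        sub = ProjectionSet(measured.intensities[:2], measured.angles_deg[:2],
                            measured.flat_field)
        kwargs = dict(kernels=small_kernel_db, tolerance=1e-9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, _, _ = run_scatter_correction(sub, CorrectionConfig(max_iterations=15, **kwargs))
            b, _, _ = run_scatter_correction(sub, CorrectionConfig(max_iterations=30, **kwargs))
        assert np.abs(a.intensities - b.intensities).max() < 1e-4 * FLAT

    def test_nonconvergence_warns_not_raises(
            self, small_cylinder_projections, small_kernel_db):
        from cbctscatter import ProjectionSet
        _, _, _, measured = small_cylinder_projections
        sub = ProjectionSet(measured.intensities[:1], measured.angles_deg[:1],
                            measured.flat_field)
        config = CorrectionConfig(kernels=small_kernel_db, max_iterations=2,
                                  tolerance=1e-15)
        with pytest.warns(UserWarning, match="max_iterations"):
            _, states, _ = run_scatter_correction(sub, config)
        assert not states[0].converged
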