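import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crefkit.saltation import (
    ComparisonError,
    StabilityError,
    classify_levels,
    compare_motif_eigenvectors,
    deming_fit,
    perturb_first_order,
    relative_distances,
    rotation_angle,
    sensitivity_curve,
)


class TestRelativeDistances:
    def test_simple_pair(self):
        prof = relative_distances([10.0, 8.0])
        assert prof.relative_distances == {1: pytest.approx(0.2)}

    def test_degenerate_pair_has_zero_distance(self):
        prof = relative_distances([7.0, 7.0])
        assert prof.relative_distances[1] == 0.0

    def test_three_levels(self):
        prof = relative_distances([100.0, 98.3, 60.0])
        assert prof.relative_distances[1] == pytest.approx(0.017)
        assert prof.relative_distances[2] == pytest.approx(0.38962360122)

    def test_increasing_values_rejected(self):
        with pytest.raises(StabilityError, match="non-increasing"):
            relative_distances([5.0, 6.0])

    def test_zero_denominator_rejected(self):
        with pytest.raises(StabilityError, match="zero"):
            relative_distances([0.0, 0.0])

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_global_rescaling(self, scale):
        rho = np.array([12.0, 9.0, 8.8, 4.0])
        a = relative_distances(rho).relative_distances
        b = relative_distances(scale * rho).relative_distances
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9)


class TestCompareEigenvectors:
    def test_identical_vectors(self):
        v = np.array([0.3, -0.8, 0.5])
        r, flipped = compare_motif_eigenvectors(v, v)
        assert r == pytest.approx(1.0)
        assert not flipped

    def test_sign_flip_is_detected_and_undone(self):
        v = np.array([0.3, -0.8, 0.5, 0.1])
        r, flipped = compare_motif_eigenvectors(v, -v)
        assert r == pytest.approx(1.0)
        assert flipped

    def test_label_mismatch_rejected(self):
        v = np.zeros(3)
        with pytest.raises(ComparisonError, match="label"):
            compare_motif_eigenvectors(v, v, ["a", "b", "c"], ["a", "c", "b"])

    def test_planted_rotation_gives_cosine_correlation(self):
        # rotating within the span of two orthonormal mean-zero vectors by
        # theta leaves a correlation of cos(theta)
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(
            np.column_stack([np.ones(200), rng.standard_normal((200, 2))])
        )
        v1, v2 = q[:, 1], q[:, 2]
        theta = np.radians(40.0)
        rotated = np.cos(theta) * v1 + np.sin(theta) * v2
        r, _ = compare_motif_eigenvectors(v1, rotated)
        assert r == pytest.approx(np.cos(theta), abs=1e-12)


class TestDemingFit:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        slope, intercept = deming_fit(x, x)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.1, 0.9, 2.1, 2.9])
        slope, intercept = deming_fit(x, y)
        # closed form evaluated by hand: sxx=5/3, syy=1.52267, sxy=1.58333
        sxx, syy, sxy = 5 / 3, np.var(y, ddof=1), np.cov(x, y, ddof=1)[0, 1]
        expect = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
        assert slope == pytest.approx(expect)
        assert intercept == pytest.approx(np.mean(y) - expect * np.mean(x))

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_swapping_axes_inverts_slope(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(30)
        y = 0.7 * x + 0.1 * rng.standard_normal(30)
        s_xy, _ = deming_fit(x, y)
        s_yx, _ = deming_fit(y, x)
        assert s_xy == pytest.approx(1.0 / s_yx, rel=1e-9)

    def test_zero_covariance_rejected(self):
        with pytest.raises(ComparisonError, match="slope"):
            deming_fit(np.array([1.0, 1.0, 1.0]), np.array([0.0, 1.0, 2.0]))


class TestRotationAngle:
    @staticmethod
    def basis(n=50, seed=0):
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.standard_normal((n, 2)))
        return q[:, 0], q[:, 1]

    def test_probe_equal_to_first_vector(self):
        v1, v2 = self.basis()
        angle, oop = rotation_angle(v1, v2, v1)
        assert angle == pytest.approx(0.0, abs=1e-10)
        assert oop == pytest.approx(0.0, abs=1e-10)

    def test_probe_equal_to_second_vector(self):
        v1, v2 = self.basis()
        angle, _ = rotation_angle(v1, v2, v2)
        assert angle == pytest.approx(90.0)

    @pytest.mark.parametrize("theta", [10.0, 31.0, 53.0])
    def test_planted_rotation_recovered(self, theta):
        v1, v2 = self.basis(seed=4)
        t = np.radians(theta)
        probe = np.cos(t) * v1 + np.sin(t) * v2
        angle, oop = rotation_angle(v1, v2, probe)
        assert angle == pytest.approx(theta, abs=1e-6)
        assert oop == pytest.approx(0.0, abs=1e-10)

    def test_sign_free(self):
        v1, v2 = self.basis(seed=5)
        t = np.radians(31.0)
        probe = np.cos(t) * v1 + np.sin(t) * v2
        angle_pos, _ = rotation_angle(v1, v2, probe)
        angle_neg, _ = rotation_angle(v1, v2, -probe)
        assert angle_pos == pytest.approx(angle_neg)

    def test_out_of_plane_leakage_reported(self):
        rng = np.random.default_rng(6)
        q, _ = np.linalg.qr(rng.standard_normal((50, 3)))
        probe = 0.8 * q[:, 0] + 0.6 * q[:, 2]  # 36% outside span(v1, v2)
        _, oop = rotation_angle(q[:, 0], q[:, 1], probe)
        assert oop == pytest.approx(0.36)

    def test_collinear_reference_rejected(self):
        v1, _ = self.basis()
        with pytest.raises(ComparisonError, match="degenerate"):
            rotation_angle(v1, v1, v1)


class TestPerturbation:
    @staticmethod
    def matrix(n=30, m=12, seed=0):
        rng = np.random.default_rng(seed)
        U, _, Vt = np.linalg.svd(rng.standard_normal((n, m)), full_matrices=False)
        return (U * np.linspace(5.0, 1.0, m)) @ Vt

    def test_zero_perturbation_is_identity(self):
        C = self.matrix()
        _, _, Vt = np.linalg.svd(C, full_matrices=False)
        vk, vk1 = perturb_first_order(C, np.zeros((12, 12)), 3)
        assert abs(abs(vk @ Vt[3]) - 1.0) < 1e-12
        assert abs(abs(vk1 @ Vt[4]) - 1.0) < 1e-12

    def test_small_diagonal_case_matches_exact_eigensolver(self):
        C = np.diag([3.0, 2.0, 1.0])
        rng = np.random.default_rng(7)
        A = rng.standard_normal((3, 3))
        E = 1e-4 * 0.5 * (A + A.T)
        vk, _ = perturb_first_order(C, E, 0)
        w, V = np.linalg.eigh(C.T @ C + E)
        exact = V[:, ::-1][:, 0]
        exact = exact * np.sign(exact @ vk)
        assert np.linalg.norm(vk - exact) < 1e-7  # O(||E||^2 / gap^2)

    def test_quadratic_convergence(self):
        C = self.matrix(seed=8)
        rng = np.random.default_rng(9)
        A = rng.standard_normal((12, 12))
        E0 = 0.5 * (A + A.T)
        E0 /= np.linalg.norm(E0, 2)
        residuals = []
        for scale in (1e-2, 5e-3, 2.5e-3):
            vk, _ = perturb_first_order(C, scale * E0, 3)
            w, V = np.linalg.eigh(C.T @ C + scale * E0)
            exact = V[:, ::-1][:, 3]
            exact = exact * np.sign(exact @ vk)
            residuals.append(np.linalg.norm(vk - exact))
        assert residuals[0] / residuals[1] == pytest.approx(4.0, rel=0.2)
        assert residuals[1] / residuals[2] == pytest.approx(4.0, rel=0.2)

    def test_asymmetric_perturbation_rejected(self):
        C = self.matrix()
        E = np.zeros((12, 12))
        E[0, 1] = 1.0
        with pytest.raises(StabilityError, match="symmetric"):
            perturb_first_order(C, E, 1)


class TestSensitivityCurve:
    def test_inverse_gap_scaling_law(self):
        gaps = np.logspace(-3, -1, 7)
        table = sensitivity_curve(gaps, n_reps=50, seed=1)
        slope = np.polyfit(
            np.log10(table["d_k"]), np.log10(table["mean_deviation_rad"]), 1
        )[0]
        assert -1.3 <= slope <= -0.7

    def test_monotone_in_gap(self):
        table = sensitivity_curve(np.array([0.01, 0.2]), n_reps=50, seed=2)
        dev = table["mean_deviation_rad"].to_numpy()
        assert dev[0] > dev[1]

    def test_linear_in_perturbation_scale(self):
        a = sensitivity_curve(np.array([0.05]), perturb_scale=1e-3,
                              n_reps=50, seed=3)["mean_deviation_rad"][0]
        b = sensitivity_curve(np.array([0.05]), perturb_scale=2e-3,
                              n_reps=50, seed=3)["mean_deviation_rad"][0]
        assert b / a == pytest.approx(2.0, rel=0.05)

    def test_reproducible_under_seed(self):
        gaps = np.array([0.01, 0.1])
        a = sensitivity_curve(gaps, n_reps=20, seed=4)
        b = sensitivity_curve(gaps, n_reps=20, seed=4)
        assert a.equals(b)


class TestClassifyLevels:
    @pytest.mark.parametrize(
        "r, d, expected",
        [
            (0.99, 0.5, "conserved"),
            (0.99, 0.01, "conserved"),
            (0.61, 0.01, "saltation"),
            (0.85, 0.20, "divergent"),
        ],
    )
    def test_threshold_rules(self, r, d, expected):
        stability = relative_distances([1.0, 1.0 - d])
        labels = classify_levels(stability, {1: r})
        assert labels[1] == expected

    def test_invalid_thresholds_rejected(self):
        stability = relative_distances([1.0, 0.9])
        with pytest.raises(ComparisonError):
            classify_levels(stability, {1: 0.5}, r_conserved=1.5)
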