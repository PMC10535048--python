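"""Stationarity system, multistart solver, classification, post-processing."""

import numpy as np
import pytest

from steeropt.field_model import BasisFieldSet, RegionSpec
from steeropt.smooth_ops import Configuration, SmoothingParams
from steeropt.single_objective import (
    SolverSettings,
    classify_constrained,
    correct_fractions,
    jacobian_single,
    multistart_solve,
    residual_single,
    round_fractions,
)

from conftest import balanced_grid, fd_jacobian


def _basis(values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    m, n = values.shape
    region = RegionSpec(
        name="r", points=np.zeros((m, 3)) + np.arange(m)[:, None],
        direction=(0, 0, 1.0),
    )
    return BasisFieldSet(region=region, values=values,
                         contact_labels=tuple(f"c{i}" for i in range(n)))


class TestResidual:
    @pytest.mark.parametrize("n", [2, 4, 16])
    def test_length_is_n_plus_two(self, n):
        rng = np.random.default_rng(n)
        basis = _basis(rng.normal(size=(3, n)))
        r = residual_single(rng.normal(size=n), rng.normal(size=2), basis,
                            SmoothingParams(beta=1.0, gamma=50.0))
        assert r.shape == (n + 2,)

    def test_hand_solved_two_contact_stationarity(self):
        # m = 1, n = 2: soft max is the field itself, and at the exact
        # bipole (1, -1) with saturated tanh the multipliers solve in
        # closed form: lam1 = (f2 - f1)/2, lam2 = (f1 + f2)/2.
        f1, f2 = 3.0, 1.0
        basis = _basis([[f1, f2]])
        lam = np.array([(f2 - f1) / 2.0, (f1 + f2) / 2.0])
        r = residual_single([1.0, -1.0], lam, basis,
                            SmoothingParams(beta=4.0, gamma=60.0))
        assert np.linalg.norm(r) <= 1e-8

    def test_dimension_mismatch(self):
        basis = _basis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            residual_single([1.0, -1.0, 0.0], [0.0, 0.0], basis,
                            SmoothingParams(beta=1.0))


class TestJacobian:
    def test_matches_finite_differences_on_random_states(self):
        rng = np.random.default_rng(12)
        params = SmoothingParams(beta=2.0, gamma=25.0)
        basis = _basis(rng.normal(size=(4, 5)))
        n = 5
        for _ in range(10):
            a = rng.uniform(-0.9, 0.9, size=n)
            lam = rng.uniform(-2, 2, size=2)
            J = jacobian_single(a, lam, basis, params)

            def fun(z):
                return residual_single(z[:n], z[n:], basis, params)

            ref = fd_jacobian(fun, np.concatenate([a, lam]))
            np.testing.assert_allclose(J, ref, rtol=1e-6, atol=1e-7)

    def test_constraint_rows_are_constraint_gradients(self):
        from steeropt.smooth_ops import balance_gradients

        rng = np.random.default_rng(13)
        basis = _basis(rng.normal(size=(2, 3)))
        params = SmoothingParams(beta=1.5, gamma=40.0)
        a = rng.uniform(-1, 1, size=3)
        J = jacobian_single(a, [0.3, -0.2], basis, params)
        g1, g2 = balance_gradients(a, params.gamma)
        np.testing.assert_allclose(J[3, :3], g1, rtol=1e-14)
        np.testing.assert_allclose(J[4, :3], g2, rtol=1e-14)

    def test_pure_function_of_state(self):
        rng = np.random.default_rng(14)
        basis = _basis(rng.normal(size=(2, 3)))
        params = SmoothingParams(beta=1.0, gamma=30.0)
        a, lam = rng.normal(size=3), rng.normal(size=2)
        J1 = jacobian_single(a, lam, basis, params)
        J2 = jacobian_single(a, lam, basis, params)
        np.testing.assert_array_equal(J1, J2)


class TestMultistart:
    def test_two_contacts_forced_bipole(self):
        # constraints leave only (1,-1) and (-1,1); the max picks the
        # one aligned with the larger basis entry
        basis = _basis([[5.0, 2.0]])
        pts = multistart_solve(basis, settings=SolverSettings(seed=0,
                                                              n_starts=12))
        maxima = [p for p in pts if p.classification == "maximum"]
        assert maxima
        best = maxima[0]
        np.testing.assert_allclose(best.alpha.alpha, [1.0, -1.0], atol=5e-3)
        assert best.primary_objective == pytest.approx(3.0, rel=5e-3)

    def test_four_contact_matches_grid_oracle(self, four_contact_point_roi):
        grid = balanced_grid(4, 0.05)
        oracle = float(np.max(four_contact_point_roi.values @ grid.T))
        pts = multistart_solve(four_contact_point_roi,
                               settings=SolverSettings(seed=5, n_starts=25))
        maxima = [p for p in pts if p.classification == "maximum"]
        best = max(
            float(np.max(four_contact_point_roi.values @ p.alpha.alpha))
            for p in maxima
        )
        assert best == pytest.approx(oracle, rel=0.02)

    def test_deterministic_for_fixed_seed(self, four_contact_point_roi):
        s = SolverSettings(seed=123, n_starts=10)
        p1 = multistart_solve(four_contact_point_roi, settings=s)
        p2 = multistart_solve(four_contact_point_roi, settings=s)
        assert len(p1) == len(p2)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.alpha.alpha, b.alpha.alpha)
            assert a.classification == b.classification

    def test_residuals_revalidate_from_scratch(self, four_contact_point_roi):
        from steeropt.single_objective import _normalized

        settings = SolverSettings(seed=9, n_starts=10)
        pts = multistart_solve(four_contact_point_roi, settings=settings)
        scaled, scale = _normalized(four_contact_point_roi)
        from steeropt.smooth_ops import auto_beta

        params = SmoothingParams(beta=auto_beta(scaled))
        for p in pts:
            r = residual_single(p.alpha_raw, p.lam, scaled, params)
            assert np.linalg.norm(r) <= settings.residual_tol * 10

    def test_mirror_with_negative_beta(self, four_contact_point_roi):
        # the objective is linear in alpha, so flipping beta's sign
        # mirrors the critical set: the most negative soft objective sits
        # at the negated optimum
        from steeropt.single_objective import _normalized
        from steeropt.smooth_ops import auto_beta

        scaled, scale = _normalized(four_contact_point_roi)
        beta = auto_beta(scaled) / scale
        s = SolverSettings(seed=21, n_starts=20)
        pos = multistart_solve(four_contact_point_roi,
                               params=SmoothingParams(beta=beta), settings=s)
        neg = multistart_solve(four_contact_point_roi,
                               params=SmoothingParams(beta=-beta), settings=s)
        best = max(p.primary_objective for p in pos)
        worst = min(p.primary_objective for p in neg)
        assert worst == pytest.approx(-best, rel=1e-6)
        a_best = next(p for p in pos if p.primary_objective == best)
        a_worst = next(p for p in neg if p.primary_objective == worst)
        np.testing.assert_allclose(a_worst.alpha.alpha, -a_best.alpha.alpha,
                                   atol=1e-6)

    def test_scale_invariance(self, four_contact_point_roi):
        # multiplying the basis by c scales objectives by c and leaves
        # the corrected fractions unchanged (beta rescaled by 1/c)
        basis = four_contact_point_roi
        c = 37.0
        scaled_up = BasisFieldSet(
            region=basis.region, values=c * basis.values,
            contact_labels=basis.contact_labels,
        )
        s = SolverSettings(seed=2, n_starts=10)
        p1 = multistart_solve(basis, settings=s)
        p2 = multistart_solve(scaled_up, settings=s)
        b1 = max(p.primary_objective for p in p1)
        b2 = max(p.primary_objective for p in p2)
        assert b2 == pytest.approx(c * b1, rel=1e-9)
        a1 = next(p for p in p1 if p.primary_objective == b1).alpha.alpha
        a2 = next(p for p in p2 if p.primary_objective == b2).alpha.alpha
        np.testing.assert_allclose(a2, a1, atol=1e-8)


class TestClassify:
    def test_interior_maximum_of_negative_quadratic(self):
        # maximize -||x||^2 subject to sum x = 0: classified maximum
        H = -2.0 * np.eye(3)
        Jg = np.ones((1, 3))
        assert classify_constrained(H, Jg) == "maximum"

    def test_minimum_of_positive_quadratic(self):
        H = 2.0 * np.eye(3)
        Jg = np.ones((1, 3))
        assert classify_constrained(H, Jg) == "minimum"

    def test_constructed_saddle(self):
        # indefinite on the tangent space of a single linear constraint
        H = np.diag([2.0, -2.0, 1.0])
        Jg = np.array([[0.0, 0.0, 1.0]])
        assert classify_constrained(H, Jg) == "saddle"

    def test_agrees_with_projected_eigenvalue_oracle(self):
        from scipy.linalg import null_space

        rng = np.random.default_rng(31)
        for _ in range(30):
            n, k = 5, 2
            A = rng.normal(size=(n, n))
            H = (A + A.T) / 2.0
            Jg = rng.normal(size=(k, n))
            Z = null_space(Jg)
            eig = np.linalg.eigvalsh(Z.T @ H @ Z)
            if np.all(eig < -1e-8):
                expected = "maximum"
            elif np.all(eig > 1e-8):
                expected = "minimum"
            elif np.any(eig < -1e-8) and np.any(eig > 1e-8):
                expected = "saddle"
            else:
                continue
            assert classify_constrained(H, Jg) == expected

    def test_rank_deficient_constraints_invalid(self):
        H = np.eye(3)
        Jg = np.array([[1.0, 0, 0], [2.0, 0, 0]])
        assert classify_constrained(H, Jg) == "invalid"


class TestCorrectFractions:
    def test_symmetric_pair(self):
        c = correct_fractions(np.array([0.6, -0.6]))
        np.testing.assert_allclose(c.alpha, [1.0, -1.0])

    def test_three_contact_arithmetic(self):
        # sum|alpha| = 1.6, so each entry is scaled by 2/1.6 = 1.25
        c = correct_fractions(np.array([0.5, 0.3, -0.8]))
        np.testing.assert_allclose(c.alpha, [0.625, 0.375, -1.0], rtol=1e-15)

    def test_idempotent_on_satisfying_input(self):
        a = np.array([0.625, 0.375, -1.0])
        c = correct_fractions(a)
        np.testing.assert_allclose(c.alpha, a, rtol=1e-15)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            correct_fractions(np.zeros(4))

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            correct_fractions(np.array([1.0, -0.5]))

    def test_machine_precision_sum(self):
        rng = np.random.default_rng(8)
        raw = rng.normal(size=10)
        raw -= raw.mean()
        c = correct_fractions(raw, imbalance_tol=1.0)
        assert np.sum(np.abs(c.alpha)) == pytest.approx(2.0, abs=4e-16)


class TestRoundFractions:
    def test_bipole_unchanged(self):
        c = Configuration(alpha=np.array([1.0, -1.0]),
                          provenance="corrected")
        r = round_fractions(c)
        np.testing.assert_array_equal(r.alpha, [1.0, -1.0])

    def test_three_digit_balanced_unchanged(self):
        c = Configuration(alpha=np.array([0.625, 0.375, -1.0]),
                          provenance="corrected")
        r = round_fractions(c)
        np.testing.assert_allclose(r.alpha, [0.625, 0.375, -1.0], rtol=1e-15)

    def test_sixteen_fraction_machine_entries_rebalance(self):
        rng = np.random.default_rng(17)
        raw = rng.uniform(-1, 1, size=16)
        raw -= raw.mean()
        c = correct_fractions(raw, imbalance_tol=1.0)
        r = round_fractions(c)
        pos = r.alpha[r.alpha > 0]
        neg = r.alpha[r.alpha < 0]
        assert abs(float(np.sum(pos)) - 1.0) <= 1e-12
        assert abs(float(np.sum(neg)) + 1.0) <= 1e-12

    def test_raw_configuration_rejected(self):
        with pytest.raises(ValueError):
            round_fractions(Configuration(alpha=np.array([0.5, -0.5]),
                                          provenance="raw"))
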