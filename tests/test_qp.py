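"""Fused-lasso QP: fusion weights, solver correctness, budget behavior."""

import numpy as np
import pytest

from fusedcna import (
    AnnotationError,
    FusedLassoParams,
    FusionWeights,
    ProbeMap,
    QPSpec,
    compute_fusion_weights,
    make_probe_map,
    qp_objective,
    solve_qp,
)

from helpers import chain_pairs, slsqp_fused_lasso


def _one_arm_map(positions):
    n = len(positions)
    return ProbeMap(
        [f"P{j}" for j in range(n)], ["1"] * n, positions, ["p"] * n
    )


class TestFusionWeights:
    def test_equal_gaps_give_unit_weights(self):
        pm = _one_arm_map([1, 2001, 4001])
        fw = compute_fusion_weights(pm)
        np.testing.assert_array_equal(fw.weights, [1.0, 1.0])
        np.testing.assert_array_equal(fw.pairs, [[0, 1], [1, 2]])

    def test_inverse_median_hand_values(self):
        # gaps 1000, 2000, 4000 -> median 2000 -> weights 1, 1, 0.5
        pm = _one_arm_map([1, 1001, 3001, 7001])
        fw = compute_fusion_weights(pm)
        np.testing.assert_allclose(fw.weights, [1.0, 1.0, 0.5])

    def test_no_pair_across_arm_boundary(self, probe_map_10):
        fw = compute_fusion_weights(probe_map_10)
        # probes 0-4 are p-arm, 5-9 q-arm: the (4, 5) pair must be absent
        assert len(fw) == 8
        assert [4, 5] not in fw.pairs.tolist()

    def test_no_pair_across_chromosomes(self):
        pm = ProbeMap(
            ["A", "B", "C"], ["1", "1", "2"], [100, 200, 50], ["q", "q", "p"]
        )
        fw = compute_fusion_weights(pm)
        assert fw.pairs.tolist() == [[0, 1]]

    def test_single_probe_arm_has_no_pairs(self):
        pm = ProbeMap(["A"], ["1"], [100], ["p"])
        assert len(compute_fusion_weights(pm)) == 0

    def test_uniform_form_and_callable(self):
        pm = _one_arm_map([1, 1001, 3001])
        assert compute_fusion_weights(pm, form="uniform").weights.tolist() == [1.0, 1.0]
        fw = compute_fusion_weights(pm, form=lambda d: np.full(len(d), 0.25))
        assert fw.weights.tolist() == [0.25, 0.25]

    def test_weights_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            FusionWeights(np.array([[0, 1]]), np.array([1.5]))


def _random_instance(rng, n=None, p=None):
    n = n or int(rng.integers(2, 7))
    p = p or int(rng.integers(2, 9))
    X = rng.normal(size=(n, p))
    y = rng.choice([-1.0, 1.0], size=n)
    pairs = chain_pairs(p)
    w = rng.uniform(0.3, 1.0, size=len(pairs))
    return X, y, pairs, w


class TestSolveQP:
    def test_zero_sparsity_budget_forces_constant_model(self, rng):
        X = rng.normal(size=(5, 4))
        y = rng.normal(size=5)
        fw = FusionWeights(chain_pairs(4), np.ones(3))
        sep = solve_qp(QPSpec(X, y, fw, FusedLassoParams(s1=0.0, s2=1.0)))
        assert np.all(sep.beta == 0.0)
        assert sep.bias == pytest.approx(np.mean(y), abs=1e-14)

    def test_orthogonality_to_coordinate_axis_zeroes_that_weight(self, rng):
        X = rng.normal(size=(6, 5))
        y = rng.choice([-1.0, 1.0], size=6)
        fw = FusionWeights(chain_pairs(5), np.ones(4))
        e1 = np.zeros(5)
        e1[0] = 1.0
        sep = solve_qp(QPSpec(X, y, fw, FusedLassoParams(2.0, 2.0), [e1]))
        assert abs(sep.beta[0]) <= 1e-6

    @pytest.mark.parametrize("seed", range(8))
    def test_objective_matches_generic_convex_solver(self, seed):
        rng = np.random.default_rng(seed)
        X, y, pairs, w = _random_instance(rng)
        s1, s2 = rng.uniform(0.1, 5.0, size=2)
        orth = [rng.normal(size=X.shape[1])] if seed % 3 == 0 else []
        sep = solve_qp(
            QPSpec(X, y, FusionWeights(pairs, w), FusedLassoParams(s1, s2), orth)
        )
        obj = qp_objective(X, y, sep.beta, sep.bias)
        obj_oracle, _, _ = slsqp_fused_lasso(X, y, s1, s2, pairs, w, orth)
        assert obj == pytest.approx(obj_oracle, abs=1e-5)

    @pytest.mark.parametrize("seed", range(6))
    def test_solution_feasible_within_tolerance(self, seed):
        rng = np.random.default_rng(100 + seed)
        X, y, pairs, w = _random_instance(rng)
        s1, s2 = rng.uniform(0.1, 5.0, size=2)
        v = rng.normal(size=X.shape[1])
        sep = solve_qp(
            QPSpec(X, y, FusionWeights(pairs, w), FusedLassoParams(s1, s2), [v])
        )
        assert np.abs(sep.beta).sum() <= s1 + 1e-6
        diffs = sep.beta[pairs[:, 1]] - sep.beta[pairs[:, 0]]
        assert np.abs(diffs) @ w <= s2 + 1e-6
        assert abs(v @ sep.beta) <= 1e-6

    def test_permissive_budgets_match_unconstrained_least_squares(self, rng):
        X = rng.normal(size=(8, 4))  # full-rank tall instance
        y = rng.normal(size=8)
        fw = FusionWeights(chain_pairs(4), np.ones(3))
        sep = solve_qp(QPSpec(X, y, fw, FusedLassoParams(1e6, 1e6)))
        Z = np.column_stack([X, np.ones(8)])
        coef = np.linalg.lstsq(Z, y, rcond=None)[0]
        np.testing.assert_allclose(np.r_[sep.beta, sep.bias], coef, atol=1e-4)

    def test_objective_nonincreasing_in_budgets(self):
        rng = np.random.default_rng(7)
        X, y, pairs, w = _random_instance(rng, n=6, p=6)
        fw = FusionWeights(pairs, w)

        def optimum(s1, s2):
            sep = solve_qp(QPSpec(X, y, fw, FusedLassoParams(s1, s2)))
            return qp_objective(X, y, sep.beta, sep.bias)

        grid = [0.2, 0.5, 1.0, 2.0, 4.0]
        for s2 in (0.5, 2.0):
            objs = [optimum(s1, s2) for s1 in grid]
            assert all(b <= a + 1e-7 for a, b in zip(objs, objs[1:]))
        for s1 in (0.5, 2.0):
            objs = [optimum(s1, s2) for s2 in grid]
            assert all(b <= a + 1e-7 for a, b in zip(objs, objs[1:]))

    def test_zero_fusion_budget_collapses_arms(self, rng):
        X = rng.normal(size=(6, 6))
        y = rng.choice([-1.0, 1.0], size=6)
        pairs = chain_pairs(6, boundary=3)  # two chains: 0-2 and 3-5
        fw = FusionWeights(pairs, np.ones(len(pairs)))
        sep = solve_qp(QPSpec(X, y, fw, FusedLassoParams(2.0, 0.0)))
        assert np.ptp(sep.beta[:3]) <= 1e-8
        assert np.ptp(sep.beta[3:]) <= 1e-8
        # oracle: plain L1 problem on the two collapsed columns
        Xc = np.column_stack([X[:, :3].sum(axis=1), X[:, 3:].sum(axis=1)])
        obj_oracle, _, _ = slsqp_fused_lasso(
            Xc / 3.0, y, 2.0, np.inf, np.empty((0, 2), int), np.empty(0)
        )
        # rescale: beta_c on collapsed columns has L1 weight 3 per unit
        obj = qp_objective(X, y, sep.beta, sep.bias)
        assert obj == pytest.approx(obj_oracle, abs=1e-5)

    def test_full_rank_orthogonality_set_raises(self, rng):
        X = rng.normal(size=(4, 3))
        y = rng.choice([-1.0, 1.0], size=4)
        fw = FusionWeights(chain_pairs(3), np.ones(2))
        orth = [np.eye(3)[i] for i in range(3)]
        with pytest.raises(np.linalg.LinAlgError):
            solve_qp(QPSpec(X, y, fw, FusedLassoParams(1.0, 1.0), orth))

    def test_nonpositive_gap_rejected(self):
        with pytest.raises(AnnotationError):
            ProbeMap(["A", "B"], ["1", "1"], [100, 100], ["p", "p"])

    def test_negative_budgets_rejected(self):
        with pytest.raises(ValueError):
            FusedLassoParams(s1=-1.0)
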