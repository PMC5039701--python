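"""Outer LLA loop: initialization, weights, convergence rule, full fits."""

import numpy as np
import pytest

from tdjgl import (
    ADMMSettings,
    LLASettings,
    MultiPlatformData,
    ObjectiveConfig,
    PrecisionSet,
    SampleCovarianceSet,
    check_convergence,
    compute_sample_covariances,
    fit_baseline,
    fit_tdjgl,
    initialize,
    sample_scenario,
    update_weights,
)
from tdjgl.simulate import ScenarioConfig


class TestInitialize:
    def test_regularized_inverse_when_n_at_least_p(self):
        p = 3
        cov = SampleCovarianceSet(
            S=[[np.eye(p), np.eye(p)]], n=(10, 10), weights=(10.0, 10.0)
        )
        theta0 = initialize(cov, LLASettings(delta=1e-3))
        np.testing.assert_allclose(
            theta0.Theta[0][0], np.eye(p) / 1.001, rtol=1e-12
        )

    def test_default_delta(self):
        assert LLASettings().delta == 1e-3

    def test_high_dimensional_fallback_is_fused_solution(self, rng):
        # n < p: initializer comes from the constant-weight fused solve,
        # so its support is sparse rather than dense
        p, n = 12, 6
        X = [[rng.normal(size=(n, p)) for _ in range(2)]]
        data = MultiPlatformData(X=X, genes=[f"g{i}" for i in range(p)])
        cov = compute_sample_covariances(data, equal_group_weights=True)
        theta0 = initialize(cov, LLASettings(), ObjectiveConfig(lambda1=0.3))
        assert theta0.Z is not None
        off = ~np.eye(p, dtype=bool)
        assert (theta0.Z[0][0][off] == 0).sum() > 0


class TestUpdateWeights:
    def test_direct_formula(self):
        # |theta_12| = 0.25 in all six matrices -> omega = 1/(2 sqrt(1.5))
        T = np.eye(2)
        T[0, 1] = T[1, 0] = 0.25
        theta = PrecisionSet(Theta=[[T.copy(), T.copy()] for _ in range(3)])
        Omega, _ = update_weights(theta, LLASettings(epsilon=1e-12))
        assert Omega[0, 1] == pytest.approx(1 / (2 * np.sqrt(1.5)), rel=1e-6)
        assert Omega[0, 0] == 0.0

    def test_zero_support_gives_large_weight(self):
        theta = PrecisionSet(Theta=[[np.eye(3), np.eye(3)]])
        eps = 1e-8
        Omega, _ = update_weights(theta, LLASettings(epsilon=eps))
        assert Omega[0, 1] == pytest.approx(1 / (2 * np.sqrt(eps)))

    def test_identical_groups_give_large_fusion_weight(self):
        T = np.eye(3)
        T[0, 1] = T[1, 0] = 0.4
        theta = PrecisionSet(Theta=[[T.copy(), T.copy()]])
        eps = 1e-8
        _, Psi = update_weights(theta, LLASettings(epsilon=eps))
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(Psi[off], 1 / (2 * np.sqrt(eps)))


class TestCheckConvergence:
    def test_identical_iterates_converge(self):
        theta = PrecisionSet(Theta=[[np.eye(3), np.eye(3)]])
        assert check_convergence(theta, theta, tol=1e-3)

    def test_relative_l1_arithmetic(self):
        prev = PrecisionSet(Theta=[[np.ones((2, 2))] * 2 for _ in range(3)])
        curr_mats = [[np.ones((2, 2)) for _ in range(2)] for _ in range(3)]
        curr_mats[0][0] = np.ones((2, 2)) + np.array(
            [[0.012, 0.0], [0.0, 0.0]]
        )
        curr = PrecisionSet(Theta=curr_mats)
        # denominator 24, change 0.012 -> ratio 5e-4 < 1e-3
        assert check_convergence(prev, curr, tol=1e-3)
        assert not check_convergence(prev, curr, tol=4e-4)

    def test_strict_inequality_at_zero_tol(self):
        theta = PrecisionSet(Theta=[[np.eye(2), np.eye(2)]])
        assert not check_convergence(theta, theta, tol=0.0)

    def test_all_zero_previous_iterate_rejected(self):
        z = PrecisionSet(Theta=[[np.zeros((2, 2))] * 2])
        with pytest.raises(ValueError, match="undefined"):
            check_convergence(z, z, tol=1e-3)


class TestFitTDJGL:
    def test_heavy_lasso_empties_all_networks(self, small_scenario):
        data, _ = small_scenario
        cov = compute_sample_covariances(data, equal_group_weights=True)
        lam = 1e3 * max(np.abs(S).max() for row in cov.S for S in row)
        fit = fit_tdjgl(data, cfg=ObjectiveConfig(lambda1=lam, equal_group_weights=True))
        for k in range(data.K):
            for c in range(2):
                assert not fit.precisions.support(k, c).any()

    def test_heavy_fusion_makes_groups_identical(self, small_scenario):
        data, _ = small_scenario
        fit = fit_tdjgl(
            data,
            cfg=ObjectiveConfig(
                lambda1=0.05, lambda2=100.0, equal_group_weights=True
            ),
        )
        for k in range(data.K):
            np.testing.assert_array_equal(
                fit.precisions.Z[k][0], fit.precisions.Z[k][1]
            )

    def test_objective_trace_non_increasing(self, small_fit):
        trace = small_fit.objective_trace
        for a, b in zip(trace, trace[1:]):
            assert b <= a + 1e-3 * abs(a)

    def test_supports_symmetric(self, small_fit):
        for k in range(small_fit.precisions.K):
            for c in range(2):
                sup = small_fit.precisions.support(k, c)
                np.testing.assert_array_equal(sup, sup.T)

    def test_platform_permutation_equivariance(self, small_scenario):
        data, _ = small_scenario
        cfg = ObjectiveConfig(lambda1=0.1, lambda2=0.05, equal_group_weights=True)
        fit = fit_tdjgl(data, cfg=cfg)
        perm = [2, 0, 1]
        data_p = MultiPlatformData(
            X=[data.X[k] for k in perm],
            genes=data.genes,
            platform_labels=[data.platform_labels[k] for k in perm],
        )
        fit_p = fit_tdjgl(data_p, cfg=cfg)
        for new_k, old_k in enumerate(perm):
            np.testing.assert_allclose(
                fit_p.precisions.Z[new_k][0],
                fit.precisions.Z[old_k][0],
                atol=1e-8,
            )

    def test_error_decreases_with_sample_size(self):
        # estimation consistency on the Erdos-Renyi design
        from tdjgl.evaluation import estimation_error

        errors = []
        for n in (50, 200, 500):
            errs = []
            for seed in range(5):
                cfg = ScenarioConfig(
                    network_type="erdos_renyi", p=20, n=n, K=2, tau=0.1,
                    edge_prob=0.1, seed=100 + seed,
                )
                data, truth = sample_scenario(cfg)
                fit = fit_tdjgl(
                    data,
                    cfg=ObjectiveConfig(
                        lambda1=0.1, lambda2=0.02, equal_group_weights=True
                    ),
                )
                errs.append(estimation_error(fit.precisions, truth))
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]

    def test_cross_platform_support_overlap_beats_gl(self, small_scenario):
        # shared true support: joint fitting should align platform supports
        # more than independent graphical lassos do
        data, _ = small_scenario

        def jaccard(fit):
            sups = [fit.precisions.support(k, 0) for k in range(data.K)]
            inter = sups[0] & sups[1] & sups[2]
            union = sups[0] | sups[1] | sups[2]
            return inter.sum() / max(union.sum(), 1)

        cfg = ObjectiveConfig(lambda1=0.15, lambda2=0.02, equal_group_weights=True)
        j_tdjgl = jaccard(fit_tdjgl(data, cfg=cfg))
        j_gl = jaccard(fit_baseline(data, "GL", cfg=cfg))
        assert j_tdjgl > j_gl


class TestFitBaseline:
    def test_fgl_with_zero_fusion_equals_gl(self, small_scenario):
        data, _ = small_scenario
        cfg_gl = ObjectiveConfig(lambda1=0.15, equal_group_weights=True)
        cfg_fgl = ObjectiveConfig(lambda1=0.15, lambda2=0.0, equal_group_weights=True)
        tight = ADMMSettings(tol_abs=1e-9, tol_rel=1e-8, max_iter=3000)
        gl = fit_baseline(data, "GL", cfg=cfg_gl, admm=tight)
        fgl = fit_baseline(data, "FGL", cfg=cfg_fgl, admm=tight)
        for k in range(data.K):
            for c in range(2):
                np.testing.assert_allclose(
                    gl.precisions.Z[k][c], fgl.precisions.Z[k][c], atol=1e-6
                )

    def test_gl_matches_reference_graphical_lasso(self, rng):
        from sklearn.covariance import graphical_lasso as reference_gl

        p = 4
        X = [[rng.normal(size=(150, p)) for _ in range(2)]]
        data = MultiPlatformData(X=X, genes=[f"g{i}" for i in range(p)])
        cfg = ObjectiveConfig(lambda1=0.08, equal_group_weights=True)
        tight = ADMMSettings(tol_abs=1e-9, tol_rel=1e-8, max_iter=3000)
        fit = fit_baseline(data, "GL", cfg=cfg, admm=tight)
        cov = compute_sample_covariances(data, equal_group_weights=True)
        for c in range(2):
            _, prec_ref = reference_gl(cov.S[0][c], alpha=0.08)
            np.testing.assert_allclose(
                fit.precisions.Z[0][c], prec_ref, atol=1e-3
            )

    def test_strong_fusion_aligns_group_supports(self, small_scenario):
        data, _ = small_scenario
        fit = fit_baseline(
            data,
            "FGL",
            cfg=ObjectiveConfig(
                lambda1=0.1, lambda2=50.0, equal_group_weights=True
            ),
        )
        for k in range(data.K):
            np.testing.assert_array_equal(
                fit.precisions.support(k, 0), fit.precisions.support(k, 1)
            )

    def test_unknown_method_rejected(self, small_scenario):
        data, _ = small_scenario
        with pytest.raises(ValueError, match="unknown"):
            fit_baseline(data, "GGL")
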