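import numpy as np
import pytest

from fuseaft import (
    CancerDataset,
    PenaltySpec,
    fit_joint,
    joint_objective,
    mcp_prox,
    mcp_value,
    magnitude_fusion_value,
    predict_survival_scores,
    sign_fusion_value,
    weighted_standardize,
)
from fuseaft.exceptions import DataFormatError
from fuseaft.kmweights import KMWeights, compute_km_weights

from conftest import make_cohorts


def objective_oracle(beta, alpha, dsets, weights, spec):
    total = 0.0
    for k, ds in enumerate(dsets):
        for i in range(ds.n):
            r = ds.y[i] - alpha[k] - float(ds.X[i] @ beta[:, k])
            total += weights[k].w[i] * r * r / (2 * ds.n)
    for k in range(len(dsets)):
        for j in range(beta.shape[0]):
            total += mcp_value(abs(beta[j, k]), spec.lambda_sparsity, spec.gamma)
    for j in range(beta.shape[0]):
        if spec.fusion_type == "magnitude":
            total += 0.5 * spec.lambda_fusion * magnitude_fusion_value(beta[j])
        elif spec.fusion_type == "sign":
            total += 0.5 * spec.lambda_fusion * sign_fusion_value(beta[j])
    return total


class TestJointObjective:
    def test_zero_beta_weighted_rss(self, small_cohorts):
        dsets, weights = small_cohorts
        spec = PenaltySpec("magnitude", 0.2, 0.5)
        got = joint_objective(np.zeros((6, 3)), np.zeros(3), dsets, weights, spec)
        expected = sum(0.5 / ds.n * float(w.w @ (ds.y**2))
                       for ds, w in zip(dsets, weights))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_single_cohort_no_fusion_term(self):
        dsets, weights = make_cohorts(K=1, p=4, n=30, seed=4)
        rng = np.random.default_rng(0)
        beta = rng.normal(size=(4, 1))
        spec_mag = PenaltySpec("magnitude", 0.1, 5.0)
        spec_none = PenaltySpec("none", 0.1, 0.0)
        a = np.zeros(1)
        assert joint_objective(beta, a, dsets, weights, spec_mag) == (
            pytest.approx(joint_objective(beta, a, dsets, weights, spec_none))
        )

    @pytest.mark.parametrize("fusion", ["magnitude", "sign"])
    def test_matches_reevaluation_oracle(self, fusion):
        dsets, weights = make_cohorts(K=2, p=3, n=15, seed=9)
        spec = PenaltySpec(fusion, 0.15, 0.4)
        rng = np.random.default_rng(2)
        beta, alpha = rng.normal(size=(3, 2)), rng.normal(size=2)
        got = joint_objective(beta, alpha, dsets, weights, spec)
        assert got == pytest.approx(
            objective_oracle(beta, alpha, dsets, weights, spec), abs=1e-12
        )

    def test_shape_error(self, small_cohorts):
        dsets, weights = small_cohorts
        with pytest.raises(DataFormatError):
            joint_objective(np.zeros((2, 3)), np.zeros(3), dsets, weights,
                            PenaltySpec())


class TestFitJoint:
    def test_fusion_zero_reduces_to_separate_fits(self, small_cohorts):
        dsets, weights = small_cohorts
        spec = PenaltySpec("none", 0.05, 0.0)
        fit = fit_joint(dsets, weights, spec, tol=1e-8)
        for k in range(len(dsets)):
            single = fit_joint([dsets[k]], [weights[k]], spec, tol=1e-8)
            assert np.max(np.abs(fit.beta[:, k] - single.beta[:, 0])) < 1e-6

    def test_orthonormal_design_analytic_update(self):
        """K=1, weighted-orthonormal design: solution is the coordinatewise
        prox of the weighted inner products."""
        rng = np.random.default_rng(5)
        n, p = 40, 4
        w = np.full(n, 1.0)  # equal unit weights: events everywhere
        M = rng.standard_normal((n, p))
        # Gram-Schmidt in the (1/n) sum w a b inner product, after centering
        Q = np.empty_like(M)
        for j in range(p):
            v = M[:, j] - np.mean(M[:, j])
            for l in range(j):
                v -= (v @ (w * Q[:, l]) / n) * Q[:, l]
            Q[:, j] = v / np.sqrt(v @ (w * v) / n)
        beta_true = np.array([2.0, -1.0, 0.0, 0.0])
        y = Q @ beta_true + 0.1 * rng.standard_normal(n)
        ds = CancerDataset.from_log_times(
            "C1", [f"G{j}" for j in range(p)], Q, y, np.ones(n, dtype=int)
        )
        kw = KMWeights(w=w)
        spec = PenaltySpec("none", 0.3, 0.0)
        fit = fit_joint([ds], [kw], spec, tol=1e-10)
        std, rec = weighted_standardize(ds, kw)
        u = (kw.w * std.y) @ std.X / n
        expected = mcp_prox(u, 1.0, 0.3, 3.0)
        assert np.max(np.abs(fit.beta_std[:, 0] - expected)) < 1e-8

    def test_perturbation_oracle(self):
        dsets, weights = make_cohorts(K=2, p=3, n=30, seed=17)
        spec = PenaltySpec("magnitude", 0.05, 0.3)
        fit = fit_joint(dsets, weights, spec, tol=1e-8)
        stds = [weighted_standardize(d, w)[0] for d, w in zip(dsets, weights)]
        base = joint_objective(fit.beta_std, np.zeros(2), stds, weights, spec)
        rng = np.random.default_rng(3)
        for _ in range(10000):
            pert = fit.beta_std + rng.uniform(-0.05, 0.05, size=fit.beta_std.shape)
            assert joint_objective(pert, np.zeros(2), stds, weights, spec) >= (
                base - 1e-10
            )

    def test_kkt_resolve_moves_small(self, small_cohorts):
        dsets, weights = small_cohorts
        tol = 1e-6
        fit = fit_joint(dsets, weights, PenaltySpec("magnitude", 0.05, 0.2),
                        tol=tol, max_iter=5000)
        assert fit.converged
        assert fit.diagnostics["max_resolve_move"] < 10 * tol

    def test_objective_trace_finite(self, small_cohorts):
        dsets, weights = small_cohorts
        fit = fit_joint(dsets, weights, PenaltySpec("sign", 0.05, 0.1))
        assert np.all(np.isfinite(fit.objective_trace))

    @pytest.mark.parametrize("fusion", ["magnitude", "sign"])
    def test_frozen_surrogate_non_increasing(self, fusion):
        dsets, weights = make_cohorts(K=3, p=5, n=50, seed=23)
        fit = fit_joint(dsets, weights, PenaltySpec(fusion, 0.03, 0.4),
                        monitor=True)
        for before, after in fit.diagnostics["monitor_pairs"]:
            assert after <= before + 1e-10

    def test_cohort_permutation_equivariance(self, small_cohorts):
        dsets, weights = small_cohorts
        spec = PenaltySpec("magnitude", 0.05, 0.3)
        fit = fit_joint(dsets, weights, spec, tol=1e-10, max_iter=3000)
        perm = [1, 2, 0]
        fit_p = fit_joint([dsets[i] for i in perm], [weights[i] for i in perm],
                          spec, tol=1e-10, max_iter=3000)
        assert np.max(np.abs(fit_p.beta - fit.beta[:, perm])) < 1e-6

    def test_warm_start_same_solution(self, small_cohorts):
        dsets, weights = small_cohorts
        spec = PenaltySpec("magnitude", 0.05, 0.2)
        cold = fit_joint(dsets, weights, spec, tol=1e-8)
        warm = fit_joint(dsets, weights, spec, tol=1e-8,
                         beta_init=cold.beta_std)
        assert np.max(np.abs(cold.beta - warm.beta)) < 1e-6


class TestPredict:
    def _fit(self):
        dsets, weights = make_cohorts(K=2, p=4, n=40, seed=31)
        fit = fit_joint(dsets, weights, PenaltySpec("none", 0.05, 0.0))
        return fit, dsets

    def test_zero_beta_constant(self):
        fit, dsets = self._fit()
        fit.beta[:] = 0.0
        scores = predict_survival_scores(fit, dsets[0], "C1")
        assert np.allclose(scores, fit.alpha[0])

    def test_single_coefficient(self):
        fit, dsets = self._fit()
        fit.beta[:] = 0.0
        fit.beta[2, 0] = 1.0
        scores = predict_survival_scores(fit, dsets[0], "C1")
        assert np.allclose(scores, fit.alpha[0] + dsets[0].X[:, 2])

    def test_affine_map(self):
        fit, dsets = self._fit()
        scores = predict_survival_scores(fit, dsets[1], "C2")
        expected = fit.alpha[1] + dsets[1].X @ fit.beta[:, 1]
        assert np.allclose(scores, expected)

    def test_gene_mismatch_error(self):
        fit, dsets = self._fit()
        bad = CancerDataset(
            "C1", ["X1", "X2", "X3", "X4"], dsets[0].X, dsets[0].y,
            dsets[0].delta,
        )
        with pytest.raises(DataFormatError):
            predict_survival_scores(fit, bad, "C1")
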