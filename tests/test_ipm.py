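import numpy as np
import pandas as pd
import pytest
from scipy import linalg
from scipy.special import expit, logit

from skinkipm import ipm as ipm_mod
from skinkipm.cjs import CJSModel, CJSModelSpec
from skinkipm.gompertz import GompertzFit, survival_by_size
from skinkipm.growth import GrowthFit, growth_transition
from skinkipm.ipm import (
    IPMKernel,
    assemble_month,
    build_F,
    build_P,
    combine_survival,
    lambda_eigen,
    make_mesh,
    monthly_lambda_series,
    perturbation_analysis,
    yearly_matrix,
)

MESH, H = make_mesh()
GROWTH = GrowthFit(linf=79.0, k=0.094, sigma=0.4, birth_svl=35.0)
GOMP = GompertzFit(-3.5, 0.02)


def _cjs_stub(beta_tmax=-0.5):
    m = CJSModel(CJSModelSpec(("tmax",), ()))
    m.cov_means_ = {"tmax": 28.0, "precip": 100.0, "mean_svl": 55.0}
    m.cov_sds_ = {"tmax": 2.0, "precip": 80.0, "mean_svl": 3.0}
    m.beta_phi_ = np.array([2.5, beta_tmax])
    m.beta_p_ = np.array([0.0])
    return m


def _survival_vec():
    return survival_by_size(MESH, GOMP, GROWTH, clamp_warn=False)


class TestBuildP:
    def test_column_sums_equal_survival_exactly(self):
        G = growth_transition(MESH, GROWTH)
        S = _survival_vec()
        P = build_P(MESH, S, G)
        np.testing.assert_allclose(P.sum(axis=0), S, atol=1e-12)

    def test_identity_limit(self):
        # asymptote far above the mesh so every size class is non-degenerate
        G = growth_transition(MESH, GrowthFit(linf=500.0, k=1e-12, sigma=1e-14))
        P = build_P(MESH, np.ones(MESH.size), G)
        np.testing.assert_allclose(P, np.eye(MESH.size), atol=1e-12)

    def test_projection_conserves_survivors(self):
        G = growth_transition(MESH, GROWTH)
        S = _survival_vec()
        P = build_P(MESH, S, G)
        rng = np.random.default_rng(0)
        n = rng.uniform(0, 5, MESH.size)
        assert (P @ n).sum() * H == pytest.approx(float(S @ n) * H, abs=1e-10)

    def test_rejects_survival_outside_unit_interval(self):
        G = growth_transition(MESH, GROWTH)
        with pytest.raises(ValueError):
            build_P(MESH, np.full(MESH.size, 1.2), G)


class TestBuildF:
    def test_zero_outside_breeding_season(self):
        F = build_F(MESH, 6, litter_mean=3.3)
        assert not F.any()

    def test_immature_columns_are_zero(self):
        F = build_F(MESH, 10, litter_mean=3.3)
        assert not F[:, MESH < 54.0].any()
        assert F[:, MESH >= 54.0].any()

    def test_annual_recruitment_sums_to_litter_times_sex_ratio(self):
        total = sum(
            build_F(MESH, m, litter_mean=3.3, sex_ratio=0.5).sum(axis=0)
            for m in (9, 10, 11, 12, 1)
        )
        mature = MESH >= 54.0
        np.testing.assert_allclose(total[mature], 3.3 * 0.5, atol=1e-10)
        np.testing.assert_allclose(total[~mature], 0.0, atol=1e-12)

    def test_neonate_mass_escaping_mesh_rejected(self):
        with pytest.raises(ValueError, match="neonate"):
            build_F(MESH, 10, litter_mean=3.3, neonate_mu=30.2, neonate_sd=3.0)

    def test_maturity_outside_mesh_rejected(self):
        with pytest.raises(ValueError, match="maturity"):
            build_F(MESH, 10, litter_mean=3.3, maturity_svl=200.0)


class TestCombineSurvival:
    def test_reduces_to_size_survival_at_mean_environment(self):
        cjs = _cjs_stub()
        env = {"tmax": 28.0, "precip": 100.0, "mean_svl": 55.0}
        s = combine_survival(MESH, env, GOMP, cjs, GROWTH)
        np.testing.assert_allclose(s, _survival_vec(), atol=1e-9)

    def test_hot_month_lowers_survival_everywhere(self):
        cjs = _cjs_stub(beta_tmax=-0.5)
        hot = {"tmax": 31.0, "precip": 100.0, "mean_svl": 55.0}
        s = combine_survival(MESH, hot, GOMP, cjs, GROWTH)
        assert np.all(s < _survival_vec())


class TestYearlyMatrix:
    def test_identity_kernels(self):
        eye = [np.eye(4)] * 12
        np.testing.assert_allclose(yearly_matrix(eye), np.eye(4))

    def test_wrong_month_count_rejected(self):
        with pytest.raises(ValueError, match="12"):
            yearly_matrix([np.eye(3)] * 11)

    def test_commuting_diagonal_kernels(self):
        rng = np.random.default_rng(1)
        diags = [np.diag(rng.uniform(0.5, 1.5, 5)) for _ in range(12)]
        expected = np.diag(np.prod([np.diag(d) for d in diags], axis=0))
        np.testing.assert_allclose(yearly_matrix(diags), expected)

    def test_product_matches_sequential_stepping(self):
        rng = np.random.default_rng(2)
        mats = [rng.uniform(0, 0.3, (20, 20)) for _ in range(12)]
        n0 = rng.uniform(0, 1, 20)
        stepped = n0.copy()
        for K in mats:
            stepped = K @ stepped
        np.testing.assert_allclose(yearly_matrix(mats) @ n0, stepped, atol=1e-12)


class TestLambdaEigen:
    def test_two_by_two_closed_form(self):
        s, f = 0.3, 2.1
        res = lambda_eigen(np.array([[0.0, f], [s, 0.0]]) + 1e-14)
        assert res.lam == pytest.approx(np.sqrt(s * f), rel=1e-9)

    def test_matches_dense_eigensolver_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            A = rng.uniform(0.01, 1.0, (30, 30))
            res = lambda_eigen(A)
            dense = np.max(np.real(linalg.eigvals(A)))
            assert res.lam == pytest.approx(dense, abs=1e-8)
            # w, v are the dominant right/left eigenvectors
            np.testing.assert_allclose(A @ res.w, res.lam * res.w, atol=1e-7)
            np.testing.assert_allclose(res.v @ A, res.lam * res.v, atol=1e-6)

    def test_reducible_matrix_rejected(self):
        A = np.array([[0.5, 0.0], [0.0, 0.5]])
        with pytest.raises(ValueError, match="reducible"):
            lambda_eigen(A)

    def test_r0_and_generation_time(self):
        # single-class sanity: survival s, fecundity f per step
        s, f = 0.5, 0.8
        A = np.array([[s + f]])
        res = lambda_eigen(A, mean_P=np.array([[s]]), mean_F=np.array([[f]]),
                           months_per_step=1.0)
        R0 = f / (1 - s)
        assert res.R0 == pytest.approx(R0, rel=1e-9)
        assert res.T_gen == pytest.approx(np.log(R0) / np.log(s + f), rel=1e-9)


def _study_kernels(litter=3.3, beta_tmax=-0.5):
    cjs = _cjs_stub(beta_tmax)
    kernels = []
    rng = np.random.default_rng(12)
    for month in range(1, 13):
        env = {
            "tmax": 28.0 + 2.0 * np.cos(2 * np.pi * (month - 9) / 12),
            "precip": 100.0,
            "mean_svl": 55.0,
        }
        kernels.append(
            assemble_month(
                MESH, month, env, GROWTH, GOMP, cjs, litter_mean=litter
            )
        )
    return kernels


class TestPerturbation:
    def test_elasticities_sum_to_one(self):
        pert = perturbation_analysis(_study_kernels())
        assert pert["elasticity"].sum() == pytest.approx(1.0, abs=1e-8)

    def test_numeric_sensitivity_matches_analytic(self):
        kernels = _study_kernels()
        A = yearly_matrix(kernels)
        res = lambda_eigen(A)
        sens = np.outer(res.v, res.w) / float(res.v @ res.w)
        # finite-difference check on a handful of entries
        rng = np.random.default_rng(4)
        for _ in range(5):
            i, j = rng.integers(0, A.shape[0], 2)
            dA = 1e-6 * max(A[i, j], 1e-3)
            Ap = A.copy()
            Ap[i, j] += dA
            num = (lambda_eigen(Ap).lam - res.lam) / dA
            assert num == pytest.approx(sens[i, j], abs=1e-4)

    def test_survival_elasticity_dominates_fecundity(self):
        pert = perturbation_analysis(_study_kernels())
        vital = pert["vital_rate_elasticity"]
        assert vital["survival"] > vital["fecundity"] > 0


class TestMeshAdequacy:
    def test_lambda_stable_under_mesh_refinement(self):
        lams = {}
        for n in (50, 500):
            mesh, h = make_mesh(n)
            G = growth_transition(mesh, GROWTH)
            S = survival_by_size(mesh, GOMP, GROWTH, clamp_warn=False)
            P = build_P(mesh, S, G)
            F = build_F(mesh, 10, litter_mean=3.3)
            lams[n] = lambda_eigen(P + F).lam
        assert abs(lams[50] - lams[500]) / lams[500] < 0.01


class TestMonthlyLambdaSeries:
    def test_constant_environment_repeats_monthly_lambda(self):
        kernels = _study_kernels()
        lams, gm = monthly_lambda_series(kernels)
        # all breeding kernels share env only through month; the two January-like
        # cold months differ, but a truly constant series collapses:
        const = [kernels[5]] * 12
        lams_c, gm_c = monthly_lambda_series(const)
        np.testing.assert_allclose(lams_c, lams_c[0])
        assert gm_c == pytest.approx(lams_c[0], rel=1e-12)

    def test_geometric_mean_of_constant_series(self):
        lams, gm = monthly_lambda_series([np.eye(3) * 1.07] * 12)
        assert gm == pytest.approx(1.07, rel=1e-10)

    def test_conservation_without_fecundity(self):
        """With F = 0 total density never grows; S = 1 conserves it exactly."""
        G = growth_transition(MESH, GROWTH)
        P = build_P(MESH, np.ones(MESH.size), G)
        rng = np.random.default_rng(8)
        n = rng.uniform(0, 1, MESH.size)
        assert (P @ n).sum() == pytest.approx(n.sum(), abs=1e-10)
        S = _survival_vec()
        P2 = build_P(MESH, S, G)
        assert (P2 @ n).sum() < n.sum()

    def test_lambda_monotone_in_kernel_entries(self):
        kernels = _study_kernels()
        A = yearly_matrix(kernels)
        lam = lambda_eigen(A).lam
        assert lambda_eigen(A * 1.01).lam > lam
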