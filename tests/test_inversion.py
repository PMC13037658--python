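"""Covariance-component model, free energy, ReML, priors, GS and LCMV."""

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import solve

import cortexbench as cb
from cortexbench.inversion import CovarianceComponent


def _random_system(rng, nc=4, nv=6, nt=5):
    L = rng.normal(size=(nc, nv))
    q = rng.uniform(0.5, 2.0, size=nv)
    qe = rng.uniform(0.5, 2.0, size=nc)
    Y = rng.normal(size=(nc, nt))
    return L, q, qe, Y


class TestDataCovariance:
    def test_constant_channel_diagonal(self):
        Y = np.vstack([np.full(8, 3.0), np.zeros(8)])
        sigma = cb.data_covariance(Y)
        assert sigma[0, 0] == pytest.approx(9.0)
        assert sigma[1, 1] == 0.0

    def test_symmetric_psd_and_matches_sample_sum(self, rng):
        Y = rng.normal(size=(5, 40))
        sigma = cb.data_covariance(Y)
        oracle = sum(np.outer(Y[:, t], Y[:, t]) for t in range(40)) / 40
        np.testing.assert_allclose(sigma, oracle, rtol=1e-12)
        np.testing.assert_allclose(sigma, sigma.T)
        assert np.linalg.eigvalsh(sigma).min() >= -1e-12


class TestFreeEnergy:
    def test_identity_model_closed_form(self):
        # Sigma = Sigma_Y = I, Nc=2, Nt=4, lam=v, Sigma_lam = Pi^-1:
        # F = -4 - 4 log(2 pi), prior terms vanish
        F, terms = cb.free_energy(
            np.eye(2),
            np.eye(2),
            Nt=4,
            lam=np.zeros(1),
            v=np.zeros(1),
            Pi=np.eye(1),
            Sigma_lam=np.eye(1),
        )
        assert F == pytest.approx(-4.0 - 4.0 * np.log(2.0 * np.pi), abs=1e-12)
        assert F == pytest.approx(-11.3515, abs=5e-5)
        assert terms["hyperprior"] == 0.0
        assert terms["hyperposterior"] == 0.0

    def test_first_three_terms_equal_gaussian_loglik(self, rng):
        nc, nt = 5, 30
        Y = rng.normal(size=(nc, nt))
        A = rng.normal(size=(nc, nc))
        sigma_model = A @ A.T + nc * np.eye(nc)
        F, terms = cb.free_energy(cb.data_covariance(Y), sigma_model, Nt=nt)
        loglik = terms["complexity"] + terms["accuracy"] + terms["constant"]
        oracle = stats.multivariate_normal(np.zeros(nc), sigma_model).logpdf(Y.T).sum()
        assert loglik == pytest.approx(oracle, abs=1e-8)


class TestReml:
    def test_single_component_variance_mle(self, rng):
        # flat hyperprior: exp(lam) should match the sample variance ~ 2.5
        nc, nt = 10, 500
        Y = np.sqrt(2.5) * rng.normal(size=(nc, nt))
        sigma_Y = cb.data_covariance(Y)
        comp = CovarianceComponent(domain="sensor", diag=np.ones(nc))
        hyper, F, terms, conv = cb.reml_optimize(
            sigma_Y, None, [comp], nt, hyperprior_prec=0.0
        )
        assert conv
        assert hyper.scales[0] == pytest.approx(np.trace(sigma_Y) / nc, rel=1e-3)
        assert hyper.scales[0] == pytest.approx(2.5, rel=0.05)

    @pytest.mark.parametrize("a,b", [(0.1, 1.0), (1.0, 10.0), (5.0, 0.5)])
    def test_two_component_scale_recovery(self, a, b, rng):
        # disjoint channel blocks keep both scales identifiable at Nt=500
        nc, nt = 16, 500
        C1 = np.diag([1.0] * 8 + [0.0] * 8)
        C2 = np.diag([0.0] * 8 + [1.0] * 8)
        cov = a * C1 + b * C2
        Y = np.linalg.cholesky(cov) @ rng.normal(size=(nc, nt))
        comps = [
            CovarianceComponent(domain="sensor", matrix=C1),
            CovarianceComponent(domain="sensor", matrix=C2),
        ]
        hyper, *_ = cb.reml_optimize(cb.data_covariance(Y), None, comps, nt)
        assert hyper.scales[0] == pytest.approx(a, rel=0.2)
        assert hyper.scales[1] == pytest.approx(b, rel=0.2)

    def test_true_mixture_beats_reduced_model(self, rng):
        # dropping the active source component should not raise the evidence
        nc, nv, nt = 8, 16, 200
        wins = 0
        for rep in range(20):
            r = np.random.default_rng(1000 + rep)
            L = r.normal(size=(nc, nv))
            q = np.zeros(nv)
            q[r.integers(nv)] = 1.0
            cov = 4.0 * (L * q) @ L.T + np.eye(nc)
            Y = np.linalg.cholesky(cov) @ r.normal(size=(nc, nt))
            sigma_Y = cb.data_covariance(Y)
            noise = CovarianceComponent(domain="sensor", diag=np.ones(nc))
            src = CovarianceComponent(domain="source", diag=q)
            _, F_full, *_ = cb.reml_optimize(sigma_Y, L, [src, noise], nt)
            _, F_red, *_ = cb.reml_optimize(sigma_Y, L, [noise], nt)
            wins += F_full >= F_red
        assert wins >= 19

    def test_requires_noise_component(self, rng):
        src = CovarianceComponent(domain="source", diag=np.ones(4))
        with pytest.raises(ValueError, match="sensor-level"):
            cb.reml_optimize(np.eye(3), rng.normal(size=(3, 4)), [src], 10)


class TestPosterior:
    def test_scalar_system(self):
        J = cb.compute_posterior(np.array([[2.0, 2.0]]), np.eye(1), np.ones(1), np.ones(1))
        np.testing.assert_allclose(J, [[1.0, 1.0]])

    def test_vanishing_prior_shrinks_to_zero(self, rng):
        L, _, _, Y = _random_system(rng)
        J = cb.compute_posterior(Y, L, 1e-14 * np.ones(6), np.ones(4))
        assert np.abs(J).max() < 1e-10

    def test_matrix_inversion_lemma_equivalence(self, rng):
        for _ in range(25):
            L, q, qe, Y = _random_system(rng)
            J = cb.compute_posterior(Y, L, q, qe)
            # source-space form (L' Qe^-1 L + Qa^-1)^-1 L' Qe^-1 Y
            oracle = solve(
                L.T @ np.diag(1.0 / qe) @ L + np.diag(1.0 / q),
                L.T @ np.diag(1.0 / qe) @ Y,
            )
            np.testing.assert_allclose(J, oracle, rtol=1e-10, atol=1e-12)

    def test_singular_model_covariance_named_error(self):
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            cb.compute_posterior(
                np.ones((2, 3)), np.ones((2, 1)), np.zeros(1), np.zeros(2)
            )


class TestPriors:
    def test_iid_prior_is_unit_diagonal(self):
        comp = cb.prior_iid(7)
        np.testing.assert_array_equal(comp.diag, np.ones(7))

    def test_iid_matches_tikhonov_minimum_norm(self, rng):
        # with Qa = I and Qe = lam I the posterior is classical ridge
        L = rng.normal(size=(5, 9))
        Y = rng.normal(size=(5, 3))
        lam = 0.7
        J = cb.compute_posterior(Y, L, np.ones(9), lam * np.ones(5))
        ridge = solve(L.T @ L + lam * np.eye(9), L.T @ Y)
        np.testing.assert_allclose(J, ridge, rtol=1e-9, atol=1e-12)

    def test_ebb_uniform_under_white_data_orthonormal_leads(self):
        L = np.eye(6)
        comp = cb.prior_ebb(L, np.eye(6), ridge=0.0)
        np.testing.assert_allclose(comp.diag, np.full(6, 1.0 / 6.0), rtol=1e-12)

    def test_ebb_positive_and_unit_trace(self, leadfield, evoked):
        comp = cb.prior_ebb(leadfield.matrix, cb.data_covariance(evoked))
        assert np.all(comp.diag > 0)
        assert comp.diag.sum() == pytest.approx(1.0)

    def test_ebb_peaks_at_simulated_source(self, fx, leadfield):
        spec = cb.SimulationSpec(source_vertex=fx.sim_spec.source_vertex, snr_db=20.0, seed=4)
        data = cb.simulate_evoked(fx.mesh, leadfield, spec)
        comp = cb.prior_ebb(leadfield.matrix, cb.data_covariance(data))
        assert int(np.argmax(comp.diag)) == spec.source_vertex


class TestPatchLibrary:
    def test_count_and_seed_vertex_maxima(self, fx):
        patches = cb.make_patch_library(fx.mesh, Np=12, sigma_patch=10.0, seed=0)
        assert len(patches) == 12
        for p in patches:
            seed_vertex = int(p.label.removeprefix("patch"))
            assert int(np.argmax(p.profile)) == seed_vertex
            assert p.profile[seed_vertex] == pytest.approx(1.0)

    def test_profile_matches_dijkstra_kernel(self, fx):
        import networkx as nx

        patches = cb.make_patch_library(fx.mesh, Np=3, sigma_patch=8.0, seed=1)
        g = nx.Graph()
        for (i, j) in fx.mesh.edges():
            g.add_edge(
                int(i),
                int(j),
                weight=float(np.linalg.norm(fx.mesh.vertices[i] - fx.mesh.vertices[j])),
            )
        p = patches[1]
        seed_vertex = int(p.label.removeprefix("patch"))
        dist = nx.single_source_dijkstra_path_length(g, seed_vertex)
        oracle = np.exp(-np.array([dist[i] for i in range(fx.mesh.n_vertices)]) / 8.0)
        np.testing.assert_allclose(p.profile, oracle, rtol=1e-9)

    def test_empty_library_rejected(self, fx, evoked, leadfield):
        with pytest.raises(ValueError, match="empty"):
            cb.greedy_search_invert(evoked, leadfield, [])


class TestGreedySearch:
    def test_recovers_generating_patch_first(self, fx, leadfield, rng):
        patches = cb.make_patch_library(fx.mesh, Np=8, sigma_patch=10.0, seed=0)
        true_p = patches[3]
        w = np.sin(2 * np.pi * 20 * np.arange(60) / 250.0)
        Y = 5.0 * np.outer(leadfield.matrix @ true_p.profile, w)
        Y += 1e-3 * np.abs(Y).max() * rng.normal(size=Y.shape)
        res = cb.greedy_search_invert(Y, leadfield, patches, max_patches=3)
        assert res.active_patches[0] == 3
        assert res.method == "GS"

    def test_zero_profile_patches_leave_noise_only_model(self, fx, leadfield, rng):
        Y = rng.normal(size=(leadfield.n_channels, 50))
        dead = [
            CovarianceComponent(
                domain="source", profile=np.zeros(fx.mesh.n_vertices), label="p0"
            )
        ]
        res = cb.greedy_search_invert(Y, leadfield, dead)
        assert res.active_patches == []
        assert np.all(res.J == 0)


class TestLcmv:
    def test_unit_gain_constraint(self, leadfield, evoked):
        W = cb.lcmv_weights(leadfield.matrix, cb.data_covariance(evoked))
        gains = np.einsum("ij,ij->j", W, leadfield.matrix)
        np.testing.assert_allclose(gains, 1.0, atol=1e-10)

    def test_white_covariance_weights_parallel_to_leads(self, rng):
        L = rng.normal(size=(4, 6))
        W = cb.lcmv_weights(L, np.eye(4), regularization=0.0)
        for i in range(6):
            cosang = (W[:, i] @ L[:, i]) / (
                np.linalg.norm(W[:, i]) * np.linalg.norm(L[:, i])
            )
            assert cosang == pytest.approx(1.0, abs=1e-12)

    def test_matches_constrained_quadratic_program(self, rng):
        # minimize w' Sigma w subject to w' l = 1, on a 3-sensor toy
        from scipy.optimize import minimize

        A = rng.normal(size=(3, 3))
        sigma = A @ A.T + np.eye(3)
        l = rng.normal(size=3)
        W = cb.lcmv_weights(l[:, None], sigma, regularization=0.0)
        res = minimize(
            lambda w: w @ sigma @ w,
            x0=l / (l @ l),
            method="SLSQP",
            constraints={"type": "eq", "fun": lambda w: w @ l - 1.0},
            options={"ftol": 1e-14, "maxiter": 1000},
        )
        np.testing.assert_allclose(W[:, 0], res.x, atol=1e-6)


class TestInvertOrchestration:
    @pytest.mark.parametrize("method", ["IID", "EBB", "GS"])
    def test_methods_run_and_satisfy_covariance_identity(self, fx, leadfield, evoked, method):
        res = cb.invert(
            evoked, leadfield, method=method, mesh=fx.mesh, Np=8, max_patches=2
        )
        Q = res.Q_source
        lql = (
            (leadfield.matrix * Q[None, :]) @ leadfield.matrix.T
            if Q.ndim == 1
            else leadfield.matrix @ Q @ leadfield.matrix.T
        )
        np.testing.assert_allclose(
            res.Sigma_alpha,
            lql + res.Q_eps,
            rtol=1e-8,
            atol=1e-8 * np.abs(res.Sigma_alpha).max(),
        )
        assert np.isfinite(res.F)

    def test_noiseless_iid_data_nearly_fully_explained(self, fx, leadfield, rng):
        # data drawn from the IID generative model with no sensor noise
        J = rng.normal(size=(fx.mesh.n_vertices, 40))
        Y = leadfield.matrix @ J
        res = cb.invert(Y, leadfield, method="IID")
        assert cb.variance_explained(Y, res.Y_hat) > 0.999

    def test_unknown_method_rejected(self, leadfield, evoked):
        with pytest.raises(ValueError, match="unknown method"):
            cb.invert(evoked, leadfield, method="MSP")

    def test_permuted_leadfield_degrades_evidence(self, fx, leadfield):
        wins = 0
        for seed in range(20):
            spec = cb.SimulationSpec(
                source_vertex=fx.sim_spec.source_vertex, seed=seed, n_trials=50
            )
            data = cb.simulate_evoked(fx.mesh, leadfield, spec)
            null_L = cb.permute_leadfield_rows(leadfield, seed=seed)
            F_ver = cb.invert(data, leadfield, method="EBB").F
            F_null = cb.invert(data, null_L, method="EBB").F
            wins += F_ver > F_null
        assert wins >= 19

    def test_temporal_projection_reduces_time_dimension(self, leadfield, evoked):
        res = cb.invert(evoked, leadfield, method="IID", temporal_projection=True)
        assert res.J.shape[1] <= evoked.n_times
        assert np.isfinite(res.F)
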