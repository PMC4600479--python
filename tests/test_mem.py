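"""MEM dual solver: oracles, limits and end-to-end sanity."""

import numpy as np
import pytest

from memfuse.geometry import build_synthetic_cortex
from memfuse.forward import meg_leadfield_sphere
from memfuse.mem import (MEMSourceImaging, build_reference_model,
                         mem_dual_objective, solve_mem, solve_mem_timepoint)
from memfuse.msp import Parcellation, ddp_parcellate

from conftest import mesh_from_edges


def toy_model(rng, q=6, parcel_sizes=(2, 3), alpha=None, eta=0.5,
              mesh_edges=None):
    """Small hand-built reference model on a chain mesh."""
    p = sum(parcel_sizes)
    labels = np.concatenate([[k + 1] * n
                             for k, n in enumerate(parcel_sizes)])
    parc = Parcellation(labels=labels, n_parcels=len(parcel_sizes),
                        seeds=np.array([0, parcel_sizes[0]]), scale=1)
    mesh = mesh_from_edges(p, mesh_edges or [(i, i + 1)
                                             for i in range(p - 1)])
    if alpha is None:
        alpha = rng.uniform(0.2, 0.8, size=len(parcel_sizes))
    model = build_reference_model(parc, alpha, mesh, eta=eta,
                                  smoothing_order=1)
    G = rng.normal(size=(q, p))
    noise_var = rng.uniform(0.5, 2.0, size=q)
    return model, G, noise_var


class TestDualObjective:
    def test_value_and_gradient_at_zero(self, rng):
        model, G, nv = toy_model(rng)
        m = rng.normal(size=G.shape[0])
        val, grad = mem_dual_objective(np.zeros(G.shape[0]), model, m, G, nv)
        assert val == pytest.approx(0.0, abs=1e-14)
        np.testing.assert_allclose(grad, m, atol=1e-14)

    def test_gradient_matches_finite_differences(self, rng):
        model, G, nv = toy_model(rng)
        m = rng.normal(size=G.shape[0])
        lam = 0.3 * rng.normal(size=G.shape[0])
        _, grad = mem_dual_objective(lam, model, m, G, nv)
        eps = 1e-6
        for i in range(len(lam)):
            e = np.zeros_like(lam)
            e[i] = eps
            vp, _ = mem_dual_objective(lam + e, model, m, G, nv)
            vm, _ = mem_dual_objective(lam - e, model, m, G, nv)
            assert grad[i] == pytest.approx((vp - vm) / (2 * eps), rel=1e-4,
                                            abs=1e-7)

    def test_alpha_to_one_limit_is_gaussian_dual(self, rng):
        model, G, nv = toy_model(rng, alpha=np.array([1 - 1e-13, 1 - 1e-13]))
        m = rng.normal(size=G.shape[0])
        lam = 0.2 * rng.normal(size=G.shape[0])
        val, _ = mem_dual_objective(lam, model, m, G, nv)
        Sigma_s = np.zeros((G.shape[1], G.shape[1]))
        for k, idx in enumerate(model.parcel_vertices):
            Sigma_s[np.ix_(idx, idx)] = model.sigma[k]
        gauss = (lam @ m - 0.5 * lam @ (np.diag(nv) + G @ Sigma_s @ G.T)
                 @ lam)
        assert val == pytest.approx(gauss, rel=1e-9)

    def test_concave_along_random_lines(self, rng):
        model, G, nv = toy_model(rng)
        m = rng.normal(size=G.shape[0])
        for _ in range(20):
            a = rng.normal(size=G.shape[0])
            b = rng.normal(size=G.shape[0])
            ts = np.linspace(-1, 1, 9)
            vals = [mem_dual_objective(a + t * b, model, m, G, nv)[0]
                    for t in ts]
            second = np.diff(vals, 2)
            assert np.all(second <= 1e-8 * max(1.0, np.abs(vals).max()))

    def test_nan_rejected(self, rng):
        model, G, nv = toy_model(rng)
        with pytest.raises(ValueError):
            mem_dual_objective(np.full(G.shape[0], np.nan), model,
                               np.zeros(G.shape[0]), G, nv)


class TestSolveTimepoint:
    def test_zero_data_zero_solution(self, rng):
        model, G, nv = toy_model(rng)
        j, state = solve_mem_timepoint(np.zeros(G.shape[0]), G, model, nv)
        np.testing.assert_allclose(j, 0.0, atol=1e-12)
        np.testing.assert_allclose(state.lam, 0.0, atol=1e-12)

    def test_gaussian_limit_closed_form(self, rng):
        # alpha -> 1: MEM equals the Gaussian-prior (ridge) estimate
        for _ in range(20):
            model, G, nv = toy_model(
                rng, alpha=np.array([1 - 1e-12, 1 - 1e-12]))
            m = rng.normal(size=G.shape[0])
            j, state = solve_mem_timepoint(m, G, model, nv,
                                           grad_tol_rel=1e-12)
            Sigma_s = np.zeros((G.shape[1], G.shape[1]))
            for k, idx in enumerate(model.parcel_vertices):
                Sigma_s[np.ix_(idx, idx)] = model.sigma[k]
            expected = Sigma_s @ G.T @ np.linalg.solve(
                G @ Sigma_s @ G.T + np.diag(nv), m)
            np.testing.assert_allclose(j, expected, rtol=1e-6, atol=1e-10)

    def test_scalar_toy_matches_grid_search(self, rng):
        # q = 1, one singleton parcel: dense grid search over the dual
        parc = Parcellation(labels=np.array([1]), n_parcels=1,
                            seeds=np.array([0]), scale=1)
        mesh = mesh_from_edges(1, [])
        model = build_reference_model(parc, np.array([0.6]), mesh, eta=0.8)
        G = np.array([[1.7]])
        nv = np.array([0.9])
        m = np.array([2.3])
        j, state = solve_mem_timepoint(m, G, model, nv)
        grid = np.linspace(-10.0, 10.0, 2001)  # resolution 0.01
        vals = np.array([mem_dual_objective(np.array([t]), model, m, G,
                                            nv)[0] for t in grid])
        coarse = grid[np.argmax(vals)]
        assert state.lam[0] == pytest.approx(coarse, abs=0.02)

    def test_primal_feasibility_at_optimum(self, rng):
        model, G, nv = toy_model(rng)
        m = rng.normal(size=G.shape[0])
        j, state = solve_mem_timepoint(m, G, model, nv, grad_tol_rel=1e-10)
        residual = m - G @ j - nv * state.lam
        assert np.linalg.norm(residual, np.inf) <= \
            max(1e-8 * np.linalg.norm(m), 10 * state.grad_norm)

    def test_shutdown_continuity(self, rng):
        # as alpha_k -> 0 the parcel's current vanishes continuously
        m = None
        norms = []
        for a in [0.3, 0.1, 0.03, 0.01, 1e-3, 1e-5]:
            rng2 = np.random.default_rng(7)
            model, G, nv = toy_model(rng2, alpha=np.array([0.5, a]))
            if m is None:
                m = rng2.normal(size=G.shape[0])
            j, _ = solve_mem_timepoint(m, G, model, nv)
            idx = model.parcel_vertices[1]
            norms.append(np.linalg.norm(j[idx]))
        assert np.all(np.diff(norms) <= 0.05 * norms[0])
        assert norms[-1] < 1e-3 * norms[0]

    def test_posterior_activation_in_unit_interval(self, rng):
        model, G, nv = toy_model(rng)
        m = 5.0 * rng.normal(size=G.shape[0])
        _, state = solve_mem_timepoint(m, G, model, nv)
        assert np.all(state.alpha_hat >= 0) and np.all(state.alpha_hat <= 1)


class TestReferenceModel:
    def test_singleton_parcel_scalar_covariance(self, rng):
        parc = Parcellation(labels=np.array([1]), n_parcels=1,
                            seeds=np.array([0]), scale=1)
        mesh = mesh_from_edges(1, [])
        model = build_reference_model(parc, np.array([0.5]), mesh, eta=2.0)
        assert model.sigma[0].shape == (1, 1)
        assert model.sigma[0][0, 0] > 0

    def test_smoothing_order_zero_gives_scaled_identity(self, rng):
        parc = Parcellation(labels=np.array([1, 1, 1]), n_parcels=1,
                            seeds=np.array([0]), scale=1)
        mesh = mesh_from_edges(3, [(0, 1), (1, 2)])
        model = build_reference_model(parc, np.array([0.5]), mesh, eta=3.0,
                                      smoothing_order=0)
        np.testing.assert_allclose(model.sigma[0], 3.0 * np.eye(3),
                                   rtol=1e-12)

    def test_covariances_spd_random_parcellations(self, medium_geometry):
        mesh = medium_geometry[0]
        rng = np.random.default_rng(3)
        for _ in range(50):
            scores = rng.uniform(size=mesh.n_vertices)
            parc = ddp_parcellate(scores, mesh,
                                  scale=int(rng.integers(2, 6)))
            alpha = rng.uniform(0.05, 0.95, size=parc.n_parcels)
            model = build_reference_model(parc, alpha, mesh, eta=1.0,
                                          smoothing_order=2)
            for S in model.sigma:
                assert np.allclose(S, S.T)
                assert np.linalg.eigvalsh(S).min() > 0

    def test_invalid_alpha_rejected(self, rng):
        parc = Parcellation(labels=np.array([1, 1]), n_parcels=1,
                            seeds=np.array([0]), scale=1)
        mesh = mesh_from_edges(2, [(0, 1)])
        with pytest.raises(ValueError):
            build_reference_model(parc, np.array([0.0]), mesh, eta=1.0)
        with pytest.raises(ValueError):
            build_reference_model(parc, np.array([0.5]), mesh, eta=-1.0)


class TestSolveWindow:
    def test_single_sample_matches_timepoint(self, rng):
        model, G, nv = toy_model(rng)
        m = rng.normal(size=G.shape[0])
        J, states = solve_mem(m[:, None], G, model, nv)
        j, _ = solve_mem_timepoint(m, G, model, nv)
        np.testing.assert_allclose(J[:, 0], j)

    def test_time_reversal_equivariance(self, rng):
        model, G, nv = toy_model(rng)
        M = rng.normal(size=(G.shape[0], 5))
        J1, _ = solve_mem(M, G, model, nv)
        J2, _ = solve_mem(M[:, ::-1], G, model, nv)
        np.testing.assert_allclose(J1, J2[:, ::-1], atol=1e-10)


class TestEndToEnd:
    def test_noiseless_patch_energy_concentrates(self):
        # one extended patch, no noise: the cMEM energy at the peak lands
        # in and around the patch (detection AUC on the toy > 0.9)
        from memfuse.forward import eeg_leadfield_sphere
        from memfuse.metrics import roc_auc
        from memfuse.spike import simulate_static

        mesh, head, eeg, meg = build_synthetic_cortex(
            n_subdivisions=3, seed=5, n_eeg=32, n_meg=64)
        lfs = {"MEG": meg_leadfield_sphere(mesh, head, meg)}
        ds = simulate_static(mesh, lfs, seed_vertex=37, extent_order=2,
                             target_ratio=None, seed=0)
        tau0 = ds.peak_index
        M = ds.recordings["MEG"]
        scale = np.abs(M).max()
        model = MEMSourceImaging(M[:, [tau0]] / scale,
                                 lfs["MEG"].G / scale,
                                 np.full(M.shape[0], 1e-6), mesh,
                                 modality="MEG")
        res = model.fit()
        auc = roc_auc(res.j[:, 0], ds.patches[0].vertices, mesh, seed=3)
        assert auc > 0.9

    def test_summary_mentions_key_quantities(self, rng):
        mesh, head, eeg, meg = build_synthetic_cortex(
            n_subdivisions=2, seed=11, n_eeg=16, n_meg=24)
        lf = meg_leadfield_sphere(mesh, head, meg)
        M = lf.G @ rng.normal(size=(mesh.n_vertices, 3)) * 1e-9
        scale = np.abs(M).max()
        model = MEMSourceImaging(M / scale, lf.G / scale,
                                 np.full(M.shape[0], 1e-4), mesh,
                                 modality="MEG")
        res = model.fit()
        text = res.summary()
        assert "parcels" in text and "MEG" in text
        assert res.alpha_hat.shape == (res.reference.n_parcels, 3)
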