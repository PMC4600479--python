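"""Spike waveform, patches, background noise and simulation bookkeeping."""

import numpy as np
import pytest

from memfuse.forward import eeg_leadfield_sphere, meg_leadfield_sphere
from memfuse.geometry import graph_distances
from memfuse.spike import (cancellation_index, compute_snr, gamma_spike,
                           generate_background, grow_patch, perturb_rbs,
                           scale_background, simulate_propagation,
                           simulate_static, NAM_TO_AM)

from conftest import mesh_from_edges


@pytest.fixture(scope="module")
def leadfields(small_geometry):
    mesh, head, eeg, meg = small_geometry
    return {"EEG": eeg_leadfield_sphere(mesh, head, eeg),
            "MEG": meg_leadfield_sphere(mesh, head, meg)}


class TestGammaSpike:
    def test_single_component_peaks_at_gamma_mode(self):
        sp = gamma_spike(components=[(2.0, 0.01, 1.0, 0.0)],
                         sampling_rate=10_000.0, duration=0.2)
        # Gamma(k=2, theta=0.01) has its mode at (k-1)*theta = 0.01 s
        assert sp.t[sp.peak_index] == pytest.approx(0.01, abs=1e-4)
        assert np.max(np.abs(sp.w)) == pytest.approx(1.0)

    def test_single_amplitude_reduces_to_one_component(self):
        full = gamma_spike(components=[(12.0, 0.006, 0.7, 0.0),
                                       (5.0, 0.02, 0.0, 0.03),
                                       (3.0, 0.05, 0.0, 0.1)])
        solo = gamma_spike(components=[(12.0, 0.006, 1.0, 0.0)])
        np.testing.assert_allclose(full.w, solo.w, atol=1e-12)

    def test_default_has_unique_unit_peak(self):
        sp = gamma_spike()
        peaks = np.flatnonzero(np.abs(np.abs(sp.w) - 1.0) < 1e-12)
        assert len(peaks) == 1
        assert np.abs(sp.w).max() == pytest.approx(1.0)

    def test_all_zero_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="no spike peak"):
            gamma_spike(components=[(2.0, 0.01, 0.0, 0.0)])

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            gamma_spike(components=[(-1.0, 0.01, 1.0, 0.0)])


class TestGrowPatch:
    def test_order_zero_singleton(self, small_geometry):
        patch = grow_patch(small_geometry[0], 3, 0)
        assert patch.vertices.tolist() == [3]
        assert patch.seed_vertex == 3

    def test_area_matches_hand_summed_triangles(self):
        # two right triangles sharing an edge: total area = 0.5 + 0.5 mm^2
        verts = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]
        faces = np.array([[0, 1, 2], [1, 3, 2]])
        from memfuse.geometry import _mesh_from_vertices
        mesh = _mesh_from_vertices(np.array(verts, float), faces,
                                   np.array([0.5, 0.5, -1.0]))
        patch = grow_patch(mesh, 0, 10)
        assert patch.area_cm2 == pytest.approx(1.0 / 100.0)

    def test_extent_three_area_near_four_cm2(self):
        # clinical-resolution mesh: order-3 patches on the order of 4 cm^2
        from memfuse.geometry import build_synthetic_cortex
        mesh = build_synthetic_cortex(n_subdivisions=4, seed=0)[0]
        patch = grow_patch(mesh, 100, 3)
        assert 2.0 <= patch.area_cm2 <= 8.0  # within a factor of two


class TestBackground:
    def test_white_noise_std_matches_target(self):
        n = generate_background(4, 10_000, std=2.5, spectral_slope=0.0,
                                alpha_power=0.0, mixing=0.0, seed=2)
        np.testing.assert_allclose(n.std(axis=1), 2.5, rtol=0.05)

    def test_zero_mean_per_channel(self):
        n = generate_background(6, 4096, seed=3)
        bound = 3.0 * n.std(axis=1) / np.sqrt(n.shape[1])
        assert np.all(np.abs(n.mean(axis=1)) < bound)

    def test_reproducible_from_seed(self):
        a = generate_background(5, 256, seed=42)
        b = generate_background(5, 256, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_one_over_f_spectrum_tilts_down(self):
        n = generate_background(2, 2 ** 14, std=1.0, spectral_slope=2.0,
                                alpha_power=0.0, mixing=0.0, seed=5)
        spec = np.abs(np.fft.rfft(n, axis=1)).mean(axis=0)
        freqs = np.fft.rfftfreq(n.shape[1], 1 / 600.0)
        low = spec[(freqs > 1) & (freqs < 5)].mean()
        high = spec[(freqs > 100) & (freqs < 200)].mean()
        assert low > 10 * high


class TestSNRConventions:
    def test_compute_snr_hand_value(self):
        M = np.array([[0.0, 4.0, 1.0]])
        baseline = np.array([[2.0, -2.0, 2.0, -2.0]])
        assert compute_snr(M, baseline) == pytest.approx(4.0 / 2.0)

    def test_zero_signal(self):
        baseline = np.array([[1.0, -1.0]])
        assert compute_snr(np.zeros((1, 3)), baseline) == 0.0

    def test_homogeneity(self, rng):
        M = rng.normal(size=(4, 50))
        baseline = rng.normal(size=(4, 50))
        assert compute_snr(3 * M, baseline) == pytest.approx(
            3 * compute_snr(M, baseline))

    def test_constant_baseline_rejected(self):
        with pytest.raises(ValueError, match="zero std"):
            compute_snr(np.ones((2, 3)), np.ones((2, 4)))

    def test_scale_is_fixed_point(self, rng):
        signal = rng.normal(size=(5, 100))
        noise = rng.normal(size=(5, 100))
        for metric in ("peak", "gfp", "window", "rms"):
            c = scale_background(signal, noise, 2.0, metric=metric)
            c2 = scale_background(signal, c * noise, 2.0, metric=metric)
            assert c2 == pytest.approx(1.0, abs=1e-9)

    def test_satisfied_target_gives_unit_scale(self, rng):
        signal = rng.normal(size=(3, 64))
        noise = rng.normal(size=(3, 64))
        snr = compute_snr(signal, noise)
        assert scale_background(signal, noise, snr) == pytest.approx(1.0)

    def test_doubling_target_halves_scale(self, rng):
        signal = rng.normal(size=(3, 64))
        noise = rng.normal(size=(3, 64))
        c1 = scale_background(signal, noise, 1.0)
        c2 = scale_background(signal, noise, 2.0)
        assert c2 == pytest.approx(c1 / 2.0)

    def test_zero_noise_rejected(self, rng):
        with pytest.raises(ValueError):
            scale_background(rng.normal(size=(2, 10)), np.zeros((2, 10)), 1.0)


class TestCancellationIndex:
    def test_opposed_columns_full_cancellation(self, rng):
        col = rng.normal(size=10)
        G = np.column_stack([col, -col])
        assert cancellation_index(G, [0, 1]) == pytest.approx(1.0)

    def test_single_dipole_no_cancellation(self, rng):
        G = rng.normal(size=(10, 3))
        assert cancellation_index(G, [1]) == pytest.approx(0.0)

    def test_orthogonal_pair_hand_value(self):
        G = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cancellation_index(G, [0, 1]) == pytest.approx(
            1.0 - np.sqrt(2.0) / 2.0)

    def test_invariant_to_global_gain_scaling(self, rng):
        G = rng.normal(size=(8, 5))
        patch = [0, 2, 4]
        assert cancellation_index(13.7 * G, patch) == pytest.approx(
            cancellation_index(G, patch))

    def test_zero_column_rejected(self):
        G = np.zeros((4, 2))
        G[:, 0] = 1.0
        with pytest.raises(ValueError):
            cancellation_index(G, [0, 1])


class TestPerturbRbs:
    def test_zero_sd_returns_mean(self, small_geometry):
        head = small_geometry[1]
        assert perturb_rbs(head, sd=0.0).rbs == pytest.approx(20.0)

    def test_draws_truncated_and_centred(self, small_geometry):
        head = small_geometry[1]
        rng = np.random.default_rng(0)
        draws = np.array([perturb_rbs(head, seed=rng).rbs
                          for _ in range(10_000)])
        assert draws.min() >= 15.0 and draws.max() <= 25.0
        assert abs(draws.mean() - 20.0) < 0.1

    def test_same_seed_same_rbs(self, small_geometry):
        head = small_geometry[1]
        assert perturb_rbs(head, seed=7).rbs == perturb_rbs(head, seed=7).rbs

    def test_degenerate_params_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            perturb_rbs(small_geometry[1], lower=25.0, upper=15.0)


class TestSimulateStatic:
    def test_noiseless_forward_consistency(self, small_geometry, leadfields):
        mesh = small_geometry[0]
        ds = simulate_static(mesh, leadfields, seed_vertex=10, extent_order=2,
                             target_ratio=None, seed=0)
        for mod, lf in leadfields.items():
            np.testing.assert_allclose(
                ds.recordings[mod], lf.G @ (ds.jth * NAM_TO_AM), atol=0)

    def test_noiseless_data_rank_one(self, small_geometry, leadfields):
        mesh = small_geometry[0]
        ds = simulate_static(mesh, leadfields, seed_vertex=10, extent_order=2,
                             target_ratio=None, seed=0)
        s = np.linalg.svd(ds.recordings["MEG"], compute_uv=False)
        assert s[1] < 1e-10 * s[0]

    def test_residual_equals_scaled_noise(self, small_geometry, leadfields):
        mesh = small_geometry[0]
        ds = simulate_static(mesh, leadfields, seed_vertex=4, extent_order=2,
                             target_ratio=1.0, seed=1)
        for mod, lf in leadfields.items():
            diff = ds.recordings[mod] - ds.noise[mod] - lf.G @ (ds.jth * NAM_TO_AM)
            assert np.abs(diff).max() < 1e-12 * np.abs(ds.recordings[mod]).max()

    def test_ground_truth_support_and_amplitude(self, small_geometry,
                                                leadfields):
        mesh = small_geometry[0]
        ds = simulate_static(mesh, leadfields, seed_vertex=4, extent_order=2,
                             amplitude_nam=9.5, target_ratio=1.0, seed=1)
        patch = ds.patches[0].vertices
        outside = np.setdiff1d(np.arange(mesh.n_vertices), patch)
        assert np.all(ds.jth[outside] == 0)
        assert np.abs(ds.jth).max() == pytest.approx(9.5)

    def test_same_seed_identical_dataset(self, small_geometry, leadfields):
        mesh = small_geometry[0]
        a = simulate_static(mesh, leadfields, 7, target_ratio=1.0, seed=9)
        b = simulate_static(mesh, leadfields, 7, target_ratio=1.0, seed=9)
        for mod in a.recordings:
            np.testing.assert_array_equal(a.recordings[mod],
                                          b.recordings[mod])

    def test_missing_leadfield_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            simulate_static(small_geometry[0], {}, 0)


class TestSimulatePropagation:
    def test_seed_separation_is_exact(self, medium_geometry):
        mesh, head, eeg, meg = medium_geometry
        lfs = {"EEG": eeg_leadfield_sphere(mesh, head, eeg),
               "MEG": meg_leadfield_sphere(mesh, head, meg)}
        ds = simulate_propagation(mesh, lfs, seed_vertex=20,
                                  separation_order=10, target_ratio=None,
                                  seed=3)
        seed2 = ds.patches[1].seed_vertex
        d = graph_distances(mesh, np.array([20]))[seed2]
        assert d == 10

    def test_zero_delay_equals_two_patch_static(self, medium_geometry):
        mesh, head, eeg, meg = medium_geometry
        lfs = {"EEG": eeg_leadfield_sphere(mesh, head, eeg),
               "MEG": meg_leadfield_sphere(mesh, head, meg)}
        ds = simulate_propagation(mesh, lfs, seed_vertex=20, delay_ms=0.0,
                                  separation_order=10, target_ratio=None,
                                  seed=3)
        w = ds.spike.w
        for patch in ds.patches:
            expected = np.tile(patch.amplitude_nam * w,
                               (len(patch.vertices), 1))
            np.testing.assert_allclose(ds.jth[patch.vertices], expected)

    def test_second_source_weaker_at_first_peak(self, medium_geometry):
        mesh, head, eeg, meg = medium_geometry
        lfs = {"MEG": meg_leadfield_sphere(mesh, head, meg),
               "EEG": eeg_leadfield_sphere(mesh, head, eeg)}
        ds = simulate_propagation(mesh, lfs, seed_vertex=20, delay_ms=15.0,
                                  separation_order=10, target_ratio=None,
                                  seed=3)
        tau0 = ds.peak_index
        G = lfs["MEG"].G
        contrib = []
        for patch in ds.patches:
            j = np.zeros(mesh.n_vertices)
            j[patch.vertices] = ds.jth[patch.vertices, tau0]
            contrib.append(np.linalg.norm(G @ (j * NAM_TO_AM)))
        assert contrib[1] < contrib[0]

    def test_overlapping_patches_rejected(self, medium_geometry):
        mesh, head, eeg, meg = medium_geometry
        lfs = {"EEG": eeg_leadfield_sphere(mesh, head, eeg),
               "MEG": meg_leadfield_sphere(mesh, head, meg)}
        with pytest.raises(ValueError, match="overlap|distance"):
            simulate_propagation(mesh, lfs, seed_vertex=20,
                                 separation_order=4, extent_order=3,
                                 target_ratio=None, seed=3)
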