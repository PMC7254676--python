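"""Ground-truth generator: planted networks, rasters, traces, movies."""

from dataclasses import replace

import numpy as np
import pytest

from calnet.imaging import FluorescenceMovie, detect_rois
from calnet.params import GeneratorParams, get_preset, list_presets
from calnet.spikes import CalciumKernel, reconstruct_spikes
from calnet.synthetic import (
    make_ground_truth_network,
    render_movie,
    render_traces,
    simulate_raster,
)


class TestPlantedNetwork:
    def test_full_intra_connectivity_gives_complete_digraph(self):
        adj, labels = make_ground_truth_network(4, 1, p_intra=1.0, p_inter=0.0, seed=3)
        assert adj.sum() == 12  # n*(n-1) directed edges
        assert not adj.diagonal().any()

    def test_realized_intra_density_within_binomial_ci(self):
        n, m, p = 100, 4, 0.3
        adj, labels = make_ground_truth_network(n, m, p, 0.01, seed=1)
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        n_intra_pairs = same.sum()
        k = adj[same].sum()
        sd = np.sqrt(n_intra_pairs * p * (1 - p))
        assert abs(k - n_intra_pairs * p) < 3 * sd

    def test_zero_inter_probability_disconnects_modules(self):
        import networkx as nx

        adj, labels = make_ground_truth_network(60, 3, 0.4, 0.0, seed=2)
        G = nx.from_numpy_array(adj, create_using=nx.DiGraph)
        comps = list(nx.weakly_connected_components(G))
        assert len(comps) == 3
        for comp in comps:
            assert len({labels[v] for v in comp}) == 1

    def test_balanced_labels_and_errors(self):
        _, labels = make_ground_truth_network(10, 3, 0.5, 0.1, seed=0)
        _, counts = np.unique(labels, return_counts=True)
        assert counts.max() - counts.min() <= 1
        with pytest.raises(ValueError):
            make_ground_truth_network(3, 5, 0.5, 0.1, seed=0)
        with pytest.raises(ValueError):
            make_ground_truth_network(5, 2, 1.5, 0.1, seed=0)


class TestSimulateRaster:
    def test_no_bursts_no_background_gives_empty_raster(self, small_params):
        p = replace(small_params, burst_participation=0.0, independent_rate=0.0)
        culture = simulate_raster(p)
        assert culture.raster.sum() == 0

    def test_background_spike_count_is_poisson(self):
        # 10 active neurons at 0.5 spikes/s for 600 s -> 3000 +- 3 SD
        p = GeneratorParams(
            n_rois=12, frac_glia=0.0, frac_active=10 / 12, duration=600.0,
            mean_ibi=np.inf, burst_participation=0.0, independent_rate=0.5,
            n_modules=1, seed=5,
        )
        culture = simulate_raster(p)
        total = culture.raster.sum()
        assert abs(total - 3000) < 3 * np.sqrt(3000)

    def test_schedule_mean_ibi_matches_preset(self):
        p = get_preset("WT-STR")
        means = []
        for seed in range(10):
            culture = simulate_raster(p, seed=seed)
            onsets = np.array([a for a, _, _ in culture.burst_schedule])
            means.append(np.mean(np.diff(onsets)))
        assert abs(np.mean(means) - p.mean_ibi) / p.mean_ibi < 0.10

    def test_determinism_and_conservation(self, small_params):
        c1 = simulate_raster(small_params, seed=9)
        c2 = simulate_raster(small_params, seed=9)
        assert np.array_equal(c1.raster, c2.raster)
        assert np.array_equal(c1.network, c2.network)
        assert c1.raster.sum() == c1.n_burst_spikes + c1.n_background_spikes

    def test_only_active_neurons_spike(self, small_params):
        culture = simulate_raster(small_params, seed=4)
        spiking = np.flatnonzero(culture.raster.any(axis=1))
        assert set(spiking) <= set(culture.active_ids)

    def test_network_shape_mismatch_raises(self, small_params):
        bad = np.zeros((3, 3), dtype=bool)
        with pytest.raises(ValueError):
            simulate_raster(small_params, network=bad, seed=0)


class TestRenderTraces:
    def test_single_spike_kernel_closed_form(self, small_params):
        p = replace(small_params, noise_sd=0.0, drift_amplitude=0.0,
                    frac_glia=0.0, burst_participation=0.0, independent_rate=0.0)
        culture = simulate_raster(p, seed=0)
        culture.raster[culture.active_ids[0], 50] = True
        rend = render_traces(culture, noiseless=True)
        tr = rend.normalized[culture.active_ids[0]]
        fr, tau, A = p.frame_rate, p.kernel_decay, p.kernel_amplitude
        for k in (0, 1, 5, 40):
            assert tr[50 + k] == pytest.approx(A * np.exp(-k / (tau * fr)), abs=1e-10)
        assert tr[49] == 0.0

    def test_two_spikes_superpose_linearly(self, small_params):
        p = replace(small_params, noise_sd=0.0, drift_amplitude=0.0,
                    frac_glia=0.0, burst_participation=0.0, independent_rate=0.0)
        culture = simulate_raster(p, seed=0)
        i = culture.active_ids[0]
        culture.raster[i, 100] = True
        culture.raster[i, 101] = True
        rend = render_traces(culture, noiseless=True)
        fr, tau, A = p.frame_rate, p.kernel_decay, p.kernel_amplitude
        expected_peak = A * (1 + np.exp(-1 / (tau * fr)))
        assert rend.normalized[i, 101] == pytest.approx(expected_peak, abs=1e-10)

    def test_noiseless_render_then_peel_is_identity(self, small_params):
        p = replace(small_params, noise_sd=0.0, drift_amplitude=0.0)
        culture = simulate_raster(p, seed=7)
        rend = render_traces(culture, noiseless=True)
        kernel = CalciumKernel(p.kernel_amplitude, p.kernel_decay)
        for i in culture.active_ids:
            train, flagged = reconstruct_spikes(
                rend.normalized[i], kernel, p.frame_rate
            )
            assert not flagged
            assert np.array_equal(train, culture.raster[i])

    def test_silent_rois_are_noise_only(self, small_params):
        culture = simulate_raster(small_params, seed=3)
        rend = render_traces(culture)
        silent = culture.roles == "silent"
        assert np.abs(rend.clean[silent]).max() == 0.0

    def test_glia_have_slow_large_waves(self, small_params):
        culture = simulate_raster(small_params, seed=3)
        rend = render_traces(culture)
        glia = culture.roles == "glia"
        assert glia.any()
        assert rend.clean[glia].max() >= 5.0


class TestRenderMovie:
    def test_zero_rois_gives_pure_background(self):
        movie = render_movie(np.empty((0, 50)), [], (32, 32), seed=0,
                             background=100.0, pixel_noise_sd=1.0)
        assert movie.shape == (50, 32, 32)
        assert abs(movie.mean() - 100.0) < 1.0

    def test_three_disks_recovered_by_roi_detection(self):
        from tests.conftest import make_disk_movie

        centers = [(60, 60), (130, 85), (90, 150)]
        movie, layout = make_disk_movie(centers)
        rois = detect_rois(FluorescenceMovie(movie, 20.0))
        assert len(rois) == 3
        planted = np.array(sorted(tuple(p.mean(axis=0)) for p in layout))
        found = np.array(sorted(map(tuple, rois.centroids())))
        assert np.abs(planted - found).max() < 2.0

    def test_nine_pixel_component_is_dropped(self):
        # a 3x3 block (9 px) is below the 10-pixel floor and thinner than the
        # 4x4 opening element, so it must not survive ROI detection
        from tests.conftest import make_disk_movie

        rr, cc = np.mgrid[100:103, 40:43]
        block = np.column_stack([rr.ravel(), cc.ravel()])
        movie, layout = make_disk_movie([(60, 60)], extra_pixels=block)
        rois = detect_rois(FluorescenceMovie(movie, 20.0))
        assert len(rois) == 1
        assert np.abs(rois.centroids()[0] - (60, 60)).max() < 2.0

    def test_footprint_outside_image_raises(self):
        layout = [np.array([[40, 40], [41, 40]])]
        with pytest.raises(ValueError):
            render_movie(np.ones((1, 10)), layout, (32, 32), seed=0)


class TestPresets:
    def test_wt_striatal_active_fraction(self):
        assert get_preset("WT-STR").frac_active == pytest.approx(0.14)

    def test_hd_striatal_mean_ibi(self):
        assert get_preset("HD-STR").mean_ibi == pytest.approx(24.0)

    def test_unknown_preset_raises(self):
        with pytest.raises(KeyError):
            get_preset("WT-HIP")

    def test_nmda_like_disables_coherent_bursts(self):
        p = get_preset("NMDA-like")
        assert not np.isfinite(p.mean_ibi) or p.burst_participation == 0.0
        culture = simulate_raster(p, seed=1)
        assert len(culture.burst_schedule) == 0
        assert culture.raster.sum() > 0

    def test_all_presets_load(self):
        for name in list_presets():
            p = get_preset(name)
            assert 0 <= p.frac_active <= 1
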