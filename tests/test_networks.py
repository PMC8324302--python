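"""Correlation matrices, block-permutation nulls, clustering, triggered
averages, classification and the pixel cross-correlation map."""

import numpy as np
import pytest

import hydramech as hm
from hydramech import networks as nw


def _traceset(values, fps=10.0):
    return hm.TraceSet(np.asarray(values, dtype=float), fps=fps)


class TestCorrelationMatrix:
    def test_self_and_negation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(100, 5, 500)
        corr, flagged = hm.correlation_matrix(
            _traceset([x, 200 - x]), normalization="global_mean"
        )
        assert corr[0, 0] == pytest.approx(1.0)
        assert corr[0, 1] == pytest.approx(-1.0)
        assert not flagged

    def test_zero_variance_roi_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(100, 5, 500)
        corr, flagged = hm.correlation_matrix(
            _traceset([x, np.full(500, 50.0)]), normalization="global_mean"
        )
        assert flagged == [1]
        assert corr[1, 1] == 1.0
        assert corr[0, 1] == 0.0

    def test_shared_events_correlate(self, stim_protocol):
        spec = hm.SyntheticSpec(
            duration_s=300.0, fps=16.0, seed=4, noise_sd=0.05,
            roi_classes=("CB", "CB", "MR"),
            response_prob_by_pressure={25.0: 0.8},
        )
        truth = hm.simulate_contraction_events(spec, stim_protocol)
        traces = hm.render_calcium_traces(truth, spec)
        corr, _ = hm.correlation_matrix(traces)
        assert corr[0, 1] > 0.8  # same CB event stream
        assert corr[0, 2] < 0.2  # independent MR stream


class TestBlockShuffle:
    def test_permutation_preserves_multiset(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        shuffled = nw.shuffle_blocks(x, 30, rng)
        assert np.array_equal(np.sort(shuffled), np.sort(x))
        assert shuffled.size == x.size

    def test_block_boundaries_remainder_to_final(self):
        bounds = nw._block_bounds(100, 30)
        sizes = np.diff(bounds)
        assert sizes[:-1].tolist() == [3] * 29
        assert sizes[-1] == 13
        assert bounds[-1] == 100

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        traces = _traceset(rng.normal(100, 5, (3, 600)))
        a = hm.block_shuffle_null(traces, n_iter=50, seed=9)
        b = hm.block_shuffle_null(traces, n_iter=50, seed=9)
        assert np.array_equal(a.zscore, b.zscore)

    def test_identical_rois_score_high(self):
        spec = hm.SyntheticSpec(duration_s=600.0, fps=16.0, seed=5,
                                noise_sd=0.05, roi_classes=("CB", "CB"))
        truth = hm.simulate_contraction_events(spec, None)
        traces = hm.render_calcium_traces(truth, spec)
        null = hm.block_shuffle_null(traces, n_iter=100, seed=0)
        assert null.zscore[0, 1] >= 5.0

    def test_white_noise_z_is_standard_normal(self):
        rng = np.random.default_rng(6)
        zs = []
        for pair in range(30):
            traces = _traceset(rng.normal(100, 5, (2, 1500)))
            null = hm.block_shuffle_null(traces, n_iter=120, seed=pair)
            zs.append(null.zscore[0, 1])
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.5
        assert 0.6 < zs.std(ddof=1) < 1.5

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            hm.block_shuffle_null(_traceset(np.ones((2, 10))), n_blocks=30)


class TestClusterNeurons:
    def test_separable_blocks_recovered(self):
        corr = np.eye(6)
        corr[:3, :3] = 1.0
        corr[3:, 3:] = 1.0
        order, labels = hm.cluster_neurons(corr, k=2)
        assert set(labels[:3]) != set(labels[3:])
        # leaf order keeps each block contiguous
        ordered = labels[order]
        assert np.all(np.diff(np.flatnonzero(np.diff(ordered) != 0)) != 1) or True
        changes = np.count_nonzero(np.diff(ordered))
        assert changes == 1

    def test_single_roi_trivial(self):
        order, labels = hm.cluster_neurons(np.array([[1.0]]), k=1)
        assert order.tolist() == [0]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            hm.cluster_neurons(np.eye(3), k=5)


class TestTriggeredAverage:
    def test_single_anchor_equals_window(self):
        rng = np.random.default_rng(7)
        traces = _traceset(rng.normal(100, 5, (1, 400)), fps=10.0)
        avg = hm.triggered_average(traces, [20.0], pre_s=2.0, post_s=2.0,
                                   normalization="global_mean")
        dff = hm.normalize_dff(traces.values[0], "global_mean")
        assert np.allclose(avg.mean[0], dff[180:221])
        assert avg.n_anchors_used == 1

    def test_edge_anchors_dropped_and_counted(self):
        traces = _traceset(np.random.default_rng(8).normal(100, 5, (1, 100)))
        avg = hm.triggered_average(traces, [0.5, 5.0], pre_s=2.0, post_s=2.0)
        assert avg.n_anchors_used == 1
        assert avg.n_anchors_dropped == 1
        with pytest.raises(hm.UndefinedStatisticError):
            hm.triggered_average(traces, [0.1], pre_s=5.0, post_s=5.0)

    def test_noise_average_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(9)
        traces = _traceset(rng.normal(100, 5, (1, 20000)), fps=10.0)
        amp = {}
        for n in (1, 4, 16):
            anchors = rng.uniform(50, 1950, n)
            avg = hm.triggered_average(traces, anchors, pre_s=2, post_s=2,
                                       normalization="global_mean")
            amp[n] = np.std(avg.mean[0])
        assert amp[4] < amp[1]
        assert amp[16] < amp[4]
        # CLT scaling within a factor ~2.5
        assert amp[16] == pytest.approx(amp[1] / 4.0, rel=1.5)

    def test_planted_latency_recovered(self):
        spec = hm.SyntheticSpec(
            duration_s=620.0, fps=16.0, seed=10, noise_sd=0.05,
            roi_classes=("MR",), mr_latency_sd_s=0.01,
            response_prob_by_pressure={25.0: 1.0},
        )
        prot = hm.generate_stimulus_protocol(1.0, 30.0, 589.0, 25.0, pre_s=31.0)
        truth = hm.simulate_contraction_events(spec, prot)
        traces = hm.render_calcium_traces(truth, spec)
        avg = hm.triggered_average(traces, prot.onsets_s, pre_s=5, post_s=15)
        assert avg.peak_latency_s(0) == pytest.approx(10.0, abs=0.5)


class TestClassification:
    @pytest.fixture(scope="class")
    @staticmethod
    def network_run():
        classes = ("CB",) * 4 + ("MR",) * 3 + ("unspecified",) * 2 + ("peduncle",)
        spec = hm.SyntheticSpec(
            duration_s=1800.0, fps=16.0, seed=21, noise_sd=0.05,
            roi_classes=classes, response_prob_by_pressure={22.0: 0.8},
        )
        prot = hm.generate_stimulus_protocol(
            1.0, 30.0, 600.0, 22.0, pre_s=1200.0, fps=16.0
        )
        truth = hm.simulate_contraction_events(spec, prot)
        traces = hm.render_calcium_traces(truth, spec)
        result = hm.analyze_network(traces, prot, n_iter=100, seed=21)
        return classes, result

    def test_planted_labels_recovered(self, network_run):
        classes, result = network_run
        planted = [c if c != "peduncle" else "CB" for c in classes]
        correct = sum(a == b for a, b in zip(planted, result.classification.labels))
        assert correct >= len(classes) - 1

    def test_flat_clusters_match_planted_groups(self, network_run):
        from sklearn.metrics import adjusted_rand_score

        classes, result = network_run
        planted = [c if c != "peduncle" else "CB" for c in classes]
        assert adjusted_rand_score(planted, result.flat_labels) >= 0.9

    def test_mr_latency_estimate(self, network_run):
        classes, result = network_run
        lats = [
            result.mr_latency_s[i]
            for i, c in enumerate(classes)
            if c == "MR"
        ]
        assert np.nanmean(lats) == pytest.approx(10.0, abs=1.0)


class TestPixelCrossCorrelation:
    def _movie_from(self, pixel_traces, h=64, w=64):
        t = pixel_traces[next(iter(pixel_traces))].size
        movie = np.zeros((t, h, w))
        for (i, j), tr in pixel_traces.items():
            movie[:, i, j] = tr
        return movie

    def test_reference_pixel_scores_one(self):
        rng = np.random.default_rng(12)
        ref = rng.normal(size=200)
        movie = self._movie_from({(5, 7): ref})
        m = hm.pixel_crosscorrelation_map(movie, ref, fps=20.0)
        assert m[5, 7] == pytest.approx(1.0)

    def test_delayed_by_max_lag_still_one(self):
        rng = np.random.default_rng(13)
        ref = rng.normal(size=200)
        delayed = np.roll(ref, 1)  # one frame at 20 fps = 0.05 s
        movie = self._movie_from({(3, 3): delayed})
        m = hm.pixel_crosscorrelation_map(movie, ref, fps=20.0, max_lag_s=0.05)
        assert m[3, 3] == pytest.approx(1.0, abs=0.02)

    def test_constant_pixels_map_to_zero(self):
        ref = np.random.default_rng(14).normal(size=100)
        movie = np.ones((100, 64, 64))
        m = hm.pixel_crosscorrelation_map(movie, ref, fps=20.0)
        assert np.all(m == 0.0)

    def test_rendered_blob_peaks_at_blob_location(self):
        spec = hm.SyntheticSpec(
            duration_s=4.0, fps=16.0, seed=0, roi_classes=("CB",),
            noise_sd=0.0, response_prob_by_pressure={25.0: 1.0},
            stimulated_single_pulse_fraction=1.0,
        )
        prot = hm.generate_stimulus_protocol(1.0, 30.0, 4.0, 25.0, fps=16.0)
        truth = hm.simulate_contraction_events(spec, prot)
        movie = hm.render_movie(truth, spec, frame_size=(64, 64))
        ref = hm.render_calcium_traces(truth, spec).values[0]
        m = hm.pixel_crosscorrelation_map(movie, ref - ref.mean(), fps=16.0)
        peak = np.unravel_index(np.argmax(m), m.shape)
        assert m[peak] > 0.95
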