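"""Displacement statistics, radial profiles and body-length measurement."""

import numpy as np
import pandas as pd
import pytest

import hydramech as hm
from hydramech import kinematics as km


def _table(rows):
    return pd.DataFrame(rows, columns=["frame", "neuron_id", "x_um", "y_um"])


class TestFrameDisplacements:
    def test_stationary_neuron_is_zero(self):
        table = _table([(f, 0, 10.0, 20.0) for f in range(5)])
        tracks = km.NeuronTrackTable(table, frame_period_s=0.05)
        disp = km.frame_displacements(tracks)
        assert np.allclose(disp["displacement_um"], 0.0)

    def test_three_four_five(self):
        table = _table([(0, 0, 0.0, 0.0), (1, 0, 3.0, 4.0)])
        tracks = km.NeuronTrackTable(table, frame_period_s=0.05)
        disp = km.frame_displacements(tracks)
        assert disp["displacement_um"].iloc[0] == pytest.approx(5.0)

    def test_missing_frames_produce_gaps(self):
        table = _table([(0, 0, 0.0, 0.0), (1, 0, 1.0, 0.0), (5, 0, 9.0, 0.0)])
        tracks = km.NeuronTrackTable(table, frame_period_s=0.05)
        disp = km.frame_displacements(tracks)
        assert disp["frame"].tolist() == [1]  # the 1->5 jump is not bridged

    def test_single_frame_neuron_excluded(self):
        table = _table([(0, 0, 0.0, 0.0), (1, 0, 1.0, 0.0), (3, 1, 5.0, 5.0)])
        tracks = km.NeuronTrackTable(table, frame_period_s=0.05)
        disp = km.frame_displacements(tracks)
        assert set(disp["neuron_id"]) == {0}

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 100, (20, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        rows, rows_t = [], []
        for f in range(20):
            for n, p in enumerate(xy + f * 0.3):
                rows.append((f, n, p[0], p[1]))
                q = rot @ p + np.array([55.0, -20.0])
                rows_t.append((f, n, q[0], q[1]))
        d1 = km.frame_displacements(
            km.NeuronTrackTable(_table(rows), frame_period_s=0.05)
        )
        d2 = km.frame_displacements(
            km.NeuronTrackTable(_table(rows_t), frame_period_s=0.05)
        )
        assert np.allclose(
            d1["displacement_um"], d2["displacement_um"], rtol=1e-9
        )

    def test_duplicate_entries_rejected(self):
        table = _table([(0, 0, 0.0, 0.0), (0, 0, 1.0, 1.0)])
        with pytest.raises(ValueError):
            km.NeuronTrackTable(table, frame_period_s=0.05)


class TestStimulusDisplacementStats:
    def test_all_zero_displacements(self):
        prot = hm.StimulusProtocol(onsets_s=np.array([2.0]), on_s=1.0)
        disp = pd.DataFrame(
            {"neuron_id": 0, "frame": np.arange(1, 100),
             "displacement_um": np.zeros(99)}
        )
        stats = km.stimulus_displacement_stats(disp, prot, fps=16.0)
        assert stats.baseline_mean_um == 0.0
        assert stats.evoked_mean_um == 0.0

    def test_planted_baseline_and_evoked_recovered(self):
        # baseline 0.4 um jitter, evoked ~6.2 um at the valve transitions
        spec = hm.SyntheticSpec(duration_s=187.0, fps=16.0, seed=6)
        prot = hm.generate_stimulus_protocol(1.0, 30.0, 185.0, 22.0, pre_s=2.0)
        df = hm.simulate_neuron_tracks(
            100, (750.0, 750.0), lambda r: np.full_like(r, 6.2), prot, spec,
            jitter_um=0.4,
        )
        tracks = km.NeuronTrackTable(df, frame_period_s=1 / 16.0,
                                     valve_center_um=(750.0, 750.0))
        disp = km.frame_displacements(tracks)
        stats = km.stimulus_displacement_stats(disp, prot, fps=16.0)
        assert stats.baseline_mean_um == pytest.approx(0.4, rel=0.10)
        assert stats.evoked_mean_um == pytest.approx(6.2, rel=0.10)
        assert stats.p_value < 0.001

    def test_type_one_error_controlled(self):
        # evoked drawn from the baseline distribution: p > 0.05 usually
        rng = np.random.default_rng(0)
        prot = hm.StimulusProtocol(onsets_s=np.array([2.0, 5.0]), on_s=1.0)
        rejections = 0
        n_runs = 60
        for _ in range(n_runs):
            disp = pd.DataFrame(
                {"neuron_id": 0, "frame": np.arange(1, 200),
                 "displacement_um": rng.exponential(0.4, 199)}
            )
            stats = km.stimulus_displacement_stats(disp, prot, fps=16.0)
            rejections += stats.p_value < 0.05
        assert rejections <= 0.07 * n_runs + 3

    def test_no_transitions_undefined(self):
        prot = hm.StimulusProtocol(onsets_s=np.array([]), on_s=1.0)
        disp = pd.DataFrame(
            {"neuron_id": [0], "frame": [1], "displacement_um": [0.1]}
        )
        with pytest.raises(hm.UndefinedStatisticError):
            km.stimulus_displacement_stats(disp, prot, fps=16.0)


class TestRadialBandProfile:
    def _one_per_band(self):
        rows = []
        # neurons at radii 25, 75, 125 um east of the valve center
        for n, r in enumerate([25.0, 75.0, 125.0]):
            rows.append((0, n, 500.0 + r, 500.0))
            rows.append((1, n, 500.0 + r + (n + 1.0), 500.0))
        return km.NeuronTrackTable(
            _table(rows), frame_period_s=0.05, valve_center_um=(500.0, 500.0)
        )

    def test_top3_of_one_is_the_value(self):
        tracks = self._one_per_band()
        disp = km.frame_displacements(tracks)
        profile = km.radial_band_profile(tracks, disp, np.array([1]),
                                         reference_frame=0)
        tab = profile.to_frame().dropna()
        assert np.allclose(tab["topk_mean_um"], [1.0, 2.0, 3.0])
        assert np.allclose(tab["n"], 1)

    def test_uniform_field_is_flat(self):
        rng = np.random.default_rng(4)
        rows = [(0, n, x, y) for n, (x, y) in
                enumerate(rng.uniform(0, 1000, (200, 2)))]
        rows += [(1, n, x + 7.0, y) for n, (x, y) in
                 enumerate(rng.uniform(0, 1000, (200, 2)))]
        # rebuild frame 1 from frame 0 positions shifted by exactly 7 um
        table = _table([r for r in rows if r[0] == 0])
        shifted = table.copy()
        shifted["frame"] = 1
        shifted["x_um"] += 7.0
        tracks = km.NeuronTrackTable(
            pd.concat([table, shifted], ignore_index=True),
            frame_period_s=0.05,
            valve_center_um=(500.0, 500.0),
        )
        disp = km.frame_displacements(tracks)
        profile = km.radial_band_profile(tracks, disp, np.array([1]),
                                         reference_frame=0)
        vals = profile.to_frame().dropna()["topk_mean_um"]
        assert np.allclose(vals, 7.0)

    def test_band_partition(self):
        # every neuron with a stimulus-frame displacement lands in one band
        tracks = self._one_per_band()
        disp = km.frame_displacements(tracks)
        profile = km.radial_band_profile(tracks, disp, np.array([1]),
                                         reference_frame=0)
        assert int(profile.n_per_band.sum()) == 3

    def test_planted_decay_with_far_bands_negligible(self):
        spec = hm.SyntheticSpec(duration_s=64.0, fps=16.0, seed=7)
        prot = hm.generate_stimulus_protocol(1.0, 30.0, 62.0, 22.0, pre_s=2.0)

        def profile_fn(r):
            return 40.0 * np.exp(-r / 300.0)

        df = hm.simulate_neuron_tracks(222, (750.0, 750.0), profile_fn, prot,
                                       spec, jitter_um=0.4)
        tracks = km.NeuronTrackTable(df, frame_period_s=1 / 16.0,
                                     valve_center_um=(750.0, 750.0))
        disp = km.frame_displacements(tracks)
        on_f = np.round(prot.onsets_s * 16).astype(int)
        off_f = np.round(prot.offsets_s() * 16).astype(int)
        prof = km.radial_band_profile(tracks, disp,
                                      np.concatenate([on_f, off_f]))
        tab = prof.to_frame().dropna()
        far = tab[tab.band_lo_um >= 750.0]
        assert (far["topk_mean_um"] < 5.0).all()
        near = tab[tab.band_lo_um < 300.0]
        # decay shape: strictly decreasing over the near bands
        assert np.all(np.diff(near["topk_mean_um"]) < 0)


class TestBodyLength:
    @staticmethod
    def _ellipse(a, b, h=256, w=256, angle=0.0):
        yy, xx = np.mgrid[0:h, 0:w]
        xc, yc = w / 2, h / 2
        ca, sa = np.cos(angle), np.sin(angle)
        u = (xx - xc) * ca + (yy - yc) * sa
        v = -(xx - xc) * sa + (yy - yc) * ca
        return ((u / (a / 2)) ** 2 + (v / (b / 2)) ** 2 <= 1).astype(float)

    def test_major_axis_of_planted_ellipse(self):
        img = self._ellipse(100, 40)
        assert hm.body_length(img) == pytest.approx(100.0, abs=2.0)

    def test_circle_major_equals_minor(self):
        img = self._ellipse(100, 100)
        assert hm.body_length(img) == pytest.approx(100.0, abs=2.0)

    def test_rotation_invariance(self):
        lengths = [
            hm.body_length(self._ellipse(120, 40, angle=a))
            for a in (0.0, 0.5, 1.1)
        ]
        assert max(lengths) - min(lengths) < 0.02 * 120

    def test_largest_component_wins(self):
        img = self._ellipse(100, 40)
        img[5:10, 5:10] = 1.0  # a tiny second blob
        assert hm.body_length(img) == pytest.approx(100.0, abs=2.0)

    def test_degenerate_inputs(self):
        with pytest.raises(hm.DegenerateInputError):
            hm.body_length(np.zeros((32, 32)))
        with pytest.raises(hm.DegenerateInputError):
            hm.body_length(np.array([]))
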