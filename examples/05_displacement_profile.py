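"""How far does the valve's mechanical force reach through the tissue?

Simulates tracked neurons under a 400 um valve whose pressurization
displaces tissue radially with an exponentially decaying profile, then
recovers the baseline vs evoked displacement and the radial band profile
(mean of the top-3 displacements per 50 um band).
"""

import numpy as np

import hydramech as hm

spec = hm.SyntheticSpec(duration_s=64.0, fps=16.0, seed=4)
protocol = hm.generate_stimulus_protocol(1.0, 30.0, 62.0, 22.0, pre_s=2.0)


def planted_profile(r_um):
    return 40.0 * np.exp(-r_um / 300.0)


tracks_df = hm.simulate_neuron_tracks(
    222, (750.0, 750.0), planted_profile, protocol, spec, jitter_um=0.4
)
tracks = hm.NeuronTrackTable(
    tracks_df, frame_period_s=1 / 16.0, valve_center_um=(750.0, 750.0)
)
disp = hm.frame_displacements(tracks)
stats = hm.stimulus_displacement_stats(disp, protocol, fps=16.0)

print(f"baseline displacement: {stats.baseline_mean_um:.2f} um/frame")
print(f"evoked  displacement : {stats.evoked_mean_um:.2f} um/frame "
      f"(rank-sum p = {stats.p_value:.1e})")

on_f = np.round(protocol.onsets_s * 16).astype(int)
off_f = np.round(protocol.offsets_s() * 16).astype(int)
profile = hm.radial_band_profile(tracks, disp, np.concatenate([on_f, off_f]))
print("\nband (um)      top-3 mean (um)   planted at band lo")
for _, row in profile.to_frame().dropna().iterrows():
    print(
        f"{row.band_lo_um:4.0f}-{row.band_hi_um:4.0f}  {row.topk_mean_um:15.1f}"
        f"   {planted_profile(row.band_lo_um):18.1f}"
    )
print(
    "\nDisplacement decays with distance from the valve center and falls"
    "\nbelow the 5 um negligibility level well before 750 um."
)
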