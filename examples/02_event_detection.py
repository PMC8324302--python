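"""Contraction pulses and bursts from a raw fluorescence trace.

Renders a 10-minute synthetic peduncle recording, normalizes it to dF/F
with a running-minimum baseline, detects calcium spikes, groups them into
contraction events, and prints the interval/duration summary.
"""

import hydramech as hm
from hydramech import events as ev

spec = hm.SyntheticSpec(duration_s=600.0, fps=16.0, seed=7, noise_sd=0.05)
truth = hm.simulate_contraction_events(spec, None)  # spontaneous only
traces = hm.render_calcium_traces(truth, spec)

dff = ev.normalize_dff(traces.values[0])
spikes = ev.detect_spikes(dff, spec.fps)
events = ev.segment_events(spikes, dff, spec.fps)
summary = ev.event_metrics(events)

print(f"planted pulses : {truth.event_times_s[0].size}")
print(f"detected spikes: {spikes.n_spikes}")
print(f"events         : {summary.n_events} "
      f"({summary.n_pulse_kind} single pulses, {summary.n_burst_kind} bursts)")
print(f"percent single : {summary.percent_single:.1f}%")
iv = summary.stat("intervals_s")
print(f"interval       : mean {iv['mean']:.1f} s, median {iv['median']:.1f} s")
du = summary.stat("durations_s")
print(f"duration       : mean {du['mean']:.1f} s")
print(
    "\nIntervals are measured end-of-event to start-of-next; with a ~73 s"
    "\nrenewal process and multi-second bursts the mean interval sits in"
    "\nthe sixties, below the planted start-to-start mean."
)
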