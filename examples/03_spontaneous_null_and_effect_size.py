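"""Spontaneous null vs evoked response, with effect sizes.

For each of six simulated animals: the spontaneous contraction
probability from the 20-minute unstimulated lead-in (a 1 s window slid in
0.3 s steps across 30 s pseudo-trials) and the evoked response
probability from the 20-minute stimulation block. The paired comparison
reports a paired t-test, Cohen's d and Cliff's delta.
"""

import numpy as np

import hydramech as hm

spont, evoked = [], []
protocol = hm.generate_stimulus_protocol(
    1.0, 30.0, 40 * 31.0, 22.0, pre_s=1200.0, fps=16.0
)
for animal in range(6):
    spec = hm.SyntheticSpec(
        duration_s=1200.0 + 40 * 31.0,
        fps=16.0,
        seed=animal,
        response_prob_by_pressure={22.0: 0.6},
    )
    truth = hm.simulate_contraction_events(spec, protocol)
    traces = hm.render_calcium_traces(truth, spec)
    result = hm.analyze_recording(
        traces, protocol, spontaneous_segment=(0.0, 1200.0)
    )
    spont.append(result.spontaneous.mean)
    evoked.append(result.response_probability)

cmp = hm.compare_conditions(np.array(spont), np.array(evoked))
print("animal  spontaneous  evoked")
for i, (s, e) in enumerate(zip(spont, evoked)):
    print(f"{i:6d}  {s:11.3f}  {e:6.3f}")
print(f"\npaired t = {cmp.t_statistic:.2f}, p = {cmp.p_value:.2g}")
print(f"Cohen's d = {cmp.cohens_d:.2f}, Cliff's delta = {cmp.cliffs_delta:.2f}")
print(
    "\nEvery animal responds far above its own spontaneous rate; with a"
    "\nplanted 0.6 evoked probability against a ~0.05 spontaneous null the"
    "\neffect sizes saturate (delta = 1 means complete separation)."
)
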