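"""Stimulus-intensity dependence of the mechanosensory response.

Simulates three animals at a weak (5 psi) and a strong (25 psi) valve
pressure, runs the full detection pipeline on each recording, and prints
the per-pressure response probability: the fraction of 1 s valve-on
windows containing at least one contraction pulse.
"""

import numpy as np
import pandas as pd

import hydramech as hm

rows = []
for pressure, prob in {5.0: 0.09, 25.0: 0.77}.items():
    protocol = hm.generate_stimulus_protocol(1.0, 30.0, 40 * 31.0, pressure, fps=16.0)
    for animal in range(3):
        spec = hm.SyntheticSpec(
            duration_s=40 * 31.0,
            fps=16.0,
            seed=100 * int(pressure) + animal,
            spontaneous_mean_interval_s=np.inf,  # isolate the evoked channel
            response_prob_by_pressure={pressure: prob},
        )
        truth = hm.simulate_contraction_events(spec, protocol)
        traces = hm.render_calcium_traces(truth, spec)
        result = hm.analyze_recording(traces, protocol)
        rows.append(
            {
                "animal": animal,
                "pressure_psi": pressure,
                "response_probability": result.response_probability,
            }
        )

table = hm.psychometric_table(pd.DataFrame(rows))
print(table.to_string(index=False))
print(
    "\nEach row: mean +- SEM of the per-animal probability that a 1 s"
    "\nvalve-on window contains a contraction pulse (40 trials/animal)."
    "\nWeak stimuli sit near the planted 0.09; strong ones near 0.77."
)
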