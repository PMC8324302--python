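"""Identifying CB and MR neuron groups from single-neuron traces.

Simulates a 30-minute whole-animal recording (20 min spontaneous, 10 min
stimulated) with planted contraction-burst (CB), mechanically responsive
(MR) and unspecified neurons plus the peduncle readout, then runs the
correlation-network pipeline: block-permutation z-scores, hierarchical
clustering, triggered averages and per-ROI classification.
"""

import numpy as np

import hydramech as hm

classes = ("CB",) * 4 + ("MR",) * 3 + ("unspecified",) * 2 + ("peduncle",)
spec = hm.SyntheticSpec(
    duration_s=1800.0,
    fps=16.0,
    seed=1,
    roi_classes=classes,
    response_prob_by_pressure={22.0: 0.8},
)
protocol = hm.generate_stimulus_protocol(
    1.0, 30.0, 600.0, 22.0, pre_s=1200.0, fps=16.0
)
truth = hm.simulate_contraction_events(spec, protocol)
traces = hm.render_calcium_traces(truth, spec)

result = hm.analyze_network(traces, protocol, n_iter=200, seed=1)

print(f"{'ROI':12s} {'planted':12s} {'assigned':12s} {'z vs peduncle':>13s} "
      f"{'latency (s)':>11s}")
ped = list(traces.roi_labels).index("peduncle")
for i, (roi, planted) in enumerate(zip(traces.roi_labels, classes)):
    lat = result.mr_latency_s[i]
    print(
        f"{roi:12s} {planted:12s} {result.classification.labels[i]:12s} "
        f"{result.null.zscore[i, ped]:13.1f} "
        f"{lat if np.isfinite(lat) else float('nan'):11.2f}"
    )
print(f"\nleaf order: {result.leaf_order.tolist()}")
print(
    "\nCB neurons co-fire with the peduncle (large permutation z); MR"
    "\nneurons are uncorrelated with it but spike ~10 s after the valve on"
    "\nmost trials; the remaining ROIs fall to 'unspecified'."
)
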