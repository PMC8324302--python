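"""End-to-end per-recording analysis.

Chains normalization -> spike detection -> raster -> response probability
-> event segmentation/metrics -> sliding-window spontaneous null for one
recording, returning a tidy result that the CLI, the examples and the
per-condition aggregation all consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import events as ev
from . import networks as nw
from . import response as resp
from .trace_io import StimulusProtocol, TraceSet

__all__ = [
    "RecordingResult",
    "NetworkResult",
    "analyze_recording",
    "analyze_network",
]


@dataclass
class RecordingResult:
    """Everything the event/response analysis extracts from one recording."""

    spikes: ev.SpikeTrain
    events: list[ev.ContractionEvent]
    summary: ev.EventSummary | None
    raster: resp.Raster | None
    response_probability: float | None
    spontaneous: resp.SpontaneousNull | None
    condition: str = ""

    def row(self) -> dict:
        """Flatten into one tidy-table row."""
        out: dict = {"condition": self.condition, "n_spikes": self.spikes.n_spikes}
        if self.response_probability is not None:
            out["response_probability"] = self.response_probability
        if self.spontaneous is not None:
            out["spontaneous_mean"] = self.spontaneous.mean
        if self.summary is not None:
            out["mean_interval_s"] = self.summary.stat("intervals_s")["mean"]
            out["median_interval_s"] = self.summary.stat("intervals_s")["median"]
            out["percent_single"] = self.summary.percent_single
            out["n_events"] = self.summary.n_events
        return out


def analyze_recording(
    traces: TraceSet,
    protocol: StimulusProtocol | None = None,
    roi: str | int = 0,
    spontaneous_segment: tuple[float, float] | None = None,
    normalization: str = "running_min",
    min_prominence_frac: float = 0.2,
    min_separation_s: float = 1.0,
    response_window_s: float = 1.0,
    pre_s: float = 15.0,
    post_s: float = 15.0,
    condition: str = "",
) -> RecordingResult:
    """Run the full event/response analysis on one ROI of a recording.

    ``roi`` selects the trace by label or row index (typically the
    peduncle or whole-frame readout). ``spontaneous_segment`` bounds the
    unstimulated stretch used for the sliding-window null; when omitted
    and the protocol has onsets, the pre-stimulation stretch before the
    first onset is used if it spans at least one 30 s pseudo-trial.
    """
    raw = traces.roi(roi) if isinstance(roi, str) else traces.values[roi]
    dff = ev.normalize_dff(raw, normalization)
    spikes = ev.detect_spikes(
        dff,
        traces.fps,
        min_prominence_frac=min_prominence_frac,
        min_separation_s=min_separation_s,
    )
    contraction_events = ev.segment_events(spikes, dff, traces.fps)
    summary = ev.event_metrics(contraction_events) if contraction_events else None

    raster = None
    probability = None
    if protocol is not None and protocol.onsets_s.size:
        raster = resp.build_raster(spikes, protocol, pre_s=pre_s, post_s=post_s)
        probability = resp.response_probability(raster, window_s=response_window_s)

    if spontaneous_segment is None and protocol is not None and protocol.onsets_s.size:
        first = float(protocol.onsets_s[0])
        if first >= 30.0:
            spontaneous_segment = (0.0, first)
    spontaneous = None
    if spontaneous_segment is not None:
        spontaneous = resp.spontaneous_probability_null(spikes, spontaneous_segment)

    return RecordingResult(
        spikes=spikes,
        events=contraction_events,
        summary=summary,
        raster=raster,
        response_probability=probability,
        spontaneous=spontaneous,
        condition=condition,
    )


@dataclass
class NetworkResult:
    """Full network analysis of a multi-ROI recording."""

    null: nw.BlockShuffleNull
    leaf_order: np.ndarray
    flat_labels: np.ndarray | None
    classification: nw.NeuronClassification
    stim_triggered: nw.TriggeredAverage
    contraction_triggered: nw.TriggeredAverage
    mr_latency_s: np.ndarray  # median stimulus-locked spike latency per ROI


def analyze_network(
    traces: TraceSet,
    protocol: StimulusProtocol,
    peduncle: str | int = "peduncle",
    n_blocks: int = 30,
    n_iter: int = 1000,
    seed: int | None = None,
    k: int | None = 3,
    mr_latency_window_s: tuple[float, float] = (5.0, 15.0),
    normalization: str = "detrended_mean",
) -> NetworkResult:
    """Correlation network, clustering and CB/MR classification.

    Runs the block-permutation null, clusters the correlation matrix,
    builds contraction- and stimulus-triggered averages anchored on the
    peduncle readout's detected contraction onsets, and classifies every
    ROI. Per-ROI spikes are re-detected on detrended traces to supply the
    trial-consistency evidence for the MR gate (hits in the latency
    window per trial, against the ROI's own spontaneous window
    probability from the pre-stimulation segment) and the median
    stimulus-locked spike latency.
    """
    labels = list(traces.roi_labels)
    ped = labels.index(peduncle) if isinstance(peduncle, str) else int(peduncle)
    null = nw.block_shuffle_null(
        traces, n_blocks=n_blocks, n_iter=n_iter, seed=seed,
        normalization=normalization,
    )
    leaf_order, flat = nw.cluster_neurons(null.corr, k=k)

    ped_dff = ev.normalize_dff(traces.values[ped], "running_min")
    ped_spikes = ev.detect_spikes(ped_dff, traces.fps)
    contraction = ev.segment_events(ped_spikes, ped_dff, traces.fps)
    anchors = ev.event_onset_peaks(ped_spikes, contraction)
    stim_avg = nw.triggered_average(
        traces, protocol.onsets_s, pre_s=10.0, post_s=15.0,
        normalization=normalization,
    )
    con_avg = nw.triggered_average(
        traces, anchors, pre_s=5.0, post_s=5.0, normalization=normalization
    )

    lo, hi = mr_latency_window_s
    dff = nw._dff_matrix(traces, normalization)
    n_roi = traces.n_roi
    hits = np.zeros(n_roi, dtype=int)
    null_p = np.full(n_roi, 0.5)
    latencies = np.full(n_roi, np.nan)
    first_onset = float(protocol.onsets_s[0])
    window_width = hi - lo
    for i in range(n_roi):
        spikes_i = ev.detect_spikes(dff[i], traces.fps)
        raster = resp.build_raster(spikes_i, protocol, pre_s=0.0, post_s=hi)
        hits[i] = sum(
            bool(np.any((r >= lo) & (r < hi)))
            for r in raster.relative_spike_times
        )
        latencies[i] = resp.response_latency(raster, (lo, hi))
        if first_onset >= 30.0:
            spont = resp.spontaneous_probability_null(
                spikes_i, (0.0, first_onset), interval_s=30.0,
                window_s=min(window_width, 29.0),
            )
            null_p[i] = spont.mean
    classification = nw.classify_neurons(
        null.zscore,
        ped,
        stim_avg,
        con_avg,
        mr_latency_window_s=mr_latency_window_s,
        mr_hit_counts=hits,
        mr_n_trials=protocol.n_trials,
        mr_null_probability=null_p,
    )
    return NetworkResult(
        null=null,
        leaf_order=leaf_order,
        flat_labels=flat,
        classification=classification,
        stim_triggered=stim_avg,
        contraction_triggered=con_avg,
        mr_latency_s=latencies,
    )
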