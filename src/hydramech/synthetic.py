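"""Synthetic recordings with known ground truth.

Generates fluorescence traces, neuron tracks and small movies carrying the
statistical structure the analysis assumes, so every estimator in the
pipeline can be exercised against planted parameters:

* spontaneous contraction events as a gamma-renewal process (mean interval
  ~73 s; shape 2 avoids the unrealistic memorylessness of exponential
  spacing), most of them multi-pulse bursts;
* pressure-dependent stimulus-locked responses whose first calcium pulse
  falls 0.1-0.6 s after valve onset, predominantly single pulses;
* a slow mechanically-responsive (MR) population responding ~10 s after
  stimulation, shared across MR ROIs (they form a correlated group);
* GCaMP-like difference-of-exponentials kernel dynamics, lognormal pulse
  amplitudes, exponential bleaching and additive Gaussian noise.

All randomness flows from one seed; independent sub-streams are derived per
stage so individual outputs are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .trace_io import StimulusProtocol, TraceSet

__all__ = [
    "SyntheticSpec",
    "SimEvent",
    "GroundTruth",
    "PSYCHOMETRIC_MAP",
    "generate_stimulus_protocol",
    "simulate_contraction_events",
    "render_calcium_traces",
    "simulate_neuron_tracks",
    "render_movie",
    "expected_peak_lag",
]

#: measured response probability per valve pressure (psi); the 0 psi entry
#: is the spontaneous-coincidence floor of the unstimulated control
PSYCHOMETRIC_MAP: dict[float, float] = {
    0.0: 0.0,
    5.0: 0.09,
    10.0: 0.23,
    15.0: 0.24,
    20.0: 0.60,
    25.0: 0.77,
}

#: spontaneous events are suppressed for this long after a stimulated event,
#: preventing double-counting in interval statistics
REFRACTORY_S = 5.0


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic recording.

    Defaults mirror the study conditions: spontaneous contraction events
    every ~73 s, ~83% of them bursts, ~16 Hz imaging, MR latency 10 +- 2 s.
    """

    duration_s: float = 600.0
    fps: float = 16.0
    spontaneous_mean_interval_s: float = 72.98
    burst_fraction: float = 0.83
    pulses_per_burst_mean: float = 4.0
    intra_burst_interval_s: float = 1.5
    response_prob_by_pressure: Mapping[float, float] = field(
        default_factory=lambda: dict(PSYCHOMETRIC_MAP)
    )
    stimulated_single_pulse_fraction: float = 0.60
    mr_latency_mean_s: float = 10.0
    mr_latency_sd_s: float = 2.0
    kernel_rise_s: float = 0.1
    kernel_decay_s: float = 1.0
    noise_sd: float = 0.05
    bleach_halflife_s: float = 7200.0
    seed: int = 0
    #: class per ROI: "CB", "MR", "unspecified" or "peduncle" (a CB-stream
    #: readout mirroring the large-ROI average used in the recordings)
    roi_classes: tuple[str, ...] = ("peduncle",)
    gamma_shape: float = 2.0
    amplitude_sigma: float = 0.25
    baseline_f0: float = 100.0

    def __post_init__(self) -> None:
        probs = [self.burst_fraction, self.stimulated_single_pulse_fraction]
        probs += list(self.response_prob_by_pressure.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        durations = [
            self.duration_s,
            self.fps,
            self.spontaneous_mean_interval_s,
            self.intra_burst_interval_s,
            self.kernel_rise_s,
            self.kernel_decay_s,
            self.bleach_halflife_s,
        ]
        if any(d <= 0 for d in durations):
            raise ValueError("all durations and rates must be positive")
        n = self.fps * self.duration_s
        if abs(n - round(n)) > 1e-6:
            raise ValueError(
                f"fps * duration_s = {n} is not an integer frame count"
            )
        bad = set(self.roi_classes) - {"CB", "MR", "unspecified", "peduncle"}
        if bad:
            raise ValueError(f"unknown ROI classes: {bad}")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    def with_(self, **kwargs) -> "SyntheticSpec":
        """Return a copy with fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SimEvent:
    """One planted contraction event: a pulse or a burst of pulses."""

    pulse_times_s: np.ndarray
    kind: str  # "pulse" | "burst"
    stimulated: bool = False

    @property
    def start_s(self) -> float:
        return float(self.pulse_times_s[0])


@dataclass
class GroundTruth:
    """Planted events and class labels returned alongside synthetic data."""

    duration_s: float
    events_by_roi: list[list[SimEvent]]
    neuron_classes: list[str]
    responded_trials: np.ndarray  # bool per stimulus onset (CB channel)
    mr_responded_trials: np.ndarray  # bool per stimulus onset (MR channel)

    @property
    def event_times_s(self) -> list[np.ndarray]:
        """Pulse times per ROI (flat, sorted)."""
        out = []
        for events in self.events_by_roi:
            if events:
                out.append(np.sort(np.concatenate([e.pulse_times_s for e in events])))
            else:
                out.append(np.array([]))
        return out

    @property
    def event_labels(self) -> list[np.ndarray]:
        """Per-pulse kind membership ("pulse"/"burst") per ROI."""
        out = []
        for events in self.events_by_roi:
            labels = []
            for e in sorted(events, key=lambda e: e.start_s):
                labels.extend([e.kind] * e.pulse_times_s.size)
            out.append(np.array(labels))
        return out


# ---------------------------------------------------------------------------
# protocol


def generate_stimulus_protocol(
    on_s: float,
    off_s: float,
    total_s: float,
    pressure_psi: float = 0.0,
    pre_s: float = 0.0,
    post_s: float = 0.0,
    fps: float | None = None,
) -> StimulusProtocol:
    """Build the valve schedule: ``on_s`` on / ``off_s`` off cycles.

    Onsets run ``pre_s, pre_s + (on_s+off_s), ...`` while
    ``onset + on_s <= pre_s + total_s``. If ``fps`` is given, a per-frame
    0/1 valve trace covering ``pre_s + total_s + post_s`` is rendered.
    """
    if on_s <= 0 or total_s <= 0:
        raise ValueError("on_s and total_s must be positive")
    if off_s < 0 or pre_s < 0 or post_s < 0:
        raise ValueError("off_s, pre_s and post_s must be non-negative")
    if total_s < on_s:
        raise ValueError("total_s must be at least on_s")
    cycle = on_s + off_s
    n = int(math.floor((total_s - on_s) / cycle)) + 1 if cycle > 0 else 1
    onsets = pre_s + np.arange(n) * cycle
    frame_trace = None
    if fps is not None:
        if fps <= 0:
            raise ValueError("fps must be positive")
        n_frames = int(round((pre_s + total_s + post_s) * fps))
        t = np.arange(n_frames) / fps
        frame_trace = np.zeros(n_frames, dtype=int)
        for onset in onsets:
            frame_trace[(t >= onset) & (t < onset + on_s)] = 1
    return StimulusProtocol(
        onsets_s=onsets,
        on_s=on_s,
        pressure_psi=pressure_psi,
        frame_trace=frame_trace,
        fps=fps,
    )


# ---------------------------------------------------------------------------
# events


def _renewal_times(
    rng: np.random.Generator, duration_s: float, mean_s: float, shape: float
) -> np.ndarray:
    """Gamma-renewal event starts on [0, duration)."""
    if not np.isfinite(mean_s):
        return np.array([])
    scale = mean_s / shape
    times = []
    t = rng.gamma(shape, scale)
    while t < duration_s:
        times.append(t)
        t += rng.gamma(shape, scale)
    return np.asarray(times)


def _make_event(
    rng: np.random.Generator,
    start_s: float,
    duration_s: float,
    spec: SyntheticSpec,
    burst_prob: float,
    stimulated: bool,
) -> SimEvent | None:
    is_burst = rng.random() < burst_prob
    if is_burst:
        n_pulses = 1 + rng.poisson(max(spec.pulses_per_burst_mean - 1.0, 0.0))
    else:
        n_pulses = 1
    pulses = start_s + np.arange(n_pulses) * spec.intra_burst_interval_s
    pulses = pulses[pulses <= duration_s]
    if pulses.size == 0:
        return None
    kind = "burst" if pulses.size > 1 else "pulse"
    return SimEvent(pulse_times_s=pulses, kind=kind, stimulated=stimulated)


def simulate_contraction_events(
    spec: SyntheticSpec, protocol: StimulusProtocol | None = None
) -> GroundTruth:
    """Draw the planted event streams for every ROI class.

    The CB stream (shared by CB and peduncle ROIs) mixes gamma-renewal
    spontaneous events with Bernoulli stimulus-locked events whose first
    pulse falls 0.1-0.6 s after onset. Spontaneous events within 5 s after
    a stimulated event are suppressed. MR ROIs share one slow response per
    responded stimulus (latency ~ Normal(mr_latency_mean_s,
    mr_latency_sd_s), clipped >= 1 s). Unspecified ROIs get independent
    renewal streams.
    """
    root = np.random.SeedSequence((spec.seed, 0))
    n_unspec = sum(c == "unspecified" for c in spec.roi_classes)
    streams = root.spawn(4 + n_unspec)
    rng_stim = np.random.default_rng(streams[0])
    rng_spont = np.random.default_rng(streams[1])
    rng_mr = np.random.default_rng(streams[2])

    onsets = np.array([])
    p_resp = 0.0
    if protocol is not None and protocol.onsets_s.size:
        onsets = protocol.onsets_s
        try:
            p_resp = float(spec.response_prob_by_pressure[protocol.pressure_psi])
        except KeyError:
            raise ValueError(
                f"pressure {protocol.pressure_psi} psi not in "
                f"response_prob_by_pressure map"
            ) from None

    # CB channel: stimulated events
    responded = (
        rng_stim.random(onsets.size) < p_resp
        if onsets.size
        else np.array([], dtype=bool)
    )
    cb_events: list[SimEvent] = []
    for onset, hit in zip(onsets, responded):
        if not hit:
            continue
        first = onset + rng_stim.uniform(0.1, 0.6)
        if first > spec.duration_s:
            continue
        ev = _make_event(
            rng_stim,
            first,
            spec.duration_s,
            spec,
            burst_prob=1.0 - spec.stimulated_single_pulse_fraction,
            stimulated=True,
        )
        if ev is not None:
            cb_events.append(ev)

    # CB channel: spontaneous renewal, refractory after stimulated events
    stim_starts = np.array([e.start_s for e in cb_events])
    for start in _renewal_times(
        rng_spont, spec.duration_s, spec.spontaneous_mean_interval_s, spec.gamma_shape
    ):
        if stim_starts.size and np.any(
            (start >= stim_starts) & (start < stim_starts + REFRACTORY_S)
        ):
            continue
        ev = _make_event(
            rng_spont, start, spec.duration_s, spec, spec.burst_fraction, False
        )
        if ev is not None:
            cb_events.append(ev)
    cb_events.sort(key=lambda e: e.start_s)

    # MR channel: one shared slow response per responded stimulus
    mr_responded = (
        rng_mr.random(onsets.size) < p_resp
        if onsets.size
        else np.array([], dtype=bool)
    )
    mr_events: list[SimEvent] = []
    for onset, hit in zip(onsets, mr_responded):
        if not hit:
            continue
        latency = max(
            rng_mr.normal(spec.mr_latency_mean_s, spec.mr_latency_sd_s), 1.0
        )
        t = onset + latency
        if t <= spec.duration_s:
            mr_events.append(
                SimEvent(pulse_times_s=np.array([t]), kind="pulse", stimulated=True)
            )

    events_by_roi: list[list[SimEvent]] = []
    unspec_i = 0
    for cls in spec.roi_classes:
        if cls in ("CB", "peduncle"):
            events_by_roi.append(list(cb_events))
        elif cls == "MR":
            events_by_roi.append(list(mr_events))
        else:
            rng_u = np.random.default_rng(streams[4 + unspec_i])
            unspec_i += 1
            evs = []
            for start in _renewal_times(
                rng_u,
                spec.duration_s,
                spec.spontaneous_mean_interval_s,
                spec.gamma_shape,
            ):
                ev = _make_event(
                    rng_u, start, spec.duration_s, spec, spec.burst_fraction, False
                )
                if ev is not None:
                    evs.append(ev)
            events_by_roi.append(evs)

    return GroundTruth(
        duration_s=spec.duration_s,
        events_by_roi=events_by_roi,
        neuron_classes=list(spec.roi_classes),
        responded_trials=responded,
        mr_responded_trials=mr_responded,
    )


# ---------------------------------------------------------------------------
# rendering


def _kernel(spec: SyntheticSpec) -> np.ndarray:
    """Difference-of-exponentials calcium kernel, peak-normalized to 1."""
    tr, td = spec.kernel_rise_s, spec.kernel_decay_s
    n = max(int(math.ceil(7.0 * td * spec.fps)), 2)
    t = np.arange(n) / spec.fps
    if abs(td - tr) < 1e-12:
        k = (t / tr) * np.exp(1.0 - t / tr)
    else:
        k = np.exp(-t / td) - np.exp(-t / tr)
    peak = k.max()
    return k / peak if peak > 0 else k


def expected_peak_lag(spec: SyntheticSpec) -> float:
    """Analytic lag from a pulse time to its fluorescence peak, seconds."""
    tr, td = spec.kernel_rise_s, spec.kernel_decay_s
    if abs(td - tr) < 1e-12:
        return tr
    return tr * td / (td - tr) * math.log(td / tr)


def render_calcium_traces(
    truth: GroundTruth, spec: SyntheticSpec
) -> TraceSet:
    """Convolve planted pulses into raw fluorescence traces.

    Each pulse contributes a kernel scaled by a per-pulse lognormal
    amplitude; the baseline decays exponentially with
    ``bleach_halflife_s``; Gaussian noise of ``noise_sd`` (dF/F units) is
    added multiplicatively on the baseline, so with no events and no noise
    the trace equals the bleach baseline exactly.
    """
    n = spec.n_frames
    t = np.arange(n) / spec.fps
    kernel = _kernel(spec)
    root = np.random.SeedSequence((spec.seed, 1))
    streams = root.spawn(len(truth.events_by_roi))
    bleach = spec.baseline_f0 * np.power(2.0, -t / spec.bleach_halflife_s)
    values = np.empty((len(truth.events_by_roi), n))
    labels = []
    counter = 0
    for i, (events, cls) in enumerate(
        zip(truth.events_by_roi, truth.neuron_classes)
    ):
        rng = np.random.default_rng(streams[i])
        impulses = np.zeros(n)
        pulses = (
            np.concatenate([e.pulse_times_s for e in events])
            if events
            else np.array([])
        )
        for pt in pulses:
            idx = int(round(pt * spec.fps))
            if 0 <= idx < n:
                amp = rng.lognormal(0.0, spec.amplitude_sigma)
                impulses[idx] += amp
        signal = np.convolve(impulses, kernel)[:n]
        values[i] = bleach * (1.0 + signal)
        if spec.noise_sd > 0:
            # additive noise in dF/F units of the unbleached baseline, so
            # its scale is stationary over the recording
            values[i] += spec.baseline_f0 * rng.normal(0.0, spec.noise_sd, size=n)
        if cls == "peduncle":
            labels.append("peduncle")
        else:
            labels.append(f"neuron_{counter:02d}")
            counter += 1
    return TraceSet(values=values, fps=spec.fps, roi_labels=labels)


# ---------------------------------------------------------------------------
# tracks


def simulate_neuron_tracks(
    n_neurons: int,
    valve_center: tuple[float, float],
    displacement_profile: Callable[[np.ndarray], np.ndarray],
    protocol: StimulusProtocol,
    spec: SyntheticSpec,
    field_um: tuple[float, float] = (1500.0, 1500.0),
    jitter_um: float = 0.4,
) -> pd.DataFrame:
    """Simulate tracked neuron positions under valve stimulation.

    Neurons are placed uniformly over the field. On the frame where the
    valve turns on, each neuron is displaced radially away from the valve
    center by ``displacement_profile(r)``; on the off frame it returns.
    All other frames receive Brownian jitter whose mean per-frame step
    magnitude is ``jitter_um`` (0.4 um matches the baseline cellular
    displacement of the recordings).

    Returns a long-format table (frame, neuron_id, x_um, y_um).
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 2)))
    n = spec.n_frames
    pos = np.empty((n, n_neurons, 2))
    pos[0, :, 0] = rng.uniform(0, field_um[0], n_neurons)
    pos[0, :, 1] = rng.uniform(0, field_um[1], n_neurons)
    # mean |step| of an isotropic 2-D gaussian is sigma*sqrt(pi/2)
    sigma = jitter_um / math.sqrt(math.pi / 2.0) if jitter_um > 0 else 0.0
    steps = (
        rng.normal(0.0, sigma, size=(n - 1, n_neurons, 2)) if sigma > 0 else 0.0
    )

    on_frames = {int(round(o * spec.fps)) for o in protocol.onsets_s}
    off_frames = {int(round((o + protocol.on_s) * spec.fps)) for o in protocol.onsets_s}
    center = np.asarray(valve_center, dtype=float)
    pending_return: dict[int, np.ndarray] = {}

    for f in range(1, n):
        pos[f] = pos[f - 1] + (steps[f - 1] if sigma > 0 else 0.0)
        if f in on_frames:
            rel = pos[f - 1] - center
            r = np.hypot(rel[:, 0], rel[:, 1])
            unit = np.where(r[:, None] > 0, rel / np.maximum(r, 1e-9)[:, None], 0.0)
            shift = unit * np.asarray(displacement_profile(r), dtype=float)[:, None]
            pos[f] += shift
            pending_return[f] = shift
        if f in off_frames:
            # tissue relaxes back by the shift applied at the paired onset
            on_f = f - int(round(protocol.on_s * spec.fps))
            shift = pending_return.pop(on_f, None)
            if shift is not None:
                pos[f] -= shift

    frames = np.arange(n)
    return pd.DataFrame(
        {
            "frame": np.repeat(frames, n_neurons),
            "neuron_id": np.tile(np.arange(n_neurons), n),
            "x_um": pos[:, :, 0].ravel(),
            "y_um": pos[:, :, 1].ravel(),
        }
    )


# ---------------------------------------------------------------------------
# movies


def render_movie(
    truth: GroundTruth,
    spec: SyntheticSpec,
    positions: pd.DataFrame | None = None,
    frame_size: tuple[int, int] = (64, 64),
    body_ellipse: tuple[float, float] = (48.0, 20.0),
    background: float = 30.0,
    blob_sigma_px: float = 2.0,
    blob_gain: float = 80.0,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """Render a small image stack: elliptical body + neuron blobs.

    Each frame is an elliptical body-shaped background (major/minor axis
    lengths ``body_ellipse`` in px, centered) plus Gaussian blobs at the
    neuron positions scaled by the instantaneous dF/F, plus optional
    noise. Returns a float32 array (frames, height, width).
    """
    h, w = frame_size
    if h < 64 or w < 64:
        raise ValueError("frame_size must be at least 64x64")
    clean = spec.with_(noise_sd=0.0)
    traces = render_calcium_traces(truth, clean)
    dff = traces.values / (
        spec.baseline_f0
        * np.power(2.0, -traces.time_s / spec.bleach_halflife_s)
    ) - 1.0
    n = spec.n_frames
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a, b = body_ellipse[0] / 2.0, body_ellipse[1] / 2.0
    body = (((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0) * background

    if positions is not None:
        pivot_x = positions.pivot(index="frame", columns="neuron_id", values="x_um")
        pivot_y = positions.pivot(index="frame", columns="neuron_id", values="y_um")
        px = pivot_x.to_numpy()
        py = pivot_y.to_numpy()
    else:
        rng0 = np.random.default_rng(np.random.SeedSequence((spec.seed, 3)))
        n_roi = dff.shape[0]
        px = np.tile(rng0.uniform(0.2 * w, 0.8 * w, n_roi), (n, 1))
        py = np.tile(rng0.uniform(0.2 * h, 0.8 * h, n_roi), (n, 1))

    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 4)))
    movie = np.empty((n, h, w), dtype=np.float32)
    n_blobs = min(dff.shape[0], px.shape[1])
    for f in range(n):
        frame = body.astype(np.float64).copy()
        for j in range(n_blobs):
            amp = blob_gain * max(dff[j, f], 0.0)
            if amp <= 0:
                continue
            x0, y0 = px[f, j], py[f, j]
            d2 = (xx - x0) ** 2 + (yy - y0) ** 2
            frame += amp * np.exp(-d2 / (2.0 * blob_sigma_px**2))
        if noise_sd > 0:
            frame += rng.normal(0.0, noise_sd, size=frame.shape)
        movie[f] = frame
    return movie
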