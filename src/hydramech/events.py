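"""Trace normalization, calcium-spike detection and event segmentation.

A contraction event is one or more large calcium spikes in the peduncle
(or whole-frame) fluorescence: a single spike is a contraction *pulse*, a
volley of spikes a contraction *burst*. This module turns a raw trace into
a :class:`SpikeTrain`, groups spikes into annotated
:class:`ContractionEvent` records, and summarizes inter-contraction
intervals, durations and the single-pulse percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .errors import DegenerateInputError, UndefinedStatisticError

__all__ = [
    "SpikeTrain",
    "ContractionEvent",
    "EventSummary",
    "normalize_dff",
    "estimate_noise_sd",
    "detect_spikes",
    "segment_events",
    "event_onset_peaks",
    "event_metrics",
]

EPS = 1e-9


@dataclass
class SpikeTrain:
    """Detected calcium spike peaks of one ROI."""

    peak_times_s: np.ndarray
    peak_amplitudes: np.ndarray
    trace_ref: str = ""

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if self.peak_times_s.size != self.peak_amplitudes.size:
            raise ValueError("times and amplitudes must have equal length")
        if np.any(np.diff(self.peak_times_s) <= 0):
            raise ValueError("peak times must be sorted and unique")

    @property
    def n_spikes(self) -> int:
        return int(self.peak_times_s.size)


@dataclass
class ContractionEvent:
    """A detected pulse or burst with its extent on the trace."""

    start_s: float
    end_s: float
    n_pulses: int
    kind: str = field(init=False)
    clamped: bool = False  # baseline crossing not found within search window

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("start_s must precede end_s")
        if self.n_pulses < 1:
            raise ValueError("an event has at least one pulse")
        self.kind = "pulse" if self.n_pulses == 1 else "burst"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def normalize_dff(
    trace: np.ndarray, method: str = "running_min", eps: float = EPS
) -> np.ndarray:
    """Baseline-normalize a raw fluorescence trace to dF/F.

    ``running_min``: F0 at time t is the minimum over all prior samples,
    so slow monotone bleaching is tracked intrinsically.
    ``global_mean``: F0 is the trace mean (the convention of the
    single-neuron network analysis).
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("trace must be 1-D with at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    if method == "running_min":
        f0 = np.minimum.accumulate(x)
        return (x - f0) / np.maximum(f0, eps)
    if method == "global_mean":
        f0 = float(np.mean(x))
        if f0 <= 0:
            raise DegenerateInputError(
                f"global-mean baseline is non-positive ({f0:.3g})"
            )
        return (x - f0) / f0
    raise ValueError(f"unknown normalization method {method!r}")


def estimate_noise_sd(dff: np.ndarray) -> float:
    """Robust noise scale: 1.4826 * MAD of the first difference / sqrt(2).

    First-differencing removes slow structure; the MAD ignores the sparse
    large excursions of contraction events.
    """
    d = np.diff(np.asarray(dff, dtype=float))
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _worst_case_noise_sd(
    dff: np.ndarray, fps: float, window_s: float = 60.0, q: float = 0.95
) -> float:
    """Upper noise scale: the ``q`` quantile of rolling MAD-based noise
    estimates.

    Normalization against a decaying baseline amplifies noise late in a
    recording, so a single global estimate understates the worst local
    noise; the detection floor must clear it everywhere.
    """
    x = np.asarray(dff, dtype=float)
    d = np.abs(np.diff(x) - np.median(np.diff(x))) if x.size > 1 else np.array([])
    if d.size == 0:
        return 0.0
    window = max(int(round(window_s * fps)), 3)
    rolling = (
        pd.Series(d)
        .rolling(window, center=True, min_periods=max(1, min(window // 4, d.size)))
        .median()
        .to_numpy()
    )
    if np.all(np.isnan(rolling)):
        return estimate_noise_sd(x)
    mad = float(np.nanpercentile(rolling, 100.0 * q))
    return 1.4826 * mad / np.sqrt(2.0)


def detect_spikes(
    dff: np.ndarray,
    fps: float,
    min_prominence_frac: float = 0.2,
    min_separation_s: float = 1.0,
    noise_floor_k: float = 6.0,
) -> SpikeTrain:
    """Detect calcium-spike peaks on a normalized trace.

    A peak qualifies if its prominence reaches
    ``max(min_prominence_frac * P95(dF/F), noise_floor_k * sigma_noise)``
    and it is at least ``min_separation_s`` from any larger accepted peak
    (closer pairs keep the larger; exact ties keep the earlier). The noise
    floor keeps the relative criterion from collapsing into the baseline
    on recordings where events occupy a small fraction of the trace.
    """
    x = np.asarray(dff, dtype=float)
    if min_prominence_frac <= 0 or min_separation_s <= 0 or fps <= 0:
        raise ValueError("detection parameters must be positive")
    threshold = max(
        min_prominence_frac * float(np.percentile(x, 95)),
        noise_floor_k * _worst_case_noise_sd(x, fps),
    )
    if threshold <= 0:  # flat trace
        return SpikeTrain(np.array([]), np.array([]))
    distance = max(int(round(min_separation_s * fps)), 1)
    idx, _ = scipy.signal.find_peaks(x, prominence=threshold, distance=distance)
    return SpikeTrain(peak_times_s=idx / fps, peak_amplitudes=x[idx])


def _rolling_baseline(
    dff: np.ndarray, fps: float, window_s: float = 60.0, q: float = 0.10
) -> np.ndarray:
    """Rolling low-quantile baseline, robust to bursts occupying a large
    fraction of the trace."""
    window = max(int(round(window_s * fps)), 1)
    return (
        pd.Series(dff)
        .rolling(window, center=True, min_periods=1)
        .quantile(q)
        .to_numpy()
    )


def segment_events(
    spikes: SpikeTrain,
    dff: np.ndarray,
    fps: float,
    max_gap_s: float = 5.0,
    baseline_k: float = 3.0,
    search_s: float = 30.0,
) -> list[ContractionEvent]:
    """Merge spikes into contraction events and find their extents.

    Spikes separated by <= ``max_gap_s`` belong to one event. The event
    starts at the last upward crossing of (rolling baseline +
    ``baseline_k`` * sigma_noise) before its first pulse and ends at the
    first downward crossing after its last pulse; if no crossing exists
    within ``search_s``, the bound is clamped to the search window and the
    event flagged.
    """
    if spikes.n_spikes == 0:
        return []
    x = np.asarray(dff, dtype=float)
    n = x.size
    sigma = estimate_noise_sd(x)
    thresh = _rolling_baseline(x, fps) + baseline_k * sigma
    above = x > thresh

    groups: list[list[float]] = [[spikes.peak_times_s[0]]]
    for t in spikes.peak_times_s[1:]:
        if t - groups[-1][-1] <= max_gap_s:
            groups[-1].append(t)
        else:
            groups.append([t])

    search = max(int(round(search_s * fps)), 1)
    events: list[ContractionEvent] = []
    for gp in groups:
        first_i = int(round(gp[0] * fps))
        last_i = int(round(gp[-1] * fps))
        clamped = False
        lo = max(first_i - search, 0)
        seg = above[lo : first_i + 1]
        below = np.flatnonzero(~seg)
        if below.size:
            start_i = lo + below[-1] + 1  # first sample above after last below
            start_i = min(start_i, first_i)
        else:
            start_i = lo
            clamped = True
        hi = min(last_i + search, n - 1)
        seg = above[last_i : hi + 1]
        below = np.flatnonzero(~seg)
        if below.size:
            end_i = last_i + below[0]
        else:
            end_i = hi
            clamped = True
        if end_i <= start_i:
            end_i = start_i + 1
        events.append(
            ContractionEvent(
                start_s=start_i / fps,
                end_s=end_i / fps,
                n_pulses=len(gp),
                clamped=clamped,
            )
        )
    return events


def event_onset_peaks(
    spikes: SpikeTrain, events: list[ContractionEvent]
) -> np.ndarray:
    """Time of the first spike peak of each event (contraction onsets).

    These are the anchors for contraction-triggered averaging: the first
    pulse peak is sharper than the baseline-crossing event start.
    """
    t = spikes.peak_times_s
    out = []
    for e in events:
        inside = t[(t >= e.start_s) & (t <= e.end_s)]
        if inside.size:
            out.append(float(inside[0]))
    return np.asarray(out)


@dataclass
class EventSummary:
    """Interval, duration and composition statistics of an event list."""

    intervals_s: np.ndarray
    durations_s: np.ndarray
    percent_single: float
    n_events: int
    n_pulse_kind: int
    n_burst_kind: int
    too_few_for_intervals: bool

    def stat(self, which: str) -> dict[str, float]:
        """mean / median / SEM of 'intervals_s' or 'durations_s'."""
        x = getattr(self, which)
        if x.size == 0:
            return {"mean": np.nan, "median": np.nan, "sem": np.nan}
        sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan
        return {"mean": float(np.mean(x)), "median": float(np.median(x)), "sem": sem}


def event_metrics(events: list[ContractionEvent]) -> EventSummary:
    """Summarize sorted, non-overlapping contraction events.

    The inter-contraction interval is the time from the *end* of one event
    to the *start* of the next; ``percent_single`` is 100 x (#pulse-kind
    events / #events).
    """
    if not events:
        raise UndefinedStatisticError("no events to summarize")
    starts = np.array([e.start_s for e in events])
    ends = np.array([e.end_s for e in events])
    if np.any(np.diff(starts) < 0) or np.any(starts[1:] < ends[:-1]):
        raise ValueError("events must be sorted and non-overlapping")
    intervals = starts[1:] - ends[:-1]
    durations = ends - starts
    n_pulse = sum(e.kind == "pulse" for e in events)
    return EventSummary(
        intervals_s=intervals,
        durations_s=durations,
        percent_single=100.0 * n_pulse / len(events),
        n_events=len(events),
        n_pulse_kind=n_pulse,
        n_burst_kind=len(events) - n_pulse,
        too_few_for_intervals=len(events) < 2,
    )
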