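"""Single-neuron correlation networks.

Identifies functionally coupled neuron groups from single-ROI calcium
traces: Pearson correlation over the full record, significance against a
block-permutation null (each trace cut into contiguous blocks whose order
is independently reshuffled per ROI, z = (x - mu)/sigma over iterations),
hierarchical clustering with dendrogram leaf ordering, event-triggered
averages, and a rule-based CB / MR / unspecified classification:

* CB (contraction burst) neurons co-fire with the peduncle readout and
  their contraction-triggered average peaks at the contraction onset;
* MR (mechanically responsive) neurons show a stimulus-triggered average
  peaking ~10 s after valve onset, independent of the CB network;
* everything else is unspecified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats

from .errors import DegenerateInputError, UndefinedStatisticError
from .events import normalize_dff
from .trace_io import TraceSet

__all__ = [
    "BlockShuffleNull",
    "TriggeredAverage",
    "NeuronClassification",
    "correlation_matrix",
    "block_shuffle_null",
    "cluster_neurons",
    "triggered_average",
    "classify_neurons",
    "pixel_crosscorrelation_map",
]


def _dff_matrix(traces: TraceSet, normalization: str) -> np.ndarray:
    """Normalized dF/F per ROI.

    ``detrended_mean`` (the network default) subtracts a rolling
    10th-percentile baseline (60 s window) before dividing by the trace
    mean: photobleaching is a *shared* slow trend across ROIs, and under
    a plain global-mean convention it masquerades as network-wide
    correlation that the block-permutation null rightly flags as
    significant. ``global_mean`` and ``running_min`` apply the plain
    conventions.
    """
    if normalization in ("global_mean", "running_min"):
        return np.stack([normalize_dff(row, normalization) for row in traces.values])
    if normalization != "detrended_mean":
        raise ValueError(f"unknown normalization {normalization!r}")
    window = max(int(round(60.0 * traces.fps)), 1)
    out = np.empty_like(traces.values)
    for i, row in enumerate(traces.values):
        baseline = (
            pd.Series(row)
            .rolling(window, center=True, min_periods=1)
            .quantile(0.10)
            .to_numpy()
        )
        mean = float(np.mean(row))
        if mean <= 0:
            raise DegenerateInputError("non-positive mean fluorescence")
        out[i] = (row - baseline) / mean
    return out


def correlation_matrix(
    traces: TraceSet, normalization: str = "detrended_mean"
) -> tuple[np.ndarray, list[int]]:
    """Pairwise Pearson correlation of dF/F traces over the full record.

    Zero-variance ROIs get their row/column set to 0 (diagonal 1) and are
    returned in the flagged index list.
    """
    if traces.n_roi < 2:
        raise ValueError("need at least 2 ROIs for a correlation matrix")
    dff = _dff_matrix(traces, normalization)
    sd = dff.std(axis=1)
    flagged = [int(i) for i in np.flatnonzero(sd == 0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(dff)
    for i in flagged:
        corr[i, :] = 0.0
        corr[:, i] = 0.0
        corr[i, i] = 1.0
    return corr, flagged


def _block_bounds(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous near-equal blocks; the remainder goes to the final block."""
    base = n // n_blocks
    bounds = np.arange(n_blocks + 1) * base
    bounds[-1] = n
    return bounds


@dataclass
class BlockShuffleNull:
    """Permutation null for pairwise correlations."""

    mu: np.ndarray
    sigma: np.ndarray
    zscore: np.ndarray
    corr: np.ndarray
    n_blocks: int
    n_iter: int
    undefined_pairs: list[tuple[int, int]]


def shuffle_blocks(
    x: np.ndarray, n_blocks: int, rng: np.random.Generator
) -> np.ndarray:
    """Return the series with its contiguous blocks in permuted order."""
    bounds = _block_bounds(x.size, n_blocks)
    order = rng.permutation(n_blocks)
    return np.concatenate([x[bounds[b] : bounds[b + 1]] for b in order])


def block_shuffle_null(
    traces: TraceSet,
    n_blocks: int = 30,
    n_iter: int = 1000,
    seed: int | None = None,
    normalization: str = "detrended_mean",
) -> BlockShuffleNull:
    """Block-permutation significance of the correlation matrix.

    Each dF/F series is cut into ``n_blocks`` contiguous blocks; every
    iteration independently permutes the block order of each ROI (a
    permutation without replacement) and recomputes the correlation
    matrix. mu and sigma are the per-pair mean/SD over iterations and
    z = (x - mu)/sigma. Pairs with sigma = 0 are flagged undefined.
    """
    if traces.n_frames < n_blocks:
        raise ValueError("trace length must be at least n_blocks")
    dff = _dff_matrix(traces, normalization)
    r, n = dff.shape
    corr, _ = correlation_matrix(traces, normalization)
    rng = np.random.default_rng(seed)
    bounds = _block_bounds(n, n_blocks)
    blocks = [dff[:, bounds[b] : bounds[b + 1]] for b in range(n_blocks)]
    acc = np.zeros((r, r))
    acc2 = np.zeros((r, r))
    shuffled = np.empty_like(dff)
    for _ in range(n_iter):
        for i in range(r):
            order = rng.permutation(n_blocks)
            shuffled[i] = np.concatenate([blocks[b][i] for b in order])
        c = np.corrcoef(shuffled)
        acc += c
        acc2 += c * c
    mu = acc / n_iter
    var = np.maximum(acc2 / n_iter - mu * mu, 0.0) * n_iter / max(n_iter - 1, 1)
    sigma = np.sqrt(var)
    zscore = np.full_like(mu, np.nan)
    ok = sigma > 0
    zscore[ok] = (corr[ok] - mu[ok]) / sigma[ok]
    undefined = [
        (int(i), int(j))
        for i, j in zip(*np.nonzero(~ok))
        if i < j
    ]
    np.fill_diagonal(zscore, 0.0)
    return BlockShuffleNull(
        mu=mu,
        sigma=sigma,
        zscore=zscore,
        corr=corr,
        n_blocks=n_blocks,
        n_iter=n_iter,
        undefined_pairs=undefined,
    )


def cluster_neurons(
    corr: np.ndarray, k: int | None = None, method: str = "average"
) -> tuple[np.ndarray, np.ndarray | None]:
    """Agglomerative clustering on the rows of the correlation matrix.

    Euclidean distance between correlation-matrix rows; leaf order comes
    from the dendrogram; optional flat labels by cutting at ``k``
    clusters. Average linkage by default (single linkage, the historical
    default of the referenced routine, chains badly on correlated neural
    data; set ``method="single"`` to reproduce orderings built with it).
    """
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    n = corr.shape[0]
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds the number of ROIs ({n})")
    if n == 1:
        return np.array([0]), (np.array([1]) if k else None)
    linkage = sch.linkage(corr, method=method, metric="euclidean")
    leaf_order = np.asarray(sch.leaves_list(linkage))
    labels = None
    if k is not None:
        labels = sch.fcluster(linkage, t=k, criterion="maxclust")
    return leaf_order, labels


@dataclass
class TriggeredAverage:
    """Per-ROI mean dF/F around anchor events on a common relative grid."""

    rel_time_s: np.ndarray
    mean: np.ndarray  # (n_roi, n_grid)
    n_anchors_used: int
    n_anchors_dropped: int
    roi_labels: list[str]

    def peak_latency_s(self, roi: int, window: tuple[float, float] | None = None) -> float:
        """Relative time of the maximum of one ROI's average."""
        mask = (
            (self.rel_time_s >= window[0]) & (self.rel_time_s <= window[1])
            if window
            else np.ones_like(self.rel_time_s, dtype=bool)
        )
        idx = np.flatnonzero(mask)[np.argmax(self.mean[roi][mask])]
        return float(self.rel_time_s[idx])


def triggered_average(
    traces: TraceSet,
    anchors_s: np.ndarray,
    pre_s: float = 5.0,
    post_s: float = 15.0,
    normalization: str = "detrended_mean",
) -> TriggeredAverage:
    """Average dF/F in ``[anchor - pre_s, anchor + post_s]`` over anchors.

    Anchors whose window falls outside the record are dropped and
    counted; if all are dropped the statistic is undefined.
    """
    anchors = np.asarray(anchors_s, dtype=float)
    if anchors.size == 0:
        raise UndefinedStatisticError("no anchor events supplied")
    dff = _dff_matrix(traces, normalization)
    fps = traces.fps
    pre_f = int(round(pre_s * fps))
    post_f = int(round(post_s * fps))
    n = traces.n_frames
    windows = []
    dropped = 0
    for a in anchors:
        ai = int(round(a * fps))
        if ai - pre_f < 0 or ai + post_f >= n:
            dropped += 1
            continue
        windows.append(dff[:, ai - pre_f : ai + post_f + 1])
    if not windows:
        raise UndefinedStatisticError("all anchors fell outside the record")
    mean = np.mean(np.stack(windows), axis=0)
    rel = np.arange(-pre_f, post_f + 1) / fps
    return TriggeredAverage(
        rel_time_s=rel,
        mean=mean,
        n_anchors_used=len(windows),
        n_anchors_dropped=dropped,
        roi_labels=list(traces.roi_labels),
    )


@dataclass
class NeuronClassification:
    """CB / MR / unspecified assignment per ROI."""

    labels: list[str]
    stim_peak_latency_s: np.ndarray
    contraction_locked: np.ndarray
    roi_labels: list[str]


def _peak_height(
    avg: TriggeredAverage, roi: int, window: tuple[float, float]
) -> tuple[float, float]:
    """Peak height above the pre-anchor baseline mean, and the baseline SD.

    Referencing the height to the pre-anchor baseline makes the criterion
    insensitive to slow offsets in the normalized trace.
    """
    mask = (avg.rel_time_s >= window[0]) & (avg.rel_time_s <= window[1])
    peak = float(np.max(avg.mean[roi][mask]))
    pre = avg.mean[roi][avg.rel_time_s < 0]
    if pre.size < 2:
        return peak, 0.0
    return peak - float(pre.mean()), float(pre.std(ddof=1))


def classify_neurons(
    zscore: np.ndarray,
    peduncle_index: int,
    stim_triggered: TriggeredAverage,
    contraction_triggered: TriggeredAverage,
    z_cb: float = 3.0,
    mr_latency_window_s: tuple[float, float] = (5.0, 15.0),
    contraction_lock_s: float = 2.0,
    amplitude_floor: float = 0.05,
    baseline_k: float = 5.0,
    mr_hit_counts: np.ndarray | None = None,
    mr_n_trials: int | None = None,
    mr_null_probability: np.ndarray | None = None,
    mr_alpha: float = 0.01,
) -> NeuronClassification:
    """Assign CB / MR / unspecified labels to each neuron ROI.

    CB: permutation z-score against the peduncle readout >= ``z_cb`` AND
    the contraction-triggered average peaks within
    ``contraction_lock_s`` of contraction onset (the tolerance admits
    burst events whose averaged maximum sits on the second pulse).

    MR: not CB, the stimulus-triggered average peaks inside
    ``mr_latency_window_s``, and the response is stimulus-locked. When
    per-trial evidence is supplied (``mr_hit_counts`` = trials with a
    spike inside the latency window, out of ``mr_n_trials``, against the
    ROI's own spontaneous window probability ``mr_null_probability``),
    locking means a one-sided binomial test at ``mr_alpha`` — trial
    consistency separates genuine slow responses from spontaneous
    coincidences far better than average amplitude. Without it, the
    fallback requires the average's peak height above the pre-stimulus
    baseline to reach ``max(amplitude_floor, baseline_k * baseline SD)``.

    The peduncle ROI itself is labelled CB.
    """
    n = zscore.shape[0]
    use_trials = mr_hit_counts is not None and mr_n_trials is not None
    labels: list[str] = []
    latencies = np.full(n, np.nan)
    locked = np.zeros(n, dtype=bool)
    for i in range(n):
        lat = stim_triggered.peak_latency_s(i)
        latencies[i] = lat
        c_lat = contraction_triggered.peak_latency_s(i)
        locked[i] = abs(c_lat) <= contraction_lock_s
        if i == peduncle_index:
            labels.append("CB")
            continue
        if zscore[i, peduncle_index] >= z_cb and locked[i]:
            labels.append("CB")
            continue
        in_window = mr_latency_window_s[0] <= lat <= mr_latency_window_s[1]
        if use_trials:
            p0 = 0.5
            if mr_null_probability is not None:
                p0 = float(np.clip(mr_null_probability[i], 1e-6, 1.0 - 1e-6))
            test = scipy.stats.binomtest(
                int(mr_hit_counts[i]), int(mr_n_trials), p0, alternative="greater"
            )
            stim_locked = test.pvalue < mr_alpha
        else:
            height, base_sd = _peak_height(stim_triggered, i, mr_latency_window_s)
            stim_locked = height >= max(amplitude_floor, baseline_k * base_sd)
        if in_window and stim_locked:
            labels.append("MR")
        else:
            labels.append("unspecified")
    return NeuronClassification(
        labels=labels,
        stim_peak_latency_s=latencies,
        contraction_locked=locked,
        roi_labels=list(stim_triggered.roi_labels),
    )


def pixel_crosscorrelation_map(
    movie: np.ndarray,
    reference: np.ndarray,
    fps: float,
    grid: tuple[int, int] = (64, 64),
    max_lag_s: float = 0.05,
) -> np.ndarray:
    """Map of max cross-correlation between each pixel and a reference.

    Each frame is downsampled to ``grid`` by block averaging; every
    downsampled pixel's time series is Pearson-correlated with the
    reference at all integer-frame lags with |lag| <= ``max_lag_s``
    (boundary included), and the maximum is kept. Constant pixels map to
    0.
    """
    movie = np.asarray(movie, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, height, width)")
    if movie.shape[0] != ref.size:
        raise ValueError("movie and reference must have equal length")
    t, h, w = movie.shape
    gh, gw = grid
    if h % gh or w % gw:
        raise ValueError(f"frame size {h}x{w} not divisible by grid {gh}x{gw}")
    small = movie.reshape(t, gh, h // gh, gw, w // gw).mean(axis=(2, 4))
    x = small.reshape(t, gh * gw)
    max_lag = int(round(max_lag_s * fps))
    lags = range(-max_lag, max_lag + 1)
    best = np.full(gh * gw, -np.inf)
    const = x.std(axis=0) == 0
    for lag in lags:
        if lag >= 0:
            a, b = ref[: t - lag], x[lag:]
        else:
            a, b = ref[-lag:], x[: t + lag]
        if a.size < 2 or a.std() == 0:
            continue
        az = (a - a.mean()) / a.std()
        bs = b.std(axis=0)
        bz = (b - b.mean(axis=0)) / np.where(bs > 0, bs, 1.0)
        corr = (az[:, None] * bz).mean(axis=0)
        best = np.maximum(best, corr)
    best[const] = 0.0
    return best.reshape(gh, gw)
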