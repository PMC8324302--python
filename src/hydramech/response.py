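"""Stimulus-aligned response statistics.

The mechanosensory response probability is the fraction of stimulation
trials with at least one calcium spike inside the 1 s response window
following valve onset. Its spontaneous null is obtained by cutting an
unstimulated segment into 30 s pseudo-trials and sliding a 1 s window in
~0.3 s steps across them: the per-offset hit fractions form the null
distribution and their mean is the spontaneous contraction probability.
Paired condition comparisons report a paired t-test together with Cohen's
d (pooled SD) and Cliff's delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import UndefinedStatisticError
from .events import SpikeTrain
from .trace_io import StimulusProtocol

__all__ = [
    "Raster",
    "SpontaneousNull",
    "ComparisonResult",
    "build_raster",
    "response_probability",
    "response_latency",
    "spontaneous_probability_null",
    "cohens_d",
    "cliffs_delta",
    "compare_conditions",
    "psychometric_table",
]


@dataclass
class Raster:
    """Stimulus-aligned spike times: one row of relative times per trial.

    Windows are ``[onset - pre_s, onset + post_s)``; a spike may appear in
    several trials when the stimulation cycle is shorter than
    ``pre_s + post_s``.
    """

    trial_onsets_s: np.ndarray
    relative_spike_times: list[np.ndarray]
    pre_s: float = 15.0
    post_s: float = 15.0

    def __post_init__(self) -> None:
        self.trial_onsets_s = np.asarray(self.trial_onsets_s, dtype=float)
        if len(self.relative_spike_times) != self.trial_onsets_s.size:
            raise ValueError("one row of relative times required per trial")

    @property
    def n_trials(self) -> int:
        return int(self.trial_onsets_s.size)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (trial, rel_time_s)."""
        rows = [
            (i, t)
            for i, rel in enumerate(self.relative_spike_times)
            for t in rel
        ]
        return pd.DataFrame(rows, columns=["trial", "rel_time_s"])


def build_raster(
    spikes: SpikeTrain,
    protocol: StimulusProtocol,
    pre_s: float = 15.0,
    post_s: float = 15.0,
) -> Raster:
    """Align spike times to stimulus onsets.

    Each spike is assigned to every trial window it falls in. An empty
    spike train yields a raster with empty rows (a valid null recording).
    """
    if protocol.onsets_s.size == 0:
        raise UndefinedStatisticError("protocol has no stimulus onsets")
    if pre_s < 0 or post_s < 0:
        raise ValueError("pre_s and post_s must be non-negative")
    rows = []
    t = spikes.peak_times_s
    for onset in protocol.onsets_s:
        rel = t[(t >= onset - pre_s) & (t < onset + post_s)] - onset
        rows.append(rel)
    return Raster(
        trial_onsets_s=protocol.onsets_s,
        relative_spike_times=rows,
        pre_s=pre_s,
        post_s=post_s,
    )


def response_probability(raster: Raster, window_s: float = 1.0) -> float:
    """Fraction of trials with >= 1 spike in ``[0, window_s)`` after onset."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if raster.n_trials == 0:
        raise UndefinedStatisticError("cannot compute probability on 0 trials")
    hits = sum(
        bool(np.any((rel >= 0.0) & (rel < window_s)))
        for rel in raster.relative_spike_times
    )
    return hits / raster.n_trials


@dataclass
class SpontaneousNull:
    """Sliding-window null: hit fraction per window offset, and its mean."""

    offsets_s: np.ndarray
    probability_dist: np.ndarray
    mean: float
    n_pseudo_trials: int


def spontaneous_probability_null(
    spikes: SpikeTrain,
    segment: tuple[float, float],
    interval_s: float = 30.0,
    window_s: float = 1.0,
    step_s: float = 0.3,
) -> SpontaneousNull:
    """Spontaneous contraction probability from unstimulated activity.

    The segment is cut into consecutive ``interval_s``-long pseudo-trials.
    For each window offset w in {0, step_s, 2*step_s, ...} with
    ``w + window_s <= interval_s``, the fraction of pseudo-trials with at
    least one spike in ``[w, w + window_s)`` is recorded; the mean over
    offsets is the spontaneous probability.
    """
    t0, t1 = segment
    if t1 - t0 < interval_s:
        raise ValueError("segment shorter than one pseudo-trial interval")
    n_trials = int(np.floor((t1 - t0) / interval_s))
    if n_trials == 0:
        raise UndefinedStatisticError("zero pseudo-trials in segment")
    offsets = np.arange(0.0, interval_s - window_s + 1e-9, step_s)
    t = spikes.peak_times_s
    t = t[(t >= t0) & (t < t0 + n_trials * interval_s)]
    trial_idx = np.floor((t - t0) / interval_s).astype(int)
    phase = (t - t0) - trial_idx * interval_s
    dist = np.empty(offsets.size)
    for j, w in enumerate(offsets):
        hit = (phase >= w) & (phase < w + window_s)
        dist[j] = np.unique(trial_idx[hit]).size / n_trials
    return SpontaneousNull(
        offsets_s=offsets,
        probability_dist=dist,
        mean=float(dist.mean()),
        n_pseudo_trials=n_trials,
    )


def response_latency(
    raster: Raster, window_s: tuple[float, float] = (0.0, 15.0)
) -> float:
    """Median relative spike-peak time within a post-onset window.

    Pooling relative spike times across trials and taking the median makes
    the latency estimate robust to trial-to-trial jitter, unlike the peak
    of a triggered average, which is smeared (and its mode shifted) by the
    asymmetric calcium kernel. Returns NaN when no spikes fall in the
    window.
    """
    lo, hi = window_s
    rel = np.concatenate(
        [r[(r >= lo) & (r < hi)] for r in raster.relative_spike_times]
        or [np.array([])]
    )
    return float(np.median(rel)) if rel.size else float("nan")


# ---------------------------------------------------------------------------
# effect sizes and paired comparison


def cohens_d(x1: np.ndarray, x2: np.ndarray) -> float:
    """Two-sample Cohen's d with pooled SD (n-1 denominators).

    Returns 0 when both samples are constant and identical in mean,
    signed infinity when the means differ with zero pooled variance.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    diff = float(np.mean(x2) - np.mean(x1))
    pooled_var = (
        (n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1)
    ) / (n1 + n2 - 2)
    if pooled_var == 0:
        return 0.0 if diff == 0 else float(np.sign(diff)) * np.inf
    return diff / float(np.sqrt(pooled_var))


def cliffs_delta(x1: np.ndarray, x2: np.ndarray) -> float:
    """Cliff's delta over all cross pairs: P(x2 > x1) - P(x2 < x1)."""
    x1 = np.asarray(x1, dtype=float)[:, None]
    x2 = np.asarray(x2, dtype=float)[None, :]
    greater = np.count_nonzero(x2 > x1)
    less = np.count_nonzero(x2 < x1)
    return (greater - less) / (x1.size * x2.size)


@dataclass
class ComparisonResult:
    """Paired t-test plus effect sizes for two paired samples."""

    t_statistic: float
    p_value: float
    cohens_d: float
    cliffs_delta: float
    paired_dz: float
    n: int
    degenerate: bool  # zero variance in both samples


def compare_conditions(
    per_animal_spontaneous: np.ndarray, per_animal_stimulated: np.ndarray
) -> ComparisonResult:
    """Compare paired per-animal spontaneous vs stimulated probabilities.

    Cohen's d uses the two-sample pooled-SD form (the rank-based Cliff's
    delta reported beside it is likewise group-wise); the paired
    standardized mean difference dz is returned as well.
    """
    x1 = np.asarray(per_animal_spontaneous, dtype=float)
    x2 = np.asarray(per_animal_stimulated, dtype=float)
    if x1.size != x2.size:
        raise ValueError("paired samples must have equal length")
    if x1.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = x2 - x1
    sd_diff = float(np.std(diffs, ddof=1))
    if sd_diff == 0:
        t_stat, p = (0.0, 1.0) if np.all(diffs == 0) else (np.inf, 0.0)
        dz = 0.0 if np.all(diffs == 0) else float(np.sign(np.mean(diffs))) * np.inf
    else:
        t_stat, p = scipy.stats.ttest_rel(x2, x1)
        dz = float(np.mean(diffs)) / sd_diff
    degenerate = np.var(x1) == 0 and np.var(x2) == 0
    return ComparisonResult(
        t_statistic=float(t_stat),
        p_value=float(p),
        cohens_d=cohens_d(x1, x2),
        cliffs_delta=cliffs_delta(x1, x2),
        paired_dz=dz,
        n=int(x1.size),
        degenerate=degenerate,
    )


def psychometric_table(per_animal: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-animal statistics into a per-pressure table.

    ``per_animal`` has one row per (animal, pressure) with columns
    ``pressure_psi``, ``response_probability`` and optionally
    ``mean_interval_s`` and ``percent_single``. Returns mean and SEM per
    pressure (SEM is NaN for single-animal conditions, flagged via
    ``n_animals``).
    """
    required = {"pressure_psi", "response_probability"}
    missing = required - set(per_animal.columns)
    if missing:
        raise ValueError(f"per_animal table missing columns {sorted(missing)}")
    metrics = [
        c
        for c in ("response_probability", "mean_interval_s", "percent_single")
        if c in per_animal.columns
    ]
    rows = []
    for pressure, grp in per_animal.groupby("pressure_psi"):
        row: dict[str, float] = {
            "pressure_psi": pressure,
            "n_animals": len(grp),
        }
        for m in metrics:
            vals = grp[m].to_numpy(dtype=float)
            row[f"{m}_mean"] = float(np.mean(vals))
            row[f"{m}_sem"] = (
                float(np.std(vals, ddof=1) / np.sqrt(vals.size))
                if vals.size > 1
                else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("pressure_psi").reset_index(drop=True)
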