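"""Tissue displacement and body-shape measurements.

Quantifies how far the mechanical stimulus reaches through the tissue:
per-frame displacement of tracked neurons, a baseline vs valve-transition
comparison, and the radial decay profile (mean of the top-3 stimulus-frame
displacements in 50 um bands from the valve center). Also measures body
length from a fluorescence frame as the major axis of a moment-matched
ellipse on the largest binarized component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import skimage.filters
import skimage.measure
import skimage.morphology

from .errors import DegenerateInputError, UndefinedStatisticError
from .trace_io import StimulusProtocol

log = logging.getLogger(__name__)

__all__ = [
    "NeuronTrackTable",
    "DisplacementStats",
    "DisplacementProfile",
    "frame_displacements",
    "stimulus_displacement_stats",
    "radial_band_profile",
    "body_length",
]

TRACK_COLUMNS = ("frame", "neuron_id", "x_um", "y_um")


@dataclass
class NeuronTrackTable:
    """Per-neuron positions over frames, plus valve geometry.

    ``table`` is long-format with columns frame, neuron_id, x_um, y_um;
    each (neuron_id, frame) appears at most once.
    """

    table: pd.DataFrame
    frame_period_s: float
    valve_center_um: tuple[float, float] | None = None
    valve_radius_um: float = 200.0

    def __post_init__(self) -> None:
        missing = set(TRACK_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"track table missing columns {sorted(missing)}")
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be positive")
        if self.table.duplicated(subset=["frame", "neuron_id"]).any():
            raise ValueError("duplicate (neuron_id, frame) entries")
        if not np.all(np.isfinite(self.table[["x_um", "y_um"]].to_numpy())):
            raise ValueError("coordinates must be finite")

    @property
    def fps(self) -> float:
        return 1.0 / self.frame_period_s

    def to_csv(self, path) -> None:
        self.table[list(TRACK_COLUMNS)].to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path,
        frame_period_s: float,
        valve_center_um: tuple[float, float] | None = None,
        valve_radius_um: float = 200.0,
    ) -> "NeuronTrackTable":
        return cls(
            table=pd.read_csv(path),
            frame_period_s=frame_period_s,
            valve_center_um=valve_center_um,
            valve_radius_um=valve_radius_um,
        )


def frame_displacements(tracks: NeuronTrackTable) -> pd.DataFrame:
    """Euclidean displacement of each neuron between consecutive frames.

    Missing frames produce gaps (no interpolation): a displacement at
    frame f exists only if the neuron was also present at frame f-1.
    Neurons present in a single frame are excluded and logged. Returns a
    table (neuron_id, frame, displacement_um).
    """
    out = []
    for nid, grp in tracks.table.sort_values("frame").groupby("neuron_id"):
        frames = grp["frame"].to_numpy()
        if frames.size < 2:
            log.info("neuron %s has a single frame; excluded", nid)
            continue
        xy = grp[["x_um", "y_um"]].to_numpy()
        consecutive = np.diff(frames) == 1
        disp = np.hypot(*(np.diff(xy, axis=0).T))
        out.append(
            pd.DataFrame(
                {
                    "neuron_id": nid,
                    "frame": frames[1:][consecutive],
                    "displacement_um": disp[consecutive],
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["neuron_id", "frame", "displacement_um"])
    return pd.concat(out, ignore_index=True)


@dataclass
class DisplacementStats:
    """Baseline vs valve-transition displacement comparison."""

    baseline_mean_um: float
    evoked_on_mean_um: float
    evoked_off_mean_um: float
    evoked_mean_um: float
    p_value: float
    n_baseline: int
    n_evoked: int


def _transition_frames(
    protocol: StimulusProtocol, fps: float
) -> tuple[np.ndarray, np.ndarray]:
    on = np.round(protocol.onsets_s * fps).astype(int)
    off = np.round(protocol.offsets_s() * fps).astype(int)
    return on, off


def stimulus_displacement_stats(
    displacements: pd.DataFrame,
    protocol: StimulusProtocol,
    fps: float,
) -> DisplacementStats:
    """Compare displacements on valve-transition frames with baseline.

    Evoked = displacements on the frames immediately after valve
    pressurization and after depressurization (both reported separately
    and pooled); baseline = all remaining valve-off frames. Significance
    via a two-sided rank-sum test.
    """
    if protocol.onsets_s.size == 0:
        raise UndefinedStatisticError("protocol has no valve-on transitions")
    on_f, off_f = _transition_frames(protocol, fps)
    frames = displacements["frame"].to_numpy()
    d = displacements["displacement_um"].to_numpy()
    is_on = np.isin(frames, on_f)
    is_off = np.isin(frames, off_f)
    valve_high = np.zeros(frames.max() + 1 if frames.size else 1, dtype=bool)
    for a, b in zip(on_f, off_f):
        valve_high[a : min(b + 1, valve_high.size)] = True
    in_high = valve_high[np.clip(frames, 0, valve_high.size - 1)]
    baseline_mask = ~(is_on | is_off | in_high)
    evoked_mask = is_on | is_off
    if not evoked_mask.any():
        raise UndefinedStatisticError("no displacements on valve-transition frames")
    baseline = d[baseline_mask]
    evoked = d[evoked_mask]
    if baseline.size and (np.ptp(baseline) > 0 or np.ptp(evoked) > 0):
        p = float(scipy.stats.ranksums(evoked, baseline).pvalue)
    else:
        p = 1.0 if np.mean(evoked) == np.mean(baseline) else 0.0
    return DisplacementStats(
        baseline_mean_um=float(baseline.mean()) if baseline.size else np.nan,
        evoked_on_mean_um=float(d[is_on].mean()) if is_on.any() else np.nan,
        evoked_off_mean_um=float(d[is_off].mean()) if is_off.any() else np.nan,
        evoked_mean_um=float(evoked.mean()),
        p_value=p,
        n_baseline=int(baseline.size),
        n_evoked=int(evoked.size),
    )


@dataclass
class DisplacementProfile:
    """Top-k mean displacement in half-open radial bands [r, r + band)."""

    band_edges_um: np.ndarray  # length n_bands + 1
    topk_mean_um: np.ndarray  # NaN for empty bands
    n_per_band: np.ndarray
    top_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band_lo_um": self.band_edges_um[:-1],
                "band_hi_um": self.band_edges_um[1:],
                "topk_mean_um": self.topk_mean_um,
                "n": self.n_per_band,
            }
        )


def radial_band_profile(
    tracks: NeuronTrackTable,
    displacements: pd.DataFrame,
    stim_frames: np.ndarray,
    band_um: float = 50.0,
    top_k: int = 3,
    reference_frame: int | None = None,
) -> DisplacementProfile:
    """Radial decay of stimulus-frame displacement around the valve.

    Neurons are binned by their distance to the valve center at the
    pre-stimulus reference frame (default: the frame before the first
    stimulus frame). Per 50 um band, the mean of the ``top_k`` largest
    stimulus-frame displacements is reported (all values when a band
    holds fewer than ``top_k``); empty bands are NaN.
    """
    if tracks.valve_center_um is None:
        raise ValueError("track table has no valve center")
    stim_frames = np.asarray(stim_frames, dtype=int)
    if stim_frames.size == 0:
        raise ValueError("need at least one stimulus frame")
    ref = (
        int(reference_frame)
        if reference_frame is not None
        else int(stim_frames.min()) - 1
    )
    first_frame = int(tracks.table["frame"].min())
    if ref < first_frame:
        log.info("reference frame %d precedes the record; using %d", ref, first_frame)
        ref = first_frame
    pos = tracks.table[tracks.table["frame"] == ref]
    if pos.empty:
        raise ValueError(f"no positions at reference frame {ref}")
    cx, cy = tracks.valve_center_um
    radii = pd.Series(
        np.hypot(pos["x_um"] - cx, pos["y_um"] - cy).to_numpy(),
        index=pos["neuron_id"].to_numpy(),
    )
    stim_disp = displacements[displacements["frame"].isin(stim_frames)]
    r_of = stim_disp["neuron_id"].map(radii)
    keep = r_of.notna()
    stim_disp = stim_disp[keep]
    r_of = r_of[keep].to_numpy()
    n_bands = int(np.ceil((radii.max() + 1e-9) / band_um)) if len(radii) else 1
    edges = np.arange(n_bands + 1) * band_um
    band_idx = np.minimum((r_of // band_um).astype(int), n_bands - 1)
    topk = np.full(n_bands, np.nan)
    counts = np.zeros(n_bands, dtype=int)
    d = stim_disp["displacement_um"].to_numpy()
    for b in range(n_bands):
        vals = d[band_idx == b]
        counts[b] = vals.size
        if vals.size:
            top = np.sort(vals)[-top_k:]
            topk[b] = float(top.mean())
    return DisplacementProfile(
        band_edges_um=edges, topk_mean_um=topk, n_per_band=counts, top_k=top_k
    )


def body_length(
    frame: np.ndarray,
    threshold_method: str = "otsu",
    closing_radius_px: int = 2,
    um_per_px: float | None = None,
) -> float:
    """Body length as the major axis of an ellipse fit to the body mask.

    The frame is binarized (Otsu), closed with a small disk, the largest
    connected component kept, and the major-axis length of the
    moment-matched ellipse returned (px, or um when a scale is given).
    """
    img = np.asarray(frame, dtype=float)
    if img.size == 0:
        raise DegenerateInputError("empty image")
    if threshold_method != "otsu":
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    if np.ptp(img) == 0:
        raise DegenerateInputError("constant image: binarization yields no mask")
    mask = img > skimage.filters.threshold_otsu(img)
    if closing_radius_px > 0:
        mask = skimage.morphology.closing(
            mask, skimage.morphology.disk(closing_radius_px)
        )
    if not mask.any():
        raise DegenerateInputError("binarization yields an empty mask")
    labels = skimage.measure.label(mask)
    props = skimage.measure.regionprops(labels)
    largest = max(props, key=lambda p: p.area)
    length = float(largest.axis_major_length)
    return length * um_per_px if um_per_px is not None else length
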