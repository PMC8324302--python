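"""Trace containers and file I/O.

The analysis operates on two in-memory objects: :class:`TraceSet`, a
(ROI x frame) matrix of raw fluorescence with timing metadata, and
:class:`StimulusProtocol`, the valve on/off schedule that defines trials.
This module reads and writes the standard containers the pipeline touches
(MAT source-data structs, CSV trace tables, HDF5) and reconstructs timing
from per-frame 0/1 stimulation traces.

Conventions: frames are 0-based, times are in seconds, windows are
half-open ``[a, b)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.io

from .errors import CannotInferError, IntegrityError, SchemaError

log = logging.getLogger(__name__)

#: stimulation cycle (valve on 1 s + off 30 s) used to infer the frame rate
#: of containers that carry no timestamps
DEFAULT_CYCLE_S = 31.0

__all__ = [
    "TraceSet",
    "StimulusProtocol",
    "Record",
    "onsets_from_frame_trace",
    "infer_fps",
    "read_source_container",
    "write_trace_csv",
    "read_trace_csv",
    "write_hdf5",
    "read_hdf5",
]


@dataclass
class StimulusProtocol:
    """Valve on/off schedule with pressure.

    Parameters
    ----------
    onsets_s : array of float
        Valve-on (rising edge) times in seconds, sorted.
    on_s : float
        Valve-on duration per trial, seconds.
    pressure_psi : float
        Valve pressure during 'on' periods.
    frame_trace : array of {0,1}, optional
        Per-frame valve state, if the protocol has been rendered on a
        frame grid.
    fps : float, optional
        Frame rate of ``frame_trace``.
    """

    onsets_s: np.ndarray
    on_s: float
    pressure_psi: float = 0.0
    frame_trace: np.ndarray | None = None
    fps: float | None = None

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.on_s <= 0:
            raise ValueError(f"on_s must be positive, got {self.on_s}")
        if self.onsets_s.ndim != 1:
            raise ValueError("onsets_s must be one-dimensional")
        if np.any(np.diff(self.onsets_s) < self.on_s):
            raise ValueError("onsets must be sorted with spacing >= on_s")
        if self.frame_trace is not None:
            self.frame_trace = np.asarray(self.frame_trace)
            bad = set(np.unique(self.frame_trace)) - {0, 1}
            if bad:
                raise ValueError(f"frame_trace values must be 0/1, got {bad}")

    @property
    def n_trials(self) -> int:
        return int(self.onsets_s.size)

    def offsets_s(self) -> np.ndarray:
        """Valve-off (depressurization) times, seconds."""
        return self.onsets_s + self.on_s


@dataclass
class TraceSet:
    """Multi-ROI raw fluorescence time series.

    ``values`` is (n_roi, n_frames); ``roi_labels`` names each row
    (e.g. ``"peduncle"``, ``"whole_frame"``, ``"neuron_03"``).
    """

    values: np.ndarray
    fps: float
    time_s: np.ndarray | None = None
    roi_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        n = self.values.shape[1]
        if self.time_s is None:
            self.time_s = np.arange(n) / self.fps
        else:
            self.time_s = np.asarray(self.time_s, dtype=float)
            if self.time_s.size != n:
                raise IntegrityError(
                    f"time_s has {self.time_s.size} samples, values have {n}"
                )
            if np.any(np.diff(self.time_s) <= 0):
                raise ValueError("time_s must be strictly increasing")
            med = float(np.median(np.diff(self.time_s)))
            if n > 1 and abs(med - 1.0 / self.fps) > 0.05 / self.fps:
                raise IntegrityError(
                    f"fps={self.fps} inconsistent with median frame "
                    f"spacing {med:.6g} s"
                )
        if self.roi_labels is None:
            self.roi_labels = [f"roi_{i:02d}" for i in range(self.values.shape[0])]
        else:
            self.roi_labels = list(self.roi_labels)
            if len(self.roi_labels) != self.values.shape[0]:
                raise IntegrityError("one label required per ROI row")
            if len(set(self.roi_labels)) != len(self.roi_labels):
                raise ValueError("roi_labels must be unique")

    @property
    def n_roi(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def roi(self, label: str) -> np.ndarray:
        """Return the raw trace of one labelled ROI."""
        try:
            idx = self.roi_labels.index(label)
        except ValueError:
            raise KeyError(f"no ROI labelled {label!r}") from None
        return self.values[idx]


@dataclass
class Record:
    """One trial row from a source container: traces + protocol + label."""

    traces: TraceSet
    protocol: StimulusProtocol | None
    condition: str
    tracks: "pd.DataFrame | None" = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# timing reconstruction


def onsets_from_frame_trace(
    frame_trace: np.ndarray, time_s: np.ndarray
) -> tuple[np.ndarray, float]:
    """Recover stimulus onsets from a per-frame 0/1 valve trace.

    An onset is the first frame of each run of 1s (rising edge); the
    on-duration is the median run length of 1s times the frame period.
    An all-zero trace is a valid unstimulated control and returns an
    empty onset list with on-duration 0.
    """
    x = np.asarray(frame_trace).astype(int)
    bad = set(np.unique(x)) - {0, 1}
    if bad:
        raise ValueError(f"frame_trace values must be 0/1, got {bad}")
    time_s = np.asarray(time_s, dtype=float)
    if x.size != time_s.size:
        raise IntegrityError("frame_trace and time_s lengths differ")
    if not x.any():
        return np.array([]), 0.0
    padded = np.concatenate([[0], x, [0]])
    rises = np.flatnonzero(np.diff(padded) == 1)  # index of first 1-frame
    falls = np.flatnonzero(np.diff(padded) == -1)  # index one past last 1
    run_lengths = falls - rises
    period = float(np.median(np.diff(time_s))) if x.size > 1 else 0.0
    on_s = float(np.median(run_lengths)) * period
    return time_s[rises], on_s


def infer_fps(
    n_frames: int,
    frame_trace: np.ndarray | None,
    nominal_cycle_s: float = DEFAULT_CYCLE_S,
    fallback_fps: float | None = None,
) -> float:
    """Infer frames/second from the stimulation cycle.

    Deposited containers carry no explicit frame rate; the valve cycle
    (nominally 31 s) is the only clock they embed, so
    ``fps = median inter-onset frame gap / nominal_cycle_s``. Unstimulated
    traces fall back to ``fallback_fps``.
    """
    if frame_trace is not None:
        x = np.asarray(frame_trace).astype(int)
        padded = np.concatenate([[0], x, [0]])
        rises = np.flatnonzero(np.diff(padded) == 1)
        if rises.size >= 2:
            gap = float(np.median(np.diff(rises)))
            return gap / nominal_cycle_s
    if fallback_fps is not None:
        return float(fallback_fps)
    raise CannotInferError(
        "fewer than 2 stimulus edges and no fallback fps supplied"
    )


# ---------------------------------------------------------------------------
# non-finite repair


def repair_nonfinite(values: np.ndarray, max_run: int = 5) -> np.ndarray:
    """Linearly interpolate short runs of non-finite samples.

    Runs longer than ``max_run`` frames raise :class:`IntegrityError`
    (callers reject the trial with a logged reason).
    """
    x = np.asarray(values, dtype=float).copy()
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    padded = np.concatenate([[False], bad, [False]])
    starts = np.flatnonzero(np.diff(padded.astype(int)) == 1)
    ends = np.flatnonzero(np.diff(padded.astype(int)) == -1)
    if int(np.max(ends - starts)) > max_run:
        raise IntegrityError(
            f"non-finite run of {int(np.max(ends - starts))} frames exceeds "
            f"repair limit of {max_run}"
        )
    idx = np.arange(x.size)
    x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x


# ---------------------------------------------------------------------------
# MAT source containers

_FIG23_FIELDS = ("StimCondition", "RawFluorescenceFoot", "StimulationTrace")
_FIG4_FIELDS = (
    "NeuronROI_RawFluorAllFrames",
    "ROI_xLocAllFrames",
    "ROI_yLocAllFrames",
)


def _is_hdf5(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(8) == b"\x89HDF\r\n\x1a\n"


def _mat_rows_v5(path: Path, varname: str) -> list[dict]:
    mat = scipy.io.loadmat(path, squeeze_me=False, struct_as_record=True)
    if varname not in mat:
        raise SchemaError(f"variable {varname!r} not found in {path}")
    arr = mat[varname]
    rows = []
    for rec in arr.ravel():
        rows.append({name: rec[name] for name in arr.dtype.names or ()})
    return rows


def _deref(h5: h5py.File, obj):
    if isinstance(obj, h5py.Reference):
        return np.asarray(h5[obj])
    return np.asarray(obj)


def _mat_rows_v73(path: Path, varname: str) -> list[dict]:
    rows: list[dict] = []
    with h5py.File(path, "r") as h5:
        if varname not in h5:
            raise SchemaError(f"variable {varname!r} not found in {path}")
        grp = h5[varname]
        names = list(grp.keys())
        n = None
        cols = {}
        for name in names:
            ds = np.asarray(grp[name])
            refs = ds.ravel()
            cols[name] = [_deref(h5, r) for r in refs]
            n = len(cols[name]) if n is None else n
        for i in range(n or 0):
            rows.append({name: cols[name][i] for name in names})
    return rows


def _scalar_label(value) -> str:
    """Render a MAT StimCondition cell (string or number) as a label."""
    arr = np.asarray(value)
    if arr.dtype.kind in "US":
        return str(arr.ravel()[0])
    if arr.dtype.kind == "u" and arr.ndim == 2 and arr.shape[0] > 1:
        # v7.3 stores char arrays as uint16 column vectors
        return "".join(chr(int(c)) for c in arr.ravel())
    flat = arr.ravel()
    if flat.size == 1:
        v = flat[0]
        return str(int(v)) if float(v) == int(v) else str(float(v))
    return str(value)


def read_source_container(
    path: str | Path,
    figure_schema: str,
    fallback_fps: float | None = None,
    nominal_cycle_s: float = DEFAULT_CYCLE_S,
) -> list[Record]:
    """Read a deposited source-data container into analysis records.

    ``figure_schema`` selects the layout: ``"fig2"``/``"fig3"`` expect a
    struct ``HydraData`` with one trial per row and fields
    ``StimCondition``, ``RawFluorescenceFoot``, ``StimulationTrace``;
    ``"fig4"`` expects per-neuron matrices
    ``NeuronROI_RawFluorAllFrames`` (last row = peduncle ROI average),
    ``ROI_xLocAllFrames`` and ``ROI_yLocAllFrames``.

    Returns one :class:`Record` per trial. Trials whose fluorescence
    cannot be repaired (non-finite runs > 5 frames) are dropped with a
    logged reason.
    """
    path = Path(path)
    if figure_schema not in {"fig2", "fig3", "fig4"}:
        raise ValueError(f"unknown figure_schema {figure_schema!r}")
    if figure_schema == "fig4":
        return _read_fig4(path, fallback_fps)

    reader = _mat_rows_v73 if _is_hdf5(path) else _mat_rows_v5
    rows = reader(path, "HydraData")
    records: list[Record] = []
    for i, row in enumerate(rows):
        for name in _FIG23_FIELDS:
            if name not in row:
                raise SchemaError(
                    f"trial {i}: required field {name!r} missing from "
                    f"{figure_schema} schema"
                )
        fluor = np.asarray(row["RawFluorescenceFoot"], dtype=float).ravel()
        stim = np.asarray(row["StimulationTrace"]).ravel()
        if fluor.size != stim.size:
            raise IntegrityError(
                f"trial {i}: fluorescence has {fluor.size} frames but "
                f"stimulation trace has {stim.size}"
            )
        try:
            fluor = repair_nonfinite(fluor)
        except IntegrityError as err:
            log.warning("trial %d rejected: %s", i, err)
            continue
        fps = infer_fps(fluor.size, stim, nominal_cycle_s, fallback_fps)
        time_s = np.arange(fluor.size) / fps
        onsets, on_s = onsets_from_frame_trace(stim, time_s)
        condition = _scalar_label(row["StimCondition"])
        try:
            pressure = float(condition)
        except ValueError:
            pressure = 0.0
        protocol = None
        if onsets.size:
            protocol = StimulusProtocol(
                onsets_s=onsets,
                on_s=on_s if on_s > 0 else 1.0,
                pressure_psi=pressure,
                frame_trace=stim.astype(int),
                fps=fps,
            )
        traces = TraceSet(
            values=fluor[None, :],
            fps=fps,
            roi_labels=["peduncle" if figure_schema == "fig2" else "whole_frame"],
        )
        records.append(Record(traces=traces, protocol=protocol, condition=condition))
    return records


def _read_fig4(path: Path, fallback_fps: float | None) -> list[Record]:
    if _is_hdf5(path):
        with h5py.File(path, "r") as h5:
            data = {}
            for name in _FIG4_FIELDS:
                if name not in h5:
                    raise SchemaError(f"required field {name!r} missing from fig4 schema")
                # MATLAB v7.3 stores column-major; transpose back
                data[name] = np.asarray(h5[name]).T
    else:
        mat = scipy.io.loadmat(path)
        data = {}
        for name in _FIG4_FIELDS:
            if name not in mat:
                raise SchemaError(f"required field {name!r} missing from fig4 schema")
            data[name] = np.asarray(mat[name], dtype=float)
    fluor = data["NeuronROI_RawFluorAllFrames"]
    xs = data["ROI_xLocAllFrames"]
    ys = data["ROI_yLocAllFrames"]
    n_neurons = fluor.shape[0] - 1  # last row is the peduncle ROI average
    if xs.shape[0] != n_neurons or ys.shape[0] != n_neurons:
        raise IntegrityError(
            f"position matrices cover {xs.shape[0]} neurons but fluorescence "
            f"has {n_neurons} neuron rows"
        )
    if xs.shape[1] != fluor.shape[1]:
        raise IntegrityError("position and fluorescence frame counts differ")
    fps = fallback_fps if fallback_fps is not None else 16.0
    labels = [f"neuron_{i:02d}" for i in range(n_neurons)] + ["peduncle"]
    values = np.stack([repair_nonfinite(r) for r in fluor])
    traces = TraceSet(values=values, fps=fps, roi_labels=labels)
    frames = np.arange(fluor.shape[1])
    tracks = pd.DataFrame(
        {
            "frame": np.tile(frames, n_neurons),
            "neuron_id": np.repeat(np.arange(n_neurons), frames.size),
            "x_um": xs.ravel(),
            "y_um": ys.ravel(),
        }
    )
    return [Record(traces=traces, protocol=None, condition=path.stem, tracks=tracks)]


# ---------------------------------------------------------------------------
# CSV / HDF5 round trip


def write_trace_csv(
    path: str | Path, traces: TraceSet, protocol: StimulusProtocol | None = None
) -> None:
    """Write a trace table: columns ``time_s, stim, roi_<label>``."""
    stim = np.zeros(traces.n_frames, dtype=int)
    if protocol is not None and protocol.frame_trace is not None:
        ft = np.asarray(protocol.frame_trace, dtype=int)
        if ft.size != traces.n_frames:
            raise IntegrityError("protocol frame_trace length differs from traces")
        stim = ft
    cols = {"time_s": traces.time_s, "stim": stim}
    for label, row in zip(traces.roi_labels, traces.values):
        cols[f"roi_{label}"] = row
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> tuple[TraceSet, StimulusProtocol | None]:
    df = pd.read_csv(path)
    for required in ("time_s", "stim"):
        if required not in df.columns:
            raise SchemaError(f"trace CSV missing column {required!r}")
    roi_cols = [c for c in df.columns if c.startswith("roi_")]
    if not roi_cols:
        raise SchemaError("trace CSV has no roi_* columns")
    time_s = df["time_s"].to_numpy()
    fps = 1.0 / float(np.median(np.diff(time_s)))
    traces = TraceSet(
        values=df[roi_cols].to_numpy().T,
        fps=fps,
        time_s=time_s,
        roi_labels=[c[len("roi_") :] for c in roi_cols],
    )
    stim = df["stim"].to_numpy().astype(int)
    protocol = None
    if stim.any():
        onsets, on_s = onsets_from_frame_trace(stim, time_s)
        protocol = StimulusProtocol(
            onsets_s=onsets, on_s=max(on_s, 1.0 / fps), frame_trace=stim, fps=fps
        )
    return traces, protocol


def write_hdf5(
    path: str | Path,
    traces: TraceSet,
    protocol: StimulusProtocol | None = None,
    tracks: pd.DataFrame | None = None,
) -> None:
    """Write traces (+ optional protocol, tracks) to HDF5 groups
    ``/traces``, ``/protocol``, ``/tracks``."""
    with h5py.File(path, "w") as h5:
        g = h5.create_group("traces")
        g.create_dataset("values", data=traces.values)
        g.create_dataset("time_s", data=traces.time_s)
        g.create_dataset(
            "roi_labels",
            data=np.array(traces.roi_labels, dtype=h5py.string_dtype()),
        )
        g.attrs["fps"] = traces.fps
        if protocol is not None:
            p = h5.create_group("protocol")
            p.create_dataset("onsets_s", data=protocol.onsets_s)
            p.attrs["on_s"] = protocol.on_s
            p.attrs["pressure_psi"] = protocol.pressure_psi
            if protocol.frame_trace is not None:
                p.create_dataset("frame_trace", data=protocol.frame_trace)
            if protocol.fps is not None:
                p.attrs["fps"] = protocol.fps
        if tracks is not None:
            t = h5.create_group("tracks")
            for col in ("frame", "neuron_id", "x_um", "y_um"):
                t.create_dataset(col, data=tracks[col].to_numpy())


def read_hdf5(
    path: str | Path,
) -> tuple[TraceSet, StimulusProtocol | None, pd.DataFrame | None]:
    with h5py.File(path, "r") as h5:
        if "traces" not in h5:
            raise SchemaError("HDF5 file has no /traces group")
        g = h5["traces"]
        traces = TraceSet(
            values=np.asarray(g["values"]),
            fps=float(g.attrs["fps"]),
            time_s=np.asarray(g["time_s"]),
            roi_labels=[s.decode() if isinstance(s, bytes) else str(s) for s in g["roi_labels"]],
        )
        protocol = None
        if "protocol" in h5:
            p = h5["protocol"]
            protocol = StimulusProtocol(
                onsets_s=np.asarray(p["onsets_s"]),
                on_s=float(p.attrs["on_s"]),
                pressure_psi=float(p.attrs["pressure_psi"]),
                frame_trace=np.asarray(p["frame_trace"]) if "frame_trace" in p else None,
                fps=float(p.attrs["fps"]) if "fps" in p.attrs else None,
            )
        tracks = None
        if "tracks" in h5:
            t = h5["tracks"]
            tracks = pd.DataFrame({c: np.asarray(t[c]) for c in ("frame", "neuron_id", "x_um", "y_um")})
    return traces, protocol, tracks
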