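"""Shared data model and on-disk formats.

All stages of the pipeline exchange a handful of containers: uniformly
sampled signals (:class:`TimeSeries`), sorted spike-event tables
(:class:`SpikeSet`), ROI x frame fluorescence matrices
(:class:`TraceMatrix`), labeled ROI maps (:class:`RoiSet`), overlapping
scoring epochs (:class:`EpochSet`) and longitudinal spine presence tables
(:class:`PresenceTable`).

Conventions: time in seconds, frequency in Hz, distances in micrometers;
frame and sample indices are 0-based; epochs are half-open ``[start, end)``.
Tables are comma-delimited text with a header row, signals are flat float64
binary with a JSON sidecar, label masks are 16-bit TIFF.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger("statekit")

STATE_LABELS = ("wake", "NREM", "REM", "uncertain")

EPOCH_LEN = 30.0  #: epoch length (s)
EPOCH_STEP = 15.0  #: epoch start spacing (s); 50% overlap


class FormatError(ValueError):
    """Malformed or incomplete on-disk input (e.g. missing JSON sidecar)."""


class ValidationError(ValueError):
    """In-memory object violates a container invariant."""


def _interp_nan(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).copy()
    bad = ~np.isfinite(x)
    if bad.all():
        raise ValidationError("signal is entirely NaN")
    if bad.any():
        idx = np.arange(x.size)
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x


@dataclass
class TimeSeries:
    """Uniformly sampled signal (LFP, EMG, population rate, pupil trace)."""

    samples: np.ndarray
    fs: float
    units: str = "a.u."
    t0: float = 0.0
    channel: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("samples must be a non-empty 1-D vector")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        if not np.isfinite(self.samples).all():
            raise ValidationError("NaN/inf in samples; load with interpolate_nan=True")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class SpikeSet:
    """Per-unit sorted spike times over a recording of length ``duration``."""

    units: dict[str, np.ndarray]
    duration: float

    def __post_init__(self):
        if not self.duration > 0:
            raise ValidationError("duration must be positive")
        clean = {}
        for uid, t in self.units.items():
            t = np.asarray(t, dtype=float)
            if t.size and (np.any(np.diff(t) <= 0)):
                raise ValidationError(f"unit {uid}: spike times not strictly increasing")
            if t.size and (t[0] < 0 or t[-1] > self.duration):
                raise ValidationError(f"unit {uid}: spike times outside [0, duration]")
            clean[str(uid)] = t
        self.units = clean

    @property
    def n_units(self) -> int:
        return len(self.units)

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.units.values()))


@dataclass
class TraceMatrix:
    """ROI x frame fluorescence with matched neuropil (and optional
    deconvolved) channels."""

    F: np.ndarray
    Fneu: np.ndarray
    fs: float
    roi_ids: list[str] = field(default_factory=list)
    S: np.ndarray | None = None

    def __post_init__(self):
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        self.Fneu = np.atleast_2d(np.asarray(self.Fneu, dtype=float))
        if self.F.shape != self.Fneu.shape:
            raise ValidationError(
                f"F {self.F.shape} and Fneu {self.Fneu.shape} must have the same shape"
            )
        if self.S is not None:
            self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
            if self.S.shape != self.F.shape:
                raise ValidationError("S must match F shape")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        if not self.roi_ids:
            self.roi_ids = [f"roi{i}" for i in range(self.F.shape[0])]
        self.roi_ids = [str(r) for r in self.roi_ids]
        if len(self.roi_ids) != self.F.shape[0]:
            raise ValidationError("roi_ids length must equal number of rows")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValidationError("roi_ids must be unique")

    @property
    def n_rois(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]


@dataclass
class RoiSet:
    """Labeled ROI map tied to a session image.

    ``mask`` is a 2-D integer label image (0 = background); ``centroids``
    maps label -> (x, y) in micrometers and always equals the pixel-set
    centroid scaled by ``px_size``.
    """

    mask: np.ndarray
    px_size: float
    image: np.ndarray | None = None
    enhanced_image: np.ndarray | None = None
    centroids: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ValidationError("mask must be 2-D")
        if not self.px_size > 0:
            raise ValidationError("px_size must be positive")
        labels = np.unique(self.mask)
        labels = labels[labels > 0]
        self._labels = [int(l) for l in labels]
        computed = {}
        for l in self._labels:
            ys, xs = np.nonzero(self.mask == l)
            computed[l] = (float(xs.mean() * self.px_size), float(ys.mean() * self.px_size))
        if self.centroids:
            for l, (cx, cy) in computed.items():
                gx, gy = self.centroids.get(l, (np.nan, np.nan))
                if abs(gx - cx) > 1e-6 or abs(gy - cy) > 1e-6:
                    raise ValidationError(
                        f"centroid of ROI {l} does not match its pixel set"
                    )
        self.centroids = computed

    @property
    def labels(self) -> list[int]:
        return list(self._labels)

    @property
    def n_rois(self) -> int:
        return len(self._labels)

    def pixels(self, label: int) -> set[tuple[int, int]]:
        ys, xs = np.nonzero(self.mask == label)
        return set(zip(ys.tolist(), xs.tolist()))


@dataclass
class EpochSet:
    """Contiguous 30-s scoring epochs at 50% overlap with per-epoch
    features and state labels."""

    epochs: list[tuple[float, float]]
    features: pd.DataFrame
    labels: list[str] | None = None

    def __post_init__(self):
        for (s, e) in self.epochs:
            if abs((e - s) - EPOCH_LEN) > 1e-6:
                raise ValidationError("every epoch must be 30 s long")
        starts = [s for s, _ in self.epochs]
        if len(starts) > 1 and np.any(np.abs(np.diff(starts) - EPOCH_STEP) > 1e-6):
            raise ValidationError("consecutive epoch starts must be 15 s apart")
        if len(self.features) != len(self.epochs):
            raise ValidationError("features must have one row per epoch")
        if self.labels is None:
            self.labels = ["uncertain"] * len(self.epochs)
        if len(self.labels) != len(self.epochs):
            raise ValidationError("labels must have one entry per epoch")
        for lab in self.labels:
            if lab not in STATE_LABELS:
                raise ValidationError(f"unknown state label {lab!r}")

    def __len__(self) -> int:
        return len(self.epochs)

    def with_labels(self, labels: list[str]) -> "EpochSet":
        return EpochSet(list(self.epochs), self.features.copy(), list(labels))


@dataclass
class PresenceTable:
    """Spine x session boolean presence with dendrite metadata."""

    presence: np.ndarray
    dendrite_length: float
    dendrite_id: str = "d0"
    session_times: np.ndarray | None = None

    def __post_init__(self):
        self.presence = np.atleast_2d(np.asarray(self.presence, dtype=bool))
        if self.presence.shape[1] < 2:
            raise ValidationError("at least 2 sessions required")
        if not self.dendrite_length > 0:
            raise ValidationError("dendrite_length must be positive")
        if self.session_times is None:
            self.session_times = np.arange(self.presence.shape[1], dtype=float)
        self.session_times = np.asarray(self.session_times, dtype=float)
        if self.session_times.size != self.presence.shape[1]:
            raise ValidationError("session_times must match number of sessions")

    @property
    def n_sessions(self) -> int:
        return self.presence.shape[1]

    @property
    def n_spines(self) -> int:
        return self.presence.shape[0]


# ---------------------------------------------------------------------------
# readers / writers


def save_timeseries(ts: TimeSeries, path: str | Path) -> None:
    path = Path(path)
    ts.samples.astype(np.float64).tofile(path)
    meta = {"fs": ts.fs, "units": ts.units, "t0": ts.t0, "channel": ts.channel}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_timeseries(path: str | Path, interpolate_nan: bool = False) -> TimeSeries:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    samples = np.fromfile(path, dtype=np.float64)
    if interpolate_nan:
        samples = _interp_nan(samples)
    return TimeSeries(samples, fs=meta["fs"], units=meta.get("units", "a.u."),
                      t0=meta.get("t0", 0.0), channel=meta.get("channel", ""))


def save_spikeset(ss: SpikeSet, path: str | Path) -> None:
    path = Path(path)
    rows = [(uid, t) for uid, times in ss.units.items() for t in times]
    df = pd.DataFrame(rows, columns=["unit", "time"])
    df.to_csv(path, index=False)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps({"duration": ss.duration}))


def load_spikeset(path: str | Path, duration: float | None = None) -> SpikeSet:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"unit", "time"}.issubset(df.columns):
        raise FormatError("spike table must have 'unit' and 'time' columns")
    if duration is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FormatError(f"missing JSON sidecar {sidecar} (recording duration)")
        duration = json.loads(sidecar.read_text())["duration"]
    units = {str(u): np.sort(g["time"].to_numpy(dtype=float))
             for u, g in df.groupby("unit", sort=True)}
    # strict monotonicity (duplicates) still rejected by the constructor
    units = {u: t for u, t in units.items()}
    return SpikeSet(units, duration=float(duration))


def save_tracematrix(tm: TraceMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    pd.DataFrame(tm.F, index=tm.roi_ids).to_csv(prefix.with_name(prefix.name + "_F.csv"))
    pd.DataFrame(tm.Fneu, index=tm.roi_ids).to_csv(prefix.with_name(prefix.name + "_Fneu.csv"))
    if tm.S is not None:
        pd.DataFrame(tm.S, index=tm.roi_ids).to_csv(prefix.with_name(prefix.name + "_S.csv"))
    meta = {"fs": tm.fs, "has_S": tm.S is not None}
    prefix.with_name(prefix.name + "_meta.json").write_text(json.dumps(meta))


def load_tracematrix(prefix: str | Path) -> TraceMatrix:
    prefix = Path(prefix)
    meta_path = prefix.with_name(prefix.name + "_meta.json")
    if not meta_path.exists():
        raise FormatError(f"missing JSON sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    f = pd.read_csv(prefix.with_name(prefix.name + "_F.csv"), index_col=0)
    fneu = pd.read_csv(prefix.with_name(prefix.name + "_Fneu.csv"), index_col=0)
    S = None
    if meta.get("has_S"):
        S = pd.read_csv(prefix.with_name(prefix.name + "_S.csv"), index_col=0).to_numpy()
    return TraceMatrix(f.to_numpy(), fneu.to_numpy(), fs=meta["fs"],
                       roi_ids=[str(i) for i in f.index], S=S)


def save_roiset(rs: RoiSet, prefix: str | Path) -> None:
    prefix = Path(prefix)
    tifffile.imwrite(prefix.with_name(prefix.name + "_mask.tif"),
                     rs.mask.astype(np.uint16))
    if rs.image is not None:
        tifffile.imwrite(prefix.with_name(prefix.name + "_mean.tif"),
                         rs.image.astype(np.float32))
    if rs.enhanced_image is not None:
        tifffile.imwrite(prefix.with_name(prefix.name + "_meanE.tif"),
                         rs.enhanced_image.astype(np.float32))
    prefix.with_name(prefix.name + "_meta.json").write_text(
        json.dumps({"px_size": rs.px_size}))


def load_roiset(prefix: str | Path) -> RoiSet:
    prefix = Path(prefix)
    meta_path = prefix.with_name(prefix.name + "_meta.json")
    if not meta_path.exists():
        raise FormatError(f"missing JSON sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    mask = tifffile.imread(prefix.with_name(prefix.name + "_mask.tif"))
    image = enh = None
    p = prefix.with_name(prefix.name + "_mean.tif")
    if p.exists():
        image = tifffile.imread(p)
    p = prefix.with_name(prefix.name + "_meanE.tif")
    if p.exists():
        enh = tifffile.imread(p)
    return RoiSet(mask.astype(int), px_size=meta["px_size"], image=image,
                  enhanced_image=enh)


def save_epochset(es: EpochSet, path: str | Path) -> None:
    df = es.features.copy()
    df.insert(0, "start", [s for s, _ in es.epochs])
    df.insert(1, "end", [e for _, e in es.epochs])
    df["state"] = es.labels
    df.to_csv(path, index=False)


def load_epochset(path: str | Path) -> EpochSet:
    df = pd.read_csv(path)
    if not {"start", "end"}.issubset(df.columns):
        raise FormatError("epoch table must have 'start' and 'end' columns")
    epochs = list(zip(df["start"].astype(float), df["end"].astype(float)))
    labels = df["state"].tolist() if "state" in df.columns else None
    feats = df.drop(columns=[c for c in ("start", "end", "state") if c in df.columns])
    return EpochSet(epochs, feats.reset_index(drop=True), labels)


def save_presencetable(pt: PresenceTable, path: str | Path) -> None:
    cols = {f"s{j}": pt.presence[:, j].astype(int) for j in range(pt.n_sessions)}
    df = pd.DataFrame(cols)
    df.insert(0, "spine", [f"sp{i}" for i in range(pt.n_spines)])
    df.to_csv(path, index=False)
    meta = {"dendrite_id": pt.dendrite_id, "dendrite_length": pt.dendrite_length,
            "session_times": pt.session_times.tolist()}
    Path(path).with_suffix(Path(path).suffix + ".json").write_text(json.dumps(meta))


def load_presencetable(path: str | Path) -> PresenceTable:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path)
    pres = df[[c for c in df.columns if c.startswith("s") and c != "spine"]].to_numpy(bool)
    return PresenceTable(pres, dendrite_length=meta["dendrite_length"],
                         dendrite_id=meta.get("dendrite_id", "d0"),
                         session_times=np.asarray(meta["session_times"]))


_LOADERS = {
    "timeseries": load_timeseries,
    "spikes": load_spikeset,
    "traces": load_tracematrix,
    "rois": load_roiset,
    "epochs": load_epochset,
    "spines": load_presencetable,
}


def load_dataset(path: str | Path, kind: str, **kwargs):
    """Dispatching loader; ``kind`` is one of %s.""" % (tuple(_LOADERS),)
    if kind not in _LOADERS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {tuple(_LOADERS)}")
    return _LOADERS[kind](path, **kwargs)


# ---------------------------------------------------------------------------
# basic signal utilities


def zscore_rows(M: np.ndarray) -> np.ndarray:
    """Z-score each row; rows with zero variance are mapped to zeros."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    degenerate = (sd == 0).ravel()
    if degenerate.any():
        log.debug("zscore_rows: %d constant rows mapped to zeros", degenerate.sum())
    sd = np.where(sd == 0, 1.0, sd)
    Z = (M - mu) / sd
    Z[degenerate, :] = 0.0
    return Z
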