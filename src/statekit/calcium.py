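"""Calcium-trace preprocessing and statistics.

Neuropil correction (F - 0.7 Fneu), transient detection with the
height/distance/prominence criteria, per-ROI decay-constant estimation on
the best-isolated transients, detection-free activity metrics,
Fisher-transformed pairwise correlations with an optional distance profile,
population coupling, population spectral power, and normalization of
recovery trajectories to the awake baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .core_io import RoiSet, TraceMatrix, zscore_rows

log = logging.getLogger("statekit")

FRAME_S = 1.0 / 30.0  # nominal two-photon frame interval


@dataclass
class TransientSet:
    peaks: dict[str, np.ndarray]        # roi -> peak frame indices
    heights: dict[str, np.ndarray]
    prominences: dict[str, np.ndarray]
    fs: float
    params: dict = field(default_factory=dict)

    def rate_per_min(self, n_frames: int) -> dict[str, float]:
        minutes = n_frames / self.fs / 60.0
        return {r: p.size / minutes for r, p in self.peaks.items()}


@dataclass
class DecayEstimate:
    tau: dict[str, float]               # per-ROI decay constant (s); NaN = missing
    n_used: dict[str, int]
    excluded: list[str]                 # failed extraction (tau > max_tau)
    method: str = "exp_fit"


def preprocess_traces(tm: TraceMatrix, neuropil_frac: float = 0.7,
                      dff: bool = False, baseline_percentile: float = 8.0,
                      baseline_window_s: float = 60.0) -> TraceMatrix:
    """Neuropil-corrected traces: F' = F - neuropil_frac * Fneu.

    With ``dff`` the corrected trace is further normalized to
    (F' - F0)/F0 with F0 the rolling ``baseline_percentile`` percentile
    over ``baseline_window_s``; ROIs whose baseline is non-positive are
    flagged and excluded.
    """
    F = tm.F - neuropil_frac * tm.Fneu
    roi_ids = list(tm.roi_ids)
    if dff:
        w = max(3, int(round(baseline_window_s * tm.fs)))
        out = []
        kept = []
        for i in range(F.shape[0]):
            f0 = (pd.Series(F[i]).rolling(w, min_periods=1, center=True)
                  .quantile(baseline_percentile / 100.0).to_numpy())
            if np.any(f0 <= 0):
                log.debug("preprocess_traces: ROI %s non-positive baseline, excluded",
                          roi_ids[i])
                continue
            out.append((F[i] - f0) / f0)
            kept.append(i)
        if not out:
            raise ValueError("all ROIs excluded in dF/F mode")
        F = np.array(out)
        roi_ids = [roi_ids[i] for i in kept]
        Fneu = tm.Fneu[kept]
        S = tm.S[kept] if tm.S is not None else None
    else:
        Fneu = tm.Fneu
        S = tm.S
    return TraceMatrix(F, Fneu, fs=tm.fs, roi_ids=roi_ids, S=S)


def detect_transients(tm: TraceMatrix, height: float = 200.0,
                      distance: int = 10, prominence: float = 200.0
                      ) -> TransientSet:
    """Calcium-transient peaks satisfying height, minimum-distance and
    prominence criteria simultaneously (local-maxima detection)."""
    peaks, heights, proms = {}, {}, {}
    for i, roi in enumerate(tm.roi_ids):
        idx, props = signal.find_peaks(tm.F[i], height=height,
                                       distance=distance, prominence=prominence)
        peaks[roi] = idx
        heights[roi] = props.get("peak_heights", np.array([]))
        proms[roi] = props.get("prominences", np.array([]))
    return TransientSet(peaks, heights, proms, fs=tm.fs,
                        params={"height": height, "distance": distance,
                                "prominence": prominence})


def threshold_sweep(tm: TraceMatrix, thresholds: np.ndarray,
                    distance: int = 10) -> pd.DataFrame:
    """Transient count and mean height per ROI across a grid of
    height/prominence thresholds (robustness analysis)."""
    rows = []
    for thr in thresholds:
        det = detect_transients(tm, height=thr, distance=distance, prominence=thr)
        for roi in tm.roi_ids:
            h = det.heights[roi]
            rows.append({"threshold": thr, "roi": roi,
                         "n_transients": det.peaks[roi].size,
                         "mean_height": float(h.mean()) if h.size else np.nan})
    return pd.DataFrame(rows)


def _fit_exp_decay(y: np.ndarray, fs: float) -> float:
    """Single-exponential fit A exp(-t/tau) + c to a post-peak segment."""
    t = np.arange(y.size) / fs
    a0 = max(y[0] - y.min(), 1e-6)
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau, c: a * np.exp(-tt / tau) + c, t, y,
            p0=(a0, 0.5, y.min()), bounds=([0, 1e-3, -np.inf], [np.inf, 20.0, np.inf]),
            maxfev=2000)
        return float(popt[1])
    except RuntimeError:
        return float("nan")


def estimate_decay(tm: TraceMatrix, transients: TransientSet, n_best: int = 10,
                   max_tau: float = 2.0, max_segment_s: float = 2.0,
                   method: str = "exp_fit") -> DecayEstimate:
    """Per-ROI decay constant from the ``n_best`` best isolated transients.

    "Best isolated" = largest minimum gap to the neighboring transients
    (ties broken by larger prominence). Each transient contributes a
    single-exponential fit of the post-peak segment (up to the next
    transient or ``max_segment_s``, whichever is shorter); the ROI's tau is
    the median of the fits. Estimates above ``max_tau`` are treated as
    failed extraction and excluded. ``method='ar1'`` instead regresses
    frame t+1 on frame t over the segments, with tau = -dt/ln(g).
    """
    taus, n_used = {}, {}
    excluded = []
    dt = 1.0 / tm.fs
    for i, roi in enumerate(tm.roi_ids):
        pk = transients.peaks[roi]
        if pk.size == 0:
            taus[roi] = float("nan")
            n_used[roi] = 0
            continue
        if pk.size == 1:
            order = np.array([0])
        else:
            gaps = np.empty(pk.size)
            for j in range(pk.size):
                left = pk[j] - pk[j - 1] if j > 0 else np.inf
                right = pk[j + 1] - pk[j] if j < pk.size - 1 else np.inf
                gaps[j] = min(left, right)
            prom = transients.prominences[roi]
            order = np.lexsort((-prom, -gaps))  # gap desc, prominence desc
        best = order[:n_best]
        fits = []
        segs = []
        for j in best:
            start = pk[j]
            stop = pk[j + 1] if j < pk.size - 1 else tm.n_frames
            stop = min(stop, start + int(round(max_segment_s * tm.fs)))
            seg = tm.F[i, start:stop]
            if seg.size < 4:
                continue
            segs.append(seg)
            if method == "exp_fit":
                fits.append(_fit_exp_decay(seg, tm.fs))
        if method == "ar1" and segs:
            # lag-2 / lag-1 autocovariance ratio: consistent for the AR
            # coefficient under white measurement noise (which only
            # inflates lag 0)
            c1 = c2 = 0.0
            for s in segs:
                # no demeaning: for a deterministic decay the raw
                # lag-moment ratio is exact, and zero-mean noise terms
                # cancel in expectation
                if s.size >= 3:
                    c1 += float(s[:-1] @ s[1:])
                    c2 += float(s[:-2] @ s[2:])
            g = c2 / c1 if c1 > 0 else np.nan
            fits = [-dt / np.log(g)] if 0 < g < 1 else []
        fits = [f for f in fits if np.isfinite(f)]
        if not fits:
            taus[roi] = float("nan")
            n_used[roi] = 0
            continue
        tau = float(np.median(fits))
        n_used[roi] = len(fits)
        if tau > max_tau:
            excluded.append(roi)
            taus[roi] = float("nan")
        else:
            taus[roi] = tau
    return DecayEstimate(taus, n_used, excluded, method=method)


def trace_activity_metrics(tm: TraceMatrix) -> pd.DataFrame:
    """Detection-free activity metrics: time-integral and SD per ROI."""
    integral = tm.F.sum(axis=1)
    sd = tm.F.std(axis=1)
    return pd.DataFrame({"roi": tm.roi_ids, "integral": integral, "sd": sd})


def fisher_z(r: np.ndarray, clip: float = 1.0 - 1e-7) -> np.ndarray:
    """arctanh with |r| clipped below 1 so degenerate pairs stay finite."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= clip):
        log.debug("fisher_z: clipping %d coefficients at |r|=%g",
                  int((np.abs(r) >= clip).sum()), clip)
    return np.arctanh(np.clip(r, -clip, clip))


@dataclass
class CorrMatrix:
    z: np.ndarray                       # ROI x ROI Fisher-transformed
    method: str
    roi_ids: list[str]
    distance_profile: pd.DataFrame | None = None

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(self.z.shape[0], k=1)
        return self.z[iu]

    def quartile_occupancy(self) -> tuple[float, float]:
        """Fraction of pairs in the first (most negative) and fourth (most
        positive) quartile of the pooled coefficient distribution."""
        v = self.offdiag()
        q1, q3 = np.percentile(v, [25, 75])
        return float(np.mean(v <= q1)), float(np.mean(v >= q3))


def pairwise_correlations(tm: TraceMatrix, method: str = "pearson",
                          rois: RoiSet | None = None,
                          distance_bin_um: float = 25.0) -> CorrMatrix:
    """Fisher-transformed pairwise correlation matrix of z-scored traces.

    With ``rois`` given, also returns the mean |z| versus centroid distance
    in 25-um bins (pairs beyond the last bin pooled into an open final bin).
    """
    if tm.n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    Z = zscore_rows(tm.F)
    if method == "pearson":
        r = np.corrcoef(Z)
    elif method == "spearman":
        ranks = np.apply_along_axis(lambda x: pd.Series(x).rank().to_numpy(), 1, Z)
        r = np.corrcoef(ranks)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    profile = None
    if rois is not None:
        cents = np.array([rois.centroids[l] for l in rois.labels], dtype=float)
        n = min(len(cents), tm.n_rois)
        iu = np.triu_indices(n, k=1)
        d = np.hypot(*(cents[iu[0]] - cents[iu[1]]).T)
        zz = np.abs(z[:n, :n][iu])
        edges = np.arange(0, d.max() + distance_bin_um, distance_bin_um)
        idx = np.digitize(d, edges) - 1
        rows = []
        for b in range(edges.size - 1):
            sel = idx == b
            if sel.any():
                rows.append({"bin_low": edges[b], "bin_high": edges[b + 1],
                             "mean_abs_z": float(zz[sel].mean()),
                             "n_pairs": int(sel.sum())})
        profile = pd.DataFrame(rows)
    return CorrMatrix(z, method, list(tm.roi_ids), profile)


def population_coupling(tm: TraceMatrix) -> pd.DataFrame:
    """Leave-one-out population coupling: correlation of each z-scored ROI
    trace with the summed z-scored trace of all other ROIs."""
    if tm.n_rois < 3:
        raise ValueError("need at least 3 ROIs")
    Z = zscore_rows(tm.F)
    total = Z.sum(axis=0)
    coup = np.empty(tm.n_rois)
    for i in range(tm.n_rois):
        rest = total - Z[i]
        sd = rest.std() * Z[i].std()
        coup[i] = (np.mean((Z[i] - Z[i].mean()) * (rest - rest.mean())) / sd
                   if sd > 0 else 0.0)
    df = pd.DataFrame({"roi": tm.roi_ids, "coupling": coup})
    q1, q3 = np.percentile(coup, [25, 75])
    df.attrs["quartile_occupancy"] = (float(np.mean(coup <= q1)),
                                      float(np.mean(coup >= q3)))
    return df


def population_power(tm: TraceMatrix, nfft: int = 1024):
    """Spectrum of the summed z-scored population trace (Welch, no
    overlap, segment length = FFT length)."""
    from .lfp import PsdResult
    if tm.n_frames / tm.fs < 30.0:
        raise ValueError("need at least 30 s of frames")
    pop = zscore_rows(tm.F).sum(axis=0)
    nper = min(nfft, pop.size)
    f, p = signal.welch(pop, fs=tm.fs, nperseg=nper, nfft=nfft, noverlap=0)
    return PsdResult(f, p, window_len=nper / tm.fs, overlap=0.0)


def recovery_normalization(metrics: pd.DataFrame, baseline: str,
                           min_tau: float = FRAME_S) -> pd.DataFrame:
    """Median-normalized recovery trajectories.

    ``metrics`` has columns (roi, timepoint, rate, amplitude, tau).
    Per metric and timepoint the median over ROIs is divided by the
    baseline-timepoint median. ROIs without detected peaks (rate 0 at
    baseline and NaN tau) are dropped, as are ROIs with tau <= ``min_tau``
    (single-noise-peak artifacts).
    """
    df = metrics.copy()
    bad = set(df.loc[(df["timepoint"] == baseline) & (df["rate"] <= 0), "roi"])
    bad |= set(df.loc[df["tau"] <= min_tau, "roi"])
    df = df[~df["roi"].isin(bad)]
    if df.empty:
        raise ValueError("no ROIs survive the exclusion rules")
    value_cols = [c for c in df.columns if c not in ("roi", "timepoint")]
    med = df.groupby("timepoint")[value_cols].median()
    base = med.loc[baseline]
    for c in value_cols:
        if base[c] == 0:
            log.debug("recovery_normalization: baseline median 0 for %s", c)
            med[c] = np.nan
        else:
            med[c] = med[c] / base[c]
    return med
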