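"""LFP-level statistics.

Zero-phase Butterworth filtering, Welch spectra on 30-s windows, the
(a - b)/(a + b) relative-change index, the aperiodic 1/f exponent from a
robust log-log fit over 30-50 Hz, hysteresis detection of active periods,
and phase-amplitude coupling with circular-shift surrogate rejection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import warnings

import numpy as np
import statsmodels.api as sm
from scipy import ndimage, signal

from .core_io import TimeSeries

log = logging.getLogger("statekit")


@dataclass
class PsdResult:
    freqs: np.ndarray
    power: np.ndarray
    window_len: float = 30.0
    overlap: float = 15.0


@dataclass
class ActivePeriods:
    periods: list[tuple[float, float]]
    fraction_active: np.ndarray          # per 15-min bin
    bin_edges: np.ndarray                # seconds, half-open bins
    thresholds: tuple[float, float, float, float] = (7.0, 15.0, 1.0, 2.0)


@dataclass
class SlopeFit:
    slope: float
    intercept: float
    fit_band: tuple[float, float] = (30.0, 50.0)
    method: str = "robust"


@dataclass
class PacMap:
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    pac: np.ndarray                      # phase x amp, non-significant -> 0
    significant: np.ndarray
    raw: np.ndarray = field(default=None)


def bandpass(ts: TimeSeries, low: float, high: float, order: int = 3) -> TimeSeries:
    """Zero-phase (forward-backward) Butterworth band-pass; ``low=0`` gives
    a low-pass."""
    nyq = ts.fs / 2.0
    if not (0 <= low < high < nyq):
        raise ValueError(f"band ({low}, {high}) outside (0, {nyq}) Hz")
    if low == 0:
        sos = signal.butter(order, high, btype="low", fs=ts.fs, output="sos")
    else:
        sos = signal.butter(order, [low, high], btype="band", fs=ts.fs, output="sos")
    y = signal.sosfiltfilt(sos, ts.samples)
    return TimeSeries(y, fs=ts.fs, units=ts.units, t0=ts.t0, channel=ts.channel)


def welch_psd(ts: TimeSeries, window_len: float = 30.0, overlap: float = 15.0) -> PsdResult:
    """Welch average periodogram; defaults match 30-s windows with 15-s
    overlap (frequency resolution 1/window_len)."""
    nperseg = int(round(window_len * ts.fs))
    if ts.samples.size < 2 * nperseg - int(round(overlap * ts.fs)):
        raise ValueError("signal shorter than two Welch windows")
    f, p = signal.welch(ts.samples, fs=ts.fs, nperseg=nperseg,
                        noverlap=int(round(overlap * ts.fs)))
    return PsdResult(f, p, window_len=window_len, overlap=overlap)


def relative_change(a: float, b: float) -> float:
    """(a - b)/(a + b); NaN (with a warning) when the denominator is 0."""
    if a + b == 0:
        warnings.warn("relative_change: a + b = 0, returning NaN")
        return float("nan")
    return (a - b) / (a + b)


def aperiodic_slope(psd: PsdResult, band: tuple[float, float] = (30.0, 50.0),
                    log_freq: bool = True) -> SlopeFit:
    """Aperiodic 1/f exponent: robust (iteratively reweighted, Tukey
    biweight) line fit of log10 power over ``band``.

    With ``log_freq`` (default) the abscissa is log10 frequency, so a
    P(f) = f**(-beta) spectrum yields slope exactly -beta.
    """
    sel = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    f = psd.freqs[sel]
    p = psd.power[sel]
    pos = p > 0
    if (~pos).any():
        log.debug("aperiodic_slope: excluding %d non-positive power bins", (~pos).sum())
    f, p = f[pos], p[pos]
    if f.size < 5:
        raise ValueError("fewer than 5 usable frequency bins in fit band")
    x = np.log10(f) if log_freq else f
    X = sm.add_constant(x)
    fit = sm.RLM(np.log10(p), X, M=sm.robust.norms.TukeyBiweight()).fit()
    return SlopeFit(slope=float(fit.params[1]), intercept=float(fit.params[0]),
                    fit_band=band)


# ---------------------------------------------------------------------------
# active periods


def _hysteresis_regions(x: np.ndarray, low: float, high: float) -> np.ndarray:
    """Boolean mask of contiguous x > low regions that contain at least one
    x > high sample."""
    above_low, n = ndimage.label(x > low)
    if n == 0:
        return np.zeros(x.size, dtype=bool)
    has_seed = ndimage.maximum(x > high, labels=above_low, index=np.arange(1, n + 1))
    good = np.flatnonzero(np.asarray(has_seed) > 0) + 1
    return np.isin(above_low, good)


def detect_active_periods(ts: TimeSeries,
                          abs_thresholds: tuple[float, float] = (7.0, 15.0),
                          rel_thresholds: tuple[float, float] = (1.0, 2.0),
                          band: tuple[float, float] = (4.0, 20.0),
                          boxcar_s: float = 0.01,
                          merge_gap_s: float = 0.9,
                          min_len_s: float = 0.5,
                          frac_bin_s: float = 900.0) -> ActivePeriods:
    """Detect active periods on the 4-20 Hz band-passed signal.

    Hysteresis thresholding is applied twice — to the boxcar-smoothed
    rectified envelope against the absolute thresholds (in signal units)
    and to the z-scored smoothed squared signal against the relative
    thresholds — and a sample is active if either detector marks it
    (seeding requires exceeding the matching high threshold). Resulting
    periods are merged when separated by less than ``merge_gap_s`` and
    discarded when shorter than ``min_len_s``; the active fraction is
    reported per 15-min half-open bin (trailing partial bin kept).
    """
    if ts.duration < min_len_s:
        edges = np.array([0.0, ts.duration])
        return ActivePeriods([], np.zeros(1), edges,
                             (*abs_thresholds, *rel_thresholds))
    bp = bandpass(ts, *band).samples
    w = max(1, int(round(boxcar_s * ts.fs)))
    box = np.ones(w) / w
    envelope = np.convolve(np.abs(bp), box, mode="same")
    sq = np.convolve(bp ** 2, box, mode="same")
    z = (sq - sq.mean()) / sq.std() if sq.std() > 0 else np.zeros_like(sq)

    active = (_hysteresis_regions(envelope, *abs_thresholds)
              | _hysteresis_regions(z, *rel_thresholds))

    lab, n = ndimage.label(active)
    slices = ndimage.find_objects(lab)
    periods = [(s[0].start / ts.fs, s[0].stop / ts.fs) for s in slices]

    # merge inter-period gaps < 900 ms
    merged: list[list[float]] = []
    for s, e in periods:
        if merged and s - merged[-1][1] < merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    # discard periods < 500 ms
    kept = [(s, e) for s, e in merged if (e - s) >= min_len_s]

    edges = np.arange(0.0, ts.duration, frac_bin_s)
    edges = np.append(edges, ts.duration)
    frac = np.zeros(edges.size - 1)
    for i in range(edges.size - 1):
        lo, hi = edges[i], edges[i + 1]
        covered = sum(max(0.0, min(e, hi) - max(s, lo)) for s, e in kept)
        frac[i] = covered / (hi - lo) if hi > lo else 0.0
    return ActivePeriods(kept, frac, edges, (*abs_thresholds, *rel_thresholds))


# ---------------------------------------------------------------------------
# phase-amplitude coupling


def _binned_pac(phase: np.ndarray, amp: np.ndarray, n_bins: int) -> float:
    """(max - min)/(max + min) of the mean amplitude over phase bins."""
    bins = np.minimum(((phase + np.pi) / (2 * np.pi) * n_bins).astype(int), n_bins - 1)
    sums = np.bincount(bins, weights=amp, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    means = sums[counts > 0] / counts[counts > 0]
    hi, lo = means.max(), means.min()
    return float((hi - lo) / (hi + lo)) if (hi + lo) > 0 else 0.0


def phase_amplitude_coupling(ts: TimeSeries,
                             phase_range: tuple[float, float] = (0.1, 8.0),
                             amp_range: tuple[float, float] = (20.0, 100.0),
                             phase_bin: float = 1.0,
                             amp_bin: float = 10.0,
                             n_phase_bins: int = 18,
                             n_shuffles: int = 200,
                             alpha: float = 0.05,
                             amp_floor_frac: float = 1e-3,
                             seed: int = 0) -> PacMap:
    """Phase-amplitude coupling map over a 0.1-8 Hz phase grid and a
    20-100 Hz amplitude grid.

    Per cell: narrow-band filter both components, extract analytic phase
    and amplitude, bin the amplitude by phase (18 bins) and take the
    (max - min)/(max + min) modulation statistic. Significance is assessed
    against circular time-shift surrogates of the amplitude envelope;
    cells not exceeding the surrogate ``1 - alpha`` quantile are rejected
    (set to 0). Cells whose mean band amplitude falls below
    ``amp_floor_frac`` of the signal SD carry no measurable fast rhythm
    (filter leakage only, where the scale-invariant modulation statistic
    is meaningless) and are likewise reported as 0.
    """
    rng = np.random.default_rng(seed)
    phase_centers = np.arange(phase_range[0] + phase_bin / 2, phase_range[1],
                              phase_bin)
    amp_centers = np.arange(amp_range[0] + amp_bin / 2, amp_range[1], amp_bin)
    slowest = max(phase_centers[0] - phase_bin / 2, 0.05)
    if ts.duration < 10.0 / slowest:
        raise ValueError("signal shorter than 10 cycles of the slowest phase frequency")
    n = ts.samples.size
    min_shift = int(ts.fs)  # at least 1 s
    shifts = rng.integers(min_shift, n - min_shift, size=n_shuffles)

    phases = []
    for fc in phase_centers:
        lo = max(fc - phase_bin / 2, 0.01)
        band = bandpass(ts, lo, fc + phase_bin / 2).samples
        phases.append(np.angle(signal.hilbert(band)))
    amps = []
    for fc in amp_centers:
        band = bandpass(ts, fc - amp_bin / 2, fc + amp_bin / 2).samples
        amps.append(np.abs(signal.hilbert(band)))

    amp_floor = amp_floor_frac * float(np.std(ts.samples))
    pac = np.zeros((len(phase_centers), len(amp_centers)))
    sig = np.zeros_like(pac, dtype=bool)
    for i, ph in enumerate(phases):
        bins = np.minimum(((ph + np.pi) / (2 * np.pi) * n_phase_bins).astype(int),
                          n_phase_bins - 1)
        counts = np.bincount(bins, minlength=n_phase_bins)
        for j, am in enumerate(amps):
            if am.mean() < amp_floor:
                continue
            obs = _binned_pac(ph, am, n_phase_bins)
            null = np.empty(n_shuffles)
            for k, sh in enumerate(shifts):
                am_s = np.roll(am, int(sh))
                sums = np.bincount(bins, weights=am_s, minlength=n_phase_bins)
                means = sums[counts > 0] / counts[counts > 0]
                hi, lo = means.max(), means.min()
                null[k] = (hi - lo) / (hi + lo) if (hi + lo) > 0 else 0.0
            p_val = (1 + np.sum(null >= obs)) / (1 + n_shuffles)
            pac[i, j] = obs
            sig[i, j] = p_val < alpha
    rejected = np.where(sig, pac, 0.0)
    return PacMap(phase_centers, amp_centers, rejected, sig, raw=pac)
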