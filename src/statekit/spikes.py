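"""Spike-train statistics.

The central quantity is the spike time tiling coefficient (STTC), a
firing-rate-insensitive pairwise correlation:

    STTC = 1/2 [ (P_A - T_B)/(1 - P_A T_B) + (P_B - T_A)/(1 - P_B T_A) ]

where P_A is the proportion of spikes of train A falling within +-dt of a
spike of train B, and T_A the proportion of recording time tiled by the
union of +-dt windows around the spikes of A (clipped to [0, T]). Also
here: pairwise phase consistency (PPC), rate-normalized population-rate
spectra, and active-unit bookkeeping in 15-minute bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_io import SpikeSet, TimeSeries
from .lfp import bandpass

log = logging.getLogger("statekit")


@dataclass
class SttcResult:
    value: float
    dt: float
    p_a: float
    p_b: float
    t_a: float
    t_b: float


@dataclass
class PopRateSpectrum:
    freqs: np.ndarray
    power: np.ndarray       # averaged over windows, each normalized by its rate
    bin_width: float = 0.001
    n_windows: int = 0


def tiled_fraction(times: np.ndarray, dt: float, T: float) -> float:
    """Fraction of [0, T] covered by the union of [t - dt, t + dt] windows.

    Overlapping windows are counted once; edges are clipped to [0, T].
    """
    if times.size == 0:
        return 0.0
    starts = np.clip(times - dt, 0.0, T)
    ends = np.clip(times + dt, 0.0, T)
    total = 0.0
    cur_s, cur_e = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    total += cur_e - cur_s
    return total / T


def _prop_tiled(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """Proportion of spikes of ``a`` within +-dt of a spike of ``b``."""
    idx = np.searchsorted(b, a)
    near = np.zeros(a.size, dtype=bool)
    right = idx < b.size
    near[right] = (b[idx[right]] - a[right]) <= dt
    left = idx > 0
    near[left] |= (a[left] - b[idx[left] - 1]) <= dt
    return float(near.mean())


def sttc(a: np.ndarray, b: np.ndarray, dt: float, T: float) -> SttcResult:
    """Spike time tiling coefficient of two sorted spike-time vectors.

    Empty trains and vanishing denominators give NaN (missing), not an
    exception; downstream distributions simply omit them.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if T <= 0:
        raise ValueError("T must be positive")
    if a.size == 0 or b.size == 0:
        log.debug("sttc: empty train, returning missing value")
        return SttcResult(np.nan, dt, np.nan, np.nan, np.nan, np.nan)
    p_a = _prop_tiled(a, b, dt)
    p_b = _prop_tiled(b, a, dt)
    t_a = tiled_fraction(a, dt, T)
    t_b = tiled_fraction(b, dt, T)
    halves = []
    for p, t in ((p_a, t_b), (p_b, t_a)):
        denom = 1.0 - p * t
        halves.append((p - t) / denom if denom != 0 else np.nan)
    value = np.nan if np.any(np.isnan(halves)) else 0.5 * (halves[0] + halves[1])
    return SttcResult(float(value), dt, p_a, p_b, t_a, t_b)


def sttc_matrix(spikes: SpikeSet, dt: float) -> dict[tuple[str, str], SttcResult]:
    """STTC for all unordered unit pairs (symmetric by construction)."""
    uids = [u for u in spikes.units]
    if sum(spikes.units[u].size > 0 for u in uids) < 2:
        raise ValueError("need at least 2 non-empty units")
    out = {}
    for i, ua in enumerate(uids):
        for ub in uids[i + 1:]:
            out[(ua, ub)] = sttc(spikes.units[ua], spikes.units[ub], dt,
                                 spikes.duration)
    return out


def ppc(phases: np.ndarray) -> float:
    """Pairwise phase consistency: mean of cos(theta_i - theta_j) over all
    unordered spike pairs of a unit. Missing (NaN) below 2 spikes.

    Computed in closed form from the resultant vector:
    ((sum cos)^2 + (sum sin)^2 - n) / (n (n - 1)).
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 2:
        return float("nan")
    c = np.cos(phases).sum()
    s = np.sin(phases).sum()
    return float((c * c + s * s - n) / (n * (n - 1)))


def spike_phases(ts: TimeSeries, times: np.ndarray,
                 band: tuple[float, float]) -> np.ndarray:
    """Analytic-signal phase of ``ts`` in ``band`` sampled at spike times."""
    filt = bandpass(ts, *band)
    ph = np.angle(signal.hilbert(filt.samples))
    idx = np.clip(np.round((times - ts.t0) * ts.fs).astype(int), 0, ph.size - 1)
    return ph[idx]


def ppc_by_band(spikes: SpikeSet, lfp: TimeSeries,
                bands: list[tuple[float, float]]) -> dict[str, dict[tuple, float]]:
    """Per-unit PPC for each frequency band."""
    out: dict[str, dict[tuple, float]] = {}
    for uid, times in spikes.units.items():
        out[uid] = {}
        for band in bands:
            if times.size < 2:
                out[uid][band] = float("nan")
            else:
                out[uid][band] = ppc(spike_phases(lfp, times, band))
    return out


def population_rate_power(spikes: SpikeSet, bin_width: float = 0.001,
                          window_len: float = 30.0, overlap: float = 15.0
                          ) -> PopRateSpectrum:
    """Spectrum of the summed (1-ms binned) population spike train.

    Welch-style: periodogram per 30-s window (15-s overlap), each window's
    PSD divided by its mean firing rate before averaging; windows with no
    spikes are skipped.
    """
    if spikes.duration < 60.0:
        raise ValueError("need at least 60 s of recording")
    fs = 1.0 / bin_width
    n = int(round(spikes.duration * fs))
    pop = np.zeros(n)
    for t in spikes.units.values():
        idx = np.minimum((t / bin_width).astype(int), n - 1)
        np.add.at(pop, idx, 1.0)
    nper = int(round(window_len * fs))
    step = nper - int(round(overlap * fs))
    psds = []
    freqs = np.fft.rfftfreq(nper, d=bin_width)
    win = np.hanning(nper)
    u = (win ** 2).sum()
    start = 0
    skipped = 0
    while start + nper <= n:
        seg = pop[start:start + nper]
        rate = seg.sum() / window_len    # spikes/s in this window
        if rate == 0:
            skipped += 1
            start += step
            continue
        segd = seg - seg.mean()
        spec = np.abs(np.fft.rfft(segd * win)) ** 2 / (fs * u)
        spec[1:-1] *= 2.0
        psds.append(spec / rate)
        start += step
    if skipped:
        log.debug("population_rate_power: skipped %d empty windows", skipped)
    if not psds:
        raise ValueError("no windows with spikes")
    return PopRateSpectrum(freqs, np.mean(psds, axis=0), bin_width, len(psds))


def active_unit_fraction(spikes: SpikeSet, bin_s: float = 900.0,
                         min_spikes: int = 5, reference_bin: int = 0
                         ) -> np.ndarray:
    """Per-bin count of active units (>= ``min_spikes`` spikes in the
    15-min bin), expressed as a fraction of the count in the reference bin.
    """
    edges = np.arange(0.0, spikes.duration + 1e-9, bin_s)
    if edges[-1] < spikes.duration:
        edges = np.append(edges, spikes.duration)
    if edges.size < 2:
        raise ValueError("recording shorter than one bin")
    n_bins = edges.size - 1
    counts = np.zeros(n_bins, dtype=int)
    for t in spikes.units.values():
        per_bin, _ = np.histogram(t, bins=edges)
        counts += per_bin >= min_spikes
    if counts[reference_bin] == 0:
        raise ValueError("reference bin has no active units")
    return counts / counts[reference_bin]
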