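"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: the STTC oracle is a
double loop plus an explicit interval-union sweep, and the active-period
oracle applies the detection rules sample by sample with plain Python
state machines.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfiltfilt


def sttc_bruteforce(a, b, dt, T):
    """STTC by double loops and a literal interval-union sweep."""
    a = list(map(float, a))
    b = list(map(float, b))
    if not a or not b:
        return float("nan")

    def prop(x, y):
        hits = 0
        for t in x:
            for s in y:
                if abs(t - s) <= dt:
                    hits += 1
                    break
        return hits / len(x)

    def tiled(x):
        # sweep a fine union of clipped intervals
        ivs = sorted((max(0.0, t - dt), min(T, t + dt)) for t in x)
        total = 0.0
        cs, ce = ivs[0]
        for s, e in ivs[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                total += ce - cs
                cs, ce = s, e
        total += ce - cs
        return total / T

    pa, pb = prop(a, b), prop(b, a)
    ta, tb = tiled(a), tiled(b)
    halves = []
    for p, t in ((pa, tb), (pb, ta)):
        denom = 1.0 - p * t
        if denom == 0:
            return float("nan")
        halves.append((p - t) / denom)
    return 0.5 * (halves[0] + halves[1])


def active_periods_literal(samples, fs,
                           abs_low=7.0, abs_high=15.0,
                           rel_low=1.0, rel_high=2.0,
                           band=(4.0, 20.0), boxcar_s=0.01,
                           merge_gap_s=0.9, min_len_s=0.5):
    """Literal, unoptimized application of the active-period rules.

    Same preprocessing formulas (zero-phase band-pass, boxcar smoothing of
    the rectified envelope and of the squared signal, z-scoring), but the
    hysteresis, merging and discarding rules are applied sample by sample
    with explicit loops.
    """
    sos = butter(3, band, btype="band", fs=fs, output="sos")
    bp = sosfiltfilt(sos, np.asarray(samples, dtype=float))
    w = max(1, int(round(boxcar_s * fs)))
    box = np.ones(w) / w
    env = np.convolve(np.abs(bp), box, mode="same")
    sq = np.convolve(bp ** 2, box, mode="same")
    sd = sq.std()
    z = (sq - sq.mean()) / sd if sd > 0 else np.zeros_like(sq)

    n = len(bp)

    def hysteresis(x, low, high):
        active = [False] * n
        i = 0
        while i < n:
            if x[i] > high:
                # extend left and right to the low threshold
                j = i
                while j >= 0 and x[j] > low:
                    j -= 1
                k = i
                while k < n and x[k] > low:
                    k += 1
                for m in range(j + 1, k):
                    active[m] = True
                i = k
            else:
                i += 1
        return active

    act_abs = hysteresis(env, abs_low, abs_high)
    act_rel = hysteresis(z, rel_low, rel_high)
    active = [p or q for p, q in zip(act_abs, act_rel)]

    # contiguous runs -> (start, end) in seconds
    periods = []
    i = 0
    while i < n:
        if active[i]:
            j = i
            while j < n and active[j]:
                j += 1
            periods.append((i / fs, j / fs))
            i = j
        else:
            i += 1

    merged = []
    for s, e in periods:
        if merged and s - merged[-1][1] < merge_gap_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s >= min_len_s]


def ppc_pairs(phases):
    """PPC by the explicit double loop over spike pairs."""
    phases = list(map(float, phases))
    n = len(phases)
    if n < 2:
        return float("nan")
    acc = 0.0
    cnt = 0
    for i in range(n):
        for j in range(i + 1, n):
            acc += np.cos(phases[i] - phases[j])
            cnt += 1
    return acc / cnt
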