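"""Synthetic recordings with known ground truth.

Each generator emulates one input of the analysis pipeline — state-dependent
oscillatory LFP over a 1/f background, coupled doubly-stochastic spike
trains, calcium traces built from spikes, ROI-map pairs related by a known
geometric transform, sleep-scoring epoch features, and spine gain/loss
histories — and returns the ground truth needed to verify recovery.

The generators are statistical emulators of the phenomenology only: no
biophysics, no anesthetic pharmacology. Every generator is deterministic per
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import (EpochSet, PresenceTable, RoiSet, SpikeSet, TimeSeries,
                      TraceMatrix)


@dataclass
class StateParams:
    """Parameters of one brain-state regime.

    ``osc_components`` lists ``(freq_hz, amplitude, phase_mod_depth)``
    oscillations; ``phase_mod_depth`` modulates spiking rate by the
    oscillation phase. ``aperiodic_exponent`` is the 1/f^beta exponent of
    the background spectrum; ``coupling`` the target pairwise spike-train
    coupling in [0, 1]; ``rate_scale`` a mean-rate multiplier relative to
    wakefulness.
    """

    name: str = "wake"
    rate_scale: float = 1.0
    osc_components: list[tuple[float, float, float]] = field(default_factory=list)
    coupling: float = 0.0
    noise_sd: float = 0.0
    aperiodic_exponent: float = 1.0

    def __post_init__(self):
        if self.rate_scale < 0:
            raise ValueError("rate_scale must be >= 0")
        if self.aperiodic_exponent < 0:
            raise ValueError("aperiodic_exponent must be >= 0")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")


@dataclass
class GroundTruth:
    """Whatever the corresponding generator can guarantee by construction."""

    spike_times: dict[str, np.ndarray] | None = None
    coupling: float | None = None
    tau: float | None = None
    roi_pairs: dict[int, int] | None = None
    epoch_labels: list[str] | None = None
    spine_events: dict | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# LFP


def powerlaw_noise(n: int, beta: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise spectrally shaped to an exact 1/f^beta power spectrum
    (FFT filtering of white noise), unit variance."""
    white = rng.standard_normal(n)
    if beta == 0:
        return white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-beta / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_lfp(params: StateParams, duration: float, fs: float, seed: int,
            background_sd: float = 1.0) -> TimeSeries:
    """State-dependent LFP: summed oscillations + 1/f^beta background +
    white noise."""
    if params.osc_components:
        fmax = max(f for f, _, _ in params.osc_components)
        if fs < 2 * fmax:
            raise ValueError(f"fs={fs} below Nyquist for {fmax} Hz oscillation")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for f, amp, _depth in params.osc_components:
        phase = rng.uniform(0, 2 * np.pi)
        x += amp * np.sin(2 * np.pi * f * t + phase)
    if background_sd > 0 and params.aperiodic_exponent >= 0:
        x += background_sd * powerlaw_noise(n, params.aperiodic_exponent, fs, rng)
    if params.noise_sd > 0:
        x += params.noise_sd * rng.standard_normal(n)
    return TimeSeries(x, fs=fs, units="uV", channel=f"lfp-{params.name}")


# ---------------------------------------------------------------------------
# spikes


def _inhom_poisson(rate_fn, duration: float, rate_max: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson times by thinning a homogeneous process."""
    n = rng.poisson(rate_max * duration)
    cand = np.sort(rng.uniform(0, duration, n))
    keep = rng.uniform(0, 1, n) < rate_fn(cand) / rate_max
    return cand[keep]


def gen_spikes(params: StateParams, n_units: int, duration: float, seed: int,
               base_rate: float = 5.0, jitter: float = 0.0
               ) -> tuple[SpikeSet, GroundTruth]:
    """Coupled doubly-stochastic spike trains.

    Common-parent construction: a shared mother Poisson train is inherited
    by each unit with probability ``coupling`` (optionally time-jittered);
    the complement of the rate comes from per-unit independent Poisson
    spiking. Both components share the sinusoidal rate modulation given by
    ``osc_components`` (phase-locked spiking), and ``rate_scale`` thins the
    overall rate. Pairwise coupling and firing rate are therefore
    independently controllable.
    """
    if n_units < 2:
        raise ValueError("n_units must be >= 2")
    rng = np.random.default_rng(seed)
    r = base_rate * params.rate_scale
    c = params.coupling

    mod_comps = [(f, depth) for f, _a, depth in params.osc_components if depth > 0]

    def rate_fn(t):
        m = np.ones_like(t)
        for f, depth in mod_comps:
            m = m * (1.0 + depth * np.sin(2 * np.pi * f * t))
        return np.clip(m, 0, None)

    rate_max = float(np.prod([1.0 + d for _f, d in mod_comps])) if mod_comps else 1.0

    mother = (_inhom_poisson(lambda t: r * rate_fn(t), duration, r * rate_max, rng)
              if r > 0 else np.array([]))

    units: dict[str, np.ndarray] = {}
    for i in range(n_units):
        if c >= 1.0:
            shared = mother.copy()
        elif c <= 0.0:
            shared = np.array([])
        else:
            shared = mother[rng.uniform(0, 1, mother.size) < c]
        if jitter > 0 and shared.size:
            shared = shared + rng.normal(0, jitter, shared.size)
        if c < 1.0 and r > 0:
            indep = _inhom_poisson(lambda t: (1 - c) * r * rate_fn(t), duration,
                                   (1 - c) * r * rate_max, rng)
        else:
            indep = np.array([])
        t = np.sort(np.concatenate([shared, indep]))
        t = t[(t >= 0) & (t <= duration)]
        t = np.unique(t)
        units[f"u{i:03d}"] = t
    ss = SpikeSet(units, duration=duration)
    gt = GroundTruth(spike_times={u: t.copy() for u, t in units.items()},
                     coupling=c, extra={"base_rate": base_rate,
                                        "rate_scale": params.rate_scale})
    return ss, gt


def gen_isolated_spikes(n_units: int, n_spikes: int, duration: float,
                        min_gap: float, seed: int) -> SpikeSet:
    """Spike trains with a guaranteed minimum inter-spike gap per unit
    (transient-recovery scenarios where every event must be resolvable)."""
    rng = np.random.default_rng(seed)
    if n_spikes * min_gap >= duration:
        raise ValueError("cannot fit n_spikes with min_gap into duration")
    units = {}
    slack = duration - n_spikes * min_gap
    for i in range(n_units):
        gaps = rng.dirichlet(np.ones(n_spikes + 1)) * slack
        t = np.cumsum(gaps[:-1] + min_gap) - min_gap / 2
        units[f"u{i:03d}"] = np.sort(t)
    return SpikeSet(units, duration=duration)


# ---------------------------------------------------------------------------
# calcium


def gen_calcium(spikes: SpikeSet, tau: float, fs: float, seed: int,
                amp: float = 400.0, neuropil_frac: float = 0.7,
                noise_sd: float = 40.0, background_sd: float = 100.0,
                baseline: float = 0.0) -> tuple[TraceMatrix, GroundTruth]:
    """Calcium traces: spike trains convolved with ``amp * exp(-t/tau)``
    plus a shared slow neuropil background and Gaussian noise.

    ``Fneu`` carries the shared background (plus its own noise); ``F``
    receives ``neuropil_frac`` of it, so the standard neuropil subtraction
    removes it exactly in expectation.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(spikes.duration * fs))
    kernel_len = int(np.ceil(5 * tau * fs))
    kt = np.arange(kernel_len) / fs
    kernel = amp * np.exp(-kt / tau)

    # shared neuropil background: noise smoothed to a ~0.2 s correlation
    # time, offset to be positive-going
    from scipy.ndimage import gaussian_filter1d
    slow = gaussian_filter1d(rng.standard_normal(n_frames), sigma=0.2 * fs)
    slow = slow / max(slow.std(), 1e-12)
    background = background_sd * (slow - slow.min()) * 0.3

    F = np.zeros((spikes.n_units, n_frames))
    roi_ids = []
    for i, (uid, times) in enumerate(spikes.units.items()):
        binned = np.zeros(n_frames)
        idx = np.floor(times * fs).astype(int)
        idx = idx[idx < n_frames]
        np.add.at(binned, idx, 1.0)
        trace = np.convolve(binned, kernel)[:n_frames]
        F[i] = (baseline + trace + neuropil_frac * background
                + (noise_sd * rng.standard_normal(n_frames) if noise_sd > 0 else 0))
        roi_ids.append(uid)
    Fneu = np.tile(background, (spikes.n_units, 1))
    if noise_sd > 0:
        Fneu = Fneu + noise_sd * 0.3 * rng.standard_normal(Fneu.shape)
    tm = TraceMatrix(F, Fneu, fs=fs, roi_ids=roi_ids)
    gt = GroundTruth(spike_times={u: t.copy() for u, t in spikes.units.items()},
                     tau=tau, extra={"amp": amp, "background": background})
    return tm, gt


# ---------------------------------------------------------------------------
# ROI map pairs


_TRANSFORMS = ("translation", "rigid", "affine")


def _apply_transform(xy: np.ndarray, kind: str, rng: np.random.Generator,
                     magnitude: float) -> tuple[np.ndarray, dict]:
    """Random transform of the requested family; ``magnitude`` scales the
    translation (um) and the rotation/shear extent."""
    params: dict = {"kind": kind}
    # translation of exactly `magnitude` um in a random direction
    ang = rng.uniform(0, 2 * np.pi)
    shift = magnitude * np.array([np.cos(ang), np.sin(ang)])
    A = np.eye(2)
    if kind in ("rigid", "affine"):
        theta = rng.uniform(-0.02, 0.02) * max(magnitude, 1.0)
        scale = 1.0 + rng.uniform(-0.01, 0.01)
        ct, st = np.cos(theta), np.sin(theta)
        A = scale * np.array([[ct, -st], [st, ct]])
        params.update(theta=theta, scale=scale)
    if kind == "affine":
        shear = rng.uniform(0.01, 0.02) * max(magnitude, 1.0) * rng.choice([-1, 1])
        A = A @ np.array([[1.0, shear], [0.0, 1.0]])
        params.update(shear=shear)
    params.update(shift=shift, A=A)
    center = xy.mean(axis=0)
    return (xy - center) @ A.T + center + shift, params


def _rasterize_rois(xy_um: np.ndarray, radius_um: float, px_size: float,
                    shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=np.uint16)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for i, (cx, cy) in enumerate(xy_um, start=1):
        d2 = (xx * px_size - cx) ** 2 + (yy * px_size - cy) ** 2
        mask[d2 <= radius_um ** 2] = i
    return mask


def gen_roi_pair(n_rois: int, seed: int, px_size: float = 0.8,
                 transform: str = "translation", transform_magnitude: float = 0.0,
                 centroid_jitter: float = 0.0, drop_frac: float = 0.0,
                 radius_um: float = 5.0, fov_um: float = 200.0,
                 max_retries: int = 50) -> tuple[RoiSet, RoiSet, GroundTruth]:
    """A pair of ROI maps related by a known transform.

    The second map is the transformed copy of the first with per-ROI
    centroid jitter (uniform within a disk of radius ``centroid_jitter``
    um, i.e. a bounded displacement), ``drop_frac`` of ROIs removed and
    replaced by new ones placed far (> 8 um) from every existing centroid.
    The truth map lists surviving pairs as ``label_a -> label_b``.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"transform must be one of {_TRANSFORMS}")
    if centroid_jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    # keep ROIs inside the central ~75% so border truncation in alignment
    # scoring does not clip genuine signal
    margin = radius_um + 0.12 * fov_um + 8.0
    min_sep = 2 * radius_um + 4.0

    def place(n, existing, tries=4000):
        pts = list(existing)
        out = []
        for _ in range(tries):
            if len(out) == n:
                break
            p = rng.uniform(margin, fov_um - margin, 2)
            if all(np.hypot(*(p - q)) >= min_sep for q in pts):
                pts.append(p)
                out.append(p)
        if len(out) < n:
            raise RuntimeError("could not place non-overlapping ROIs")
        return np.array(out)

    for _attempt in range(max_retries):
        try:
            xy_a = place(n_rois, [])
            break
        except RuntimeError:
            continue
    else:
        raise RuntimeError("ROI placement failed after bounded retries")

    xy_b, tparams = _apply_transform(xy_a, transform, rng, transform_magnitude)
    if centroid_jitter > 0:
        ang = rng.uniform(0, 2 * np.pi, n_rois)
        rad = centroid_jitter * np.sqrt(rng.uniform(0, 1, n_rois))
        xy_b = xy_b + np.c_[rad * np.cos(ang), rad * np.sin(ang)]

    n_drop = int(round(drop_frac * n_rois))
    dropped = rng.choice(n_rois, size=n_drop, replace=False) if n_drop else np.array([], int)
    survivors = np.setdiff1d(np.arange(n_rois), dropped)

    # replacement ROIs: far from every existing centroid in either map
    avoid = [p for p in xy_a] + [xy_b[i] for i in survivors]
    new_pts = []
    for _ in range(20000):
        if len(new_pts) == n_drop:
            break
        p = rng.uniform(margin, fov_um - margin, 2)
        if all(np.hypot(*(p - q)) >= max(min_sep, 2 * radius_um + 8.0)
               for q in avoid + new_pts):
            new_pts.append(p)
    if len(new_pts) < n_drop:
        raise RuntimeError("could not place replacement ROIs")

    xy_b_final = np.array([xy_b[i] for i in survivors] + new_pts)

    npx = int(round(fov_um / px_size))
    mask_a = _rasterize_rois(xy_a, radius_um, px_size, (npx, npx))
    mask_b = _rasterize_rois(xy_b_final, radius_um, px_size, (npx, npx))

    def mean_image(mask):
        img = (mask > 0).astype(float)
        img += 0.05 * rng.standard_normal(mask.shape)
        return img

    rs_a = RoiSet(mask_a, px_size=px_size, image=mean_image(mask_a),
                  enhanced_image=mean_image(mask_a) * 1.5)
    rs_b = RoiSet(mask_b, px_size=px_size, image=mean_image(mask_b),
                  enhanced_image=mean_image(mask_b) * 1.5)
    pairs = {int(i + 1): int(j + 1) for j, i in enumerate(survivors)}
    gt = GroundTruth(roi_pairs=pairs, extra={"transform": tparams,
                                             "dropped": dropped.tolist()})
    return rs_a, rs_b, gt


def gen_roi_sessions(n_rois: int, n_sessions: int, seed: int,
                     px_size: float = 0.8, centroid_jitter: float = 0.5,
                     drop_frac: float = 0.2, radius_um: float = 5.0,
                     fov_um: float = 200.0) -> tuple[list[RoiSet], GroundTruth]:
    """A chain of aligned sessions with known neuron persistence.

    Session 0 seeds true neuron IDs 0..n-1. Each later session drops
    ``drop_frac`` of the previous session's neurons (their chains end for
    good), jitters the survivors (bounded, uniform in a disk of radius
    ``centroid_jitter``), and adds replacements — under fresh true IDs —
    far from every live centroid and from every past (ended-chain)
    centroid, so a dead neuron can never be spuriously re-identified. The ground truth carries
    ``extra['membership']`` — per session a dict label -> true neuron
    ID — and ``extra['presence']``, the true ID x session boolean matrix.
    """
    rng = np.random.default_rng(seed)
    margin = radius_um + 0.12 * fov_um + 8.0
    min_sep = 2 * radius_um + 4.0
    npx = int(round(fov_um / px_size))

    def far_point(avoid, gap):
        for _ in range(20000):
            p = rng.uniform(margin, fov_um - margin, 2)
            if all(np.hypot(*(p - q)) >= gap for q in avoid):
                return p
        raise RuntimeError("could not place ROI")

    # session 0
    pts: list[np.ndarray] = []
    for _ in range(n_rois):
        pts.append(far_point(pts, min_sep))
    current = {tid: p for tid, p in enumerate(pts)}   # true id -> centroid
    graveyard: list[np.ndarray] = []  # centroids of ended chains: new ROIs
    # must stay clear of them or a dead neuron could be "resurrected"
    next_tid = n_rois

    sessions = []
    membership: list[dict[int, int]] = []
    presence_rows: dict[int, list[int]] = {tid: [0] * n_sessions
                                           for tid in current}
    for s in range(n_sessions):
        if s > 0:
            tids = list(current)
            n_drop = int(round(drop_frac * len(tids)))
            dropped = set(rng.choice(tids, size=n_drop, replace=False).tolist())
            survivors = {}
            for tid in tids:
                if tid in dropped:
                    graveyard.append(current[tid])
                    continue
                ang = rng.uniform(0, 2 * np.pi)
                rad = centroid_jitter * np.sqrt(rng.uniform())
                survivors[tid] = current[tid] + np.array(
                    [rad * np.cos(ang), rad * np.sin(ang)])
            for _ in range(n_drop):
                p = far_point([*survivors.values(), *current.values(),
                               *graveyard],
                              2 * radius_um + 8.0)
                survivors[next_tid] = p
                presence_rows[next_tid] = [0] * n_sessions
                next_tid += 1
            current = survivors
        order = sorted(current)
        xy = np.array([current[tid] for tid in order])
        mask = _rasterize_rois(xy, radius_um, px_size, (npx, npx))
        sessions.append(RoiSet(mask, px_size=px_size))
        membership.append({lab: tid for lab, tid in enumerate(order, start=1)})
        for tid in order:
            presence_rows[tid][s] = 1
    pres = np.array([presence_rows[tid] for tid in sorted(presence_rows)],
                    dtype=bool)
    gt = GroundTruth(extra={"membership": membership, "presence": pres})
    return sessions, gt


# ---------------------------------------------------------------------------
# sleep-scoring epoch features

# class-conditional geometry (log-space offsets, units of one noise SD at
# separability 1): wake moves, has high EMG; NREM has high delta, low EMG;
# REM has the highest theta/delta ratio and the lowest EMG.
_CLASS_OFFSETS = {
    #            delta  theta   emg   motion  pupil_diam  eyelid
    "wake":    (0.0,   0.5,    2.0,  2.0,    1.5,        1.0),
    "NREM":    (2.0,   0.0,    0.0,  0.0,    0.0,        0.0),
    "REM":     (0.0,   2.0,   -2.0,  0.0,   -1.0,        0.0),
}
_FEATURES = ("delta", "theta", "emg", "motion", "pupil_diam", "eyelid")
_MOTION_THRESHOLD = 1.0  # global movement-flag cut on the motion feature


def gen_epoch_features(n_epochs: int, seed: int,
                       class_mix: tuple[float, float, float] = (0.5, 0.4, 0.1),
                       separability: float = 4.0,
                       rem_overlap_nrem: bool = False
                       ) -> tuple[EpochSet, GroundTruth]:
    """Per-epoch sleep-scoring features from class-conditional Gaussians.

    ``class_mix`` is (wake, NREM, REM) probabilities; ``separability``
    scales the distance between class means in units of the within-class
    SD. ``rem_overlap_nrem`` collapses the REM pupil features onto the NREM
    ones (used to reproduce the hard-to-classify REM scenario).
    """
    import pandas as pd

    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    rng = np.random.default_rng(seed)
    states = ["wake", "NREM", "REM"]
    labels = rng.choice(states, size=n_epochs, p=list(class_mix))

    rows = np.empty((n_epochs, len(_FEATURES)))
    for i, lab in enumerate(labels):
        off = np.array(_CLASS_OFFSETS[lab], dtype=float)
        if rem_overlap_nrem and lab == "REM":
            off[4:] = np.array(_CLASS_OFFSETS["NREM"][4:])
        rows[i] = off * separability + rng.standard_normal(len(_FEATURES))
    feats = pd.DataFrame(rows, columns=_FEATURES)
    feats["ratio"] = feats["theta"] - feats["delta"]  # log-space power ratio
    # movement flag: fixed global cut halfway up the wake motion offset
    feats["movement"] = rows[:, 3] > _MOTION_THRESHOLD * separability
    # derived pupil features for the videography classifier
    feats["pupil_diam_max"] = feats["pupil_diam"] + 0.5
    feats["pupil_diam_min"] = feats["pupil_diam"] - 0.5
    feats["pupil_sd"] = np.abs(feats["pupil_diam"]) * 0.1 + 0.05
    feats["pupil_area"] = feats["pupil_diam"] * 2.0
    feats["pupil_motion"] = feats["motion"]

    epochs = [(15.0 * i, 15.0 * i + 30.0) for i in range(n_epochs)]
    es = EpochSet(epochs, feats)
    gt = GroundTruth(epoch_labels=[str(l) for l in labels])
    return es, gt


# ---------------------------------------------------------------------------
# ensemble-structure populations


def gen_state_population(n_neurons: int, n_frames: int, seed: int,
                         n_assemblies: int = 2, coupling: float = 0.9,
                         noise_sd: float = 0.6, membership_mixing: float = 0.0,
                         pattern: str = "assembly", dwell_frames: int = 15,
                         fs: float = 10.0) -> np.ndarray:
    """Time x neuron activity with temporal states and tunable spatial
    coupling structure.

    A Markov state sequence (mean dwell ``dwell_frames`` frames) selects
    one of ``n_assemblies`` states at each frame; each neuron's trace is
    ``coupling`` times its loading on the smoothed state activations plus
    Gaussian noise.

    ``pattern='assembly'``: neurons split evenly into co-active groups,
    one per state — distinct temporal states *and* crisp correlation
    blocks (strong modular structure). ``membership_mixing`` > 0 spreads
    a random Dirichlet share of each neuron's loading over the other
    assemblies, blurring the blocks.

    ``pattern='distributed'``: every state is a dense random pattern over
    all neurons. Temporal states stay well separated (population vectors
    differ across the whole population) while time-averaged pairwise
    correlations are near zero — fragmented microstates without modular
    correlation structure.

    Wake-like activity is emulated by few crisp assemblies with strong
    coupling; anesthesia-like activity by many distributed microstates.
    """
    from scipy.ndimage import gaussian_filter1d
    rng = np.random.default_rng(seed)
    states = np.empty(n_frames, dtype=int)
    states[0] = rng.integers(n_assemblies)
    for t in range(1, n_frames):
        if n_assemblies > 1 and rng.uniform() < 1.0 / dwell_frames:
            # cyclic state progression with random dwell lengths: every
            # state is visited and occupancy stays balanced
            states[t] = (states[t - 1] + 1) % n_assemblies
        else:
            states[t] = states[t - 1]
    courses = np.zeros((n_assemblies, n_frames))
    courses[states, np.arange(n_frames)] = 1.0
    courses = gaussian_filter1d(courses, sigma=2.0, axis=1)
    # activations as zero-mean deviations from the mean rate
    courses -= courses.mean(axis=1, keepdims=True)
    courses /= courses.std(axis=1, keepdims=True).clip(1e-12)
    if pattern == "assembly":
        member = np.arange(n_neurons) % n_assemblies
        weights = np.zeros((n_neurons, n_assemblies))
        weights[np.arange(n_neurons), member] = 1.0
        if membership_mixing > 0 and n_assemblies > 1:
            mix = rng.dirichlet(np.ones(n_assemblies), size=n_neurons)
            weights = ((1.0 - membership_mixing) * weights
                       + membership_mixing * mix)
    elif pattern == "distributed":
        # unit-RMS rows: per-neuron signal power matches the assembly case
        weights = rng.standard_normal((n_neurons, n_assemblies)) / np.sqrt(n_assemblies)
    else:
        raise ValueError("pattern must be 'assembly' or 'distributed'")
    M = (coupling * weights @ courses
         + noise_sd * rng.standard_normal((n_neurons, n_frames)))
    return M.T


# ---------------------------------------------------------------------------
# spine histories


def gen_spine_history(n_spines: int, n_sessions: int, seed: int,
                      p_loss: float = 0.1, p_gain: float = 0.1,
                      length_um: float = 40.0
                      ) -> tuple[PresenceTable, GroundTruth]:
    """Markov spine presence chain.

    Each initial spine survives each inter-session step with probability
    ``1 - p_loss`` and, once lost, never rejoins (a reappearing protrusion
    is a new spine by the upstream identity rule). At each later session
    ``Binomial(n_spines, p_gain)`` new spines are appended as fresh rows and
    follow the same survival process.
    """
    if not (0 <= p_loss <= 1 and 0 <= p_gain <= 1):
        raise ValueError("probabilities must be in [0, 1]")
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    rng = np.random.default_rng(seed)

    rows = []
    births = []

    def life_row(birth: int) -> np.ndarray:
        row = np.zeros(n_sessions, dtype=bool)
        alive = True
        for s in range(birth, n_sessions):
            if alive:
                row[s] = True
                if s < n_sessions - 1 and rng.uniform() < p_loss:
                    alive = False
        return row

    for _ in range(n_spines):
        rows.append(life_row(0))
        births.append(0)
    for s in range(1, n_sessions):
        for _ in range(rng.binomial(n_spines, p_gain)):
            rows.append(life_row(s))
            births.append(s)

    pres = np.array(rows, dtype=bool)
    pt = PresenceTable(pres, dendrite_length=length_um)
    gt = GroundTruth(spine_events={"births": births,
                                   "p_loss": p_loss, "p_gain": p_gain})
    return pt, gt
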