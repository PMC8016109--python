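"""Fragmentation metrics of population activity.

All metrics operate on a time x neuron matrix matched across conditions:
neurons are subsampled to the minimum count present in any compared
recording (five independent draws, median-reported) and the signal is
down-sampled from 30 to 10 Hz. Temporal structure is quantified by the
number of PCA components to 90% variance and the log-log variance-decay
slope, by density-based cluster counting of a 2-D tSNE embedding, and by
affinity-propagation exemplar counts; spatial structure by Louvain
community detection on full signed (unthresholded) correlation matrices
across a resolution-parameter scan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import AffinityPropagation
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics.pairwise import cosine_similarity

from .core_io import TraceMatrix

log = logging.getLogger("statekit")


@dataclass
class EnsembleConfig:
    n_min: int = 50
    n_reps: int = 5
    target_fs: float = 10.0
    signal_kind: str = "raw"            # 'raw' (mean-bin) | 'deconvolved' (sum-bin)
    seed: int = 0
    perplexities: tuple = tuple(range(5, 50, 5))
    tsne_grid: int = 100                # density histogram resolution
    rolling_ball_radius: int = 50   # must exceed the blob scale (bins)
    minima_depth_frac: float = 0.20

    def __post_init__(self):
        if self.n_min < 2:
            raise ValueError("n_min must be >= 2")


@dataclass
class PartitionScan:
    gammas: np.ndarray
    n_communities: np.ndarray
    modularity: np.ndarray
    partitions: list[np.ndarray] = field(default_factory=list)


def prepare_matrix(tm: TraceMatrix, cfg: EnsembleConfig) -> list[np.ndarray]:
    """``n_reps`` matched subsamples of ``n_min`` neurons, down-sampled to
    ``target_fs`` (mean over bins for raw traces, sum for deconvolved),
    returned as time x neuron matrices."""
    if tm.n_rois < cfg.n_min:
        raise ValueError(f"ROI count {tm.n_rois} < n_min {cfg.n_min}")
    rng = np.random.default_rng(cfg.seed)
    factor = int(round(tm.fs / cfg.target_fs))
    X = tm.S if (cfg.signal_kind == "deconvolved" and tm.S is not None) else tm.F
    n_bins = X.shape[1] // factor
    Xb = X[:, :n_bins * factor].reshape(X.shape[0], n_bins, factor)
    Xd = Xb.sum(axis=2) if cfg.signal_kind == "deconvolved" else Xb.mean(axis=2)
    out = []
    for _ in range(cfg.n_reps):
        cols = rng.choice(tm.n_rois, size=cfg.n_min, replace=False)
        out.append(Xd[np.sort(cols)].T.copy())
    return out


def pca_clusters(M: np.ndarray, var_target: float = 0.90,
                 max_components: int = 100) -> tuple[int, float]:
    """(number of components to 90% cumulative variance, log-log slope of
    variance explained vs component index over the first 100 components)."""
    M = np.asarray(M, dtype=float)
    if M.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    if np.allclose(M.std(axis=0), 0):
        raise ValueError("zero-variance matrix")
    pca = PCA()
    pca.fit(M)
    ev = pca.explained_variance_ratio_
    cum = np.cumsum(ev)
    n90 = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    k = min(max_components, ev.size)
    idx = np.arange(1, k + 1)
    pos = ev[:k] > 0
    slope = float(np.polyfit(np.log10(idx[pos]), np.log10(ev[:k][pos]), 1)[0])
    return n90, slope


def _count_density_clusters(xy: np.ndarray, grid: int, sd_frac: float,
                            ball_radius: int, minima_depth_frac: float) -> int:
    """Cluster count of a 2-D embedding by the image pipeline: occupancy
    histogram -> Gaussian smoothing (SD = extent/40) -> rolling-ball
    background subtraction -> 3x3 median filter -> Otsu threshold ->
    watershed with extended-maxima markers -> count of exterior objects."""
    from skimage.filters import threshold_otsu
    from skimage.morphology import h_maxima
    from skimage.restoration import rolling_ball
    from skimage.segmentation import watershed

    span = xy.max(axis=0) - xy.min(axis=0)
    if np.all(span < 1e-9):
        return 1
    H, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=grid)
    dens = ndimage.gaussian_filter(H, sigma=grid * sd_frac)
    bg = rolling_ball(dens, radius=ball_radius)
    dens = dens - bg
    dens = ndimage.median_filter(dens, size=3)
    if dens.max() <= 0:
        return 1
    try:
        thr = threshold_otsu(dens)
    except ValueError:
        return 1
    mask = dens > thr
    if not mask.any():
        return 1
    depth = minima_depth_frac * dens.max()
    markers, n_mark = ndimage.label(h_maxima(dens, depth))
    if n_mark == 0:
        markers, n_mark = ndimage.label(mask)
    labels = watershed(-dens, markers=markers, mask=mask)
    ids = np.unique(labels[labels > 0])
    if ids.size == 0:
        return 1
    # drop speckle objects carrying a negligible share of the density
    # (scattered state-transition frames produce satellite fragments)
    masses = np.array([dens[labels == i].sum() for i in ids])
    keep = masses >= 0.02 * masses.sum()
    return max(int(keep.sum()), 1)


def tsne_clusters(M: np.ndarray, cfg: EnsembleConfig) -> int:
    """Cluster count of the tSNE embedding of time points.

    The perplexity (grid 5-45, step 5) minimizing the final embedding cost
    is selected; input is pre-reduced to 30 linear components; the metric
    is Euclidean for raw traces and cosine for deconvolved signal. The 2-D
    embedding is converted to a density image and segmented (see
    :func:`_count_density_clusters`).
    """
    M = np.asarray(M, dtype=float)
    if M.shape[0] < 100:
        raise ValueError("need at least 100 time points")
    n_comp = min(30, M.shape[1], M.shape[0] - 1)
    X = PCA(n_components=n_comp, random_state=cfg.seed).fit_transform(M)
    metric = "cosine" if cfg.signal_kind == "deconvolved" else "euclidean"
    best = None
    for perp in cfg.perplexities:
        if perp >= M.shape[0]:
            continue
        ts = TSNE(n_components=2, perplexity=perp, metric=metric,
                  init="pca", random_state=cfg.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = ts.fit_transform(X)
        if best is None or ts.kl_divergence_ < best[0]:
            best = (ts.kl_divergence_, emb)
    if best is None:
        raise ValueError("no usable perplexity value")
    emb = best[1]
    if np.allclose(emb.std(axis=0), 0):
        return 1
    return _count_density_clusters(emb, cfg.tsne_grid, 1.0 / 40.0,
                                   cfg.rolling_ball_radius, cfg.minima_depth_frac)


def ap_clusters(M: np.ndarray, seed: int = 0, max_iter: int = 1000,
                damping: float = 0.9) -> tuple[int, bool]:
    """Affinity-propagation exemplar count on time points.

    Similarity = 1 - pairwise cosine distance between observations (rows);
    the input preference is the median of the similarity matrix. Returns
    (n_exemplars, converged).
    """
    M = np.asarray(M, dtype=float)
    if M.shape[0] < 10:
        raise ValueError("need at least 10 time points")
    S = cosine_similarity(M)
    pref = float(np.median(S))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ap = AffinityPropagation(affinity="precomputed", preference=pref,
                                 random_state=seed, max_iter=max_iter,
                                 damping=damping)
        labels = ap.fit_predict(S)
    converged = ap.n_iter_ < max_iter and len(ap.cluster_centers_indices_) > 0
    n = len(np.unique(labels[labels >= 0])) if converged else len(np.unique(labels))
    return max(int(n), 1), bool(converged)


# ---------------------------------------------------------------------------
# signed-modularity Louvain


def signed_modularity(W: np.ndarray, comm: np.ndarray, gamma: float = 1.0) -> float:
    """Asymmetric signed modularity.

    Positive and negative weights get separate configuration null models;
    the negative contribution is down-weighted by v-/(v+ + v-) so that
    positive structure dominates (the standard convention for
    unthresholded signed correlation networks)."""
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    out = 0.0
    vp = Wp.sum()
    vn = Wn.sum()
    for Wx, vx, sgn, norm in ((Wp, vp, 1.0, vp), (Wn, vn, -1.0, vp + vn)):
        if vx <= 0 or norm <= 0:
            continue
        k = Wx.sum(axis=1)
        q = 0.0
        for c in np.unique(comm):
            sel = comm == c
            q += Wx[np.ix_(sel, sel)].sum() - gamma * (k[sel].sum() ** 2) / vx
        out += sgn * q / norm
    return float(out)


def _louvain_one_level(W: np.ndarray, gamma: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Greedy node moves maximizing signed modularity; one Louvain level."""
    n = W.shape[0]
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    kp, kn = Wp.sum(axis=1), Wn.sum(axis=1)
    vp, vn = kp.sum(), kn.sum()
    comm = np.arange(n)
    sp = kp.copy()     # community total positive strength
    sn = kn.copy()
    coef_n = (1.0 / (vp + vn)) if (vp + vn) > 0 else 0.0
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = comm[i]
            # link weights of i to each community
            lp = np.bincount(comm, weights=Wp[i], minlength=n)
            ln = np.bincount(comm, weights=Wn[i], minlength=n)
            sp[ci] -= kp[i]
            sn[ci] -= kn[i]
            lp[ci] -= Wp[i, i]
            ln[ci] -= Wn[i, i]

            def gain(c):
                g = 0.0
                if vp > 0:
                    g += (lp[c] - gamma * kp[i] * sp[c] / vp) / vp
                if vn > 0:
                    g -= coef_n * (ln[c] - gamma * kn[i] * sn[c] / vn)
                return g

            neigh = np.unique(comm[(Wp[i] > 0) | (Wn[i] > 0)])
            cand = set(neigh.tolist()) | {ci}
            best_c, best_g = ci, gain(ci)
            for c in cand:
                g = gain(c)
                if g > best_g + 1e-12:
                    best_c, best_g = c, g
            comm[i] = best_c
            sp[best_c] += kp[i]
            sn[best_c] += kn[i]
            if best_c != ci:
                improved = True
    _, comm = np.unique(comm, return_inverse=True)
    return comm


def louvain_signed(W: np.ndarray, gamma: float = 1.0, seed: int = 0,
                   max_levels: int = 20) -> tuple[np.ndarray, float]:
    """Multi-level Louvain on a signed weight matrix; returns (partition,
    signed modularity Q)."""
    W = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    rng = np.random.default_rng(seed)
    n = W.shape[0]
    assign = np.arange(n)
    Wc = W
    for _ in range(max_levels):
        comm = _louvain_one_level(Wc, gamma, rng)
        assign = comm[assign]
        k = comm.max() + 1
        if k == Wc.shape[0]:
            break
        # aggregate
        P = np.zeros((Wc.shape[0], k))
        P[np.arange(Wc.shape[0]), comm] = 1.0
        Wc = P.T @ Wc @ P
    return assign, signed_modularity(W, assign, gamma)


def louvain_scan(corr: np.ndarray, gammas: np.ndarray | None = None,
                 n_runs: int = 10, seed: int = 0) -> PartitionScan:
    """Community count and signed modularity across the resolution scan
    gamma = 0..3 in steps of 0.1; ``n_runs`` restarts per gamma, keeping
    the max-Q partition."""
    W = np.asarray(corr, dtype=float)
    if W.shape[0] != W.shape[1] or not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("corr must be a symmetric square matrix")
    if gammas is None:
        gammas = np.round(np.arange(0.0, 3.0 + 1e-9, 0.1), 10)
    gammas = np.asarray(gammas, dtype=float)
    ncom = np.zeros(gammas.size, dtype=int)
    qs = np.zeros(gammas.size)
    parts = []
    for gi, g in enumerate(gammas):
        best = None
        for r in range(n_runs):
            part, q = louvain_signed(W, gamma=g, seed=seed * 1000 + gi * 37 + r)
            if best is None or q > best[1]:
                best = (part, q)
        parts.append(best[0])
        ncom[gi] = best[0].max() + 1
        qs[gi] = best[1]
    return PartitionScan(gammas, ncom, qs, parts)
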