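"""Cross-session field-of-view alignment and persistent neuron identities.

Alignment candidates (rigid/affine transform x mean/enhanced-mean image)
are scored by the squared intensity difference over the central part of
the field of view; the candidate with the smallest score among those
keeping >90% of the non-empty pixels in the central region wins. ROIs of
aligned sessions are then matched when their centroids lie within 3 um and
their pixel sets overlap (intersection-over-union) above 70%, and matched
chains inherit a single global neuron ID across recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .core_io import RoiSet

log = logging.getLogger("statekit")

CENTROID_MAX_UM = 3.0
OVERLAP_MIN = 0.70
CENTER_FILL_MIN = 0.90
TRUNC_FRAC = 0.10  # border cropped per side for the central region


@dataclass
class AlignmentCandidate:
    transform_kind: str                 # 'rigid' | 'affine'
    image_kind: str                     # 'mean' | 'enhanced_mean'
    d: float                            # squared-difference score, central region
    center_fill: float                  # fraction of the central region with warped data
    params: np.ndarray | None = None    # fitted transform parameters
    valid: bool = True

    @property
    def eligible(self) -> bool:
        return self.valid and self.center_fill > CENTER_FILL_MIN


@dataclass
class IdentityMap:
    table: pd.DataFrame                 # recording, roi_label, global_id, overlap, centroid_dist
    centroid_max: float = CENTROID_MAX_UM
    overlap_min: float = OVERLAP_MIN

    def persistence_matrix(self) -> pd.DataFrame:
        """global_id x recording boolean presence."""
        return (self.table.assign(present=True)
                .pivot_table(index="global_id", columns="recording",
                             values="present", aggfunc="any", fill_value=False))


def _central(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    dh, dw = int(h * TRUNC_FRAC), int(w * TRUNC_FRAC)
    return img[dh:h - dh, dw:w - dw]


def _warp(img: np.ndarray, params: np.ndarray, kind: str) -> np.ndarray:
    """Apply a parametric transform about the image center.

    rigid: (tx, ty, theta, log_scale); affine: 6-parameter matrix + shift.
    """
    h, w = img.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    if kind == "rigid":
        tx, ty, theta, ls = params
        s = np.exp(ls)
        ct, st = np.cos(theta), np.sin(theta)
        A = s * np.array([[ct, -st], [st, ct]])
        shift = np.array([ty, tx])
    elif kind == "affine":
        A = params[:4].reshape(2, 2)
        shift = params[4:][::-1]
    else:
        raise ValueError(f"unknown transform kind {kind!r}")
    # output coords -> input coords for ndimage (inverse map)
    Ainv = np.linalg.inv(A)
    offset = center - Ainv @ (center + shift)
    return ndimage.affine_transform(img, Ainv, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def _initial_params(ref: np.ndarray, mov: np.ndarray, kind: str) -> np.ndarray:
    shift, _err, _ph = phase_cross_correlation(ref, mov, upsample_factor=4)
    dy, dx = -shift  # shift to apply to mov
    if kind == "rigid":
        return np.array([-dx, -dy, 0.0, 0.0])
    return np.array([1.0, 0.0, 0.0, 1.0, -dx, -dy])


def _rigid_to_affine(p: np.ndarray) -> np.ndarray:
    tx, ty, theta, ls = p
    s = np.exp(ls)
    ct, st = np.cos(theta), np.sin(theta)
    return np.array([s * ct, -s * st, s * st, s * ct, tx, ty])


def score_alignment(ref_img: np.ndarray, moving_img: np.ndarray,
                    transform_kind: str = "rigid", image_kind: str = "mean",
                    optimize_transform: bool = True,
                    extra_starts: list[np.ndarray] | None = None
                    ) -> AlignmentCandidate:
    """Fit a transform of ``moving_img`` onto ``ref_img`` and score it.

    d = sum over the truncated central region of the squared intensity
    difference between reference and aligned image; center_fill = fraction
    of the central region still covered by warped data (a collapsed or
    diverged transform leaves it mostly empty).
    The intensity-based optimizer (Powell over the transform parameters,
    seeded by phase cross-correlation) is pluggable and non-normative.
    """
    ref = np.asarray(ref_img, dtype=float)
    mov = np.asarray(moving_img, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("images must have the same shape")

    def cost(p):
        warped = _warp(mov, p, transform_kind)
        diff = _central(ref) - _central(warped)
        return float(np.sum(diff ** 2))

    identity = (np.zeros(4) if transform_kind == "rigid"
                else np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0]))
    starts = [_initial_params(ref, mov, transform_kind), identity]
    starts += [np.asarray(s, dtype=float) for s in (extra_starts or [])]
    params = min(starts, key=cost)
    valid = True
    if optimize_transform:
        try:
            res = optimize.minimize(cost, params, method="Powell",
                                    options={"maxiter": 200, "xtol": 1e-3})
            # keep the start if the optimizer wandered to a worse point
            if np.isfinite(res.fun) and res.fun <= cost(params):
                params = res.x
        except Exception:
            valid = False
    warped = _warp(mov, params, transform_kind)
    diff = _central(ref) - _central(warped)
    d = float(np.sum(diff ** 2))
    # fraction of the central region still covered by warped data; a
    # collapsed/diverged transform leaves most of it empty
    support = _warp(np.ones_like(mov), params, transform_kind) > 0.5
    fill = float(_central(support).mean())
    return AlignmentCandidate(transform_kind, image_kind, d, fill,
                              params=np.asarray(params), valid=valid)


def align_candidates(ref: RoiSet, mov: RoiSet) -> list[AlignmentCandidate]:
    """All four transform x image combinations for a session pair.

    The affine fit is additionally seeded from the fitted rigid solution
    of the same image kind (the rigid optimum is a good affine start)."""
    out = []
    rigid_by_img: dict[str, np.ndarray] = {}
    for kind in ("rigid", "affine"):
        for img_kind, attr in (("mean", "image"), ("enhanced_mean", "enhanced_image")):
            ri, mi = getattr(ref, attr), getattr(mov, attr)
            if ri is None or mi is None:
                continue
            extra = None
            if kind == "affine" and img_kind in rigid_by_img:
                extra = [_rigid_to_affine(rigid_by_img[img_kind])]
            cand = score_alignment(ri, mi, kind, img_kind, extra_starts=extra)
            if kind == "rigid" and cand.params is not None:
                rigid_by_img[img_kind] = cand.params
            out.append(cand)
    return out


def select_best_alignment(candidates: list[AlignmentCandidate]) -> AlignmentCandidate:
    """Minimum-d candidate among those passing the >90% center-fill guard."""
    if not candidates:
        raise ValueError("no candidates")
    eligible = [c for c in candidates if c.eligible]
    if not eligible:
        raise ValueError("alignment failure: no candidate passes the center-fill guard")
    return min(eligible, key=lambda c: c.d)


# ---------------------------------------------------------------------------
# ROI matching


def match_rois(a: RoiSet, b: RoiSet, centroid_max: float = CENTROID_MAX_UM,
               overlap_min: float = OVERLAP_MIN) -> pd.DataFrame:
    """One-to-one ROI matches between two aligned sessions.

    A candidate pair must have centroid distance < ``centroid_max`` um and
    pixel intersection-over-union > ``overlap_min``. Conflicts are resolved
    greedily by descending overlap, ties by smaller centroid distance.
    Returns columns (label_a, label_b, overlap, centroid_dist).
    """
    pix_a = {l: a.pixels(l) for l in a.labels}
    pix_b = {l: b.pixels(l) for l in b.labels}
    cands = []
    for la in a.labels:
        cxa, cya = a.centroids[la]
        for lb in b.labels:
            cxb, cyb = b.centroids[lb]
            dist = np.hypot(cxa - cxb, cya - cyb)
            if dist >= centroid_max:
                continue
            inter = len(pix_a[la] & pix_b[lb])
            union = len(pix_a[la] | pix_b[lb])
            iou = inter / union if union else 0.0
            if iou > overlap_min:
                cands.append((la, lb, iou, float(dist)))
    cands.sort(key=lambda c: (-c[2], c[3]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for la, lb, iou, dist in cands:
        if la in used_a or lb in used_b:
            continue
        used_a.add(la)
        used_b.add(lb)
        rows.append({"label_a": la, "label_b": lb, "overlap": iou,
                     "centroid_dist": dist})
    return pd.DataFrame(rows, columns=["label_a", "label_b", "overlap",
                                       "centroid_dist"])


def assign_global_ids(recordings: list[RoiSet], reference_index: int = 0,
                      centroid_max: float = CENTROID_MAX_UM,
                      overlap_min: float = OVERLAP_MIN) -> IdentityMap:
    """Sequential global neuron-ID assignment across aligned recordings.

    The reference recording seeds IDs 0..N-1; every other recording is
    processed in order, each ROI compared against all already-processed
    ROIs (any earlier recording). A match inherits the global ID, otherwise
    the next fresh ID is assigned. Deterministic given the recording order;
    a global ID appears at most once within a recording.
    """
    order = [reference_index] + [i for i in range(len(recordings))
                                 if i != reference_index]
    registry: list[dict] = []   # processed ROIs: global_id, rec, pixels, centroid
    rows = []
    next_id = 0
    for rec_idx in order:
        rs = recordings[rec_idx]
        used_here: set[int] = set()
        for lab in rs.labels:
            pix = rs.pixels(lab)
            cx, cy = rs.centroids[lab]
            best = None
            for entry in registry:
                if entry["rec"] == rec_idx or entry["global_id"] in used_here:
                    continue
                dist = np.hypot(cx - entry["cx"], cy - entry["cy"])
                if dist >= centroid_max:
                    continue
                inter = len(pix & entry["pixels"])
                union = len(pix | entry["pixels"])
                iou = inter / union if union else 0.0
                if iou > overlap_min and (best is None or iou > best[1]
                                          or (iou == best[1] and dist < best[2])):
                    best = (entry["global_id"], iou, dist)
            if best is None:
                gid, iou, dist = next_id, np.nan, np.nan
                next_id += 1
            else:
                gid, iou, dist = best
            if gid in used_here:
                raise RuntimeError("duplicate global ID within one recording")
            used_here.add(gid)
            registry.append({"global_id": gid, "rec": rec_idx, "pixels": pix,
                             "cx": cx, "cy": cy})
            rows.append({"recording": rec_idx, "roi_label": lab,
                         "global_id": gid, "overlap": iou,
                         "centroid_dist": dist})
    table = pd.DataFrame(rows)
    return IdentityMap(table, centroid_max, overlap_min)
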