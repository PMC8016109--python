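"""Two-stage behavioral-state classification.

Stage 1 labels 30-s epochs (50% overlap) by percentile rules on LFP delta
power, theta/delta ratio, EMG broadband power and movement; a
distance-weighted k-NN then extends the labels to uncertain epochs,
keeping only predictions above 99% class probability. Stage 2 trains a
pupil/eyelid-feature k-NN (quantile-transformed, grid-searched) on the
stage-1 labels so the state can be read out from eye videography alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import QuantileTransformer

from .core_io import EPOCH_LEN, EPOCH_STEP, EpochSet, TimeSeries

log = logging.getLogger("statekit")

RULE_FEATURES = ["delta", "theta", "ratio", "emg", "movement"]
PUPIL_FEATURES = ["pupil_diam_max", "pupil_diam_min", "pupil_sd",
                  "pupil_area", "pupil_motion", "eyelid"]


@dataclass
class RuleThresholds:
    delta_pct: float = 70.0       # NREM: delta power above this percentile
    theta_delta_pct: float = 70.0  # REM: theta/delta ratio above this percentile
    emg_low_pct: float = 25.0     # REM: EMG below this percentile
    emg_wake_pct: float = 80.0    # wake: EMG above this percentile
    # NREM uses EMG below the median (50th percentile)


def _band_power(x: np.ndarray, fs: float, low: float, high: float) -> float:
    from scipy.signal import welch
    nper = min(x.size, int(4 * fs))
    f, p = welch(x, fs=fs, nperseg=nper)
    sel = (f >= low) & (f <= high)
    return float(np.trapezoid(p[sel], f[sel])) if sel.sum() > 1 else float(p[sel].sum())


def epoch_features(lfp: TimeSeries, emg: TimeSeries,
                   movement: np.ndarray) -> EpochSet:
    """Per-epoch scoring features over 30-s epochs starting every 15 s.

    delta = 1-4 Hz LFP power, theta = 6-12 Hz LFP power, ratio =
    theta/delta, emg = 30-300 Hz broadband EMG power, movement = any
    above-threshold motion sample in the epoch. ``movement`` is a boolean
    per-LFP-sample series.
    """
    if abs(lfp.duration - emg.duration) > 1.0 / min(lfp.fs, emg.fs):
        raise ValueError("LFP and EMG cover different durations")
    movement = np.asarray(movement).astype(bool)
    if movement.size != lfp.samples.size:
        raise ValueError("movement series must align with the LFP samples")
    if lfp.duration < 60.0:
        raise ValueError("need at least 60 s of aligned signal")
    n_epochs = int(np.floor((lfp.duration - EPOCH_LEN) / EPOCH_STEP)) + 1
    rows = []
    epochs = []
    for k in range(n_epochs):
        s = k * EPOCH_STEP
        e = s + EPOCH_LEN
        epochs.append((s, e))
        li, lj = int(s * lfp.fs), int(e * lfp.fs)
        ei, ej = int(s * emg.fs), int(e * emg.fs)
        seg_l = lfp.samples[li:lj]
        seg_e = emg.samples[ei:ej]
        delta = _band_power(seg_l, lfp.fs, 1.0, 4.0)
        theta = _band_power(seg_l, lfp.fs, 6.0, 12.0)
        emg_p = _band_power(seg_e, emg.fs, 30.0, 300.0)
        rows.append({"delta": delta, "theta": theta,
                     "ratio": theta / delta if delta > 0 else np.inf,
                     "emg": emg_p,
                     "movement": bool(movement[li:lj].any())})
    return EpochSet(epochs, pd.DataFrame(rows))


def rule_classify(epochs: EpochSet, thr: RuleThresholds | None = None) -> EpochSet:
    """Percentile-rule state labels.

    wake: EMG power above the 80th percentile OR movement;
    REM: theta/delta ratio above the 70th percentile, EMG below the 25th
    percentile, no movement;
    NREM: delta power above the 70th percentile, EMG below the median, no
    movement. Precedence wake > REM > NREM; anything else is uncertain.
    Percentiles are computed within the recording over all epochs.
    """
    thr = thr or RuleThresholds()
    f = epochs.features
    delta_hi = np.percentile(f["delta"], thr.delta_pct)
    ratio_hi = np.percentile(f["ratio"], thr.theta_delta_pct)
    emg_med = np.percentile(f["emg"], 50.0)
    emg_low = np.percentile(f["emg"], thr.emg_low_pct)
    emg_wake = np.percentile(f["emg"], thr.emg_wake_pct)
    labels = []
    for _, row in f.iterrows():
        moving = bool(row["movement"])
        if row["emg"] > emg_wake or moving:
            labels.append("wake")
        elif row["ratio"] > ratio_hi and row["emg"] < emg_low and not moving:
            labels.append("REM")
        elif row["delta"] > delta_hi and row["emg"] < emg_med and not moving:
            labels.append("NREM")
        else:
            labels.append("uncertain")
    return epochs.with_labels(labels)


def knn_extend(epochs: EpochSet, k: int = 20, n_quantiles: int = 20,
               keep_prob: float = 0.99,
               feature_cols: list[str] | None = None) -> EpochSet:
    """Extend rule labels to uncertain epochs with a distance-weighted
    k-NN on quantile-transformed features; predictions at class
    probability <= ``keep_prob`` stay uncertain. Rule-labeled epochs are
    never relabeled."""
    feature_cols = feature_cols or RULE_FEATURES
    labels = np.array(epochs.labels)
    labeled = labels != "uncertain"
    if labeled.sum() == 0:
        raise ValueError("no rule-labeled epochs to train on")
    if labeled.sum() < k:
        raise ValueError(f"need at least k={k} labeled epochs")
    X = epochs.features[feature_cols].astype(float).to_numpy()
    qt = QuantileTransformer(n_quantiles=min(n_quantiles, labeled.sum()),
                             output_distribution="uniform")
    Xq = qt.fit_transform(X)
    clf = KNeighborsClassifier(n_neighbors=k, weights="distance", leaf_size=5, p=2)
    clf.fit(Xq[labeled], labels[labeled])
    out = labels.copy()
    todo = ~labeled
    if todo.any():
        proba = clf.predict_proba(Xq[todo])
        pred = clf.classes_[np.argmax(proba, axis=1)]
        conf = proba.max(axis=1)
        accepted = conf > keep_prob
        idx = np.flatnonzero(todo)
        out[idx[accepted]] = pred[accepted]
    return epochs.with_labels(out.tolist())


# ---------------------------------------------------------------------------
# pupil pipeline


@dataclass
class PupilSeries:
    values: np.ndarray                  # e.g. eyelid opening or pupil diameter
    certainty: np.ndarray
    fs: float


def _interp_over(values: np.ndarray, bad: np.ndarray) -> np.ndarray:
    out = values.astype(float).copy()
    if bad.all():
        raise ValueError("all samples flagged; nothing to interpolate from")
    if bad.any():
        idx = np.arange(out.size)
        out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def clean_pupil_series(p: PupilSeries, certainty_min: float = 0.5,
                       mad_window_s: float = 30.0, mad_k: float = 3.0
                       ) -> PupilSeries:
    """Tracking cleanup: samples with certainty < 0.5 are linearly
    interpolated between flanking certain samples; blink dips — samples
    below the moving median minus ``mad_k`` moving MADs (30-s window) —
    are then replaced by interpolation as well."""
    vals = _interp_over(p.values, p.certainty < certainty_min)
    w = max(3, int(round(mad_window_s * p.fs)) | 1)
    movmed = ndimage.median_filter(vals, size=w, mode="reflect")
    movmad = ndimage.median_filter(np.abs(vals - movmed), size=w, mode="reflect")
    blink = vals < (movmed - mad_k * movmad)
    vals = _interp_over(vals, blink)
    cert = p.certainty.copy()
    return PupilSeries(vals, cert, p.fs)


def classify_from_pupil(features: pd.DataFrame, labels: list[str],
                        feature_cols: list[str] | None = None,
                        quantile_grid: tuple = (50, 100, 500),
                        k_grid: tuple = (5, 10), cv: int = 4,
                        n_eval_splits: int = 20, test_frac: float = 0.25,
                        seed: int = 0) -> dict:
    """Pupil/eyelid-feature state classifier.

    Quantile transform (grid of 50/100/500 quantiles) + k-NN (k in {5,10},
    uniform weights), selected by ``cv``-fold cross-validated macro F1;
    per-class accuracy from repeated stratified 75/25 splits. Classes
    absent from the training labels are reported as unpredictable.
    """
    feature_cols = feature_cols or [c for c in PUPIL_FEATURES
                                    if c in features.columns]
    y = np.asarray(labels)
    keep = y != "uncertain"
    X = features.loc[keep, feature_cols].astype(float).to_numpy()
    y = y[keep]
    classes, counts = np.unique(y, return_counts=True)
    n = len(y)
    pipe = Pipeline([
        ("qt", QuantileTransformer(output_distribution="uniform")),
        ("knn", KNeighborsClassifier(weights="uniform", leaf_size=1, p=2)),
    ])
    max_q = max(2, int(n * min((cv - 1) / cv, 1 - test_frac)))
    grid = {"qt__n_quantiles": sorted({min(q, max_q) for q in quantile_grid}),
            "knn__n_neighbors": [k for k in k_grid if k < n]}
    gs = GridSearchCV(pipe, grid, scoring="f1_macro", cv=cv)
    gs.fit(X, y)

    per_class = {c: [] for c in classes}
    cm_total = np.zeros((len(classes), len(classes)), dtype=int)
    splitter = StratifiedShuffleSplit(n_splits=n_eval_splits,
                                      test_size=test_frac, random_state=seed)
    for tr, te in splitter.split(X, y):
        est = gs.best_estimator_
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        cm = confusion_matrix(y[te], pred, labels=classes)
        cm_total += cm
        for ci, c in enumerate(classes):
            if cm[ci].sum() > 0:
                per_class[c].append(cm[ci, ci] / cm[ci].sum())
    acc = {c: (float(np.mean(v)) if v else float("nan"))
           for c, v in per_class.items()}
    est = gs.best_estimator_.fit(X, y)
    return {"classifier": est, "best_params": gs.best_params_,
            "classes": classes.tolist(), "per_class_accuracy": acc,
            "confusion_matrix": cm_total,
            "unpredictable": [s for s in ("wake", "NREM", "REM")
                              if s not in classes]}
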