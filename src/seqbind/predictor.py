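"""Random-Forest regression of binding enrichment from k-mer composition.

A forest of CART regression trees is trained on the per-window frequencies
of reverse-complement-collapsed k-mers (GC% alone stands in for all four
mononucleotides, which are mutually constrained by strand symmetry) against
a continuous per-window enrichment target. The regressor doubles as a
binding classifier by thresholding its prediction; classification is scored
against peak calls by ROC, with the operating point fixed where false
positive and false negative rates are equal (EER).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .tracks import FeatureTable, MaskTrack, SignalTrack


@dataclass
class TrainingSet:
    window_ids: np.ndarray  # flat bin indices into the feature grid
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    seed: int


@dataclass
class RFModel:
    estimator: RandomForestRegressor
    feature_names: list[str]
    seed: int
    train_r: float  # training-set predicted-vs-actual Pearson r


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    eer_threshold: float
    eer_accuracy: float
    n_pos: int
    n_neg: int


@dataclass
class ImportanceTable:
    frame: pd.DataFrame  # feature, importance
    method: str


def build_training_set(
    features: FeatureTable,
    target: SignalTrack,
    mask: MaskTrack | None = None,
    k_set=(1, 2),
    n: int = 10_000,
    seed: int = 0,
) -> TrainingSet:
    """Seeded uniform sample of eligible windows, without replacement."""
    X_all, names = features.predictor_matrix(k_set)
    ok = features.defined & target.defined & np.isfinite(X_all).all(axis=1)
    if mask is not None:
        ok &= ~mask.values
    eligible = np.flatnonzero(ok)
    if eligible.size < n:
        raise ValueError(f"only {eligible.size} eligible windows, need {n}")
    rng = np.random.default_rng(seed)
    ids = np.sort(rng.choice(eligible, size=n, replace=False))
    return TrainingSet(ids, X_all[ids], target.values[ids], names, seed)


def train_regressor(
    ts: TrainingSet, n_trees: int = 100, max_depth: int = 6, seed: int = 0
) -> RFModel:
    """Fit the forest; depth is kept in the 3..8 robustness range."""
    if not (3 <= max_depth <= 8):
        raise ValueError("max_depth must be in [3, 8]")
    if len(ts.y) == 0:
        raise ValueError("empty training set")
    if np.std(ts.y) == 0:
        raise ValueError("constant target")
    est = RandomForestRegressor(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed, n_jobs=1
    )
    est.fit(ts.X, ts.y)
    pred = est.predict(ts.X)
    r = float(np.corrcoef(pred, ts.y)[0, 1])
    return RFModel(est, ts.feature_names, seed, r)


def window_peak_labels(
    grid, peaks: pd.DataFrame, overlap_min: int = 50
) -> np.ndarray:
    """True for windows overlapping any peak by at least ``overlap_min`` bp."""
    labels = np.zeros(grid.n_bins, dtype=bool)
    W = grid.width
    for chrom, sub in peaks.groupby("chrom", sort=False):
        if chrom not in grid.chroms:
            continue
        ci = grid.chroms.index(chrom)
        nb = grid.n_bins_per_chrom[ci]
        starts = grid.bin_starts(chrom)
        ov = np.zeros(nb)
        for s, e in zip(sub["start"], sub["end"]):
            lo = np.maximum(starts, int(s))
            hi = np.minimum(starts + W, int(e))
            ov = np.maximum(ov, hi - lo)
        labels[grid.chrom_slice(chrom)] = ov >= overlap_min
    return labels


def classify_and_roc(
    model: RFModel,
    features: FeatureTable,
    peaks: pd.DataFrame,
    mask: MaskTrack | None = None,
    k_set=(1, 2),
    overlap_min: int = 50,
    exclude_ids: np.ndarray | None = None,
) -> ROCResult:
    """ROC of thresholded predictions against peak-overlap labels.

    Evaluation windows are all defined, unmasked windows minus
    ``exclude_ids`` (typically the training sample). AUC is the trapezoid
    integral; the equal-error-rate accuracy is 1 - FPR at the threshold
    where FPR = FNR (linearly interpolated along the curve).
    """
    X_all, _ = features.predictor_matrix(k_set)
    ok = features.defined & np.isfinite(X_all).all(axis=1)
    if mask is not None:
        ok &= ~mask.values
    if exclude_ids is not None:
        ok[exclude_ids] = False
    ids = np.flatnonzero(ok)
    labels = window_peak_labels(features.grid, peaks, overlap_min)[ids]
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"degenerate labels: {n_pos} positive, {n_neg} negative")
    scores = model.estimator.predict(X_all[ids])
    fpr, tpr, thr = roc_curve(labels, scores)
    roc_auc = float(_trapezoid_auc(fpr, tpr))
    fnr = 1.0 - tpr
    # FPR - FNR is monotone non-decreasing along the curve; find the sign change
    diff = fpr - fnr
    k = int(np.searchsorted(diff, 0.0))
    if k == 0:
        eer_fpr, eer_thr = fpr[0], thr[0]
    elif k >= len(diff):
        eer_fpr, eer_thr = fpr[-1], thr[-1]
    else:
        w = -diff[k - 1] / (diff[k] - diff[k - 1]) if diff[k] != diff[k - 1] else 0.0
        eer_fpr = fpr[k - 1] + w * (fpr[k] - fpr[k - 1])
        eer_thr = thr[k - 1] + w * (thr[k] - thr[k - 1])
    return ROCResult(fpr, tpr, thr, roc_auc, float(eer_thr), float(1.0 - eer_fpr), n_pos, n_neg)


def _depth_importances(est: RandomForestRegressor, n_features: int) -> np.ndarray:
    """Importance from the average relative depth of each feature's splits.

    Splits near the root carry more weight: every split on feature f adds
    ``1 - depth/tree_depth``. Features never used score 0. Normalized to
    sum to 1.
    """
    imp = np.zeros(n_features)
    for tree in est.estimators_:
        t = tree.tree_
        depth = np.zeros(t.node_count, dtype=int)
        stack = [(0, 0)]
        while stack:
            node, d = stack.pop()
            depth[node] = d
            if t.children_left[node] != -1:
                stack.append((t.children_left[node], d + 1))
                stack.append((t.children_right[node], d + 1))
        max_d = depth.max()
        if max_d == 0:
            continue
        internal = t.children_left != -1
        for node in np.flatnonzero(internal):
            imp[t.feature[node]] += 1.0 - depth[node] / max_d
    s = imp.sum()
    return imp / s if s > 0 else imp


def feature_importance(model: RFModel, method: str = "depth") -> ImportanceTable:
    """Per-feature importances, normalized to sum to 1.

    ``depth`` weights each split by its closeness to the root (the field's
    tree-depth heuristic); ``impurity`` is the standard mean decrease in
    impurity from the fitted ensemble.
    """
    n = len(model.feature_names)
    if method == "depth":
        imp = _depth_importances(model.estimator, n)
    elif method == "impurity":
        imp = model.estimator.feature_importances_
    else:
        raise ValueError("method must be 'depth' or 'impurity'")
    df = pd.DataFrame({"feature": model.feature_names, "importance": imp})
    df = df.sort_values("importance", ascending=False).reset_index(drop=True)
    return ImportanceTable(df, method)
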