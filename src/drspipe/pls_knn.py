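"""PLS feature extraction and weighted-KNN classification.

Reflectance matrices are first rescaled per wavelength to [−1, +1], then
reduced to a small number of partial-least-squares components (PLSCs)
fitted against the class coding {mucosa: −1, tumor: +1}.  Classification
in score space uses a weighted k-nearest-neighbors vote (k = 10,
squared-inverse-distance weights) evaluated with a 2-fold × 20-iteration
cross-validation protocol; by default the scaling and the PLSCs are
fitted once on the full dataset before cross-validation (the protocol
this pipeline replicates), with an optional leakage-free mode that
refits both inside each training fold.

Reported metrics: sensitivity (tumor positive), specificity, accuracy —
in percent, mean ± SD over the 20 iterations — and the rank-based AUC of
the KNN tumor posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import roc_auc_score

from .band_selection import BandSet, restrict_dataset
from .spectra import LabeledSpectraSet

__all__ = [
    "ScalingParams",
    "PLSModel",
    "ClassificationReport",
    "fit_scaling",
    "apply_scaling",
    "fit_pls",
    "project",
    "select_n_components",
    "knn_predict",
    "confusion_metrics",
    "cross_validate",
]

POSITIVE = "tumor"   # positive class throughout
Y_CODING = {"mucosa": -1.0, "tumor": 1.0}


@dataclass(frozen=True)
class ScalingParams:
    """Per-wavelength observed min/max used for the [−1, +1] rescaling."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.maxs < self.mins):
            raise ValueError("max must be >= min per column")


def fit_scaling(X: np.ndarray) -> ScalingParams:
    """Record per-column min and max of the fitting data."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 rows")
    return ScalingParams(mins=X.min(axis=0), maxs=X.max(axis=0))


def apply_scaling(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Map each column to [−1, +1]: x' = 2(x − min)/(max − min) − 1.

    Columns that were constant in the fitting data map to 0.
    """
    X = np.asarray(X, dtype=float)
    span = params.maxs - params.mins
    out = np.zeros_like(X)
    nz = span > 0
    out[:, nz] = 2.0 * (X[:, nz] - params.mins[nz]) / span[nz] - 1.0
    return out


@dataclass
class PLSModel:
    """Fitted single-response PLS: weights, loadings, scores, rotation."""

    n_components: int
    weights: np.ndarray     # (n_wavelengths, k)
    loadings: np.ndarray    # (n_wavelengths, k)
    scores: np.ndarray      # (n_sites, k)
    rotations: np.ndarray   # (n_wavelengths, k): X_c @ rotations = scores
    x_mean: np.ndarray
    wavelengths: np.ndarray | None = None
    y_coding: dict = field(default_factory=lambda: dict(Y_CODING))


def _code_labels(labels: np.ndarray) -> np.ndarray:
    return np.array([Y_CODING[l] for l in labels], dtype=float)


def fit_pls(X_scaled: np.ndarray, labels: np.ndarray, n_components: int,
            wavelengths: np.ndarray | None = None) -> PLSModel:
    """Fit single-response PLS of the scaled matrix against coded labels.

    NIPALS with iterative deflation; the first weight vector is
    proportional to the covariance of centered X with the coded response.
    """
    X_scaled = np.asarray(X_scaled, dtype=float)
    y = _code_labels(np.asarray(labels, dtype=object))
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present")
    rank = int(np.linalg.matrix_rank(X_scaled - X_scaled.mean(axis=0)))
    if n_components < 1 or n_components > rank:
        raise ValueError(f"n_components must be in [1, rank={rank}]")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X_scaled, y)
    return PLSModel(
        n_components=n_components,
        weights=pls.x_weights_.copy(),
        loadings=pls.x_loadings_.copy(),
        scores=pls.x_scores_.copy(),
        rotations=pls.x_rotations_.copy(),
        x_mean=pls._x_mean.copy(),
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
    )


def project(model: PLSModel, X_scaled: np.ndarray) -> np.ndarray:
    """Project (scaled) spectra into the model's score space."""
    X_scaled = np.asarray(X_scaled, dtype=float)
    if X_scaled.shape[1] != model.x_mean.size:
        raise ValueError(
            f"column mismatch: model expects {model.x_mean.size}, got {X_scaled.shape[1]}"
        )
    return (X_scaled - model.x_mean) @ model.rotations


def knn_predict(train_scores: np.ndarray, train_labels: np.ndarray,
                query_scores: np.ndarray, k: int = 10) -> np.ndarray:
    """Weighted KNN posterior P(tumor) per query point.

    Euclidean distance in score space; each of the k nearest neighbors
    votes with weight 1/d².  A zero-distance neighbor dominates: the
    posterior is then the tumor fraction among the zero-distance
    neighbors.  Ties in the posterior break toward tumor downstream.
    """
    train_scores = np.atleast_2d(np.asarray(train_scores, dtype=float))
    query_scores = np.atleast_2d(np.asarray(query_scores, dtype=float))
    train_labels = np.asarray(train_labels, dtype=object)
    n_train = train_scores.shape[0]
    if k > n_train:
        raise ValueError(f"k={k} exceeds n_train={n_train}")
    is_tumor = (train_labels == POSITIVE).astype(float)
    d = cdist(query_scores, train_scores)
    posteriors = np.empty(query_scores.shape[0])
    for i, drow in enumerate(d):
        nn = np.argpartition(drow, k - 1)[:k]
        dn = drow[nn]
        zero = dn == 0.0
        if zero.any():
            posteriors[i] = is_tumor[nn[zero]].mean()
            continue
        w = 1.0 / dn**2
        posteriors[i] = float(np.sum(w * is_tumor[nn]) / np.sum(w))
    return posteriors


def predicted_labels(posteriors: np.ndarray) -> np.ndarray:
    """Posterior >= 0.5 -> tumor (ties favor the positive class)."""
    return np.where(np.asarray(posteriors) >= 0.5, "tumor", "mucosa").astype(object)


def confusion_metrics(true_labels: np.ndarray, pred_labels: np.ndarray,
                      posteriors: np.ndarray) -> dict:
    """Sensitivity/specificity/accuracy in percent plus rank-based AUC."""
    true_labels = np.asarray(true_labels, dtype=object)
    pred_labels = np.asarray(pred_labels, dtype=object)
    pos = true_labels == POSITIVE
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present in the true labels")
    tp = np.sum(pos & (pred_labels == POSITIVE))
    fn = np.sum(pos & (pred_labels != POSITIVE))
    tn = np.sum(~pos & (pred_labels != POSITIVE))
    fp = np.sum(~pos & (pred_labels == POSITIVE))
    auc = float(roc_auc_score(pos.astype(int), np.asarray(posteriors, dtype=float)))
    return {
        "sensitivity": 100.0 * tp / (tp + fn),
        "specificity": 100.0 * tn / (tn + fp),
        "accuracy": 100.0 * (tp + tn) / pos.size,
        "auc": auc,
    }


def increment_rule(accuracies, threshold: float = 2.0) -> int:
    """Smallest k whose next component adds < threshold accuracy points."""
    accs = list(accuracies)
    for k in range(1, len(accs)):
        if accs[k] - accs[k - 1] < threshold:
            return k
    return len(accs)


def select_n_components(X_scaled: np.ndarray, labels: np.ndarray,
                        threshold: float = 2.0, max_k: int = 10,
                        k_nn: int = 10, iterations: int = 5,
                        seed: int = 0) -> int:
    """Accuracy-increment rule for the PLSC count.

    Cross-validated accuracy acc(k) is computed for k = 1..max_k with the
    2-fold protocol; the smallest k with acc(k+1) − acc(k) < threshold
    (percentage points) is returned.  The default pipeline bypasses this
    rule and fixes k = 4.
    """
    labels = np.asarray(labels, dtype=object)
    rank = int(np.linalg.matrix_rank(X_scaled - X_scaled.mean(axis=0)))
    max_k = min(max_k, rank)
    accs = []
    for k in range(1, max_k + 1):
        model = fit_pls(X_scaled, labels, k)
        accs.append(_cv_scores(model.scores, labels, k_nn, iterations, seed)["accuracy"][0])
    return increment_rule(accs, threshold)


@dataclass
class ClassificationReport:
    """Cross-validated performance: mean ± SD over the CV iterations."""

    sensitivity: tuple
    specificity: tuple
    accuracy: tuple
    auc: tuple
    per_iteration: pd.DataFrame
    band_set: BandSet | None = None
    probe: str | None = None
    n_components: int = 4
    k_nn: int = 10

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "accuracy"):
            m, s = getattr(self, name)
            if not (0.0 <= m <= 100.0) or s < 0:
                raise ValueError(f"{name} mean/SD out of range")
        m, s = self.auc
        if not (0.0 <= m <= 1.0) or s < 0:
            raise ValueError("auc mean/SD out of range")

    def to_row(self) -> dict:
        bands = ("all" if self.band_set is None
                 else "; ".join(f"{lo:g}-{hi:g} nm" for lo, hi in self.band_set.intervals))
        out = {"bands": bands, "probe": self.probe}
        for name in ("sensitivity", "specificity", "accuracy", "auc"):
            m, s = getattr(self, name)
            out[name] = m
            out[f"{name}_sd"] = s
        return out


def _stratified_halves(labels: np.ndarray, rng: np.random.Generator):
    """Randomly split indices into two halves, stratified by class."""
    a_idx, b_idx = [], []
    for cls in ("mucosa", "tumor"):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        half = idx.size // 2
        a_idx.append(idx[:half])
        b_idx.append(idx[half:])
    return np.concatenate(a_idx), np.concatenate(b_idx)


def _fold_metrics(train_scores, train_labels, test_scores, test_labels, k_nn):
    post = knn_predict(train_scores, train_labels, test_scores, k=k_nn)
    return confusion_metrics(test_labels, predicted_labels(post), post)


def _cv_scores(scores: np.ndarray, labels: np.ndarray, k_nn: int,
               iterations: int, seed: int) -> dict:
    """2-fold x N iterations on precomputed scores; mean ± SD per metric."""
    rng = np.random.default_rng(seed)
    records = []
    for it in range(iterations):
        a, b = _stratified_halves(labels, rng)
        m1 = _fold_metrics(scores[a], labels[a], scores[b], labels[b], k_nn)
        m2 = _fold_metrics(scores[b], labels[b], scores[a], labels[a], k_nn)
        rec = {k: 0.5 * (m1[k] + m2[k]) for k in m1}
        rec["iteration"] = it
        records.append(rec)
    df = pd.DataFrame(records)
    out = {k: (float(df[k].mean()), float(df[k].std(ddof=1)))
           for k in ("sensitivity", "specificity", "accuracy", "auc")}
    out["per_iteration"] = df
    return out


def cross_validate(dataset: LabeledSpectraSet, bands: BandSet | None = None,
                   n_components: int = 4, k_nn: int = 10, iterations: int = 20,
                   seed: int = 0, leakage_free: bool = False) -> ClassificationReport:
    """Run the full PLS-KNN protocol on one dataset and band set.

    Default protocol: restrict to the bands, fit the [−1, +1] scaling and
    the PLSCs once on the entire dataset, then repeat ``iterations``
    random stratified equal-half splits; per iteration, KNN is trained on
    each half's scores and evaluated on the other, and the two folds'
    metrics are averaged.  With ``leakage_free=True`` the scaling and PLS
    are refit inside each training fold instead.
    """
    dataset.require_both_classes()
    if bands is not None:
        dataset = restrict_dataset(dataset, bands)
    X, labels = dataset.spectra, dataset.labels

    if not leakage_free:
        params = fit_scaling(X)
        Xs = apply_scaling(X, params)
        model = fit_pls(Xs, labels, n_components, wavelengths=dataset.wavelengths)
        res = _cv_scores(model.scores, labels, k_nn, iterations, seed)
    else:
        rng = np.random.default_rng(seed)
        records = []
        for it in range(iterations):
            a, b = _stratified_halves(labels, rng)
            rec = {}
            for train, test in ((a, b), (b, a)):
                params = fit_scaling(X[train])
                m = fit_pls(apply_scaling(X[train], params), labels[train], n_components)
                fold = _fold_metrics(m.scores, labels[train],
                                     project(m, apply_scaling(X[test], params)),
                                     labels[test], k_nn)
                for k, v in fold.items():
                    rec[k] = rec.get(k, 0.0) + 0.5 * v
            rec["iteration"] = it
            records.append(rec)
        df = pd.DataFrame(records)
        res = {k: (float(df[k].mean()), float(df[k].std(ddof=1)))
               for k in ("sensitivity", "specificity", "accuracy", "auc")}
        res["per_iteration"] = df

    return ClassificationReport(
        sensitivity=res["sensitivity"], specificity=res["specificity"],
        accuracy=res["accuracy"], auc=res["auc"],
        per_iteration=res["per_iteration"], band_set=bands,
        probe=dataset.probe, n_components=n_components, k_nn=k_nn,
    )
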