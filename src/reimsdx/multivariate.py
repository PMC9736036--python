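"""PC-LDA modelling of binned REIMS spectra.

The classifier is linear discriminant analysis fitted in the space of the
leading principal components of the mean-centred feature matrix (PC-LDA):
PCA absorbs the rank deficiency of a 4000-bin matrix with ~10² samples, and
the two-class LDA direction w = S_w⁻¹(μ_cancer − μ_normal) (pooled
within-class covariance S_w, equal priors) gives a single discriminant
axis. Validation is leave-one-patient-out (LOPO): every fold holds out all
samples of one patient and refits PCA *and* LDA from scratch on the rest,
so no patient ever contributes to the model that scores it.

Conventions:

* cancer is the positive class throughout (sensitivity = cancer recall);
* predicted label is the nearer class mean along the discriminant axis,
  with ties broken toward "normal" (favouring specificity);
* PCA component signs are fixed (largest-magnitude loading positive) so
  results are reproducible across linear-algebra backends;
* "auto" PC selection keeps the smallest number of components explaining
  ≥95% of variance, capped at n_samples − 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .preprocessing import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PCAModel",
    "PCLDAModel",
    "ConfusionTable",
    "CVMetrics",
    "fit_pca",
    "fit_pclda",
    "predict_sample",
    "cross_validate_lopo",
    "metrics_from_confusion",
    "learning_curve",
]

NEGATIVE_CLASS = "normal"
POSITIVE_CLASS = "cancer"


@dataclass
class PCAModel:
    mean_vector: np.ndarray
    loadings: np.ndarray  # components × bins, orthonormal rows
    explained_variance_pct: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean_vector) @ self.loadings.T


@dataclass
class PCLDAModel:
    pca: PCAModel
    n_pcs_used: int
    lda_direction: np.ndarray  # vector in PC space
    class_means: dict[str, float]  # class → position on discriminant axis
    class_labels: tuple[str, str] = (NEGATIVE_CLASS, POSITIVE_CLASS)
    threshold: float = 0.0  # decision point on the discriminant axis
    ridge_used: bool = False

    def discriminant_scores(self, X: np.ndarray) -> np.ndarray:
        scores = self.pca.transform(X)[:, : self.n_pcs_used]
        return scores @ self.lda_direction


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    out = loadings.copy()
    for i in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[i])))
        if out[i, j] < 0:
            out[i] = -out[i]
    return out


def fit_pca(M: FeatureMatrix | np.ndarray, n_components: int) -> PCAModel:
    """Mean-centred PCA with a deterministic sign convention."""
    X = M.X if isinstance(M, FeatureMatrix) else np.asarray(M, dtype=float)
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if not (1 <= n_components <= max_comp):
        raise ValueError(f"n_components must be in [1, {max_comp}], got {n_components}")
    sk = _SKPCA(n_components=n_components, svd_solver="full").fit(X)
    return PCAModel(
        mean_vector=sk.mean_,
        loadings=_fix_signs(sk.components_),
        explained_variance_pct=100.0 * sk.explained_variance_ratio_,
    )


def _pooled_lda_direction(
    scores: np.ndarray, y: np.ndarray, ridge: float = 1e-6
) -> tuple[np.ndarray, bool]:
    """w = S_w⁻¹ (μ₊ − μ₋) with a ridge fallback on singular S_w."""
    pos = scores[y]
    neg = scores[~y]
    n, d = scores.shape
    sw = (
        (pos - pos.mean(axis=0)).T @ (pos - pos.mean(axis=0))
        + (neg - neg.mean(axis=0)).T @ (neg - neg.mean(axis=0))
    ) / max(n - 2, 1)
    delta = pos.mean(axis=0) - neg.mean(axis=0)
    try:
        # reject numerically singular systems, not just exactly singular ones
        if np.linalg.cond(sw) > 1e10:
            raise np.linalg.LinAlgError("ill-conditioned within-class covariance")
        return np.linalg.solve(sw, delta), False
    except np.linalg.LinAlgError:
        reg = ridge * np.trace(sw) / d
        if reg <= 0:
            reg = ridge
        logger.info("singular within-class covariance: adding ridge %.3g", reg)
        return np.linalg.solve(sw + reg * np.eye(d), delta), True


def fit_pclda(
    M: FeatureMatrix,
    n_pcs: int | str = "auto",
    priors: str = "equal",
    variance_target: float = 95.0,
) -> PCLDAModel:
    """Fit PCA then a two-class LDA on the leading PC scores.

    ``n_pcs="auto"`` keeps the smallest number of components explaining
    ``variance_target`` percent of variance, capped at n_samples − 2.
    ``priors`` is "equal" (default; the class imbalance does not shift the
    boundary) or "frequency".
    """
    labels = np.asarray(M.labels)
    classes = set(labels.tolist())
    if not classes <= {NEGATIVE_CLASS, POSITIVE_CLASS}:
        raise ValueError(f"PC-LDA is binary (normal vs cancer); got labels {sorted(classes)}")
    y = labels == POSITIVE_CLASS
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("each class needs at least 2 samples")

    cap = max(1, min(M.n_samples - 2, M.n_bins))
    pca = fit_pca(M, cap)
    if n_pcs == "auto":
        cum = np.cumsum(pca.explained_variance_pct)
        k = int(np.searchsorted(cum, variance_target) + 1)
        k = min(k, cap)
    else:
        k = int(n_pcs)
        if not (1 <= k <= cap):
            raise ValueError(f"n_pcs must be in [1, {cap}], got {k}")
    scores = pca.transform(M.X)[:, :k]
    w, ridge_used = _pooled_lda_direction(scores, y)

    proj = scores @ w
    mean_pos = float(proj[y].mean())
    mean_neg = float(proj[~y].mean())
    threshold = 0.5 * (mean_pos + mean_neg)
    if priors == "frequency":
        # LDA log-prior shift along the discriminant axis
        gap = mean_pos - mean_neg
        if abs(gap) > 0:
            threshold += math.log(n_neg / n_pos) * float(
                np.var(proj[y], ddof=1) * (n_pos - 1) + np.var(proj[~y], ddof=1) * (n_neg - 1)
            ) / ((len(proj) - 2) * gap)
    elif priors != "equal":
        raise ValueError("priors must be 'equal' or 'frequency'")

    return PCLDAModel(
        pca=pca, n_pcs_used=k, lda_direction=w,
        class_means={POSITIVE_CLASS: mean_pos, NEGATIVE_CLASS: mean_neg},
        threshold=threshold, ridge_used=ridge_used,
    )


def predict_sample(model: PCLDAModel, x: np.ndarray) -> tuple[str, float]:
    """Classify one binned vector; returns (label, discriminant score).

    The score is the signed position relative to the decision threshold
    (positive ⇒ cancer side); an exact tie goes to "normal".
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != model.pca.mean_vector.size:
        raise ValueError(
            f"expected a vector of length {model.pca.mean_vector.size}, got shape {x.shape}"
        )
    raw = float(model.discriminant_scores(x[None, :])[0])
    sign = 1.0 if model.class_means[POSITIVE_CLASS] >= model.class_means[NEGATIVE_CLASS] else -1.0
    score = sign * (raw - model.threshold)
    label = POSITIVE_CLASS if score > 0 else NEGATIVE_CLASS
    return label, score


@dataclass(frozen=True)
class ConfusionTable:
    """Counts with cancer as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class CVMetrics:
    """Diagnostic percentages; undefined ratios are NaN, never 0."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


def metrics_from_confusion(c: ConfusionTable) -> CVMetrics:
    if c.total == 0:
        raise ValueError("empty confusion table")

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else float("nan")

    return CVMetrics(
        sensitivity=pct(c.tp, c.tp + c.fn),
        specificity=pct(c.tn, c.tn + c.fp),
        ppv=pct(c.tp, c.tp + c.fp),
        npv=pct(c.tn, c.tn + c.fn),
        accuracy=pct(c.tp + c.tn, c.total),
    )


def _confusion_from_predictions(truth: Sequence[str], predicted: Sequence[str]) -> ConfusionTable:
    tp = sum(1 for t, p in zip(truth, predicted) if t == POSITIVE_CLASS and p == POSITIVE_CLASS)
    fn = sum(1 for t, p in zip(truth, predicted) if t == POSITIVE_CLASS and p == NEGATIVE_CLASS)
    fp = sum(1 for t, p in zip(truth, predicted) if t == NEGATIVE_CLASS and p == POSITIVE_CLASS)
    tn = sum(1 for t, p in zip(truth, predicted) if t == NEGATIVE_CLASS and p == NEGATIVE_CLASS)
    return ConfusionTable(tp, fn, fp, tn)


def cross_validate_lopo(
    M: FeatureMatrix, n_pcs: int | str = "auto", priors: str = "equal"
) -> tuple[ConfusionTable, CVMetrics, pd.DataFrame]:
    """Leave-one-patient-out cross-validation of the PC-LDA model.

    Every fold drops all samples of one patient, refits PCA + LDA on the
    remainder, and scores the held-out samples. The aggregated confusion
    table covers every evaluated sample exactly once.
    """
    labels = np.asarray(M.labels)
    patients = np.asarray(M.patient_ids)
    sample_ids = np.asarray(M.sample_ids)
    rows: list[dict] = []
    for patient in pd.unique(patients):
        held = patients == patient
        train = M.subset(~held)
        # leakage guard: the held-out patient must be absent from training
        assert patient not in set(train.patient_ids), "patient leakage in LOPO fold"
        assert not (set(sample_ids[held]) & set(train.sample_ids)), "sample leakage in LOPO fold"
        train_classes = set(train.labels)
        if not {NEGATIVE_CLASS, POSITIVE_CLASS} <= train_classes:
            raise ValueError(
                f"LOPO fold for patient {patient!r} leaves training set without both classes"
            )
        model = fit_pclda(train, n_pcs=n_pcs, priors=priors)
        for i in np.flatnonzero(held):
            pred, score = predict_sample(model, M.X[i])
            rows.append({
                "sample_id": sample_ids[i],
                "patient_id": patient,
                "truth": labels[i],
                "predicted": pred,
                "score": score,
            })
    preds = pd.DataFrame(rows)
    confusion = _confusion_from_predictions(preds["truth"], preds["predicted"])
    return confusion, metrics_from_confusion(confusion), preds


def learning_curve(
    M: FeatureMatrix,
    start_per_class: int = 5,
    step: int = 1,
    max_per_class: int = 32,
    n_iterations: int = 20,
    seed: int = 0,
    n_pcs: int | str = "auto",
) -> pd.DataFrame:
    """Resampled learning curve: accuracy vs training-set size.

    For each k from ``start_per_class`` to ``max_per_class`` (inclusive),
    the cohort is randomly partitioned ``n_iterations`` times: k patients
    per class train a PC-LDA model and all remaining samples are tested.
    Returns one row per k with mean and SD of accuracy, sensitivity and
    specificity over the iterations.
    """
    labels = np.asarray(M.labels)
    patients = np.asarray(M.patient_ids)
    pos_patients = pd.unique(patients[labels == POSITIVE_CLASS])
    neg_patients = pd.unique(patients[labels == NEGATIVE_CLASS])
    smallest = min(len(pos_patients), len(neg_patients))
    if max_per_class >= smallest:
        raise ValueError(
            f"max_per_class={max_per_class} must be < smallest class size ({smallest}) "
            "so the test set is never empty"
        )
    rng_root = np.random.SeedSequence(seed)
    ks = list(range(start_per_class, max_per_class + 1, step))
    records = []
    for k, child in zip(ks, rng_root.spawn(len(ks))):
        rng = np.random.default_rng(child)
        accs, senss, specs = [], [], []
        for _ in range(n_iterations):
            train_pos = rng.choice(pos_patients, size=k, replace=False)
            train_neg = rng.choice(neg_patients, size=k, replace=False)
            train_set = set(train_pos) | set(train_neg)
            in_train = np.array([p in train_set for p in patients])
            model = fit_pclda(M.subset(in_train), n_pcs=n_pcs)
            test_idx = np.flatnonzero(~in_train)
            predicted = [predict_sample(model, M.X[i])[0] for i in test_idx]
            conf = _confusion_from_predictions(labels[test_idx], predicted)
            met = metrics_from_confusion(conf)
            accs.append(met.accuracy)
            senss.append(met.sensitivity)
            specs.append(met.specificity)
        records.append({
            "k_per_class": k,
            "mean_accuracy": float(np.mean(accs)),
            "sd_accuracy": float(np.std(accs, ddof=1)),
            "mean_sensitivity": float(np.mean(senss)),
            "sd_sensitivity": float(np.std(senss, ddof=1)),
            "mean_specificity": float(np.mean(specs)),
            "sd_specificity": float(np.std(specs, ddof=1)),
        })
    return pd.DataFrame.from_records(records)
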