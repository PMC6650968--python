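"""Emotion classification: z-score normalization, SVD-based PCA, Gaussian
discriminant classifiers, stratified cross-validation and agreement metrics.

The normalization and PCA models are always fitted on training data only
and re-applied to validation data.  All Gaussian classifiers are closed
form; the linear SVM delegates to scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CLASSIFIER_KINDS",
    "NormalizationModel",
    "PCAModel",
    "ClassifierModel",
    "EvaluationResult",
    "fit_normalization",
    "apply_normalization",
    "fit_pca",
    "project",
    "fit_classifier",
    "predict",
    "confusion_and_metrics",
    "stratified_folds",
    "cross_validate",
]

CLASSIFIER_KINDS = (
    "lda_full",
    "lda_diag",
    "qda_full",
    "qda_diag",
    "mahalanobis",
    "naive_bayes",
    "linear_svm",
)

#: ridge added to covariance diagonals, as a fraction of mean eigenvalue
COV_EPSILON = 1e-6


# ---------------------------------------------------------------------------
# normalization

@dataclass(frozen=True)
class NormalizationModel:
    mean: np.ndarray
    scale: np.ndarray  # per-feature sd; zero-sd features use scale 1


def fit_normalization(x: np.ndarray) -> NormalizationModel:
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    scale = np.where(scale > 0, scale, 1.0)
    return NormalizationModel(mean, scale)


def apply_normalization(model: NormalizationModel, x: np.ndarray) -> np.ndarray:
    return (np.asarray(x, dtype=float) - model.mean) / model.scale


# ---------------------------------------------------------------------------
# PCA via SVD

@dataclass(frozen=True)
class PCAModel:
    components: np.ndarray  # (d, q), orthonormal columns
    mean: np.ndarray
    explained_variance: np.ndarray  # non-increasing


def fit_pca(x: np.ndarray, q: int = 60) -> PCAModel:
    """Principal components of the centered data by singular value
    decomposition.

    Component signs are fixed so that each component's largest-magnitude
    entry is positive, making the decomposition deterministic.
    """
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not 1 <= q <= min(n - 1, d):
        raise ValueError(f"q must be in [1, min(n-1, d)] = [1, {min(n - 1, d)}]")
    mean = x.mean(axis=0)
    _, s, vt = np.linalg.svd(x - mean, full_matrices=False)
    components = vt[:q].T
    flip = np.sign(components[np.abs(components).argmax(axis=0), np.arange(q)])
    components = components * flip
    explained = (s[:q] ** 2) / (n - 1)
    return PCAModel(components, mean, explained)


def project(model: PCAModel, x: np.ndarray) -> np.ndarray:
    return (np.asarray(x, dtype=float) - model.mean) @ model.components


# ---------------------------------------------------------------------------
# Gaussian discriminant classifiers

@dataclass(frozen=True)
class ClassifierModel:
    kind: str
    classes: np.ndarray
    means: np.ndarray  # (g, q)
    priors: np.ndarray  # (g,)
    pooled_cov: np.ndarray | None = None  # lda/mahalanobis kinds
    class_covs: np.ndarray | None = None  # qda/naive_bayes kinds
    sklearn_model: object | None = None  # linear_svm delegate


def _regularize(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    ridge = COV_EPSILON * np.trace(cov) / d
    if ridge <= 0:
        ridge = COV_EPSILON
    return cov + ridge * np.eye(d)


def fit_classifier(kind: str, x: np.ndarray, y: np.ndarray) -> ClassifierModel:
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    n, d = x.shape
    g = len(classes)
    means = np.vstack([x[y == c].mean(axis=0) for c in classes])
    priors = counts / n

    if kind == "linear_svm":
        from sklearn.svm import LinearSVC

        svm = LinearSVC()
        svm.fit(x, y)
        return ClassifierModel(kind, classes, means, priors, sklearn_model=svm)

    centered = x - means[np.searchsorted(classes, y)]
    if kind in ("lda_full", "mahalanobis"):
        pooled = _regularize(centered.T @ centered / (n - g))
        return ClassifierModel(kind, classes, means, priors, pooled_cov=pooled)
    if kind == "lda_diag":
        pooled = _regularize(np.diag((centered**2).sum(axis=0) / (n - g)))
        return ClassifierModel(kind, classes, means, priors, pooled_cov=pooled)

    covs = []
    for c in classes:
        xc = x[y == c]
        if xc.shape[0] < 2:
            cov = np.zeros((d, d))
        else:
            diff = xc - xc.mean(axis=0)
            cov = diff.T @ diff / (xc.shape[0] - 1)
        if kind in ("qda_diag", "naive_bayes"):
            cov = np.diag(np.diag(cov))
        covs.append(_regularize(cov))
    return ClassifierModel(kind, classes, means, priors, class_covs=np.stack(covs))


def _log_gaussian(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance is not positive-definite")
    diff = x - mean
    maha = np.einsum("ij,ij->i", diff @ np.linalg.inv(cov), diff)
    return -0.5 * (logdet + maha)


def predict(model: ClassifierModel, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if model.kind == "linear_svm":
        return np.asarray(model.sklearn_model.predict(x))

    g = len(model.classes)
    scores = np.empty((x.shape[0], g))
    if model.kind == "mahalanobis":
        inv = np.linalg.inv(model.pooled_cov)
        for j in range(g):
            diff = x - model.means[j]
            scores[:, j] = -np.einsum("ij,ij->i", diff @ inv, diff)
    elif model.kind in ("lda_full", "lda_diag"):
        for j in range(g):
            scores[:, j] = _log_gaussian(x, model.means[j], model.pooled_cov)
        scores += np.log(model.priors)
    else:  # qda_full, qda_diag, naive_bayes
        for j in range(g):
            scores[:, j] = _log_gaussian(x, model.means[j], model.class_covs[j])
        scores += np.log(model.priors)
    return model.classes[scores.argmax(axis=1)]


# ---------------------------------------------------------------------------
# metrics

@dataclass
class EvaluationResult:
    confusion: np.ndarray
    acc: float
    kappa: float
    tpr: np.ndarray
    fpr: np.ndarray
    classes: np.ndarray
    acc_se: float = 0.0
    kappa_se: float = 0.0
    tpr_se: np.ndarray | None = None
    fpr_se: np.ndarray | None = None
    fold_records: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "acc": self.acc,
            "acc_se": self.acc_se,
            "kappa": self.kappa,
            "kappa_se": self.kappa_se,
            "confusion": self.confusion.tolist(),
            "classes": [str(c) for c in self.classes],
            "tpr": self.tpr.tolist(),
            "fpr": self.fpr.tolist(),
        }
        if self.tpr_se is not None:
            out["tpr_se"] = self.tpr_se.tolist()
        if self.fpr_se is not None:
            out["fpr_se"] = self.fpr_se.tolist()
        return out


def confusion_and_metrics(
    y_true: Sequence, y_pred: Sequence, n_classes: int = 5, classes=None
) -> EvaluationResult:
    """Confusion matrix with accuracy, Cohen's kappa and per-class
    one-vs-rest TPR/FPR.

    Kappa is ``(p_o - p_e) / (1 - p_e)`` with the expected agreement ``p_e``
    computed from the row/column marginals.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label lists")
    if y_true.shape != y_pred.shape:
        raise ValueError("label lists must have equal length")
    if classes is None:
        classes = np.arange(1, n_classes + 1)
    classes = np.asarray(classes)
    g = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((g, g), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[index[t], index[p]] += 1

    total = conf.sum()
    acc = conf.trace() / total
    p_e = float((conf.sum(axis=1) / total) @ (conf.sum(axis=0) / total))
    kappa = 1.0 if p_e == 1.0 else (acc - p_e) / (1.0 - p_e)

    tp = np.diag(conf).astype(float)
    fn = conf.sum(axis=1) - tp
    fp = conf.sum(axis=0) - tp
    tn = total - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        fpr = np.where(fp + tn > 0, fp / (fp + tn), 0.0)
    return EvaluationResult(conf, float(acc), float(kappa), tpr, fpr, classes)


# ---------------------------------------------------------------------------
# stratified cross-validation

def stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Assign each sample to one of ``k`` folds, stratified by class.

    Within each class, shuffled indices are dealt round-robin, so per-fold
    class counts differ by at most one sample.  Folds are disjoint and
    cover the data.
    """
    y = np.asarray(y)
    assignment = np.empty(len(y), dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < k:
            raise ValueError(f"class {c!r} has {len(idx)} samples, fewer than k={k}")
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return assignment


def cross_validate(
    x: np.ndarray,
    y: np.ndarray,
    kind: str = "lda_full",
    components: int = 60,
    k: int = 3,
    runs: int = 10,
    seed: int = 0,
    use_pca: bool = True,
) -> EvaluationResult:
    """Repeated stratified k-fold evaluation of the full pipeline.

    Normalization and PCA are re-fitted inside every training fold; each
    run re-randomizes the fold assignment.  Metrics are reported as the
    mean with standard error over all folds x runs; the confusion matrix
    is summed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    rng = np.random.default_rng(seed)

    records: list[dict] = []
    conf_total = np.zeros((len(classes), len(classes)), dtype=int)
    for run in range(runs):
        assignment = stratified_folds(y, k, rng)
        for fold in range(k):
            val = assignment == fold
            train = ~val
            norm = fit_normalization(x[train])
            xt = apply_normalization(norm, x[train])
            xv = apply_normalization(norm, x[val])
            if use_pca:
                q = min(components, xt.shape[0] - 1, xt.shape[1])
                pca = fit_pca(xt, q)
                xt = project(pca, xt)
                xv = project(pca, xv)
            model = fit_classifier(kind, xt, y[train])
            pred = predict(model, xv)
            res = confusion_and_metrics(y[val], pred, classes=classes)
            conf_total += res.confusion
            records.append(
                {
                    "run": run,
                    "fold": fold,
                    "acc": res.acc,
                    "kappa": res.kappa,
                    "tpr": res.tpr,
                    "fpr": res.fpr,
                }
            )

    def mean_se(values: np.ndarray) -> tuple[float, float]:
        values = np.asarray(values, dtype=float)
        m = float(values.mean())
        se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
        return m, se

    acc, acc_se = mean_se([r["acc"] for r in records])
    kappa, kappa_se = mean_se([r["kappa"] for r in records])
    tprs = np.vstack([r["tpr"] for r in records])
    fprs = np.vstack([r["fpr"] for r in records])
    n_rec = len(records)
    tpr_se = tprs.std(axis=0, ddof=1) / np.sqrt(n_rec) if n_rec > 1 else np.zeros(len(classes))
    fpr_se = fprs.std(axis=0, ddof=1) / np.sqrt(n_rec) if n_rec > 1 else np.zeros(len(classes))
    return EvaluationResult(
        conf_total,
        acc,
        kappa,
        tprs.mean(axis=0),
        fprs.mean(axis=0),
        classes,
        acc_se,
        kappa_se,
        tpr_se,
        fpr_se,
        records,
    )


# ---------------------------------------------------------------------------
# model serialization (JSON with embedded arrays; text-only artifact)

def save_models(
    path: str | Path,
    norm: NormalizationModel,
    pca: PCAModel | None,
    clf: ClassifierModel,
) -> None:
    if clf.kind == "linear_svm":
        raise ValueError("linear_svm models are not serialized by this writer")
    payload = {
        "normalization": {"mean": norm.mean.tolist(), "scale": norm.scale.tolist()},
        "pca": None
        if pca is None
        else {
            "components": pca.components.tolist(),
            "mean": pca.mean.tolist(),
            "explained_variance": pca.explained_variance.tolist(),
        },
        "classifier": {
            "kind": clf.kind,
            "classes": clf.classes.tolist(),
            "means": clf.means.tolist(),
            "priors": clf.priors.tolist(),
            "pooled_cov": None if clf.pooled_cov is None else clf.pooled_cov.tolist(),
            "class_covs": None if clf.class_covs is None else clf.class_covs.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_models(
    path: str | Path,
) -> tuple[NormalizationModel, PCAModel | None, ClassifierModel]:
    data = json.loads(Path(path).read_text())
    norm = NormalizationModel(
        np.array(data["normalization"]["mean"]),
        np.array(data["normalization"]["scale"]),
    )
    pca = None
    if data["pca"] is not None:
        pca = PCAModel(
            np.array(data["pca"]["components"]),
            np.array(data["pca"]["mean"]),
            np.array(data["pca"]["explained_variance"]),
        )
    c = data["classifier"]
    clf = ClassifierModel(
        c["kind"],
        np.array(c["classes"]),
        np.array(c["means"]),
        np.array(c["priors"]),
        None if c["pooled_cov"] is None else np.array(c["pooled_cov"]),
        None if c["class_covs"] is None else np.array(c["class_covs"]),
    )
    return norm, pca, clf
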