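"""Classification harness: PCA projection, 1-NN / LDA identification, ridge logistic.

Multiclass identification mirrors the spectroscopy convention: PCA is fitted
on the training spectra only, and the classifier operates in the projected
space. With a single training instance per class a nearest-neighbor rule is
used (there is no within-class scatter to estimate); with more instances a
linear discriminant with pooled within-class covariance is fitted. Binary
case-control scoring uses ridge-penalized logistic regression on standardized
channels. Models are frozen after fitting: prediction never adapts to test
data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .errors import (
    AxisMismatchError,
    DegenerateTaskError,
    InsufficientClassError,
    InsufficientDataError,
    LabelDomainError,
    ParameterError,
)
from .spectra_io import SpectraSet, SpectralAxis, assert_same_axis


@dataclass
class FittedModel:
    """A frozen classifier: projection (optional) + classifier parameters.

    ``kind`` is one of ``one_nn`` (nearest projected training row),
    ``pca_lda`` (linear discriminant in PCA space) or ``ridge_logistic``
    (binary probability scorer on standardized channels).
    """

    kind: str
    axis: SpectralAxis
    classes: np.ndarray
    center: np.ndarray | None = None        # projection centering vector
    basis: np.ndarray | None = None         # channels x q, orthonormal columns
    params: dict = field(default_factory=dict)
    train_meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int | None:
        return None if self.basis is None else self.basis.shape[1]

    def project(self, X: np.ndarray) -> np.ndarray:
        if self.basis is None:
            return X
        return (X - self.center) @ self.basis


@dataclass
class EvalResult:
    """Held-out evaluation readouts: accuracy, per-class accuracy, AUC, confusion."""

    accuracy: float
    per_class: dict
    n_test: int
    confusion: np.ndarray | None = None
    classes: np.ndarray | None = None
    auc: float | None = None


def _fit_pca(X: np.ndarray, variance_kept: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA via eigendecomposition of the channel covariance.

    Returns (center, basis, explained_variance_ratio of kept components).
    The component count q is the smallest number of leading components whose
    cumulative explained variance reaches ``variance_kept``, capped at
    n_train - 1. Deterministic: component signs are fixed so each component's
    largest-magnitude loading is positive.
    """
    n, p = X.shape
    center = X.mean(axis=0)
    Xc = X - center
    cov = (Xc.T @ Xc) / max(n - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    total = evals.sum()
    cap = max(min(n - 1, p), 1)
    if total <= 0.0:
        q = 1
        ratios = np.zeros(1)
    else:
        ratios = evals / total
        cum = np.cumsum(ratios)
        reached = np.flatnonzero(cum >= variance_kept - 1e-12)
        q = int(reached[0]) + 1 if reached.size else len(evals)
        q = min(q, cap)
    basis = evecs[:, :q].copy()
    flip = np.abs(basis).argmax(axis=0)
    signs = np.sign(basis[flip, np.arange(q)])
    signs[signs == 0] = 1.0
    basis *= signs
    return center, basis, ratios[:q]


def _fit_lda(Z: np.ndarray, y: np.ndarray, classes: np.ndarray) -> dict:
    """Pooled-covariance linear discriminant in the projected space.

    A small ridge (1e-8 x mean diagonal, with an absolute floor for exactly
    degenerate scatter) keeps the pooled covariance invertible when classes
    are duplicated rows or q approaches n - K.
    """
    n, q = Z.shape
    means = np.vstack([Z[y == c].mean(axis=0) for c in classes])
    counts = np.array([(y == c).sum() for c in classes], dtype=float)
    Sw = np.zeros((q, q))
    for k, c in enumerate(classes):
        R = Z[y == c] - means[k]
        Sw += R.T @ R
    dof = max(n - len(classes), 1)
    Sw /= dof
    ridge = 1e-8 * max(np.trace(Sw) / q, 0.0)
    Sw[np.diag_indices(q)] += max(ridge, 1e-12)
    Sw_inv_means = np.linalg.solve(Sw, means.T)          # q x K
    const = -0.5 * np.einsum("kq,qk->k", means, Sw_inv_means) + np.log(counts / n)
    return {"coef": Sw_inv_means, "const": const, "means": means}


def fit_identifier(train: SpectraSet, mode: str = "auto",
                   variance_kept: float = 0.99) -> FittedModel:
    """Fit the multiclass identification model (PCA + 1-NN or PCA + LDA).

    ``mode="auto"`` selects ``one_nn`` iff every class has exactly one
    training row (the single-baseline protocol), else ``pca_lda``. PCA is
    fitted on the training rows only; the model is frozen afterwards.
    """
    if not (0.0 < variance_kept <= 1.0):
        raise ParameterError("variance_kept must lie in (0, 1]")
    classes, counts = np.unique(train.labels, return_counts=True)
    if len(classes) < 2:
        raise DegenerateTaskError("identification needs >= 2 classes")
    if mode == "auto":
        mode = "one_nn" if np.all(counts == 1) else "pca_lda"
    if mode not in ("one_nn", "pca_lda"):
        raise ParameterError(f"unknown identifier mode {mode!r}")
    center, basis, ratio = _fit_pca(train.data, variance_kept)
    Z = (train.data - center) @ basis
    if mode == "one_nn":
        params = {"train_proj": Z, "train_labels": train.labels.copy()}
    else:
        params = _fit_lda(Z, train.labels, classes)
    return FittedModel(
        kind=mode, axis=train.axis, classes=classes, center=center, basis=basis,
        params=params,
        train_meta={
            "n_train": train.n, "variance_kept": variance_kept,
            "n_components": basis.shape[1],
            "explained_variance": float(ratio.sum()),
        },
    )


def fit_binary(train: SpectraSet, ridge_strength: float = 1.0) -> FittedModel:
    """Ridge-penalized logistic regression on standardized channels.

    The positive class is the lexicographically larger of the two labels.
    Standardization statistics come from the training set only.
    """
    if ridge_strength < 0:
        raise ParameterError("ridge_strength must be nonnegative")
    classes, counts = np.unique(train.labels, return_counts=True)
    if len(classes) != 2:
        raise DegenerateTaskError("binary classification needs exactly 2 classes")
    if counts.min() < 2:
        raise InsufficientClassError("each class needs >= 2 training rows")
    mu = train.data.mean(axis=0)
    sd = train.data.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (train.data - mu) / sd
    y = (train.labels == classes[1]).astype(int)
    C = 1.0 / ridge_strength if ridge_strength > 0 else 1e12
    clf = LogisticRegression(C=C, solver="lbfgs", tol=1e-10, max_iter=10_000)
    clf.fit(Xs, y)
    return FittedModel(
        kind="ridge_logistic", axis=train.axis, classes=classes,
        params={
            "scale_mu": mu, "scale_sd": sd,
            "weights": clf.coef_[0].copy(), "intercept": float(clf.intercept_[0]),
            "positive_class": str(classes[1]),
        },
        train_meta={"n_train": train.n, "ridge_strength": ridge_strength},
    )


def predict(model: FittedModel, test: SpectraSet) -> np.ndarray:
    """Labels (identification models) or positive-class probabilities (binary).

    1-NN ties are broken by the lowest training-row index; LDA ties by the
    first class in sorted order. Deterministic for a frozen model.
    """
    if not assert_same_axis(model.axis, test.axis):
        raise AxisMismatchError("test axis differs from training axis")
    if test.n == 0:
        return np.array([], dtype=float if model.kind == "ridge_logistic" else test.labels.dtype)
    if model.kind == "ridge_logistic":
        Xs = (test.data - model.params["scale_mu"]) / model.params["scale_sd"]
        z = Xs @ model.params["weights"] + model.params["intercept"]
        return 1.0 / (1.0 + np.exp(-z))
    Z = model.project(test.data)
    if model.kind == "one_nn":
        D = cdist(Z, model.params["train_proj"])
        return model.params["train_labels"][D.argmin(axis=1)]
    scores = Z @ model.params["coef"] + model.params["const"]
    return model.classes[scores.argmax(axis=1)]


def evaluate(model: FittedModel, test: SpectraSet) -> EvalResult:
    """Accuracy / confusion (multiclass) or accuracy + rank-statistic AUC (binary)."""
    unknown = np.setdiff1d(np.unique(test.labels), model.classes)
    if unknown.size:
        raise LabelDomainError(f"test labels outside training classes: {unknown.tolist()}")
    out = predict(model, test)
    classes = model.classes
    idx = {c: k for k, c in enumerate(classes)}
    if model.kind == "ridge_logistic":
        positive = model.params["positive_class"]
        pred_labels = np.where(out >= 0.5, classes[1], classes[0])
        y_true = (test.labels == positive).astype(int)
        auc = None
        if len(np.unique(y_true)) == 2:
            auc = float(roc_auc_score(y_true, out))
    else:
        pred_labels = out
        auc = None
    K = len(classes)
    confusion = np.zeros((K, K), dtype=int)
    for t, p in zip(test.labels, pred_labels):
        confusion[idx[t], idx[p]] += 1
    accuracy = float(np.trace(confusion)) / max(confusion.sum(), 1)
    per_class = {}
    for k, c in enumerate(classes):
        row = confusion[k].sum()
        if row:
            per_class[str(c)] = float(confusion[k, k]) / row
    return EvalResult(accuracy=accuracy, per_class=per_class, n_test=test.n,
                      confusion=confusion, classes=classes, auc=auc)


def fit_log_trend(sizes, accuracies) -> tuple[float, float, float]:
    """OLS of accuracy on log2(population size): (slope, intercept, r_squared).

    Captures the empirical finding that identification accuracy declines
    almost linearly in the logarithm of the number of candidate individuals.
    Constant accuracies give slope 0 with r_squared defined as 0.
    """
    sizes = np.asarray(sizes, dtype=float)
    accuracies = np.asarray(accuracies, dtype=float)
    if np.unique(sizes).size < 3:
        raise InsufficientDataError("need >= 3 distinct population sizes")
    if np.any(sizes < 2):
        raise ParameterError("population sizes must be >= 2")
    x = np.log2(sizes)
    xc, yc = x - x.mean(), accuracies - accuracies.mean()
    ss_tot = float(yc @ yc)
    slope = float(xc @ yc) / float(xc @ xc)
    intercept = float(accuracies.mean() - slope * x.mean())
    if ss_tot == 0.0:
        return 0.0, intercept, 0.0
    resid = yc - slope * xc
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return slope, intercept, r2


# -- model persistence (single-file JSON container) -----------------------

def save_model(model: FittedModel, path) -> None:
    """Serialize a frozen model to a single JSON file."""
    def enc(a):
        return None if a is None else np.asarray(a).tolist()

    payload = {
        "kind": model.kind,
        "axis": model.axis.values.tolist(),
        "classes": model.classes.tolist(),
        "center": enc(model.center),
        "basis": enc(model.basis),
        "params": {k: (enc(v) if isinstance(v, np.ndarray) else v)
                   for k, v in model.params.items()},
        "train_meta": model.train_meta,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> FittedModel:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    arr = lambda v: None if v is None else np.asarray(v)
    params = {}
    for k, v in payload["params"].items():
        params[k] = np.asarray(v) if isinstance(v, list) else v
    if "train_labels" in params:
        params["train_labels"] = np.asarray(params["train_labels"], dtype=str)
    return FittedModel(
        kind=payload["kind"],
        axis=SpectralAxis(np.asarray(payload["axis"])),
        classes=np.asarray(payload["classes"], dtype=str),
        center=arr(payload["center"]),
        basis=arr(payload["basis"]),
        params=params,
        train_meta=payload["train_meta"],
    )
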