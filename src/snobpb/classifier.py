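"""Class-weighted soft-margin RBF kernel classification.

The classifier is a standard soft-margin SVM with kernel
k(x, y) = exp(-gamma ||x - y||^2) in which the misclassification penalty is
C * W_pos for the (rarer) modified class and C * W_neg for the unmodified
class. Fitting goes through scikit-learn's libsvm binding; the fitted
machine is stored as plain arrays (support vectors, dual coefficients,
intercept) so that prediction — and JSON round-tripping — is bit-exact and
independent of the fitting backend.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import product
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .features import FeatureLayout
from .io import SnobpbError
from .profiles import BiProfile

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """SVM hyper-parameters. Defaults are the published operating point."""

    C: float = 22.6274  # = 2**4.5
    gamma: float = 0.03125  # = 2**-5
    W_pos: float = 2.0
    W_neg: float = 1.0
    kernel: str = "rbf"
    tol: float = 1e-6  # optimizer tolerance, recorded for reproducibility

    def __post_init__(self) -> None:
        if min(self.C, self.gamma, self.W_pos, self.W_neg) <= 0:
            raise SnobpbError("C, gamma and class weights must be positive")
        if self.kernel != "rbf":
            raise SnobpbError("only the RBF kernel is supported")


def rbf_kernel(X: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * cdist(np.atleast_2d(X), np.atleast_2d(Y), "sqeuclidean"))


@dataclass
class TrainedModel:
    """A fitted decision function plus everything needed to reuse it safely."""

    config: ModelConfig
    support_vectors: np.ndarray  # (m, d)
    dual_coef: np.ndarray  # (m,) signed alpha_i y_i
    intercept: float
    layout: Optional[FeatureLayout] = None
    biprofile: Optional[BiProfile] = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self._check_layout(X)
        K = rbf_kernel(X, self.support_vectors, self.config.gamma)
        return K @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (labels, decision values); a decision value of exactly 0
        is called negative (conservative for site calling)."""
        scores = self.decision_function(X)
        labels = np.where(scores > 0, 1, -1)
        return labels, scores

    def _check_layout(self, X: np.ndarray) -> None:
        if self.layout is not None and X.shape[1] != self.layout.n_features:
            raise SnobpbError(
                f"feature matrix has {X.shape[1]} columns but the model "
                f"expects {self.layout.n_features}"
            )
        if X.shape[1] != self.support_vectors.shape[1]:
            raise SnobpbError("feature dimension does not match the model")

    # -- persistence ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "config": asdict(self.config),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "layout": self.layout.to_dict() if self.layout else None,
            "biprofile": json.loads(self.biprofile.to_json()) if self.biprofile else None,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise SnobpbError(
                f"unsupported model format version {d.get('format_version')!r}"
            )
        return cls(
            config=ModelConfig(**d["config"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            layout=FeatureLayout.from_dict(d["layout"]) if d["layout"] else None,
            biprofile=BiProfile.from_json(json.dumps(d["biprofile"]))
            if d["biprofile"] else None,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig = ModelConfig(),
    *,
    layout: Optional[FeatureLayout] = None,
    biprofile: Optional[BiProfile] = None,
) -> TrainedModel:
    """Fit the class-weighted RBF SVM on a feature matrix and +/-1 labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise SnobpbError("feature matrix and label vector shapes disagree")
    if not np.all(np.isfinite(X)):
        raise SnobpbError("feature matrix contains non-finite values")
    if set(np.unique(y)) != {-1, 1}:
        raise SnobpbError("training needs at least one sample of each class (+1/-1)")
    svc = SVC(
        C=config.C,
        kernel="rbf",
        gamma=config.gamma,
        class_weight={1: config.W_pos, -1: config.W_neg},
        tol=config.tol,
        shrinking=True,
        cache_size=256,
    )
    svc.fit(X, y)
    # classes_ is sorted [-1, 1], so positive decision values mean class +1
    return TrainedModel(
        config=config,
        support_vectors=np.asarray(svc.support_vectors_, dtype=float),
        dual_coef=np.asarray(svc.dual_coef_[0], dtype=float),
        intercept=float(svc.intercept_[0]),
        layout=layout,
        biprofile=biprofile,
    )


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Functional alias for :meth:`TrainedModel.predict`."""
    return model.predict(X)


def grid_search_weight(
    evaluator: Callable[[float], "object"],
    candidates: Sequence[float] = (1.0, 1.5, 2.0, 2.5),
) -> tuple[float, dict[float, "object"]]:
    """Pick the positive-class weight W_pos maximizing evaluated MCC.

    ``evaluator(W)`` must return an object with an ``mcc`` attribute (a
    MetricsReport). Ties break toward the smaller weight.
    """
    if not candidates:
        raise SnobpbError("empty candidate set")
    reports = {float(w): evaluator(float(w)) for w in candidates}
    best = min(reports, key=lambda w: (-reports[w].mcc, w))
    return best, reports


def grid_search_cost_gamma(
    X: np.ndarray,
    y: np.ndarray,
    log2C: Sequence[float] = tuple(np.arange(-5, 15.5, 0.5)),
    log2gamma: Sequence[float] = tuple(np.arange(-15, 4, 1.0)),
    folds: int = 15,
    config: ModelConfig = ModelConfig(),
) -> tuple[float, float, dict[tuple[float, float], float]]:
    """Exhaustive (C, gamma) grid search by stratified k-fold accuracy.

    Returns (C, gamma, accuracy-per-grid-point). Ties break toward smaller
    C, then smaller gamma. The default grid follows the common
    SVMcgForClass convention and contains the published optimum
    (2**4.5, 2**-5).
    """
    from sklearn.model_selection import StratifiedKFold

    if len(log2C) == 0 or len(log2gamma) == 0:
        raise SnobpbError("empty grid")
    y = np.asarray(y, dtype=int)
    n_min = min(np.sum(y == 1), np.sum(y == -1))
    if folds > n_min:
        raise SnobpbError(
            f"{folds}-fold CV impossible with minority class size {n_min}"
        )
    splits = list(StratifiedKFold(n_splits=folds, shuffle=False).split(X, y))
    accs: dict[tuple[float, float], float] = {}
    for a, b in product(log2C, log2gamma):
        cfg = ModelConfig(
            C=2.0 ** a, gamma=2.0 ** b,
            W_pos=config.W_pos, W_neg=config.W_neg, tol=config.tol,
        )
        correct = 0
        for tr, te in splits:
            m = train(X[tr], y[tr], cfg)
            labels, _ = m.predict(X[te])
            correct += int(np.sum(labels == y[te]))
        accs[(cfg.C, cfg.gamma)] = correct / len(y)
    best = min(accs, key=lambda cg: (-accs[cg], cg[0], cg[1]))
    return best[0], best[1], accs
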