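"""Soft-margin SVM training and scoring on precomputed kernel matrices.

Training solves the standard dual problem (box constraints ``0 <= alpha_i <= C``
and the equality ``sum alpha_i y_i = 0``) with the libsvm SMO solver exposed by
scikit-learn, on a precomputed Gram; the trained model keeps only what is needed
to score new instances from a cross-kernel block: the dual coefficients, the
bias, and the support-vector indices within the training ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .kernels import KernelConfig, KernelGram


class SolverError(RuntimeError):
    """The dual solver failed to produce a feasible solution."""


@dataclass
class TrainedSVM:
    """Dual solution of a soft-margin SVM over a precomputed kernel.

    ``alpha`` holds the nonnegative dual coefficients for every training
    instance (zero off the support); the decision function is
    ``f(x) = sum_j alpha_j y_j k(x_j, x) + bias``.
    """

    alpha: np.ndarray
    labels: np.ndarray
    bias: float
    C: float
    train_ids: tuple[str, ...]
    kernel_config: KernelConfig = field(default_factory=KernelConfig)

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.alpha.shape != self.labels.shape:
            raise ValueError("alpha and labels must have the same shape")
        self.train_ids = tuple(str(i) for i in self.train_ids)
        if len(self.train_ids) != self.alpha.size:
            raise ValueError("train_ids length must match alpha")
        n = self.alpha.size
        if np.any(self.alpha < -1e-9) or np.any(self.alpha > self.C * (1 + 1e-9)):
            raise ValueError("dual coefficients violate the box constraint 0 <= alpha <= C")
        if abs(float(self.alpha @ self.labels)) > 1e-6 * self.C * max(n, 1):
            raise ValueError("dual coefficients violate sum alpha_i y_i = 0")

    @property
    def support_indices(self) -> np.ndarray:
        return np.flatnonzero(self.alpha > 0)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        sup = self.support_indices
        return {
            "bias": self.bias,
            "C": self.C,
            "n_train": int(self.alpha.size),
            "support_indices": sup.tolist(),
            "support_alpha": self.alpha[sup].tolist(),
            "support_labels": self.labels[sup].tolist(),
            "train_ids": list(self.train_ids),
            "kernel_config": self.kernel_config.to_dict(),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, data: dict) -> "TrainedSVM":
        n = int(data["n_train"])
        alpha = np.zeros(n)
        labels = np.ones(n)
        sup = np.asarray(data["support_indices"], dtype=int)
        alpha[sup] = np.asarray(data["support_alpha"], dtype=float)
        labels[sup] = np.asarray(data["support_labels"], dtype=float)
        # non-support labels are irrelevant to scoring (their alpha is zero)
        return cls(alpha=alpha, labels=labels, bias=float(data["bias"]),
                   C=float(data["C"]), train_ids=tuple(data["train_ids"]),
                   kernel_config=KernelConfig.from_dict(data["kernel_config"]))

    @classmethod
    def load_json(cls, path) -> "TrainedSVM":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _gram_values(gram) -> tuple[np.ndarray, tuple[str, ...], KernelConfig]:
    if isinstance(gram, KernelGram):
        return gram.values, gram.instance_ids, gram.config
    values = np.asarray(gram, dtype=float)
    ids = tuple(str(i) for i in range(values.shape[0]))
    return values, ids, KernelConfig()


def svm_train(gram, labels: Sequence[float], C: float, tol: float = 1e-6) -> TrainedSVM:
    """Train a soft-margin SVM on a precomputed Gram matrix.

    ``labels`` must be in {-1, +1} with both classes present; ``C`` is the
    soft-margin regularization; ``tol`` the solver's KKT stopping tolerance.
    """
    K, ids, config = _gram_values(gram)
    y = np.asarray(labels, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("gram must be a square matrix")
    if not np.allclose(K, K.T, atol=1e-8 * max(1.0, float(np.abs(K).max()))):
        raise ValueError("gram matrix is not symmetric")
    if y.shape != (K.shape[0],):
        raise ValueError("labels must align with the gram matrix")
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("labels must be -1/+1 with both classes present")
    if not C > 0:
        raise ValueError("C must be positive")
    clf = SVC(C=C, kernel="precomputed", tol=tol, shrinking=True, cache_size=200)
    clf.fit(K, y)
    alpha = np.zeros(K.shape[0])
    # dual_coef_ holds alpha_i * y_i for the support vectors
    alpha[clf.support_] = np.abs(clf.dual_coef_[0])
    model = TrainedSVM(alpha=alpha, labels=y, bias=float(clf.intercept_[0]),
                       C=float(C), train_ids=ids, kernel_config=config)
    return model


def svm_score(model: TrainedSVM, gram_cross: np.ndarray) -> np.ndarray:
    """Decision values for query instances.

    ``gram_cross`` has one row per query and one column per *training*
    instance (aligned with ``model.train_ids``); the raw score is the ROC
    threshold variable and its sign the predicted class.
    """
    K = np.atleast_2d(np.asarray(gram_cross, dtype=float))
    if K.shape[1] != model.alpha.size:
        raise ValueError(
            f"cross-kernel has {K.shape[1]} columns but the model was trained "
            f"on {model.alpha.size} instances")
    sup = model.support_indices
    return K[:, sup] @ (model.alpha[sup] * model.labels[sup]) + model.bias


def dual_objective(gram, labels, alpha) -> float:
    """Dual objective sum(alpha) - 1/2 alpha^T (yy^T * K) alpha (for diagnostics)."""
    K, _, _ = _gram_values(gram)
    y = np.asarray(labels, float)
    a = np.asarray(alpha, float)
    return float(a.sum() - 0.5 * a @ ((np.outer(y, y) * K) @ a))
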