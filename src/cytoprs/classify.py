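"""Two-class linear discriminant analysis with ROC operating-point metrics.

The LDA is closed form: pooled within-class covariance (ridge-stabilized),
discriminant weights ``S^-1 (mu1 - mu0)`` and an intercept placing the
zero-score surface on the equal-posterior boundary. The ROC operating
point is the threshold maximizing overall accuracy, ties broken toward
higher sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class LDAModel:
    classes: tuple
    class_means: np.ndarray  # (2, d): row 0 = negative class, row 1 = positive
    pooled_cov: np.ndarray
    weights: np.ndarray
    intercept: float
    priors: tuple[float, float]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_scores(X) >= 0, self.classes[1], self.classes[0])


def fit_lda(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float | None = None,
    equal_priors: bool = False,
) -> LDAModel:
    """Closed-form two-class LDA on ``X`` (n x d) with labels ``y``.

    ``ridge`` defaults to ``1e-6 * trace(S)/d``; pass 0 to disable
    (singular covariance then raises with advice).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"fit_lda requires exactly two classes, got {len(classes)}")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    n0, n1 = len(X0), len(X1)
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    d = X.shape[1]

    s0 = (X0 - mu0).T @ (X0 - mu0)
    s1 = (X1 - mu1).T @ (X1 - mu1)
    denom = max(n0 + n1 - 2, 1)
    cov = (s0 + s1) / denom
    if ridge is None:
        ridge = 1e-6 * np.trace(cov) / d
    cov_r = cov + ridge * np.eye(d)
    try:
        weights = np.linalg.solve(cov_r, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; pass a positive ridge epsilon"
        ) from exc

    if equal_priors:
        pri0 = pri1 = 0.5
    else:
        pri0, pri1 = n0 / (n0 + n1), n1 / (n0 + n1)
    intercept = float(-0.5 * (mu0 + mu1) @ weights + np.log(pri1 / pri0))
    return LDAModel(
        classes=tuple(classes),
        class_means=np.vstack([mu0, mu1]),
        pooled_cov=cov_r,
        weights=weights,
        intercept=intercept,
        priors=(pri0, pri1),
    )


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    oop_threshold: float
    oop_metrics: dict[str, float]


def roc_analysis(scores: np.ndarray, y: np.ndarray) -> ROCResult:
    """ROC curve, trapezoid AUC and accuracy-maximizing operating point."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = _sk_roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))

    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    accuracy = (tpr * n_pos + (1.0 - fpr) * n_neg) / len(y)
    best_acc = accuracy.max()
    candidates = np.flatnonzero(np.isclose(accuracy, best_acc))
    best = candidates[np.argmax(tpr[candidates])]  # tie -> higher sensitivity

    thr = float(thresholds[best])
    pred = scores >= thr
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    metrics = {
        "accuracy": float(accuracy[best]),
        "sensitivity": float(tpr[best]),
        "specificity": float(1.0 - fpr[best]),
        "precision": tp / (tp + fp) if (tp + fp) > 0 else 0.0,
    }
    return ROCResult(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc, oop_threshold=thr, oop_metrics=metrics
    )
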