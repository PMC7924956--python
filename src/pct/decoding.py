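"""Diagonal-covariance LDA decoding with leave-one-out cross-validation.

The classifier assumes Gaussian class-conditional densities that differ only
in their means and share a single diagonal covariance pooled across classes
(variances estimated per unit).  With ~10 trials per condition this pooled
diagonal model is far better conditioned than a full covariance estimate.
Priors are uniform; argmax ties break toward the earlier class in label
order, deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import FiringRateMatrix

__all__ = ["DecoderModel", "ConfusionMatrix", "fit_lda_diag", "predict", "loo_confusion", "average_confusions"]

#: Variance floor (Hz^2) applied per unit to avoid degenerate discriminants.
VAR_FLOOR = 1e-6


@dataclass
class DecoderModel:
    """Per-class mean vectors and one pooled diagonal variance vector."""

    classes: list
    means: np.ndarray  # classes x units
    var: np.ndarray  # units (pooled within-class, floored)


@dataclass
class ConfusionMatrix:
    """Row-stochastic confusion matrix over conditions."""

    classes: list
    accuracy: np.ndarray  # true x predicted, rows sum to 1
    n_trials: np.ndarray  # trials per true class

    @property
    def overall_accuracy(self) -> float:
        """Trial-weighted share of correct predictions."""
        correct = np.diag(self.accuracy) * self.n_trials
        return float(correct.sum() / self.n_trials.sum())


def _class_stats(X: np.ndarray, y: np.ndarray, classes: list):
    """Means and pooled within-class variance; X is trials x units."""
    k = len(classes)
    means = np.empty((k, X.shape[1]))
    ss = np.zeros(X.shape[1])
    n_tot = 0
    for j in range(k):
        rows = X[y == j]
        means[j] = rows.mean(axis=0)
        ss += np.sum((rows - means[j]) ** 2, axis=0)
        n_tot += len(rows)
    dof = max(n_tot - k, 1)
    var = np.maximum(ss / dof, VAR_FLOOR)
    return means, var


def fit_lda_diag(rates: FiringRateMatrix) -> DecoderModel:
    """Fit the shared-diagonal-covariance LDA on all trials of the matrix."""
    classes = rates.conditions()
    if len(classes) < 2:
        raise ValueError("need at least 2 conditions to fit a decoder")
    for cond in classes:
        if len(rates.condition_trials(cond)) < 2:
            raise ValueError(f"condition {cond} has fewer than 2 trials")
    X = rates.rates.T
    y = np.array([classes.index(lab) for lab in rates.labels])
    means, var = _class_stats(X, y, classes)
    return DecoderModel(classes=list(classes), means=means, var=var)


def predict(model: DecoderModel, X: np.ndarray) -> np.ndarray:
    """Class indices for rows of X (trials x units); ties break to the first class."""
    X = np.atleast_2d(X)
    # log-likelihood up to shared constants: -0.5 * sum (x - mu)^2 / var
    d = X[:, None, :] - model.means[None, :, :]
    scores = -0.5 * np.sum(d**2 / model.var[None, None, :], axis=2)
    return np.argmax(scores, axis=1)


def loo_confusion(rates: FiringRateMatrix) -> ConfusionMatrix:
    """Stratified leave-one-out confusion matrix.

    Each trial is predicted by a model fit on all remaining trials; rows are
    normalised by the true class trial counts.  Folds iterate trials in
    stored order, so the result is reproducible bit-for-bit.
    """
    classes = rates.conditions()
    if len(classes) < 2:
        raise ValueError("need at least 2 conditions")
    X = rates.rates.T
    y = np.array([classes.index(lab) for lab in rates.labels])
    counts = np.bincount(y, minlength=len(classes))
    if counts.min() < 2:
        raise ValueError("every condition needs at least 2 trials for LOO")

    k = len(classes)
    n = len(y)
    # leave-one-out via rank-one downdates of the per-class sufficient
    # statistics (sums and sums of squares)
    S1 = np.zeros((k, X.shape[1]))
    S2 = np.zeros((k, X.shape[1]))
    for c in range(k):
        S1[c] = X[y == c].sum(axis=0)
        S2[c] = (X[y == c] ** 2).sum(axis=0)
    conf = np.zeros((k, k))
    for t in range(n):
        c_t = y[t]
        n_c = counts.astype(float).copy()
        n_c[c_t] -= 1
        s1 = S1.copy()
        s2 = S2.copy()
        s1[c_t] -= X[t]
        s2[c_t] -= X[t] ** 2
        means = s1 / n_c[:, None]
        ss = (s2 - n_c[:, None] * means**2).sum(axis=0)
        var = np.maximum(ss / max(n - 1 - k, 1), VAR_FLOOR)
        scores = -np.sum((X[t][None, :] - means) ** 2 / var[None, :], axis=1)
        conf[c_t, int(np.argmax(scores))] += 1
    return ConfusionMatrix(
        classes=list(classes),
        accuracy=conf / counts[:, None],
        n_trials=counts,
    )


def average_confusions(confusions: list) -> ConfusionMatrix:
    """Element-wise mean of per-session confusion matrices (same conditions)."""
    if not confusions:
        raise ValueError("no confusion matrices given")
    classes = confusions[0].classes
    for cm in confusions[1:]:
        if cm.classes != classes:
            raise ValueError("confusion matrices have mismatched condition sets")
    acc = np.mean([cm.accuracy for cm in confusions], axis=0)
    row_sums = acc.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-9):
        raise ValueError("averaged confusion rows do not sum to 1")
    n_trials = np.sum([cm.n_trials for cm in confusions], axis=0)
    return ConfusionMatrix(classes=list(classes), accuracy=acc, n_trials=n_trials)
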