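"""Cross-validated split-half population similarity and permutation contrasts.

Condition similarity is measured between independent halves of the trials:
per resample, each condition's trials are split 50-50, condition-mean
population vectors are computed per half, and the chosen metric compares
half-A of condition i with half-B of condition j — including i = j, whose
value is the within-condition noise ceiling.  The matrix is averaged over
resamples and symmetrised.
"""

from __future__ import annotations

from dataclasses import dataclass

import logging

import numpy as np

from .preprocess import FiringRateMatrix

__all__ = [
    "CorrelationMatrix",
    "cv_condition_correlation",
    "correlation_contrast_test",
    "mirror_symmetry_contrast",
    "MirrorSymmetryReport",
]

logger = logging.getLogger(__name__)

_METRICS = ("pearson", "euclidean", "cosine")


@dataclass
class CorrelationMatrix:
    """Split-half similarity matrix with per-pair resample distributions."""

    conditions: list
    mean_corr: np.ndarray  # condition x condition
    split_samples: np.ndarray  # condition x condition x n_splits (symmetrised)
    metric: str

    def pair_samples(self, cond_i, cond_j) -> np.ndarray:
        i = self.conditions.index(cond_i)
        j = self.conditions.index(cond_j)
        return self.split_samples[i, j]


def _metric_matrix(A: np.ndarray, B: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise metric between columns of A (units x k) and columns of B."""
    if metric == "pearson":
        Ac = A - A.mean(axis=0)
        Bc = B - B.mean(axis=0)
    elif metric == "cosine":
        Ac, Bc = A, B
    elif metric == "euclidean":
        # negative distance, so that larger still means more similar
        d2 = (
            np.sum(A**2, axis=0)[:, None]
            + np.sum(B**2, axis=0)[None, :]
            - 2 * A.T @ B
        )
        return -np.sqrt(np.maximum(d2, 0.0))
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    norm_a = np.sqrt(np.sum(Ac**2, axis=0))
    norm_b = np.sqrt(np.sum(Bc**2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (Ac.T @ Bc) / np.outer(norm_a, norm_b)
    return np.nan_to_num(out, nan=0.0)


def cv_condition_correlation(
    rates: FiringRateMatrix,
    n_splits: int = 250,
    metric: str = "pearson",
    seed: int = 0,
) -> CorrelationMatrix:
    """Cross-validated condition-similarity matrix over random 50-50 splits.

    Odd trial counts put the extra trial in the A half (fixed rule).  The
    i->j and j->i estimates are computed independently per split and averaged
    into a symmetric matrix.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    conds = rates.conditions()
    k = len(conds)
    trial_sets = [rates.condition_trials(c) for c in conds]
    for c, idx in zip(conds, trial_sets):
        if len(idx) < 2:
            raise ValueError(f"condition {c} has fewer than 2 trials")

    rng = np.random.default_rng(seed)
    samples = np.empty((k, k, n_splits))
    half_a = np.empty((rates.n_units, k))
    half_b = np.empty((rates.n_units, k))
    for s in range(n_splits):
        for j, idx in enumerate(trial_sets):
            perm = rng.permutation(idx)
            cut = (len(idx) + 1) // 2  # extra trial goes to the A half
            half_a[:, j] = rates.rates[:, perm[:cut]].mean(axis=1)
            half_b[:, j] = rates.rates[:, perm[cut:]].mean(axis=1)
        raw = _metric_matrix(half_a, half_b, metric)
        samples[:, :, s] = 0.5 * (raw + raw.T)
    return CorrelationMatrix(
        conditions=list(conds),
        mean_corr=samples.mean(axis=2),
        split_samples=samples,
        metric=metric,
    )


def correlation_contrast_test(
    samples_a,
    samples_b,
    n_shuffles: int = 2000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for a difference in mean correlation.

    The two resample distributions are pooled and reassigned at random
    ``n_shuffles`` times; p = (1 + #{|null diff| >= |observed|}) / (1 + n).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample lists must be non-empty")
    if n_shuffles < 100:
        logger.warning("n_shuffles=%d is small; permutation p will be coarse", n_shuffles)
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    # vectorised label shuffles: each row of a random matrix argsorted gives
    # one permutation of the pooled samples
    order = np.argsort(rng.random((n_shuffles, pooled.size)), axis=1)
    shuffled = pooled[order]
    diff = shuffled[:, : a.size].mean(axis=1) - shuffled[:, a.size :].mean(axis=1)
    count = int(np.sum(np.abs(diff) >= observed - 1e-15))
    return (1 + count) / (1 + n_shuffles)


@dataclass
class MirrorSymmetryReport:
    """Per lateral pair: L<->R correlation vs the within-condition ceiling."""

    pairs: list  # (left condition, right condition)
    cross_corr: np.ndarray  # mean L<->R correlation per pair
    ceiling_corr: np.ndarray  # mean within-condition correlation per pair
    p_values: np.ndarray  # permutation p per pair (side-relabeling null)
    at_ceiling: np.ndarray  # bool: indistinguishable from the ceiling

    @property
    def fraction_at_ceiling(self) -> float:
        return float(self.at_ceiling.mean())


def _split_half_means(X: np.ndarray, n_splits: int, rng: np.random.Generator):
    """Random 50-50 half-means of the columns of X, for n_splits splits.

    Returns (A, B), each units x n_splits; an odd trial goes to the A half.
    """
    n = X.shape[1]
    cut = (n + 1) // 2
    order = np.argsort(rng.random((n_splits, n)), axis=1)
    choose_a = np.zeros((n_splits, n))
    np.put_along_axis(choose_a, order[:, :cut], 1.0, axis=1)
    A = X @ choose_a.T / cut
    B = X @ (1.0 - choose_a).T / (n - cut)
    return A, B


def _columnwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    num = np.sum(Ac * Bc, axis=0)
    den = np.sqrt(np.sum(Ac**2, axis=0) * np.sum(Bc**2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.nan_to_num(out, nan=0.0)


def _mirror_stat(X_left, X_right, n_splits, rng):
    """(mean within-side corr, mean cross-side corr) over split halves."""
    A_L, B_L = _split_half_means(X_left, n_splits, rng)
    A_R, B_R = _split_half_means(X_right, n_splits, rng)
    within = 0.5 * (_columnwise_pearson(A_L, B_L) + _columnwise_pearson(A_R, B_R))
    cross = 0.5 * (_columnwise_pearson(A_L, B_R) + _columnwise_pearson(A_R, B_L))
    return float(within.mean()), float(cross.mean())


def mirror_symmetry_contrast(
    rates: FiringRateMatrix,
    lateral_pairs: list,
    n_splits: int = 50,
    n_shuffles: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> MirrorSymmetryReport:
    """Test, per (left, right) condition pair, whether the L<->R population
    correlation is statistically indistinguishable from the within-condition
    noise ceiling.

    The statistic is the split-half ceiling-minus-cross correlation deficit.
    Its null distribution is built by relabeling which body side each trial
    belongs to: under mirror-symmetric coding the two sides' trials are
    exchangeable, so the side-relabeling permutation test is exactly
    calibrated (a contrast test over the correlated split resamples is not:
    its null width shrinks with the number of splits while the trial-sampling
    noise in the statistic does not).  One-sided p: cross below ceiling.
    """
    conds = rates.conditions()
    for left, right in lateral_pairs:
        if left not in conds or right not in conds:
            raise ValueError(f"pair ({left}, {right}) not present in the rate matrix")
    rng = np.random.default_rng(seed)
    cross = np.empty(len(lateral_pairs))
    ceiling = np.empty(len(lateral_pairs))
    pvals = np.empty(len(lateral_pairs))
    for i, (left, right) in enumerate(lateral_pairs):
        X_L = rates.rates[:, rates.condition_trials(left)]
        X_R = rates.rates[:, rates.condition_trials(right)]
        n_L = X_L.shape[1]
        within, crossed = _mirror_stat(X_L, X_R, n_splits, rng)
        ceiling[i] = within
        cross[i] = crossed
        observed = within - crossed
        pooled = np.concatenate([X_L, X_R], axis=1)
        null = np.empty(n_shuffles)
        for s in range(n_shuffles):
            perm = rng.permutation(pooled.shape[1])
            w, c = _mirror_stat(
                pooled[:, perm[:n_L]], pooled[:, perm[n_L:]], n_splits, rng
            )
            null[s] = w - c
        pvals[i] = (1 + int(np.sum(null >= observed - 1e-15))) / (1 + n_shuffles)
    return MirrorSymmetryReport(
        pairs=list(lateral_pairs),
        cross_corr=cross,
        ceiling_corr=ceiling,
        p_values=pvals,
        at_ceiling=pvals > alpha,
    )
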