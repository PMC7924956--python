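"""Sliding-window population dynamics.

Cross-temporal generalization: a diagonal-covariance LDA is trained on the
population response averaged in one 500 ms window and tested in every other
window, with one leave-one-trial-out partition reused across all window
pairs so every matrix entry reflects the same amount of training and test
data.  Change vs a post-cue reference is quantified with the cross-validated
(unbiased) Mahalanobis distance, and actual/imagined coding overlap with a
cross-validated sliding-window pattern correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoding import VAR_FLOOR
from .preprocess import BinnedTensor
from .session import ConditionLabel

__all__ = [
    "DynClassMatrix",
    "CrossnobisSeries",
    "DynFormatCorr",
    "DynPCA",
    "window_average",
    "dynamic_classification",
    "crossnobis_distance",
    "crossnobis_timecourse",
    "unit_dynamic_pca",
    "dynamic_format_correlation",
]


def window_average(binned: BinnedTensor, onsets: np.ndarray, window: float) -> np.ndarray:
    """Mean rate (Hz) per unit x trial x window, windows [onset, onset+window).

    Window edges must fall on bin edges of the tensor.
    """
    onsets = np.asarray(onsets, dtype=float)
    nb = binned.n_bins
    cum = np.concatenate(
        [np.zeros(binned.counts.shape[:2] + (1,)), np.cumsum(binned.counts, axis=2)], axis=2
    )
    start_f = (onsets - binned.t_start) / binned.bin_size
    len_f = window / binned.bin_size
    starts = np.round(start_f).astype(int)
    length = int(round(len_f))
    if np.any(np.abs(start_f - starts) > 1e-6) or abs(len_f - length) > 1e-6:
        raise ValueError("window onsets and size must align with tensor bin edges")
    if starts.min() < 0 or (starts + length).max() > nb:
        raise ValueError("a window extends outside the binned range")
    sums = cum[:, :, starts + length] - cum[:, :, starts]
    return sums / window


def default_onsets(t_first: float, t_last: float, step: float = 0.1) -> np.ndarray:
    """Window-onset grid from t_first to t_last inclusive."""
    n = int(round((t_last - t_first) / step))
    return t_first + step * np.arange(n + 1)


@dataclass
class DynClassMatrix:
    """Train-window x test-window cross-validated accuracy matrix."""

    accuracy: np.ndarray  # (n_windows, n_windows)
    window_onsets: np.ndarray
    window_size: float
    step: float
    scope: str  # "population" or "single_unit"
    classes: list

    @property
    def chance(self) -> float:
        return 1.0 / len(self.classes)


def _loo_dynamic_accuracy(W: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Generalization accuracy over all window pairs, leave-one-trial-out.

    W: trials x windows x units; y: class index per trial.  The same fold
    partition (each trial held out once) is reused at every window pair.
    """
    n_trials, n_w, n_u = W.shape
    counts = np.bincount(y, minlength=k).astype(float)
    S1 = np.zeros((k, n_w, n_u))
    S2 = np.zeros((k, n_w, n_u))
    for c in range(k):
        S1[c] = W[y == c].sum(axis=0)
        S2[c] = (W[y == c] ** 2).sum(axis=0)

    correct = np.zeros((n_w, n_w))
    for t in range(n_trials):
        c_t = y[t]
        n_c = counts.copy()
        n_c[c_t] -= 1
        s1 = S1.copy()
        s2 = S2.copy()
        s1[c_t] -= W[t]
        s2[c_t] -= W[t] ** 2
        means = s1 / n_c[:, None, None]
        # pooled within-class variance per (window, unit)
        ss = (s2 - n_c[:, None, None] * means**2).sum(axis=0)
        var = np.maximum(ss / max(n_trials - 1 - k, 1), VAR_FLOOR)
        invv = 1.0 / var  # (n_w, n_u)
        x = W[t]  # (n_w, n_u) test features at every window
        A = (x**2) @ invv.T  # (j_test, i_train)
        C = np.einsum("ju,ciu,iu->icj", x, means, invv, optimize=True)
        D = np.einsum("ciu,iu->ic", means**2, invv)
        # score[i, c, j] up to a -1/2 factor; argmax over c (ties -> first class)
        scores = -(A.T[:, None, :] - 2 * C + D[:, :, None])
        pred = np.argmax(scores, axis=1)  # (i, j)
        correct += pred == c_t
    return correct / n_trials


def dynamic_classification(
    binned: BinnedTensor,
    conditions: list,
    window: float = 0.5,
    step: float = 0.1,
    onsets: np.ndarray | None = None,
    scope: str = "population",
):
    """Cross-temporal classification matrix (population, or one per unit).

    Trials are restricted to ``conditions``; features are window-averaged
    rates.  ``scope="single_unit"`` runs the identical procedure per unit on
    its one-dimensional feature and returns a list of matrices.
    """
    if scope not in ("population", "single_unit"):
        raise ValueError(f"unknown scope {scope!r}")
    if onsets is None:
        onsets = default_onsets(binned.t_start, binned.t_end - window, step)
    keep = np.flatnonzero([lab in conditions for lab in binned.labels])
    if keep.size == 0:
        raise ValueError("no trials match the requested conditions")
    y = np.array([conditions.index(binned.labels[i]) for i in keep])
    k = len(conditions)
    Wavg = window_average(binned, onsets, window)[:, keep, :]  # units x trials x windows
    W = np.transpose(Wavg, (1, 2, 0))  # trials x windows x units

    if scope == "population":
        acc = _loo_dynamic_accuracy(W, y, k)
        return DynClassMatrix(
            accuracy=acc,
            window_onsets=np.asarray(onsets),
            window_size=window,
            step=step,
            scope=scope,
            classes=list(conditions),
        )
    out = []
    for u in range(W.shape[2]):
        acc = _loo_dynamic_accuracy(W[:, :, u : u + 1], y, k)
        out.append(
            DynClassMatrix(
                accuracy=acc,
                window_onsets=np.asarray(onsets),
                window_size=window,
                step=step,
                scope=scope,
                classes=list(conditions),
            )
        )
    return out


@dataclass
class CrossnobisSeries:
    """Cross-validated Mahalanobis distance per window (may be negative)."""

    distance: np.ndarray  # mean over conditions, per window
    per_condition: np.ndarray  # conditions x windows
    window_onsets: np.ndarray
    reference_window: tuple
    conditions: list


def crossnobis_distance(
    X_target: np.ndarray,
    X_ref: np.ndarray,
    inv_var: np.ndarray,
    n_splits: int,
    rng: np.random.Generator,
) -> float:
    """Unbiased squared Mahalanobis distance between target and reference.

    ``X_target`` and ``X_ref`` are paired trials x units samples of the same
    trials at two windows.  Trials are split 50-50; the fold-1 and fold-2
    mean difference vectors are whitened by the diagonal ``inv_var`` and
    multiplied, so independent noise cancels in expectation.
    """
    n = X_target.shape[0]
    if n < 2:
        raise ValueError("need at least 2 trials")
    delta = X_target - X_ref
    half = n // 2
    est = 0.0
    for _ in range(n_splits):
        perm = rng.permutation(n)
        d1 = delta[perm[:half]].mean(axis=0)
        d2 = delta[perm[half:]].mean(axis=0)
        est += float(np.sum(d1 * inv_var * d2))
    return est / n_splits


def crossnobis_timecourse(
    binned: BinnedTensor,
    conditions: list,
    reference_window: tuple = (0.25, 0.75),
    window: float = 0.5,
    step: float = 0.1,
    onsets: np.ndarray | None = None,
    n_splits: int = 20,
    seed: int = 0,
) -> CrossnobisSeries:
    """Crossnobis distance of every window from the post-cue reference.

    The diagonal noise covariance is pooled from reference-window residuals
    around condition means, floored like the decoder variances.  Distances
    are computed per condition and averaged.
    """
    if onsets is None:
        onsets = default_onsets(binned.t_start, binned.t_end - window, step)
    keep = np.flatnonzero([lab in conditions for lab in binned.labels])
    y = np.array([conditions.index(binned.labels[i]) for i in keep])
    ref = window_average(binned, np.array([reference_window[0]]), reference_window[1] - reference_window[0])[:, keep, 0]
    Wavg = window_average(binned, onsets, window)[:, keep, :]  # units x trials x windows

    # pooled diagonal covariance from reference residuals
    resid_ss = np.zeros(binned.counts.shape[0])
    dof = 0
    for c in range(len(conditions)):
        vals = ref[:, y == c]
        resid_ss += np.sum((vals - vals.mean(axis=1, keepdims=True)) ** 2, axis=1)
        dof += vals.shape[1] - 1
    var = np.maximum(resid_ss / max(dof, 1), VAR_FLOOR)
    if not np.all(np.isfinite(var)) or np.any(var <= 0):
        raise ValueError("singular reference covariance")
    inv_var = 1.0 / var

    rng = np.random.default_rng(seed)
    per_cond = np.empty((len(conditions), len(onsets)))
    for c in range(len(conditions)):
        rows = np.flatnonzero(y == c)
        for w in range(len(onsets)):
            per_cond[c, w] = crossnobis_distance(
                Wavg[:, rows, w].T, ref[:, rows].T, inv_var, n_splits, rng
            )
    return CrossnobisSeries(
        distance=per_cond.mean(axis=0),
        per_condition=per_cond,
        window_onsets=np.asarray(onsets),
        reference_window=tuple(reference_window),
        conditions=list(conditions),
    )


@dataclass
class DynPCA:
    """PCA of single-unit dynamic classification matrices."""

    components: np.ndarray  # n_components x windows x windows
    variance_explained: np.ndarray
    mean_matrix: np.ndarray
    degenerate: bool


def unit_dynamic_pca(per_unit_matrices: list) -> DynPCA:
    """Mean-centered PCA with units as the independent observations.

    Each unit's train x test accuracy matrix is flattened to one observation;
    components are reshaped back to matrix form.  All-identical inputs give a
    flagged degenerate result.
    """
    if len(per_unit_matrices) < 3:
        raise ValueError("need at least 3 units")
    shape = per_unit_matrices[0].accuracy.shape
    rows = []
    for m in per_unit_matrices:
        if m.accuracy.shape != shape:
            raise ValueError("matrices must share one shape")
        rows.append(m.accuracy.ravel())
    X = np.array(rows)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 1e-24:
        return DynPCA(
            components=np.zeros((1,) + shape),
            variance_explained=np.zeros(1),
            mean_matrix=mean.reshape(shape),
            degenerate=True,
        )
    var_exp = s**2 / total
    comps = Vt.reshape(-1, *shape)
    return DynPCA(
        components=comps,
        variance_explained=var_exp,
        mean_matrix=mean.reshape(shape),
        degenerate=False,
    )


@dataclass
class DynFormatCorr:
    """Within- and across-format sliding-window pattern correlations."""

    corr: np.ndarray  # (2 formats train, 2 formats test, windows, windows)
    formats: tuple
    window_onsets: np.ndarray
    n_splits: int

    def pair(self, train_format: str, test_format: str) -> np.ndarray:
        i = self.formats.index(train_format)
        j = self.formats.index(test_format)
        return self.corr[i, j]


def dynamic_format_correlation(
    binned: BinnedTensor,
    parts: tuple = ("cheek", "shoulder"),
    window: float = 0.5,
    step: float = 0.1,
    onsets: np.ndarray | None = None,
    n_splits: int = 50,
    seed: int = 0,
) -> DynFormatCorr:
    """Cross-validated actual vs imagined pattern correlation over windows.

    Uses right-side trials of the two given body parts in both formats.  Per
    50-50 trial split and window, a (2N x 2) matrix of trial-averaged rates
    (rows: units x parts, columns: formats) is built for each half and its
    global mean subtracted; the correlation between a train-half column at
    window i and a test-half column at window j is their cosine after this
    centering, averaged over splits.
    """
    formats = ("actual", "imagery")
    if onsets is None:
        onsets = default_onsets(binned.t_start, binned.t_end - window, step)
    trial_sets = {}
    for fmt in formats:
        for part in parts:
            cond = ConditionLabel(part, "right", fmt)
            idx = np.flatnonzero([lab == cond for lab in binned.labels])
            if len(idx) < 4:
                raise ValueError(f"condition {cond} needs at least 4 trials")
            trial_sets[(fmt, part)] = idx

    Wavg = window_average(binned, onsets, window)  # units x trials x windows
    n_w = len(onsets)
    rng = np.random.default_rng(seed)
    acc = np.zeros((2, 2, n_w, n_w))
    for _ in range(n_splits):
        halves = {"train": {}, "test": {}}
        for key, idx in trial_sets.items():
            perm = rng.permutation(idx)
            cut = (len(idx) + 1) // 2
            halves["train"][key] = Wavg[:, perm[:cut], :].mean(axis=1)
            halves["test"][key] = Wavg[:, perm[cut:], :].mean(axis=1)
        cols = {}
        for half in ("train", "test"):
            # (windows, formats, units*parts)
            stack = np.stack(
                [
                    np.concatenate([halves[half][(fmt, part)] for part in parts], axis=0)
                    for fmt in formats
                ],
                axis=0,
            )  # formats x 2N x windows
            stack = np.transpose(stack, (2, 0, 1))  # windows x formats x 2N
            stack = stack - stack.mean(axis=(1, 2), keepdims=True)
            cols[half] = stack
        a = cols["train"]
        b = cols["test"]
        na = np.sqrt(np.sum(a**2, axis=2))
        nb = np.sqrt(np.sum(b**2, axis=2))
        dots = np.einsum("ifn,jgn->fgij", a, b, optimize=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = dots / (na.T[:, None, :, None] * nb.T[None, :, None, :])
        acc += np.nan_to_num(corr, nan=0.0)
    return DynFormatCorr(
        corr=acc / n_splits,
        formats=formats,
        window_onsets=np.asarray(onsets),
        n_splits=n_splits,
    )
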