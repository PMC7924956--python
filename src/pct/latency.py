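"""Population response-latency estimation.

The population time course is summarised by the first principal component of
the units x (time * condition * repetition) activity matrix, averaged over
conditions and repetitions.  A continuous three-segment piecewise-linear
function (baseline, rise, plateau) is fit by least squares with both
breakpoints free, and latency is read off as the earliest time the fitted
function crosses the 95th percentile of the pre-stimulus baseline values.
Uncertainty comes from re-estimating on bootstrap resamples of the
single-trial PC1 traces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .preprocess import BinnedTensor
from .similarity import correlation_contrast_test

__all__ = [
    "PopulationTimeSeries",
    "PiecewiseFit",
    "LatencyEstimate",
    "population_pc1",
    "fit_piecewise_linear",
    "estimate_latency",
    "bootstrap_latency",
    "latency_side_test",
]

logger = logging.getLogger(__name__)


@dataclass
class PopulationTimeSeries:
    """PC1 population time course with per-trial projections."""

    values: np.ndarray  # mean PC1 score per bin
    times: np.ndarray  # bin centers, s relative to the alignment event
    trial_traces: np.ndarray  # trials x bins, single-trial PC1 projections
    loadings: np.ndarray  # unit weights (sign-oriented)
    conditions: list
    sign_flipped: bool


@dataclass
class PiecewiseFit:
    """Continuous 3-segment piecewise-linear least-squares fit.

    The function is beta0 + beta1*t + beta2*(t-tau1)_+ + beta3*(t-tau2)_+,
    so segment slopes are beta1, beta1+beta2 and beta1+beta2+beta3.
    """

    tau1: float
    tau2: float
    coef: np.ndarray  # (4,)
    sse: float
    degenerate: bool = False

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            self.coef[0]
            + self.coef[1] * t
            + self.coef[2] * np.maximum(t - self.tau1, 0.0)
            + self.coef[3] * np.maximum(t - self.tau2, 0.0)
        )

    @property
    def slopes(self) -> tuple:
        b = self.coef
        return (float(b[1]), float(b[1] + b[2]), float(b[1] + b[2] + b[3]))


@dataclass
class LatencyEstimate:
    """Point latency with optional bootstrap spread."""

    latency: float  # seconds; nan when undefined
    defined: bool
    baseline_threshold: float
    fit: PiecewiseFit
    bootstrap_samples: np.ndarray | None = None
    iqr: tuple | None = None  # (q25, q75)


def population_pc1(binned: BinnedTensor, conditions=None) -> PopulationTimeSeries:
    """First principal component of the population response.

    The units x (time * trial) matrix is row-centered and decomposed by SVD;
    single-trial traces are the projections of each trial's unit x time slice
    onto the PC1 loadings.  The sign is oriented so the post-event mean of the
    averaged trace exceeds its pre-event mean.
    """
    if binned.counts.shape[0] < 2:
        raise ValueError("population PC1 needs at least 2 units")
    if conditions is not None:
        keep = np.flatnonzero([lab in conditions for lab in binned.labels])
        if keep.size == 0:
            raise ValueError("no trials match the requested conditions")
        counts = binned.counts[:, keep, :]
        used_conditions = list(conditions)
    else:
        counts = binned.counts
        used_conditions = list(dict.fromkeys(binned.labels))

    n_units, n_trials, n_bins = counts.shape
    D = counts.reshape(n_units, n_trials * n_bins)
    unit_mean = D.mean(axis=1)
    Dc = D - unit_mean[:, None]
    U, _, _ = np.linalg.svd(Dc, full_matrices=False)
    loadings = U[:, 0]

    centered = counts - unit_mean[:, None, None]
    traces = np.einsum("u,utb->tb", loadings, centered)
    mean_trace = traces.mean(axis=0)
    times = binned.bin_centers()
    post = times > 0
    flipped = False
    if mean_trace[post].mean() < mean_trace[~post].mean():
        loadings = -loadings
        traces = -traces
        mean_trace = -mean_trace
        flipped = True
    return PopulationTimeSeries(
        values=mean_trace,
        times=times,
        trial_traces=traces,
        loadings=loadings,
        conditions=used_conditions,
        sign_flipped=flipped,
    )


class _BreakpointGrid:
    """Exhaustive least-squares search over breakpoint pairs on the time grid.

    For every candidate pair (tau1 < tau2) the 4-parameter linear fit is
    solved through precomputed Gram matrices, so re-fitting new data vectors
    (bootstrap resamples) costs one matrix-vector product per candidate pair.
    """

    def __init__(self, t: np.ndarray, min_sep: int = 2):
        self.t = np.asarray(t, dtype=float)
        T = len(t)
        if T < 10:
            raise ValueError("need at least 10 bins for the piecewise fit")
        cand = np.arange(1, T - 1)
        self.tau = self.t[cand]
        n_tau = len(cand)
        B = np.maximum(self.t[None, :] - self.tau[:, None], 0.0)  # n_tau x T
        self.B = B
        ii, jj = np.meshgrid(np.arange(n_tau), np.arange(n_tau), indexing="ij")
        mask = (jj - ii) >= min_sep
        self.I = ii[mask]
        self.J = jj[mask]
        P = len(self.I)

        one = np.ones(T)
        S_BB = B @ B.T
        S_B1 = B @ one
        S_Bt = B @ self.t
        n = float(T)
        St = self.t.sum()
        Stt = float(self.t @ self.t)

        G = np.empty((P, 4, 4))
        G[:, 0, 0] = n
        G[:, 0, 1] = G[:, 1, 0] = St
        G[:, 1, 1] = Stt
        G[:, 0, 2] = G[:, 2, 0] = S_B1[self.I]
        G[:, 0, 3] = G[:, 3, 0] = S_B1[self.J]
        G[:, 1, 2] = G[:, 2, 1] = S_Bt[self.I]
        G[:, 1, 3] = G[:, 3, 1] = S_Bt[self.J]
        G[:, 2, 2] = S_BB[self.I, self.I]
        G[:, 2, 3] = G[:, 3, 2] = S_BB[self.I, self.J]
        G[:, 3, 3] = S_BB[self.J, self.J]
        # tiny ridge for numerically singular corner candidates
        G += 1e-10 * np.eye(4)[None, :, :] * max(1.0, Stt)
        self.Ginv = np.linalg.inv(G)

    def fit(self, y: np.ndarray):
        """Best (tau1, tau2, coef, sse) over the candidate grid for data y."""
        y = np.asarray(y, dtype=float)
        S_By = self.B @ y
        rhs = np.empty((len(self.I), 4))
        rhs[:, 0] = y.sum()
        rhs[:, 1] = self.t @ y
        rhs[:, 2] = S_By[self.I]
        rhs[:, 3] = S_By[self.J]
        beta = np.einsum("pij,pj->pi", self.Ginv, rhs)
        syy = float(y @ y)
        sse = syy - np.einsum("pi,pi->p", beta, rhs)
        best = int(np.argmin(sse))
        return (
            float(self.tau[self.I[best]]),
            float(self.tau[self.J[best]]),
            beta[best].copy(),
            float(max(sse[best], 0.0)),
        )


def _sse_at(t: np.ndarray, y: np.ndarray, tau1: float, tau2: float):
    X = np.column_stack(
        [
            np.ones_like(t),
            t,
            np.maximum(t - tau1, 0.0),
            np.maximum(t - tau2, 0.0),
        ]
    )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def fit_piecewise_linear(
    ts: PopulationTimeSeries,
    n_breakpoints: int = 2,
    refine: bool = True,
    grid: "_BreakpointGrid | None" = None,
) -> PiecewiseFit:
    """Globally fit the 3-segment piecewise-linear model.

    The breakpoint pair is found by exhaustive search over the bin-position
    grid, optionally followed by continuous Nelder-Mead refinement.  A flat
    series yields a zero-residual fit flagged as degenerate.
    """
    if n_breakpoints != 2:
        raise ValueError("only n_breakpoints=2 (3 segments) is supported")
    t, y = ts.times, ts.values
    if np.ptp(y) < 1e-12 * max(1.0, float(np.abs(y).max())):
        # flat series: any breakpoint pair fits exactly; flag as degenerate
        mid = t[0] + (t[-1] - t[0]) / 3
        return PiecewiseFit(
            tau1=float(mid),
            tau2=float(2 * mid),
            coef=np.array([float(y.mean()), 0.0, 0.0, 0.0]),
            sse=0.0,
            degenerate=True,
        )
    if grid is None:
        grid = _BreakpointGrid(t)
    tau1, tau2, coef, sse = grid.fit(y)

    if refine and np.ptp(y) > 0:
        span = t[-1] - t[0]

        def objective(params):
            a, b = params
            if not (t[0] < a < b < t[-1]) or (b - a) < 1e-4 * span:
                return np.inf
            return _sse_at(t, y, a, b)[0]

        res = optimize.minimize(
            objective,
            x0=[tau1, tau2],
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-12, "maxiter": 200},
        )
        if np.isfinite(res.fun) and res.fun <= sse:
            tau1, tau2 = float(res.x[0]), float(res.x[1])
            sse, coef = _sse_at(t, y, tau1, tau2)

    return PiecewiseFit(tau1=tau1, tau2=tau2, coef=np.asarray(coef), sse=sse)


def _crossing_time(fit: PiecewiseFit, threshold: float, t_start: float, t_end: float):
    """Earliest t in [t_start, t_end] where the fitted function exceeds threshold."""
    knots = [t_start] + [k for k in (fit.tau1, fit.tau2) if t_start < k < t_end] + [t_end]
    for a, b in zip(knots[:-1], knots[1:]):
        fa, fb = float(fit(a)), float(fit(b))
        if fa > threshold:
            return a
        slope = (fb - fa) / (b - a) if b > a else 0.0
        if slope > 0 and fb > threshold:
            return a + (threshold - fa) / slope
    if float(fit(t_end)) > threshold:
        return t_end
    return None


def estimate_latency(
    ts: PopulationTimeSeries,
    fit: PiecewiseFit,
    baseline_window: tuple = (-0.150, 0.0),
    percentile: float = 95.0,
) -> LatencyEstimate:
    """Latency = earliest crossing of the fit above the baseline percentile.

    The threshold is the given percentile of the *raw* (not fitted) PC1
    values inside the baseline window.  A never-crossing fit yields a
    flagged undefined estimate rather than an exception.
    """
    lo, hi = baseline_window
    in_base = (ts.times >= lo) & (ts.times < hi)
    if not in_base.any():
        raise ValueError("baseline window contains no bins")
    threshold = float(np.percentile(ts.values[in_base], percentile))
    t_cross = _crossing_time(fit, threshold, lo, float(ts.times[-1]))
    if t_cross is None:
        return LatencyEstimate(
            latency=float("nan"), defined=False, baseline_threshold=threshold, fit=fit
        )
    return LatencyEstimate(
        latency=float(t_cross), defined=True, baseline_threshold=threshold, fit=fit
    )


def bootstrap_latency(
    ts: PopulationTimeSeries,
    n_boot: int = 1000,
    seed: int = 0,
    baseline_window: tuple = (-0.150, 0.0),
    percentile: float = 95.0,
) -> LatencyEstimate:
    """Point estimate plus bootstrap IQR of the latency.

    Single-trial PC1 traces are resampled with replacement, re-averaged,
    re-fit (grid search at bin resolution) and re-thresholded.  PC1 loadings
    are fixed from the full data.  More than 20% undefined resamples logs a
    warning.
    """
    grid = _BreakpointGrid(ts.times)
    point_fit = fit_piecewise_linear(ts, grid=grid)
    point = estimate_latency(ts, point_fit, baseline_window, percentile)

    rng = np.random.default_rng(seed)
    n_trials = ts.trial_traces.shape[0]
    lo, hi = baseline_window
    in_base = (ts.times >= lo) & (ts.times < hi)
    samples = np.full(n_boot, np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n_trials, size=n_trials)
        yb = ts.trial_traces[idx].mean(axis=0)
        tau1, tau2, coef, sse = grid.fit(yb)
        fit_b = PiecewiseFit(tau1=tau1, tau2=tau2, coef=coef, sse=sse)
        thr = float(np.percentile(yb[in_base], percentile))
        t_cross = _crossing_time(fit_b, thr, lo, float(ts.times[-1]))
        if t_cross is not None:
            samples[b] = t_cross
    defined = np.isfinite(samples)
    if defined.mean() < 0.8:
        logger.warning(
            "%.0f%% of bootstrap resamples had undefined latency", 100 * (1 - defined.mean())
        )
    if defined.any():
        iqr = (
            float(np.percentile(samples[defined], 25)),
            float(np.percentile(samples[defined], 75)),
        )
    else:
        iqr = (float("nan"), float("nan"))
    return LatencyEstimate(
        latency=point.latency,
        defined=point.defined,
        baseline_threshold=point.baseline_threshold,
        fit=point_fit,
        bootstrap_samples=samples,
        iqr=iqr,
    )


def latency_side_test(
    samples_left,
    samples_right,
    n_perm: int = 2000,
    seed: int = 0,
) -> float:
    """Permutation p-value for a latency difference between body sides.

    The observed mean difference between the two latency-sample sets is
    ranked against a label-shuffle null, as in the correlation contrasts.
    """
    a = np.asarray(samples_left, dtype=float)
    b = np.asarray(samples_right, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    return correlation_contrast_test(a, b, n_shuffles=n_perm, seed=seed)
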