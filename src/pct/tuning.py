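"""Per-unit linear tuning models, FDR correction and population summaries.

Firing rate in the stimulus window is modelled per unit as

    FR = beta0 + sum_c beta_c X_c

with one indicator ``X_c`` per condition and all baseline-window samples
pooled as the zero-indicator reference.  A unit is *responsive* to a
condition if the t-test on ``beta_c`` survives Benjamini-Hochberg FDR
(one family pooling all unit x condition tests), and *tuned* if the overall
F-test on the condition coefficients survives FDR across units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import FiringRateMatrix

__all__ = [
    "TuningResult",
    "PopulationSummary",
    "fit_linear_tuning",
    "fdr_correct",
    "population_summary",
    "anova_discrimination",
]

_VAR_EPS = 1e-12


@dataclass
class TuningResult:
    """Linear-model output for one unit."""

    unit_id: str
    conditions: list
    beta0: float
    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    F: float
    p_F: float
    responsive: np.ndarray  # bool per condition, post-FDR
    tuned: bool  # post-FDR F-test

    def responsive_to(self, cond) -> bool:
        return bool(self.responsive[self.conditions.index(cond)])


@dataclass
class PopulationSummary:
    """Population tuning summary with bootstrap CIs."""

    conditions: list
    fraction_responsive: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_responsive: int
    n_tuned: int
    n_units: int
    chi2: float
    chi2_p: float


def fdr_correct(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up: (rejected flags, monotone adjusted p)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj


def fit_linear_tuning(
    rates: FiringRateMatrix,
    baseline: FiringRateMatrix | None,
    q: float = 0.05,
) -> list:
    """Fit the indicator-variable model for every unit.

    ``rates`` holds stimulus-window samples (labelled by condition);
    ``baseline`` holds the pre-cue samples, pooled with all indicators at
    zero.  With ``baseline=None`` the model is fit on stimulus samples only,
    in which case its F-test is algebraically the one-way ANOVA across
    conditions.  Degenerate zero-residual-variance fits get p=1 and
    tuned=False.
    """
    conds = rates.conditions()
    k = len(conds)
    for cond in conds:
        if len(rates.condition_trials(cond)) < 2:
            raise ValueError(f"condition {cond} has fewer than 2 samples")
    if baseline is not None and rates.n_units != baseline.n_units:
        raise ValueError("rates and baseline must cover the same units")

    if baseline is not None:
        Y = np.concatenate([rates.rates, baseline.rates], axis=1).T  # samples x units
    else:
        Y = rates.rates.T
    n_samples = Y.shape[0]
    X = np.zeros((n_samples, k + 1))
    X[:, 0] = 1.0
    cond_index = {c: j for j, c in enumerate(conds)}
    for i, lab in enumerate(rates.labels):
        X[i, 1 + cond_index[lab]] = 1.0

    # Without baseline rows the intercept and indicators are collinear; the
    # pseudoinverse fit with rank-based dof keeps the F-test exact either way.
    rank = np.linalg.matrix_rank(X)
    df_model = rank - 1
    dof = n_samples - rank
    if dof < 1:
        raise ValueError("not enough samples for the linear model")
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y  # (k+1) x units
    resid = Y - X @ beta
    ssr = np.sum(resid**2, axis=0)
    s2 = ssr / dof
    se = np.sqrt(np.outer(np.diag(pinv @ pinv.T), s2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    # Zero residual variance: no evidence against the null is quantifiable.
    degenerate = s2 <= _VAR_EPS
    pvals[:, degenerate] = 1.0

    sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((sst - ssr) / df_model) / (ssr / dof)
    p_F = stats.f.sf(F, df_model, dof)
    F = np.where(sst - ssr <= _VAR_EPS, 0.0, F)
    p_F = np.where(sst - ssr <= _VAR_EPS, 1.0, p_F)
    p_F = np.where(degenerate, 1.0, p_F)

    # One pooled BH family over all unit x condition t-tests.
    flat_p = pvals[1:, :].T.ravel()
    reject_t, _ = fdr_correct(flat_p, q)
    responsive = reject_t.reshape(Y.shape[1], k)
    reject_f, _ = fdr_correct(p_F, q)

    results = []
    for j, uid in enumerate(rates.unit_ids):
        results.append(
            TuningResult(
                unit_id=uid,
                conditions=list(conds),
                beta0=float(beta[0, j]),
                beta=beta[1:, j].copy(),
                t=tvals[1:, j].copy(),
                p=pvals[1:, j].copy(),
                F=float(F[j]),
                p_F=float(p_F[j]),
                responsive=responsive[j].copy(),
                tuned=bool(reject_f[j]),
            )
        )
    return results


def anova_discrimination(rates: FiringRateMatrix):
    """One-way ANOVA across conditions per unit: arrays (F, p).

    Uses stimulus-window samples only (no baseline pooling); algebraically
    identical to the linear model's F-test when baseline is excluded.
    """
    conds = rates.conditions()
    if len(conds) < 2:
        raise ValueError("need at least 2 conditions")
    groups = []
    for cond in conds:
        idx = rates.condition_trials(cond)
        if len(idx) < 2:
            raise ValueError(f"condition {cond} has fewer than 2 trials")
        groups.append(rates.rates[:, idx])

    n_units = rates.n_units
    N = sum(g.shape[1] for g in groups)
    grand = np.concatenate(groups, axis=1).mean(axis=1)
    ssb = np.zeros(n_units)
    ssw = np.zeros(n_units)
    for g in groups:
        mean_g = g.mean(axis=1)
        ssb += g.shape[1] * (mean_g - grand) ** 2
        ssw += np.sum((g - mean_g[:, None]) ** 2, axis=1)
    df_b = len(groups) - 1
    df_w = N - len(groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    p = stats.f.sf(F, df_b, df_w)
    # Degenerate cases: no between-group variance -> F=0, p=1; perfect
    # separation with zero within-group variance -> p at machine floor.
    zero_between = ssb <= _VAR_EPS
    F = np.where(zero_between, 0.0, F)
    p = np.where(zero_between, 1.0, p)
    perfect = (ssw <= _VAR_EPS) & ~zero_between
    F = np.where(perfect, np.inf, F)
    p = np.where(perfect, 0.0, p)
    return F, p


def population_summary(
    results: list,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> PopulationSummary:
    """Responsive fractions with percentile bootstrap CIs over units, plus a
    chi-square goodness-of-fit (df=1) of the responsive unit count against the
    alpha*N count expected by chance."""
    if len(results) < 2:
        raise ValueError("need at least 2 units")
    conds = results[0].conditions
    resp = np.array([r.responsive for r in results])  # units x conditions
    n_units = resp.shape[0]
    frac = resp.mean(axis=0)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_units, size=(n_boot, n_units))
    boot_frac = resp[idx].mean(axis=1)  # n_boot x conditions
    ci_low = np.percentile(boot_frac, 2.5, axis=0)
    ci_high = np.percentile(boot_frac, 97.5, axis=0)

    any_resp = int(resp.any(axis=1).sum())
    expected = np.array([alpha * n_units, (1 - alpha) * n_units])
    observed = np.array([any_resp, n_units - any_resp])
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    chi2_p = float(stats.chi2.sf(chi2, df=1))

    return PopulationSummary(
        conditions=list(conds),
        fraction_responsive=frac,
        ci_low=np.minimum(ci_low, frac),
        ci_high=np.maximum(ci_high, frac),
        n_responsive=any_resp,
        n_tuned=int(sum(r.tuned for r in results)),
        n_units=n_units,
        chi2=chi2,
        chi2_p=chi2_p,
    )
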