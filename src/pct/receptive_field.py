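"""Receptive-field characterisation.

Covers four analyses: tallies of how many lateralised body parts each unit
responds to per side; classification of response profiles over four
collinear sites as single- vs multi-peaked; Gaussian receptive-field sizing
(FWHM) over the nine-site gradient; and single-unit mirror-symmetry R^2
comparing left-side predictions from left-side vs right-side tuning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .preprocess import FiringRateMatrix
from .session import ConditionLabel
from .simulate import LATERAL_PARTS
from .tuning import anova_discrimination, fdr_correct

__all__ = [
    "FieldCountMatrix",
    "GaussianRF",
    "MirrorR2",
    "field_count_matrix",
    "classify_peak_structure",
    "fit_rf_gaussian",
    "mirror_symmetry_r2",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class FieldCountMatrix:
    """Counts of units by (number of left fields, number of right fields)."""

    counts: np.ndarray  # 5 x 5, rows = left count 0..4, cols = right count 0..4

    @property
    def n_units(self) -> int:
        return int(self.counts.sum())

    @property
    def diagonal_fraction(self) -> float:
        return float(np.trace(self.counts) / max(self.counts.sum(), 1))


def field_count_matrix(tuning_results: list) -> FieldCountMatrix:
    """Tally FDR-significant lateralised fields per side for every unit.

    Considers the four body parts tested on both sides (back of head, cheek,
    neck, shoulder), so each unit contributes one count in 0..4 per side.
    """
    counts = np.zeros((5, 5), dtype=int)
    for res in tuning_results:
        n_side = {"left": 0, "right": 0}
        seen = {"left": 0, "right": 0}
        for j, cond in enumerate(res.conditions):
            if cond.body_part in LATERAL_PARTS and cond.side in ("left", "right"):
                seen[cond.side] += 1
                if res.responsive[j]:
                    n_side[cond.side] += 1
        if seen["left"] != len(LATERAL_PARTS) or seen["right"] != len(LATERAL_PARTS):
            raise ValueError(
                f"unit {res.unit_id}: tuning lacks the full set of lateralised conditions"
            )
        counts[n_side["left"], n_side["right"]] += 1
    return FieldCountMatrix(counts=counts)


def classify_peak_structure(
    rates: FiringRateMatrix,
    ordered_sites: list,
    alpha: float = 0.05,
    criterion: str = "significant_reversal",
) -> list:
    """Classify each unit's profile over 4 collinear sites.

    Units without an FDR-significant ANOVA across the four sites are
    ``not_selective``.  For selective units the preferred site is the argmax
    of the mean rates (ties to the earlier site); walking outward from the
    peak, each adjacent pair beyond the peak is tested one-tailed.  Under the
    default ``significant_reversal`` criterion a unit is ``multi_peak`` when
    any farther site significantly exceeds its nearer neighbour
    (Benjamini-Hochberg over the unit's pair tests); under
    ``nonsignificant_decay`` it is ``multi_peak`` when any nearer-greater
    test fails to reach corrected significance.
    """
    if len(ordered_sites) != 4:
        raise ValueError("ordered_sites must name exactly 4 collinear conditions")
    if criterion not in ("significant_reversal", "nonsignificant_decay"):
        raise ValueError(f"unknown criterion {criterion!r}")
    sub = rates.subset_conditions(ordered_sites)
    groups = [sub.rates[:, sub.condition_trials(c)] for c in ordered_sites]
    for c, g in zip(ordered_sites, groups):
        if g.shape[1] < 2:
            raise ValueError(f"site {c} has fewer than 2 trials")
    _, p_anova = anova_discrimination(sub)
    selective, _ = fdr_correct(p_anova, alpha)

    labels = []
    for u in range(sub.n_units):
        if not selective[u]:
            labels.append("not_selective")
            continue
        means = np.array([g[u].mean() for g in groups])
        peak = int(np.argmax(means))  # argmax ties break toward the list start
        pairs = []  # (nearer_idx, farther_idx) strictly beyond the peak
        for j in range(peak + 1, 3):
            pairs.append((j, j + 1))
        for j in range(peak - 1, 0, -1):
            pairs.append((j, j - 1))
        if not pairs:
            labels.append("single_peak")
            continue
        pvals = []
        for nearer, farther in pairs:
            if criterion == "significant_reversal":
                res = stats.ttest_ind(groups[farther][u], groups[nearer][u], alternative="greater")
            else:
                res = stats.ttest_ind(groups[nearer][u], groups[farther][u], alternative="greater")
            pvals.append(res.pvalue if np.isfinite(res.pvalue) else 1.0)
        reject, _ = fdr_correct(np.array(pvals), alpha)
        if criterion == "significant_reversal":
            multi = bool(reject.any())
        else:
            multi = bool((~reject).any())
        labels.append("multi_peak" if multi else "single_peak")
    return labels


@dataclass
class GaussianRF:
    """Fixed-center Gaussian receptive field: A*exp(-((x-mu)/sigma)^2/2)+c."""

    amplitude: float  # Hz
    sigma: float  # cm
    offset: float  # Hz
    mu: float  # cm (fixed at the preferred site)
    flagged: bool = False

    @property
    def fwhm(self) -> float:
        """Field size as full width at half maximum, 2*sqrt(2 ln 2)*sigma."""
        return FWHM_FACTOR * self.sigma


def fit_rf_gaussian(
    profile: np.ndarray,
    preferred: int,
    site_spacing: float = 2.0,
) -> GaussianRF:
    """Nonlinear least-squares Gaussian fit to a 9-site response profile.

    ``preferred`` is the index (0-based) of the maximal site; the Gaussian
    center is fixed at its coordinate.  Sites sit at spacing*1..9 cm.  Flat
    or unidentifiable profiles are returned flagged rather than raising.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (9,):
        raise ValueError("profile must have exactly 9 sites")
    x = site_spacing * np.arange(1, 10)
    mu = float(x[preferred])

    if np.ptp(profile) < 1e-12:
        return GaussianRF(
            amplitude=0.0, sigma=site_spacing, offset=float(profile.mean()), mu=mu, flagged=True
        )

    def model(xv, A, sigma, c):
        return A * np.exp(-0.5 * ((xv - mu) / sigma) ** 2) + c

    best = None
    for sigma0 in (site_spacing, 2 * site_spacing, 4 * site_spacing):
        try:
            popt, _ = optimize.curve_fit(
                model,
                x,
                profile,
                p0=[profile[preferred] - profile.min(), sigma0, profile.min()],
                bounds=([0.0, 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((model(x, *popt) - profile) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        return GaussianRF(
            amplitude=0.0, sigma=site_spacing, offset=float(profile.mean()), mu=mu, flagged=True
        )
    A, sigma, c = best[0]
    flagged = A < 1e-6 or sigma > 10 * site_spacing * 9
    return GaussianRF(amplitude=float(A), sigma=float(sigma), offset=float(c), mu=mu, flagged=flagged)


@dataclass
class MirrorR2:
    """Cross-validated single-unit mirror-symmetry R^2 values (may be < 0)."""

    unit_id: str
    r2_within: float  # left predicted from left, leave-one-out
    r2_across: float  # left predicted from right, training size matched


def _condition_by_part(rates: FiringRateMatrix, parts, side: str):
    out = {}
    for part in parts:
        cond = ConditionLabel(part, side, "actual")
        idx = rates.condition_trials(cond)
        if len(idx) == 0:
            raise ValueError(f"missing condition {cond}")
        out[part] = idx
    return out


def mirror_symmetry_r2(
    rates_left: FiringRateMatrix,
    rates_right: FiringRateMatrix,
    parts=LATERAL_PARTS,
    seed: int = 0,
) -> list:
    """Leave-one-out R^2 of left-side responses from left vs right tuning.

    Within: each left trial is predicted by its condition's mean over the
    remaining left trials.  Across: per fold, one randomly chosen right-side
    trial is dropped (matching the training-set size) and the left trial is
    predicted by the corresponding right-side condition mean.  R^2 is
    1 - SS_res/SS_tot over the held-out predictions.
    """
    left_idx = _condition_by_part(rates_left, parts, "left")
    right_idx = _condition_by_part(rates_right, parts, "right")
    for part in parts:
        if len(left_idx[part]) < 3 or len(right_idx[part]) < 3:
            raise ValueError(f"part {part}: need at least 3 trials per condition and side")

    rng = np.random.default_rng(seed)
    results = []
    n_right_total = rates_right.n_trials
    for u, uid in enumerate(rates_left.unit_ids):
        y_true, pred_within, pred_across = [], [], []
        for part in parts:
            li = left_idx[part]
            ri = right_idx[part]
            left_vals = rates_left.rates[u, li]
            right_vals = rates_right.rates[u, ri]
            for k in range(len(li)):
                y_true.append(left_vals[k])
                rest = np.delete(left_vals, k)
                pred_within.append(rest.mean())
                # drop one random right trial anywhere to match training size
                drop = int(rng.integers(n_right_total))
                if drop in ri:
                    rv = np.delete(right_vals, int(np.flatnonzero(ri == drop)[0]))
                else:
                    rv = right_vals
                pred_across.append(rv.mean())
        y = np.array(y_true)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot <= 0:
            results.append(MirrorR2(unit_id=uid, r2_within=0.0, r2_across=0.0))
            continue
        ss_w = float(np.sum((y - np.array(pred_within)) ** 2))
        ss_a = float(np.sum((y - np.array(pred_across)) ** 2))
        results.append(
            MirrorR2(unit_id=uid, r2_within=1 - ss_w / ss_tot, r2_across=1 - ss_a / ss_tot)
        )
    return results
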