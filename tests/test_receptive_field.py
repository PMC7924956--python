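"""Field counts, peak-structure classification, Gaussian RF sizing, mirror R^2."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import pct
from pct.preprocess import FiringRateMatrix
from pct.receptive_field import FWHM_FACTOR
from pct.simulate import LATERAL_PARTS
from pct.tuning import TuningResult


def _lateral_conditions():
    return [
        pct.ConditionLabel(part, side, "actual")
        for part in LATERAL_PARTS
        for side in ("left", "right")
    ]


def _tuning_result(uid, responsive_map):
    conds = _lateral_conditions()
    resp = np.array([responsive_map.get((c.body_part, c.side), False) for c in conds])
    return TuningResult(
        unit_id=uid,
        conditions=conds,
        beta0=0.0,
        beta=np.zeros(len(conds)),
        t=np.zeros(len(conds)),
        p=np.ones(len(conds)),
        F=0.0,
        p_F=1.0,
        responsive=resp,
        tuned=True,
    )


class TestFieldCounts:
    def test_exact_tallies_for_hand_flagged_units(self):
        results = [
            _tuning_result("a", {}),  # (0, 0)
            _tuning_result("b", {("cheek", "left"): True, ("cheek", "right"): True}),  # (1, 1)
            _tuning_result(
                "c",
                {
                    ("cheek", "right"): True,
                    ("neck", "right"): True,
                    ("shoulder", "right"): True,
                },
            ),  # (0, 3)
        ]
        fc = pct.field_count_matrix(results)
        assert fc.counts[0, 0] == 1 and fc.counts[1, 1] == 1 and fc.counts[0, 3] == 1
        assert fc.n_units == 3

    def test_missing_conditions_rejected(self):
        res = _tuning_result("a", {})
        res.conditions = res.conditions[:-1]
        res.responsive = res.responsive[:-1]
        with pytest.raises(ValueError, match="lateralised"):
            pct.field_count_matrix([res])


SITES = [
    pct.ConditionLabel("forehead", "midline", "actual"),
    pct.ConditionLabel("cheek", "right", "actual"),
    pct.ConditionLabel("neck", "right", "actual"),
    pct.ConditionLabel("shoulder", "right", "actual"),
]


def _site_matrix(means, noise_sd=0.1, n_trials=10, seed=0, n_units=1):
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    for cond, m in zip(SITES, means):
        for _ in range(n_trials):
            cols.append(m)
            labels.append(cond)
    rates = np.array(cols)[None, :] + rng.normal(0, noise_sd, size=(n_units, len(cols)))
    return FiringRateMatrix(
        rates=rates,
        unit_ids=[f"u{i}" for i in range(n_units)],
        labels=labels,
        window=("go_onset", 0.5, 2.5),
    )


class TestPeakStructure:
    def test_monotone_profile_is_single_peak(self):
        rates = _site_matrix([10, 7, 4, 1], noise_sd=0.2, seed=1)
        assert pct.classify_peak_structure(rates, SITES) == ["single_peak"]

    def test_w_profile_is_multi_peak(self):
        rates = _site_matrix([10, 1, 1, 9], noise_sd=0.2, seed=2)
        assert pct.classify_peak_structure(rates, SITES) == ["multi_peak"]

    def test_flat_profile_is_not_selective(self):
        rates = _site_matrix([5, 5, 5, 5], noise_sd=0.3, seed=3)
        assert pct.classify_peak_structure(rates, SITES) == ["not_selective"]

    def test_borderline_matches_manual_t_and_bh(self):
        rates = _site_matrix([8, 5, 4.7, 5.2], noise_sd=1.0, n_trials=10, seed=4)
        got = pct.classify_peak_structure(rates, SITES)[0]
        groups = [rates.rates[0, rates.condition_trials(c)] for c in SITES]
        # peak at site 0: walk outward over pairs (1,2) and (2,3), testing the
        # farther site against the nearer one-tailed
        p1 = stats.ttest_ind(groups[2], groups[1], alternative="greater").pvalue
        p2 = stats.ttest_ind(groups[3], groups[2], alternative="greater").pvalue
        reject, _ = pct.fdr_correct([p1, p2], 0.05)
        expected = "multi_peak" if reject.any() else "single_peak"
        assert got == expected

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0.1, 50.0), min_size=4, max_size=4, unique=True))
    def test_noiseless_monotone_profiles_never_multi_peak(self, values):
        means = sorted(values, reverse=True)
        rates = _site_matrix(means, noise_sd=0.0, n_trials=5)
        label = pct.classify_peak_structure(rates, SITES)[0]
        assert label != "multi_peak"


class TestGaussianRF:
    def test_exact_gaussian_recovers_sigma_and_fwhm(self):
        x = 2.0 * np.arange(1, 10)
        profile = 12.0 * np.exp(-0.5 * ((x - 10.0) / 2.0) ** 2) + 3.0
        rf = pct.fit_rf_gaussian(profile, preferred=4)
        assert rf.sigma == pytest.approx(2.0, abs=1e-6)
        assert rf.fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 2.0, abs=1e-6)

    def test_fwhm_identity_holds_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            profile = np.abs(rng.normal(5, 2, 9))
            rf = pct.fit_rf_gaussian(profile, int(np.argmax(profile)))
            assert abs(rf.fwhm - FWHM_FACTOR * rf.sigma) < 1e-12

    def test_flat_profile_flagged(self):
        rf = pct.fit_rf_gaussian(np.full(9, 4.0), preferred=0)
        assert rf.flagged and rf.amplitude == 0.0

    def test_noisy_recovery_matches_grid_oracle(self):
        rng = np.random.default_rng(6)
        x = 2.0 * np.arange(1, 10)
        sigmas = []
        for rep in range(20):
            profile = 10.0 * np.exp(-0.5 * ((x - 8.0) / 3.0) ** 2) + 2.0
            noisy = profile + rng.normal(0, 0.4, 9)
            rf = pct.fit_rf_gaussian(noisy, preferred=3)
            sigmas.append(rf.sigma)
            # fine-grid oracle: best sigma on a grid with A, c solved linearly
            best = (np.inf, None)
            for sg in np.arange(0.5, 12.0, 0.01):
                g = np.exp(-0.5 * ((x - 8.0) / sg) ** 2)
                X = np.column_stack([g, np.ones(9)])
                resid = noisy - X @ np.linalg.lstsq(X, noisy, rcond=None)[0]
                sse = float(resid @ resid)
                if sse < best[0]:
                    best = (sse, sg)
            assert rf.sigma == pytest.approx(best[1], abs=0.05)
        assert abs(float(np.median(sigmas)) - 3.0) < 0.5


class TestMirrorR2:
    def _side_matrix(self, gains, side, n_trials=4, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        cols, labels = [], []
        for part in LATERAL_PARTS:
            for _ in range(n_trials):
                cols.append(gains[part])
                labels.append(pct.ConditionLabel(part, side, "actual"))
        rates = np.array(cols)[None, :] + rng.normal(0, noise_sd, size=(1, len(cols)))
        return FiringRateMatrix(
            rates=rates,
            unit_ids=["u0"],
            labels=labels,
            window=("go_onset", 0.5, 2.5),
        )

    def test_exact_mirror_zero_noise_gives_unity(self):
        gains = {"back_head": 2.0, "cheek": 9.0, "neck": 4.0, "shoulder": 7.0}
        left = self._side_matrix(gains, "left")
        right = self._side_matrix(gains, "right")
        res = pct.mirror_symmetry_r2(left, right, seed=0)[0]
        assert res.r2_within == pytest.approx(1.0)
        assert res.r2_across == pytest.approx(1.0)

    def test_independent_sides_drop_across_r2(self):
        rng = np.random.default_rng(7)
        within_vals, across_vals = [], []
        for rep in range(20):
            gl = dict(zip(LATERAL_PARTS, rng.uniform(0, 10, 4)))
            gr = dict(zip(LATERAL_PARTS, rng.uniform(0, 10, 4)))
            left = self._side_matrix(gl, "left", noise_sd=0.5, seed=rep)
            right = self._side_matrix(gr, "right", noise_sd=0.5, seed=100 + rep)
            res = pct.mirror_symmetry_r2(left, right, seed=rep)[0]
            within_vals.append(res.r2_within)
            across_vals.append(res.r2_across)
        assert np.mean(within_vals) > 0.5
        assert np.mean(across_vals) <= 0.0

    def test_matches_exhaustive_loo_loop(self):
        rng = np.random.default_rng(8)
        gains = {"back_head": 1.0, "cheek": 6.0, "neck": 3.0, "shoulder": 8.0}
        left = self._side_matrix(gains, "left", n_trials=3, noise_sd=1.0, seed=9)
        right = self._side_matrix(gains, "right", n_trials=3, noise_sd=1.0, seed=10)
        res = pct.mirror_symmetry_r2(left, right, seed=11)[0]

        # independent within-side LOO loop
        y, preds = [], []
        for part in LATERAL_PARTS:
            cond = pct.ConditionLabel(part, "left", "actual")
            vals = left.rates[0, left.condition_trials(cond)]
            for k in range(3):
                y.append(vals[k])
                preds.append(np.delete(vals, k).mean())
        y = np.array(y)
        expected = 1 - np.sum((y - preds) ** 2) / np.sum((y - y.mean()) ** 2)
        assert res.r2_within == pytest.approx(expected)

    def test_too_few_trials_rejected(self):
        gains = dict.fromkeys(LATERAL_PARTS, 1.0)
        left = self._side_matrix(gains, "left", n_trials=2)
        right = self._side_matrix(gains, "right", n_trials=2)
        with pytest.raises(ValueError, match="3 trials"):
            pct.mirror_symmetry_r2(left, right)
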