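"""Split-half similarity matrices and permutation contrast tests."""

import numpy as np
import pytest
from scipy import stats

import pct
from pct.preprocess import FiringRateMatrix

COND_A = pct.ConditionLabel("cheek", "right", "actual")
COND_B = pct.ConditionLabel("cheek", "left", "actual")
COND_C = pct.ConditionLabel("shoulder", "right", "actual")


def _noiseless_matrix(patterns, n_trials=4):
    """Each condition's trials all equal its pattern vector."""
    cols, labels = [], []
    for cond, pat in patterns.items():
        for _ in range(n_trials):
            cols.append(pat)
            labels.append(cond)
    return FiringRateMatrix(
        rates=np.array(cols, dtype=float).T,
        unit_ids=[f"u{i}" for i in range(len(next(iter(patterns.values()))))],
        labels=labels,
        window=("go_onset", 0.5, 2.5),
    )


class TestCvConditionCorrelation:
    def test_noiseless_patterns_give_exact_correlations(self):
        patterns = {
            COND_A: [1.0, 5.0, 2.0, 8.0],
            COND_B: [2.0, 4.0, 1.0, 9.0],
            COND_C: [8.0, 1.0, 7.0, 0.0],
        }
        corr = pct.cv_condition_correlation(_noiseless_matrix(patterns), n_splits=3, seed=0)
        np.testing.assert_allclose(np.diag(corr.mean_corr), 1.0, atol=1e-12)
        expected = np.corrcoef(np.array(list(patterns.values())))
        np.testing.assert_allclose(corr.mean_corr, expected, atol=1e-12)

    def test_untuned_condition_correlates_at_zero(self):
        # pure-noise conditions: mean correlation within 3 SE of zero
        rng = np.random.default_rng(5)
        rates = FiringRateMatrix(
            rates=rng.normal(5, 1, size=(40, 20)),
            unit_ids=[f"u{i}" for i in range(40)],
            labels=[COND_A] * 10 + [COND_B] * 10,
            window=("go_onset", 0.5, 2.5),
        )
        corr = pct.cv_condition_correlation(rates, n_splits=100, seed=1)
        samples = corr.pair_samples(COND_A, COND_B)
        se = samples.std(ddof=1) / np.sqrt(len(samples))
        assert abs(samples.mean()) < 3 * se + 0.05

    def test_within_condition_ceiling_below_one_with_noise(self):
        rng = np.random.default_rng(6)
        pattern = rng.normal(5, 3, size=30)
        rates = FiringRateMatrix(
            rates=pattern[:, None] + rng.normal(0, 2.0, size=(30, 10)),
            unit_ids=[f"u{i}" for i in range(30)],
            labels=[COND_A] * 10,
            window=("go_onset", 0.5, 2.5),
        )
        corr = pct.cv_condition_correlation(rates, n_splits=100, seed=2)
        assert 0.3 < corr.mean_corr[0, 0] < 0.999

    def test_invariant_under_unit_permutation(self):
        rng = np.random.default_rng(7)
        rates = FiringRateMatrix(
            rates=rng.normal(5, 2, size=(20, 8)),
            unit_ids=[f"u{i}" for i in range(20)],
            labels=[COND_A] * 4 + [COND_C] * 4,
            window=("go_onset", 0.5, 2.5),
        )
        perm = rng.permutation(20)
        shuffled = FiringRateMatrix(
            rates=rates.rates[perm],
            unit_ids=[rates.unit_ids[i] for i in perm],
            labels=rates.labels,
            window=rates.window,
        )
        a = pct.cv_condition_correlation(rates, n_splits=10, seed=3)
        b = pct.cv_condition_correlation(shuffled, n_splits=10, seed=3)
        np.testing.assert_allclose(a.mean_corr, b.mean_corr, atol=1e-12)

    def test_pearson_invariant_to_global_vector_offset(self):
        rng = np.random.default_rng(8)
        rates = FiringRateMatrix(
            rates=rng.normal(5, 2, size=(20, 8)),
            unit_ids=[f"u{i}" for i in range(20)],
            labels=[COND_A] * 4 + [COND_C] * 4,
            window=("go_onset", 0.5, 2.5),
        )
        shifted = FiringRateMatrix(
            rates=rates.rates + 11.5,  # same offset on every entry
            unit_ids=rates.unit_ids,
            labels=rates.labels,
            window=rates.window,
        )
        a = pct.cv_condition_correlation(rates, n_splits=10, seed=4)
        b = pct.cv_condition_correlation(shifted, n_splits=10, seed=4)
        np.testing.assert_allclose(a.mean_corr, b.mean_corr, atol=1e-9)

    def test_alternative_metrics_run(self):
        rng = np.random.default_rng(9)
        rates = FiringRateMatrix(
            rates=rng.normal(5, 2, size=(10, 8)),
            unit_ids=[f"u{i}" for i in range(10)],
            labels=[COND_A] * 4 + [COND_C] * 4,
            window=("go_onset", 0.5, 2.5),
        )
        cos = pct.cv_condition_correlation(rates, n_splits=5, metric="cosine", seed=0)
        assert np.abs(cos.mean_corr).max() <= 1 + 1e-12
        euc = pct.cv_condition_correlation(rates, n_splits=5, metric="euclidean", seed=0)
        assert np.all(euc.mean_corr <= 0)  # negative distances

    def test_single_trial_condition_rejected(self):
        rates = FiringRateMatrix(
            rates=np.ones((3, 3)),
            unit_ids=["a", "b", "c"],
            labels=[COND_A, COND_A, COND_C],
            window=("go_onset", 0.5, 2.5),
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            pct.cv_condition_correlation(rates, n_splits=2, seed=0)


class TestContrastTest:
    def test_identical_samples_not_significant(self):
        samples = [0.5, 0.6, 0.7, 0.8]
        assert pct.correlation_contrast_test(samples, samples, n_shuffles=500, seed=0) >= 0.9

    def test_fully_separated_samples_reach_floor(self):
        p = pct.correlation_contrast_test([1, 1, 1, 1], [0, 0, 0, 0], n_shuffles=2000, seed=1)
        # only 2 of the 70 equal-size splits reproduce |diff| = 1
        assert 1 / 2001 <= p < 0.05

    def test_p_values_uniform_under_null(self):
        rng = np.random.default_rng(10)
        pvals = [
            pct.correlation_contrast_test(
                rng.normal(0, 1, 30), rng.normal(0, 1, 30), n_shuffles=499, seed=int(rng.integers(2**31))
            )
            for _ in range(200)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            pct.correlation_contrast_test([], [1.0], n_shuffles=100, seed=0)


class TestMirrorSymmetryContrast:
    def _paired_rates(self, pattern_left, pattern_right, noise_sd=1.0, n_trials=10, seed=0):
        rng = np.random.default_rng(seed)
        cols, labels = [], []
        for cond, pat in ((COND_B, pattern_left), (COND_A, pattern_right)):
            for _ in range(n_trials):
                cols.append(pat)
                labels.append(cond)
        rates = np.array(cols, dtype=float).T + rng.normal(0, noise_sd, (len(pattern_left), 2 * n_trials))
        return FiringRateMatrix(
            rates=rates,
            unit_ids=[f"u{i}" for i in range(len(pattern_left))],
            labels=labels,
            window=("go_onset", 0.5, 2.5),
        )

    def test_identical_side_patterns_at_ceiling(self):
        rng = np.random.default_rng(11)
        pat = rng.normal(10, 5, 40)
        rates = self._paired_rates(pat, pat, noise_sd=1.0, seed=12)
        report = pct.mirror_symmetry_contrast(
            rates, [(COND_B, COND_A)], n_splits=20, n_shuffles=200, seed=0
        )
        assert report.p_values[0] > 0.05 and report.at_ceiling[0]

    def test_calibrated_under_exchangeable_sides(self):
        # exact mirror symmetry: side labels are exchangeable, so p should be
        # roughly uniform; check the rejection rate at alpha=0.2 over repeats
        rng = np.random.default_rng(13)
        rejections = 0
        n_rep = 25
        for r in range(n_rep):
            pat = rng.normal(10, 5, 25)
            rates = self._paired_rates(pat, pat, noise_sd=2.0, n_trials=8, seed=100 + r)
            rep = pct.mirror_symmetry_contrast(
                rates, [(COND_B, COND_A)], n_splits=15, n_shuffles=100, seed=r
            )
            rejections += rep.p_values[0] <= 0.2
        # binomial(25, 0.2): central 99% range is about [1, 11]
        assert 0 <= rejections <= 11

    def test_distinct_side_patterns_detected(self):
        rng = np.random.default_rng(14)
        left = rng.normal(10, 5, 40)
        right = rng.permutation(left)
        rates = self._paired_rates(left, right, noise_sd=1.0, seed=15)
        report = pct.mirror_symmetry_contrast(
            rates, [(COND_B, COND_A)], n_splits=20, n_shuffles=200, seed=1
        )
        assert report.p_values[0] < 0.05 and not report.at_ceiling[0]
        assert report.cross_corr[0] < report.ceiling_corr[0]

    def test_missing_condition_rejected(self):
        rng = np.random.default_rng(16)
        rates = FiringRateMatrix(
            rates=rng.normal(5, 1, (4, 8)),
            unit_ids=list("abcd"),
            labels=[COND_A] * 8,
            window=("go_onset", 0.5, 2.5),
        )
        with pytest.raises(ValueError, match="not present"):
            pct.mirror_symmetry_contrast(rates, [(COND_B, COND_A)], n_shuffles=50, seed=0)
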