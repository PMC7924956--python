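"""Cross-temporal classification, crossnobis distance, dynamic PCA and
cross-format correlation."""

import numpy as np
import pytest

import pct
from pct.dynamics import DynClassMatrix, default_onsets, window_average
from pct.preprocess import BinnedTensor, FiringRateMatrix

IMAG = [pct.ConditionLabel(p, "right", "imagery") for p in ("cheek", "shoulder", "hand")]


def _tensor(counts, labels, bin_size=0.1, t_start=0.0):
    counts = np.asarray(counts, dtype=float)
    return BinnedTensor(
        counts=counts,
        unit_ids=[f"u{i}" for i in range(counts.shape[0])],
        labels=list(labels),
        bin_size=bin_size,
        align_event="cue_onset",
        t_start=t_start,
        t_end=t_start + bin_size * counts.shape[2],
    )


def _gaussian_tensor(class_means, n_trials, n_bins, noise_sd, seed, bin_size=0.1):
    """class_means: (k, units, bins) mean rates; returns tensor + labels."""
    rng = np.random.default_rng(seed)
    k, n_units, _ = class_means.shape
    counts, labels = [], []
    for c in range(k):
        for _ in range(n_trials):
            counts.append(class_means[c] + rng.normal(0, noise_sd, (n_units, n_bins)))
            labels.append(IMAG[c])
    counts = np.transpose(np.array(counts), (1, 0, 2)) * bin_size  # to counts
    return _tensor(counts, labels, bin_size=bin_size)


class TestWindowAverage:
    def test_matches_manual_sum(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(3, 4, 20)).astype(float)
        binned = _tensor(counts, [IMAG[0]] * 4)
        got = window_average(binned, np.array([0.0, 0.5]), 0.5)
        np.testing.assert_allclose(got[:, :, 0], counts[:, :, :5].sum(axis=2) / 0.5)
        np.testing.assert_allclose(got[:, :, 1], counts[:, :, 5:10].sum(axis=2) / 0.5)

    def test_misaligned_window_rejected(self):
        binned = _tensor(np.zeros((2, 2, 10)), [IMAG[0]] * 2)
        with pytest.raises(ValueError, match="align"):
            window_average(binned, np.array([0.03]), 0.5)
        with pytest.raises(ValueError, match="outside"):
            window_average(binned, np.array([0.9]), 0.5)


class TestDynamicClassification:
    def test_time_constant_coding_gives_uniform_matrix(self):
        # class patterns constant in time: generalization equals within-window
        # accuracy everywhere
        rng = np.random.default_rng(1)
        patterns = rng.normal(10, 4, size=(3, 12))
        class_means = np.repeat(patterns[:, :, None], 20, axis=2)
        binned = _gaussian_tensor(class_means, n_trials=8, n_bins=20, noise_sd=2.0, seed=2)
        dyn = pct.dynamic_classification(binned, IMAG, window=0.5, step=0.5)
        assert dyn.accuracy.shape == (4, 4)
        diag = np.diag(dyn.accuracy).mean()
        assert diag > 0.8
        assert np.all(np.abs(dyn.accuracy - diag) < 0.25)

    def test_orthogonal_epoch_codes_give_block_structure(self):
        # epoch-1 classes live on disjoint groups of 4 units; epoch-2 classes
        # pick one unit per group, so every epoch-2 pattern overlaps every
        # epoch-1 class mean equally and cross-epoch decoding is exactly at
        # chance up to trial noise
        pat_a = np.zeros((3, 12))
        pat_b = np.zeros((3, 12))
        for c in range(3):
            pat_a[c, 4 * c : 4 * c + 4] = 20.0
            pat_b[c, [4 * g + c for g in range(3)]] = 20.0
        class_means = np.concatenate(
            [np.repeat(pat_a[:, :, None], 10, axis=2), np.repeat(pat_b[:, :, None], 10, axis=2)],
            axis=2,
        )
        binned = _gaussian_tensor(class_means, n_trials=8, n_bins=20, noise_sd=2.0, seed=4)
        dyn = pct.dynamic_classification(binned, IMAG, window=0.5, step=0.5)
        within_a = dyn.accuracy[:2, :2].diagonal().mean()
        within_b = dyn.accuracy[2:, 2:].diagonal().mean()
        cross = np.concatenate([dyn.accuracy[:2, 2:].ravel(), dyn.accuracy[2:, :2].ravel()])
        assert within_a > 0.8 and within_b > 0.8
        assert abs(cross.mean() - 1 / 3) < 0.12

    def test_shuffled_labels_stay_at_chance(self):
        rng = np.random.default_rng(5)
        class_means = np.full((3, 10, 10), 10.0)  # no class information at all
        binned = _gaussian_tensor(class_means, n_trials=8, n_bins=10, noise_sd=3.0, seed=6)
        dyn = pct.dynamic_classification(binned, IMAG, window=0.5, step=0.5)
        # exact binomial 99% band around 1/3 with 24 trials per entry
        from scipy import stats

        lo, hi = stats.binom.interval(0.99, 24, 1 / 3)
        assert np.all(dyn.accuracy * 24 >= lo - 1e-9)
        assert np.all(dyn.accuracy * 24 <= hi + 1e-9)

    def test_diagonal_matches_static_loo_decoder(self, imagery_session):
        # window (go+0.5, go+2.5) as one dynamic window must reproduce the
        # static leave-one-out confusion accuracy exactly
        session = pct.select_units(imagery_session)
        go = session.trials[0].events["go_onset"] - session.trials[0].events["cue_onset"]
        binned = pct.bin_spikes(session, "cue_onset", -0.5, go + 3.0, 0.05)
        dyn = pct.dynamic_classification(
            binned, IMAG, window=2.0, step=0.1, onsets=np.array([go + 0.5])
        )
        rates = pct.window_rates(session, "go_onset", 0.5, 2.5).subset_conditions(IMAG)
        cm = pct.loo_confusion(rates)
        # reorder confusion classes to IMAG order
        order = [cm.classes.index(c) for c in IMAG]
        acc = np.diag(cm.accuracy[np.ix_(order, order)]).mean()
        assert dyn.accuracy[0, 0] == pytest.approx(acc, abs=1e-12)

    def test_single_unit_scope_returns_one_matrix_per_unit(self):
        rng = np.random.default_rng(7)
        class_means = rng.normal(10, 3, size=(3, 4, 10))
        binned = _gaussian_tensor(class_means, n_trials=6, n_bins=10, noise_sd=1.0, seed=8)
        out = pct.dynamic_classification(binned, IMAG, window=0.5, step=0.5, scope="single_unit")
        assert len(out) == 4
        assert all(m.accuracy.shape == (2, 2) for m in out)


class TestCrossnobis:
    def test_unbiased_at_null(self):
        rng = np.random.default_rng(9)
        vals = []
        inv_var = np.ones(6)
        for _ in range(100):
            X_t = rng.normal(0, 1, size=(8, 6))
            X_r = rng.normal(0, 1, size=(8, 6))
            vals.append(pct.crossnobis_distance(X_t, X_r, inv_var, n_splits=5, rng=rng))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se

    def test_recovers_sum_of_squared_shifts(self):
        # +1 sigma shift in each of 4 independent units -> expected distance 4
        rng = np.random.default_rng(10)
        delta = np.array([1.0, 1.0, 1.0, 1.0])
        vals = []
        for _ in range(200):
            X_r = rng.normal(0, 1, size=(10, 4))
            X_t = rng.normal(0, 1, size=(10, 4)) + delta
            vals.append(pct.crossnobis_distance(X_t, X_r, np.ones(4), n_splits=5, rng=rng))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(4.0, abs=3 * se)

    def test_deterministic_shift_exact_arithmetic(self):
        # zero-variance data shifted by delta: estimate is exactly
        # sum(delta^2 * inv_var) for every split
        delta = np.array([2.0, -1.0, 0.5])
        inv_var = np.array([1.0, 4.0, 2.0])
        X_r = np.tile([1.0, 2.0, 3.0], (6, 1))
        X_t = X_r + delta
        rng = np.random.default_rng(11)
        d = pct.crossnobis_distance(X_t, X_r, inv_var, n_splits=3, rng=rng)
        assert d == pytest.approx(float(np.sum(delta**2 * inv_var)), rel=1e-12)

    def test_timecourse_near_zero_at_reference(self, imagery_session):
        session = pct.select_units(imagery_session)
        go = session.trials[0].events["go_onset"] - session.trials[0].events["cue_onset"]
        binned = pct.bin_spikes(session, "cue_onset", -0.7, go + 3.5, 0.05)
        onsets = default_onsets(-0.7, go + 3.0, 0.1)
        series = pct.crossnobis_timecourse(binned, IMAG, onsets=onsets, seed=0)
        at_ref = series.distance[np.argmin(np.abs(onsets - 0.25))]
        post_go = series.distance[np.argmin(np.abs(onsets - (go + 1.0)))]
        assert abs(at_ref) < 5.0
        assert post_go > 10 * max(abs(at_ref), 1.0)


class TestUnitDynamicPca:
    def _matrices(self, arrays):
        return [
            DynClassMatrix(
                accuracy=a,
                window_onsets=np.arange(a.shape[0]) * 0.1,
                window_size=0.5,
                step=0.1,
                scope="single_unit",
                classes=IMAG,
            )
            for a in arrays
        ]

    def test_two_archetypes_explained_by_one_component(self):
        rng = np.random.default_rng(12)
        arch_a = rng.random((5, 5))
        arch_b = rng.random((5, 5))
        pca = pct.unit_dynamic_pca(self._matrices([arch_a, arch_b] * 3))
        assert pca.variance_explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(13)
        pca = pct.unit_dynamic_pca(self._matrices([rng.random((5, 5)) for _ in range(6)]))
        assert pca.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(14)
        arrays = [rng.random((5, 5)) for _ in range(6)]
        pca = pct.unit_dynamic_pca(self._matrices(arrays))
        X = np.array([a.ravel() for a in arrays])
        Xc = X - X.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        evals = evals[evals > 1e-12]
        np.testing.assert_allclose(
            pca.variance_explained[: len(evals)], evals / evals.sum(), atol=1e-9
        )

    def test_identical_units_flagged_degenerate(self):
        a = np.full((4, 4), 0.5)
        pca = pct.unit_dynamic_pca(self._matrices([a.copy() for _ in range(4)]))
        assert pca.degenerate

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError, match="3 units"):
            pct.unit_dynamic_pca(self._matrices([np.eye(3)] * 2))


class TestDynamicFormatCorrelation:
    def _deterministic_tensor(self, shared=True, n_bins=12):
        """Constant-in-time patterns; imagery pattern either equals the actual
        one or is an orthogonal permutation of it."""
        rng = np.random.default_rng(15)
        n_units = 10
        pats = {
            ("actual", "cheek"): rng.normal(10, 3, n_units),
            ("actual", "shoulder"): rng.normal(10, 3, n_units),
        }
        if shared:
            pats[("imagery", "cheek")] = pats[("actual", "cheek")]
            pats[("imagery", "shoulder")] = pats[("actual", "shoulder")]
        else:
            pats[("imagery", "cheek")] = rng.normal(10, 3, n_units)
            pats[("imagery", "shoulder")] = rng.normal(10, 3, n_units)
        counts, labels = [], []
        for (fmt, part), pat in pats.items():
            for _ in range(4):
                counts.append(np.repeat(pat[:, None], n_bins, axis=1) * 0.1)
                labels.append(pct.ConditionLabel(part, "right", fmt))
        counts = np.transpose(np.array(counts), (1, 0, 2))
        return _tensor(counts, labels)

    def test_identical_patterns_give_unit_cross_format_correlation(self):
        binned = self._deterministic_tensor(shared=True)
        fc = pct.dynamic_format_correlation(binned, window=0.5, step=0.5, n_splits=3, seed=0)
        np.testing.assert_allclose(fc.pair("actual", "imagery"), 1.0, atol=1e-9)
        np.testing.assert_allclose(fc.pair("actual", "actual"), 1.0, atol=1e-9)

    def test_unrelated_patterns_give_low_cross_format_correlation(self):
        binned = self._deterministic_tensor(shared=False)
        fc = pct.dynamic_format_correlation(binned, window=0.5, step=0.5, n_splits=3, seed=0)
        assert np.diag(fc.pair("actual", "actual")).min() > 0.99
        assert np.abs(fc.pair("actual", "imagery")).max() < 0.6

    def test_insufficient_trials_rejected(self):
        binned = self._deterministic_tensor()
        binned.labels[0] = pct.ConditionLabel("hand", "right", "actual")
        with pytest.raises(ValueError, match="at least 4"):
            pct.dynamic_format_correlation(binned, window=0.5, step=0.5, n_splits=2, seed=0)
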