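"""Metric, cross-validation, and perturbation-harness tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from oracles import auprc_brute, auroc_brute, fixed_sensitivity_brute

from icuward.evaluation import (
    PerturbationSpec,
    UndefinedMetricError,
    auprc,
    auroc,
    delay_input_array,
    inject_noise_array,
    metrics_at_fixed_sensitivity,
    patient_folds,
    robustness_experiment,
)
from icuward.channels import CHANNEL_INDEX, VITAL_NAMES


class TestAuroc:
    def test_perfect_ranking(self):
        assert auroc([0, 1], [0.1, 0.9]) == 1.0

    def test_all_ties_half(self):
        assert auroc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_hand_example_three_of_four_pairs(self):
        assert auroc([0, 0, 1, 1], [0.1, 0.8, 0.4, 0.9]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auroc([1, 1], [0.2, 0.3])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        a = auroc(labels, scores)
        assert a == pytest.approx(auroc_brute(labels, scores), abs=1e-12)
        assert a == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        scores = rng.random(40)
        assert auroc(labels, scores) == pytest.approx(
            auroc(labels, np.exp(3 * scores)), abs=1e-12)


class TestAuprc:
    def test_perfect_separation(self):
        assert auprc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_positive_ranked_second_of_two(self):
        assert auprc([1, 0], [0.2, 0.9]) == 0.5

    def test_no_positive_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auprc([0, 0], [0.2, 0.3])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() == 0:
            labels[0] = 1
        scores = np.round(rng.random(n), 2)
        a = auprc(labels, scores)
        assert a == pytest.approx(auprc_brute(labels, scores), abs=1e-12)
        assert a == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12)

    def test_random_scores_approach_prevalence(self, rng):
        n, prevalence = 20000, 0.15
        labels = (rng.random(n) < prevalence).astype(int)
        scores = rng.random(n)
        assert auprc(labels, scores) == pytest.approx(prevalence, abs=0.02)


class TestFixedSensitivity:
    def test_perfectly_separated(self):
        """With all positives above all negatives, the largest threshold
        reaching the 0.85 target lands exactly on the first crossing:
        sensitivity 17/20, specificity 1, no false positives."""
        labels = np.r_[np.ones(20), np.zeros(30)]
        scores = np.r_[np.linspace(0.6, 1, 20), np.linspace(0, 0.4, 30)]
        rep = metrics_at_fixed_sensitivity(labels, scores)
        assert rep.sensitivity == pytest.approx(17 / 20)
        assert rep.specificity == 1.0
        assert rep.f1 == pytest.approx(2 * 17 / (2 * 17 + 3))
        assert rep.sensitivity_reachable

    def test_identical_scores_admit_all(self):
        rep = metrics_at_fixed_sensitivity([1, 0, 0, 1], [0.4] * 4)
        assert rep.specificity == 0.0 and rep.sensitivity == 1.0

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_exhaustive_threshold_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        scores = np.round(rng.random(n), 1)
        rep = metrics_at_fixed_sensitivity(labels, scores)
        thr, spec, f1 = fixed_sensitivity_brute(labels, scores)
        assert rep.threshold == pytest.approx(thr, abs=1e-12)
        assert rep.specificity == pytest.approx(spec, abs=1e-12)
        assert rep.f1 == pytest.approx(f1, abs=1e-12)


class TestPatientFolds:
    def test_partition_every_patient_once(self, rng):
        pids = [f"P{i % 100}" for i in range(1000)]
        folds = patient_folds(pids, 5, rng)
        assert sorted(np.concatenate(folds).tolist()) == list(range(1000))
        for f, idx in enumerate(folds):
            test_p = {pids[i] for i in idx}
            other = {pids[i] for g, jdx in enumerate(folds) if g != f
                     for i in jdx}
            assert not test_p & other

    def test_fold_patient_counts_balanced(self, rng):
        pids = [f"P{i}" for i in range(103)]
        folds = patient_folds(pids, 5, rng)
        sizes = sorted(len({pids[i] for i in f}) for f in folds)
        assert sizes[-1] - sizes[0] <= 1


class TestPerturbations:
    def _data(self, rng, n=6, t=20):
        X = rng.random((n, t, 18))
        lengths = rng.integers(10, t + 1, size=n)
        for b, ln in enumerate(lengths):
            X[b, ln:] = 0
        return X, lengths

    def test_zero_scale_is_exact_identity(self, rng):
        X, lengths = self._data(rng)
        assert inject_noise_array(X, lengths, 0.0, rng) is X

    def test_corrupted_cell_count(self, rng):
        X, lengths = self._data(rng)
        Xp = inject_noise_array(X, lengths, 5.0, rng)  # huge SD: all change
        for b, ln in enumerate(lengths):
            changed = np.nonzero((Xp[b] != X[b]).any(axis=0))[0]
            vital_cols = {CHANNEL_INDEX[v] for v in VITAL_NAMES}
            assert set(changed.tolist()) <= vital_cols
            assert len(changed) <= 2
            rows_changed = (Xp[b] != X[b]).any(axis=1).sum()
            assert rows_changed <= max(1, int(round(0.10 * ln)))

    def test_noise_sd_calibrated(self, rng):
        scale = 0.05
        X = np.full((200, 40, 18), 0.5)
        lengths = np.full(200, 40)
        Xp = inject_noise_array(X, lengths, scale, rng)
        diffs = (Xp - X)[Xp != X]
        assert len(diffs) > 1000
        assert np.std(diffs) == pytest.approx(scale, rel=0.1)

    def test_seed_determinism(self, rng):
        X, lengths = self._data(rng)
        a = inject_noise_array(X, lengths, 0.2, np.random.default_rng(5))
        b = inject_noise_array(X, lengths, 0.2, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_zero_delay_is_exact_identity(self, rng):
        X, lengths = self._data(rng)
        assert delay_input_array(X, lengths, 0, rng) is X

    def test_delay_constant_channel_unchanged(self, rng):
        X = np.full((1, 12, 18), 0.3)
        lengths = np.array([12])
        Xp = delay_input_array(X, lengths, 3, rng)
        assert np.array_equal(Xp, X)

    def test_delay_carries_forward_on_increasing_channel(self, rng):
        X = np.tile(np.linspace(0, 1, 12)[None, :, None], (1, 1, 18))
        lengths = np.array([12])
        Xp = delay_input_array(X, lengths, 3, np.random.default_rng(0))
        changed_cols = np.nonzero((Xp[0] != X[0]).any(axis=0))[0]
        assert len(changed_cols) == 2
        for c in changed_cols:
            assert np.all(Xp[0, 9:, c] == X[0, 8, c])

    def test_delay_idempotent_for_same_channels(self, rng):
        X, lengths = self._data(rng)
        seed = np.random.default_rng(7)
        once = delay_input_array(X, lengths, 4, np.random.default_rng(7))
        twice = delay_input_array(once, lengths, 4, np.random.default_rng(7))
        assert np.array_equal(once, twice)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="unknown perturbation"):
            PerturbationSpec("scramble")
        with pytest.raises(ValueError, match="non-negative"):
            PerturbationSpec("noise", noise_scale=-1.0)


class TestRobustnessExperiment:
    def _setup(self, rng):
        n, t = 80, 15
        X = rng.random((n, t, 18))
        lengths = np.full(n, t)
        static = rng.random((n, 1))
        y = rng.integers(0, 2, size=n).astype(float)
        y[:2] = [0, 1]

        def score_fn(Xq, lq, sq):
            # deterministic scorer reading the two noisiest channels
            return Xq[np.arange(len(Xq)), lq - 1, :2].sum(axis=1)

        return score_fn, X, lengths, static, y

    def test_identity_spec_reports_exact_zero(self, rng):
        score_fn, X, lengths, static, y = self._setup(rng)
        res = robustness_experiment(
            score_fn, X, lengths, static, y,
            [PerturbationSpec("delay", delay_hours=0, repeats=5),
             PerturbationSpec("noise", noise_scale=0.0, repeats=5)], seed=3)
        assert res[0].mean_delta == 0.0 and res[0].sd_delta == 0.0
        assert res[1].mean_delta == 0.0 and res[1].sd_delta == 0.0

    def test_single_repeat_flagged(self, rng):
        score_fn, X, lengths, static, y = self._setup(rng)
        with pytest.warns(UserWarning, match="single repeat"):
            res = robustness_experiment(
                score_fn, X, lengths, static, y,
                [PerturbationSpec("noise", noise_scale=0.5, repeats=1)],
                seed=3)
        assert res[0].degenerate_sd and res[0].sd_delta == 0.0

    def test_seed_reproducibility(self, rng):
        score_fn, X, lengths, static, y = self._setup(rng)
        specs = [PerturbationSpec("noise", noise_scale=0.3, repeats=4)]
        r1 = robustness_experiment(score_fn, X, lengths, static, y, specs,
                                   seed=11)
        r2 = robustness_experiment(score_fn, X, lengths, static, y, specs,
                                   seed=11)
        assert r1[0].mean_delta == r2[0].mean_delta
        assert r1[0].sd_delta == r2[0].sd_delta
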