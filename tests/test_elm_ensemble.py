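"""Under-sampling ELM ensemble: balance, voting arithmetic, reproducibility."""

import numpy as np
import pytest

from tbipred.elm_ensemble import (
    build_ensemble,
    classify,
    ensemble_from_json,
    ensemble_to_json,
    features_matrix,
    risk_score,
    score_cohort,
    train_elm,
    undersample,
)
from tbipred.evaluation import roc_curve
from tbipred.synthetic_data import MODEL_PREDICTORS, CohortSpec, generate_cohort

TOY_X = np.array([[1.0], [1.0], [1.0], [0.0], [0.0], [0.0]])
TOY_P, TOY_N = TOY_X[:3], TOY_X[3:]


class TestUndersample:
    def test_study_sizes_give_balanced_78(self, rng):
        P = rng.random((39, 7))
        N = rng.random((156, 7))
        ts = undersample(P, N, seed=0)
        assert len(ts.y) == 78
        assert ts.y.sum() == 39

    def test_equal_sizes_use_all_negatives(self, rng):
        P, N = rng.random((10, 3)), rng.random((10, 3))
        ts = undersample(P, N, seed=1)
        neg = ts.X[ts.y == 0]
        assert {tuple(r) for r in neg} == {tuple(r) for r in N}

    def test_more_positives_than_negatives_fails(self, rng):
        with pytest.raises(ValueError, match=r"\|P\| > \|N\|"):
            undersample(rng.random((5, 2)), rng.random((3, 2)))

    def test_uniform_sampling_of_negatives(self):
        """Over 1000 seeds with |P|=5, |N|=20, each negative is drawn with
        frequency ~ 5/20, within 3 binomial SEs."""
        P = np.zeros((5, 1))
        N = np.arange(20, dtype=float).reshape(-1, 1)
        counts = np.zeros(20)
        for seed in range(1000):
            ts = undersample(P, N, seed=seed)
            counts[ts.X[ts.y == 0].ravel().astype(int)] += 1
        freq = counts / 1000
        se = np.sqrt(0.25 * 0.75 / 1000)
        assert (np.abs(freq - 0.25) < 3 * se).all()


class TestTrainElm:
    def _ts(self, rng, n=40, d=3):
        from tbipred.elm_ensemble import TrainingSet
        X = rng.random((n, d))
        y = (X[:, 0] > 0.5).astype(float)
        return TrainingSet(X=X, y=y)

    def test_default_width_is_30(self, rng):
        clf = train_elm(self._ts(rng), rng=0)
        assert clf.n_hidden == 30

    def test_separable_toy_perfect_training_accuracy(self):
        """On y = x with x in {0,1}, every trained network reproduces the
        labels — verified on the entire 2-point input space."""
        ts = undersample(TOY_P, TOY_N, seed=0)
        for seed in range(10):
            clf = train_elm(ts, rng=seed)
            assert classify(clf, np.array([[1.0]]))[0] == 1
            assert classify(clf, np.array([[0.0]]))[0] == 0

    def test_output_weights_satisfy_normal_equations(self, rng):
        ts = self._ts(rng)
        clf = train_elm(ts, rng=2)
        H = clf.hidden(ts.X)
        residual = H.T @ (H @ clf.output_weights - ts.y)
        assert np.abs(residual).max() < 1e-8

    def test_deterministic_given_rng_state(self, rng):
        ts = self._ts(rng)
        a = train_elm(ts, rng=7)
        b = train_elm(ts, rng=7)
        assert np.array_equal(a.input_weights, b.input_weights)
        assert np.array_equal(a.output_weights, b.output_weights)

    def test_single_class_rejected(self):
        from tbipred.elm_ensemble import TrainingSet
        with pytest.raises(ValueError, match="both classes"):
            train_elm(TrainingSet(X=np.ones((4, 2)), y=np.ones(4)))


class TestClassify:
    def test_pure_function(self, rng):
        ts = undersample(TOY_P, TOY_N, seed=0)
        clf = train_elm(ts, rng=1)
        x = np.array([[0.7]])
        assert classify(clf, x)[0] == classify(clf, x)[0]
        assert np.array_equal(classify(clf, np.vstack([x, x])),
                              np.repeat(classify(clf, x), 2))

    def test_raising_threshold_never_adds_positives(self, rng):
        ts = self._random_ts(rng)
        clf = train_elm(ts, rng=3)
        probe = rng.random((50, 3))
        n_low = classify(clf, probe).sum()
        clf.threshold = 1.0
        assert classify(clf, probe).sum() <= n_low

    def test_dimension_mismatch(self, rng):
        clf = train_elm(self._random_ts(rng), rng=0)
        with pytest.raises(ValueError, match="dimension"):
            classify(clf, np.ones((1, 5)))

    def _random_ts(self, rng):
        from tbipred.elm_ensemble import TrainingSet
        X = rng.random((30, 3))
        return TrainingSet(X=X, y=(X[:, 0] > 0.5).astype(float))


class TestEnsemble:
    def test_default_size_100(self):
        ens = build_ensemble(TOY_P, TOY_N, seed=0)
        assert ens.T == 100

    def test_single_voter_scores_are_0_or_100(self, rng):
        ens = build_ensemble(rng.random((10, 2)), rng.random((20, 2)), T=1, seed=0)
        scores = score_cohort(ens, rng.random((40, 2)))
        assert set(np.unique(scores)) <= {0.0, 100.0}

    def test_same_seed_same_scores(self, rng):
        P, N = rng.random((15, 4)), rng.random((60, 4))
        probe = rng.random((25, 4))
        s1 = score_cohort(build_ensemble(P, N, T=20, seed=9), probe)
        s2 = score_cohort(build_ensemble(P, N, T=20, seed=9), probe)
        assert np.array_equal(s1, s2)

    def test_growing_T_preserves_earlier_members(self, rng):
        """The per-classifier substream protocol: the first 10 members of a
        T=20 build equal the members of a T=10 build with the same seed."""
        P, N = rng.random((12, 3)), rng.random((50, 3))
        small = build_ensemble(P, N, T=10, seed=4)
        big = build_ensemble(P, N, T=20, seed=4)
        probe = rng.random((30, 3))
        for a, b in zip(small.classifiers, big.classifiers[:10]):
            assert np.array_equal(a.decision(probe), b.decision(probe))

    def test_score_bounds_and_granularity(self, rng):
        ens = build_ensemble(rng.random((10, 2)), rng.random((40, 2)),
                             T=7, seed=1)
        scores = score_cohort(ens, rng.random((60, 2)))
        assert (scores >= 0).all() and (scores <= 100).all()
        votes = scores * 7 / 100
        assert np.allclose(votes, np.round(votes))

    def test_unanimous_votes_hit_exact_bounds(self):
        ens = build_ensemble(TOY_P, TOY_N, T=100, seed=0)
        assert risk_score(ens, [1.0]) == 100.0
        assert risk_score(ens, [0.0]) == 0.0

    def test_score_cohort_matches_risk_score_and_permutes(self, rng):
        ens = build_ensemble(rng.random((8, 2)), rng.random((30, 2)), T=10, seed=2)
        probe = rng.random((12, 2))
        scores = score_cohort(ens, probe)
        assert scores[3] == risk_score(ens, probe[3])
        perm = rng.permutation(12)
        assert np.array_equal(score_cohort(ens, probe[perm]), scores[perm])

    def test_label_flip_symmetry(self, rng):
        """Swapping the class roles yields scores ~ 100 - original,
        within resampling noise."""
        X = rng.integers(0, 2, size=(60, 5)).astype(float)
        y = np.r_[np.ones(30), np.zeros(30)]
        X[:, 0] = np.where(y == 1, rng.random(60) < 0.9, rng.random(60) < 0.1)
        s1 = score_cohort(build_ensemble(X[y == 1], X[y == 0], seed=3), X)
        s2 = score_cohort(build_ensemble(X[y == 0], X[y == 1], seed=3), X)
        assert np.abs(s1 + s2 - 100).mean() < 10

    def test_separable_data_auc_one(self):
        """Linearly separated classes with a margin: ensemble AUC is 1 for
        at least 95% of seeds."""
        perfect = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.r_[np.ones(100), np.zeros(100)]
            x0 = np.where(y == 1, rng.uniform(0.6, 1.0, 200), rng.uniform(0.0, 0.4, 200))
            X = np.c_[x0, rng.standard_normal(200)]
            ens = build_ensemble(X[y == 1], X[y == 0], seed=seed)
            perfect += roc_curve(score_cohort(ens, X), y).auc == 1.0
        assert perfect >= 19

    def test_ensemble_at_least_median_single_auc(self):
        """Vote aggregation does not underperform the median base
        classifier (variance reduction), checked over 20 seeds."""
        wins = 0
        for seed in range(20):
            cohort = generate_cohort(CohortSpec(n_cases=20, seed=100 + seed))
            y = cohort.data["group"].to_numpy(int)
            X = features_matrix(cohort)
            ens = build_ensemble(X[y == 1], X[y == 0], T=25, seed=seed,
                                 feature_names=list(MODEL_PREDICTORS))
            ens_auc = roc_curve(score_cohort(ens, cohort), y).auc
            singles = [roc_curve(clf.decision(X), y).auc for clf in ens.classifiers]
            wins += ens_auc >= np.median(singles)
        assert wins >= 15

    def test_cases_outscore_controls_on_calibrated_cohorts(self):
        gaps = []
        for seed in range(20):
            cohort = generate_cohort(CohortSpec(n_cases=39, seed=seed))
            y = cohort.data["group"].to_numpy(int)
            X = features_matrix(cohort)
            ens = build_ensemble(X[y == 1], X[y == 0], seed=seed,
                                 feature_names=list(MODEL_PREDICTORS))
            s = score_cohort(ens, cohort)
            gaps.append(s[y == 1].mean() - s[y == 0].mean())
        assert min(gaps) > 0

    def test_json_round_trip(self, rng, tmp_path):
        ens = build_ensemble(rng.random((8, 3)), rng.random((30, 3)), T=5, seed=6)
        path = tmp_path / "ens.json"
        ensemble_to_json(ens, path)
        back = ensemble_from_json(path)
        probe = rng.random((10, 3))
        assert np.array_equal(score_cohort(back, probe), score_cohort(ens, probe))
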