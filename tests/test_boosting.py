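"""AdaBoost engine: exact arithmetic, oracle equivalence, ensemble votes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from noduleboost.boosting import (
    BoostRound,
    EnsembleModel,
    fit_ensemble,
    init_weights,
    load_ensemble,
    predict_ensemble,
    save_ensemble,
    training_error_bound,
    update_weights,
    voting_weight,
    weighted_error,
)
from noduleboost.stumps import DecisionStump

from oracles import best_single_stump_error, naive_adaboost_transcript


def stump_factory(round_index, round_seed):
    return DecisionStump()


class FixedLearner:
    """Returns canned ±1 predictions; for vote-arithmetic tests."""

    def __init__(self, preds):
        self.preds = np.asarray(preds)

    def fit(self, x, labels, sample_weights=None):
        return self

    def predict_hard(self, x):
        return self.preds[: len(x)]


def fixed_ensemble(votes, per_round_preds, scheme="weighted"):
    rounds = [
        BoostRound(m, 0.1, v, 1.0, FixedLearner(p))
        for m, (v, p) in enumerate(zip(votes, per_round_preds))
    ]
    return EnsembleModel(rounds=rounds, voting_scheme=scheme)


class TestWeightPrimitives:
    def test_init_uniform(self):
        assert np.array_equal(init_weights(4), [0.25] * 4)
        assert np.array_equal(init_weights(1), [1.0])
        for n in (3, 7, 1000):
            assert abs(init_weights(n).sum() - 1.0) < 1e-12

    def test_init_rejects_zero(self):
        with pytest.raises(ValueError):
            init_weights(0)

    def test_weighted_error_examples(self):
        labels = np.array([1, 1, -1, -1])
        assert weighted_error(labels, labels, init_weights(4)) == 0.0
        one_wrong = np.array([1, 1, -1, 1])
        assert weighted_error(one_wrong, labels, init_weights(4)) == pytest.approx(0.25)
        # hand-summed oracle: wrong at samples 1 and 4
        preds = np.array([-1, 1, -1, 1])
        w = np.array([0.5, 0.2, 0.2, 0.1])
        assert weighted_error(preds, labels, w) == pytest.approx(0.6)

    def test_weighted_error_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            weighted_error(np.ones(3), np.ones(4), init_weights(4))

    def test_voting_weight_closed_form(self):
        assert voting_weight(0.5) == 0.0
        assert voting_weight(0.1) == pytest.approx(0.5 * np.log(9.0), abs=1e-12)
        # eps = 0 clamps to 1e-10 and stays finite
        d0 = voting_weight(0.0)
        assert d0 == pytest.approx(0.5 * np.log((1 - 1e-10) / 1e-10), abs=1e-12)
        assert d0 == pytest.approx(11.5129, abs=1e-3)
        assert voting_weight(0.9) < 0 < voting_weight(0.2)

    def test_update_identity_at_zero_vote(self):
        w = np.array([0.4, 0.3, 0.2, 0.1])
        labels = np.array([1, -1, 1, -1])
        preds = np.array([1, 1, -1, -1])
        new, z = update_weights(w, 0.0, labels, preds)
        assert np.array_equal(new, w) and z == 1.0

    def test_update_two_sample_hand_oracle(self):
        """Hand-evaluated update: unnormalized [0.5e^-0.5, 0.5e^0.5]."""
        w = np.array([0.5, 0.5])
        labels = np.array([1, 1])
        preds = np.array([1, -1])  # sample 1 correct, sample 2 wrong
        new, z = update_weights(w, 0.5, labels, preds)
        expect = np.array([0.5 * np.exp(-0.5), 0.5 * np.exp(0.5)])
        expect /= expect.sum()
        assert np.allclose(new, expect, atol=1e-12)
        assert new[1] == pytest.approx(0.7310585786300049, abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_exact_update_puts_half_mass_on_mistakes(self, seed):
        """After an update with d from the unclamped error, the mistake set
        holds exactly half the weight — the re-balancing at AdaBoost's core."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        w = rng.dirichlet(np.ones(n))
        labels = rng.choice([-1, 1], size=n)
        preds = labels.copy()
        flip = rng.random(n) < 0.4
        if not flip.any() or flip.all():
            flip[0] = True
            flip[1] = False
        preds[flip] *= -1
        eps = weighted_error(preds, labels, w)
        d = 0.5 * np.log((1 - eps) / eps)  # exact, unclamped
        new, _ = update_weights(w, d, labels, preds)
        assert new[preds != labels].sum() == pytest.approx(0.5, abs=1e-10)
        assert new.sum() == pytest.approx(1.0, abs=1e-12)

    def test_correct_shrink_mistakes_grow(self):
        w = init_weights(4)
        labels = np.array([1, 1, -1, -1])
        preds = np.array([1, -1, -1, 1])
        new, _ = update_weights(w, 0.7, labels, preds)
        assert np.all(new[[1, 3]] > w[[1, 3]])
        assert np.all(new[[0, 2]] < w[[0, 2]])


class TestOracleEquivalence:
    def test_matches_naive_transcript_on_random_datasets(self):
        """Engine vs looped scalar AdaBoost: eps, d and every weight vector
        agree to 1e-10 over 25 random stump problems."""
        rng = np.random.default_rng(2024)
        for _case in range(25):
            n = int(rng.integers(5, 21))
            m = int(rng.integers(1, 6))
            x = rng.normal(size=(n, 2))
            labels = rng.choice([-1, 1], size=n)
            if len(np.unique(labels)) < 2:
                labels[0] *= -1
            ensemble = fit_ensemble(x, labels, m, stump_factory, seed=0)
            transcript = naive_adaboost_transcript(x, labels, m)
            weights = init_weights(n)
            for r, t in zip(ensemble.rounds, transcript):
                assert np.allclose(weights, t["weights_before"], atol=1e-10)
                assert r.epsilon == pytest.approx(
                    min(max(t["epsilon"], 1e-10), 1 - 1e-10), abs=1e-10
                )
                assert r.vote == pytest.approx(t["d"], abs=1e-10)
                preds = r.learner.predict_hard(x)
                weights, _ = update_weights(weights, r.vote, labels, preds)
                assert np.allclose(weights, t["weights_after"], atol=1e-10)


class TestFitEnsemble:
    def test_single_round_equals_single_learner(self, rng):
        x = rng.normal(size=(20, 3))
        labels = np.where(x[:, 0] > 0, 1, -1)
        for scheme in ("weighted", "simple"):
            ens = fit_ensemble(x, labels, 1, stump_factory, voting_scheme=scheme)
            hard, _ = predict_ensemble(ens, x)
            assert np.array_equal(hard, ens.rounds[0].learner.predict_hard(x))

    def test_boosting_beats_best_stump_on_hard_1d_instance(self):
        """x = 1..8 with labels (+,+,+,-,-,-,+,+): no single stump goes below
        2/8 error; five boosted stumps must."""
        x = np.arange(1.0, 9.0)[:, None]
        labels = np.array([1, 1, 1, -1, -1, -1, 1, 1])
        best_single = best_single_stump_error(x[:, 0], labels)
        assert best_single == pytest.approx(0.25)  # sanity of the instance
        ens = fit_ensemble(x, labels, 5, stump_factory, seed=1)
        hard, _ = predict_ensemble(ens, x)
        boosted_error = np.mean(hard != labels)
        assert boosted_error < best_single

    def test_training_error_bound_holds_and_decreases(self, rng):
        """Empirical training error <= prod 2*sqrt(eps(1-eps)), and the bound
        is non-increasing in the number of rounds."""
        for _case in range(5):
            x = rng.normal(size=(16, 2))
            labels = rng.choice([-1, 1], size=16)
            if len(np.unique(labels)) < 2:
                labels[0] *= -1
            ens = fit_ensemble(x, labels, 5, stump_factory)
            bounds = [
                training_error_bound(ens.epsilons[: m + 1])
                for m in range(len(ens.rounds))
            ]
            assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(bounds, bounds[1:]))
            for m in range(len(ens.rounds)):
                partial = EnsembleModel(rounds=ens.rounds[: m + 1])
                hard, _ = predict_ensemble(partial, x)
                assert np.mean(hard != labels) <= bounds[m] + 1e-12

    def test_permutation_equivariance(self, rng):
        x = rng.normal(size=(12, 2))
        labels = rng.choice([-1, 1], size=12)
        labels[:2] = [1, -1]
        perm = rng.permutation(12)
        e1 = fit_ensemble(x, labels, 3, stump_factory)
        e2 = fit_ensemble(x[perm], labels[perm], 3, stump_factory)
        assert np.allclose(e1.epsilons, e2.epsilons, atol=1e-10)
        assert np.allclose(e1.votes, e2.votes, atol=1e-10)

    def test_high_error_round_policies(self, rng):
        """A learner stuck at eps >= 0.5 warns; policy picks continue/stop."""

        class BadLearner(FixedLearner):
            pass

        x = rng.normal(size=(10, 2))
        labels = np.array([1, -1] * 5)
        bad = lambda m, s: BadLearner(-labels)  # always wrong: eps = 1
        with pytest.warns(UserWarning, match=">= 0.5"):
            ens = fit_ensemble(x, labels, 3, bad, epsilon_policy="continue")
        assert len(ens.rounds) == 3
        assert all(r.vote < 0 for r in ens.rounds)
        with pytest.warns(UserWarning):
            ens_stop = fit_ensemble(x, labels, 3, bad, epsilon_policy="stop")
        assert len(ens_stop.rounds) == 1

    def test_label_validation(self, rng):
        x = rng.normal(size=(6, 2))
        with pytest.raises(ValueError, match="±1"):
            fit_ensemble(x, np.array([0, 1, 0, 1, 0, 1]), 2, stump_factory)
        with pytest.raises(ValueError, match="both classes"):
            fit_ensemble(x, np.ones(6), 2, stump_factory)


class TestPredictEnsemble:
    def test_weighted_margin_arithmetic(self):
        ens = fixed_ensemble([1.0, 2.0], [np.array([1]), np.array([-1])])
        hard, margin = predict_ensemble(ens, np.zeros((1, 1)))
        assert margin[0] == pytest.approx(-1.0)
        assert hard[0] == -1

    def test_zero_margin_tie_maps_positive(self):
        ens = fixed_ensemble([1.0, 1.0], [np.array([1]), np.array([-1])])
        hard, margin = predict_ensemble(ens, np.zeros((1, 1)))
        assert margin[0] == 0.0 and hard[0] == 1

    def test_simple_voting_ignores_vote_weights(self):
        preds = [np.array([1]), np.array([-1]), np.array([1])]
        weighted = fixed_ensemble([0.2, 5.0, 0.2], preds, scheme="weighted")
        simple = fixed_ensemble([0.2, 5.0, 0.2], preds, scheme="simple")
        assert predict_ensemble(weighted, np.zeros((1, 1)))[0][0] == -1
        assert predict_ensemble(simple, np.zeros((1, 1)))[0][0] == 1


class TestSerialization:
    def test_stump_ensemble_round_trip_bitwise(self, rng, tmp_path):
        x = rng.normal(size=(14, 3))
        labels = np.where(x[:, 1] > 0.2, 1, -1)
        labels[:2] = [1, -1]
        ens = fit_ensemble(x, labels, 4, stump_factory, seed=9)
        save_ensemble(ens, tmp_path / "ens")
        clone = load_ensemble(tmp_path / "ens")
        assert np.array_equal(clone.votes, ens.votes)
        _, m1 = predict_ensemble(ens, x)
        _, m2 = predict_ensemble(clone, x)
        assert np.array_equal(m1, m2)

    def test_cnn_ensemble_round_trip_bitwise(self, tmp_path):
        from noduleboost.network import BaseLearnerSpec
        from noduleboost.pipeline import make_cnn_factory

        rng = np.random.default_rng(0)
        x = rng.normal(size=(16, 2, 8, 8))
        labels = np.where(np.arange(16) % 2 == 0, 1, -1)
        x[labels == 1, :, 2:6, 2:6] += 2.0
        spec = BaseLearnerSpec(
            input_size=8, n_views=2, conv_blocks=((4, 3),), fc_widths=(8,),
            learning_rate=3e-3, batch_size=8, epochs=2,
        )
        ens = fit_ensemble(x, labels, 2, make_cnn_factory(spec), seed=3)
        save_ensemble(ens, tmp_path / "cnn_ens")
        clone = load_ensemble(tmp_path / "cnn_ens")
        _, m1 = predict_ensemble(ens, x)
        _, m2 = predict_ensemble(clone, x)
        assert np.array_equal(m1, m2)
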