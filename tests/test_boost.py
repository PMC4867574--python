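import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirstart import (
    EnsembleModel,
    SvmConfig,
    apply_normalization,
    build_training_set,
    feature_matrix,
    fit_normalization,
    generate_windows,
    predict_top_k,
    round_alpha,
    round_error,
    score_candidates,
    train_ensemble,
    train_round,
    update_weights,
)
from mirstart.boost import BoostError
from mirstart.io import MirstartError
from mirstart.synth import SynthConfig, make_dataset


class TestRoundError:
    def test_all_correct_is_zero(self):
        D = np.full(4, 0.25)
        y = np.array([1, -1, 1, -1])
        assert round_error(y, y, D) == 0.0

    def test_uniform_weights_half_wrong(self):
        D = np.full(4, 0.25)
        y = np.array([1, 1, -1, -1])
        pred = np.array([1, -1, -1, 1])
        assert round_error(pred, y, D) == pytest.approx(0.5)

    def test_published_round_one_error(self):
        # 248 of 19216 windows misclassified under uniform weights
        n, wrong = 19216, 248
        D = np.full(n, 1.0 / n)
        y = np.ones(n, dtype=int)
        pred = y.copy()
        pred[:wrong] = -1
        e = round_error(pred, y, D)
        assert round(e, 3) == 0.013

    def test_unnormalized_weights_rejected(self):
        y = np.array([1, -1])
        with pytest.raises(MirstartError, match="sum to 1"):
            round_error(y, y, np.array([0.7, 0.7]))


class TestRoundAlpha:
    @pytest.mark.parametrize(
        "e, expected",
        [(0.5, 0.0), (0.3533, 0.3023), (0.4337, 0.1334)],
    )
    def test_vote_weight_formula(self, e, expected):
        assert round_alpha(e) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("e", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_errors_rejected(self, e):
        with pytest.raises(MirstartError):
            round_alpha(e)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(e=st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_antisymmetry_and_sign(self, e):
        assert round_alpha(e) == pytest.approx(-round_alpha(1 - e), abs=1e-9)
        if e < 0.5:
            assert round_alpha(e) > 0

    def test_strictly_decreasing(self):
        es = np.linspace(0.01, 0.99, 50)
        alphas = [round_alpha(e) for e in es]
        assert all(b < a for a, b in zip(alphas, alphas[1:]))


class TestUpdateWeights:
    def test_all_correct_leaves_distribution_unchanged(self):
        D = np.array([0.2, 0.3, 0.5])
        y = np.array([1, -1, 1])
        D2 = update_weights(D, 0.7, y, y)
        assert D2 == pytest.approx(D)

    def test_hand_computed_two_sample_update(self):
        # uniform weights, one of two wrong, alpha = ln(3)/2:
        # the correct sample drops to 1/4, the wrong one rises to 3/4
        D = np.array([0.5, 0.5])
        y = np.array([1, 1])
        pred = np.array([1, -1])
        D2 = update_weights(D, 0.5 * np.log(3), pred, y)
        assert D2 == pytest.approx([0.25, 0.75])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=5000))
    def test_distribution_stays_normalized(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        D = rng.random(n)
        D /= D.sum()
        y = rng.choice([-1, 1], size=n)
        pred = rng.choice([-1, 1], size=n)
        alpha = rng.uniform(-2, 2)
        D2 = update_weights(D, alpha, pred, y)
        assert abs(D2.sum() - 1.0) < 1e-12
        assert np.all(D2 >= 0)


class TestTrainRound:
    def test_separable_toy_set_is_fit_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(4, 0.3, (20, 2))])
        y = np.array([1] * 20 + [-1] * 20)
        rc = train_round(X, y, SvmConfig(seed=0))
        assert (rc.predict(X) == y).mean() == 1.0
        assert (rc.C, rc.g) in SvmConfig().grid

    def test_xor_needs_the_kernel(self):
        X = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
        y = np.array([1, 1, -1, -1])
        rc = train_round(X, y, SvmConfig(seed=0))
        assert (rc.predict(X) == y).mean() > 0.9
        # independent oracle: no linear rule beats 3/4 on these points
        best_linear = 0.0
        for theta in np.linspace(0, 2 * np.pi, 180, endpoint=False):
            w = np.array([np.cos(theta), np.sin(theta)])
            for b in np.linspace(-2, 2, 41):
                pred = np.where(X @ w + b >= 0, 1, -1)
                best_linear = max(best_linear, (pred == y).mean())
        assert best_linear <= 0.75

    def test_single_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(BoostError, match="single class"):
            train_round(X, np.ones(5, dtype=int), SvmConfig())


class _StubRound:
    """Hand-set per-start probabilities for vote-aggregation tests."""

    def __init__(self, probs_by_row):
        self.probs = np.asarray(probs_by_row, dtype=float)

    def prob(self, X):
        return self.probs[: X.shape[0]]


@pytest.fixture(scope="module")
def scored_hairpin():
    from mirstart.synth import SynthConfig, make_hairpin

    return make_hairpin(SynthConfig(seed=6), 0)


@pytest.fixture(scope="module")
def planted():
    train, _ = make_dataset(SynthConfig(n_hairpins=40, seed=13))
    return build_training_set(train)


def _stub_model(hairpin, round_probs, alphas):
    windows = generate_windows(hairpin, 22)
    X = feature_matrix(hairpin, windows)
    norm = fit_normalization(X)
    rounds = [
        (_StubRound(p), a) for p, a in zip(round_probs, alphas)
    ]
    return EnsembleModel(rounds=rounds, normalization=norm, window_len=22), len(windows)


class TestScoreAggregation:
    def test_single_round_ranking_equals_probability_ranking(self, scored_hairpin):
        rng = np.random.default_rng(0)
        n = len(scored_hairpin) - 21
        probs = rng.random(n)
        model, _ = _stub_model(scored_hairpin, [probs], [1.0])
        ranked = score_candidates(model, scored_hairpin)
        expected = sorted(
            zip(range(1, n + 1), probs.tolist()), key=lambda t: (-t[1], t[0])
        )
        assert [s for s, _ in ranked] == [s for s, _ in expected]

    def test_vote_matches_brute_force_weighted_majority_oracle(self, scored_hairpin):
        rng = np.random.default_rng(1)
        n = len(scored_hairpin) - 21
        for n_rounds in (2, 5, 8):
            round_probs = rng.random((n_rounds, n))
            alphas = rng.uniform(0.05, 2.0, size=n_rounds).tolist()
            model, _ = _stub_model(scored_hairpin, round_probs, alphas)
            ranked = score_candidates(model, scored_hairpin)
            # brute force: accumulate weighted votes per start, then
            # repeatedly pull out the best remaining candidate
            totals = {
                s: sum(a * round_probs[m][s - 1] for m, a in enumerate(alphas))
                for s in range(1, n + 1)
            }
            oracle = []
            remaining = dict(totals)
            while remaining:
                best = min(remaining, key=lambda s: (-remaining[s], s))
                oracle.append(best)
                del remaining[best]
            assert [s for s, _ in ranked] == oracle
            for s, score in ranked:
                assert score == pytest.approx(totals[s])

    def test_ties_break_toward_smaller_start(self, scored_hairpin):
        n = len(scored_hairpin) - 21
        model, _ = _stub_model(scored_hairpin, [np.full(n, 0.4)], [1.0])
        ranked = score_candidates(model, scored_hairpin)
        assert [s for s, _ in ranked] == list(range(1, n + 1))


class TestPredictTopK:
    def test_prefix_property_and_full_ranking(self, scored_hairpin):
        rng = np.random.default_rng(2)
        n = len(scored_hairpin) - 21
        model, _ = _stub_model(scored_hairpin, [rng.random(n)], [1.0])
        top1 = predict_top_k(model, scored_hairpin, k=1)
        top5 = predict_top_k(model, scored_hairpin, k=5)
        assert top1[0] == top5[0] and top1[0] in top5
        assert len(predict_top_k(model, scored_hairpin, k=n)) == n

    def test_k_beyond_window_count_returns_all_with_warning(self, scored_hairpin):
        n = len(scored_hairpin) - 21
        model, _ = _stub_model(scored_hairpin, [np.zeros(n)], [1.0])
        with pytest.warns(UserWarning, match="returning all"):
            starts = predict_top_k(model, scored_hairpin, k=n + 50)
        assert len(starts) == n


class TestTrainEnsemble:
    def test_strong_signal_gives_positive_round_weights(self, planted):
        model = train_ensemble(planted, M=3, seed=13)
        assert 1 <= len(model.rounds) <= 3
        assert all(alpha > 0 for _, alpha in model.rounds)
        sizes = [row["subset_size"] for row in model.round_log]
        assert sizes == sorted(sizes)

    def test_randomized_labels_abort_early(self, planted):
        from mirstart import TrainingSet

        rng = np.random.default_rng(0)
        shuffled = TrainingSet(
            vectors=planted.vectors.copy(),
            labels=rng.permutation(planted.labels),
            sample_keys=list(planted.sample_keys),
        )
        try:
            model = train_ensemble(shuffled, M=10, seed=13)
            assert len(model.rounds) <= 2
        except BoostError:
            pass  # round 1 already at chance

    def test_same_seed_reproduces_round_log(self, planted):
        m1 = train_ensemble(planted, M=2, seed=5)
        m2 = train_ensemble(planted, M=2, seed=5)
        assert m1.round_log == m2.round_log
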