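"""Discriminant and overrepresentation evidence channels."""

import numpy as np
import pytest

from auxre_fusion.features import (
    LABEL_NEG,
    LABEL_POS,
    MarkovBackground,
    TrainingMotif,
    estimate_background,
    lda_features,
    one_hot,
    overrepresentation,
    train_lda,
)
from auxre_fusion.motif_scan import find_core_matches
from auxre_fusion.sequence_io import UpstreamSequence
from auxre_fusion.synthetic_data import make_training_set
from conftest import holdout_accuracy


class TestOneHot:
    def test_encodes_one_indicator_per_position(self):
        x = one_hot("acgtTGTCTCacgt")
        assert x.shape == (56,)
        assert x.sum() == 14
        # position 0 is 'a' -> first block is [1,0,0,0]
        assert list(x[:4]) == [1, 0, 0, 0]

    def test_padding_gives_zero_column(self):
        x = one_hot("....TGTCTCacgt")
        assert x.sum() == 10
        assert x[:16].sum() == 0


class TestTrainLda:
    def test_separable_singleton_classes_saturate(self):
        pos = [TrainingMotif("ccttTGTCTCctct", LABEL_POS)] * 6
        neg = [TrainingMotif("aaaaGGGGGGaaaa", LABEL_NEG)] * 6
        model = train_lda(pos + neg)
        for t in pos:
            assert lda_features(model, t.context)[1] > 0.99
        for t in neg:
            assert lda_features(model, t.context)[1] < 0.01

    def test_class_minimum_enforced(self):
        pos = [TrainingMotif("ccttTGTCTCctct", LABEL_POS)] * 4
        neg = [TrainingMotif("aaaaGGGGGGaaaa", LABEL_NEG)] * 6
        with pytest.raises(ValueError, match="at least 5"):
            train_lda(pos + neg)

    def test_duplicating_training_set_leaves_model_unchanged(self, training_high):
        """The fit depends only on class sufficient statistics."""
        m1 = train_lda(training_high)
        m2 = train_lda(list(training_high) * 2)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-8)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-8)

    def test_order_independence(self, training_high):
        shuffled = list(training_high)[::-1]
        m1 = train_lda(training_high)
        m2 = train_lda(shuffled)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-10)

    def test_high_separation_holdout_accuracy(self):
        acc = holdout_accuracy(make_training_set(200, 200, "high", seed=1))
        assert acc >= 0.9

    def test_shuffled_labels_give_chance_level_holdout(self):
        """Permutation null: with labels detached from contexts the
        held-out accuracy sits at chance."""
        rng = np.random.default_rng(3)
        accs = []
        for rep in range(50):
            motifs = make_training_set(100, 100, "high", seed=200 + rep)
            labels = [m.label for m in motifs]
            rng.shuffle(labels)
            shuffled = [
                TrainingMotif(m.context, lab) for m, lab in zip(motifs, labels)
            ]
            accs.append(holdout_accuracy(shuffled, seed=rep))
        assert abs(np.mean(accs) - 0.5) <= 0.1

    def test_recovered_direction_correlates_with_planted_contrast(self):
        """The discriminant direction lines up with the difference of the
        planted class means (|cosine| >= 0.8 at high separation)."""
        motifs = make_training_set(400, 400, "high", seed=1)
        model = train_lda(motifs)
        contrast = model.mean_pos - model.mean_neg
        cos = model.weights @ contrast / (
            np.linalg.norm(model.weights) * np.linalg.norm(contrast)
        )
        assert abs(cos) >= 0.8

    def test_sklearn_cross_check(self, training_high):
        """Independent oracle: sklearn's shrunk-covariance LDA agrees with
        our Fisher discriminant on held-out decisions."""
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        from conftest import split_half

        train, test = split_half(list(training_high))
        model = train_lda(train, shrinkage=0.1)
        X = np.array([one_hot(t.context) for t in train])
        y = np.array([t.label == LABEL_POS for t in train])
        ref = sklearn.LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.1)
        ref.fit(X, y)
        Xt = np.array([one_hot(t.context) for t in test])
        ours = np.array([model.score(t.context) > 0 for t in test])
        theirs = ref.predict(Xt)
        assert np.mean(ours == theirs) >= 0.95


class TestLdaFeatures:
    def test_posterior_is_logistic_of_score(self, lda_high, training_high):
        from scipy.special import expit

        for t in list(training_high)[:20]:
            a1, a2 = lda_features(lda_high, t.context)
            assert a2 == pytest.approx(float(expit(a1)))

    def test_decision_boundary_gives_even_posterior(self):
        from auxre_fusion.features import LdaModel

        flat = LdaModel(
            weights=np.zeros(56), intercept=0.0,
            mean_pos=np.zeros(56), mean_neg=np.zeros(56), shrinkage=0.1,
        )
        a1, a2 = lda_features(flat, "ccttTGTCTCctct")
        assert (a1, a2) == (0.0, 0.5)

    def test_posterior_monotone_in_score(self, lda_high, training_high):
        pairs = [lda_features(lda_high, t.context) for t in training_high]
        pairs.sort()
        a2s = [a2 for _, a2 in pairs]
        assert all(x <= y + 1e-12 for x, y in zip(a2s, a2s[1:]))
        assert all(0.0 <= a2 <= 1.0 for a2 in a2s)


class TestOverrepresentation:
    def test_absent_word_forced_arithmetic(self):
        # exp = 1.5 forced via a background with p(word) = 1.5 / (L - 5)
        length = 1505
        p = 1.5 / (length - 5)
        bg = MarkovBackground(order=0, base_freqs={"A": p ** (1 / 6), "C": 0.1, "G": 0.1, "T": 0.1})
        seq = UpstreamSequence("g", "C" * length)
        b1, b2 = overrepresentation("AAAAAA", [seq], bg)
        assert b1 == pytest.approx(np.log2(0.5 / 2.0))
        assert b1 == pytest.approx(-2.0)

    def test_uniform_background_closed_form_expectation(self):
        seq = UpstreamSequence("g", "G" * 1005)
        bg = MarkovBackground(order=0, base_freqs={b: 0.25 for b in "ACGT"})
        exp = 1000 * 0.25**6
        b1, b2 = overrepresentation("TGTCTC", [seq], bg)
        assert b1 == pytest.approx(np.log2(0.5 / (exp + 0.5)))
        assert b2 == pytest.approx(-exp / np.sqrt(exp * (1 - 0.25**6)))
        assert exp == pytest.approx(0.2441, abs=5e-4)

    def test_empty_promoter_list_rejected(self):
        bg = MarkovBackground(order=0, base_freqs={b: 0.25 for b in "ACGT"})
        with pytest.raises(ValueError, match="empty"):
            overrepresentation("TGTCTC", [], bg)

    def test_observed_count_agrees_with_scanner(self, fixture_promoters):
        """Cross-module consistency: obs equals the scan's total hit count."""
        bg = estimate_background(fixture_promoters)
        total_hits = sum(len(find_core_matches(p)) for p in fixture_promoters)
        p = bg.word_prob("TGTCTC")
        exp = sum((rec.length - 5) * p for rec in fixture_promoters)
        b1, _ = overrepresentation("TGTCTC", fixture_promoters, bg)
        assert b1 == pytest.approx(np.log2((total_hits + 0.5) / (exp + 0.5)))

    def test_null_z_scores_are_calibrated(self):
        """For random words over random promoters, the binomial z-score
        rarely leaves (-4, 4)."""
        rng = np.random.default_rng(5)
        promoters = [
            UpstreamSequence(f"g{k}", "".join(rng.choice(list("ACGT"), size=300)))
            for k in range(100)
        ]
        bg = estimate_background(promoters)
        inside = 0
        trials = 500
        for _ in range(trials):
            word = "".join(rng.choice(list("ACGT"), size=6))
            _, b2 = overrepresentation(word, promoters, bg)
            if -4 < b2 < 4:
                inside += 1
        assert inside / trials >= 0.99


class TestBackground:
    def test_order0_frequencies_sum_to_one(self, fixture_promoters):
        bg = estimate_background(fixture_promoters, order=0)
        assert sum(bg.base_freqs.values()) == pytest.approx(1.0)
        assert all(v > 0 for v in bg.base_freqs.values())

    def test_order1_conditionals_sum_to_one(self, fixture_promoters):
        bg = estimate_background(fixture_promoters, order=1)
        for row in bg.transition.values():
            assert sum(row.values()) == pytest.approx(1.0)

    def test_order1_word_prob_chains_transitions(self):
        seq = UpstreamSequence("g", "ACACACACAC")
        bg = estimate_background([seq], order=1)
        manual = bg.base_freqs["A"]
        for prev, cur in zip("ACACAC", "CACAC"):
            manual *= bg.transition[prev][cur]
        assert bg.word_prob("ACACAC") == pytest.approx(manual)
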