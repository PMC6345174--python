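"""Contingency tables, risk/odds ratios, and the diagnosis classifier."""

import numpy as np
import pytest

import ccsynth as cs
from ccsynth.validation import (ClassifierConfig, ContingencyTable,
                                primary_diagnosis, ratios, score_classifier,
                                train_cc_classifier, validity_comparison,
                                word_variable_table)


class TestContingency:
    def test_empty_corpus_all_cells_zero(self):
        t = word_variable_table([], "fall", "age", 4, 0,
                                schema=cs.build_schema([("age", 5)]))
        assert (t.exposed_with, t.exposed_total,
                t.unexposed_with, t.unexposed_total) == (0, 0, 0, 0)

    def test_hand_built_corpus_counts(self):
        schema = cs.build_schema([("age", 5)])
        recs = [
            cs.RawRecord({"age": [4]}, "fall at home"),
            cs.RawRecord({"age": [4]}, "fall fall again"),  # counts once
            cs.RawRecord({"age": [4]}, "chest pain"),
            cs.RawRecord({"age": [0]}, "fall outside"),
            cs.RawRecord({"age": [0]}, "fever"),
            cs.RawRecord({"age": [2]}, "fall ignored stratum"),
        ]
        t = word_variable_table(recs, "fall", "age", 4, 0, schema=schema)
        assert (t.exposed_with, t.exposed_total) == (2, 3)
        assert (t.unexposed_with, t.unexposed_total) == (1, 2)

    def test_matches_simulator_truth(self, toy_pairs):
        pairs, truth = toy_pairs
        t = word_variable_table(pairs, "preg", "gender",
                                cs.simulate.FEMALE, cs.simulate.MALE)
        assert (t.exposed_with, t.exposed_total) == \
            truth.exclusivity_counts["preg"]["allowed"]

    def test_unknown_variable_or_stratum(self):
        schema = cs.build_schema([("age", 5)])
        with pytest.raises(KeyError):
            word_variable_table([], "x", "bogus", 0, 1, schema=schema)
        with pytest.raises(ValueError):
            word_variable_table([], "x", "age", 0, 9, schema=schema)


class TestRatios:
    def test_fall_by_age_published_counts(self):
        # 207/2234 over-80s vs 48/4009 20-24s: risk ratio ~7.74 (odds 8.43)
        r = ratios(ContingencyTable(207, 2234, 48, 4009))
        assert r.risk_ratio == pytest.approx(7.74, abs=0.005)
        assert r.odds_ratio == pytest.approx(8.43, abs=0.005)
        assert round(r.risk_ratio) == 8

    def test_synthetic_fall_counts(self):
        # 229 vs 27 reporting: risk ratio ~15.22
        r = ratios(ContingencyTable(229, 2234, 27, 4009))
        assert r.risk_ratio == pytest.approx(15.22, abs=0.005)
        assert round(r.risk_ratio) == 15

    def test_equal_proportions_give_unity(self):
        r = ratios(ContingencyTable(10, 100, 30, 300))
        assert r.risk_ratio == pytest.approx(1.0)
        assert r.odds_ratio == pytest.approx(1.0)

    def test_zero_cells_flagged_infinite(self):
        r = ratios(ContingencyTable(5, 10, 0, 10))
        assert r.risk_infinite and r.odds_infinite
        assert np.isinf(r.risk_ratio) and np.isinf(r.odds_ratio)
        rh = ratios(ContingencyTable(5, 10, 0, 10), haldane=True)
        assert np.isfinite(rh.odds_ratio)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ratios(ContingencyTable(0, 0, 1, 10))

    def test_agrees_with_statsmodels_on_random_tables(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 1000:
            ta, tb = rng.integers(2, 500, size=2)
            a = int(rng.integers(1, ta))
            b = int(rng.integers(1, tb))
            t2 = sm.stats.Table2x2([[a, ta - a], [b, tb - b]])
            r = ratios(ContingencyTable(a, int(ta), b, int(tb)))
            assert r.odds_ratio == pytest.approx(t2.oddsratio, abs=1e-12)
            assert r.risk_ratio == pytest.approx(t2.riskratio, abs=1e-12)
            checked += 1


def separable_corpus(n_pairs=1200, seed=0):
    """Four diagnosis codes with disjoint template vocabularies."""
    schema = cs.build_schema([("age", 3, False, True),
                              ("diagnosis", 4, True, True)])
    phrasebook = {
        0: [cs.Template("alpha bravo charlie"), cs.Template("bravo alpha")],
        1: [cs.Template("delta echo foxtrot"), cs.Template("echo delta")],
        2: [cs.Template("golf hotel india"), cs.Template("hotel golf")],
        3: [cs.Template("juliet kilo lima"), cs.Template("kilo juliet")],
    }
    cfg = cs.SimulationConfig(n_pairs=n_pairs, schema=schema,
                              phrasebook=phrasebook, noise_rate=0.0,
                              secondary_diagnosis_rate=0.0, seed=seed)
    pairs, _ = cs.generate_pairs(cfg)
    corpus, vocab, _ = cs.preprocess_text(pairs, schema, min_freq=1)
    return corpus, vocab


class TestClassifier:
    def test_separable_corpus_learned_perfectly(self):
        corpus, vocab = separable_corpus()
        tr, va, _ = cs.split_corpus(corpus, seed=1, test_size=100)
        clf, _ = train_cc_classifier(
            tr, va, ClassifierConfig(vocab_size=len(vocab), n_classes=4,
                                     hidden_dim=16, embed_dim=8,
                                     max_epochs=30, seed=0))
        rep = score_classifier(clf, tr.raw_texts, primary_diagnosis(tr))
        assert rep.f1 >= 0.99

    def test_shuffled_labels_near_chance(self):
        corpus, vocab = separable_corpus(seed=5)
        rng = np.random.default_rng(0)
        # destroy the text-label relationship by permuting record vectors
        perm = rng.permutation(len(corpus))
        corpus.record_bits = corpus.record_bits[perm]
        tr, va, _ = cs.split_corpus(corpus, seed=1, test_size=100)
        clf, _ = train_cc_classifier(
            tr, va, ClassifierConfig(vocab_size=len(vocab), n_classes=4,
                                     hidden_dim=16, embed_dim=8,
                                     max_epochs=10, seed=0))
        rep = score_classifier(clf, va.raw_texts, primary_diagnosis(va))
        assert rep.f1 < 0.45  # four roughly balanced classes: chance ~ 0.25

    def test_deterministic_given_seed(self):
        corpus, vocab = separable_corpus(n_pairs=300)
        tr, va, _ = cs.split_corpus(corpus, seed=1, test_size=50)
        cfg = ClassifierConfig(vocab_size=len(vocab), n_classes=4,
                               hidden_dim=8, embed_dim=8, max_epochs=3,
                               seed=4)
        c1, l1 = train_cc_classifier(tr, va, cfg)
        c2, l2 = train_cc_classifier(tr, va, cfg)
        assert l1 == l2
        for k in c1.weights:
            assert np.array_equal(c1.weights[k], c2.weights[k])

    def test_single_class_rejected(self):
        schema = cs.build_schema([("diagnosis", 4, True, True)])
        pairs = [cs.RawRecord({"diagnosis": [1]}, "alpha bravo")] * 40
        corpus, vocab, _ = cs.preprocess_text(pairs, schema, min_freq=1)
        with pytest.raises(ValueError, match="2 diagnosis classes"):
            train_cc_classifier(corpus, corpus,
                                ClassifierConfig(vocab_size=len(vocab),
                                                 n_classes=4))


class TestScoreClassifier:
    def test_perfect_predictions(self):
        rep = score_classifier(None, None, [0, 1, 2, 1],
                               predictions=np.array([0, 1, 2, 1]))
        assert (rep.sens, rep.ppv, rep.f1) == (1.0, 1.0, 1.0)

    def test_hand_computed_weighted_macro(self):
        # confusion [[2,0,0],[1,1,0],[0,0,2]] worked by hand:
        # sens: (2/6)*1 + (2/6)*0.5 + (2/6)*1 = 0.8333
        y_true = [0, 0, 1, 1, 2, 2]
        y_pred = [0, 0, 0, 1, 2, 2]
        rep = score_classifier(None, None, y_true, predictions=y_pred)
        assert rep.sens == pytest.approx(5 / 6)
        # ppv: class0 2/3, class1 1/1, class2 1 -> (2/3 + 1 + 1)/3 weighted
        assert rep.ppv == pytest.approx((2 / 3 + 1 + 1) / 3)

    def test_matches_sklearn_weighted_average(self):
        from sklearn.metrics import precision_recall_fscore_support
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 5, size=400)
        y_pred = rng.integers(0, 5, size=400)
        rep = score_classifier(None, None, y_true, predictions=y_pred)
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, average="weighted", zero_division=0)
        assert rep.ppv == pytest.approx(p, abs=1e-12)
        assert rep.sens == pytest.approx(r, abs=1e-12)
        assert rep.f1 == pytest.approx(f, abs=1e-12)

    def test_single_predicted_class_degenerate(self):
        rep = score_classifier(None, None, [0, 1, 1, 2],
                               predictions=np.array([1, 1, 1, 1]))
        # unpredicted classes get ppv 0; class 1 ppv = 2/4
        assert rep.ppv == pytest.approx((2 / 4) * (2 / 4))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            score_classifier(None, None, [0, 1], predictions=np.array([0]))


class TestValidityComparison:
    def test_memorized_generator_matches_original_row(self, memorized_model):
        params, corpus, _ = memorized_model
        clf, _ = train_cc_classifier(
            corpus, corpus,
            ClassifierConfig(vocab_size=len(corpus.vocab), n_classes=10,
                             hidden_dim=8, embed_dim=8, max_epochs=5,
                             batch_size=10, seed=0))
        reports = validity_comparison(
            params, clf, corpus,
            {"greedy": cs.SamplingConfig("greedy"),
             "beam_k3": cs.SamplingConfig("beam", beam_width=3)})
        assert set(reports) == {"original", "greedy", "beam_k3"}
        for row in ("greedy", "beam_k3"):
            assert reports[row].to_dict() == reports["original"].to_dict()
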