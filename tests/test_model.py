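"""Encoder pretraining, training dynamics, step probabilities, serialization."""

import numpy as np
import pytest

import ccsynth as cs
from ccsynth import _nn
from ccsynth.model import (ModelConfig, ModelParams, autoencoder_reconstruction,
                           early_stop_state, evaluate_loss,
                           pretrain_record_encoder, step_probabilities)
from helpers import make_vocab, table_model_params, transition_table


class TestAutoencoderPretraining:
    def test_reconstructs_one_hot_records(self):
        # 500 one-hot records over 10 codes, hidden 8: argmax of the
        # reconstruction recovers the input code for >= 95% of records
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 10, size=500)
        records = np.zeros((500, 10))
        records[np.arange(500), codes] = 1
        config = ModelConfig(record_dim=10, vocab_size=5, hidden_dim=8,
                             word_embed_dim=4, pretrain_epochs=1500,
                             batch_size=128, seed=0)
        recon = autoencoder_reconstruction(records, config)
        assert np.mean(np.abs(recon - records)) < 0.05
        assert (recon.argmax(axis=1) == codes).mean() >= 0.95

    def test_all_zero_record_reconstruction_defined(self):
        config = ModelConfig(record_dim=6, vocab_size=5, hidden_dim=3,
                             word_embed_dim=4, pretrain_epochs=5, seed=0)
        recon = autoencoder_reconstruction(np.zeros((4, 6)), config)
        assert np.isfinite(recon).all()

    def test_encoder_output_dimension(self):
        config = ModelConfig(record_dim=12, vocab_size=5, hidden_dim=7,
                             word_embed_dim=4, pretrain_epochs=2, seed=0)
        W, b = pretrain_record_encoder(np.eye(12), config)
        assert W.shape == (12, 7) and b.shape == (7,)

    def test_no_compression_warns(self, caplog):
        config = ModelConfig(record_dim=4, vocab_size=5, hidden_dim=8,
                             word_embed_dim=4, pretrain_epochs=1, seed=0)
        with caplog.at_level("WARNING"):
            pretrain_record_encoder(np.eye(4), config)
        assert "compress" in caplog.text


class TestEarlyStopping:
    @pytest.mark.parametrize("losses,patience,best,stop", [
        ([2.0, 1.5, 1.6, 1.7], 2, 2, 4),         # worked by hand
        ([3.0, 2.0, 1.0], 2, 3, 3),              # never fires
        ([1.0, 1.0, 1.0], 2, 1, 3),              # equal = not a decrease
        ([2.0, 1.9, 2.1, 1.8, 1.85, 1.9], 2, 4, 6),
    ])
    def test_patience_rule(self, losses, patience, best, stop):
        assert early_stop_state(losses, patience) == (best, stop)

    def test_training_log_respects_rule(self, memorized_model):
        _, _, log = memorized_model
        best, stop = early_stop_state(log.val_losses, 500)
        assert log.best_epoch == best and log.stopped_epoch == stop


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        """Full-model analytic gradients agree with central differences."""
        vocab = make_vocab(["a", "b", "c"])
        schema = cs.build_schema([("x", 3)])
        config = ModelConfig(record_dim=3, vocab_size=len(vocab),
                             hidden_dim=4, word_embed_dim=3, seed=1)
        params = ModelParams.initialize(config, schema, vocab)
        rng = np.random.default_rng(0)
        R = rng.integers(0, 2, size=(5, 3)).astype(float)
        X = np.array([[1, 3, 4, 5, 0]] * 5)   # SOS a b c pad
        Y = np.array([[3, 4, 5, 2, 0]] * 5)   # a b c EOS pad
        _, grads = params.loss_and_grads(R, X, Y)
        eps = 1e-6
        for key in ["W_enc", "Wx", "Wh", "b", "Wy", "E"]:
            w = params.weights[key]
            flat = w.ravel()
            idxs = rng.choice(flat.size, size=min(8, flat.size), replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                lp = params.loss(R, X, Y)
                flat[i] = orig - eps
                lm = params.loss(R, X, Y)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[key].ravel()[i]
                assert ana == pytest.approx(num, abs=1e-5), key

    def test_gru_backward_matches_numerical(self):
        rng = np.random.default_rng(3)
        B, T, D, H = 4, 5, 3, 4
        X = rng.normal(size=(B, T, D))
        h0 = np.zeros((B, H))
        Wx = rng.normal(scale=0.3, size=(D, 3 * H))
        Wh = rng.normal(scale=0.3, size=(H, 3 * H))
        b = np.zeros(3 * H)
        target = rng.normal(size=(B, T, H))

        def loss_of(Wx_, Wh_, b_):
            Hs, _ = _nn.gru_forward(X, h0, Wx_, Wh_, b_)
            return 0.5 * np.sum((Hs - target) ** 2)

        Hs, cache = _nn.gru_forward(X, h0, Wx, Wh, b)
        dX, dh0, dWx, dWh, db = _nn.gru_backward(Hs - target, cache, Wx, Wh)
        eps = 1e-6
        for arr, grad in [(Wx, dWx), (Wh, dWh), (b, db)]:
            flat = arr.ravel()
            for i in rng.choice(flat.size, size=6, replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss_of(Wx, Wh, b)
                flat[i] = orig - eps
                lm = loss_of(Wx, Wh, b)
                flat[i] = orig
                assert grad.ravel()[i] == pytest.approx(
                    (lp - lm) / (2 * eps), abs=1e-5)


class TestTraining:
    def test_memorizes_ten_pairs(self, memorized_model):
        params, corpus, _ = memorized_model
        sents = cs.generate_corpus(params, corpus.record_bits,
                                   cs.SamplingConfig("greedy"))
        assert sents == corpus.raw_texts

    def test_loss_beats_uniform_model(self, memorized_model):
        params, corpus, log = memorized_model
        assert log.train_losses[0] <= np.log(params.config.vocab_size) + 0.1
        assert evaluate_loss(params, corpus) < log.train_losses[0]

    def test_training_deterministic(self):
        schema = cs.build_schema([("age", 3)])
        pairs = [cs.RawRecord({"age": [i % 3]}, t) for i, t in
                 enumerate(["chest pain", "abd pain", "leg pain"] * 20)]
        corpus, vocab, _ = cs.preprocess_text(pairs, schema, min_freq=1)
        config = ModelConfig(record_dim=3, vocab_size=len(vocab),
                             hidden_dim=8, word_embed_dim=4, batch_size=16,
                             max_epochs=3, seed=9)
        p1, l1 = cs.train(corpus, corpus, config)
        p2, l2 = cs.train(corpus, corpus, config)
        assert l1.val_losses == l2.val_losses
        for k in p1.weights:
            assert np.array_equal(p1.weights[k], p2.weights[k])

    def test_batch_clamp_warning(self, caplog):
        schema = cs.build_schema([("age", 3)])
        pairs = [cs.RawRecord({"age": [0]}, "chest pain")] * 10
        corpus, vocab, _ = cs.preprocess_text(pairs, schema, min_freq=1)
        config = ModelConfig(record_dim=3, vocab_size=len(vocab),
                             hidden_dim=4, word_embed_dim=4, batch_size=512,
                             max_epochs=1, pretrain_epochs=1, seed=0)
        with caplog.at_level("WARNING"):
            cs.train(corpus, corpus, config)
        assert "clamping" in caplog.text


class TestStepProbabilities:
    def test_probabilities_normalized_and_pure(self, trained_small):
        params, (train_c, _, _), _ = trained_small
        record = train_c.record_bits[0]
        prefix = [params.sos_id, train_c.sequences[0][1]]
        p1 = step_probabilities(params, record, prefix)
        p2 = step_probabilities(params, record, prefix)
        assert p1.sum() == pytest.approx(1.0, abs=1e-6)
        assert (p1 >= 0).all()
        assert p1[cs.PAD_INDEX] < 1e-12
        assert np.array_equal(p1, p2)

    def test_hand_built_weights_realize_transition_table(self):
        vocab = make_vocab(["chest", "pain"])
        table = transition_table(vocab, {
            "<s>": {"chest": 0.7, "pain": 0.3},
            "chest": {"pain": 0.9, "</s>": 0.1},
            "pain": {"</s>": 1.0},
        })
        params = table_model_params(vocab, table)
        record = np.zeros(4)
        p0 = step_probabilities(params, record, [vocab.sos_id])
        assert p0[vocab.index["chest"]] == pytest.approx(0.7, abs=1e-6)
        assert p0[vocab.index["pain"]] == pytest.approx(0.3, abs=1e-6)
        p1 = step_probabilities(params, record,
                                [vocab.sos_id, vocab.index["chest"]])
        assert p1[vocab.index["pain"]] == pytest.approx(0.9, abs=1e-6)
        assert p1[vocab.eos_id] == pytest.approx(0.1, abs=1e-6)

    def test_prefix_must_start_with_sos(self, trained_small):
        params, (train_c, _, _), _ = trained_small
        with pytest.raises(ValueError, match="start-of-sequence"):
            step_probabilities(params, train_c.record_bits[0], [5])

    def test_prefix_length_limit(self, trained_small):
        params, (train_c, _, _), _ = trained_small
        prefix = [params.sos_id] + [3] * 25
        with pytest.raises(ValueError, match="longer"):
            step_probabilities(params, train_c.record_bits[0], prefix)


class TestSerialization:
    def test_save_load_bit_exact(self, tmp_path, trained_small):
        params, (train_c, _, _), _ = trained_small
        path = tmp_path / "ckpt.h5"
        params.save(path)
        loaded = ModelParams.load(path)
        for k in params.weights:
            assert np.array_equal(params.weights[k], loaded.weights[k])
        assert loaded.vocab.tokens == params.vocab.tokens
        assert loaded.schema == params.schema
        rec = train_c.record_bits[0]
        a = step_probabilities(params, rec, [params.sos_id])
        b = step_probabilities(loaded, rec, [loaded.sos_id])
        assert np.array_equal(a, b)


class TestConditioning:
    def test_female_exclusive_token_suppressed_for_males(self, trained_small,
                                                         toy_config):
        """The model must assign the female-only token lower probability
        under every male record than its maximum under female records."""
        params, (train_c, _, _), _ = trained_small
        preg = params.vocab.index["preg"]
        g_off = toy_config.schema.offset("gender")
        bits = train_c.record_bits
        female = bits[:, g_off + cs.simulate.FEMALE] == 1
        male = bits[:, g_off + cs.simulate.MALE] == 1
        f_recs = bits[female][:50]
        m_recs = bits[male][:50]
        p_f = [step_probabilities(params, r, [params.sos_id])[preg]
               for r in f_recs]
        p_m = [step_probabilities(params, r, [params.sos_id])[preg]
               for r in m_recs]
        assert max(p_m) < max(p_f)
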