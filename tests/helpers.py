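"""Shared test utilities: hand-constructable models with known transition
tables, plus an independent brute-force n-gram scorer used as an oracle."""

from __future__ import annotations

import numpy as np

from ccsynth.model import ModelConfig, ModelParams
from ccsynth.schema import EOS_TOKEN, SOS_TOKEN, Vocabulary, build_schema

LOG_ZERO = -1e3


def make_vocab(words: list[str]) -> Vocabulary:
    return Vocabulary(tokens=["<pad>", SOS_TOKEN, EOS_TOKEN] + list(words),
                      frequencies={w: 10 for w in words})


class TableModel:
    """First-order Markov sentence model implementing the decoding protocol.

    ``table[token_id]`` is a probability vector over the vocabulary for the
    next token (the start-of-sequence row gives the initial distribution).
    Used as a ground-truth oracle for the decoders.
    """

    def __init__(self, vocab: Vocabulary, table: np.ndarray,
                 record_dim: int = 4):
        self.vocab = vocab
        self.table = np.asarray(table, dtype=float)
        assert self.table.shape == (len(vocab), len(vocab))
        self.schema = build_schema([("x", record_dim, False, True)])

    @property
    def sos_id(self):
        return self.vocab.sos_id

    @property
    def eos_id(self):
        return self.vocab.eos_id

    @property
    def vocab_size(self):
        return len(self.vocab)

    def start_state(self, records):
        B = np.atleast_2d(records).shape[0]
        return (np.zeros(B),)

    def step(self, state, token_ids):
        probs = self.table[np.atleast_1d(token_ids)]
        return probs, state


def transition_table(vocab: Vocabulary, rows: dict[str, dict[str, float]]
                     ) -> np.ndarray:
    """Dense transition matrix from {token: {next_token: prob}} (token names,
    with SOS/EOS usable as keys)."""
    V = len(vocab)
    table = np.zeros((V, V))
    for tok, nxt in rows.items():
        i = vocab.index[tok]
        for t2, p in nxt.items():
            table[i, vocab.index[t2]] = p
    return table


def table_model_params(vocab: Vocabulary, table: np.ndarray,
                       record_dim: int = 4) -> ModelParams:
    """Hand-constructed LSTM weights realizing a first-order transition table.

    The input gate and output gate are saturated open and the forget gate
    saturated shut, so the hidden state after consuming token j is
    tanh(tanh(alpha)) * e_j; the output projection row for token j is then
    log(table[j]) rescaled, making the softmax reproduce the table row to
    ~1e-9.  The record encoder is zeroed (record-independent model).
    """
    V = len(vocab)
    config = ModelConfig(record_dim=record_dim, vocab_size=V,
                         hidden_dim=V, word_embed_dim=V, seed=0)
    schema = build_schema([("x", record_dim, False, True)])
    params = ModelParams.initialize(config, schema, vocab)
    w = params.weights
    alpha = 1.0
    beta = np.tanh(np.tanh(alpha))
    w["W_enc"][:] = 0.0
    w["b_enc"][:] = 0.0
    E = np.eye(V)
    E[0] = 0.0
    w["E"] = E
    w["Wx"] = np.zeros((V, 4 * V))
    w["Wx"][:, 2 * V:3 * V] = alpha * np.eye(V)   # candidate gate g
    w["Wh"] = np.zeros((V, 4 * V))
    b = np.zeros(4 * V)
    b[:V] = 40.0          # input gate open
    b[V:2 * V] = -40.0    # forget gate shut
    b[3 * V:] = 40.0      # output gate open
    w["b"] = b
    with np.errstate(divide="ignore"):
        logp = np.where(table > 0, np.log(np.maximum(table, 1e-300)), LOG_ZERO)
    w["Wy"] = logp / beta
    w["by"] = np.zeros(V)
    return params


def brute_force_ngram_scores(ref: list[str], cand: list[str], max_order: int):
    """Independent n-gram PPV/sens/F1: explicit double loops, no pooling
    shortcuts, written separately from the package implementation."""
    def grams(toks, n):
        return [tuple(toks[i:i + n]) for i in range(len(toks) - n + 1)]

    matched = cand_total = ref_total = 0
    for n in range(1, max_order + 1):
        rg = grams(ref, n)
        cg = grams(cand, n)
        cand_total += len(cg)
        ref_total += len(rg)
        remaining = list(rg)
        for g in cg:
            if g in remaining:
                remaining.remove(g)
                matched += 1
    ppv = matched / cand_total if cand_total else 0.0
    sens = matched / ref_total if ref_total else 0.0
    f1 = 0.0 if ppv + sens == 0 else 2 * ppv * sens / (ppv + sens)
    return ppv, sens, f1


def brute_force_cider(pairs: list[tuple[list[str], list[str]]],
                      max_order: int) -> float:
    """Independent TF-IDF cosine CIDEr implementation (dict arithmetic)."""
    import math

    def grams(toks):
        out = {}
        for n in range(1, min(max_order, len(toks)) + 1):
            for i in range(len(toks) - n + 1):
                g = tuple(toks[i:i + n])
                out[g] = out.get(g, 0) + 1
        return out

    N = len(pairs)
    df: dict = {}
    for ref, _ in pairs:
        for g in grams(ref):
            df[g] = df.get(g, 0) + 1
    sims = []
    for ref, cand in pairs:
        rv = {g: tf * math.log(N / max(df.get(g, 0), 1))
              for g, tf in grams(ref).items()}
        cv = {g: tf * math.log(N / max(df.get(g, 0), 1))
              for g, tf in grams(cand).items()}
        rn = math.sqrt(sum(v * v for v in rv.values()))
        cn = math.sqrt(sum(v * v for v in cv.values()))
        if rn == 0 or cn == 0:
            sims.append(0.0)
            continue
        dot = sum(v * cv.get(g, 0.0) for g, v in rv.items())
        sims.append(dot / (rn * cn))
    return sum(sims) / len(sims)


def random_sentences(rng: np.random.Generator, n: int, vocab_words: list[str],
                     max_len: int = 8) -> list[list[str]]:
    return [
        [vocab_words[i] for i in
         rng.integers(0, len(vocab_words), size=rng.integers(1, max_len + 1))]
        for _ in range(n)
    ]
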