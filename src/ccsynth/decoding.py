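"""Sampling schemes for generating complaints from a trained model.

Generation follows a four-step loop: feed the record and the
start-of-sequence token to the decoder, obtain next-word probabilities, pick
the next word by the active sampling scheme, and repeat until the
end-of-sequence token or the maximum sentence length (18 tokens).  Three
schemes are provided: greedy (argmax, ties to the lowest vocabulary index),
probabilistic (temperature-melted sampling, seeded), and beam search over
raw summed log-probabilities with no length normalization.

Decoders operate on any model exposing the incremental protocol
``start_state(records) -> state`` and ``step(state, token_ids) ->
(probs, state)`` with batch-leading state arrays, plus ``sos_id`` /
``eos_id`` / ``vocab_size`` attributes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from heapq import nlargest

import numpy as np

logger = logging.getLogger(__name__)

MAX_LEN_DEFAULT = 18


@dataclass
class SamplingConfig:
    scheme: str = "greedy"              # greedy | prob | beam
    temperature: float = 1.0            # prob scheme
    beam_width: int = 1                 # beam scheme
    max_len: int = MAX_LEN_DEFAULT
    seed: int | None = None             # prob scheme

    def __post_init__(self):
        if self.scheme not in ("greedy", "prob", "beam"):
            raise ValueError(f"unknown sampling scheme {self.scheme!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.beam_width < 1:
            raise ValueError("beam width must be at least 1")


@dataclass
class DecodeResult:
    """Decoded sequences as content token ids (specials stripped).

    ``finished[i]`` marks sequences that emitted the end token (their
    log-probability includes the end-token step); unfinished sequences have
    content length exactly ``max_len``.  Beam results are sorted by
    descending log-probability.
    """

    sequences: list[list[int]]
    log_probabilities: list[float]
    finished: list[bool] = field(default_factory=list)


def _reindex_state(state, idx):
    return tuple(a[idx] for a in state)


def _tile_state(state, k: int):
    return tuple(np.repeat(a, k, axis=0) for a in state)


def greedy_decode(model, record, config: SamplingConfig | None = None
                  ) -> DecodeResult:
    """Argmax decoding of a single record (deterministic)."""
    config = config or SamplingConfig(scheme="greedy")
    res = _batch_greedy_or_prob(model, np.atleast_2d(record), config,
                                sample=False)
    return DecodeResult(res.sequences[:1], res.log_probabilities[:1],
                        res.finished[:1])


def prob_decode(model, record, config: SamplingConfig) -> DecodeResult:
    """Temperature sampling of a single record; seeded and reproducible.

    Tokens are drawn from ``p_i^(1/t)`` renormalized; as t -> 0 this
    approaches greedy decoding, and t = 1 samples the model's distribution
    unchanged.
    """
    res = _batch_greedy_or_prob(model, np.atleast_2d(record), config,
                                sample=True)
    return DecodeResult(res.sequences[:1], res.log_probabilities[:1],
                        res.finished[:1])


def _batch_greedy_or_prob(model, records: np.ndarray, config: SamplingConfig,
                          sample: bool) -> DecodeResult:
    """Greedy or temperature decoding for a batch of records at once."""
    B = records.shape[0]
    rng = np.random.default_rng(config.seed) if sample else None
    state = model.start_state(records)
    tokens = np.full(B, model.sos_id, dtype=np.int64)
    done = np.zeros(B, dtype=bool)
    logps = np.zeros(B)
    seqs: list[list[int]] = [[] for _ in range(B)]
    for _ in range(config.max_len + 1):  # +1: the end token needs a step
        probs, state = model.step(state, tokens)
        if sample:
            if done.any():
                # finished rows may carry degenerate rows (e.g. an absorbing
                # end state); pin them to the end token to keep melting finite
                probs = probs.copy()
                probs[done] = 0.0
                probs[done, model.eos_id] = 1.0
            with np.errstate(divide="ignore"):
                melted = np.log(probs) / config.temperature
            melted -= melted.max(axis=1, keepdims=True)
            p = np.exp(melted)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(B)
            nxt = np.array([int(np.searchsorted(np.cumsum(p[i]), u[i],
                                                side="right"))
                            for i in range(B)])
            nxt = np.minimum(nxt, probs.shape[1] - 1)
        else:
            nxt = probs.argmax(axis=1)  # ties -> lowest index
        step_logp = np.log(np.maximum(probs[np.arange(B), nxt], 1e-300))
        for i in range(B):
            if done[i]:
                continue
            if nxt[i] == model.eos_id:
                done[i] = True
                logps[i] += step_logp[i]
            elif len(seqs[i]) < config.max_len:
                seqs[i].append(int(nxt[i]))
                logps[i] += step_logp[i]
        if done.all():
            break
        tokens = np.where(done, model.eos_id, nxt)
    return DecodeResult(seqs, [float(x) for x in logps],
                        [bool(d) for d in done])


def beam_decode(model, record, config: SamplingConfig) -> DecodeResult:
    """Beam search for a single record.

    Keeps the ``beam_width`` highest log-probability partial sequences per
    step; a sequence emitting the end token is frozen into a finished pool
    and competes by its final (raw, unnormalized) score while the beam
    refills from unfinished candidates.  Returns the top-k finished
    sequences, falling back to unfinished ones cut off at ``max_len``;
    results sorted by descending log-probability, ties to the lowest
    vocabulary index.
    """
    k = config.beam_width
    state = model.start_state(np.atleast_2d(record))
    # live beam: parallel arrays of scores, sequences and states
    live_seqs: list[list[int]] = [[]]
    live_scores = np.zeros(1)
    live_state = state
    finished: list[tuple[float, list[int]]] = []
    for _ in range(config.max_len + 1):
        if not live_seqs:
            break
        if len(finished) >= k:
            # a live hypothesis can only lose score as it grows, so stop
            # once none can beat the k-th best finished sequence
            kth = sorted((s for s, _ in finished), reverse=True)[k - 1]
            if live_scores.max() <= kth:
                break
        last = np.array([s[-1] if s else model.sos_id for s in live_seqs])
        probs, new_state = model.step(live_state, last)
        with np.errstate(divide="ignore"):
            scores = live_scores[:, None] + np.log(probs)  # (n_live, V)
        if len(live_seqs[0]) >= config.max_len:
            # at the length cap only the end token is a legal continuation;
            # cut-off hypotheses stay available as unfinished fallbacks
            for h, s in enumerate(live_seqs):
                sc = float(scores[h, model.eos_id])
                if sc > -np.inf:
                    finished.append((sc, s))
            break
        flat = scores.ravel()
        width = min(k, flat.size)
        # top-`width` expansions; ties resolved toward the lower flat index
        # (i.e. earlier hypothesis, then lower vocabulary index)
        order = np.lexsort((np.arange(flat.size), -flat))[:width]
        keep_idx, keep_tok, keep_score = [], [], []
        for fi in order:
            hyp, tok = divmod(int(fi), probs.shape[1])
            sc = float(flat[fi])
            if sc == -np.inf:
                continue
            if tok == model.eos_id:
                finished.append((sc, live_seqs[hyp]))
            else:
                keep_idx.append(hyp)
                keep_tok.append(tok)
                keep_score.append(sc)
        if not keep_idx:
            live_seqs = []
            break
        live_state = _reindex_state(new_state, np.array(keep_idx))
        live_seqs = [live_seqs[h] + [t] for h, t in zip(keep_idx, keep_tok)]
        live_scores = np.array(keep_score)
        if len(live_seqs[0]) >= config.max_len:
            break
    pool = sorted(finished, key=lambda x: -x[0])
    flags = [True] * len(pool)
    if len(pool) < k and live_seqs:
        rest = sorted(zip(live_scores, live_seqs), key=lambda x: -x[0])
        pool += [(float(s), q) for s, q in rest]
        flags += [False] * len(rest)
    pool, flags = pool[:k], flags[:k]
    return DecodeResult([q for _, q in pool], [s for s, _ in pool], flags)


def decode_record(model, record, config: SamplingConfig) -> DecodeResult:
    if config.scheme == "greedy":
        return greedy_decode(model, record, config)
    if config.scheme == "prob":
        return prob_decode(model, record, config)
    return beam_decode(model, record, config)


def generate_corpus(model, records: np.ndarray, config: SamplingConfig,
                    batch_size: int = 512) -> list[str]:
    """Generate one detokenized sentence per record (best-of-beam for the
    beam scheme); output is lowercase text without special tokens, aligned
    with the input row order."""
    records = np.asarray(records)
    if records.ndim == 1:
        records = records[None, :]
    if records.shape[0] and records.shape[1] != model.schema.total_dim:
        raise ValueError(
            f"record dimension {records.shape[1]} does not match the model "
            f"schema ({model.schema.total_dim})")
    sentences: list[str] = []
    if config.scheme in ("greedy", "prob"):
        for start in range(0, records.shape[0], batch_size):
            chunk = records[start:start + batch_size]
            sub = SamplingConfig(config.scheme, config.temperature,
                                 config.beam_width, config.max_len,
                                 None if config.seed is None
                                 else config.seed + start)
            res = _batch_greedy_or_prob(model, chunk, sub,
                                        sample=config.scheme == "prob")
            for seq in res.sequences:
                sentences.append(" ".join(model.vocab.decode(seq)))
            if start and start % (batch_size * 20) == 0:
                logger.info("generated %d / %d", start, records.shape[0])
    else:
        for i in range(records.shape[0]):
            res = beam_decode(model, records[i], config)
            sentences.append(" ".join(model.vocab.decode(res.sequences[0])))
            if i and i % 1000 == 0:
                logger.info("generated %d / %d", i, records.shape[0])
    return sentences


def novelty_count(generated: list[str], training_texts: list[str]
                  ) -> tuple[int, int]:
    """(unique generated sentences, of which absent from the training text)."""
    uniq = set(generated)
    train = set(training_texts)
    return len(uniq), len(uniq - train)
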