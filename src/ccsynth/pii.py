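"""Embedding-based name discovery and the authentic-vs-synthetic PII audit.

Personal names that slip into chief complaints (referring physicians,
police officers) cluster together in a word-embedding space because they
occur in interchangeable contexts.  The audit exploits this: train skipgram
word2vec vectors on the whole complaint corpus, then iteratively expand a
seed list of known names by pulling each known name's 100 nearest
neighbors and asking an oracle (a human in interactive use, a planted-truth
membership check in tests) which neighbors are names, until the list closes.
The final report compares how many authentic versus synthetic complaints
contain any discovered name; generation with probability-seeking samplers
is expected to drive the synthetic count to zero because names are
low-frequency, hence low-probability, tokens.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .schema import tokenize

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingMatrix:
    """Dense token vectors plus the training metadata."""

    tokens: list[str]
    vectors: np.ndarray  # (V, dim)
    dimension: int
    window: int
    seed: int

    def __post_init__(self):
        self.index = {t: i for i, t in enumerate(self.tokens)}
        norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
        self._unit = self.vectors / np.maximum(norms, 1e-12)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[self.index[token]]

    def most_similar(self, token: str, k: int = 10) -> list[tuple[str, float]]:
        """k nearest neighbors by cosine similarity (query excluded)."""
        if token not in self.index:
            raise KeyError(f"token {token!r} not in embedding vocabulary")
        sims = self._unit @ self._unit[self.index[token]]
        sims[self.index[token]] = -np.inf
        order = np.argsort(-sims, kind="stable")[:k]
        return [(self.tokens[i], float(sims[i])) for i in order]

    def similarity(self, a: str, b: str) -> float:
        return float(self._unit[self.index[a]] @ self._unit[self.index[b]])

    def save_word2vec(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.tokens)} {self.dimension}\n")
            for t, v in zip(self.tokens, self.vectors):
                fh.write(t + " " + " ".join(f"{x:.6f}" for x in v) + "\n")

    @classmethod
    def load_word2vec(cls, path, window: int = 0, seed: int = 0
                      ) -> "EmbeddingMatrix":
        with open(path) as fh:
            n, dim = map(int, fh.readline().split())
            tokens, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                tokens.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        assert len(tokens) == n
        return cls(tokens=tokens, vectors=np.array(rows), dimension=dim,
                   window=window, seed=seed)


def train_word_embeddings(sentences: list[str], dimension: int = 100,
                          window: int = 5, seed: int = 0,
                          min_count: int = 5, negative: int = 5,
                          epochs: int = 3, batch_size: int = 2048,
                          lr: float = 0.025) -> EmbeddingMatrix:
    """Skipgram-with-negative-sampling word vectors, deterministic per seed.

    Single-worker NumPy implementation of word2vec's skipgram objective:
    for each (center, context) pair within ``window``, maximize
    log sigma(u_ctx . v_ctr) plus ``negative`` samples drawn from the
    unigram^0.75 distribution; SGD with a linearly decaying learning rate.
    """
    if not sentences:
        raise ValueError("corpus is empty")
    token_lists = [tokenize(s) for s in sentences]
    freq: dict[str, int] = {}
    for toks in token_lists:
        for t in toks:
            freq[t] = freq.get(t, 0) + 1
    vocab = sorted((t for t, f in freq.items() if f >= min_count),
                   key=lambda t: (-freq[t], t))
    if len(vocab) < 2:
        raise ValueError("vocabulary smaller than 2 after min_count filter")
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    centers, contexts = [], []
    for toks in token_lists:
        ids = [index[t] for t in toks if t in index]
        for i, c in enumerate(ids):
            for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    centers = np.array(centers, dtype=np.int64)
    contexts = np.array(contexts, dtype=np.int64)
    if centers.size == 0:
        raise ValueError("no skipgram pairs (sentences too short?)")

    counts = np.array([freq[t] for t in vocab], dtype=float)
    noise = counts ** 0.75
    noise /= noise.sum()

    rng = np.random.default_rng(seed)
    Win = (rng.random((V, dimension)) - 0.5) / dimension
    Wout = np.zeros((V, dimension))
    n_pairs = centers.size
    total_batches = max(1, epochs * ((n_pairs + batch_size - 1) // batch_size))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            idx = order[start:start + batch_size]
            B = idx.size
            ctr, ctx = centers[idx], contexts[idx]
            neg = rng.choice(V, size=(B, negative), p=noise)
            alpha = lr * max(1e-4 / lr, 1.0 - step / total_batches)
            v = Win[ctr]                                   # (B, D)
            u_pos = Wout[ctx]                              # (B, D)
            u_neg = Wout[neg]                              # (B, K, D)
            g_pos = _sigmoid((v * u_pos).sum(axis=1)) - 1.0        # (B,)
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", v, u_neg))    # (B, K)
            dv = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
            np.add.at(Wout, ctx, -alpha * g_pos[:, None] * v)
            np.add.at(Wout, neg.ravel(),
                      -alpha * (g_neg[:, :, None] * v[:, None, :]
                                ).reshape(-1, dimension))
            np.add.at(Win, ctr, -alpha * dv)
            step += 1
    return EmbeddingMatrix(tokens=vocab, vectors=Win, dimension=dimension,
                           window=window, seed=seed)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def discover_names(embeddings: EmbeddingMatrix, seed_names: list[str],
                   oracle, neighbors_k: int = 100,
                   max_iterations: int | None = None
                   ) -> tuple[list[str], int]:
    """Iterative nearest-neighbor name discovery.

    Starting from ``seed_names``, repeatedly take the ``neighbors_k``
    cosine nearest neighbors of every known name, label each new neighbor
    with ``oracle(token) -> bool``, and add confirmed names — until an
    iteration yields no new name.  The list only grows and is bounded by
    the vocabulary, so termination is guaranteed.  Returns the closed name
    list (sorted) and the number of iterations run.
    """
    if not seed_names:
        raise ValueError("seed_names is empty")
    for s in seed_names:
        if s not in embeddings:
            raise ValueError(f"seed name {s!r} not in embedding vocabulary")
    names = set(seed_names)
    checked: set[str] = set(seed_names)
    iterations = 0
    limit = max_iterations or len(embeddings.tokens)
    while iterations < limit:
        iterations += 1
        new: set[str] = set()
        for name in sorted(names):
            for tok, _ in embeddings.most_similar(name, k=neighbors_k):
                if tok in checked:
                    continue
                checked.add(tok)
                if oracle(tok):
                    new.add(tok)
        if not new:
            break
        names |= new
    return sorted(names), iterations


def count_name_complaints(sentences: list[str], names) -> int:
    """Number of sentences containing at least one name token."""
    names = set(names)
    if not names:
        return 0
    return sum(bool(names & set(tokenize(s))) for s in sentences)


@dataclass
class NameAudit:
    names: list[str]
    iterations: int
    authentic_count: int
    synthetic_count: int

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def pii_report(authentic: list[str], synthetic: list[str], names,
               iterations: int = 0) -> NameAudit:
    """Complaint-level name counts for parallel authentic/synthetic corpora."""
    names = sorted(set(names))
    return NameAudit(
        names=names,
        iterations=iterations,
        authentic_count=count_name_complaints(authentic, names),
        synthetic_count=count_name_complaints(synthetic, names),
    )
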