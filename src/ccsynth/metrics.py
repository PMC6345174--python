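"""Text-quality metrics for synthetic-vs-authentic complaint pairs.

Standard machine-translation metrics rate short sentences harshly, so this
suite pools variable-length n-grams instead: for each sentence, n-grams of
every order from 1 up to ``max_ngram_order`` (capped at the sentence's own
length) are collected into a single bag.  PPV (precision) is the clipped
fraction of candidate n-grams found in the reference, sensitivity (recall)
the fraction of reference n-grams found in the candidate, and F1 their
harmonic mean, averaged per pair over the corpus.  A consensus-style score
(modified CIDEr) takes the mean cosine similarity of TF-IDF vectors over
the same variable-length n-gram space, with IDF from the reference corpus.
Finally, embedding similarity — cosine similarity of averaged word vectors
— credits semantically close pairs ("od" / "overdose") even with zero
n-gram overlap.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .schema import tokenize

logger = logging.getLogger(__name__)


@dataclass
class MetricConfig:
    max_ngram_order: int = 4

    def __post_init__(self):
        if self.max_ngram_order < 1:
            raise ValueError("max_ngram_order must be at least 1")


@dataclass
class MetricReport:
    """Corpus-level scores, mirroring the columns ppv / sens / f1 / CIDEr /
    embedding similarity, with the per-pair breakdown retained."""

    ppv: float
    sens: float
    f1: float
    cider: float | None = None
    embedding_similarity: float | None = None
    per_pair: dict[str, list[float]] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "ppv": self.ppv, "sens": self.sens, "f1": self.f1,
            "cider": self.cider,
            "embedding_similarity": self.embedding_similarity,
        }


def _as_tokens(sentence) -> list[str]:
    return tokenize(sentence) if isinstance(sentence, str) else list(sentence)


def ngram_bag(tokens: list[str], max_order: int) -> Counter:
    """All n-grams of orders 1..min(max_order, len(tokens)), one pooled bag."""
    bag: Counter = Counter()
    for n in range(1, min(max_order, len(tokens)) + 1):
        for i in range(len(tokens) - n + 1):
            bag[tuple(tokens[i:i + n])] += 1
    return bag


def ngram_scores(reference, candidate, config: MetricConfig | None = None
                 ) -> tuple[float, float, float]:
    """Pooled variable-length n-gram (ppv, sensitivity, f1) for one pair.

    Candidate n-grams are counted with clipping (credited at most their
    reference multiplicity).  An empty candidate scores (0, 0, 0).
    """
    config = config or MetricConfig()
    ref = _as_tokens(reference)
    cand = _as_tokens(candidate)
    ref_bag = ngram_bag(ref, config.max_ngram_order)
    cand_bag = ngram_bag(cand, config.max_ngram_order)
    matched = sum((ref_bag & cand_bag).values())
    n_cand = sum(cand_bag.values())
    n_ref = sum(ref_bag.values())
    if n_cand == 0:
        logger.debug("empty candidate; ppv undefined, returned as 0")
    ppv = matched / n_cand if n_cand else 0.0
    sens = matched / n_ref if n_ref else 0.0
    f1 = 0.0 if ppv + sens == 0 else 2 * ppv * sens / (ppv + sens)
    return ppv, sens, f1


def corpus_ngram_scores(pairs, config: MetricConfig | None = None
                        ) -> MetricReport:
    """Unweighted mean of per-pair n-gram scores over (reference, candidate)
    pairs."""
    config = config or MetricConfig()
    if not pairs:
        raise ValueError("empty pair list")
    ppvs, senss, f1s = [], [], []
    for ref, cand in pairs:
        p, s, f = ngram_scores(ref, cand, config)
        ppvs.append(p)
        senss.append(s)
        f1s.append(f)
    return MetricReport(
        ppv=float(np.mean(ppvs)), sens=float(np.mean(senss)),
        f1=float(np.mean(f1s)),
        per_pair={"ppv": ppvs, "sens": senss, "f1": f1s},
    )


def cider_score(pairs, config: MetricConfig | None = None) -> float:
    """Mean TF-IDF cosine similarity over variable-length n-grams.

    IDF is computed from the reference corpus as ln(N / df) with df clamped
    to at least 1.  A pair whose TF-IDF vectors have zero norm (or zero
    overlap) contributes 0, logged.
    """
    config = config or MetricConfig()
    if len(pairs) < 2:
        raise ValueError("CIDEr needs at least 2 pairs to define IDF")
    refs = [_as_tokens(r) for r, _ in pairs]
    cands = [_as_tokens(c) for _, c in pairs]
    N = len(pairs)
    df: Counter = Counter()
    for r in refs:
        df.update(set(ngram_bag(r, config.max_ngram_order)))

    def idf(g) -> float:
        return float(np.log(N / max(df[g], 1)))

    sims = []
    n_zero = 0
    for r, c in zip(refs, cands):
        rbag = ngram_bag(r, config.max_ngram_order)
        cbag = ngram_bag(c, config.max_ngram_order)
        rv = {g: tf * idf(g) for g, tf in rbag.items()}
        cv = {g: tf * idf(g) for g, tf in cbag.items()}
        rnorm = np.sqrt(sum(v * v for v in rv.values()))
        cnorm = np.sqrt(sum(v * v for v in cv.values()))
        if rnorm == 0 or cnorm == 0:
            sims.append(0.0)
            n_zero += 1
            continue
        dot = sum(rv[g] * cv.get(g, 0.0) for g in rv)
        sims.append(dot / (rnorm * cnorm))
    if n_zero:
        logger.info("cider: %d pairs with zero-norm TF-IDF vectors scored 0",
                    n_zero)
    return float(np.mean(sims))


def embedding_similarity(reference, candidate, embeddings) -> float:
    """Cosine similarity of the two sentences' mean word vectors.

    ``embeddings`` maps token -> vector (any mapping, or an
    :class:`~ccsynth.pii.EmbeddingMatrix`).  Raises if every token of
    either sentence is out of the embedding vocabulary.
    """
    def mean_vec(tokens, which):
        vecs = [embeddings[t] for t in tokens if t in embeddings]
        if not vecs:
            raise ValueError(f"all tokens of the {which} sentence are out of "
                             f"the embedding vocabulary: {tokens}")
        return np.mean(vecs, axis=0)

    r = mean_vec(_as_tokens(reference), "reference")
    c = mean_vec(_as_tokens(candidate), "candidate")
    denom = np.linalg.norm(r) * np.linalg.norm(c)
    if denom == 0:
        return 0.0
    return float(np.dot(r, c) / denom)


def corpus_report(pairs, config: MetricConfig | None = None,
                  embeddings=None) -> MetricReport:
    """Full corpus report: n-gram scores, CIDEr, and (when embeddings are
    supplied) mean embedding similarity."""
    config = config or MetricConfig()
    report = corpus_ngram_scores(pairs, config)
    report.cider = cider_score(pairs, config) if len(pairs) >= 2 else None
    if embeddings is not None:
        sims = []
        for ref, cand in pairs:
            try:
                sims.append(embedding_similarity(ref, cand, embeddings))
            except ValueError:
                continue
        report.embedding_similarity = float(np.mean(sims)) if sims else None
        report.per_pair["embedding_similarity"] = sims
    return report
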