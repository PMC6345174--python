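"""Epidemiological-validity checks for synthetic complaint corpora.

Two complementary views: (1) word-variable epidemiology — 2x2 contingency
tables of "complaint contains word" against a stratifying variable, with
risk and odds ratios, to check that demographic-word associations (falls
and old age, pregnancy and gender) survive into the synthetic text; and
(2) a diagnosis classifier — a word-embedding + single-layer GRU + softmax
model predicting the (primary) diagnosis code from complaint text, scored
with support-weighted macro sensitivity / PPV / F1.  Training the
classifier on authentic text and scoring it on synthetic text measures how
much diagnostic signal generation preserves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .decoding import SamplingConfig, generate_corpus
from .schema import PAD_INDEX, PairedCorpus, devectorize_record, tokenize

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# word-variable contingency tables and ratios
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """Counts of records whose complaint contains the word, by stratum."""

    exposed_with: int
    exposed_total: int
    unexposed_with: int
    unexposed_total: int

    def __post_init__(self):
        if (self.exposed_with > self.exposed_total
                or self.unexposed_with > self.unexposed_total):
            raise ValueError("cell count exceeds stratum total")


@dataclass
class RatioResult:
    risk_ratio: float
    odds_ratio: float
    risk_infinite: bool = False
    odds_infinite: bool = False


def _iter_values_text(corpus):
    if isinstance(corpus, PairedCorpus):
        for i in range(len(corpus)):
            yield (devectorize_record(corpus.record_bits[i], corpus.schema),
                   corpus.raw_texts[i])
    else:  # list of RawRecord
        for rec in corpus:
            yield rec.values, rec.complaint_text


def word_variable_table(corpus, word: str, variable: str,
                        stratum_a, stratum_b, schema=None) -> ContingencyTable:
    """2x2 table of word presence for two strata of a variable.

    ``stratum_a`` / ``stratum_b`` are codes or collections of codes; a
    record counts once regardless of how often the word occurs in its
    complaint.  ``corpus`` is a :class:`PairedCorpus` or a list of
    ``RawRecord``.
    """
    schema = schema or getattr(corpus, "schema", None)
    if schema is not None:
        var = schema.variable(variable)  # raises on unknown variable
        for s in (stratum_a, stratum_b):
            codes = [s] if np.isscalar(s) else list(s)
            for c in codes:
                if not 0 <= c < var.cardinality:
                    raise ValueError(f"stratum code {c} out of range for "
                                     f"{variable!r}")
    set_a = {stratum_a} if np.isscalar(stratum_a) else set(stratum_a)
    set_b = {stratum_b} if np.isscalar(stratum_b) else set(stratum_b)
    word = word.lower()
    aw = at = bw = bt = 0
    for values, text in _iter_values_text(corpus):
        codes = values.get(variable, [])
        has = word in tokenize(text)
        if any(c in set_a for c in codes):
            at += 1
            aw += has
        elif any(c in set_b for c in codes):
            bt += 1
            bw += has
    return ContingencyTable(aw, at, bw, bt)


def ratios(table: ContingencyTable, haldane: bool = False) -> RatioResult:
    """Risk and odds ratios from a 2x2 table.

    ``risk_ratio = (a/t_a) / (b/t_b)``; ``odds_ratio = (a/(t_a-a)) /
    (b/(t_b-b))``.  Zero denominators yield infinity with a flag.  With
    ``haldane`` a 0.5 continuity correction is added to every cell first.
    """
    a, ta = table.exposed_with, table.exposed_total
    b, tb = table.unexposed_with, table.unexposed_total
    if ta == 0 or tb == 0:
        raise ValueError("both stratum totals must be positive")
    if haldane:
        a, b = a + 0.5, b + 0.5
        ta, tb = ta + 1.0, tb + 1.0
    rr_inf = b == 0
    rr = float("inf") if rr_inf else (a / ta) / (b / tb)
    odds_denom = b * (ta - a)
    or_inf = odds_denom == 0
    orr = float("inf") if or_inf else (a * (tb - b)) / odds_denom
    return RatioResult(risk_ratio=rr, odds_ratio=orr,
                       risk_infinite=bool(rr_inf), odds_infinite=bool(or_inf))


# ---------------------------------------------------------------------------
# GRU diagnosis classifier
# ---------------------------------------------------------------------------

@dataclass
class ClassifierConfig:
    vocab_size: int
    n_classes: int
    hidden_dim: int = 32
    embed_dim: int = 16
    learning_rate: float = 0.001
    batch_size: int = 256
    patience: int = 2
    max_epochs: int = 20
    seed: int = 0


@dataclass
class ClassifierReport:
    sens: float
    ppv: float
    f1: float
    per_class: dict[int, dict[str, float]] = field(default_factory=dict,
                                                   repr=False)

    def to_dict(self) -> dict:
        return {"sens": self.sens, "ppv": self.ppv, "f1": self.f1}


class CCClassifier:
    """Embedding + single GRU layer + softmax over diagnosis codes."""

    def __init__(self, config: ClassifierConfig, vocab, classes: list[int]):
        self.config = config
        self.vocab = vocab
        self.classes = list(classes)  # class position -> diagnosis code
        self.class_index = {c: i for i, c in enumerate(self.classes)}
        rng = np.random.default_rng(config.seed)
        H, D, V, C = (config.hidden_dim, config.embed_dim,
                      config.vocab_size, len(self.classes))
        self.weights = {
            "E": rng.normal(0.0, 0.05, size=(V, D)),
            "Wx": _nn.glorot(rng, D, H, (D, 3 * H)),
            "Wh": _nn.glorot(rng, H, H, (H, 3 * H)),
            "b": np.zeros(3 * H),
            "Wo": _nn.glorot(rng, H, C),
            "bo": np.zeros(C),
        }
        self.weights["E"][PAD_INDEX] = 0.0

    def _forward(self, X_ids: np.ndarray):
        w = self.weights
        B, T = X_ids.shape
        X = w["E"][X_ids]
        h0 = np.zeros((B, self.config.hidden_dim))
        Hs, cache = _nn.gru_forward(X, h0, w["Wx"], w["Wh"], w["b"])
        last = np.maximum((X_ids != PAD_INDEX).sum(axis=1) - 1, 0)
        h_last = Hs[np.arange(B), last]
        logits = h_last @ w["Wo"] + w["bo"]
        return logits, (X, Hs, cache, last, h_last)

    def loss_and_grads(self, X_ids: np.ndarray, y: np.ndarray):
        w = self.weights
        logits, (X, Hs, cache, last, h_last) = self._forward(X_ids)
        B = X_ids.shape[0]
        p = _nn.softmax(logits, axis=-1)
        loss = -float(np.mean(np.log(np.maximum(p[np.arange(B), y], 1e-300))))
        dlogits = p
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        dWo = h_last.T @ dlogits
        dbo = dlogits.sum(axis=0)
        dHs = np.zeros_like(Hs)
        dHs[np.arange(B), last] = dlogits @ w["Wo"].T
        dX, _, dWx, dWh, db = _nn.gru_backward(dHs, cache, w["Wx"], w["Wh"])
        dE = np.zeros_like(w["E"])
        np.add.at(dE, X_ids, dX)
        dE[PAD_INDEX] = 0.0
        return loss, {"E": dE, "Wx": dWx, "Wh": dWh, "b": db,
                      "Wo": dWo, "bo": dbo}

    def loss(self, X_ids: np.ndarray, y: np.ndarray) -> float:
        logits, _ = self._forward(X_ids)
        p = _nn.softmax(logits, axis=-1)
        return -float(np.mean(np.log(
            np.maximum(p[np.arange(len(y)), y], 1e-300))))

    def encode_sentences(self, sentences: list[str], padded_len: int
                         ) -> np.ndarray:
        """Tokenize sentences under the classifier vocabulary (unknown
        tokens are skipped with a log message) and pad; the end-of-sequence
        token terminates every sequence so empty sentences stay encodable."""
        X = np.zeros((len(sentences), padded_len), dtype=np.int32)
        n_oov = 0
        for i, s in enumerate(sentences):
            ids = []
            for t in tokenize(s):
                if t in self.vocab.index:
                    ids.append(self.vocab.index[t])
                else:
                    n_oov += 1
            ids = ids[: padded_len - 1] + [self.vocab.eos_id]
            X[i, : len(ids)] = ids
        if n_oov:
            logger.info("classifier: skipped %d out-of-vocabulary tokens", n_oov)
        return X

    def predict(self, sentences_or_ids, padded_len: int = 20,
                batch_size: int = 1024) -> np.ndarray:
        """Predicted diagnosis codes for sentences (or pre-encoded ids)."""
        if isinstance(sentences_or_ids, np.ndarray):
            X = sentences_or_ids
        else:
            X = self.encode_sentences(list(sentences_or_ids), padded_len)
        preds = []
        for start in range(0, X.shape[0], batch_size):
            logits, _ = self._forward(X[start:start + batch_size])
            preds.append(logits.argmax(axis=1))
        return np.array([self.classes[i] for i in np.concatenate(preds)])


def primary_diagnosis(corpus: PairedCorpus) -> np.ndarray:
    """First (lowest-coded) diagnosis code per record; raises if any record
    has none."""
    off = corpus.schema.offset("diagnosis")
    card = corpus.schema.variable("diagnosis").cardinality
    block = corpus.record_bits[:, off: off + card]
    if (block.sum(axis=1) == 0).any():
        raise ValueError("every record needs at least one diagnosis code")
    return block.argmax(axis=1)


def _classifier_inputs(corpus: PairedCorpus) -> np.ndarray:
    # drop the start token; sequences become content + EOS + padding
    return corpus.sequences[:, 1:]


def train_cc_classifier(train_corpus: PairedCorpus, val_corpus: PairedCorpus,
                        config: ClassifierConfig | None = None,
                        ) -> tuple[CCClassifier, list[float]]:
    """Train the GRU diagnosis classifier with Adam and early stopping.

    Labels are each record's first listed diagnosis code (treated as
    primary).  Stops when validation loss fails to decrease for
    ``patience`` consecutive epochs; best-epoch weights are restored.
    Deterministic under a fixed seed.
    """
    y_train_codes = primary_diagnosis(train_corpus)
    y_val_codes = primary_diagnosis(val_corpus)
    classes = sorted(set(int(c) for c in y_train_codes))
    if len(classes) < 2:
        raise ValueError("classifier needs at least 2 diagnosis classes")
    if config is None:
        config = ClassifierConfig(vocab_size=len(train_corpus.vocab),
                                  n_classes=len(classes))
    clf = CCClassifier(config, train_corpus.vocab, classes)
    y_train = np.array([clf.class_index[int(c)] for c in y_train_codes])
    y_val = np.array([clf.class_index.get(int(c), -1) for c in y_val_codes])
    keep = y_val >= 0
    X_train = _classifier_inputs(train_corpus)
    X_val = _classifier_inputs(val_corpus)[keep]
    y_val = y_val[keep]

    opt = _nn.Adam(lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    bs = min(config.batch_size, len(y_train))
    best_loss, best_weights, bad = np.inf, None, 0
    val_losses: list[float] = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(y_train))
        for start in range(0, len(y_train), bs):
            idx = order[start:start + bs]
            _, grads = clf.loss_and_grads(X_train[idx], y_train[idx])
            opt.step(clf.weights, grads)
            clf.weights["E"][PAD_INDEX] = 0.0
        vl = float(np.mean([
            clf.loss(X_val[s:s + 1024], y_val[s:s + 1024])
            for s in range(0, len(y_val), 1024)]))
        val_losses.append(vl)
        logger.info("classifier epoch %d: val loss %.4f", epoch, vl)
        if vl < best_loss:
            best_loss, bad = vl, 0
            best_weights = {k: v.copy() for k, v in clf.weights.items()}
        else:
            bad += 1
            if bad >= config.patience:
                break
    if best_weights is not None:
        clf.weights = best_weights
    return clf, val_losses


def score_classifier(classifier: CCClassifier | None, sentences,
                     true_codes, predictions: np.ndarray | None = None
                     ) -> ClassifierReport:
    """Support-weighted macro sensitivity / PPV / F1 from the multiclass
    confusion matrix.

    Per-class one-vs-rest metrics are averaged with weights proportional to
    each class's true support; classes absent from the truth get zero
    weight, and an unpredicted class has PPV 0 (logged).
    """
    true_codes = np.asarray(true_codes)
    if predictions is None:
        predictions = classifier.predict(sentences)
    predictions = np.asarray(predictions)
    if len(predictions) != len(true_codes):
        raise ValueError(f"length mismatch: {len(predictions)} predictions "
                         f"vs {len(true_codes)} labels")
    total = len(true_codes)
    per_class: dict[int, dict[str, float]] = {}
    w_sens = w_ppv = w_f1 = 0.0
    for c in sorted(set(true_codes.tolist())):
        support = int((true_codes == c).sum())
        tp = int(((predictions == c) & (true_codes == c)).sum())
        fp = int(((predictions == c) & (true_codes != c)).sum())
        fn = support - tp
        sens = tp / support
        if tp + fp == 0:
            logger.debug("class %s never predicted; ppv set to 0", c)
            ppv = 0.0
        else:
            ppv = tp / (tp + fp)
        f1 = 0.0 if sens + ppv == 0 else 2 * sens * ppv / (sens + ppv)
        per_class[int(c)] = {"sens": sens, "ppv": ppv, "f1": f1,
                             "support": support}
        w = support / total
        w_sens += w * sens
        w_ppv += w * ppv
        w_f1 += w * f1
    return ClassifierReport(sens=w_sens, ppv=w_ppv, f1=w_f1,
                            per_class=per_class)


def validity_comparison(model, classifier: CCClassifier,
                        test_corpus: PairedCorpus,
                        sampling_configs: dict[str, SamplingConfig],
                        ) -> dict[str, ClassifierReport]:
    """Classifier scores on authentic test text ("original") and on each
    sampling scheme's synthetic text generated from the same records."""
    true_codes = primary_diagnosis(test_corpus)
    reports = {"original": score_classifier(
        classifier, test_corpus.raw_texts, true_codes)}
    for name, cfg in sampling_configs.items():
        sentences = generate_corpus(model, test_corpus.record_bits, cfg)
        reports[name] = score_classifier(classifier, sentences, true_codes)
    return reports
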