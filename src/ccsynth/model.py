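"""Record-conditioned chief-complaint language model.

A single feedforward layer compresses the sparse binary visit vector to the
dimensionality of the recurrent cell (this layer is the encoder, and is
pretrained as the encoder half of an autoencoder); a word-embedding matrix
feeds a single-layer LSTM decoder whose hidden and cell states are both
initialized from the encoded record; a dense layer plus softmax over the
vocabulary produces next-word probabilities.  Training minimizes per-token
cross-entropy under teacher forcing with Adam, stopping when the validation
loss fails to decrease for ``patience`` consecutive epochs and restoring the
best-epoch weights.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np

from . import _nn
from .schema import MAX_WORDS, PAD_INDEX, PairedCorpus, RecordSchema, Vocabulary

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    record_dim: int
    vocab_size: int
    hidden_dim: int = 32
    word_embed_dim: int = 16
    learning_rate: float = 0.001
    batch_size: int = 512
    patience: int = 2
    max_epochs: int = 30
    pretrain_epochs: int = 15
    seed: int = 0

    def __post_init__(self):
        for name in ("record_dim", "vocab_size", "hidden_dim", "word_embed_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainingLog:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = 0   # 1-based
    stopped_epoch: int = 0

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,train_loss,val_loss\n")
            for e, (tr, va) in enumerate(zip(self.train_losses, self.val_losses), 1):
                fh.write(f"{e},{tr:.6f},{va:.6f}\n")


def early_stop_state(val_losses: list[float], patience: int) -> tuple[int, int]:
    """Apply the early-stopping rule to a loss history.

    Returns ``(best_epoch, stopped_epoch)`` (1-based).  Training stops once
    the validation loss has failed to be strictly lower than the best seen
    for ``patience`` consecutive epochs; ``stopped_epoch`` is the last epoch
    that ran (``len(val_losses)`` if the rule never fired).
    """
    best = np.inf
    best_epoch = 0
    bad = 0
    for e, loss in enumerate(val_losses, 1):
        if loss < best:
            best, best_epoch, bad = loss, e, 0
        else:
            bad += 1
            if bad >= patience:
                return best_epoch, e
    return best_epoch, len(val_losses)


class ModelParams:
    """Weight container implementing the incremental decoding protocol.

    Weights: ``W_enc``/``b_enc`` (record encoder), ``E`` (word embeddings,
    row 0 frozen to zero for padding), ``Wx``/``Wh``/``b`` (LSTM), and
    ``Wy``/``by`` (output projection).  The padding column of the output
    softmax is masked so index 0 receives no probability mass.
    """

    def __init__(self, config: ModelConfig, schema: RecordSchema,
                 vocab: Vocabulary, weights: dict[str, np.ndarray]):
        self.config = config
        self.schema = schema
        self.vocab = vocab
        self.weights = weights

    @classmethod
    def initialize(cls, config: ModelConfig, schema: RecordSchema,
                   vocab: Vocabulary,
                   encoder_weights: tuple[np.ndarray, np.ndarray] | None = None,
                   ) -> "ModelParams":
        rng = np.random.default_rng(config.seed)
        R, H, D, V = (config.record_dim, config.hidden_dim,
                      config.word_embed_dim, config.vocab_size)
        w = {
            "W_enc": _nn.glorot(rng, R, H),
            "b_enc": np.zeros(H),
            "E": rng.normal(0.0, 0.05, size=(V, D)),
            "Wx": _nn.glorot(rng, D, H, (D, 4 * H)),
            "Wh": _nn.glorot(rng, H, H, (H, 4 * H)),
            "b": np.zeros(4 * H),
            "Wy": _nn.glorot(rng, H, V),
            "by": np.zeros(V),
        }
        w["b"][H:2 * H] = 1.0  # forget-gate bias
        w["E"][PAD_INDEX] = 0.0
        if encoder_weights is not None:
            w["W_enc"], w["b_enc"] = (a.copy() for a in encoder_weights)
        return cls(config, schema, vocab, w)

    @property
    def sos_id(self) -> int:
        return self.vocab.sos_id

    @property
    def eos_id(self) -> int:
        return self.vocab.eos_id

    @property
    def vocab_size(self) -> int:
        return self.config.vocab_size

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.weights.items()}

    # -- incremental decoding protocol (batched; a single record is B=1) ----

    def encode_records(self, records: np.ndarray) -> np.ndarray:
        records = np.atleast_2d(np.asarray(records, dtype=float))
        return np.tanh(records @ self.weights["W_enc"] + self.weights["b_enc"])

    def start_state(self, records: np.ndarray):
        """Initial (h, c): both copies of the encoded record."""
        h0 = self.encode_records(records)
        return h0, h0.copy()

    def step(self, state, token_ids: np.ndarray):
        """Advance one step on token_ids (B,); returns (probs (B, V), state)."""
        h, c = state
        x = self.weights["E"][np.atleast_1d(token_ids)]
        h, c = _nn.lstm_step(x, h, c, self.weights["Wx"], self.weights["Wh"],
                             self.weights["b"])
        logits = h @ self.weights["Wy"] + self.weights["by"]
        logits[:, PAD_INDEX] = _nn.NEG_INF
        return _nn.softmax(logits, axis=-1), (h, c)

    # -- training-time teacher-forced pass ---------------------------------

    def _forward(self, records: np.ndarray, dec_inputs: np.ndarray):
        w = self.weights
        h0 = self.encode_records(records)
        X = w["E"][dec_inputs]
        Hs, cache = _nn.lstm_forward(X, h0, h0.copy(), w["Wx"], w["Wh"], w["b"])
        logits = Hs @ w["Wy"] + w["by"]
        logits[..., PAD_INDEX] = _nn.NEG_INF
        return logits, (h0, X, Hs, cache)

    def loss(self, records: np.ndarray, dec_inputs: np.ndarray,
             targets: np.ndarray) -> float:
        logits, _ = self._forward(records, dec_inputs)
        loss, _ = _nn.masked_ce_loss_and_dlogits(logits, targets)
        return float(loss)

    def loss_and_grads(self, records: np.ndarray, dec_inputs: np.ndarray,
                       targets: np.ndarray):
        w = self.weights
        records = np.asarray(records, dtype=float)
        logits, (h0, X, Hs, cache) = self._forward(records, dec_inputs)
        loss, dlogits = _nn.masked_ce_loss_and_dlogits(logits, targets)
        B, T, H = Hs.shape
        dWy = Hs.reshape(-1, H).T @ dlogits.reshape(-1, self.config.vocab_size)
        dby = dlogits.sum(axis=(0, 1))
        dHs = dlogits @ w["Wy"].T
        dX, dh0, dc0, dWx, dWh, db = _nn.lstm_backward(dHs, cache, w["Wx"], w["Wh"])
        dE = np.zeros_like(w["E"])
        np.add.at(dE, dec_inputs, dX)
        dE[PAD_INDEX] = 0.0
        dr = (dh0 + dc0) * (1 - h0 * h0)
        grads = {
            "W_enc": records.T @ dr,
            "b_enc": dr.sum(axis=0),
            "E": dE,
            "Wx": dWx, "Wh": dWh, "b": db,
            "Wy": dWy, "by": dby,
        }
        return float(loss), grads

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Write weights + config + schema + vocabulary to one HDF5 file."""
        with h5py.File(path, "w") as f:
            for k, v in self.weights.items():
                f.create_dataset(f"weights/{k}", data=v)
            f.attrs["config"] = json.dumps(asdict(self.config))
            f.attrs["schema"] = json.dumps(self.schema.to_dict())
            f.attrs["vocab_tokens"] = json.dumps(self.vocab.tokens)
            f.attrs["vocab_freqs"] = json.dumps(self.vocab.frequencies)

    @classmethod
    def load(cls, path) -> "ModelParams":
        with h5py.File(path, "r") as f:
            weights = {k: f[f"weights/{k}"][()] for k in f["weights"]}
            config = ModelConfig(**json.loads(f.attrs["config"]))
            schema = RecordSchema.from_dict(json.loads(f.attrs["schema"]))
            vocab = Vocabulary(tokens=json.loads(f.attrs["vocab_tokens"]),
                               frequencies=json.loads(f.attrs["vocab_freqs"]))
        return cls(config, schema, vocab, weights)


def step_probabilities(params: ModelParams, record: np.ndarray,
                       prefix) -> np.ndarray:
    """Next-word probability vector after consuming ``prefix``.

    ``prefix`` must begin with the start-of-sequence token; the padding
    index receives (effectively) zero mass via logit masking.
    """
    prefix = list(prefix)
    if not prefix or prefix[0] != params.sos_id:
        raise ValueError("prefix must begin with the start-of-sequence token")
    if len(prefix) > MAX_WORDS + 1:
        raise ValueError(f"prefix longer than maximum length {MAX_WORDS + 1}")
    state = params.start_state(np.atleast_2d(record))
    for tok in prefix:
        probs, state = params.step(state, np.array([tok]))
    return probs[0]


def pretrain_record_encoder(records: np.ndarray, config: ModelConfig
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Autoencoder pretraining of the record-embedding layer.

    Trains record -> tanh(hidden) -> sigmoid(reconstruction) with
    elementwise binary cross-entropy and Adam, then returns the encoder-half
    weights ``(W_enc, b_enc)``.
    """
    records = np.asarray(records, dtype=float)
    if records.ndim != 2 or records.shape[0] == 0:
        raise ValueError("records must be a nonempty (n, record_dim) array")
    R, H = config.record_dim, config.hidden_dim
    if H >= R:
        logger.warning("hidden_dim %d >= record_dim %d: autoencoder does not "
                       "compress", H, R)
    rng = np.random.default_rng(config.seed)
    w = {
        "W1": _nn.glorot(rng, R, H), "b1": np.zeros(H),
        "W2": _nn.glorot(rng, H, R), "b2": np.zeros(R),
    }
    opt = _nn.Adam(lr=config.learning_rate)
    n = records.shape[0]
    bs = min(config.batch_size, n)
    for _ in range(config.pretrain_epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            Rb = records[order[start:start + bs]]
            hid = np.tanh(Rb @ w["W1"] + w["b1"])
            logits = hid @ w["W2"] + w["b2"]
            p = _nn.sigmoid(logits)
            dlogits = (p - Rb) / Rb.shape[0]
            dW2 = hid.T @ dlogits
            db2 = dlogits.sum(axis=0)
            dhid = dlogits @ w["W2"].T * (1 - hid * hid)
            grads = {"W1": Rb.T @ dhid, "b1": dhid.sum(axis=0),
                     "W2": dW2, "b2": db2}
            opt.step(w, grads)
    return w["W1"], w["b1"]


def autoencoder_reconstruction(records: np.ndarray, config: ModelConfig
                               ) -> np.ndarray:
    """Train the autoencoder as in :func:`pretrain_record_encoder` and return
    the reconstruction probabilities for ``records`` (test/inspection aid)."""
    records = np.asarray(records, dtype=float)
    R, H = config.record_dim, config.hidden_dim
    rng = np.random.default_rng(config.seed)
    w = {
        "W1": _nn.glorot(rng, R, H), "b1": np.zeros(H),
        "W2": _nn.glorot(rng, H, R), "b2": np.zeros(R),
    }
    opt = _nn.Adam(lr=config.learning_rate)
    n = records.shape[0]
    bs = min(config.batch_size, n)
    for _ in range(config.pretrain_epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            Rb = records[order[start:start + bs]]
            hid = np.tanh(Rb @ w["W1"] + w["b1"])
            p = _nn.sigmoid(hid @ w["W2"] + w["b2"])
            dlogits = (p - Rb) / Rb.shape[0]
            dhid = dlogits @ w["W2"].T * (1 - hid * hid)
            opt.step(w, {"W1": Rb.T @ dhid, "b1": dhid.sum(axis=0),
                         "W2": hid.T @ dlogits, "b2": dlogits.sum(axis=0)})
    hid = np.tanh(records @ w["W1"] + w["b1"])
    return _nn.sigmoid(hid @ w["W2"] + w["b2"])


def train(train_corpus: PairedCorpus, val_corpus: PairedCorpus,
          config: ModelConfig, pretrain: bool = True
          ) -> tuple[ModelParams, TrainingLog]:
    """Train the encoder-decoder on a train/validation corpus split.

    Teacher-forced next-word cross-entropy, Adam at ``learning_rate``,
    mini-batches of ``batch_size`` pairs; the record encoder is first
    pretrained as an autoencoder.  Stops when validation loss fails to
    decrease for ``patience`` consecutive epochs (or at ``max_epochs``) and
    returns the best-epoch weights.  Deterministic given ``config.seed``.
    """
    if len(train_corpus) == 0 or len(val_corpus) == 0:
        raise ValueError("train and validation corpora must be nonempty")
    if config.batch_size > len(train_corpus):
        logger.warning("batch_size %d > corpus size %d; clamping",
                       config.batch_size, len(train_corpus))
    bs = min(config.batch_size, len(train_corpus))

    enc = None
    if pretrain:
        enc = pretrain_record_encoder(train_corpus.record_bits, config)
    params = ModelParams.initialize(config, train_corpus.schema,
                                    train_corpus.vocab, encoder_weights=enc)
    opt = _nn.Adam(lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    R_all = train_corpus.record_bits.astype(float)
    X_all = train_corpus.decoder_inputs
    Y_all = train_corpus.targets
    log = TrainingLog()
    best_loss = np.inf
    best_weights = params.copy_weights()
    bad = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_corpus))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(train_corpus), bs):
            idx = order[start:start + bs]
            loss, grads = params.loss_and_grads(R_all[idx], X_all[idx], Y_all[idx])
            opt.step(params.weights, grads)
            params.weights["E"][PAD_INDEX] = 0.0
            epoch_loss += loss
            n_batches += 1
        val_loss = evaluate_loss(params, val_corpus)
        log.train_losses.append(epoch_loss / n_batches)
        log.val_losses.append(val_loss)
        logger.info("epoch %d: train %.4f val %.4f", epoch,
                    log.train_losses[-1], val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = params.copy_weights()
            bad = 0
        else:
            bad += 1
            if bad >= config.patience:
                break
    log.best_epoch, log.stopped_epoch = early_stop_state(
        log.val_losses, config.patience)
    params.weights = best_weights
    return params, log


def evaluate_loss(params: ModelParams, corpus: PairedCorpus,
                  batch_size: int = 1024) -> float:
    """Teacher-forced mean per-token cross-entropy on a corpus."""
    total, n_tokens = 0.0, 0
    for start in range(0, len(corpus), batch_size):
        sl = slice(start, start + batch_size)
        R = corpus.record_bits[sl].astype(float)
        X = corpus.decoder_inputs[sl]
        Y = corpus.targets[sl]
        loss = params.loss(R, X, Y)
        k = int((Y != PAD_INDEX).sum())
        total += loss * k
        n_tokens += k
    return total / n_tokens
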