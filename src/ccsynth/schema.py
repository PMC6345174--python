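"""Discrete-variable schema, record vectorization, and chief-complaint text
preprocessing.

An emergency-department visit is described by a handful of discrete
variables (age group, gender, mode of arrival, diagnosis codes, ...) plus a
short free-text chief complaint.  This module defines the variable schema,
turns a record's integer codes into a sparse binary vector (one-hot per
single-valued variable, multi-hot for diagnosis, all-zero for missing), and
preprocesses the complaint text: lowercasing, whitespace tokenization, a
minimum-token-frequency filter, a maximum-length filter, special
start/end-of-sequence tokens, integer encoding and zero padding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

PAD_INDEX = 0
SOS_TOKEN = "<s>"
EOS_TOKEN = "</s>"

#: default minimum corpus frequency for a token to enter the vocabulary
MIN_TOKEN_FREQ = 10
#: default maximum chief-complaint length in content words
MAX_WORDS = 18


# ---------------------------------------------------------------------------
# schema and records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variable:
    """One discrete visit variable.

    ``cardinality`` is the number of coded values; codes run from 0 to
    ``cardinality - 1``.  ``multi_valued`` marks variables (discharge
    diagnosis) that may carry more than one code per visit.
    """

    name: str
    cardinality: int
    multi_valued: bool = False
    missing_allowed: bool = True


@dataclass(frozen=True)
class RecordSchema:
    """Ordered collection of variables defining the sparse record layout.

    The binary record vector is the concatenation of one block per variable,
    in order; ``total_dim`` is the sum of cardinalities.
    """

    variables: tuple[Variable, ...]

    @property
    def total_dim(self) -> int:
        return sum(v.cardinality for v in self.variables)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def offset(self, name: str) -> int:
        """Start index of ``name``'s block in the record vector."""
        off = 0
        for v in self.variables:
            if v.name == name:
                return off
            off += v.cardinality
        raise KeyError(f"unknown variable {name!r}")

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(f"unknown variable {name!r}")

    def to_dict(self) -> dict:
        return {
            "variables": [
                {
                    "name": v.name,
                    "cardinality": v.cardinality,
                    "multi_valued": v.multi_valued,
                    "missing_allowed": v.missing_allowed,
                }
                for v in self.variables
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RecordSchema":
        return cls(tuple(Variable(**v) for v in d["variables"]))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RecordSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_schema(spec) -> RecordSchema:
    """Build a :class:`RecordSchema` from an ordered variable description.

    ``spec`` is a sequence of ``Variable`` objects, dicts, or
    ``(name, cardinality[, multi_valued[, missing_allowed]])`` tuples.
    Ordering is preserved exactly as given.
    """
    if not spec:
        raise ValueError("schema spec is empty")
    variables = []
    for item in spec:
        if isinstance(item, Variable):
            v = item
        elif isinstance(item, dict):
            v = Variable(**item)
        else:
            v = Variable(*item)
        if v.cardinality < 1:
            raise ValueError(f"variable {v.name!r} has non-positive cardinality")
        variables.append(v)
    names = [v.name for v in variables]
    if len(set(names)) != len(names):
        raise ValueError("duplicate variable names in schema spec")
    return RecordSchema(tuple(variables))


@dataclass
class RawRecord:
    """One visit: variable name -> list of integer codes, plus raw text."""

    values: dict[str, list[int]]
    complaint_text: str


def vectorize_record(record: RawRecord, schema: RecordSchema) -> np.ndarray:
    """Encode a record as the concatenated sparse binary vector.

    One-hot per observed single-valued variable; multi-hot for multi-valued
    variables; missing variables are coded as all-zero blocks.
    """
    bits = np.zeros(schema.total_dim, dtype=np.uint8)
    for name in record.values:
        if name not in schema.names:
            raise KeyError(f"unknown variable {name!r}")
    off = 0
    for v in schema.variables:
        codes = record.values.get(v.name, [])
        if not v.multi_valued and len(codes) > 1:
            raise ValueError(
                f"variable {v.name!r} is single-valued but got codes {codes}"
            )
        for c in codes:
            if not 0 <= c < v.cardinality:
                raise ValueError(
                    f"code {c} out of range [0, {v.cardinality - 1}] "
                    f"for variable {v.name!r}"
                )
            bits[off + c] = 1
        off += v.cardinality
    return bits


def devectorize_record(bits: np.ndarray, schema: RecordSchema) -> dict[str, list[int]]:
    """Invert :func:`vectorize_record`, recovering the code lists."""
    if bits.shape != (schema.total_dim,):
        raise ValueError(
            f"vector length {bits.shape} does not match schema dim {schema.total_dim}"
        )
    values: dict[str, list[int]] = {}
    off = 0
    for v in schema.variables:
        block = np.flatnonzero(bits[off: off + v.cardinality])
        if block.size:
            values[v.name] = [int(c) for c in block]
        off += v.cardinality
    return values


# ---------------------------------------------------------------------------
# vocabulary and token sequences
# ---------------------------------------------------------------------------

@dataclass
class Vocabulary:
    """Token <-> index bijection with training frequencies.

    Index 0 is reserved for padding.  Indices 1 and 2 are the start- and
    end-of-sequence specials; content tokens follow, ordered by descending
    raw-corpus frequency with lexicographic tie-breaks so builds are
    deterministic.
    """

    tokens: list[str]
    frequencies: dict[str, int]
    index: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @property
    def sos_id(self) -> int:
        return self.index[SOS_TOKEN]

    @property
    def eos_id(self) -> int:
        return self.index[EOS_TOKEN]

    def encode(self, words: list[str]) -> list[int]:
        return [self.index[w] for w in words]

    def decode(self, ids) -> list[str]:
        specials = {PAD_INDEX, self.sos_id, self.eos_id}
        return [self.tokens[i] for i in ids if i not in specials]

    @classmethod
    def from_frequencies(cls, freqs: dict[str, int]) -> "Vocabulary":
        content = sorted(freqs, key=lambda t: (-freqs[t], t))
        tokens = ["<pad>", SOS_TOKEN, EOS_TOKEN] + content
        return cls(tokens=tokens, frequencies=dict(freqs))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for i, t in enumerate(self.tokens):
                fh.write(f"{t}\t{i}\t{self.frequencies.get(t, 0)}\n")

    @classmethod
    def from_tsv(cls, path) -> "Vocabulary":
        tokens, freqs = [], {}
        with open(path) as fh:
            for line in fh:
                tok, idx, freq = line.rstrip("\n").split("\t")
                assert int(idx) == len(tokens), "vocabulary TSV indices not contiguous"
                tokens.append(tok)
                if int(freq) > 0:
                    freqs[tok] = int(freq)
        return cls(tokens=tokens, frequencies=freqs)


def tokenize(text: str) -> list[str]:
    """Lowercase and split on whitespace (punctuation is kept attached)."""
    return text.lower().split()


@dataclass
class PairedCorpus:
    """Aligned record vectors, padded token sequences, and raw text.

    ``sequences[i]`` is ``[SOS] + content + [EOS]`` zero-padded to
    ``max_words + 2``; the decoder input/target views drop the last/first
    column respectively.
    """

    record_bits: np.ndarray          # (n, schema.total_dim) uint8
    sequences: np.ndarray            # (n, max_words + 2) int32
    raw_texts: list[str]
    schema: RecordSchema
    vocab: Vocabulary
    max_words: int = MAX_WORDS

    def __post_init__(self):
        n = len(self.raw_texts)
        if not (self.record_bits.shape[0] == self.sequences.shape[0] == n):
            raise ValueError("corpus components have mismatched lengths")

    def __len__(self) -> int:
        return len(self.raw_texts)

    @property
    def padded_len(self) -> int:
        return self.sequences.shape[1]

    @property
    def decoder_inputs(self) -> np.ndarray:
        return self.sequences[:, :-1]

    @property
    def targets(self) -> np.ndarray:
        return self.sequences[:, 1:]

    def content_lengths(self) -> np.ndarray:
        """Number of content words per sequence (specials excluded)."""
        return (self.sequences != PAD_INDEX).sum(axis=1) - 2

    def subset(self, idx) -> "PairedCorpus":
        idx = np.asarray(idx)
        return PairedCorpus(
            record_bits=self.record_bits[idx],
            sequences=self.sequences[idx],
            raw_texts=[self.raw_texts[i] for i in idx],
            schema=self.schema,
            vocab=self.vocab,
            max_words=self.max_words,
        )


def preprocess_text(
    pairs: list[RawRecord],
    schema: RecordSchema,
    min_freq: int = MIN_TOKEN_FREQ,
    max_words: int = MAX_WORDS,
) -> tuple[PairedCorpus, Vocabulary, dict[str, int]]:
    """Filter, tokenize, and integer-encode a raw record-sentence corpus.

    Token frequencies are counted once over the whole raw corpus (after
    lowercasing).  A pair is dropped if its complaint contains any token with
    corpus frequency below ``min_freq``, or if it exceeds ``max_words``
    content words.  Surviving complaints get start/end-of-sequence specials
    and zero padding.  Returns the corpus, the vocabulary, and the number of
    pairs removed by each filter.
    """
    tokenized = [tokenize(p.complaint_text) for p in pairs]
    for p, words in zip(pairs, tokenized):
        if not words:
            raise ValueError(f"empty complaint text in record {p.values}")

    freqs: dict[str, int] = {}
    for words in tokenized:
        for w in words:
            freqs[w] = freqs.get(w, 0) + 1

    removed = {"low_frequency": 0, "too_long": 0}
    kept: list[int] = []
    for i, words in enumerate(tokenized):
        if any(freqs[w] < min_freq for w in words):
            removed["low_frequency"] += 1
        elif len(words) > max_words:
            removed["too_long"] += 1
        else:
            kept.append(i)
    if not kept:
        raise ValueError("no pairs survive the frequency/length filters")

    vocab_freqs = {w: f for w, f in freqs.items() if f >= min_freq}
    # tokens may survive the threshold yet appear only in dropped pairs;
    # keep them anyway: frequencies are defined on the raw corpus
    vocab = Vocabulary.from_frequencies(vocab_freqs)

    n = len(kept)
    bits = np.zeros((n, schema.total_dim), dtype=np.uint8)
    seqs = np.zeros((n, max_words + 2), dtype=np.int32)
    texts = []
    for row, i in enumerate(kept):
        bits[row] = vectorize_record(pairs[i], schema)
        words = tokenized[i]
        ids = [vocab.sos_id] + vocab.encode(words) + [vocab.eos_id]
        seqs[row, : len(ids)] = ids
        texts.append(" ".join(words))

    logger.info(
        "preprocess: kept %d of %d pairs (%d low-frequency, %d too long); "
        "vocabulary %d tokens",
        n, len(pairs), removed["low_frequency"], removed["too_long"], len(vocab),
    )
    corpus = PairedCorpus(bits, seqs, texts, schema, vocab, max_words=max_words)
    return corpus, vocab, removed


def split_corpus(
    corpus: PairedCorpus,
    train_frac: float = 0.75,
    test_size: int = 50_000,
    seed: int = 0,
) -> tuple[PairedCorpus, PairedCorpus, PairedCorpus]:
    """Random train/validation split plus a capped test subsample.

    Train and validation partition the corpus disjointly and exhaustively;
    the test set is a seeded subsample of the validation set of size
    ``min(test_size, len(validation))``.  Fully reproducible from ``seed``.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    if len(corpus) < 4:
        raise ValueError("corpus too small to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(corpus))
    n_train = int(round(train_frac * len(corpus)))
    train_idx, val_idx = perm[:n_train], perm[n_train:]
    test_idx = val_idx[rng.permutation(len(val_idx))[: min(test_size, len(val_idx))]]
    return corpus.subset(train_idx), corpus.subset(val_idx), corpus.subset(test_idx)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_records(path, schema: RecordSchema) -> list[RawRecord]:
    """Read raw records from CSV or JSON-lines.

    CSV: one column per schema variable (multi-valued codes separated by
    ``;``) plus a ``complaint_text`` column; empty cells are missing values.
    JSON-lines: ``{"values": {...}, "complaint_text": ...}`` per line.
    Malformed rows raise with the offending line number.
    """
    path = str(path)
    records: list[RawRecord] = []
    if path.endswith((".jsonl", ".json")):
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    d = json.loads(line)
                    rec = RawRecord(
                        values={k: [int(c) for c in v] for k, v in d["values"].items()},
                        complaint_text=d["complaint_text"],
                    )
                    vectorize_record(rec, schema)  # validates codes
                except Exception as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                records.append(rec)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        unknown = set(df.columns) - set(schema.names) - {"complaint_text"}
        if unknown:
            raise ValueError(f"unknown columns in {path}: {sorted(unknown)}")
        if "complaint_text" not in df.columns:
            raise ValueError(f"{path}: missing complaint_text column")
        for i, row in enumerate(df.itertuples(index=False), 2):  # header = line 1
            d = dict(zip(df.columns, row))
            try:
                values = {}
                for name in schema.names:
                    cell = d.get(name, "")
                    if cell != "":
                        values[name] = [int(c) for c in cell.split(";")]
                rec = RawRecord(values=values, complaint_text=d["complaint_text"])
                vectorize_record(rec, schema)
            except Exception as exc:
                raise ValueError(f"{path}:{i}: {exc}") from exc
            records.append(rec)
    if not records:
        logger.warning("no records read from %s", path)
    return records


def write_records(records: list[RawRecord], path) -> None:
    """Write raw records as JSON-lines (or CSV if the path ends in .csv)."""
    path = str(path)
    if path.endswith(".csv"):
        names = sorted({n for r in records for n in r.values})
        rows = []
        for r in records:
            row = {n: ";".join(str(c) for c in r.values.get(n, [])) for n in names}
            row["complaint_text"] = r.complaint_text
            rows.append(row)
        pd.DataFrame(rows, columns=names + ["complaint_text"]).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            for r in records:
                fh.write(json.dumps(
                    {"values": r.values, "complaint_text": r.complaint_text}) + "\n")


def write_corpus(corpus: PairedCorpus, path) -> None:
    """Serialize a processed corpus as JSON-lines with a header line.

    Record bits are stored as the list of set indices (the vectors are
    sparse); the header carries the schema, vocabulary, and padding length.
    """
    with open(path, "w") as fh:
        header = {
            "schema": corpus.schema.to_dict(),
            "vocab_tokens": corpus.vocab.tokens,
            "vocab_freqs": corpus.vocab.frequencies,
            "max_words": corpus.max_words,
        }
        fh.write(json.dumps(header) + "\n")
        for i in range(len(corpus)):
            fh.write(json.dumps({
                "bits_on": np.flatnonzero(corpus.record_bits[i]).tolist(),
                "token_indices": corpus.sequences[i][
                    corpus.sequences[i] != PAD_INDEX].tolist(),
                "raw_text": corpus.raw_texts[i],
            }) + "\n")


def read_corpus(path) -> PairedCorpus:
    """Inverse of :func:`write_corpus` (bit-exact round trip)."""
    with open(path) as fh:
        header = json.loads(fh.readline())
        schema = RecordSchema.from_dict(header["schema"])
        vocab = Vocabulary(tokens=header["vocab_tokens"],
                           frequencies=header["vocab_freqs"])
        max_words = header["max_words"]
        bits_rows, seq_rows, texts = [], [], []
        for line in fh:
            d = json.loads(line)
            bits = np.zeros(schema.total_dim, dtype=np.uint8)
            bits[d["bits_on"]] = 1
            seq = np.zeros(max_words + 2, dtype=np.int32)
            seq[: len(d["token_indices"])] = d["token_indices"]
            bits_rows.append(bits)
            seq_rows.append(seq)
            texts.append(d["raw_text"])
    n = len(texts)
    return PairedCorpus(
        record_bits=np.array(bits_rows, dtype=np.uint8).reshape(n, schema.total_dim),
        sequences=np.array(seq_rows, dtype=np.int32).reshape(n, max_words + 2),
        raw_texts=texts,
        schema=schema,
        vocab=vocab,
        max_words=max_words,
    )


#: full-scale ED visit schema (age group, gender, mode of arrival, hospital,
#: two disposition variables, month, year, CCS diagnosis); sums to 399 dims
FULL_SCALE_SPEC = [
    ("age", 23, False, True),
    ("gender", 6, False, True),
    ("arrival", 8, False, True),
    ("hospital", 44, False, True),
    ("disposition", 12, False, True),
    ("disposition_transfer", 8, False, True),
    ("month", 12, False, True),
    ("year", 2, False, True),
    ("diagnosis", 284, True, True),
]
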