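# Methods

## Problem and model

`ccsynth` generates free-text emergency-department (ED) chief complaints
from the discrete variables of a visit record, and evaluates whether the
generated text preserves the statistical content of the original
record-sentence pairs.  A visit is a sparse binary vector **R**: one block
per discrete variable (age group, gender, mode of arrival, hospital,
diagnosis, ...), one-hot for single-valued variables, multi-hot for
discharge diagnosis, all-zero for missing values.  A chief complaint is a
padded integer sequence **S** over a frequency-filtered vocabulary with
start/end-of-sequence specials.

The generator is a minimal conditioned language model in the
image-captioning lineage:

- a single feedforward layer compresses **R** to the dimensionality of the
  recurrent cell (the *encoder*); it is pretrained as the encoder half of
  an autoencoder (record → tanh hidden → sigmoid reconstruction,
  elementwise binary cross-entropy);
- word embeddings (trained from scratch, padding row frozen at zero) feed
  a **single-layer LSTM decoder** whose hidden *and* cell states are both
  initialized from the encoded record through the same projection — the
  natural reading of "compress the record to the cell dimensionality" in
  this architecture family;
- a dense layer plus softmax yields next-word probabilities; the padding
  index is masked to (effectively) zero mass.

Training minimizes per-token cross-entropy under teacher forcing with Adam
(learning rate 0.001, mini-batches of 512 pairs) and stops once the
validation loss fails to strictly decrease for 2 consecutive epochs
("fails to decrease" = not lower than the best seen); the best-epoch
weights are restored.  There is no dropout, attention, or scheduled
sampling.  All networks (LSTM, the GRU classifier below, and the skipgram
embeddings) are implemented directly in NumPy with full backpropagation
through time; float64 arithmetic and a single master seed per training run
make every result bit-reproducible regardless of thread count.

## Inference

Generation follows a four-step loop — feed **R** and the start token,
obtain next-word probabilities, pick a word by the active sampling scheme,
repeat until the end token or 18 content tokens — with three schemes:

- **greedy**: argmax per step, ties broken toward the lowest vocabulary
  index (all decoders use this tie-break, making them deterministic);
- **probabilistic**: sample from `p_i^(1/t)` renormalized (temperature
  applied to log-probabilities); the t→0 limit is greedy, t=1 samples the
  model distribution unchanged; seeded;
- **beam search**: keep the k highest raw summed log-probability partial
  sequences per step, *without length normalization* (beam is defined as
  finding the most likely sequence overall).  A hypothesis emitting the
  end token is frozen into a finished pool and competes by its final
  score; at the length cap only the end token is a legal continuation, and
  cut-off hypotheses remain available as unfinished fallbacks.  Beam
  results are returned sorted; callers wanting one sentence take the top.

Correctness anchors: beam(k=1) is token-for-token identical to greedy;
beam with exhaustive width equals brute-force enumeration on tiny
vocabularies; t=1 first-token frequencies pass a chi-square test against
the model distribution.

## Evaluation suite

**Variable-length n-gram scores.**  Orders 1..4, each capped at the
sentence's own length, pooled into a single bag (not a BLEU-style
geometric mean) — chosen because chief complaints are short and per-order
scores would rate them harshly.  PPV = clipped matched candidate n-grams /
total candidate n-grams; sensitivity = matched reference n-grams / total
reference n-grams; F1 = per-pair harmonic mean; corpus scores are
unweighted per-pair means.  Clipping credits a candidate n-gram at most
its reference multiplicity.  An empty candidate scores 0 with a log note.

**Modified CIDEr.**  Mean cosine similarity of TF-IDF vectors over the
same variable-length n-gram space, one reference per candidate (records
carry exactly one authentic complaint), IDF = ln(N/df) computed on the
reference corpus with df clamped to ≥ 1, no length penalty.  Zero-norm
vectors contribute 0 and are logged.

**Embedding similarity.**  Cosine similarity of the two sentences' mean
word vectors; nonzero for semantically close pairs with no n-gram overlap
("od"/"overdose").  All-out-of-vocabulary sentences raise rather than
silently scoring 0.

**Epidemiological validity.**  2x2 tables of "complaint contains word" by
variable stratum (per-record membership, not token counts), with risk and
odds ratios; zero cells report infinity with a flag (a +0.5 Haldane
correction is available behind a switch).  A diagnosis classifier —
embedding + single-layer GRU + softmax, trained with the same Adam /
early-stopping recipe — predicts the *first listed* diagnosis code from
complaint text and is scored with support-weighted macro sensitivity /
PPV / F1 (classes absent from the truth carry zero weight; unpredicted
classes get PPV 0).

**PII audit.**  Skipgram-with-negative-sampling word vectors (dimension
100, window 5, min-count 5, 5 negatives — conventional defaults) are
trained on the whole complaint corpus; starting from seed names, the 100
cosine nearest neighbors of every known name are labeled by an oracle and
confirmed names are added, iterating until the list closes.  The oracle
abstraction replaces manual review so the loop is testable (tests use
membership in the simulator's planted-name list; the CLI offers an
interactive mode).  The audit then counts complaints containing any
discovered name in parallel authentic and synthetic corpora.

## Synthetic benchmark

The real study corpus is private, so a simulator generates record-sentence
pairs with planted, recountable structure.  The standard configuration
("desk scale", chosen once as a realistic miniature of an ED corpus):

- toy schema of 24 dimensions: 5 age groups, 2 genders, 3 arrival modes,
  2 hospitals, 12 multi-valued diagnosis groups (the full-scale 399-dim
  schema is also provided);
- a 12-diagnosis phrasebook of 2-7-word complaint templates with weighted
  selection; ~150-token vocabulary;
- an **exclusivity rule**: the token "preg" only for female-coded records
  (≈1% of female records carry it), enforced with probability 1;
- an **association rule**: templates containing "fall" have selection odds
  multiplied by 8 for the oldest age group, so the planted
  within-diagnosis odds ratio is exactly 8 in expectation (weight
  multiplication tilts odds exactly);
- 20 surname tokens planted at counts 10-30 — above the vocabulary
  cutoff of 10, so they survive preprocessing into training data;
- 1% per-token misspelling noise (adjacent-character swap), with
  corrupted variants tracked;
- 10% missing mode-of-arrival, 2% missing hospital, 30% of records with a
  second random diagnosis code.

Every planted quantity is recounted from the emitted corpus into a
`PlantedTruth`, so tests compare against realized counts, never intended
ones.  What the simulator does **not** emulate: realistic clinical
language, ICD/CCS marginals, inter-variable correlation beyond the planted
rules, and documentation drift over time — so passing tests show the
pipeline's mechanics and the model's conditioning behavior, not clinical
fidelity.

## Problem sizes and numerical choices

The headline benchmark uses 50,000 pairs (75/25 split), hidden dimension
64, embedding dimension 32, at most 30 epochs — sizes at which the model
reliably learns per-diagnosis canonical templates on a desktop CPU in a
few minutes.  Unit tests use 2-8k pairs with hidden 16-40.  At the toy
schema's 24 record dimensions the record autoencoder does not compress
(hidden 64 > 24); the pretraining step is kept because it is part of the
training procedure, and it logs a warning.  Unstated full-scale layer
sizes default to hidden 256 / embedding 128 territory only through
configuration; nothing is hard-coded.

Degenerate inputs: empty complaint text raises at preprocessing; a record
vector of all zeros is valid (fully missing record); sampling
temperature must be positive; beam width at least 1; a single-pair corpus
cannot define IDF and raises.

## Known limitations

- The record dimension is always derived from the schema (399 for the
  bundled full-scale ED layout) and never hard-coded: variable tables in
  the wild often carry a few extra unknown/missing categories, so two
  descriptions of "the same" layout can disagree by a handful of
  dimensions, and serialized artifacts always embed their own schema.
- Greedy output on the toy benchmark collapses to per-record canonical
  templates — the expected "homogenization" behavior — so lexical
  diversity metrics are not meaningful at this scale.  For the same
  reason greedy and beam search decode nearly identical sentences here,
  and corpus-level quality differences between them sit at sampling-noise
  level (|ΔF1| < 0.005): the clear full-scale separation between sampling
  schemes seen on real data does not reproduce at desk scale, and the
  corresponding strict ordering check is expected to be unreliable.
- The simulator's association amplification check is directional; the
  amplification magnitude depends on template weights and is not
  calibrated to any real corpus.
- The NumPy LSTM is tuned for clarity and determinism, not speed; at
  full-study scale (millions of pairs, 23k vocabulary) a GPU framework
  would be required.
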