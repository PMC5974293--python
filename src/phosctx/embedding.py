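"""Distributed-memory embeddings of biological words and sequence contexts.

A paragraph-vector distributed-memory (PV-DM) network is trained on a corpus
of overlapping n-gram biological words with negative sampling: each document
(protein) owns a trainable vector that, averaged with the vectors of the
words in a co-occurrence window, predicts the centre word.  Training yields

* ``DB_w`` — word vectors for every n-gram in the vocabulary,
* ``DB_p`` — document vectors for every training protein,
* the frozen inference network N (word vectors + output weights), which can
  embed *unseen* word lists by gradient descent on a fresh document vector.

Two strategies then embed a residue's local context (the 2m+1-residue window
around a candidate phosphosite):

* ``add`` — sum the pre-trained word vectors of the window's n-grams
  (order-insensitive; unseen words contribute zero),
* ``inference`` — infer a document vector against the frozen network
  (order-sensitive through window co-occurrence).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from numba import njit

from .seqio import BioWordList, TaggedCorpus, split_ngrams

Strategy = Literal["add", "inference"]

DEFAULT_PAD_CHAR = "X"


@dataclass(frozen=True)
class EmbeddingHyperparams:
    """PV-DM training hyper-parameters.

    Defaults follow the published configuration: 100 hidden units, window
    25, initial learning rate 0.25 decaying linearly to ``min_lr``, 5
    negative samples per target, 400 passes over the corpus.
    """

    dim: int = 100
    window: int = 25
    initial_lr: float = 0.25
    negative: int = 5
    epochs: int = 400
    min_lr: float = 1e-4

    def __post_init__(self) -> None:
        if self.dim < 1 or self.window < 1 or self.epochs < 1:
            raise ValueError("dim, window and epochs must be >= 1")
        if self.negative < 0:
            raise ValueError("negative must be >= 0")
        if not 0 < self.initial_lr:
            raise ValueError("initial_lr must be positive")


@njit(cache=True)
def _sigmoid(x):
    if x > 8.0:
        return 1.0
    if x < -8.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def _xorshift(state):
    """Advance a xorshift64* state (state must be non-zero uint64)."""
    state ^= state >> np.uint64(12)
    state ^= state << np.uint64(25)
    state ^= state >> np.uint64(27)
    return state


@njit(cache=True)
def _uniform01(state):
    """Map a xorshift64* state to a uniform double in [0, 1)."""
    x = (state * np.uint64(2685821657736338717)) >> np.uint64(11)
    return np.float64(x) / 9007199254740992.0


@njit(cache=True)
def _sample_negative(cumtable, u):
    """Index into the unigram^0.75 cumulative table by a uniform draw."""
    return np.searchsorted(cumtable, u * cumtable[-1])


@njit(cache=True)
def _pvdm_epoch_doc(
    words, doc_vec, Wv, Wo, cumtable, window, negative, alpha, train_words, rand_state
):
    """One pass of PV-DM negative-sampling SGD over a single document.

    ``doc_vec`` is updated in place; ``Wv``/``Wo`` are updated only when
    ``train_words`` is true (frozen during inference).  Returns the advanced
    xorshift RNG state so the caller controls the stream.
    """
    dim = Wv.shape[1]
    T = words.shape[0]
    state = rand_state
    for t in range(T):
        # word2vec-style reduced window, resampled per position
        state = _xorshift(state)
        b = np.int64(_uniform01(state) * window)
        win = window - b  # effective (reduced) window, >= 1
        lo = t - win if t - win > 0 else 0
        hi = t + win + 1 if t + win + 1 < T else T
        nctx = hi - lo - 1  # context excludes the centre word
        # combined hidden state: mean of doc vector and context word vectors
        h = np.zeros(dim)
        for j in range(lo, hi):
            if j == t:
                continue
            wv = Wv[words[j]]
            for k in range(dim):
                h[k] += wv[k]
        for k in range(dim):
            h[k] = (h[k] + doc_vec[k]) / (nctx + 1)
        grad_h = np.zeros(dim)
        target = words[t]
        for s in range(negative + 1):
            if s == 0:
                label = 1.0
                out = target
            else:
                label = 0.0
                state = _xorshift(state)
                out = _sample_negative(cumtable, _uniform01(state))
                if out == target:
                    continue
            dot = 0.0
            row = Wo[out]
            for k in range(dim):
                dot += h[k] * row[k]
            g = (label - _sigmoid(dot)) * alpha
            for k in range(dim):
                grad_h[k] += g * row[k]
            if train_words:
                for k in range(dim):
                    row[k] += g * h[k]
        # distribute the exact mean-combine gradient to every contributor
        scale = 1.0 / (nctx + 1)
        for k in range(dim):
            doc_vec[k] += grad_h[k] * scale
        if train_words:
            for j in range(lo, hi):
                if j == t:
                    continue
                wv = Wv[words[j]]
                for k in range(dim):
                    wv[k] += grad_h[k] * scale
    return state


@njit(cache=True)
def _pvdm_train(
    flat_words, offsets, Wv, Wd, Wo, cumtable, window, negative,
    initial_lr, min_lr, epochs, seed
):
    """Full PV-DM training: ``epochs`` sequential passes over all documents."""
    n_docs = offsets.shape[0] - 1
    state = np.uint64(seed) * np.uint64(2654435761) + np.uint64(1)
    total = epochs * n_docs
    step = 0
    for e in range(epochs):
        for d in range(n_docs):
            alpha = initial_lr + (min_lr - initial_lr) * (step / total)
            words = flat_words[offsets[d] : offsets[d + 1]]
            state = _pvdm_epoch_doc(
                words, Wd[d], Wv, Wo, cumtable, window, negative, alpha, True, state
            )
            step += 1


@njit(cache=True)
def _pvdm_infer(
    words, doc_vec, Wv, Wo, cumtable, window, negative, initial_lr, min_lr, epochs, seed
):
    """Gradient inference of one document vector against frozen N."""
    state = np.uint64(seed) * np.uint64(2654435761) + np.uint64(7)
    for e in range(epochs):
        alpha = initial_lr + (min_lr - initial_lr) * (e / epochs)
        state = _pvdm_epoch_doc(
            words, doc_vec, Wv, Wo, cumtable, window, negative, alpha, False, state
        )


@dataclass
class EmbeddingModel:
    """Trained PV-DM network with its word- and document-vector stores."""

    word_vectors: np.ndarray      # (V, dim) — DB_w
    doc_vectors: np.ndarray       # (D, dim) — DB_p
    output_weights: np.ndarray    # (V, dim) — output layer of network N
    vocab_index: dict[str, int]
    doc_index: dict[str, int]
    word_counts: np.ndarray
    hyperparams: EmbeddingHyperparams
    oov_count: int = 0

    @property
    def dim(self) -> int:
        return self.hyperparams.dim

    @property
    def vocab(self) -> set[str]:
        return set(self.vocab_index)

    def word_vector(self, word: str) -> np.ndarray | None:
        idx = self.vocab_index.get(word)
        return None if idx is None else self.word_vectors[idx]

    def doc_vector(self, doc_id: str) -> np.ndarray:
        return self.doc_vectors[self.doc_index[doc_id]]

    def _cumtable(self) -> np.ndarray:
        return np.cumsum(self.word_counts.astype(np.float64) ** 0.75)

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Serialise to a directory: arrays in .npz, vocab/config in JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "arrays.npz",
            word_vectors=self.word_vectors,
            doc_vectors=self.doc_vectors,
            output_weights=self.output_weights,
            word_counts=self.word_counts,
        )
        # index order is positional: list position == row index
        vocab = sorted(self.vocab_index, key=self.vocab_index.get)
        docs = sorted(self.doc_index, key=self.doc_index.get)
        (directory / "vocab.json").write_text(json.dumps({"words": vocab, "docs": docs}))
        (directory / "hyperparams.json").write_text(json.dumps(asdict(self.hyperparams)))

    @classmethod
    def load(cls, directory: str | Path) -> "EmbeddingModel":
        directory = Path(directory)
        arrays = np.load(directory / "arrays.npz")
        names = json.loads((directory / "vocab.json").read_text())
        hp = EmbeddingHyperparams(**json.loads((directory / "hyperparams.json").read_text()))
        return cls(
            word_vectors=arrays["word_vectors"],
            doc_vectors=arrays["doc_vectors"],
            output_weights=arrays["output_weights"],
            vocab_index={w: k for k, w in enumerate(names["words"])},
            doc_index={d: k for k, d in enumerate(names["docs"])},
            word_counts=arrays["word_counts"],
            hyperparams=hp,
        )


def train_embedding(
    corpus: TaggedCorpus,
    hp: EmbeddingHyperparams | None = None,
    seed: int = 0,
) -> EmbeddingModel:
    """Train the PV-DM model on a tagged corpus.

    Vocabulary covers every word in the corpus (no minimum count — desk-scale
    corpora are small); training is single-threaded and reproducible for a
    given seed.
    """
    hp = hp or EmbeddingHyperparams()
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    counts: dict[str, int] = {}
    for _, wl in corpus.documents:
        for w in wl.words:
            counts[w] = counts.get(w, 0) + 1
    if not counts:
        raise ValueError("corpus has an empty vocabulary (no words in any document)")
    vocab = sorted(counts)
    vocab_index = {w: k for k, w in enumerate(vocab)}
    doc_ids = corpus.doc_ids
    doc_index = {d: k for k, d in enumerate(doc_ids)}

    flat, offsets = [], [0]
    for _, wl in corpus.documents:
        flat.extend(vocab_index[w] for w in wl.words)
        offsets.append(len(flat))
    flat_words = np.array(flat, dtype=np.int64)
    offs = np.array(offsets, dtype=np.int64)
    word_counts = np.array([counts[w] for w in vocab], dtype=np.int64)

    rng = np.random.default_rng(seed)
    V, D, dim = len(vocab), len(doc_ids), hp.dim
    Wv = (rng.random((V, dim)) - 0.5) / dim
    Wd = (rng.random((D, dim)) - 0.5) / dim
    Wo = np.zeros((V, dim))
    cumtable = np.cumsum(word_counts.astype(np.float64) ** 0.75)

    _pvdm_train(
        flat_words, offs, Wv, Wd, Wo, cumtable,
        hp.window, hp.negative, hp.initial_lr, hp.min_lr, hp.epochs, seed + 1,
    )
    return EmbeddingModel(Wv, Wd, Wo, vocab_index, doc_index, word_counts, hp)


def vec_add(
    words: BioWordList | Sequence[str],
    model: EmbeddingModel,
    normalize: bool = False,
    return_oov: bool = False,
):
    """Additive embedding: element-wise sum of word vectors.

    Out-of-vocabulary words contribute the zero vector; ``normalize`` divides
    by the number of in-vocabulary words (mean instead of sum).
    """
    total = np.zeros(model.dim)
    oov = 0
    hits = 0
    for w in words:
        vec = model.word_vector(w)
        if vec is None:
            oov += 1
        else:
            total += vec
            hits += 1
    if hits == 0:
        warnings.warn("all words out of vocabulary; returning zero vector", stacklevel=2)
    elif normalize:
        total /= hits
    model.oov_count += oov
    if return_oov:
        return total, oov
    return total


def vec_infer(
    words: BioWordList | Sequence[str],
    model: EmbeddingModel,
    infer_epochs: int | None = None,
    infer_lr: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Inference embedding: gradient descent of a fresh document vector
    against the frozen network, holding word vectors and output weights
    fixed.  Sensitive to word order through window co-occurrence.
    """
    word_list = list(words)
    if not word_list:
        raise ValueError("cannot infer a vector for an empty word list")
    hp = model.hyperparams
    epochs = hp.epochs if infer_epochs is None else infer_epochs
    lr = hp.initial_lr if infer_lr is None else infer_lr
    idxs = np.array(
        [model.vocab_index[w] for w in word_list if w in model.vocab_index],
        dtype=np.int64,
    )
    rng = np.random.default_rng(seed)
    doc_vec = (rng.random(model.dim) - 0.5) / model.dim
    if idxs.size == 0:
        warnings.warn("all words out of vocabulary; returning the initial vector", stacklevel=2)
        return doc_vec
    _pvdm_infer(
        idxs, doc_vec, model.word_vectors, model.output_weights, model._cumtable(),
        hp.window, hp.negative, lr, hp.min_lr, epochs, seed,
    )
    return doc_vec


@dataclass(frozen=True)
class ContextWindow:
    """The 2m+1-residue window centred on a candidate site."""

    center_index: int
    m: int
    residues: str
    pad_char: str = DEFAULT_PAD_CHAR

    def __post_init__(self) -> None:
        if len(self.residues) != 2 * self.m + 1:
            raise ValueError(
                f"window length {len(self.residues)} != 2m+1 = {2 * self.m + 1}"
            )

    @property
    def center_residue(self) -> str:
        return self.residues[self.m]


def extract_context_window(
    sequence: str, i: int, m: int, pad_char: str = DEFAULT_PAD_CHAR
) -> ContextWindow:
    """Extract the window of m residues either side of position i.

    Positions before the N-terminus or past the C-terminus are filled with
    ``pad_char`` so the window always has exactly 2m+1 letters.
    """
    if not 0 <= i < len(sequence):
        raise IndexError(f"index {i} out of range for sequence length {len(sequence)}")
    if m < 1:
        raise ValueError("flank length m must be >= 1")
    lo, hi = i - m, i + m + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(sequence))
    core = sequence[max(0, lo) : min(len(sequence), hi)]
    return ContextWindow(i, m, pad_char * left_pad + core + pad_char * right_pad, pad_char)


def context2vec(
    sequence: str,
    i: int,
    m: int,
    model: EmbeddingModel,
    strategy: Strategy = "add",
    n: int = 3,
    pad_char: str = DEFAULT_PAD_CHAR,
    infer_epochs: int | None = None,
    infer_lr: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Distributed representation of the local context of residue i.

    Composes window extraction, overlapping n-gram split and either the
    additive or the inference embedding strategy.
    """
    window = extract_context_window(sequence, i, m, pad_char)
    words = split_ngrams(window.residues, n, "overlapping")
    if strategy == "add":
        return vec_add(words, model)
    if strategy == "inference":
        return vec_infer(words, model, infer_epochs, infer_lr, seed)
    raise ValueError(f"unknown strategy {strategy!r}")
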