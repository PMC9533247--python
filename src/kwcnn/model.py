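"""Model configuration, construction, scoring and checkpointing.

The classifier is the NumPy word-CNN from :mod:`kwcnn.nn`, held behind a small
scoring contract (:func:`score`) so that training, evaluation and bigram
probing never touch its internals.  Embeddings can be initialized randomly or
by skip-gram (word2vec-style) pretraining on the training corpus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Corpus, Vocabulary, encode
from .nn import WordCnn

__all__ = [
    "ModelConfig",
    "ClassifierModel",
    "build_model",
    "score",
    "pad_batch",
    "save_model",
    "load_model",
    "pretrain_skipgram",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the word-CNN.

    Defaults are the full-scale settings (300-dim embeddings, 300 filters per
    window, windows 3/4/5, hence a 900-dim document embedding); a desk-scale
    preset for fast CPU experiments is available via :meth:`desk_scale`.
    ``max(conv_windows)`` is the minimum encodable document length (5 with the
    default windows).
    """

    embed_dim: int = 300
    conv_windows: tuple[int, ...] = (3, 4, 5)
    filters_per_window: int = 300
    n_classes: int = 2
    vocab_size: int = 2
    embedding_init: str = "random"  # or "word2vec"

    def __post_init__(self) -> None:
        self.conv_windows = tuple(self.conv_windows)
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.embedding_init not in {"random", "word2vec"}:
            raise ValueError(f"unknown embedding_init {self.embedding_init!r}")

    @property
    def min_len(self) -> int:
        return max(self.conv_windows)

    @property
    def doc_embedding_dim(self) -> int:
        return self.filters_per_window * len(self.conv_windows)

    @classmethod
    def desk_scale(cls, **overrides) -> "ModelConfig":
        """Small configuration (32/32, windows 3/4/5) for CPU-speed runs."""
        kwargs = dict(embed_dim=32, filters_per_window=32)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class ClassifierModel:
    """A (possibly trained) word-CNN plus its config and vocabulary hash."""

    net: WordCnn
    config: ModelConfig
    labels: list[str]
    vocab_hash: str

    @property
    def min_len(self) -> int:
        return self.net.min_len


def pretrain_skipgram(
    train: Corpus,
    vocab: Vocabulary,
    embed_dim: int,
    seed: int,
    window: int = 5,
    negatives: int = 5,
    epochs: int = 1,
    lr: float = 0.025,
) -> np.ndarray:
    """Skip-gram embeddings with negative sampling, trained on *train*.

    A compact word2vec-style pretrainer: for every (center, context) pair
    within ``window`` tokens, the center vector is pushed toward the context
    output vector and away from ``negatives`` samples drawn from the unigram
    distribution raised to 3/4.  Returns input vectors shaped
    ``(len(vocab), embed_dim)``; the pad row is zero.
    """
    rng = np.random.default_rng(seed)
    V = len(vocab)
    W_in = rng.uniform(-0.5 / embed_dim, 0.5 / embed_dim, size=(V, embed_dim))
    W_out = np.zeros((V, embed_dim))
    W_in[vocab.pad_id] = 0.0

    counts = np.zeros(V)
    encoded_docs = []
    for doc in train.documents:
        ids = np.array([vocab[t] for t in doc.tokens])
        encoded_docs.append(ids)
        np.add.at(counts, ids, 1)
    noise = counts**0.75
    noise[vocab.pad_id] = 0.0
    noise /= noise.sum()

    for _ in range(epochs):
        for ids in encoded_docs:
            n = len(ids)
            for i in range(n):
                c = ids[i]
                lo, hi = max(0, i - window), min(n, i + window + 1)
                for j in range(lo, hi):
                    if j == i:
                        continue
                    ctx = ids[j]
                    negs = rng.choice(V, size=negatives, p=noise)
                    targets = np.concatenate(([ctx], negs))
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    vecs = W_out[targets]  # (1+neg, d)
                    scores = 1.0 / (1.0 + np.exp(-vecs @ W_in[c]))
                    g = (scores - labels) * lr
                    grad_in = g @ vecs
                    W_out[targets] -= np.outer(g, W_in[c])
                    W_in[c] -= grad_in
    W_in[vocab.pad_id] = 0.0
    return W_in


def build_model(
    config: ModelConfig,
    vocab: Vocabulary,
    seed: int,
    labels: Sequence[str],
    train: Corpus | None = None,
) -> ClassifierModel:
    """Construct a classifier with deterministic, seed-driven initialization.

    With ``embedding_init="word2vec"`` the embedding table is pretrained by
    :func:`pretrain_skipgram` on *train* (required in that case); otherwise a
    scaled-uniform random init is used.  The pad embedding row is zero and is
    never updated during training.
    """
    if config.vocab_size != len(vocab):
        raise ValueError(
            f"config.vocab_size={config.vocab_size} does not match the "
            f"vocabulary ({len(vocab)} entries)"
        )
    if config.n_classes != len(labels):
        raise ValueError("config.n_classes does not match the label inventory")
    embeddings = None
    if config.embedding_init == "word2vec":
        if train is None:
            raise ValueError("word2vec init requires the training corpus")
        embeddings = pretrain_skipgram(train, vocab, config.embed_dim, seed)
    net = WordCnn(
        vocab_size=len(vocab),
        n_classes=config.n_classes,
        embed_dim=config.embed_dim,
        filters=config.filters_per_window,
        windows=config.conv_windows,
        pad_id=vocab.pad_id,
        seed=seed,
        embeddings=embeddings,
    )
    return ClassifierModel(
        net=net,
        config=config,
        labels=list(labels),
        vocab_hash=vocab.content_hash(),
    )


def pad_batch(
    sequences: Sequence[Sequence[int]], pad_id: int
) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad id sequences to the batch maximum; return (ids, lengths)."""
    lengths = np.array([len(s) for s in sequences])
    T = int(lengths.max())
    ids = np.full((len(sequences), T), pad_id, dtype=np.int64)
    for i, s in enumerate(sequences):
        ids[i, : len(s)] = s
    return ids, lengths


def score(
    model: ClassifierModel, encoded_batch: Sequence[Sequence[int]]
) -> np.ndarray:
    """Per-document class-probability rows for encoded id sequences.

    Every sequence must already be at least ``max(conv_windows)`` long
    (i.e. encoded with the model's minimum length); shorter input raises with
    an instruction to pad.  Batch order is preserved and scoring is
    deterministic and side-effect-free.
    """
    lengths = [len(s) for s in encoded_batch]
    if min(lengths) < model.min_len:
        raise ValueError(
            f"sequence of length {min(lengths)} is shorter than the model "
            f"minimum {model.min_len}; encode with min_len={model.min_len}"
        )
    ids, lens = pad_batch(encoded_batch, model.net.pad_id)
    return model.net.predict_proba(ids, lens)


def score_corpus(
    model: ClassifierModel,
    corpus: Corpus,
    vocab: Vocabulary,
    batch_size: int = 256,
) -> np.ndarray:
    """Probability matrix for every document of *corpus*, in document order."""
    out = []
    docs = corpus.documents
    for start in range(0, len(docs), batch_size):
        chunk = docs[start : start + batch_size]
        enc = [encode(d.tokens, vocab, model.min_len) for d in chunk]
        out.append(score(model, enc))
    return np.vstack(out)


def save_model(model: ClassifierModel, vocab: Vocabulary, path: str | Path) -> None:
    """Single-file checkpoint: config, label inventory, vocab hash, parameters."""
    path = Path(path)
    meta = {
        "config": {**asdict(model.config), "conv_windows": list(model.config.conv_windows)},
        "labels": model.labels,
        "vocab_hash": model.vocab_hash,
    }
    arrays = {f"param_{k}": v for k, v in model.net.params.arrays.items()}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path, vocab: Vocabulary) -> ClassifierModel:
    """Load a checkpoint, verifying it was built with the supplied vocabulary."""
    p = Path(path)
    if not p.exists():  # np.savez appends .npz when saving
        candidate = Path(str(p) + ".npz")
        if candidate.exists():
            p = candidate
    with np.load(p, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = {
            k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")
        }
    if meta["vocab_hash"] != vocab.content_hash():
        raise ValueError(
            "checkpoint was built with a different vocabulary (hash mismatch)"
        )
    config = ModelConfig(**{**meta["config"],
                            "conv_windows": tuple(meta["config"]["conv_windows"])})
    model = build_model(config, vocab, seed=0, labels=meta["labels"])
    for k, v in arrays.items():
        model.net.params.arrays[k] = v
    return model
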