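"""Keyword-augmented training, class-weighted training, and plain training.

Three mutually exclusive modes share one loop:

``baseline``
    Plain cross-entropy training on document mini-batches.
``keywords``
    Each training update additionally draws a batch of synthetic "keyword
    documents": ``min(n_c, C')`` classes are sampled without replacement (C' =
    classes with at least one keyword segment), ``k`` segments per class are
    drawn with replacement and concatenated into one document labeled with the
    class.  The update minimizes ``L = L_docs + alpha * L_key`` where both
    terms are cross entropies.
``class_weights``
    Document cross entropy weighted per class by ``max(1, log(mu * N / c_i))``
    with natural log, where ``c_i`` is class *i*'s training count and ``N``
    the total — rarer classes get proportionally larger loss weight.

Early stopping monitors the epoch-mean validation document loss with a
patience; the parameters from the best validation epoch are returned.  Three
independently seeded RNG streams (data shuffling, keyword sampling, parameter
init) make ``keywords`` mode with ``alpha = 0`` bit-identical to ``baseline``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import Corpus, Vocabulary, encode
from .keywords import KeywordSet, Term
from .model import ClassifierModel, ModelConfig, build_model, pad_batch
from .nn import Adam

__all__ = [
    "TrainingConfig",
    "LossBreakdown",
    "ClassWeights",
    "class_weights",
    "sample_keyword_batch",
    "train",
]

logger = logging.getLogger(__name__)

MODES = ("baseline", "keywords", "class_weights")


@dataclass
class TrainingConfig:
    """Hyperparameters of the training loop.

    Defaults are the full-scale settings: batch size 128, ``n_c`` (classes per
    keyword batch) 128, ``k`` (segments per class) 5, ``alpha`` (keyword-loss
    weight) 1.0, ``mu`` (class-weight scale) 0.15, Adam with learning rate
    1e-4, early-stopping patience 5 epochs.  ``max_epochs`` bounds the loop.
    """

    batch_size: int = 128
    n_c: int = 128
    k: int = 5
    alpha: float = 1.0
    mu: float = 0.15
    mode: str = "baseline"
    learning_rate: float = 1e-4
    patience: int = 5
    max_epochs: int = 100
    seed: int = 0
    keyword_batches_per_update: int = 1

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.k < 1 or self.n_c < 1:
            raise ValueError("k and n_c must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class LossBreakdown:
    """Per-epoch mean losses; ``l_total = l_docs + alpha * l_key`` exactly."""

    l_docs: float
    l_key: float
    l_total: float


@dataclass
class TrainingHistory:
    epochs: list[LossBreakdown] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


@dataclass
class ClassWeights:
    """Per-class loss multipliers, all >= 1."""

    weights: dict[str, float]

    def as_array(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.weights[l] for l in labels])


def class_weights(counts: dict[str, int], mu: float = 0.15) -> ClassWeights:
    """Log-inverse-frequency class weights, clamped below at 1.

    ``w_i = max(1, ln(mu * sum_j c_j / c_i))``.  A class that is rarer than a
    fraction ``mu/e`` of the corpus gets weight above 1; common classes get
    exactly 1.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    total = sum(counts.values())
    weights = {}
    for label, c in counts.items():
        if c < 1:
            raise ValueError(f"class {label!r} has zero training documents")
        weights[label] = max(1.0, math.log(mu * total / c))
    return ClassWeights(weights=weights)


def sample_keyword_batch(
    keywords: KeywordSet,
    n_c: int,
    k: int,
    rng: np.random.Generator,
) -> list[tuple[list[str], str]]:
    """Draw one batch of keyword documents.

    Samples ``min(n_c, C')`` distinct classes uniformly without replacement
    among the classes with at least one segment, then per class draws *k*
    segments uniformly with replacement and concatenates their tokens in drawn
    order into a single document labeled with that class.
    """
    eligible = keywords.nonempty_labels()
    if not eligible:
        raise ValueError("no class has any keyword segments")
    n = min(n_c, len(eligible))
    chosen = rng.choice(len(eligible), size=n, replace=False)
    batch: list[tuple[list[str], str]] = []
    for ci in chosen:
        label = eligible[int(ci)]
        segs: list[Term] = keywords.segments[label]
        picks = rng.integers(0, len(segs), size=k)
        tokens: list[str] = []
        for pi in picks:
            tokens.extend(segs[int(pi)])
        batch.append((tokens, label))
    return batch


def _encode_batch(
    token_docs: Sequence[Sequence[str]],
    vocab: Vocabulary,
    min_len: int,
) -> tuple[np.ndarray, np.ndarray]:
    enc = [encode(list(t), vocab, min_len) for t in token_docs]
    return pad_batch(enc, vocab.pad_id)


def train(
    model: ClassifierModel,
    train_corpus: Corpus,
    val_corpus: Corpus,
    vocab: Vocabulary,
    config: TrainingConfig,
    keywords: KeywordSet | None = None,
) -> tuple[ClassifierModel, TrainingHistory]:
    """Train *model* in place and return it with the per-epoch history.

    Every mini-batch computes the document loss (class-weighted iff
    ``mode="class_weights"``); in ``keywords`` mode a keyword batch is drawn
    from a dedicated RNG stream, encoded with the model's minimum length, and
    its unweighted cross entropy enters the update as ``alpha * L_key``.  One
    Adam step per mini-batch.  Early stopping tracks the epoch-mean validation
    document loss; the best-epoch parameters are restored before returning.
    """
    if not train_corpus.documents:
        raise ValueError("empty training split")
    if config.mode == "keywords":
        if keywords is None:
            raise ValueError("keywords mode requires a KeywordSet")
        if not keywords.nonempty_labels():
            raise ValueError("keywords mode requires >= 1 class with segments")

    labels = model.labels
    label_to_idx = {l: i for i, l in enumerate(labels)}
    min_len = model.min_len

    sw = None
    if config.mode == "class_weights":
        cw = class_weights(
            {l: c for l, c in train_corpus.class_counts().items() if c > 0},
            mu=config.mu,
        )
        weight_by_idx = np.array(
            [cw.weights.get(l, 1.0) for l in labels]
        )

    # independent streams: data shuffling / keyword sampling
    data_rng = np.random.default_rng((config.seed, 1))
    kw_rng = np.random.default_rng((config.seed, 2))

    docs = train_corpus.documents
    enc_train = [encode(list(d.tokens), vocab, min_len) for d in docs]
    y_train = np.array([label_to_idx[d.label] for d in docs])
    enc_val = [encode(list(d.tokens), vocab, min_len) for d in val_corpus.documents]
    y_val = np.array([label_to_idx[d.label] for d in val_corpus.documents])

    opt = Adam(lr=config.learning_rate)
    history = TrainingHistory()
    best_val = np.inf
    best_params = model.net.params.copy()
    n = len(docs)

    for epoch in range(config.max_epochs):
        order = data_rng.permutation(n)
        ep_docs, ep_key, n_batches = 0.0, 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            ids, lens = pad_batch([enc_train[i] for i in idx], vocab.pad_id)
            y = y_train[idx]
            if config.mode == "class_weights":
                sw = weight_by_idx[y]
            l_docs, grads = model.net.loss_and_grads(ids, lens, y, sample_weights=sw)
            l_key = 0.0
            if config.mode == "keywords":
                for _ in range(config.keyword_batches_per_update):
                    kb = sample_keyword_batch(keywords, config.n_c, config.k, kw_rng)
                    k_ids, k_lens = _encode_batch(
                        [t for t, _ in kb], vocab, min_len
                    )
                    k_y = np.array([label_to_idx[l] for _, l in kb])
                    l_key_b, k_grads = model.net.loss_and_grads(k_ids, k_lens, k_y)
                    l_key += l_key_b / config.keyword_batches_per_update
                    # alpha == 0 must reduce bit-exactly to baseline: skip the
                    # gradient accumulation entirely rather than adding zeros
                    if config.alpha != 0.0:
                        for name, g in k_grads.items():
                            grads[name] = grads[name] + (
                                config.alpha / config.keyword_batches_per_update
                            ) * g
            l_total = l_docs + config.alpha * l_key
            if not np.isfinite(l_total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"l_docs={l_docs}, l_key={l_key}"
                )
            opt.step(model.net.params, grads)
            ep_docs += l_docs
            ep_key += l_key
            n_batches += 1
        # l_total derived from the epoch means so the decomposition
        # l_total = l_docs + alpha * l_key holds exactly in float arithmetic
        mean_docs = ep_docs / n_batches
        mean_key = ep_key / n_batches
        bd = LossBreakdown(
            l_docs=mean_docs,
            l_key=mean_key,
            l_total=mean_docs + config.alpha * mean_key,
        )
        history.epochs.append(bd)

        val_loss = _validation_loss(model, enc_val, y_val, vocab)
        history.val_loss.append(val_loss)
        logger.info(
            "epoch=%d l_docs=%.4f l_key=%.4f l_total=%.4f val_loss=%.4f",
            epoch, bd.l_docs, bd.l_key, bd.l_total, val_loss,
        )
        if val_loss < best_val:
            best_val = val_loss
            best_params = model.net.params.copy()
            history.best_epoch = epoch
        elif epoch - history.best_epoch >= config.patience:
            break

    model.net.params = best_params
    return model, history


def _validation_loss(
    model: ClassifierModel,
    enc_val: list[list[int]],
    y_val: np.ndarray,
    vocab: Vocabulary,
    batch_size: int = 256,
) -> float:
    """Mean document cross entropy on the validation split (no keyword term)."""
    if len(enc_val) == 0:
        return float("nan")
    total = 0.0
    for start in range(0, len(enc_val), batch_size):
        chunk = enc_val[start : start + batch_size]
        ids, lens = pad_batch(chunk, vocab.pad_id)
        probs = model.net.predict_proba(ids, lens)
        y = y_val[start : start + len(chunk)]
        p_true = np.clip(probs[np.arange(len(chunk)), y], 1e-300, None)
        total += float(-np.log(p_true).sum())
    return total / len(enc_val)
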