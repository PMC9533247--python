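"""Scikit-learn estimator interface to the keyword-augmented CNN.

:class:`CnnTextClassifier` wraps corpus handling, vocabulary construction,
optional NPMI keyword extraction and the training loop behind the standard
``fit`` / ``predict`` / ``predict_proba`` contract, so the classifier composes
with sklearn pipelines and model selection.  ``X`` is a sequence of raw text
strings and ``y`` a sequence of class labels.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .corpus import Corpus, Document, build_vocab, encode, tokenize
from .keywords import KeywordSet, compute_npmi, top_keywords
from .model import ModelConfig, build_model, score
from .training import TrainingConfig, train

__all__ = ["CnnTextClassifier"]


def _corpus_from_xy(
    X: Sequence[str], y: Sequence[str], labels: Sequence[str], split: str
) -> Corpus:
    docs = []
    for i, (text, label) in enumerate(zip(X, y)):
        tokens = tuple(tokenize(text)) if isinstance(text, str) else tuple(text)
        if not tokens:
            raise ValueError(f"sample {i} tokenizes to zero tokens")
        docs.append(Document(doc_id=str(i), tokens=tokens, label=str(label)))
    return Corpus(documents=docs, labels=list(labels), split=split)


class CnnTextClassifier(BaseEstimator, ClassifierMixin):
    """Word-level CNN text classifier with optional keyword-augmented training.

    Parameters
    ----------
    mode:
        ``"baseline"`` (plain cross entropy), ``"keywords"`` (auxiliary loss
        on synthetic keyword documents) or ``"class_weights"`` (log-inverse-
        frequency weighted cross entropy).
    keywords:
        A :class:`~kwcnn.keywords.KeywordSet`, or ``"npmi"`` to extract the
        top-``npmi_top_k`` unigrams and bigrams per class from the training
        data.  Required when ``mode="keywords"``.
    n_c, k, alpha, mu:
        Keyword-batch class count, segments per keyword document, keyword-loss
        weight, and class-weight scale.
    embed_dim, filters_per_window, conv_windows, embedding_init:
        Architecture of the underlying CNN.
    batch_size, learning_rate, patience, max_epochs, validation_fraction:
        Optimization settings; a tail fraction of the training data is held
        out for early stopping unless an explicit validation set is passed to
        :meth:`fit`.
    min_count:
        Vocabulary frequency threshold.
    random_state:
        Seeds parameter init, shuffling and keyword sampling.

    Attributes
    ----------
    classes_ : ndarray of str
        Sorted class inventory.
    model_ : ClassifierModel
        The trained network.
    vocab_ : Vocabulary
        Token-id map built from the training split.
    keywords_ : KeywordSet or None
        The keyword segments used (extracted or supplied).
    history_ : TrainingHistory
        Per-epoch loss breakdown and validation losses.
    """

    def __init__(
        self,
        mode: str = "baseline",
        keywords: object = "npmi",
        npmi_top_k: int = 10,
        n_c: int = 128,
        k: int = 5,
        alpha: float = 1.0,
        mu: float = 0.15,
        embed_dim: int = 32,
        filters_per_window: int = 32,
        conv_windows: tuple[int, ...] = (3, 4, 5),
        embedding_init: str = "random",
        batch_size: int = 64,
        learning_rate: float = 2e-3,
        patience: int = 5,
        max_epochs: int = 60,
        validation_fraction: float = 0.15,
        min_count: int = 1,
        random_state: int = 0,
    ) -> None:
        self.mode = mode
        self.keywords = keywords
        self.npmi_top_k = npmi_top_k
        self.n_c = n_c
        self.k = k
        self.alpha = alpha
        self.mu = mu
        self.embed_dim = embed_dim
        self.filters_per_window = filters_per_window
        self.conv_windows = conv_windows
        self.embedding_init = embedding_init
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.min_count = min_count
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def fit(
        self,
        X: Sequence[str],
        y: Sequence[str],
        X_val: Sequence[str] | None = None,
        y_val: Sequence[str] | None = None,
    ):
        """Fit on raw texts *X* with labels *y*.

        When ``X_val`` is omitted, the last ``validation_fraction`` of the
        (seed-shuffled) training data is held out for early stopping.
        """
        X = list(X)
        y = [str(label) for label in y]
        if len(X) != len(y):
            raise ValueError("X and y have different lengths")
        labels = sorted(set(y))
        if len(labels) < 2:
            raise ValueError("need at least 2 classes")

        if X_val is None:
            rng = np.random.default_rng((self.random_state, 0))
            order = rng.permutation(len(X))
            n_val = max(1, int(round(len(X) * self.validation_fraction)))
            val_idx = set(order[:n_val].tolist())
            X_tr = [X[i] for i in range(len(X)) if i not in val_idx]
            y_tr = [y[i] for i in range(len(X)) if i not in val_idx]
            X_va = [X[i] for i in sorted(val_idx)]
            y_va = [y[i] for i in sorted(val_idx)]
            if set(y_tr) != set(labels):  # keep every class trainable
                X_tr, y_tr, X_va, y_va = X, y, X, y
        else:
            X_tr, y_tr, X_va, y_va = X, y, list(X_val), list(y_val)

        train_corpus = _corpus_from_xy(X_tr, y_tr, labels, "train")
        val_corpus = _corpus_from_xy(X_va, y_va, labels, "val")
        self.vocab_ = build_vocab(train_corpus, min_count=self.min_count)

        kws: KeywordSet | None = None
        if self.mode == "keywords":
            if isinstance(self.keywords, KeywordSet):
                kws = self.keywords
            elif self.keywords == "npmi":
                kws = top_keywords(compute_npmi(train_corpus), k=self.npmi_top_k)
            else:
                raise ValueError(
                    "keywords must be a KeywordSet or 'npmi' in keywords mode"
                )
        self.keywords_ = kws

        config = ModelConfig(
            embed_dim=self.embed_dim,
            conv_windows=tuple(self.conv_windows),
            filters_per_window=self.filters_per_window,
            n_classes=len(labels),
            vocab_size=len(self.vocab_),
            embedding_init=self.embedding_init,
        )
        model = build_model(
            config,
            self.vocab_,
            seed=self.random_state,
            labels=labels,
            train=train_corpus,
        )
        tconfig = TrainingConfig(
            batch_size=self.batch_size,
            n_c=self.n_c,
            k=self.k,
            alpha=self.alpha,
            mu=self.mu,
            mode=self.mode,
            learning_rate=self.learning_rate,
            patience=self.patience,
            max_epochs=self.max_epochs,
            seed=self.random_state,
        )
        self.model_, self.history_ = train(
            model, train_corpus, val_corpus, self.vocab_, tconfig, keywords=kws
        )
        self.classes_ = np.array(labels)
        self.train_counts_ = train_corpus.class_counts()
        return self

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        """Class-probability rows, columns ordered as ``classes_``."""
        check_is_fitted(self, "model_")
        enc = []
        for text in X:
            tokens = tokenize(text) if isinstance(text, str) else list(text)
            enc.append(encode(tokens, self.vocab_, self.model_.min_len))
        out = []
        for start in range(0, len(enc), 256):
            out.append(score(self.model_, enc[start : start + 256]))
        return np.vstack(out)

    def predict(self, X: Sequence[str]) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]
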