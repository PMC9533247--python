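"""Synthetic imbalanced corpora with planted class-specific keyword signal.

Real cancer-registry pathology corpora are access-restricted, so this module
generates stand-in data with the structural features that matter for the
keyword-augmentation mechanism: a long-tailed (Zipf) class distribution, long
documents dominated by noise tokens, and a small set of signal tokens per
class planted at a controlled rate.  The returned :class:`GroundTruth` names
the planted tokens, giving downstream tests an oracle for keyword recovery
and bigram probing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Corpus, Document, write_corpus

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "support_table"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic corpus generator.

    Class frequencies are proportional to ``rank ** -zipf_exponent`` (rank 1 =
    most common); ``zipf_exponent = 0`` gives a balanced corpus.  Each document
    of class *k* receives each of *k*'s ``signals_per_class`` signal tokens
    independently with probability ``signal_rate``, and each other class's
    signal tokens with probability ``cross_talk``, at uniform-random positions.
    All remaining tokens are uniform draws from a noise vocabulary disjoint
    from the signal tokens.
    """

    n_classes: int = 20
    n_docs: int = 5000
    zipf_exponent: float = 1.5
    doc_len_mean: int = 50
    noise_vocab_size: int = 10000
    signals_per_class: int = 3
    signal_rate: float = 0.8
    cross_talk: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_docs < self.n_classes:
            raise ValueError("n_docs must be >= n_classes")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be >= 0")
        if self.doc_len_mean < 1:
            raise ValueError("doc_len_mean must be >= 1")
        if self.noise_vocab_size < 1:
            raise ValueError("noise_vocab_size must be >= 1")
        if self.signals_per_class < 1:
            raise ValueError("signals_per_class must be >= 1")
        if not 0.0 <= self.signal_rate <= 1.0:
            raise ValueError("signal_rate must be in [0, 1]")
        if not 0.0 <= self.cross_talk < max(self.signal_rate, 1e-12):
            raise ValueError("cross_talk must satisfy 0 <= cross_talk < signal_rate")

    def class_weights(self) -> np.ndarray:
        ranks = np.arange(1, self.n_classes + 1, dtype=float)
        w = ranks ** (-self.zipf_exponent)
        return w / w.sum()


@dataclass
class GroundTruth:
    """Planted signal tokens per class label — the oracle for recovery tests."""

    planted: dict[str, list[str]] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for label in sorted(self.planted):
                for token in self.planted[label]:
                    fh.write(f"{label}\t{token}\n")


def _label_name(k: int) -> str:
    return f"class{k:02d}"


def _signal_token(k: int, j: int) -> str:
    # purely alphanumeric so the token survives the corpus tokenizer
    return f"sig{k}x{j}"


def generate(
    spec: SyntheticSpec,
) -> tuple[Corpus, Corpus, Corpus, GroundTruth]:
    """Generate (train, val, test) corpora and the planted-token ground truth.

    Splits are disjoint 70/15/15 by document, stratified so every class has at
    least one training document.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = [_label_name(k) for k in range(spec.n_classes)]
    weights = spec.class_weights()

    planted = {
        labels[k]: [_signal_token(k, j) for j in range(spec.signals_per_class)]
        for k in range(spec.n_classes)
    }
    noise_vocab = np.array(
        [f"w{i:04d}" for i in range(spec.noise_vocab_size)], dtype=object
    )

    # Draw class assignments; re-draw until every class has >= 1 train doc
    # after the 70/15/15 cut (train gets the first 70% of a permutation).
    n_train = int(round(spec.n_docs * 0.70))
    n_val = int(round(spec.n_docs * 0.15))
    for _ in range(1000):
        classes = rng.choice(spec.n_classes, size=spec.n_docs, p=weights)
        order = rng.permutation(spec.n_docs)
        train_idx = order[:n_train]
        if len(np.unique(classes[train_idx])) == spec.n_classes:
            break
    else:
        raise RuntimeError(
            "could not stratify: some class never reached the train split"
        )
    val_idx = order[n_train : n_train + n_val]
    test_idx = order[n_train + n_val :]

    documents: list[Document] = []
    for i in range(spec.n_docs):
        k = int(classes[i])
        length = max(5, int(rng.poisson(spec.doc_len_mean)))
        tokens = list(rng.choice(noise_vocab, size=length))
        # plant signal tokens: own class at signal_rate, others at cross_talk
        for kk in range(spec.n_classes):
            rate = spec.signal_rate if kk == k else spec.cross_talk
            for token in planted[labels[kk]]:
                if rng.random() < rate:
                    pos = int(rng.integers(0, len(tokens) + 1))
                    tokens.insert(pos, token)
        documents.append(
            Document(doc_id=f"d{i:06d}", tokens=tuple(tokens), label=labels[k])
        )

    def subset(idx: np.ndarray, split: str) -> Corpus:
        return Corpus(
            documents=[documents[i] for i in np.sort(idx)],
            labels=list(labels),
            split=split,
        )

    return (
        subset(train_idx, "train"),
        subset(val_idx, "val"),
        subset(test_idx, "test"),
        GroundTruth(planted=planted),
    )


def support_table(train: Corpus) -> dict[str, int]:
    """Training-document count per class, omitting classes with zero docs."""
    counts: dict[str, int] = {}
    for doc in train.documents:
        counts[doc.label] = counts.get(doc.label, 0) + 1
    return counts


def write_dataset(
    spec: SyntheticSpec, out_dir: str | Path
) -> tuple[Corpus, Corpus, Corpus, GroundTruth]:
    """Generate and write train/val/test JSONL files plus the ground truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train, val, test, truth = generate(spec)
    write_corpus(train, out / "train.jsonl")
    write_corpus(val, out / "val.jsonl")
    write_corpus(test, out / "test.jsonl")
    truth.write(out / "ground_truth.tsv")
    return train, val, test, truth
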