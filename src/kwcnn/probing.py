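"""Bigram probing: what short phrases drive each class of a trained model.

Every contiguous token pair from the training text is padded to the model's
minimum input length and scored; the per-class maxima and top-N lists reveal
whether the model has learned class-specific short phrases.  For rare classes
a low maximum bigram probability is an overfitting symptom: no short phrase in
the whole corpus confidently triggers the class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import Corpus, Vocabulary, encode
from .model import ClassifierModel, score

__all__ = [
    "BigramScoreTable",
    "enumerate_bigrams",
    "score_bigrams",
    "max_bigram_per_class",
    "top_bigrams_for_class",
    "write_probe_report",
]

Bigram = tuple[str, str]


@dataclass
class BigramScoreTable:
    """Unique sorted bigrams and their class-probability rows."""

    bigrams: list[Bigram]
    scores: np.ndarray  # (n_bigrams, n_classes), rows sum to 1
    labels: list[str]


def enumerate_bigrams(train: Corpus) -> list[Bigram]:
    """All contiguous ordered token pairs, deduplicated and sorted.

    A sliding window of size 2 within each document (no skip-grams, no pairs
    across document boundaries); single-token documents contribute nothing.
    """
    seen: set[Bigram] = set()
    for doc in train.documents:
        seen.update(zip(doc.tokens[:-1], doc.tokens[1:]))
    return sorted(seen)


def score_bigrams(
    model: ClassifierModel,
    bigrams: list[Bigram],
    vocab: Vocabulary,
    batch_size: int = 1024,
) -> BigramScoreTable:
    """Score each bigram after padding it to the model's minimum length.

    Bigrams with out-of-vocabulary tokens are still scored (tokens map to the
    unknown id).  Batched for throughput; results are exactly equal to
    one-at-a-time scoring.
    """
    if not bigrams:
        raise ValueError("no bigrams to score")
    rows = []
    for start in range(0, len(bigrams), batch_size):
        chunk = bigrams[start : start + batch_size]
        enc = [encode(list(bg), vocab, model.min_len) for bg in chunk]
        rows.append(score(model, enc))
    return BigramScoreTable(
        bigrams=list(bigrams), scores=np.vstack(rows), labels=list(model.labels)
    )


def top_bigrams_for_class(
    table: BigramScoreTable, label: str, n: int = 5
) -> list[tuple[Bigram, float]]:
    """The *n* highest-probability bigrams for *label*, descending.

    Ties are broken by lexicographic bigram order (the table is sorted, and
    the sort used here is stable).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if label not in table.labels:
        raise ValueError(f"unknown class {label!r}")
    col = table.scores[:, table.labels.index(label)]
    # stable sort on descending probability preserves lexicographic tie order
    order = np.argsort(-col, kind="stable")[:n]
    return [(table.bigrams[i], float(col[i])) for i in order]


def max_bigram_per_class(
    table: BigramScoreTable,
) -> dict[str, tuple[Bigram, float]]:
    """Per class, the argmax bigram and its probability (lexicographic ties)."""
    return {
        label: top_bigrams_for_class(table, label, 1)[0]
        for label in table.labels
    }


def write_probe_report(
    table: BigramScoreTable,
    train_counts: dict[str, int],
    out_path: str | Path,
    max_path: str | Path | None = None,
    top_n: int = 5,
) -> None:
    """Write per-class top-N bigrams (TSV) and per-class max-probability table.

    The max table pairs each class's maximum bigram probability with its
    training support, the raw material for support-vs-confidence plots.
    """
    with Path(out_path).open("w", encoding="utf-8") as fh:
        fh.write("class\trank\tbigram\tprobability\n")
        for label in table.labels:
            for rank, (bg, p) in enumerate(
                top_bigrams_for_class(table, label, top_n), start=1
            ):
                fh.write(f"{label}\t{rank}\t{' '.join(bg)}\t{p:.6f}\n")
    if max_path is not None:
        maxima = max_bigram_per_class(table)
        with Path(max_path).open("w", encoding="utf-8") as fh:
            fh.write("class\ttrain_count\tmax_probability\tbigram\n")
            for label in table.labels:
                bg, p = maxima[label]
                fh.write(
                    f"{label}\t{train_counts.get(label, 0)}\t{p:.6f}\t{' '.join(bg)}\n"
                )
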