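"""Per-class keyword extraction by normalized pointwise mutual information.

Each unigram / contiguous bigram *x* and each class *y* is treated as a binary
per-document random variable (present or not).  With probabilities estimated
as document counts over the total number of training documents,

    NPMI(x, y) = log( p(x,y) / (p(x) p(y)) ) / ( -log p(x,y) )

using natural logarithms.  NPMI lies in [-1, 1]: 1 means perfect
co-occurrence (x appears in exactly the documents of class y), 0 means
independence.  The top-ranked terms per class become the keyword segments fed
to keyword-augmented training.  Alternatively a keyword file (e.g. curated
clinical concept names per class) can be loaded in the same shape.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .corpus import Corpus, tokenize

__all__ = [
    "NpmiEntry",
    "NpmiTable",
    "KeywordSet",
    "compute_npmi",
    "top_keywords",
    "load_keyword_file",
    "write_npmi_table",
    "write_keyword_file",
]

logger = logging.getLogger(__name__)

Term = tuple[str, ...]  # unigram ("t",) or bigram ("t", "u")


@dataclass(frozen=True)
class NpmiEntry:
    p_x: float
    p_y: float
    p_xy: float
    npmi: float


@dataclass
class NpmiTable:
    """NPMI statistics for every (term, class) pair with p(x,y) > 0.

    Pairs that never co-occur are omitted: their NPMI tends to -1 and they can
    never be keywords, so omission keeps the table sparse.
    """

    entries: dict[tuple[Term, str], NpmiEntry] = field(default_factory=dict)
    labels: list[str] = field(default_factory=list)

    def terms_for_class(self, label: str) -> list[tuple[Term, NpmiEntry]]:
        return [
            (term, e) for (term, y), e in self.entries.items() if y == label
        ]


@dataclass
class KeywordSet:
    """Keyword segments per class; each segment is a non-empty token tuple."""

    segments: dict[str, list[Term]] = field(default_factory=dict)
    source: str = "npmi"

    def nonempty_labels(self) -> list[str]:
        return sorted(l for l, segs in self.segments.items() if segs)


def _doc_terms(tokens: Sequence[str]) -> set[Term]:
    """Unigrams and contiguous bigrams present in a document (binary presence)."""
    terms: set[Term] = {(t,) for t in tokens}
    terms.update(zip(tokens[:-1], tokens[1:]))
    return terms


def _npmi(p_x: float, p_y: float, p_xy: float) -> float:
    if p_xy >= 1.0:
        # term and class in every document: log ratio and -log p_xy both 0
        return 1.0
    return math.log(p_xy / (p_x * p_y)) / (-math.log(p_xy))


def compute_npmi(train: Corpus) -> NpmiTable:
    """NPMI of every unigram/bigram against every class it co-occurs with.

    Presence is per-document binary: multiple occurrences of a term within one
    document count once.  Probabilities are document counts divided by the
    total number of training documents; no smoothing.
    """
    if not train.documents:
        raise ValueError("cannot compute NPMI on an empty corpus")
    n = len(train.documents)
    term_count: dict[Term, int] = {}
    joint_count: dict[tuple[Term, str], int] = {}
    class_count: dict[str, int] = {}
    for doc in train.documents:
        class_count[doc.label] = class_count.get(doc.label, 0) + 1
        for term in _doc_terms(doc.tokens):
            term_count[term] = term_count.get(term, 0) + 1
            key = (term, doc.label)
            joint_count[key] = joint_count.get(key, 0) + 1

    entries: dict[tuple[Term, str], NpmiEntry] = {}
    for (term, label), c_xy in joint_count.items():
        p_x = term_count[term] / n
        p_y = class_count[label] / n
        p_xy = c_xy / n
        entries[(term, label)] = NpmiEntry(
            p_x=p_x, p_y=p_y, p_xy=p_xy, npmi=_npmi(p_x, p_y, p_xy)
        )
    return NpmiTable(entries=entries, labels=list(train.labels))


def top_keywords(
    table: NpmiTable, k: int = 10, per_length: bool = True
) -> KeywordSet:
    """Rank terms by NPMI per class and keep the top *k*.

    With ``per_length=True`` (default) the top *k* unigrams AND the top *k*
    bigrams are kept per class, up to ``2k`` segments; with ``False`` the top
    *k* terms overall.  Ranking is by descending NPMI with lexicographic
    tie-break on the term.  Classes with no co-occurring terms get an empty
    list and a logged warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    segments: dict[str, list[Term]] = {}
    for label in table.labels:
        ranked = sorted(
            table.terms_for_class(label), key=lambda te: (-te[1].npmi, te[0])
        )
        if per_length:
            unis = [t for t, _ in ranked if len(t) == 1][:k]
            bis = [t for t, _ in ranked if len(t) == 2][:k]
            chosen = unis + bis
        else:
            chosen = [t for t, _ in ranked[:k]]
        if not chosen:
            logger.warning("class %r has no co-occurring terms; empty keywords", label)
        segments[label] = chosen
    return KeywordSet(segments=segments, source="npmi")


def load_keyword_file(path: str | Path, labels: Sequence[str]) -> KeywordSet:
    """Load per-class keyword segments from a TSV file (class TAB segment text).

    Stands in for externally curated keyword sources such as clinical-concept
    dictionaries.  Segment text is run through the corpus tokenizer.  Rows with
    labels outside *labels* are skipped with a warning; duplicate rows are
    retained (their sampling weight doubles); classes absent from the file get
    empty lists with a warning.  Lines starting with ``#`` are comments.
    """
    inventory = set(labels)
    segments: dict[str, list[Term]] = {label: [] for label in labels}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'class<TAB>segment', got {line!r}"
                )
            label, text = parts
            if label not in inventory:
                logger.warning(
                    "%s:%d: label %r not in inventory; row skipped",
                    path, lineno, label,
                )
                continue
            tokens = tuple(tokenize(text))
            if not tokens:
                logger.warning("%s:%d: segment tokenizes to nothing; skipped",
                               path, lineno)
                continue
            segments[label].append(tokens)
    for label in labels:
        if not segments[label]:
            logger.warning("class %r has no keywords in %s", label, path)
    return KeywordSet(segments=segments, source="file")


def write_npmi_table(table: NpmiTable, path: str | Path) -> None:
    """Export the table as TSV (class, term, p_x, p_y, p_xy, npmi)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("class\tterm\tp_x\tp_y\tp_xy\tnpmi\n")
        for label in table.labels:
            ranked = sorted(
                table.terms_for_class(label), key=lambda te: (-te[1].npmi, te[0])
            )
            for term, e in ranked:
                fh.write(
                    f"{label}\t{' '.join(term)}\t{e.p_x:.10g}\t{e.p_y:.10g}"
                    f"\t{e.p_xy:.10g}\t{e.npmi:.10g}\n"
                )


def write_keyword_file(keywords: KeywordSet, path: str | Path) -> None:
    """Write a KeywordSet in the TSV dialect read by :func:`load_keyword_file`."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for label in sorted(keywords.segments):
            for seg in keywords.segments[label]:
                fh.write(f"{label}\t{' '.join(seg)}\n")
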