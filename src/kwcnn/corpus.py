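"""Labeled text corpora: reading, tokenization, vocabulary and integer encoding.

A :class:`Corpus` is the universe over which keyword statistics, training and
bigram probing operate.  Documents carry exactly one class label each (one
classification task at a time, e.g. cancer site *or* histology).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Document",
    "Corpus",
    "Vocabulary",
    "tokenize",
    "load_corpus",
    "write_corpus",
    "build_vocab",
    "encode",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"


def tokenize(text: str) -> list[str]:
    """Lowercase and split *text* into alphanumeric token spans.

    Any run of non-alphanumeric characters is a separator, so ``"C69.1"``
    yields ``["c69", "1"]``.  Deterministic; may return an empty list.
    """
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class Document:
    """One labeled document: an id, a token list and a single class label."""

    doc_id: str
    tokens: tuple[str, ...]
    label: str

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError(f"document {self.doc_id!r} has no tokens")


@dataclass
class Corpus:
    """A split of labeled documents plus the ordered class-label inventory.

    ``labels`` is the task's class inventory; for a train split it is derived
    from the documents, for val/test splits it is inherited from train so that
    classes the classifier can emit are fixed.
    """

    documents: list[Document]
    labels: list[str]
    split: str = "train"

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in inventory")
        inventory = set(self.labels)
        for doc in self.documents:
            if doc.label not in inventory:
                raise ValueError(
                    f"document {doc.doc_id!r} has label {doc.label!r} "
                    "outside the corpus label inventory"
                )

    def __len__(self) -> int:
        return len(self.documents)

    def class_counts(self) -> dict[str, int]:
        """Number of documents per class (classes with zero docs included)."""
        counts = {label: 0 for label in self.labels}
        for doc in self.documents:
            counts[doc.label] += 1
        return counts


@dataclass
class Vocabulary:
    """Injective token→id map with reserved pad and unk ids.

    ``pad_id`` is 0 so that embedding row 0 can be held at zero; real tokens
    start at 2.  Ids are contiguous from 0.
    """

    token_to_id: dict[str, int] = field(default_factory=dict)
    pad_id: int = 0
    unk_id: int = 1

    def __len__(self) -> int:
        return len(self.token_to_id) + 2

    def __getitem__(self, token: str) -> int:
        return self.token_to_id.get(token, self.unk_id)

    def content_hash(self) -> str:
        """Order-sensitive hash of the vocabulary, for checkpoint validation."""
        import hashlib

        h = hashlib.sha256()
        for token, idx in sorted(self.token_to_id.items()):
            h.update(f"{token}\t{idx}\n".encode())
        return h.hexdigest()


def _records_from_jsonl(path: Path) -> Iterable[tuple[str, str, str]]:
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            if "text" not in obj or "label" not in obj:
                raise ValueError(
                    f"{path}:{lineno}: record missing 'text' or 'label' field"
                )
            yield str(obj.get("id", lineno)), str(obj["text"]), str(obj["label"])


def _records_from_tsv(path: Path) -> Iterable[tuple[str, str, str]]:
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            yield str(lineno), parts[0], parts[1]


def load_corpus(
    path: str | Path,
    fmt: str | None = None,
    split: str = "train",
    labels: Sequence[str] | None = None,
) -> Corpus:
    """Read a labeled corpus from JSONL or TSV.

    Parameters
    ----------
    path:
        File to read.  JSONL records are objects with ``text`` and ``label``
        (and optional ``id``) keys; TSV rows are ``text TAB label``.
    fmt:
        ``"jsonl"`` or ``"tsv"``; inferred from the file suffix when omitted.
    split:
        Which split this file represents (train/val/test).
    labels:
        Fixed label inventory for non-train splits.  When omitted the
        inventory is the lexicographically sorted set of labels seen in the
        file.  Documents with labels outside a supplied inventory raise.
    """
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in {".tsv", ".txt"} else "jsonl"
    if fmt == "jsonl":
        records = _records_from_jsonl(path)
    elif fmt == "tsv":
        records = _records_from_tsv(path)
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")

    documents: list[Document] = []
    for doc_id, text, label in records:
        tokens = tuple(tokenize(text))
        if not tokens:
            raise ValueError(
                f"{path}: record {doc_id!r} tokenizes to zero tokens"
            )
        documents.append(Document(doc_id=doc_id, tokens=tokens, label=label))
    if not documents:
        raise ValueError(f"{path}: corpus file is empty")

    if labels is None:
        inventory = sorted({d.label for d in documents})
    else:
        inventory = list(labels)
    return Corpus(documents=documents, labels=inventory, split=split)


def write_corpus(corpus: Corpus, path: str | Path, fmt: str = "jsonl") -> None:
    """Write *corpus* in the JSONL or TSV dialect read by :func:`load_corpus`.

    Output is byte-identical for equal corpora (keys and order are fixed).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            text = " ".join(doc.tokens)
            if fmt == "jsonl":
                fh.write(
                    json.dumps(
                        {"id": doc.doc_id, "text": text, "label": doc.label},
                        sort_keys=True,
                    )
                    + "\n"
                )
            elif fmt == "tsv":
                fh.write(f"{text}\t{doc.label}\n")
            else:
                raise ValueError(f"unknown corpus format {fmt!r}")


def build_vocab(corpus: Corpus, min_count: int = 1) -> Vocabulary:
    """Build the token→id map from a training corpus.

    Every token occurring at least *min_count* times gets an id; rarer tokens
    encode to ``unk_id``.  Ids are assigned in descending frequency order with
    lexicographic tie-break, starting at 2 (0 = pad, 1 = unk).
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    if corpus.split != "train":
        raise ValueError("vocabulary must be built from the train split")
    freq: dict[str, int] = {}
    for doc in corpus.documents:
        for token in doc.tokens:
            freq[token] = freq.get(token, 0) + 1
    kept = sorted(
        (t for t, c in freq.items() if c >= min_count),
        key=lambda t: (-freq[t], t),
    )
    return Vocabulary(token_to_id={t: i + 2 for i, t in enumerate(kept)})


def encode(
    doc_tokens: Sequence[str], vocab: Vocabulary, min_len: int = 5
) -> list[int]:
    """Map tokens to ids, padding at the end up to *min_len*.

    Output length is ``max(len(doc_tokens), min_len)``; unknown tokens map to
    ``vocab.unk_id`` and padding uses ``vocab.pad_id``.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    ids = [vocab[t] for t in doc_tokens]
    if len(ids) < min_len:
        ids.extend([vocab.pad_id] * (min_len - len(ids)))
    return ids
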