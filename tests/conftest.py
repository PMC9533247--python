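import numpy as np
import pytest

from kwcnn.corpus import Corpus, Document, build_vocab


def make_corpus(docs: list[tuple[str, list[str]]], split: str = "train") -> Corpus:
    """Corpus from (label, tokens) pairs with auto ids and sorted inventory."""
    documents = [
        Document(doc_id=f"d{i}", tokens=tuple(toks), label=label)
        for i, (label, toks) in enumerate(docs)
    ]
    labels = sorted({label for label, _ in docs})
    return Corpus(documents=documents, labels=labels, split=split)


@pytest.fixture
def four_doc_corpus() -> Corpus:
    """d1(A:{t}), d2(A:{t}), d3(B:{u}), d4(B:{t,u}) — the NPMI hand case."""
    return make_corpus(
        [("A", ["t"]), ("A", ["t"]), ("B", ["u"]), ("B", ["t", "u"])]
    )


@pytest.fixture
def small_labeled_corpus() -> Corpus:
    rng = np.random.default_rng(42)
    vocab = [f"w{i}" for i in range(30)]
    docs = []
    for i in range(60):
        label = "pos" if i % 3 == 0 else "neg"
        toks = list(rng.choice(vocab, size=8))
        toks.append("good" if label == "pos" else "bad")
        docs.append((label, toks))
    return make_corpus(docs)


@pytest.fixture
def small_vocab(small_labeled_corpus):
    return build_vocab(small_labeled_corpus)
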