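# kwcnn — keyword-augmented CNN training for imbalanced text classification

Long-tailed label distributions are the norm in clinical text classification:
a handful of classes dominate the corpus while many classes have only a few
training documents, and classifiers overfit those rare classes badly. `kwcnn`
implements a *data-centered* remedy: a small set of keywords per class —
extracted automatically from the training corpus by normalized pointwise
mutual information (NPMI), or loaded from a curated file — is injected into
every training update as synthetic "keyword documents" with a weighted
auxiliary loss. This boosts rare-class (macro) performance without the
well-represented-class penalty that class-weighted losses incur.

The package is aimed at practitioners working with long, noisy, imbalanced
document corpora (the motivating case is cancer-registry pathology reports
labeled with ICD-O-3 site/subsite/histology codes, which are access-restricted;
a synthetic-corpus generator with planted class signal stands in for them).

## Method

**Keyword extraction.** Treat each unigram/contiguous-bigram *x* and each
class *y* as binary per-document random variables, with probabilities
estimated as document counts over the number of training documents *N*:

    NPMI(x, y) = log( p(x,y) / (p(x) p(y)) ) / ( −log p(x,y) )   ∈ [−1, 1]

The top-10 unigrams and top-10 bigrams per class become its keyword segments.

**Keyword-augmented update.** Each training update:

1. compute cross-entropy loss `L_docs` on the document mini-batch;
2. sample `min(N_C, C)` classes; per class draw `K` keyword segments with
   replacement and concatenate them into one keyword document;
3. compute cross-entropy loss `L_key` on the keyword batch;
4. back-propagate `L = L_docs + α·L_key`.

Defaults `N_C = 128`, `K = 5`, `α = 1`.

**Class-weight baseline.** For comparison, per-class loss weights
`w_i = max(1, log(μ·Σc/c_i))` with `μ = 0.15`.

**Classifier.** A word-level CNN: trainable word embeddings feed three
parallel 1-D convolutions (window sizes 3/4/5), each max-pooled over time;
the concatenated document embedding feeds a softmax layer. Trained with Adam
and validation-loss early stopping (patience 5). The network, backprop and
optimizer are implemented in NumPy, making runs exactly reproducible from a
seed on any CPU.

**Diagnostics.** Micro/macro F1 plus test accuracy binned by the true class's
training support (0–50, 50–500, 500–5000, ≥5000 documents), and a bigram
probe: every contiguous token pair of the training text is padded to the
model's minimum input length and scored, revealing the short phrases that
maximally activate each class.

## Worked example

```python
import numpy as np
from kwcnn import CnnTextClassifier, SyntheticSpec, generate

train, val, test, truth = generate(SyntheticSpec(seed=11))
to_text = lambda c: ([" ".join(d.tokens) for d in c.documents],
                     [d.label for d in c.documents])
X_tr, y_tr = to_text(train); X_va, y_va = to_text(val); X_te, y_te = to_text(test)

for mode in ("baseline", "keywords"):
    clf = CnnTextClassifier(mode=mode, random_state=11)
    clf.fit(X_tr, y_tr, X_val=X_va, y_val=y_va)
    from kwcnn import evaluate
    rep = evaluate(y_te, list(clf.predict(X_te)), list(clf.classes_))
    print(f"{mode}: micro={rep.micro_f1:.3f} macro={rep.macro_f1:.3f}")
```

Output:

```
baseline: micro=0.941 macro=0.763
keywords: micro=0.955 macro=0.827
```

Micro F1 (= accuracy) is essentially unchanged, while macro F1 — which weighs
every class equally, including the rare ones — rises by six points: the
keyword documents give the model direct evidence for classes with only a
dozen training documents.

The same pipeline is available from the shell:

```bash
kwcnn simulate --seed 11 --out-dir data/
kwcnn extract-keywords --corpus data/train.jsonl --k 10 --out keywords.tsv
kwcnn train --corpus-dir data/ --mode keywords --keywords keywords.tsv \
            --seed 11 --out model.ckpt
kwcnn evaluate --model model.ckpt --corpus data/test.jsonl \
               --train-corpus data/train.jsonl --out report.json
kwcnn probe-bigrams --model model.ckpt --train-corpus data/train.jsonl \
                    --top 5 --out probe.tsv
```

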