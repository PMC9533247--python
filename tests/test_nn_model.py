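"""Correctness of the NumPy CNN: gradients against finite differences,
softmax/simplex contracts, determinism, maxpool position invariance, and
checkpoint round-trips."""

import numpy as np
import pytest

from kwcnn.corpus import Vocabulary, build_vocab, encode
from kwcnn.model import (
    ClassifierModel,
    ModelConfig,
    build_model,
    load_model,
    pad_batch,
    pretrain_skipgram,
    save_model,
    score,
)
from .conftest import make_corpus


def tiny_vocab(n_tokens=12):
    return Vocabulary(token_to_id={f"t{i}": i + 2 for i in range(n_tokens)})


def tiny_model(seed=0, n_classes=3, vocab=None, windows=(2, 3)):
    vocab = vocab or tiny_vocab()
    config = ModelConfig(
        embed_dim=5,
        conv_windows=windows,
        filters_per_window=4,
        n_classes=n_classes,
        vocab_size=len(vocab),
    )
    return build_model(config, vocab, seed=seed, labels=[f"c{i}" for i in range(n_classes)]), vocab


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences on every
        parameter tensor, for a batch with variable lengths and weights."""
        model, vocab = tiny_model(seed=3)
        net = model.net
        rng = np.random.default_rng(0)
        seqs = [
            [2, 3, 4, 5, 6],
            [7, 8, 9, 0, 0],  # padded short doc
            [2, 9, 3, 8, 4, 5, 10],
        ]
        ids, lens = pad_batch(seqs, 0)
        y = np.array([0, 1, 2])
        sw = np.array([1.0, 2.5, 0.7])

        def loss_at():
            return net.loss_and_grads(ids, lens, y, sample_weights=sw)[0]

        _, grads = net.loss_and_grads(ids, lens, y, sample_weights=sw)
        eps = 1e-6
        d = net.embed_dim
        for name, arr in net.params.arrays.items():
            flat = arr.ravel()
            # probe a handful of coordinates per tensor
            idxs = rng.choice(flat.size, size=min(12, flat.size), replace=False)
            for i in idxs:
                if name == "emb" and i < d:
                    continue  # pad row is frozen by design; no gradient

                orig = flat[i]
                flat[i] = orig + eps
                lp = loss_at()
                flat[i] = orig - eps
                lm = loss_at()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name].ravel()[i]
                assert ana == pytest.approx(num, abs=1e-6), f"{name}[{i}]"

    def test_pad_row_never_updated(self):
        model, vocab = tiny_model()
        net = model.net
        ids, lens = pad_batch([[2, 3, 4, 0, 0]], 0)
        _, grads = net.loss_and_grads(ids, lens, np.array([1]))
        assert np.all(grads["emb"][0] == 0.0)
        from kwcnn.nn import Adam

        opt = Adam(lr=0.1)
        opt.step(net.params, grads)
        assert np.all(net.params.arrays["emb"][0] == 0.0)


class TestBuildModel:
    def test_seed_determinism(self):
        m1, v = tiny_model(seed=42)
        m2, _ = tiny_model(seed=42, vocab=v)
        for k in m1.net.params.arrays:
            assert np.array_equal(m1.net.params.arrays[k], m2.net.params.arrays[k])

    def test_document_embedding_dimension(self):
        config = ModelConfig(
            embed_dim=300, conv_windows=(3, 4, 5), filters_per_window=300,
            n_classes=5, vocab_size=10,
        )
        assert config.doc_embedding_dim == 900
        assert config.min_len == 5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_classes=1, vocab_size=10)

    def test_vocab_size_mismatch_rejected(self):
        vocab = tiny_vocab()
        config = ModelConfig(n_classes=2, vocab_size=999, embed_dim=4,
                             filters_per_window=2)
        with pytest.raises(ValueError):
            build_model(config, vocab, seed=0, labels=["a", "b"])

    def test_word2vec_init_differs_from_random_and_is_deterministic(self):
        corpus = make_corpus(
            [("A", ["t0", "t1", "t2"]), ("B", ["t3", "t4", "t5"])] * 3
        )
        vocab = build_vocab(corpus)
        config = ModelConfig(
            embed_dim=5, conv_windows=(2, 3), filters_per_window=4,
            n_classes=2, vocab_size=len(vocab), embedding_init="word2vec",
        )
        m1 = build_model(config, vocab, seed=1, labels=["A", "B"], train=corpus)
        m2 = build_model(config, vocab, seed=1, labels=["A", "B"], train=corpus)
        assert np.array_equal(m1.net.params.arrays["emb"], m2.net.params.arrays["emb"])
        rnd = build_model(
            ModelConfig(embed_dim=5, conv_windows=(2, 3), filters_per_window=4,
                        n_classes=2, vocab_size=len(vocab)),
            vocab, seed=1, labels=["A", "B"],
        )
        assert not np.array_equal(
            m1.net.params.arrays["emb"], rnd.net.params.arrays["emb"]
        )
        assert np.all(m1.net.params.arrays["emb"][vocab.pad_id] == 0.0)

    def test_word2vec_requires_corpus(self):
        vocab = tiny_vocab()
        config = ModelConfig(embed_dim=4, conv_windows=(2,), filters_per_window=2,
                             n_classes=2, vocab_size=len(vocab),
                             embedding_init="word2vec")
        with pytest.raises(ValueError):
            build_model(config, vocab, seed=0, labels=["a", "b"])


class TestScore:
    def test_rows_are_probability_simplexes(self):
        model, _ = tiny_model()
        probs = score(model, [[2, 3, 4], [5, 6, 7], [2, 2, 2]])
        assert probs.shape == (3, 3)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_rows_identical_and_order_preserved(self):
        model, _ = tiny_model()
        probs = score(model, [[2, 3, 4], [5, 6, 7], [2, 3, 4]])
        assert np.array_equal(probs[0], probs[2])

    def test_too_short_sequence_instructs_padding(self):
        model, _ = tiny_model()  # min_len = 3
        with pytest.raises(ValueError, match="pad|min"):
            score(model, [[2, 3]])

    def test_consecutive_calls_agree_exactly(self):
        model, _ = tiny_model()
        batch = [[2, 3, 4, 5], [6, 7, 8, 9]]
        assert np.array_equal(score(model, batch), score(model, batch))

    def test_batched_equals_single(self):
        """Mixed-length batching must reproduce one-at-a-time scores exactly."""
        model, _ = tiny_model(seed=5)
        seqs = [[2, 3, 4], [5, 6, 7, 8, 9, 10], [11, 12, 13, 2], [3, 3, 3]]
        batched = score(model, seqs)
        singles = np.vstack([score(model, [s]) for s in seqs])
        assert np.array_equal(batched, singles)

    def test_position_invariance_of_span_in_pad_context(self):
        """Maxpool-over-time: translating a token span inside a long pad-only
        context does not change the score (span kept >= max window - 1 away
        from both sequence ends so identical window sets arise)."""
        model, vocab = tiny_model(seed=8)
        w = model.min_len  # 3
        T = 14
        span = [4, 5]
        scores = []
        for start in (w - 1, w + 2, T - (w - 1) - len(span)):
            seq = [vocab.pad_id] * T
            seq[start : start + len(span)] = span
            scores.append(score(model, [seq])[0])
        np.testing.assert_allclose(scores[0], scores[1], atol=1e-5)
        np.testing.assert_allclose(scores[0], scores[2], atol=1e-5)

    def test_untrained_pad_only_near_uniform(self):
        """With symmetric random init, a pad-only input scores near-uniform."""
        spreads = []
        for seed in range(10):
            model, vocab = tiny_model(seed=seed, n_classes=4)
            p = score(model, [[vocab.pad_id] * 6])[0]
            spreads.append(p.max() - p.min())
        assert max(spreads) < 0.1


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        model, vocab = tiny_model(seed=13)
        path = tmp_path / "model.ckpt"
        save_model(model, vocab, path)
        back = load_model(path, vocab)
        batch = [[2, 3, 4, 5]]
        assert np.array_equal(score(model, batch), score(back, batch))
        assert back.labels == model.labels

    def test_vocab_hash_verified(self, tmp_path):
        model, vocab = tiny_model(seed=13)
        path = tmp_path / "model.ckpt"
        save_model(model, vocab, path)
        other = tiny_vocab(n_tokens=5)
        with pytest.raises(ValueError, match="vocab"):
            load_model(path, other)
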