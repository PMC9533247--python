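"""Training-loop contracts: class-weight formula, keyword batch sampling,
loss decomposition, early stopping, and seed reproducibility."""

import math

import numpy as np
import pytest

from kwcnn.corpus import build_vocab
from kwcnn.keywords import KeywordSet, compute_npmi, top_keywords
from kwcnn.model import ModelConfig, build_model
from kwcnn.synthetic import SyntheticSpec, generate
from kwcnn.training import (
    TrainingConfig,
    class_weights,
    sample_keyword_batch,
    train,
)
from .conftest import make_corpus


class TestClassWeights:
    def test_hand_case(self):
        w = class_weights({"A": 10, "B": 500, "C": 490}, mu=0.15).weights
        assert w["A"] == pytest.approx(math.log(15.0), abs=1e-12)
        assert w["B"] == 1.0
        assert w["C"] == 1.0

    def test_clamp_boundary(self):
        # c_i = mu * total exactly -> log term 0 -> clamped to 1
        w = class_weights({"A": 15, "B": 85}, mu=0.15).weights
        assert w["A"] == 1.0

    def test_oracle_on_random_counts(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            counts = {f"c{i}": int(rng.integers(1, 1000)) for i in range(n)}
            mu = float(rng.uniform(0.01, 1.5))
            got = class_weights(counts, mu=mu).weights
            total = sum(counts.values())
            for label, c in counts.items():
                expected = max(1.0, math.log(mu * total / c))
                assert got[label] == pytest.approx(expected, abs=1e-12)
                assert got[label] >= 1.0

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            class_weights({"A": 0, "B": 5})

    def test_default_mu(self):
        import inspect

        assert inspect.signature(class_weights).parameters["mu"].default == 0.15
        assert TrainingConfig().mu == 0.15


class TestSampleKeywordBatch:
    def kws(self, n_classes=20):
        return KeywordSet(
            segments={f"c{i}": [(f"s{i}a",), (f"s{i}b", f"s{i}c")] for i in range(n_classes)}
        )

    def test_min_nc_c_branch(self):
        rng = np.random.default_rng(0)
        batch = sample_keyword_batch(self.kws(20), n_c=128, k=5, rng=rng)
        assert len(batch) == 20
        assert sorted(l for _, l in batch) == sorted(f"c{i}" for i in range(20))

    def test_nc_smaller_than_c(self):
        rng = np.random.default_rng(0)
        batch = sample_keyword_batch(self.kws(20), n_c=7, k=2, rng=rng)
        assert len(batch) == 7
        assert len({l for _, l in batch}) == 7  # distinct classes

    def test_single_segment_repeated_k_times(self):
        ks = KeywordSet(segments={"A": [("tok",)], "B": [("x",)]})
        rng = np.random.default_rng(0)
        batch = sample_keyword_batch(ks, n_c=2, k=5, rng=rng)
        doc = dict((l, t) for t, l in batch)["A"]
        assert doc == ["tok"] * 5

    def test_segments_concatenated_in_drawn_order(self):
        ks = KeywordSet(segments={"A": [("a", "b")], "B": [("z",)]})
        rng = np.random.default_rng(0)
        batch = sample_keyword_batch(ks, n_c=2, k=3, rng=rng)
        doc = dict((l, t) for t, l in batch)["A"]
        assert doc == ["a", "b"] * 3

    def test_empty_classes_skipped(self):
        ks = KeywordSet(segments={"A": [("x",)], "B": []})
        rng = np.random.default_rng(0)
        batch = sample_keyword_batch(ks, n_c=5, k=2, rng=rng)
        assert [l for _, l in batch] == ["A"]

    def test_all_empty_rejected(self):
        ks = KeywordSet(segments={"A": [], "B": []})
        with pytest.raises(ValueError):
            sample_keyword_batch(ks, n_c=2, k=2, rng=np.random.default_rng(0))

    def test_class_coverage_over_many_draws(self):
        """With n_c >= C every non-empty class appears exactly once per batch."""
        ks = self.kws(6)
        rng = np.random.default_rng(123)
        for _ in range(1000):
            batch = sample_keyword_batch(ks, n_c=10, k=1, rng=rng)
            labels = [l for _, l in batch]
            assert sorted(labels) == sorted(ks.segments)

    def test_full_scale_defaults(self):
        cfg = TrainingConfig()
        assert cfg.n_c == 128 and cfg.k == 5 and cfg.alpha == 1.0
        assert cfg.batch_size == 128 and cfg.learning_rate == 1e-4
        assert cfg.patience == 5


@pytest.fixture(scope="module")
def small_setup():
    spec = SyntheticSpec(
        n_classes=5, n_docs=300, doc_len_mean=15, noise_vocab_size=300, seed=5
    )
    tr, va, _, _ = generate(spec)
    vocab = build_vocab(tr)
    kws = top_keywords(compute_npmi(tr), k=3)
    return tr, va, vocab, kws


def small_model(vocab, tr, seed):
    config = ModelConfig(
        embed_dim=8, conv_windows=(2, 3), filters_per_window=8,
        n_classes=len(tr.labels), vocab_size=len(vocab),
    )
    return build_model(config, vocab, seed=seed, labels=tr.labels)


def run_training(small_setup, mode, seed=3, alpha=1.0, max_epochs=4, patience=2):
    tr, va, vocab, kws = small_setup
    model = small_model(vocab, tr, seed)
    cfg = TrainingConfig(
        batch_size=32, n_c=8, k=3, alpha=alpha, mode=mode,
        learning_rate=1e-3, patience=patience, max_epochs=max_epochs, seed=seed,
    )
    return train(model, tr, va, vocab, cfg,
                 keywords=kws if mode == "keywords" else None)


class TestTrainLoop:
    def test_alpha_zero_equals_baseline_bitwise(self, small_setup):
        """Keyword RNG isolation: alpha=0 keyword training is bit-identical to
        baseline with the same seed."""
        m_base, _ = run_training(small_setup, "baseline")
        m_kw, h_kw = run_training(small_setup, "keywords", alpha=0.0)
        for k in m_base.net.params.arrays:
            assert np.array_equal(
                m_base.net.params.arrays[k], m_kw.net.params.arrays[k]
            ), k
        # the keyword loss is still recorded
        assert all(e.l_key > 0 for e in h_kw.epochs)

    def test_loss_decomposition_exact(self, small_setup):
        _, hist = run_training(small_setup, "keywords", alpha=0.7)
        for e in hist.epochs:
            assert e.l_total == e.l_docs + 0.7 * e.l_key

    def test_baseline_and_class_weights_have_zero_l_key(self, small_setup):
        for mode in ("baseline", "class_weights"):
            _, hist = run_training(small_setup, mode)
            assert all(e.l_key == 0.0 for e in hist.epochs)
            assert all(e.l_total == e.l_docs for e in hist.epochs)

    def test_reproducibility(self, small_setup):
        m1, h1 = run_training(small_setup, "keywords", seed=9)
        m2, h2 = run_training(small_setup, "keywords", seed=9)
        assert h1.val_loss == h2.val_loss
        assert [e.l_total for e in h1.epochs] == [e.l_total for e in h2.epochs]
        for k in m1.net.params.arrays:
            assert np.array_equal(m1.net.params.arrays[k], m2.net.params.arrays[k])

    def test_different_seed_differs(self, small_setup):
        _, h1 = run_training(small_setup, "baseline", seed=1)
        _, h2 = run_training(small_setup, "baseline", seed=2)
        assert h1.val_loss != h2.val_loss

    def test_early_stopping_bounds_epochs(self, small_setup):
        tr, va, vocab, _ = small_setup
        model = small_model(vocab, tr, seed=0)
        cfg = TrainingConfig(
            batch_size=32, mode="baseline", learning_rate=0.0,  # loss never improves
            patience=2, max_epochs=50, seed=0,
        )
        _, hist = train(model, tr, va, vocab, cfg)
        assert len(hist.val_loss) <= hist.best_epoch + 1 + cfg.patience
        assert len(hist.val_loss) < 50

    def test_best_epoch_params_returned(self, small_setup):
        model, hist = run_training(small_setup, "baseline", max_epochs=6, patience=5)
        assert min(hist.val_loss) == hist.val_loss[hist.best_epoch]

    def test_keywords_mode_requires_keywords(self, small_setup):
        tr, va, vocab, _ = small_setup
        model = small_model(vocab, tr, seed=0)
        cfg = TrainingConfig(mode="keywords", seed=0)
        with pytest.raises(ValueError, match="[Kk]eyword"):
            train(model, tr, va, vocab, cfg)

    def test_empty_train_rejected(self, small_setup):
        tr, va, vocab, _ = small_setup
        from kwcnn.corpus import Corpus

        model = small_model(vocab, tr, seed=0)
        empty = Corpus(documents=[], labels=tr.labels, split="train")
        with pytest.raises(ValueError, match="empty"):
            train(model, empty, va, vocab, TrainingConfig(seed=0))


class TestTrainingConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mode": "bogus"},
            {"alpha": -0.1},
            {"k": 0},
            {"n_c": 0},
            {"patience": 0},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            TrainingConfig(**kwargs)
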