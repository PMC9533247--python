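"""A word-level CNN text classifier implemented directly in NumPy.

Architecture: trainable word embeddings feed parallel 1D convolution layers
(one per window size), each followed by ReLU and maxpool-over-time; the pooled
feature vectors are concatenated into a document embedding and fed to a
softmax output layer.  Forward, backward and the Adam optimizer are written
against plain ``numpy.ndarray`` parameters, which keeps training exactly
reproducible from a seed on any CPU.

Variable-length batches are padded to the batch maximum; convolution windows
that extend past a sequence's own (already padding-inclusive) encoded length
are masked out of the maxpool, so batched scoring is exactly equal to
one-sequence-at-a-time scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CnnParams", "WordCnn", "Adam"]


@dataclass
class CnnParams:
    """Flat dict of named parameter arrays plus the frozen pad row index."""

    arrays: dict[str, np.ndarray]
    pad_id: int

    def copy(self) -> "CnnParams":
        return CnnParams(
            arrays={k: v.copy() for k, v in self.arrays.items()},
            pad_id=self.pad_id,
        )


class WordCnn:
    """Embedding + parallel conv/maxpool + softmax, with manual backprop.

    Parameters
    ----------
    vocab_size, n_classes:
        Sizes of the embedding table and the output layer.
    embed_dim, filters, windows:
        Embedding width, filters per convolution, and the window sizes of the
        parallel convolutions.  The document embedding has size
        ``filters * len(windows)``.
    seed:
        Seeds parameter initialization (embeddings uniform in
        ``±0.5/embed_dim``, conv and output layers Glorot-uniform).  The pad
        embedding row is fixed at zero and excluded from updates.
    """

    def __init__(
        self,
        vocab_size: int,
        n_classes: int,
        embed_dim: int = 300,
        filters: int = 300,
        windows: tuple[int, ...] = (3, 4, 5),
        pad_id: int = 0,
        seed: int = 0,
        embeddings: np.ndarray | None = None,
    ) -> None:
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if min(windows) < 1:
            raise ValueError("window sizes must be >= 1")
        self.vocab_size = vocab_size
        self.n_classes = n_classes
        self.embed_dim = embed_dim
        self.filters = filters
        self.windows = tuple(windows)
        self.pad_id = pad_id
        self.min_len = max(windows)

        rng = np.random.default_rng(seed)
        arrays: dict[str, np.ndarray] = {}
        if embeddings is not None:
            if embeddings.shape != (vocab_size, embed_dim):
                raise ValueError("pretrained embedding shape mismatch")
            arrays["emb"] = embeddings.astype(np.float64).copy()
        else:
            arrays["emb"] = rng.uniform(
                -0.5 / embed_dim, 0.5 / embed_dim, size=(vocab_size, embed_dim)
            )
        arrays["emb"][pad_id] = 0.0
        for w in self.windows:
            fan_in, fan_out = w * embed_dim, filters
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            # weights stored as (w, embed_dim, filters): one slab per offset
            arrays[f"conv{w}_W"] = rng.uniform(
                -bound, bound, size=(w, embed_dim, filters)
            )
            arrays[f"conv{w}_b"] = np.zeros(filters)
        doc_dim = filters * len(self.windows)
        bound = np.sqrt(6.0 / (doc_dim + n_classes))
        arrays["out_W"] = rng.uniform(-bound, bound, size=(doc_dim, n_classes))
        arrays["out_b"] = np.zeros(n_classes)
        self.params = CnnParams(arrays=arrays, pad_id=pad_id)

    # ------------------------------------------------------------------ #

    def _forward(
        self, ids: np.ndarray, lengths: np.ndarray, keep_cache: bool
    ) -> tuple[np.ndarray, dict | None]:
        """Return (softmax probabilities, cache for backward)."""
        P = self.params.arrays
        B, T = ids.shape
        if int(lengths.min()) < self.min_len:
            raise ValueError(
                f"sequence length {int(lengths.min())} below the model minimum "
                f"{self.min_len}; pad inputs to at least max(window sizes)"
            )
        E = P["emb"][ids]  # (B, T, d)
        d = self.embed_dim
        pooled = []
        cache: dict = {"ids": ids, "per_window": {}} if keep_cache else None
        for w in self.windows:
            n_pos = T - w + 1
            W, b = P[f"conv{w}_W"], P[f"conv{w}_b"]
            # im2col: all length-w windows as rows, one GEMM per window size
            X = np.empty((B, n_pos, w * d))
            for j in range(w):
                X[:, :, j * d : (j + 1) * d] = E[:, j : j + n_pos, :]
            Z = X.reshape(B * n_pos, w * d) @ W.reshape(w * d, self.filters)
            Z = Z.reshape(B, n_pos, self.filters) + b
            A = np.maximum(Z, 0.0)
            # mask window positions that extend past each sequence's length
            pos = np.arange(n_pos)
            invalid = pos[None, :] > (lengths[:, None] - w)
            A_masked = np.where(invalid[:, :, None], -np.inf, A)
            arg = np.argmax(A_masked, axis=1)  # (B, F)
            mx = np.take_along_axis(A_masked, arg[:, None, :], axis=1)[:, 0, :]
            pooled.append(mx)
            if keep_cache:
                cache["per_window"][w] = {"X": X, "A": A, "arg": arg, "n_pos": n_pos}
        H = np.concatenate(pooled, axis=1)  # (B, doc_dim)
        logits = H @ P["out_W"] + P["out_b"]
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        if keep_cache:
            cache["H"] = H
            cache["probs"] = probs
        return probs, cache

    def predict_proba(self, ids: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        """Class-probability rows for a padded id batch (evaluation mode)."""
        probs, _ = self._forward(
            np.asarray(ids), np.asarray(lengths), keep_cache=False
        )
        return probs

    def loss_and_grads(
        self,
        ids: np.ndarray,
        lengths: np.ndarray,
        y: np.ndarray,
        sample_weights: np.ndarray | None = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Weighted-mean cross entropy and its gradients.

        The loss is ``sum(w_i * ce_i) / sum(w_i)``; with unit weights this is
        the plain batch-mean cross entropy.
        """
        ids = np.asarray(ids)
        lengths = np.asarray(lengths)
        y = np.asarray(y)
        B = ids.shape[0]
        if sample_weights is None:
            sw = np.ones(B)
        else:
            sw = np.asarray(sample_weights, dtype=float)
        probs, cache = self._forward(ids, lengths, keep_cache=True)
        p_true = np.clip(probs[np.arange(B), y], 1e-300, None)
        w_sum = sw.sum()
        loss = float((sw * -np.log(p_true)).sum() / w_sum)

        P = self.params.arrays
        d_logits = probs.copy()
        d_logits[np.arange(B), y] -= 1.0
        d_logits *= (sw / w_sum)[:, None]

        grads: dict[str, np.ndarray] = {}
        H = cache["H"]
        grads["out_W"] = H.T @ d_logits
        grads["out_b"] = d_logits.sum(axis=0)
        dH = d_logits @ P["out_W"].T
        d = self.embed_dim
        T = ids.shape[1]
        dE = np.zeros((B, T, d))
        offset = 0
        for w in self.windows:
            cw = cache["per_window"][w]
            X, A, arg, n_pos = cw["X"], cw["A"], cw["arg"], cw["n_pos"]
            d_pool = dH[:, offset : offset + self.filters]
            offset += self.filters
            # route gradient to the argmax position, through the ReLU
            dZ = np.zeros((B, n_pos, self.filters))
            rows = np.arange(B)[:, None]
            cols = np.arange(self.filters)[None, :]
            active = A[rows, arg, cols] > 0.0
            dZ[rows, arg, cols] = np.where(active, d_pool, 0.0)
            W = P[f"conv{w}_W"]
            dZ2 = dZ.reshape(B * n_pos, self.filters)
            X2 = X.reshape(B * n_pos, w * d)
            grads[f"conv{w}_W"] = (X2.T @ dZ2).reshape(w, d, self.filters)
            grads[f"conv{w}_b"] = dZ.sum(axis=(0, 1))
            dX = (dZ2 @ W.reshape(w * d, self.filters).T).reshape(B, n_pos, w, d)
            for j in range(w):
                dE[:, j : j + n_pos, :] += dX[:, :, j, :]
        demb = np.zeros_like(P["emb"])
        np.add.at(demb, cache["ids"], dE)
        demb[self.pad_id] = 0.0  # pad row frozen
        grads["emb"] = demb
        return loss, grads


@dataclass
class Adam:
    """Adam optimizer over a named-parameter dict, with bias correction."""

    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict[str, np.ndarray] = field(default_factory=dict)
    v: dict[str, np.ndarray] = field(default_factory=dict)

    def step(self, params: CnnParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            m = self.m[name]
            v = self.v[name]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            update = (self.lr / b1t) * m / (np.sqrt(v / b2t) + self.eps)
            params.arrays[name] -= update
        params.arrays["emb"][params.pad_id] = 0.0
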