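"""Attention classifier: embedding block, multi-head self-attention
block, fully connected block, trained with class-weighted binary
cross-entropy and Adam.

The architecture is deliberately minimal: word + learned position
embedding, one multi-head self-attention layer whose per-head outputs
are concatenated, a flatten, and two dense layers (64, 1) ending in a
sigmoid. There are no residual connections, layer norms or feed-forward
sublayers. Attention logits are scaled by ``d_k`` by default (with a
``sqrt_d_k`` option), and padding positions participate in attention
unless ``mask_padding`` is set.

Implemented in NumPy with analytic gradients so training is exactly
reproducible from a seed on any machine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from plasmeld.seqio import segment_sequence

__all__ = [
    "TransformerConfig",
    "ClassWeights",
    "class_weights",
    "TransformerClassifier",
    "train",
    "augment_training_set",
    "AUGMENT_WINDOWS",
]

AUGMENT_WINDOWS = (200, 400, 600, 800, 1000, 2000, 4000)


@dataclass(frozen=True)
class TransformerConfig:
    sentence_len: int
    vocab_size: int
    d_model: int = 512
    heads: int = 8
    fc_hidden: int = 64
    dropout: float = 0.1
    lr: float = 0.001
    batch_size: int = 256
    epochs: int = 2
    attention_scale: str = "d_k"  # "d_k" (as printed) or "sqrt_d_k" (canonical)
    mask_padding: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.heads:
            raise ValueError("d_model must be divisible by heads")
        if self.attention_scale not in ("d_k", "sqrt_d_k"):
            raise ValueError("attention_scale must be 'd_k' or 'sqrt_d_k'")

    @property
    def d_k(self) -> int:
        return self.d_model // self.heads

    @property
    def flattened_len(self) -> int:
        return self.sentence_len * self.d_model

    @property
    def scale(self) -> float:
        return float(self.d_k) if self.attention_scale == "d_k" else float(np.sqrt(self.d_k))


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights max(N_p, N_c) / N_i."""

    plasmid: float
    chromosome: float


def class_weights(n_plasmid: int, n_chromosome: int) -> ClassWeights:
    if n_plasmid <= 0 or n_chromosome <= 0:
        raise ValueError("both class counts must be positive")
    top = max(n_plasmid, n_chromosome)
    return ClassWeights(top / n_plasmid, top / n_chromosome)


def _xavier(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class TransformerClassifier:
    """Single-layer attention classifier over integer token sentences."""

    PARAM_NAMES = ("W_word", "W_pos", "Wq", "Wk", "Wv", "W1", "b1", "w2", "b2")

    def __init__(self, config: TransformerConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        L, d, h, dk = config.sentence_len, config.d_model, config.heads, config.d_k
        self.params: dict[str, np.ndarray] = {
            "W_word": _xavier(rng, (config.vocab_size, d)),
            "W_pos": _xavier(rng, (L, d)),
            "Wq": _xavier(rng, (h, d, dk)),
            "Wk": _xavier(rng, (h, d, dk)),
            "Wv": _xavier(rng, (h, d, dk)),
            "W1": _xavier(rng, (L * d, config.fc_hidden)),
            "b1": np.zeros(config.fc_hidden),
            "w2": _xavier(rng, (config.fc_hidden, 1))[:, 0],
            "b2": np.zeros(1),
        }

    # ---- forward pieces (exposed for inspection and tests) ----

    def embed(self, ids: np.ndarray) -> np.ndarray:
        """Word + position embedding; row i is word[ids[i]] + position[i]."""
        ids = np.atleast_2d(ids)
        if ids.max(initial=0) >= self.params["W_word"].shape[0]:
            _, cols = np.where(ids >= self.params["W_word"].shape[0])
            raise IndexError(f"token id out of range at sentence position {int(cols[0])}")
        return self.params["W_word"][ids] + self.params["W_pos"][None, :, :]

    def attention(self, X: np.ndarray, ids: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Multi-head self-attention. Returns (Z, alpha) with Z of shape
        (B, L, d_model) and alpha of shape (B, heads, L, L)."""
        p, cfg = self.params, self.config
        Q = np.einsum("bld,hdk->bhlk", X, p["Wq"])
        K = np.einsum("bld,hdk->bhlk", X, p["Wk"])
        V = np.einsum("bld,hdk->bhlk", X, p["Wv"])
        S = np.einsum("bhlk,bhmk->bhlm", Q, K) / cfg.scale
        if cfg.mask_padding and ids is not None:
            pad = np.atleast_2d(ids) == 0
            S = np.where(pad[:, None, None, :], -1e30, S)
        A = _softmax(S)
        Zh = np.einsum("bhlm,bhmk->bhlk", A, V)
        B, L = X.shape[0], X.shape[1]
        Z = Zh.transpose(0, 2, 1, 3).reshape(B, L, cfg.d_model)
        return Z, A

    def classify(self, Z: np.ndarray) -> np.ndarray:
        """Flatten -> dense(fc_hidden, ReLU) -> dense(1) -> sigmoid."""
        p = self.params
        flat = Z.reshape(Z.shape[0], -1)
        if flat.shape[1] != self.config.flattened_len:
            raise ValueError(
                f"flattened length {flat.shape[1]} != L*d_model {self.config.flattened_len}"
            )
        h1 = np.maximum(flat @ p["W1"] + p["b1"], 0.0)
        return _sigmoid(h1 @ p["w2"] + p["b2"][0])

    def forward(self, ids: np.ndarray, return_attention: bool = False):
        ids = np.atleast_2d(ids)
        X = self.embed(ids)
        Z, A = self.attention(X, ids)
        probs = self.classify(Z)
        return (probs, A) if return_attention else probs

    def predict_proba(self, ids: np.ndarray, batch_size: int = 64) -> np.ndarray:
        ids = np.atleast_2d(ids)
        out = [self.forward(ids[i : i + batch_size]) for i in range(0, len(ids), batch_size)]
        return np.concatenate(out)

    # ---- loss and gradients ----

    def loss_and_grads(
        self,
        ids: np.ndarray,
        y: np.ndarray,
        sample_weights: np.ndarray | None = None,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean weighted binary cross-entropy and its analytic gradients.

        ``dropout_rng`` enables dropout (training mode); without it the
        pass is deterministic (used by the gradient check and inference).
        """
        p, cfg = self.params, self.config
        ids = np.atleast_2d(ids)
        B, L = ids.shape
        y = np.asarray(y, dtype=float)
        w = np.ones(B) if sample_weights is None else np.asarray(sample_weights, dtype=float)

        X = self.embed(ids)
        emb_mask = None
        if dropout_rng is not None and cfg.dropout > 0:
            emb_mask = (dropout_rng.random(X.shape) >= cfg.dropout) / (1 - cfg.dropout)
            X = X * emb_mask
        Q = np.einsum("bld,hdk->bhlk", X, p["Wq"])
        K = np.einsum("bld,hdk->bhlk", X, p["Wk"])
        V = np.einsum("bld,hdk->bhlk", X, p["Wv"])
        S = np.einsum("bhlk,bhmk->bhlm", Q, K) / cfg.scale
        if cfg.mask_padding:
            pad = ids == 0
            S = np.where(pad[:, None, None, :], -1e30, S)
        A = _softmax(S)
        Zh = np.einsum("bhlm,bhmk->bhlk", A, V)
        flat = Zh.transpose(0, 2, 1, 3).reshape(B, L * cfg.d_model)
        pre1 = flat @ p["W1"] + p["b1"]
        h1 = np.maximum(pre1, 0.0)
        h1d = h1
        fc_mask = None
        if dropout_rng is not None and cfg.dropout > 0:
            fc_mask = (dropout_rng.random(h1.shape) >= cfg.dropout) / (1 - cfg.dropout)
            h1d = h1 * fc_mask
        logit = h1d @ p["w2"] + p["b2"][0]
        prob = _sigmoid(logit)
        eps = 1e-12
        loss = float(
            np.mean(-w * (y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))
        )

        g: dict[str, np.ndarray] = {}
        dlogit = w * (prob - y) / B
        g["w2"] = h1d.T @ dlogit
        g["b2"] = np.array([dlogit.sum()])
        dh1d = np.outer(dlogit, p["w2"])
        dh1 = dh1d if fc_mask is None else dh1d * fc_mask
        dpre1 = dh1 * (pre1 > 0)
        g["W1"] = flat.T @ dpre1
        g["b1"] = dpre1.sum(axis=0)
        dflat = dpre1 @ p["W1"].T
        dZh = dflat.reshape(B, L, cfg.heads, cfg.d_k).transpose(0, 2, 1, 3)
        dA = np.einsum("bhlk,bhmk->bhlm", dZh, V)
        dV = np.einsum("bhlm,bhlk->bhmk", A, dZh)
        dS = A * (dA - np.sum(dA * A, axis=-1, keepdims=True))
        dS /= cfg.scale
        dQ = np.einsum("bhlm,bhmk->bhlk", dS, K)
        dK = np.einsum("bhlm,bhlk->bhmk", dS, Q)
        g["Wq"] = np.einsum("bld,bhlk->hdk", X, dQ)
        g["Wk"] = np.einsum("bld,bhlk->hdk", X, dK)
        g["Wv"] = np.einsum("bld,bhlk->hdk", X, dV)
        dX = (
            np.einsum("bhlk,hdk->bld", dQ, p["Wq"])
            + np.einsum("bhlk,hdk->bld", dK, p["Wk"])
            + np.einsum("bhlk,hdk->bld", dV, p["Wv"])
        )
        if emb_mask is not None:
            dX = dX * emb_mask
        g["W_pos"] = dX.sum(axis=0)
        g["W_word"] = np.zeros_like(p["W_word"])
        np.add.at(g["W_word"], ids.reshape(-1), dX.reshape(-1, cfg.d_model))
        return loss, g

    # ---- persistence ----

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(asdict(self.config), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "TransformerClassifier":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            config = TransformerConfig(**json.load(fh))
        model = cls(config)
        with np.load(path.with_suffix(".npz")) as data:
            model.params = {k: data[k] for k in cls.PARAM_NAMES}
        return model


def _softmax(S: np.ndarray) -> np.ndarray:
    S = S - S.max(axis=-1, keepdims=True)
    e = np.exp(S)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class _AdamState:
    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    t: int = 0


def train(
    model: TransformerClassifier,
    sentences: np.ndarray,
    labels: np.ndarray,
    epochs: int | None = None,
    verbose: bool = False,
) -> list[tuple[int, int, float]]:
    """Train with weighted BCE and Adam; returns the loss trace as
    (epoch, batch, loss) triples. Labels: 1 = plasmid, 0 = chromosome.
    Per-example weights follow max(N_p, N_c)/N_i. Fully deterministic
    given ``model.config.seed``. Refuses single-class datasets.
    """
    cfg = model.config
    sentences = np.asarray(sentences)
    labels = np.asarray(labels, dtype=int)
    n_p, n_c = int((labels == 1).sum()), int((labels == 0).sum())
    if n_p == 0 or n_c == 0:
        raise ValueError("training set must contain both classes")
    cw = class_weights(n_p, n_c)
    weights = np.where(labels == 1, cw.plasmid, cw.chromosome)
    rng = np.random.default_rng(cfg.seed + 1)
    adam = _AdamState(
        {k: np.zeros_like(v) for k, v in model.params.items()},
        {k: np.zeros_like(v) for k, v in model.params.items()},
    )
    trace: list[tuple[int, int, float]] = []
    epochs = cfg.epochs if epochs is None else epochs
    for epoch in range(epochs):
        order = rng.permutation(len(sentences))
        for bi, lo in enumerate(range(0, len(sentences), cfg.batch_size)):
            sel = order[lo : lo + cfg.batch_size]
            loss, grads = model.loss_and_grads(
                sentences[sel], labels[sel], weights[sel], dropout_rng=rng
            )
            _adam_step(model.params, grads, adam, cfg.lr)
            trace.append((epoch, bi, loss))
            if verbose:
                print(f"epoch {epoch} batch {bi} loss {loss:.4f}")
    return trace


def _adam_step(
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    state: _AdamState,
    lr: float,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> None:
    state.t += 1
    for k in params:
        state.m[k] = beta1 * state.m[k] + (1 - beta1) * grads[k]
        state.v[k] = beta2 * state.v[k] + (1 - beta2) * grads[k] ** 2
        mhat = state.m[k] / (1 - beta1**state.t)
        vhat = state.v[k] / (1 - beta2**state.t)
        params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


def augment_training_set(
    sequences: Iterable[tuple[str, int]],
    windows: tuple[int, ...] = AUGMENT_WINDOWS,
) -> list[tuple[str, int]]:
    """Expand (sequence, label) pairs with non-overlapping sliding
    windows of each size; originals are kept, labels inherited. A window
    larger than the sequence contributes nothing new (the original is
    already present)."""
    out: list[tuple[str, int]] = []
    for seq, label in sequences:
        out.append((seq, label))
        for window in windows:
            if window >= len(seq):
                continue
            out.extend((seg, label) for seg in segment_sequence(seq, window))
    return out
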