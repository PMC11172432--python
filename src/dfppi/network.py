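"""The two-channel pair classifier, implemented as a compact numpy network.

Architecture, per protein: a trainable embedding layer (26×d table, padding
row pinned at zero) feeds channel 2 with the flattened N×d block of a
fixed-length token sequence, while channel 1 consumes the standardized
handcrafted descriptor vector.  Each channel is a stack of
dense→relu→batchnorm→dropout layers ending at the same width; the two
channel outputs are fused by a convex combination with weight ω (ω on the
handcrafted channel).  The two per-protein fused vectors are averaged and
passed through a small dense head ending in a 2-way softmax whose second
coordinate is the interaction probability.

Training minimizes binary cross-entropy with Adam under a time-based
learning-rate decay lr_t = lr0 / (1 + δ·t) (t = epoch index).  Forward,
backward and the optimizer are written directly against numpy arrays;
reverse-mode gradients are exact and are verified against finite
differences in the test suite.  All randomness (init, shuffling, dropout)
flows from seeded generators, so runs are bitwise-reproducible on a single
worker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .embedding import EmbeddingMatrix
from .io import PAD_TOKEN, VOCAB_SIZE

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass(frozen=True)
class ModelConfig:
    """Architecture settings.

    omega weights the handcrafted channel in the fusion layer (1-omega goes
    to the embedding channel).  fixed_length is the token length N; when
    None it is inferred as the floor of the mean training-sequence length.
    The last entries of the two channel size lists must match — fusion is
    elementwise.
    """

    omega: float = 0.5
    embed_dim: int = 32
    fixed_length: int | None = None
    channel1_sizes: tuple[int, ...] = (1024, 512, 256, 128)
    channel2_sizes: tuple[int, ...] = (2048, 512, 256, 128)
    head_size: int = 16
    dropout_rate: float = 0.2
    share_block_weights: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must lie in [0, 1], got {self.omega}")
        if self.channel1_sizes[-1] != self.channel2_sizes[-1]:
            raise ValueError(
                "fusion needs equal channel output widths, got "
                f"{self.channel1_sizes[-1]} and {self.channel2_sizes[-1]}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout rate must lie in [0, 1), got {self.dropout_rate}")

    @property
    def fused_dim(self) -> int:
        return self.channel1_sizes[-1]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; decay defaults to learning_rate / epochs."""

    epochs: int = 45
    batch_size: int = 128
    learning_rate: float = 0.001
    decay: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")

    @property
    def decay_coefficient(self) -> float:
        return self.learning_rate / self.epochs if self.decay is None else self.decay


@dataclass
class PairBatch:
    """Model inputs for a batch of protein pairs.

    handcrafted_* are (n, p) float matrices (standardized descriptor
    vectors), tokens_* are (n, N) integer matrices, labels an optional
    (n,) 0/1 vector.
    """

    handcrafted_a: np.ndarray
    tokens_a: np.ndarray
    handcrafted_b: np.ndarray
    tokens_b: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.handcrafted_a = np.asarray(self.handcrafted_a, dtype=float)
        self.handcrafted_b = np.asarray(self.handcrafted_b, dtype=float)
        self.tokens_a = np.asarray(self.tokens_a, dtype=np.int64)
        self.tokens_b = np.asarray(self.tokens_b, dtype=np.int64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)

    def __len__(self) -> int:
        return self.handcrafted_a.shape[0]

    def swapped(self) -> "PairBatch":
        """The same pairs with proteins A and B exchanged."""
        return PairBatch(
            self.handcrafted_b, self.tokens_b, self.handcrafted_a, self.tokens_a, self.labels
        )

    def subset(self, idx: np.ndarray) -> "PairBatch":
        return PairBatch(
            self.handcrafted_a[idx],
            self.tokens_a[idx],
            self.handcrafted_b[idx],
            self.tokens_b[idx],
            None if self.labels is None else self.labels[idx],
        )


def fuse(h_prime: np.ndarray, e_prime: np.ndarray, omega: float) -> np.ndarray:
    """Convex combination ω·h' + (1−ω)·e' of the two channel outputs."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega must lie in [0, 1], got {omega}")
    h_prime = np.asarray(h_prime, dtype=float)
    e_prime = np.asarray(e_prime, dtype=float)
    if h_prime.shape != e_prime.shape:
        raise ValueError(
            f"fusion requires equal shapes, got {h_prime.shape} and {e_prime.shape}"
        )
    return omega * h_prime + (1.0 - omega) * e_prime


# --------------------------------------------------------------------------
# layer primitives (forward returns a cache consumed by backward)
# --------------------------------------------------------------------------


def _layer_forward(params, stats, name, x, train, rng, drop_rate):
    """dense -> relu -> batchnorm -> dropout for one named layer."""
    W, b = params[f"{name}.W"], params[f"{name}.b"]
    gamma, beta = params[f"{name}.g"], params[f"{name}.beta"]
    z = x @ W + b
    a = np.maximum(z, 0.0)
    if train:
        mu = a.mean(axis=0)
        var = a.var(axis=0)
        stats[f"{name}.mean"] = _BN_MOMENTUM * stats[f"{name}.mean"] + (1 - _BN_MOMENTUM) * mu
        stats[f"{name}.var"] = _BN_MOMENTUM * stats[f"{name}.var"] + (1 - _BN_MOMENTUM) * var
    else:
        mu = stats[f"{name}.mean"]
        var = stats[f"{name}.var"]
    ivar = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (a - mu) * ivar
    out = gamma * xhat + beta
    if train and drop_rate > 0.0:
        mask = (rng.random(out.shape) >= drop_rate) / (1.0 - drop_rate)
        out = out * mask
    else:
        mask = None
    cache = (x, z, xhat, ivar, mask, name, train)
    return out, cache


def _layer_backward(params, grads, cache, dout, drop_rate):
    x, z, xhat, ivar, mask, name, train = cache
    if mask is not None:
        dout = dout * mask
    gamma = params[f"{name}.g"]
    grads[f"{name}.g"] += (dout * xhat).sum(axis=0)
    grads[f"{name}.beta"] += dout.sum(axis=0)
    dxhat = dout * gamma
    if train:
        m = x.shape[0]
        da = (ivar / m) * (
            m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
    else:
        da = dxhat * ivar
    dz = da * (z > 0.0)
    grads[f"{name}.W"] += x.T @ dz
    grads[f"{name}.b"] += dz.sum(axis=0)
    return dz @ params[f"{name}.W"].T


class PairClassifier:
    """The pair network: parameters, forward/backward, Adam training loop."""

    def __init__(
        self,
        cfg: ModelConfig,
        embeddings: EmbeddingMatrix,
        handcrafted_dim: int,
        n_tokens: int,
    ):
        if embeddings.dim != cfg.embed_dim:
            raise ValueError(
                f"embedding matrix dim {embeddings.dim} != config embed_dim {cfg.embed_dim}"
            )
        self.cfg = cfg
        self.handcrafted_dim = handcrafted_dim
        self.n_tokens = n_tokens
        rng = np.random.default_rng(cfg.seed)

        self.params: dict[str, np.ndarray] = {"emb": embeddings.rows.copy()}
        self.bn_stats: dict[str, np.ndarray] = {}
        for blk in self._block_names():
            self._init_block(rng, f"{blk}.ch1", handcrafted_dim, cfg.channel1_sizes)
            self._init_block(rng, f"{blk}.ch2", n_tokens * cfg.embed_dim, cfg.channel2_sizes)
        self._init_layer(rng, "head.l1", cfg.fused_dim, cfg.head_size)
        self.params["head.out.W"] = rng.normal(
            0.0, np.sqrt(2.0 / cfg.head_size), (cfg.head_size, 2)
        )
        self.params["head.out.b"] = np.zeros(2)

    # -- construction helpers ------------------------------------------------

    def _block_names(self) -> tuple[str, ...]:
        return ("blk",) if self.cfg.share_block_weights else ("blkA", "blkB")

    def _block_of(self, side: str) -> str:
        return "blk" if self.cfg.share_block_weights else f"blk{side}"

    def _init_layer(self, rng, name, fan_in, width):
        self.params[f"{name}.W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, width))
        self.params[f"{name}.b"] = np.zeros(width)
        self.params[f"{name}.g"] = np.ones(width)
        self.params[f"{name}.beta"] = np.zeros(width)
        self.bn_stats[f"{name}.mean"] = np.zeros(width)
        self.bn_stats[f"{name}.var"] = np.ones(width)

    def _init_block(self, rng, prefix, in_dim, sizes):
        fan = in_dim
        for i, width in enumerate(sizes):
            self._init_layer(rng, f"{prefix}.l{i}", fan, width)
            fan = width

    # -- forward -------------------------------------------------------------

    def _channel(self, prefix, sizes, x, train, rng):
        caches = []
        for i in range(len(sizes)):
            x, cache = _layer_forward(
                self.params, self.bn_stats, f"{prefix}.l{i}", x, train,
                rng, self.cfg.dropout_rate,
            )
            caches.append(cache)
        return x, caches

    def _protein_forward(self, side, handcrafted, tokens, train, rng):
        blk = self._block_of(side)
        E = self.params["emb"]
        emb = E[tokens].reshape(tokens.shape[0], -1)
        h_prime, c1 = self._channel(f"{blk}.ch1", self.cfg.channel1_sizes, handcrafted, train, rng)
        e_prime, c2 = self._channel(f"{blk}.ch2", self.cfg.channel2_sizes, emb, train, rng)
        fused = fuse(h_prime, e_prime, self.cfg.omega)
        return fused, (blk, tokens, c1, c2)

    def forward(self, batch: PairBatch, train: bool = False, rng=None):
        """Class probabilities (n, 2); second column is P(interaction)."""
        if train and rng is None:
            rng = np.random.default_rng(0)
        fA, cacheA = self._protein_forward("A", batch.handcrafted_a, batch.tokens_a, train, rng)
        fB, cacheB = self._protein_forward("B", batch.handcrafted_b, batch.tokens_b, train, rng)
        fAB = 0.5 * (fA + fB)
        f, head_cache = _layer_forward(
            self.params, self.bn_stats, "head.l1", fAB, train, rng, self.cfg.dropout_rate
        )
        scores = f @ self.params["head.out.W"] + self.params["head.out.b"]
        scores = scores - scores.max(axis=1, keepdims=True)
        expd = np.exp(scores)
        probs = expd / expd.sum(axis=1, keepdims=True)
        cache = (cacheA, cacheB, head_cache, f, probs)
        return probs, cache

    def predict_proba(self, batch: PairBatch) -> np.ndarray:
        """Interaction probability per pair (inference mode)."""
        probs, _ = self.forward(batch, train=False)
        return probs[:, 1]

    # -- backward ------------------------------------------------------------

    def _channel_backward(self, grads, caches, dout):
        for cache in reversed(caches):
            dout = _layer_backward(self.params, grads, cache, dout, self.cfg.dropout_rate)
        return dout

    def _protein_backward(self, grads, cache, dfused):
        blk, tokens, c1, c2 = cache
        dh = self.cfg.omega * dfused
        de = (1.0 - self.cfg.omega) * dfused
        self._channel_backward(grads, c1, dh)
        demb_flat = self._channel_backward(grads, c2, de)
        demb = demb_flat.reshape(tokens.shape[0], tokens.shape[1], self.cfg.embed_dim)
        np.add.at(grads["emb"], tokens, demb)

    def loss_and_grads(self, batch: PairBatch, rng=None):
        """Mean binary cross-entropy and exact gradients for one batch."""
        if batch.labels is None:
            raise ValueError("training requires labeled pairs")
        probs, cache = self.forward(batch, train=True, rng=rng)
        cacheA, cacheB, head_cache, f, _ = cache
        n = len(batch)
        y = batch.labels
        eps = 1e-12
        loss = -np.mean(np.log(probs[np.arange(n), y] + eps))

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dscores = probs.copy()
        dscores[np.arange(n), y] -= 1.0
        dscores /= n
        grads["head.out.W"] += f.T @ dscores
        grads["head.out.b"] += dscores.sum(axis=0)
        df = dscores @ self.params["head.out.W"].T
        dfAB = _layer_backward(self.params, grads, head_cache, df, self.cfg.dropout_rate)
        self._protein_backward(grads, cacheA, 0.5 * dfAB)
        self._protein_backward(grads, cacheB, 0.5 * dfAB)
        grads["emb"][PAD_TOKEN] = 0.0  # padding embedding stays pinned at zero
        return loss, grads

    # -- training ------------------------------------------------------------

    def fit(self, batch: PairBatch, tc: TrainConfig | None = None) -> list[float]:
        """Adam with time-based learning-rate decay; returns per-epoch mean loss."""
        tc = tc or TrainConfig()
        if batch.labels is None:
            raise ValueError("training requires labeled pairs")
        rng = np.random.default_rng(tc.seed)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(p) for k, p in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        history: list[float] = []
        n = len(batch)
        for epoch in range(tc.epochs):
            lr = tc.learning_rate / (1.0 + tc.decay_coefficient * epoch)
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, tc.batch_size):
                idx = order[start : start + tc.batch_size]
                loss, grads = self.loss_and_grads(batch.subset(idx), rng=rng)
                total += loss * idx.size
                step += 1
                for key, g in grads.items():
                    m[key] = b1 * m[key] + (1 - b1) * g
                    v[key] = b2 * v[key] + (1 - b2) * g * g
                    mhat = m[key] / (1 - b1**step)
                    vhat = v[key] / (1 - b2**step)
                    self.params[key] -= lr * mhat / (np.sqrt(vhat) + eps)
            self.params["emb"][PAD_TOKEN] = 0.0
            history.append(total / n)
        return history


def channel_forward(net: PairClassifier, x: np.ndarray, side: str = "A", channel: int = 1) -> np.ndarray:
    """Inference-mode pass of one input through one channel of one block."""
    blk = net._block_of(side)
    sizes = net.cfg.channel1_sizes if channel == 1 else net.cfg.channel2_sizes
    out, _ = net._channel(f"{blk}.ch{channel}", sizes, np.atleast_2d(x), train=False, rng=None)
    return out


def forward_pair(net: PairClassifier, batch: PairBatch) -> np.ndarray:
    """Inference-mode class probabilities (n, 2) for a batch of pairs."""
    probs, _ = net.forward(batch, train=False)
    return probs
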