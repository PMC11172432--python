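"""Paragraph-vector (PV-DM) embedding of amino acids.

Each protein sequence is treated as a document and each residue as a word
(1-gram).  Training follows the distributed-memory paragraph-vector model:
the hidden state for a target position is the mean of the document vector
and the word vectors in a symmetric context window, and a full-softmax
output layer predicts the target token.  Because the vocabulary is only 26
tokens, full softmax is exact and cheap; gradients are applied in one
batched step per document (all positions of a document averaged), which
keeps training deterministic and fast.  After training the word vectors
form a 26×dim embedding matrix (padding row 25 held at zero) that seeds
the predictor's trainable embedding layer; document vectors are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import PAD_TOKEN, VOCAB_SIZE, ProteinRecord, tokenize


@dataclass(frozen=True)
class EmbeddingConfig:
    """PV-DM hyper-parameters.

    dim is the embedding width (32 performed best in the dimension sweep);
    window is the one-sided context size; min_count keeps every token (the
    vocabulary has only 25 residue tokens, none may be dropped); lr is the
    SGD step size.
    """

    dim: int = 32
    epochs: int = 10
    window: int = 5
    min_count: int = 1
    lr: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError(f"embedding dim must be positive, got {self.dim}")
        if self.epochs < 1 or self.window < 1:
            raise ValueError("epochs and window must be positive")


class EmbeddingMatrix:
    """26×dim table of token vectors; row 25 (padding) is all zeros."""

    def __init__(self, rows: np.ndarray):
        rows = np.asarray(rows, dtype=float)
        if rows.ndim != 2 or rows.shape[0] != VOCAB_SIZE:
            raise ValueError(
                f"embedding matrix must have {VOCAB_SIZE} rows, got shape {rows.shape}"
            )
        if not np.all(np.isfinite(rows)):
            raise ValueError("embedding matrix contains non-finite values")
        rows = rows.copy()
        rows[PAD_TOKEN] = 0.0
        self.rows = rows

    @property
    def dim(self) -> int:
        return self.rows.shape[1]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EmbeddingMatrix) and np.array_equal(self.rows, other.rows)


def build_corpus(
    records: Iterable[ProteinRecord],
    exclude: Iterable[ProteinRecord] = (),
) -> list[list[int]]:
    """Token documents, dropping any sequence that occurs in the exclusion set.

    Exclusion matches on the sequence string itself (not the id), so a
    sequence duplicated under two ids is removed by either copy.
    """
    banned = {r.sequence for r in exclude}
    return [tokenize(r.sequence) for r in records if r.sequence not in banned]


def train_embeddings(
    corpus: Sequence[Sequence[int]], cfg: EmbeddingConfig | None = None
) -> EmbeddingMatrix:
    """Train PV-DM word vectors over a token corpus.

    Deterministic for a fixed config: initialization, per-epoch document
    shuffling and every update are driven by one seeded generator on a
    single worker.
    """
    cfg = cfg or EmbeddingConfig()
    docs = [np.asarray(d, dtype=np.int64) for d in corpus if len(d) > 0]
    if not docs:
        raise ValueError("cannot train embeddings on an empty corpus")
    # canonical document order first, seeded shuffling after: the result does
    # not depend on the order documents were supplied in
    docs.sort(key=lambda a: (a.size, a.tobytes()))

    rng = np.random.default_rng(cfg.seed)
    d = cfg.dim
    W = (rng.random((VOCAB_SIZE, d)) - 0.5) / d       # word (input) vectors
    W[PAD_TOKEN] = 0.0
    D = (rng.random((len(docs), d)) - 0.5) / d        # document vectors
    U = np.zeros((VOCAB_SIZE, d))                     # softmax output weights

    win = cfg.window
    for _ in range(cfg.epochs):
        order = rng.permutation(len(docs))
        for di in order:
            toks = docs[di]
            L = toks.size
            # context index matrix: for each position, the window around it
            offsets = np.concatenate([np.arange(-win, 0), np.arange(1, win + 1)])
            ctx = np.arange(L)[:, None] + offsets[None, :]
            valid = (ctx >= 0) & (ctx < L)
            ctx_tok = np.where(valid, toks[np.clip(ctx, 0, L - 1)], 0)
            ctx_vec = W[ctx_tok] * valid[:, :, None]
            counts = valid.sum(axis=1) + 1.0          # + document vector
            H = (ctx_vec.sum(axis=1) + D[di]) / counts[:, None]

            scores = H @ U.T
            scores -= scores.max(axis=1, keepdims=True)
            P = np.exp(scores)
            P /= P.sum(axis=1, keepdims=True)
            P[np.arange(L), toks] -= 1.0              # softmax - one-hot
            P /= L                                    # mean loss over positions

            dU = P.T @ H
            dH = (P @ U) / counts[:, None]
            D[di] -= cfg.lr * dH.sum(axis=0)
            dW = np.zeros_like(W)
            np.add.at(dW, ctx_tok, dH[:, None, :] * valid[:, :, None])
            dW[PAD_TOKEN] = 0.0
            W -= cfg.lr * dW
            U -= cfg.lr * dU

    return EmbeddingMatrix(W)


def save_embeddings(matrix: EmbeddingMatrix, path: str | Path) -> None:
    """Write a headered TSV: version line with dim/vocab, then token rows."""
    with open(path, "w") as fh:
        fh.write(f"#dfppi-embeddings\tv1\tvocab={VOCAB_SIZE}\tdim={matrix.dim}\n")
        for t in range(VOCAB_SIZE):
            vals = "\t".join(repr(float(v)) for v in matrix.rows[t])
            fh.write(f"{t}\t{vals}\n")


def load_embeddings(path: str | Path, expect_dim: int | None = None) -> EmbeddingMatrix:
    """Read a matrix written by :func:`save_embeddings` (lossless round trip)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "#dfppi-embeddings":
            raise ValueError(f"{path}: not a dfppi embedding file")
        meta = dict(item.split("=") for item in header[2:])
        vocab, dim = int(meta["vocab"]), int(meta["dim"])
        if vocab != VOCAB_SIZE:
            raise ValueError(f"{path}: vocabulary size {vocab}, expected {VOCAB_SIZE}")
        if expect_dim is not None and dim != expect_dim:
            raise ValueError(f"{path}: embedding dim {dim}, model expects {expect_dim}")
        rows = np.zeros((VOCAB_SIZE, dim))
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows[int(parts[0])] = [float(v) for v in parts[1:]]
    return EmbeddingMatrix(rows)
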