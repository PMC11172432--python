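"""Model/Results surface for the pair-interaction predictor.

:class:`DFPPI` is built from a labeled pair table plus sequence records (or
from files) and owns feature preparation: handcrafted descriptor vectors per
unique protein, fixed-length token sequences for the embedding channel, and
a standardizer for the handcrafted block fitted on training proteins only.
``fit`` trains the two-channel network and returns a :class:`DFPPIResults`
carrying the fitted network, the loss trajectory and prediction helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import descriptors as desc
from .embedding import EmbeddingMatrix
from .io import (
    PairExample,
    ProteinRecord,
    mean_sequence_length,
    read_fasta,
    read_pair_table,
    records_by_id,
    tokenize_and_pad,
)
from .network import ModelConfig, PairBatch, PairClassifier, TrainConfig


@dataclass(frozen=True)
class Standardizer:
    """Per-feature zero-mean/unit-variance scaling from training statistics."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "Standardizer":
        std = x.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        return cls(x.mean(axis=0), std)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std


class FeatureStore:
    """Caches per-protein handcrafted vectors and token sequences."""

    def __init__(
        self,
        records: Sequence[ProteinRecord],
        n_tokens: int,
        groups: desc.GroupAlphabet | None = None,
        scheme: desc.RegionScheme | None = None,
        apaac: desc.ApaacConfig | None = None,
        props: desc.PropertyTable | None = None,
    ):
        self.records = records_by_id(records)
        self.n_tokens = n_tokens
        self.groups = groups or desc.GroupAlphabet()
        self.scheme = scheme or desc.RegionScheme()
        self.apaac = apaac or desc.ApaacConfig()
        self.props = props or desc.PropertyTable.default()
        self._handcrafted: dict[str, np.ndarray] = {}
        self._tokens: dict[str, np.ndarray] = {}

    def handcrafted(self, pid: str) -> np.ndarray:
        if pid not in self._handcrafted:
            rec = self._record(pid)
            self._handcrafted[pid] = desc.handcrafted_vector(
                rec.sequence, self.groups, self.scheme, self.apaac, self.props
            ).values
        return self._handcrafted[pid]

    def tokens(self, pid: str) -> np.ndarray:
        if pid not in self._tokens:
            rec = self._record(pid)
            self._tokens[pid] = np.asarray(
                tokenize_and_pad(rec, self.n_tokens), dtype=np.int64
            )
        return self._tokens[pid]

    def _record(self, pid: str) -> ProteinRecord:
        if pid not in self.records:
            raise KeyError(f"no sequence record for protein id {pid!r}")
        return self.records[pid]

    def batch(self, pairs: Sequence[PairExample], scaler: Standardizer | None = None) -> PairBatch:
        ha = np.array([self.handcrafted(p.id_a) for p in pairs])
        hb = np.array([self.handcrafted(p.id_b) for p in pairs])
        if scaler is not None:
            ha, hb = scaler(ha), scaler(hb)
        ta = np.array([self.tokens(p.id_a) for p in pairs])
        tb = np.array([self.tokens(p.id_b) for p in pairs])
        labels = [p.label for p in pairs]
        y = None if any(l is None for l in labels) else np.array(labels)
        return PairBatch(ha, ta, hb, tb, y)


class DFPPI:
    """Two-channel fusion model for sequence-only PPI prediction.

    Parameters
    ----------
    pairs : labeled protein pairs (training examples).
    records : sequence records covering every id in ``pairs``.
    config : architecture settings; ``config.fixed_length=None`` infers the
        token length N as the floor of the mean training-sequence length.
    embeddings : pre-trained residue embedding matrix used to initialize the
        (trainable) embedding layer; when None the layer starts from small
        seeded random vectors.
    feature_store : an existing :class:`FeatureStore` to reuse cached
        descriptor vectors (descriptors are deterministic per sequence, so
        sharing a store across folds or models leaks nothing; the
        handcrafted-feature scaler is still fitted per training set).  When
        given, its token length overrides ``config.fixed_length``.
    """

    def __init__(
        self,
        pairs: Sequence[PairExample],
        records: Sequence[ProteinRecord],
        config: ModelConfig | None = None,
        embeddings: EmbeddingMatrix | None = None,
        groups: desc.GroupAlphabet | None = None,
        scheme: desc.RegionScheme | None = None,
        apaac: desc.ApaacConfig | None = None,
        props: desc.PropertyTable | None = None,
        feature_store: FeatureStore | None = None,
    ):
        if not pairs:
            raise ValueError("no training pairs supplied")
        self.pairs = list(pairs)
        self.config = config or ModelConfig()

        index = feature_store.records if feature_store is not None else records_by_id(records)
        used_ids = sorted({p.id_a for p in self.pairs} | {p.id_b for p in self.pairs})
        missing = [pid for pid in used_ids if pid not in index]
        if missing:
            raise KeyError(f"pairs reference unknown protein ids: {missing[:5]}")
        self.train_records = [index[pid] for pid in used_ids]

        if feature_store is not None:
            self.features = feature_store
            self.n_tokens = feature_store.n_tokens
        else:
            n = self.config.fixed_length or mean_sequence_length(self.train_records)
            self.n_tokens = n
            self.features = FeatureStore(records, n, groups, scheme, apaac, props)

        if embeddings is None:
            rng = np.random.default_rng(self.config.seed)
            rows = (rng.random((26, self.config.embed_dim)) - 0.5) / self.config.embed_dim
            embeddings = EmbeddingMatrix(rows)
        self.embeddings = embeddings

    @classmethod
    def from_files(
        cls,
        pairs_path: str | Path,
        fasta_path: str | Path,
        header: bool = False,
        **kwargs,
    ) -> "DFPPI":
        return cls(read_pair_table(pairs_path, header=header), read_fasta(fasta_path), **kwargs)

    def fit(self, train_config: TrainConfig | None = None) -> "DFPPIResults":
        """Train the network; returns a results object."""
        tc = train_config or TrainConfig()
        if any(p.label is None for p in self.pairs):
            raise ValueError("fit requires every training pair to be labeled")
        train_features = np.array(
            [self.features.handcrafted(r.id) for r in self.train_records]
        )
        scaler = Standardizer.fit(train_features)
        batch = self.features.batch(self.pairs, scaler)
        net = PairClassifier(
            self.config, self.embeddings, train_features.shape[1], self.n_tokens
        )
        history = net.fit(batch, tc)
        return DFPPIResults(self, net, scaler, tc, history)


class DFPPIResults:
    """Fitted model: network parameters, scaler, loss history, predictions."""

    def __init__(
        self,
        model: DFPPI,
        net: PairClassifier,
        scaler: Standardizer,
        train_config: TrainConfig,
        loss_history: list[float],
    ):
        self.model = model
        self.net = net
        self.scaler = scaler
        self.train_config = train_config
        self.loss_history = list(loss_history)

    def predict_proba(
        self,
        pairs: Sequence[PairExample],
        records: Sequence[ProteinRecord] | None = None,
    ) -> np.ndarray:
        """Interaction probability per pair (second softmax coordinate)."""
        store = self.model.features
        if records is not None:
            merged = dict(store.records)
            for rec in records:
                if rec.id in merged and merged[rec.id].sequence != rec.sequence:
                    raise ValueError(f"record id {rec.id!r} given with two different sequences")
                merged[rec.id] = rec
            store = FeatureStore(
                list(merged.values()),
                self.model.n_tokens,
                store.groups, store.scheme, store.apaac, store.props,
            )
        batch = store.batch(pairs, self.scaler)
        return self.net.predict_proba(batch)

    def predict(
        self,
        pairs: Sequence[PairExample],
        threshold: float = 0.5,
        records: Sequence[ProteinRecord] | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """(labels, probabilities); label 1 iff probability >= threshold."""
        if not 0.0 <= threshold <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
        probs = self.predict_proba(pairs, records)
        return (probs >= threshold).astype(int), probs

    def summary(self) -> str:
        cfg, tc = self.model.config, self.train_config
        lines = [
            "Two-channel PPI fusion model",
            "=" * 40,
            f"training pairs:        {len(self.model.pairs)}",
            f"unique proteins:       {len(self.model.train_records)}",
            f"token length N:        {self.model.n_tokens}",
            f"embedding dim:         {cfg.embed_dim}",
            f"channel 1 sizes:       {list(cfg.channel1_sizes)}",
            f"channel 2 sizes:       {list(cfg.channel2_sizes)}",
            f"fusion weight omega:   {cfg.omega}",
            f"shared blocks:         {cfg.share_block_weights}",
            f"epochs / batch size:   {tc.epochs} / {tc.batch_size}",
            f"initial learning rate: {tc.learning_rate}",
            f"first-epoch loss:      {self.loss_history[0]:.4f}",
            f"final-epoch loss:      {self.loss_history[-1]:.4f}",
        ]
        return "\n".join(lines)


def predict_pairs(
    results: DFPPIResults,
    pairs: Sequence[PairExample],
    threshold: float = 0.5,
    records: Sequence[ProteinRecord] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Functional alias for :meth:`DFPPIResults.predict`."""
    return results.predict(pairs, threshold, records)
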