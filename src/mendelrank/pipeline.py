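"""End-to-end glue: variant tables -> encoded batches -> trained ensemble ->
per-variant class probabilities -> prioritization inputs."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .datasets import Label
from .encoding import (
    DEFAULT_RADIUS,
    ConservationProfile,
    ProteinRecord,
    encode_variant,
)
from .models import (
    EncodedBatch,
    Ensemble,
    HashEmbedder,
    MemberSpec,
    ModelConfig,
    QuantileNormalizer,
)
from .synthetic import SyntheticVariant
from .training import TrainConfig, TrainHistory, train_member

LABEL_INDEX = {Label.BENIGN: 0, Label.DOMINANT: 1, Label.RECESSIVE: 2}


def encode_dataset(variants: Sequence[SyntheticVariant],
                   proteins: Mapping[str, ProteinRecord],
                   profiles: Mapping[str, ConservationProfile],
                   embedder, radius: int = DEFAULT_RADIUS,
                   normalizer: Optional[QuantileNormalizer] = None
                   ) -> tuple[EncodedBatch, np.ndarray]:
    """Encode a variant table into model inputs.

    Returns the batch and the integer label vector (benign=0, dominant=1,
    recessive=2).  When ``normalizer`` is given, structured features pass
    through it; otherwise they stay raw (callers fit the normalizer on the
    training split only).
    """
    W = 2 * radius + 1
    n = len(variants)
    ref_values = np.zeros((n, W, 51))
    ref_mask = np.zeros((n, W), dtype=bool)
    alt_values = np.zeros((n, W, 51))
    alt_mask = np.zeros((n, W), dtype=bool)
    structured = np.zeros((n, 12))
    embeddings = np.zeros((n, W, embedder.embed_dim))
    labels = np.zeros(n, dtype=int)
    for i, v in enumerate(variants):
        protein = proteins[v.transcript_id]
        ref_win, alt_win = encode_variant(protein, profiles[v.transcript_id],
                                          v.edit, radius=radius)
        ref_values[i], ref_mask[i] = ref_win.values, ref_win.mask
        alt_values[i], alt_mask[i] = alt_win.values, alt_win.mask
        structured[i] = v.features.to_vector()
        embeddings[i] = embedder.embed(alt_win.decode(), W)
        labels[i] = LABEL_INDEX[v.label]
    if normalizer is not None:
        structured = normalizer.apply(structured)
    return EncodedBatch(ref_values, ref_mask, alt_values, alt_mask,
                        structured, embeddings), labels


def fit_normalizer(variants: Sequence[SyntheticVariant]) -> QuantileNormalizer:
    raw = np.stack([v.features.to_vector() for v in variants])
    return QuantileNormalizer().fit(raw)


@dataclass
class TrainedEnsembleResult:
    ensemble: Ensemble
    histories: list[TrainHistory]


def train_ensemble(train_variants: Sequence[SyntheticVariant],
                   proteins: Mapping[str, ProteinRecord],
                   profiles: Mapping[str, ConservationProfile],
                   specs: Sequence[MemberSpec],
                   model_cfg: ModelConfig,
                   train_cfg: TrainConfig,
                   radius: int = DEFAULT_RADIUS,
                   val_variants: Sequence[SyntheticVariant] = (),
                   embedder=None) -> TrainedEnsembleResult:
    """Fit the quantile normalizer on the training split, train each member
    with its own derived seed, and assemble the averaged predictor."""
    # the embedder is a frozen feature extractor shared by training and
    # inference, so its seed is a fixed contract, not a training seed
    embedder = embedder or HashEmbedder(model_cfg.embed_dim, seed=0)
    normalizer = fit_normalizer(train_variants)
    batch, labels = encode_dataset(train_variants, proteins, profiles,
                                   embedder, radius, normalizer)
    val_batch = val_labels = None
    if val_variants:
        val_batch, val_labels = encode_dataset(val_variants, proteins, profiles,
                                               embedder, radius, normalizer)
    members, histories = [], []
    for i, spec in enumerate(specs):
        member_cfg = replace(train_cfg, seed=train_cfg.seed * 1000 + i)
        model, hist = train_member(batch, labels, member_cfg, spec, model_cfg,
                                   val_batch, val_labels)
        members.append(model)
        histories.append(hist)
    return TrainedEnsembleResult(Ensemble(members, list(specs), normalizer),
                                 histories)


def predict_variants(ensemble: Ensemble,
                     variants: Sequence[SyntheticVariant],
                     proteins: Mapping[str, ProteinRecord],
                     profiles: Mapping[str, ConservationProfile],
                     radius: int = DEFAULT_RADIUS,
                     embedder=None,
                     ablation: Sequence[str] = ()) -> np.ndarray:
    """(N, 3) ensemble class probabilities for a variant table."""
    if embedder is None:
        embedder = HashEmbedder(ensemble.members[0].cfg.embed_dim, seed=0)
    batch, _ = encode_dataset(variants, proteins, profiles, embedder, radius,
                              ensemble.normalizer)
    return ensemble.predict_proba(batch, ablation=ablation)
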