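"""The three-class variant pathogenicity classifiers and their ensemble.

Two architectures are provided.  Architecture 1 contrasts the reference and
altered context windows: both are projected from 51 channels to the model
dimension, positionally encoded, and run through a single weight-shared
transformer stack; the center tokens are reduced to 64-d embeddings and the
classifier head consumes ``[d_alt, d_alt - d_ref, structured]``.
Architecture 2 drops the reference window and instead summarizes a
protein-language-model embedding of the altered sequence with a bidirectional
LSTM; its head consumes ``[lstm_summary, center_token, structured]``.

Both heads are Dense(512) -> Dense(64) -> Dense(3) with a softmax, so every
prediction lies on the 3-simplex (benign, dominant, recessive).

The production protein language model is behind ``EmbedderContract``; a
deterministic seeded mock (:class:`HashEmbedder`) stands in for it so the
architecture is exercisable without external weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Protocol, Sequence

import numpy as np
from sklearn.preprocessing import QuantileTransformer

from .encoding import AMINO_ACIDS, AA_INDEX, N_CHANNELS
from .nn.autodiff import Tensor, concat
from .nn.layers import BiLSTM, Dense, Module, TransformerStack, positional_encode

CLASSES = ("benign", "dominant", "recessive")

#: input names recognized by inference-time ablation
ABLATABLE_INPUTS = ("reference", "alternate", "embedding", "structured")

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ClassProbabilities:
    benign: float
    dominant: float
    recessive: float

    def __post_init__(self):
        s = self.benign + self.dominant + self.recessive
        if not np.isclose(s, 1.0, atol=1e-6):
            raise ValueError(f"class probabilities must sum to 1, got {s}")
        for v in (self.benign, self.dominant, self.recessive):
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError("class probabilities must lie in [0, 1]")

    def to_vector(self) -> np.ndarray:
        return np.array([self.benign, self.dominant, self.recessive])

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "ClassProbabilities":
        return cls(float(v[0]), float(v[1]), float(v[2]))


def binary_score(p: ClassProbabilities) -> float:
    """Zygosity-agnostic pathogenicity: dominant + recessive (= 1 - benign)."""
    return p.dominant + p.recessive


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The published scale is model_dim 64, 6 layers, 16 heads, ffn 256, head
    (512, 64, 3) on 201-position windows.  ``scale_factor`` < 1 shrinks the
    width-like dimensions proportionally for desk-scale experiments.
    """
    model_dim: int = 64
    n_layers: int = 6
    n_heads: int = 16
    ffn_dim: int = 256
    head_dims: tuple = (512, 64, 3)
    window_len: int = 201
    input_channels: int = N_CHANNELS
    branch_dim: int = 64          # per-branch fixed-length representation
    embed_dim: int = 64           # mock protein-language embedding width
    structured_dim: int = 12
    scale_factor: float = 1.0

    def __post_init__(self):
        if self.model_dim % self.n_heads:
            raise ValueError("model_dim must be divisible by n_heads")
        if self.head_dims[-1] != 3:
            raise ValueError("classifier head must end in 3 classes")

    def scaled(self, factor: float) -> "ModelConfig":
        """Proportionally shrunk copy for desk-scale runs."""
        def sc(x: int, quantum: int = 1) -> int:
            return max(quantum, int(round(x * factor)))
        heads = max(1, int(round(self.n_heads * factor)))
        dim = sc(self.model_dim)
        dim -= dim % heads or 0
        dim = max(heads, dim)
        return ModelConfig(
            model_dim=dim, n_layers=max(1, int(round(self.n_layers * factor))),
            n_heads=heads, ffn_dim=sc(self.ffn_dim),
            head_dims=(sc(self.head_dims[0]), sc(self.head_dims[1]), 3),
            window_len=self.window_len, input_channels=self.input_channels,
            branch_dim=sc(self.branch_dim), embed_dim=sc(self.embed_dim),
            structured_dim=self.structured_dim, scale_factor=factor,
        )


# ---------------------------------------------------------------------------
# structured-feature normalization
# ---------------------------------------------------------------------------

class QuantileNormalizer:
    """Maps each of the 12 structured features through its training-set
    empirical CDF to [0, 1]; missing values (NaN) are imputed to the training
    median before the transform.  Out-of-range values clamp to 0/1.
    """

    def __init__(self):
        self._qt: Optional[QuantileTransformer] = None
        self._medians: Optional[np.ndarray] = None

    def fit(self, features: np.ndarray) -> "QuantileNormalizer":
        x = np.asarray(features, dtype=float)
        if x.ndim != 2 or x.shape[0] < 2:
            raise ValueError("need a 2-D table with at least 2 training rows")
        self._medians = np.nanmedian(x, axis=0)
        self._medians = np.where(np.isfinite(self._medians), self._medians, 0.0)
        x = self._impute(x)
        self._qt = QuantileTransformer(
            n_quantiles=min(1000, x.shape[0]),
            output_distribution="uniform",
            subsample=1_000_000,
        )
        self._qt.fit(x)
        return self

    def _impute(self, x: np.ndarray) -> np.ndarray:
        x = x.copy()
        nan = ~np.isfinite(x)
        if nan.any():
            x[nan] = np.broadcast_to(self._medians, x.shape)[nan]
        return x

    def apply(self, features: np.ndarray) -> np.ndarray:
        if self._qt is None:
            raise RuntimeError("QuantileNormalizer.apply called before fit")
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[0] == 0:
            return x.copy()
        out = self._qt.transform(self._impute(x))
        return np.clip(out, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "medians": self._medians.tolist(),
            "quantiles": self._qt.quantiles_.tolist(),
            "references": self._qt.references_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuantileNormalizer":
        obj = cls()
        obj._medians = np.asarray(d["medians"], dtype=float)
        q = np.asarray(d["quantiles"], dtype=float)
        qt = QuantileTransformer(n_quantiles=q.shape[0],
                                 output_distribution="uniform")
        qt.quantiles_ = q
        qt.references_ = np.asarray(d["references"], dtype=float)
        qt.n_quantiles_ = q.shape[0]
        qt.n_features_in_ = q.shape[1]
        obj._qt = qt
        return obj


# ---------------------------------------------------------------------------
# embedder contract
# ---------------------------------------------------------------------------

class EmbedderContract(Protocol):
    """Per-residue sequence embedder: (sequence) -> (window_len, E) matrix,
    deterministic given the same sequence and construction seed."""

    embed_dim: int

    def embed(self, sequence: str, length: int) -> np.ndarray: ...


class HashEmbedder:
    """Deterministic stand-in embedder, labelled synthetic.

    Each residue letter maps to a fixed random vector drawn from a generator
    seeded by (seed, alphabet index), so identical sequences embed
    identically across processes.  Sequences shorter than ``length`` are
    zero-padded on the right.
    """

    def __init__(self, embed_dim: int = 64, seed: int = 0):
        self.embed_dim = embed_dim
        self._table = np.zeros((len(AMINO_ACIDS) + 1, embed_dim))
        for i in range(len(AMINO_ACIDS)):
            rng = np.random.default_rng((seed, i))
            self._table[i] = rng.standard_normal(embed_dim)
        # row -1 (unknown residue X) stays zero

    def embed(self, sequence: str, length: int) -> np.ndarray:
        out = np.zeros((length, self.embed_dim))
        for t, aa in enumerate(sequence[:length]):
            out[t] = self._table[AA_INDEX.get(aa, len(AMINO_ACIDS))]
        return out


class ZeroEmbedder:
    """Null embedder used in branch-isolation tests and ablations."""

    def __init__(self, embed_dim: int = 64):
        self.embed_dim = embed_dim

    def embed(self, sequence: str, length: int) -> np.ndarray:
        return np.zeros((length, self.embed_dim))


# ---------------------------------------------------------------------------
# batches
# ---------------------------------------------------------------------------

@dataclass
class EncodedBatch:
    """Numeric inputs for a batch of variants."""
    ref_values: np.ndarray    # (B, T, 51)
    ref_mask: np.ndarray      # (B, T) bool
    alt_values: np.ndarray    # (B, T, 51)
    alt_mask: np.ndarray      # (B, T) bool
    structured: np.ndarray    # (B, 12), already quantile-normalized
    alt_embedding: np.ndarray  # (B, T, E) protein-language embedding of alt seq

    @property
    def size(self) -> int:
        return self.ref_values.shape[0]

    def subset(self, idx: np.ndarray) -> "EncodedBatch":
        return EncodedBatch(self.ref_values[idx], self.ref_mask[idx],
                            self.alt_values[idx], self.alt_mask[idx],
                            self.structured[idx], self.alt_embedding[idx])

    def ablated(self, ablation: Iterable[str]) -> "EncodedBatch":
        """Zero the named inputs at inference time.

        Sequence inputs also get an all-attend mask so that a fully ablated
        model is a constant function of the variant.
        """
        ablation = set(ablation)
        unknown = ablation - set(ABLATABLE_INPUTS)
        if unknown:
            raise ValueError(f"unknown ablation channels: {sorted(unknown)}")
        b = EncodedBatch(self.ref_values, self.ref_mask, self.alt_values,
                         self.alt_mask, self.structured, self.alt_embedding)
        full = np.ones_like(self.ref_mask, dtype=bool)
        if "reference" in ablation:
            b.ref_values = np.zeros_like(b.ref_values)
            b.ref_mask = full
        if "alternate" in ablation:
            b.alt_values = np.zeros_like(b.alt_values)
            b.alt_mask = full
        if "embedding" in ablation:
            b.alt_embedding = np.zeros_like(b.alt_embedding)
        if "structured" in ablation:
            b.structured = np.zeros_like(b.structured)
        return b


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------

class _ClassifierHead(Module):
    def __init__(self, rng, d_in: int, head_dims: tuple):
        d1, d2, d3 = head_dims
        self.fc1 = Dense(rng, d_in, d1, activation="relu")
        self.fc2 = Dense(rng, d1, d2, activation="relu")
        self.fc3 = Dense(rng, d2, d3)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc3(self.fc2(self.fc1(x)))


class Architecture1(Module):
    """Reference/alternate contrastive transformer classifier."""

    architecture = 1

    def __init__(self, cfg: ModelConfig, seed: int):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d = cfg.model_dim
        self.proj = Dense(rng, cfg.input_channels, d)
        # one stack, applied to both windows: weight sharing by construction
        self.stack = TransformerStack(rng, d, cfg.n_heads, cfg.ffn_dim,
                                      cfg.n_layers)
        self.center_dense = Dense(rng, d, cfg.branch_dim, activation="relu")
        self.structured_dense = Dense(rng, cfg.structured_dim, cfg.branch_dim,
                                      activation="relu")
        self.head = _ClassifierHead(rng, 3 * cfg.branch_dim, cfg.head_dims)

    def _encode_window(self, values: np.ndarray, mask: np.ndarray) -> Tensor:
        x = positional_encode(Tensor(values) @ self.proj.w + self.proj.b)
        x = self.stack(x, mask)
        center = x[:, values.shape[1] // 2, :]
        return self.center_dense(center)

    def logits(self, batch: EncodedBatch) -> Tensor:
        d_ref = self._encode_window(batch.ref_values, batch.ref_mask)
        d_alt = self._encode_window(batch.alt_values, batch.alt_mask)
        s = self.structured_dense(Tensor(batch.structured))
        merged = concat([d_alt, d_alt - d_ref, s], axis=-1)
        return self.head(merged)

    def forward(self, batch: EncodedBatch) -> Tensor:
        return self.logits(batch).softmax(axis=-1)


class Architecture2(Module):
    """Alternate-window transformer + language-model-embedding classifier."""

    architecture = 2

    def __init__(self, cfg: ModelConfig, seed: int):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d = cfg.model_dim
        self.proj = Dense(rng, cfg.input_channels, d)
        self.stack = TransformerStack(rng, d, cfg.n_heads, cfg.ffn_dim,
                                      cfg.n_layers)
        self.center_dense = Dense(rng, d, cfg.branch_dim, activation="relu")
        if cfg.branch_dim % 2:
            raise ValueError("branch_dim must be even for the BiLSTM summary")
        self.lstm = BiLSTM(rng, cfg.embed_dim, cfg.branch_dim // 2)
        self.structured_dense = Dense(rng, cfg.structured_dim, cfg.branch_dim,
                                      activation="relu")
        self.head = _ClassifierHead(rng, 3 * cfg.branch_dim, cfg.head_dims)

    def logits(self, batch: EncodedBatch) -> Tensor:
        if batch.alt_embedding.shape[-1] != self.cfg.embed_dim:
            raise ValueError(
                f"embedder output width {batch.alt_embedding.shape[-1]} != "
                f"configured embed_dim {self.cfg.embed_dim}")
        x = positional_encode(Tensor(batch.alt_values) @ self.proj.w + self.proj.b)
        x = self.stack(x, batch.alt_mask)
        center = self.center_dense(x[:, batch.alt_values.shape[1] // 2, :])
        lm = self.lstm(Tensor(batch.alt_embedding))
        s = self.structured_dense(Tensor(batch.structured))
        merged = concat([lm, center, s], axis=-1)
        return self.head(merged)

    def forward(self, batch: EncodedBatch) -> Tensor:
        return self.logits(batch).softmax(axis=-1)


def build_model(architecture: int, cfg: ModelConfig, seed: int) -> Module:
    if architecture == 1:
        return Architecture1(cfg, seed)
    if architecture == 2:
        return Architecture2(cfg, seed)
    raise ValueError(f"unknown architecture {architecture}")


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MemberSpec:
    architecture: int
    class_weights: tuple = (1.0, 1.0, 1.0)  # (benign, dominant, recessive)

    def __post_init__(self):
        if self.architecture not in (1, 2):
            raise ValueError("architecture must be 1 or 2")
        if len(self.class_weights) != 3 or min(self.class_weights) <= 0:
            raise ValueError("class_weights must be 3 positive reals")


def default_ensemble_spec() -> list[MemberSpec]:
    """The published 8-member composition: three architecture-1 members with
    class weights (1,1,1), (1,2,7), (1,2,7); five architecture-2 members with
    (1,1,1) x3, (1,2,3), (1,2,7)."""
    return [
        MemberSpec(1, (1, 1, 1)),
        MemberSpec(1, (1, 2, 7)),
        MemberSpec(1, (1, 2, 7)),
        MemberSpec(2, (1, 1, 1)),
        MemberSpec(2, (1, 1, 1)),
        MemberSpec(2, (1, 1, 1)),
        MemberSpec(2, (1, 2, 3)),
        MemberSpec(2, (1, 2, 7)),
    ]


class Ensemble:
    """A set of trained members whose softmax outputs are averaged."""

    def __init__(self, members: Sequence[Module],
                 specs: Sequence[MemberSpec],
                 normalizer: Optional[QuantileNormalizer] = None):
        if not members:
            raise ValueError("ensemble needs at least one member")
        if len(members) != len(specs):
            raise ValueError("one spec per member required")
        self.members = list(members)
        self.specs = list(specs)
        self.normalizer = normalizer

    def predict_proba(self, batch: EncodedBatch,
                      ablation: Iterable[str] = ()) -> np.ndarray:
        """(B, 3) arithmetic mean of member probability vectors."""
        if batch.size == 0:
            return np.zeros((0, 3))
        batch = batch.ablated(ablation) if ablation else batch
        acc = np.zeros((batch.size, 3))
        for m in self.members:
            acc += m.forward(batch).data
        return acc / len(self.members)

    def predict(self, batch: EncodedBatch,
                ablation: Iterable[str] = ()) -> list[ClassProbabilities]:
        return [ClassProbabilities.from_vector(row)
                for row in self.predict_proba(batch, ablation)]

    def parameter_counts(self) -> list[int]:
        return [m.n_parameters() for m in self.members]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_ensemble(path, ensemble: Ensemble) -> None:
    """Single-file parameter container with embedded config + format version."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "specs": [{"architecture": s.architecture,
                   "class_weights": list(s.class_weights)} for s in ensemble.specs],
        "configs": [asdict(m.cfg) for m in ensemble.members],
        "normalizer": (ensemble.normalizer.to_dict()
                       if ensemble.normalizer is not None else None),
    }
    arrays = {"__meta__": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for i, m in enumerate(ensemble.members):
        for j, p in enumerate(m.parameters()):
            arrays[f"m{i}_p{j}"] = p.data
    np.savez(path, **arrays)


def load_ensemble(path) -> Ensemble:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
        members, specs = [], []
        for i, (spec_d, cfg_d) in enumerate(zip(meta["specs"], meta["configs"])):
            cfg_d["head_dims"] = tuple(cfg_d["head_dims"])
            cfg = ModelConfig(**cfg_d)
            spec = MemberSpec(spec_d["architecture"],
                              tuple(spec_d["class_weights"]))
            model = build_model(spec.architecture, cfg, seed=0)
            for j, p in enumerate(model.parameters()):
                p.data[...] = z[f"m{i}_p{j}"]
            members.append(model)
            specs.append(spec)
        norm = (QuantileNormalizer.from_dict(meta["normalizer"])
                if meta["normalizer"] else None)
    return Ensemble(members, specs, normalizer=norm)
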