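import numpy as np
import pytest

from mendelrank.models import HashEmbedder, ModelConfig
from mendelrank.synthetic import SynthConfig, gen_labeled_variants, gen_proteins

RADIUS = 8  # desk-scale context radius used throughout the fast tests


@pytest.fixture(scope="session")
def synth():
    """Small seeded synthetic dataset shared across tests."""
    cfg = SynthConfig(seed=11, n_genes=9, n_variants_per_class=15,
                      protein_length_range=(40, 70), signal_strength=1.0,
                      cohort_size=4, background_variants_per_sample=12)
    proteins, profiles = gen_proteins(cfg)
    variants = gen_labeled_variants(cfg, proteins)
    return cfg, proteins, profiles, variants


@pytest.fixture(scope="session")
def protein_map(synth):
    _, proteins, _, _ = synth
    return {p.transcript_id: p for p in proteins}


@pytest.fixture(scope="session")
def tiny_model_cfg():
    return ModelConfig(model_dim=16, n_layers=1, n_heads=2, ffn_dim=32,
                       head_dims=(32, 16, 3), window_len=2 * RADIUS + 1,
                       embed_dim=16)


@pytest.fixture(scope="session")
def embedder(tiny_model_cfg):
    return HashEmbedder(tiny_model_cfg.embed_dim, seed=0)


@pytest.fixture(scope="session")
def tiny_batch(synth, protein_map, tiny_model_cfg, embedder):
    """Encoded batch of the synthetic variants at desk scale."""
    from mendelrank.pipeline import encode_dataset, fit_normalizer
    _, _, profiles, variants = synth
    normalizer = fit_normalizer(variants)
    batch, labels = encode_dataset(variants, protein_map, profiles, embedder,
                                   radius=RADIUS, normalizer=normalizer)
    return batch, labels, normalizer
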