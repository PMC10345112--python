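"""Seeded generators for every input the toolkit consumes.

The generators emulate the *shape* of the real inputs — proteins with
conservation profiles, three-class variant tables with structured
annotations, control cohorts, and gene-phenotype score matrices — with
analytically controlled class separability rather than population-genetic
realism.  Benign variants carry higher allele frequencies and homozygote
counts; dominant and recessive variants carry elevated gene-constraint
scores in class-specific directions, and pathogenic variants sit on
conserved motif positions whose profile signal scales with
``signal_strength`` (0 = no class signal anywhere).

Everything is a deterministic function of ``SynthConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datasets import Label
from .encoding import (
    AMINO_ACIDS,
    N_PROFILE,
    ConservationProfile,
    EditType,
    ProteinRecord,
    StructuredFeatures,
    VariantEdit,
)
from .models import ClassProbabilities
from .prioritization import PhenoScoreTable, VariantCall, Zygosity

EDIT_TYPES = (EditType.MISSENSE, EditType.DELETION, EditType.INSERTION,
              EditType.FRAMESHIFT, EditType.STOP_GAIN, EditType.STOP_LOSS)

# per-class mean offsets (units of signal_strength) for the structured
# features, ordered as encoding.FEATURE_NAMES; benign is the reference level
_CLASS_DIRECTIONS = {
    Label.BENIGN: np.zeros(12),
    #               af  hom  pli prec pnull misz lofz pext ccr  gdi  rvis gerp
    Label.DOMINANT: np.array(
        [0.0, 0.0, 2.0, 0.0, -1.0, 2.0, 2.0, 1.0, 2.0, -1.0, -2.0, 1.0]),
    Label.RECESSIVE: np.array(
        [0.0, 0.0, 0.0, 2.0, -1.0, 0.5, 0.5, 1.0, 0.5, -0.5, -0.5, 1.0]),
}


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_genes: int = 30
    n_variants_per_class: int = 60
    protein_length_range: tuple = (80, 160)
    signal_strength: float = 1.0
    cohort_size: int = 10
    background_variants_per_sample: int = 30
    n_hpo_terms: int = 8
    profile_motif_width: int = 5

    def __post_init__(self):
        for name in ("n_genes", "n_variants_per_class", "cohort_size",
                     "background_variants_per_sample", "n_hpo_terms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SyntheticVariant:
    variant_id: str
    gene_id: str
    transcript_id: str
    label: Label
    edit: VariantEdit
    features: StructuredFeatures


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def gen_proteins(cfg: SynthConfig
                 ) -> tuple[list[ProteinRecord], dict[str, ConservationProfile]]:
    """Random proteins with smooth conservation profiles and a conserved
    motif site per gene (used as the pathogenic variant hot spot)."""
    rng = np.random.default_rng((cfg.seed, 1))
    lo, hi = cfg.protein_length_range
    proteins, profiles = [], {}
    for g in range(cfg.n_genes):
        gene = f"GENE{g:04d}"
        tx = f"TX{g:04d}"
        L = int(rng.integers(lo, hi + 1))
        seq = _random_peptide(rng, L)
        # smooth base profile: random walk per feature, standardized
        steps = rng.standard_normal((L, N_PROFILE)) * 0.3
        base = np.cumsum(steps, axis=0)
        base -= base.mean(axis=0, keepdims=True)
        # conserved motif bump centered mid-protein (class-informative site)
        motif_center = L // 2
        offsets = np.arange(L) - motif_center
        bump = np.exp(-0.5 * (offsets / max(1, cfg.profile_motif_width)) ** 2)
        base[:, : N_PROFILE // 2] += cfg.signal_strength * bump[:, None]
        proteins.append(ProteinRecord(tx, gene, seq, is_canonical=True,
                                      median_expression=float(rng.uniform(1, 10))))
        profiles[tx] = ConservationProfile(tx, base)
    return proteins, profiles


def _sample_features(rng: np.random.Generator, label: Label,
                     signal: float) -> StructuredFeatures:
    direction = _CLASS_DIRECTIONS[label] * signal
    base = rng.standard_normal(12) * 0.5 + direction
    # allele frequency: log-uniform around a common base; the benign class
    # shifts up and the pathogenic classes down by an amount proportional to
    # the signal, so signal 0 leaves every feature uninformative
    expo = rng.uniform(-6.0, -4.0)
    if label is Label.BENIGN:
        af = 10.0 ** min(expo + 0.9 * signal, -1.3)
        hom = float(rng.poisson(2.0 * max(signal, 0.0)))
    else:
        af = 10.0 ** max(expo - 0.4 * signal, -9.0)
        hom = 0.0
    vec = base.copy()
    vec[0] = af
    vec[1] = hom
    # probability-like features squash to [0, 1]
    for i in (2, 3, 4, 7, 8):
        vec[i] = 1.0 / (1.0 + np.exp(-vec[i]))
    return StructuredFeatures.from_vector(vec)


def _random_edit(rng: np.random.Generator, protein: ProteinRecord,
                 position: Optional[int] = None) -> VariantEdit:
    L = len(protein.sequence)
    t = EDIT_TYPES[rng.integers(0, len(EDIT_TYPES))]
    if t is EditType.STOP_LOSS:
        return VariantEdit(t, L, "", _random_peptide(rng, int(rng.integers(1, 8))))
    pos = int(position if position is not None else rng.integers(1, L + 1))
    ref1 = protein.sequence[pos - 1]
    if t is EditType.MISSENSE:
        alt = rng.choice([a for a in AMINO_ACIDS if a != ref1])
        return VariantEdit(t, pos, ref1, str(alt))
    if t is EditType.DELETION:
        span = int(rng.integers(1, min(4, L - pos + 1) + 1))
        return VariantEdit(t, pos, protein.sequence[pos - 1: pos - 1 + span], "")
    if t is EditType.INSERTION:
        return VariantEdit(t, pos, "", _random_peptide(rng, int(rng.integers(1, 4))))
    if t is EditType.FRAMESHIFT:
        return VariantEdit(t, pos, ref1, _random_peptide(rng, int(rng.integers(0, 12))))
    return VariantEdit(t, pos, ref1, "")  # stop_gain


def gen_labeled_variants(cfg: SynthConfig, proteins: Sequence[ProteinRecord]
                         ) -> list[SyntheticVariant]:
    """Three balanced classes with gene-wise class assignment.

    Genes rotate through benign-only / dominant / recessive roles so that
    gene-disjoint splits put whole classes of a gene on one side.  Pathogenic
    variants sit on the gene's conserved motif site; benign variants avoid
    it.
    """
    rng = np.random.default_rng((cfg.seed, 2))
    roles = {}
    for i, p in enumerate(proteins):
        roles[p.gene_id] = (Label.BENIGN, Label.DOMINANT, Label.RECESSIVE)[i % 3]
    by_role = {lab: [p for p in proteins if roles[p.gene_id] is lab]
               for lab in (Label.BENIGN, Label.DOMINANT, Label.RECESSIVE)}
    variants: list[SyntheticVariant] = []
    counter = 0
    for label in (Label.BENIGN, Label.DOMINANT, Label.RECESSIVE):
        for _ in range(cfg.n_variants_per_class):
            # benign variants appear on genes of every role; pathogenic ones
            # concentrate on genes of the matching role in proportion to the
            # signal (at signal 0 even gene identity carries no class
            # information, so a null dataset is null all the way down)
            role_informative = rng.random() < min(1.0, cfg.signal_strength)
            hosts = (by_role[label]
                     if label is not Label.BENIGN and role_informative
                     else proteins)
            protein = hosts[rng.integers(0, len(hosts))]
            L = len(protein.sequence)
            # placement carries class information only in proportion to the
            # signal: with probability min(1, signal) pathogenic variants sit
            # on the conserved motif and benign variants avoid it; otherwise
            # positions are uniform, so signal 0 leaves placement blind
            informative = rng.random() < min(1.0, cfg.signal_strength)
            if not informative:
                pos = int(rng.integers(1, L + 1))
            elif label is Label.BENIGN:
                edge = max(1, L // 5)
                side = rng.integers(0, 2)
                pos = int(rng.integers(1, edge + 1)) if side == 0 \
                    else int(rng.integers(L - edge, L + 1))
            else:
                jitter = int(rng.integers(-2, 3))
                pos = int(np.clip(L // 2 + jitter, 1, L))
            edit = _random_edit(rng, protein, position=pos)
            features = _sample_features(rng, label, cfg.signal_strength)
            variants.append(SyntheticVariant(
                f"var{counter:05d}", protein.gene_id, protein.transcript_id,
                label, edit, features))
            counter += 1
    return variants


def _benign_probs(rng: np.random.Generator) -> ClassProbabilities:
    raw = rng.dirichlet((20.0, 1.0, 1.0))
    return ClassProbabilities.from_vector(raw)


def gen_cohort(cfg: SynthConfig, variants: Sequence[SyntheticVariant],
               causal: Optional[dict[str, tuple[str, Zygosity]]] = None
               ) -> dict[str, list[VariantCall]]:
    """Per-sample call tables of benign-leaning background variants.

    ``causal`` optionally maps sample_id -> (variant_id, zygosity) to inject
    a designated causal call (probabilities strongly pathogenic, honoring
    the requested zygosity).  Depth and allele reads are drawn to pass the
    default quality filter most of the time, with realistic failures mixed
    in.
    """
    rng = np.random.default_rng((cfg.seed, 3))
    benign_pool = [v for v in variants if v.label is Label.BENIGN] or list(variants)
    by_id = {v.variant_id: v for v in variants}
    cohort: dict[str, list[VariantCall]] = {}
    for s in range(cfg.cohort_size):
        sample = f"sample{s:03d}"
        calls: list[VariantCall] = []
        picks = rng.choice(len(benign_pool),
                           size=min(cfg.background_variants_per_sample,
                                    len(benign_pool)),
                           replace=False)
        for j in picks:
            v = benign_pool[j]
            depth = int(rng.integers(15, 80))
            zyg = Zygosity.HET if rng.random() < 0.8 else Zygosity.HOM
            alt = int(rng.binomial(depth, 0.5 if zyg is Zygosity.HET else 0.97))
            calls.append(VariantCall(
                v.variant_id, v.gene_id, zyg, _benign_probs(rng),
                haplotype_group=int(rng.integers(0, 4)),
                depth=depth, alt_reads=alt, ref_reads=depth - alt,
                pop_af=float(min(v.features.gnomad_af, 1.0)),
                cohort_freq=float(rng.uniform(0, 0.02))))
        if causal and sample in causal:
            vid, zyg = causal[sample]
            v = by_id[vid]
            zyg = Zygosity(zyg)
            probs = (ClassProbabilities(0.02, 0.95, 0.03)
                     if zyg is Zygosity.HET else ClassProbabilities(0.02, 0.03, 0.95))
            depth = int(rng.integers(30, 80))
            alt = int(rng.binomial(depth, 0.5 if zyg is Zygosity.HET else 0.97))
            calls.append(VariantCall(
                vid, v.gene_id, zyg, probs,
                haplotype_group=int(rng.integers(0, 4)),
                depth=depth, alt_reads=alt, ref_reads=depth - alt,
                pop_af=1e-6, cohort_freq=0.0))
        cohort[sample] = calls
    return cohort


def gen_pheno_scores(cfg: SynthConfig, genes: Sequence[str],
                     causal_genes: Sequence[str] = ()
                     ) -> tuple[PhenoScoreTable, np.ndarray, np.ndarray]:
    """GADO-style Z matrix (genes x HPO terms) plus its squashed score table.

    Background entries are standard normal (so transformed scores center on
    0.5); causal genes carry known associations, which the transform clamps
    to Z = 3 before the logistic squash.
    """
    from .prioritization import gado_transform

    rng = np.random.default_rng((cfg.seed, 4))
    z = rng.standard_normal((len(genes), cfg.n_hpo_terms))
    known = np.zeros_like(z, dtype=bool)
    causal_set = set(causal_genes)
    for i, g in enumerate(genes):
        if g in causal_set:
            known[i, :] = True
    table = gado_transform(z, known=known, genes=list(genes))
    return table, z, known
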