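"""Zygosity-aware candidate ranking within a sample.

Per-variant three-class probabilities become candidate scores as follows:
heterozygous calls are ranked by their dominant score, homozygous calls by
their recessive score, and every pair of heterozygous calls on one gene (on
different haplotypes) forms a compound-heterozygote candidate scored by the
harmonic mean of the two recessive scores — so a pair of identical variants
scores exactly like a homozygote.  Candidates can then be filtered by the
observed inheritance pattern and fused with a per-gene phenotype score (the
arithmetic mean of the two), and are ranked by descending score with a
deterministic tie-break.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .models import ClassProbabilities

UNRANKED = 0  # sentinel returned when the causal candidate is absent

DEFAULT_PHENO_SCORE = 0.5


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"


class CandidateMode(str, enum.Enum):
    DOMINANT_HET = "dominant_het"
    RECESSIVE_HOM = "recessive_hom"
    RECESSIVE_COMPHET = "recessive_comphet"


class InheritancePattern(str, enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class VariantCall:
    variant_id: str
    gene_id: str
    zygosity: Zygosity
    probs: ClassProbabilities
    haplotype_group: Optional[int] = None
    depth: int = 0
    alt_reads: int = 0
    ref_reads: int = 0
    pop_af: float = 0.0
    cohort_freq: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "zygosity", Zygosity(self.zygosity))
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


@dataclass(frozen=True)
class CandidateScore:
    candidate_id: tuple  # (variant_id,) or sorted pair of variant ids
    gene_id: str
    mode: CandidateMode
    final_score: float
    fused_score: Optional[float] = None

    @property
    def sort_score(self) -> float:
        return self.fused_score if self.fused_score is not None else self.final_score


@dataclass(frozen=True)
class QualityConfig:
    min_depth: int = 20
    min_alt_fraction_of_ref: float = 0.5  # het: alt_reads >= 0.5 * ref_reads
    max_pop_af: float = 0.01
    max_cohort_freq: float = 0.01


def quality_filter(call: VariantCall,
                   cfg: QualityConfig = QualityConfig()) -> bool:
    """True = keep.  Depth >= 20; het calls need alt support at least half
    the reference support; population and cohort frequency capped at 1%."""
    if call.depth < cfg.min_depth:
        return False
    if (call.zygosity is Zygosity.HET
            and call.alt_reads < cfg.min_alt_fraction_of_ref * call.ref_reads):
        return False
    if call.pop_af > cfg.max_pop_af:
        return False
    if call.cohort_freq > cfg.max_cohort_freq:
        return False
    return True


def harmonic_mean(a: float, b: float) -> float:
    """HM(a, b) = 2ab/(a+b), with HM(0, 0) defined as its limit, 0."""
    if a < 0 or b < 0:
        raise ValueError("harmonic mean defined for non-negative scores")
    if a + b == 0:
        return 0.0
    return 2.0 * a * b / (a + b)


def final_scores(calls: Sequence[VariantCall],
                 blacklist: Iterable[str] = ()) -> list[CandidateScore]:
    """Build all candidates for one sample from quality-passed calls.

    One dominant candidate per heterozygous call, one recessive candidate per
    homozygous call, and one compound-het candidate per pair of heterozygous
    calls sharing a gene but not a haplotype group.  ``blacklist`` drops
    variant ids seen in unaffected samples.
    """
    blacklist = set(blacklist)
    calls = [c for c in calls if c.variant_id not in blacklist]
    out: list[CandidateScore] = []
    by_gene: dict[str, list[VariantCall]] = {}
    for call in calls:
        if call.zygosity is Zygosity.HET:
            out.append(CandidateScore((call.variant_id,), call.gene_id,
                                      CandidateMode.DOMINANT_HET,
                                      call.probs.dominant))
            by_gene.setdefault(call.gene_id, []).append(call)
        else:
            out.append(CandidateScore((call.variant_id,), call.gene_id,
                                      CandidateMode.RECESSIVE_HOM,
                                      call.probs.recessive))
    for gene, hets in by_gene.items():
        for a, b in itertools.combinations(hets, 2):
            if (a.haplotype_group is not None and b.haplotype_group is not None
                    and a.haplotype_group == b.haplotype_group):
                continue
            pair = tuple(sorted((a.variant_id, b.variant_id)))
            out.append(CandidateScore(
                pair, gene, CandidateMode.RECESSIVE_COMPHET,
                harmonic_mean(a.probs.recessive, b.probs.recessive)))
    return out


class PhenoScoreTable:
    """Per-gene phenotype relevance scores in [0, 1]; absent genes -> 0.5."""

    def __init__(self, scores: Mapping[str, float] = (),
                 default: float = DEFAULT_PHENO_SCORE):
        self._scores = dict(scores)
        bad = {g: s for g, s in self._scores.items() if not 0.0 <= s <= 1.0}
        if bad:
            raise ValueError(f"phenotype scores outside [0, 1]: {bad}")
        self.default = default

    def __getitem__(self, gene_id: str) -> float:
        return self._scores.get(gene_id, self.default)

    def __len__(self) -> int:
        return len(self._scores)

    def items(self):
        return self._scores.items()


def fuse_phenotype(cand: CandidateScore,
                   pheno: PhenoScoreTable) -> CandidateScore:
    """Arithmetic mean of the candidate's final score and its gene's
    phenotype score; compound-het pairs use their shared gene's score."""
    fused = 0.5 * (cand.final_score + pheno[cand.gene_id])
    return replace(cand, fused_score=fused)


def gado_transform(z: np.ndarray, known: Optional[np.ndarray] = None,
                   genes: Optional[Sequence[str]] = None,
                   term_indices: Optional[Sequence[int]] = None
                   ) -> PhenoScoreTable:
    """Turn a genes x HPO-terms Z-score matrix into per-gene phenotype scores.

    Known gene-term associations are first clamped to Z = 3; a unit-scale
    logistic squashes Z to (0, 1) so the matrix centers on 0.5; the gene's
    score for a term set is the arithmetic mean over the selected terms.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2:
        raise ValueError("Z matrix must be genes x terms")
    if known is not None:
        known = np.asarray(known, dtype=bool)
        if known.shape != z.shape:
            raise ValueError("known-association mask must match Z shape")
        z = np.where(known, 3.0, z)
    if term_indices is None:
        term_indices = list(range(z.shape[1]))
    if len(term_indices) == 0:
        raise ValueError("empty HPO term set")
    s = 1.0 / (1.0 + np.exp(-z[:, list(term_indices)]))
    per_gene = s.mean(axis=1)
    if genes is None:
        genes = [f"gene{i}" for i in range(z.shape[0])]
    return PhenoScoreTable(dict(zip(genes, per_gene)))


def select_hpo_terms(terms: Sequence[str], max_terms: int = 5,
                     seed: int = 0) -> list[str]:
    """At most ``max_terms`` HPO terms, sampled reproducibly when over cap."""
    if len(terms) <= max_terms:
        return list(terms)
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(terms), size=max_terms, replace=False))
    return [terms[i] for i in idx]


def inheritance_filter(cands: Iterable[CandidateScore],
                       mode: InheritancePattern) -> list[CandidateScore]:
    """Keep only candidates compatible with the observed inheritance."""
    mode = InheritancePattern(mode)
    if mode is InheritancePattern.UNKNOWN:
        return list(cands)
    if mode is InheritancePattern.DOMINANT:
        keep = {CandidateMode.DOMINANT_HET}
    else:
        keep = {CandidateMode.RECESSIVE_HOM, CandidateMode.RECESSIVE_COMPHET}
    return [c for c in cands if c.mode in keep]


def rank(cands: Iterable[CandidateScore],
         use_fused: bool = False) -> list[CandidateScore]:
    """Total order: descending score, ties broken by candidate id."""
    def key(c: CandidateScore):
        score = c.fused_score if use_fused else c.final_score
        if score is None:
            raise ValueError("use_fused=True but candidate has no fused score")
        return (-score, c.candidate_id)
    return sorted(cands, key=key)


def rank_of(cands: Sequence[CandidateScore], causal_ids: Sequence[str],
            use_fused: bool = False) -> int:
    """1-based rank of the first candidate matching the causal variant(s).

    A single causal id matches any candidate containing it; a causal pair
    matches regardless of member order.  Returns ``UNRANKED`` (0) if absent.
    """
    causal = frozenset(causal_ids)
    for i, c in enumerate(rank(cands, use_fused=use_fused), start=1):
        cid = frozenset(c.candidate_id)
        if (len(causal) > 1 and cid == causal) or (len(causal) == 1 and causal <= cid):
            return i
    return UNRANKED


def count_pathogenic(cands: Iterable[CandidateScore],
                     threshold: float = 0.5) -> dict[CandidateMode, int]:
    """Per-mode counts of candidates scoring strictly above ``threshold``."""
    counts = {mode: 0 for mode in CandidateMode}
    for c in cands:
        if c.final_score > threshold:
            counts[c.mode] += 1
    return counts
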