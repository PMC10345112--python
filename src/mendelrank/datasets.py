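"""Curation, labeling, transcript-selection and splitting rules for building
training/test sets from ClinVar-style and OMIM-style tables.

These are pure functions over user-supplied tables; no live database access.
Every rejected record carries exactly one machine-readable reason code so the
filter attrition is auditable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .encoding import ProteinRecord


class Significance(str, enum.Enum):
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    BENIGN_LIKELY_BENIGN = "benign/likely_benign"
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC_LIKELY_PATHOGENIC = "pathogenic/likely_pathogenic"
    UNCERTAIN = "uncertain_significance"
    CONFLICTING = "conflicting"

    @property
    def is_benign(self) -> bool:
        return self in (Significance.BENIGN, Significance.LIKELY_BENIGN,
                        Significance.BENIGN_LIKELY_BENIGN)

    @property
    def is_pathogenic(self) -> bool:
        return self in (Significance.PATHOGENIC, Significance.LIKELY_PATHOGENIC,
                        Significance.PATHOGENIC_LIKELY_PATHOGENIC)


class ReviewStatus(str, enum.Enum):
    """ClinVar review tiers, ordered from weakest to strongest."""
    NO_ASSERTION = "no_assertion_criteria_provided"
    CONFLICTING = "criteria_provided,_conflicting_interpretations"
    SINGLE_SUBMITTER = "criteria_provided,_single_submitter"
    MULTIPLE_NO_CONFLICT = "criteria_provided,_multiple_submitters,_no_conflicts"
    EXPERT_PANEL = "reviewed_by_expert_panel"
    PRACTICE_GUIDELINE = "practice_guideline"

    @property
    def stars(self) -> int:
        return {
            ReviewStatus.NO_ASSERTION: 0,
            ReviewStatus.CONFLICTING: 0,
            ReviewStatus.SINGLE_SUBMITTER: 1,
            ReviewStatus.MULTIPLE_NO_CONFLICT: 2,
            ReviewStatus.EXPERT_PANEL: 3,
            ReviewStatus.PRACTICE_GUIDELINE: 4,
        }[self]


class InheritanceMode(str, enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    OTHER = "other"


class PhenotypeFlag(str, enum.Enum):
    NONDISEASE = "nondisease"       # brackets in OMIM
    SUSCEPTIBILITY = "susceptibility"  # braces
    PUTATIVE = "putative"           # question mark


class Label(str, enum.Enum):
    BENIGN = "benign"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


class RejectReason(str, enum.Enum):
    LOW_REVIEW_STATUS = "low_review_status"
    NON_GERMLINE = "non_germline"
    UNINFORMATIVE_SIGNIFICANCE = "uninformative_significance"
    NO_OMIM_PHENOTYPE = "no_omim_phenotype"
    UNKNOWN_PHENOTYPE = "unknown_phenotype"
    GENE_MISMATCH = "gene_mismatch"
    FLAGGED_PHENOTYPE = "flagged_phenotype"
    DUAL_INHERITANCE = "dual_inheritance"
    NO_MENDELIAN_MODE = "no_mendelian_mode"
    SPLICE_PROXIMAL = "splice_proximal"


@dataclass(frozen=True)
class ClinVarRecord:
    variant_id: str
    gene_id: str
    review_status: ReviewStatus
    significance: Significance
    origin: str = "germline"
    omim_phenotype_id: Optional[str] = None
    variant_type: str = "single_nucleotide_variant"
    splice_distance_bp: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "review_status", ReviewStatus(self.review_status))
        object.__setattr__(self, "significance", Significance(self.significance))


@dataclass(frozen=True)
class OmimPhenotype:
    phenotype_id: str
    gene_id: str
    inheritance_modes: frozenset = frozenset()
    flags: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "inheritance_modes",
                           frozenset(InheritanceMode(m) for m in self.inheritance_modes))
        object.__setattr__(self, "flags",
                           frozenset(PhenotypeFlag(f) for f in self.flags))


@dataclass(frozen=True)
class LabeledVariant:
    variant_id: str
    gene_id: str
    label: Label
    rule: str = ""  # which rule assigned the label, for audit


@dataclass(frozen=True)
class Rejection:
    variant_id: str
    reason: RejectReason


@dataclass(frozen=True)
class CurationConfig:
    """Knobs of the labeling rules; defaults follow the published procedure."""
    min_stars: int = 1
    benign_hom_count: int = 2   # homozygotes in population data => benign


def label_variant(rec: ClinVarRecord,
                  omim: Mapping[str, OmimPhenotype],
                  gnomad_hom_count: int = 0,
                  cfg: CurationConfig = CurationConfig()
                  ) -> LabeledVariant | Rejection:
    """Assign benign / dominant / recessive, or reject with a single reason.

    Variants seen homozygous in the population at least ``benign_hom_count``
    times are benign regardless of their clinical assertion.  Pathogenic
    assertions are resolved to a Mendelian class through the phenotype's
    inheritance mode; dual-mode, flagged, or gene-mismatched phenotypes are
    rejected.
    """
    if gnomad_hom_count >= cfg.benign_hom_count:
        return LabeledVariant(rec.variant_id, rec.gene_id, Label.BENIGN,
                              rule="population_homozygotes")
    if rec.origin != "germline":
        return Rejection(rec.variant_id, RejectReason.NON_GERMLINE)
    if rec.review_status.stars < cfg.min_stars:
        return Rejection(rec.variant_id, RejectReason.LOW_REVIEW_STATUS)
    sig = rec.significance
    if sig.is_benign:
        return LabeledVariant(rec.variant_id, rec.gene_id, Label.BENIGN,
                              rule="clinvar_benign")
    if not sig.is_pathogenic:
        return Rejection(rec.variant_id, RejectReason.UNINFORMATIVE_SIGNIFICANCE)
    if rec.omim_phenotype_id is None:
        return Rejection(rec.variant_id, RejectReason.NO_OMIM_PHENOTYPE)
    pheno = omim.get(rec.omim_phenotype_id)
    if pheno is None:
        return Rejection(rec.variant_id, RejectReason.UNKNOWN_PHENOTYPE)
    if pheno.gene_id != rec.gene_id:
        return Rejection(rec.variant_id, RejectReason.GENE_MISMATCH)
    if pheno.flags:
        return Rejection(rec.variant_id, RejectReason.FLAGGED_PHENOTYPE)
    modes = pheno.inheritance_modes & {InheritanceMode.DOMINANT,
                                       InheritanceMode.RECESSIVE}
    if len(modes) == 2:
        return Rejection(rec.variant_id, RejectReason.DUAL_INHERITANCE)
    if not modes:
        return Rejection(rec.variant_id, RejectReason.NO_MENDELIAN_MODE)
    mode = next(iter(modes))
    label = Label.DOMINANT if mode is InheritanceMode.DOMINANT else Label.RECESSIVE
    return LabeledVariant(rec.variant_id, rec.gene_id, label,
                          rule="clinvar_pathogenic_omim")


def splice_filter(rec: ClinVarRecord, max_distance_bp: int = 2) -> bool:
    """True = keep.  Variants within 2 bp of a canonical splice site drop."""
    if rec.splice_distance_bp is None:
        raise ValueError(f"{rec.variant_id}: splice_distance_bp is required")
    return rec.splice_distance_bp > max_distance_bp


def select_transcript(candidates: Sequence[ProteinRecord]) -> ProteinRecord:
    """Choose the single transcript to represent a variant.

    Canonical transcripts win; otherwise the highest-expression transcript.
    When several genes are affected, a gene whose canonical transcript is hit
    is preferred, then the highest-expression gene.  Ties break on the
    lexicographically smallest transcript id, so selection is deterministic.
    """
    if not candidates:
        raise ValueError("no candidate transcripts")
    genes: dict[str, list[ProteinRecord]] = {}
    for c in candidates:
        genes.setdefault(c.gene_id, []).append(c)

    def gene_key(gene: str):
        members = genes[gene]
        has_canonical = any(m.is_canonical for m in members)
        best_expr = max(m.median_expression for m in members)
        return (not has_canonical, -best_expr, gene)

    chosen_gene = min(genes, key=gene_key)

    def transcript_key(m: ProteinRecord):
        return (not m.is_canonical, -m.median_expression, m.transcript_id)

    return min(genes[chosen_gene], key=transcript_key)


def split_known_novel(test: Iterable[LabeledVariant],
                      train: Iterable[LabeledVariant]
                      ) -> tuple[set[str], set[str]]:
    """Partition test genes by whether training holds a pathogenic variant.

    Returns ``(known_genes, novel_genes)``.  Genes with only benign training
    variants count as novel.
    """
    pathogenic_train_genes = {v.gene_id for v in train if v.label is not Label.BENIGN}
    known, novel = set(), set()
    for v in test:
        (known if v.gene_id in pathogenic_train_genes else novel).add(v.gene_id)
    return known, novel


def make_gene_folds(pathogenic_genes: Iterable[str],
                    benign_only_genes: Iterable[str],
                    k: int, seed: int) -> list[set[str]]:
    """Split genes into ``k`` disjoint folds, stratified by whether the gene
    carries pathogenic variants.  Fold sizes within each stratum differ by at
    most one gene; the shuffle is seeded.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pathogenic = sorted(set(pathogenic_genes))
    benign_only = sorted(set(benign_only_genes) - set(pathogenic))
    if k > len(pathogenic) + len(benign_only):
        raise ValueError("more folds than genes")
    rng = np.random.default_rng(seed)
    folds: list[set[str]] = [set() for _ in range(k)]
    for stratum in (pathogenic, benign_only):
        order = rng.permutation(len(stratum))
        for i, idx in enumerate(order):
            folds[i % k].add(stratum[idx])
    return folds
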