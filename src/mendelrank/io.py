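"""Readers and writers for the package's interchange formats.

Everything is auditable text: FASTA for proteins (via Biopython), TSV for
conservation profiles, variant tables, cohort call tables and phenotype
scores, and JSON for run manifests.  Readers validate schemas and report
the offending column or line; write -> read round-trips are identities.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datasets import Label
from .encoding import (
    FEATURE_NAMES,
    N_PROFILE,
    ConservationProfile,
    ProteinRecord,
    StructuredFeatures,
    VariantEdit,
)
from .models import ClassProbabilities
from .prioritization import CandidateScore, PhenoScoreTable, VariantCall, Zygosity
from .synthetic import SyntheticVariant

VARIANT_COLUMNS = ("variant_id", "gene", "transcript", "edit_type", "position",
                   "ref_res", "alt_res", "label") + FEATURE_NAMES

COHORT_COLUMNS = ("sample_id", "variant_id", "gene", "zygosity",
                  "haplotype_group", "depth", "alt_reads", "ref_reads",
                  "pop_af", "cohort_freq", "p_benign", "p_dominant",
                  "p_recessive")


class TableFormatError(ValueError):
    """A structured parse error naming the file, column, or row at fault."""


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

def write_fasta(path, proteins: Sequence[ProteinRecord]) -> None:
    records = []
    for p in proteins:
        desc = (f"gene={p.gene_id} canonical={int(p.is_canonical)} "
                f"expression={p.median_expression:.17g}")
        records.append(SeqRecord(Seq(p.sequence), id=p.transcript_id,
                                 description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[ProteinRecord]:
    proteins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(item.split("=", 1) for item in rec.description.split()
                      if "=" in item)
        proteins.append(ProteinRecord(
            transcript_id=rec.id,
            gene_id=fields.get("gene", rec.id),
            sequence=str(rec.seq),
            is_canonical=bool(int(fields.get("canonical", "0"))),
            median_expression=float(fields.get("expression", "0"))))
    return proteins


# ---------------------------------------------------------------------------
# conservation profiles
# ---------------------------------------------------------------------------

def write_profiles(path, profiles: Mapping[str, ConservationProfile]) -> None:
    """Blocked TSV: a `transcript_id<TAB>ID` header line, then L rows of 30
    floats.  A sidecar ``<path>.idx`` maps transcript -> byte offset."""
    path = Path(path)
    offsets: dict[str, int] = {}
    with open(path, "w") as fh:
        for tx in sorted(profiles):
            offsets[tx] = fh.tell()
            fh.write(f"transcript_id\t{tx}\n")
            for row in profiles[tx].matrix:
                fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
    with open(path.with_suffix(path.suffix + ".idx"), "w") as fh:
        for tx, off in offsets.items():
            fh.write(f"{tx}\t{off}\n")


def read_profiles(path, transcripts: Optional[Iterable[str]] = None
                  ) -> dict[str, ConservationProfile]:
    """Read profile blocks; with an index file present, seeks directly to
    the requested transcripts instead of scanning."""
    path = Path(path)
    idx_path = path.with_suffix(path.suffix + ".idx")
    wanted = set(transcripts) if transcripts is not None else None
    out: dict[str, ConservationProfile] = {}

    def read_block(fh, tx: str) -> ConservationProfile:
        rows = []
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line or line.startswith("transcript_id\t"):
                fh.seek(pos)
                break
            vals = line.split()
            if len(vals) != N_PROFILE:
                raise TableFormatError(
                    f"{path}: transcript {tx}: expected {N_PROFILE} profile "
                    f"values per row, got {len(vals)}")
            rows.append([float(v) for v in vals])
        return ConservationProfile(tx, np.array(rows))

    if wanted is not None and idx_path.exists():
        index = {}
        with open(idx_path) as fh:
            for line in fh:
                tx, off = line.split("\t")
                index[tx] = int(off)
        with open(path) as fh:
            for tx in wanted:
                if tx not in index:
                    raise TableFormatError(f"{path}: transcript {tx} not in index")
                fh.seek(index[tx])
                header = fh.readline()
                out[tx] = read_block(fh, tx)
        return out

    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line:
                break
            if not line.startswith("transcript_id\t"):
                raise TableFormatError(f"{path}: malformed block header: {line!r}")
            tx = line.rstrip("\n").split("\t", 1)[1]
            block = read_block(fh, tx)
            if wanted is None or tx in wanted:
                out[tx] = block
    return out


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

def write_variant_table(path, variants: Sequence[SyntheticVariant]) -> None:
    rows = []
    for v in variants:
        row = {
            "variant_id": v.variant_id, "gene": v.gene_id,
            "transcript": v.transcript_id, "edit_type": v.edit.edit_type.value,
            "position": v.edit.position, "ref_res": v.edit.ref_residues or ".",
            "alt_res": v.edit.alt_residues or ".", "label": v.label.value,
        }
        row.update(dict(zip(FEATURE_NAMES, v.features.to_vector())))
        rows.append(row)
    pd.DataFrame(rows, columns=list(VARIANT_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_variant_table(path) -> list[SyntheticVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str},
                     float_precision="round_trip")
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            edit = VariantEdit(
                edit_type=row["edit_type"], position=int(row["position"]),
                ref_residues="" if row["ref_res"] == "." else str(row["ref_res"]),
                alt_residues="" if row["alt_res"] == "." else str(row["alt_res"]))
            features = StructuredFeatures.from_vector(
                [float(row[n]) for n in FEATURE_NAMES])
            out.append(SyntheticVariant(
                str(row["variant_id"]), str(row["gene"]), str(row["transcript"]),
                Label(row["label"]), edit, features))
        except (ValueError, KeyError) as exc:
            raise TableFormatError(f"{path}: row {i + 2}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# cohort call tables
# ---------------------------------------------------------------------------

def write_cohort(path, cohort: Mapping[str, Sequence[VariantCall]]) -> None:
    rows = []
    for sample, calls in cohort.items():
        for c in calls:
            rows.append({
                "sample_id": sample, "variant_id": c.variant_id,
                "gene": c.gene_id, "zygosity": c.zygosity.value,
                "haplotype_group": (-1 if c.haplotype_group is None
                                    else c.haplotype_group),
                "depth": c.depth, "alt_reads": c.alt_reads,
                "ref_reads": c.ref_reads, "pop_af": c.pop_af,
                "cohort_freq": c.cohort_freq,
                "p_benign": c.probs.benign, "p_dominant": c.probs.dominant,
                "p_recessive": c.probs.recessive,
            })
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_cohort(path) -> dict[str, list[VariantCall]]:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "sample_id": str},
                     float_precision="round_trip")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    cohort: dict[str, list[VariantCall]] = {}
    for i, row in df.iterrows():
        try:
            probs = ClassProbabilities(float(row["p_benign"]),
                                       float(row["p_dominant"]),
                                       float(row["p_recessive"]))
            hap = int(row["haplotype_group"])
            call = VariantCall(
                str(row["variant_id"]), str(row["gene"]),
                Zygosity(row["zygosity"]), probs,
                haplotype_group=None if hap < 0 else hap,
                depth=int(row["depth"]), alt_reads=int(row["alt_reads"]),
                ref_reads=int(row["ref_reads"]), pop_af=float(row["pop_af"]),
                cohort_freq=float(row["cohort_freq"]))
        except ValueError as exc:
            raise TableFormatError(f"{path}: row {i + 2}: {exc}") from exc
        cohort.setdefault(str(row["sample_id"]), []).append(call)
    return cohort


# ---------------------------------------------------------------------------
# phenotype scores and ranked candidates
# ---------------------------------------------------------------------------

def write_pheno_table(path, table: PhenoScoreTable) -> None:
    pd.DataFrame(sorted(table.items()), columns=["gene", "score"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_pheno_table(path) -> PhenoScoreTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if not {"gene", "score"} <= set(df.columns):
        raise TableFormatError(f"{path}: needs columns gene, score")
    return PhenoScoreTable(dict(zip(df["gene"].astype(str), df["score"])))


def write_ranked(path, ranked: Sequence[CandidateScore]) -> None:
    rows = []
    for i, c in enumerate(ranked, start=1):
        rows.append({
            "rank": i, "candidate_id": "+".join(c.candidate_id),
            "gene": c.gene_id, "mode": c.mode.value,
            "final_score": c.final_score,
            "fused_score": "" if c.fused_score is None else c.fused_score,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_predictions(path, variants: Sequence[SyntheticVariant],
                      probs: np.ndarray) -> None:
    rows = []
    for v, p in zip(variants, probs):
        rows.append({"variant_id": v.variant_id, "gene": v.gene_id,
                     "label": v.label.value, "p_benign": p[0],
                     "p_dominant": p[1], "p_recessive": p[2]})
    pd.DataFrame(rows, columns=["variant_id", "gene", "label", "p_benign",
                                "p_dominant", "p_recessive"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str},
                     float_precision="round_trip")
    needed = {"variant_id", "gene", "label", "p_benign", "p_dominant",
              "p_recessive"}
    missing = needed - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(out_dir, command: str, seed: Optional[int],
                   inputs: Mapping[str, str], config: Mapping) -> Path:
    """Record what produced a set of outputs: command, seed, input digests."""
    out_dir = Path(out_dir)
    digests = {}
    for name, p in inputs.items():
        p = Path(p)
        if p.exists() and p.is_file():
            digests[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        else:
            digests[name] = None
    manifest = {"command": command, "seed": seed, "inputs": digests,
                "config": dict(config), "format": 1}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
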