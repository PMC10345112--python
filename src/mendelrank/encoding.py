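"""Protein-context variant encoding.

A variant is represented to the classifier as a pair of context windows
centered on the edited residue: the reference window and the altered window.
Each window covers the residue of interest plus up to 100 residues of flanking
sequence on either side (201 positions total by default) and carries 51
channels per position:

    channels  0-19   one-hot residue identity (alphabet ACDEFGHIKLMNPQRSTVWY)
    channels 20-49   per-residue conservation profile (30 features, derived
                     from an alignment-profile HMM)
    channel  50      presence flag: 1 if the residue exists in the altered
                     protein, 0 if it has been (logically) deleted

Positions outside the protein or outside the window span are all-zero and
masked out of attention.  Edit application follows window-local rules:

* missense     — swap the one-hot identity at the center; conservation kept.
* deletion     — presence flag of the deleted span drops to 0; identity and
                 conservation are retained so the model still sees what was
                 removed and how conserved it was.
* insertion    — new columns appear after the center carrying the inserted
                 residues with zero conservation; the tail is trimmed so the
                 span stays fixed and everything up to the center is unchanged.
* frameshift   — downstream identities are overwritten by the novel peptide
                 (conservation of the original residues kept); residues past
                 the novel stop are logically deleted like a deletion.
* stop_gain    — the center residue and everything downstream is logically
                 deleted; conservation unchanged.
* stop_loss    — treated as an insertion of the read-through peptide after
                 the final residue.

The unknown residue ``X`` encodes as all-zero identity with presence 1, so it
stays attended.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA = 20
N_PROFILE = 30
N_CHANNELS = N_AA + N_PROFILE + 1  # 51
PRESENCE = N_CHANNELS - 1
DEFAULT_RADIUS = 100

#: sentinel for a missing structured-feature value (imputed before normalization)
MISSING = float("nan")

FEATURE_NAMES = (
    "gnomad_af", "gnomad_hom_count", "pli", "prec", "pnull", "mis_z",
    "lof_z", "pext", "ccr", "gdi", "rvis", "gerp",
)


class EditType(str, enum.Enum):
    MISSENSE = "missense"
    DELETION = "deletion"
    INSERTION = "insertion"
    FRAMESHIFT = "frameshift"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"


@dataclass(frozen=True)
class ProteinRecord:
    transcript_id: str
    gene_id: str
    sequence: str
    is_canonical: bool = False
    median_expression: float = 0.0

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError("protein sequence must be non-empty")
        bad = set(self.sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(f"invalid residues in {self.transcript_id}: {sorted(bad)}")


@dataclass(frozen=True)
class ConservationProfile:
    transcript_id: str
    matrix: np.ndarray  # (L, 30)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != N_PROFILE:
            raise ValueError(f"profile must be L x {N_PROFILE}, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("profile contains non-finite entries")
        object.__setattr__(self, "matrix", m)

    def check_against(self, protein: ProteinRecord) -> None:
        if self.matrix.shape[0] != len(protein.sequence):
            raise ValueError(
                f"profile rows ({self.matrix.shape[0]}) != protein length "
                f"({len(protein.sequence)}) for {protein.transcript_id}")


@dataclass(frozen=True)
class VariantEdit:
    """A protein-level edit at a 1-based residue position."""
    edit_type: EditType
    position: int
    ref_residues: str = ""
    alt_residues: str = ""

    def __post_init__(self):
        object.__setattr__(self, "edit_type", EditType(self.edit_type))
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        t = self.edit_type
        if t is EditType.DELETION and self.alt_residues:
            raise ValueError("deletion must have empty alt_residues")
        if t is EditType.INSERTION and self.ref_residues:
            raise ValueError("insertion must have empty ref_residues")
        if t is EditType.MISSENSE and (len(self.ref_residues) != 1
                                       or len(self.alt_residues) != 1):
            raise ValueError("missense edits a single residue")


@dataclass
class ContextWindow:
    """Fixed-length encoded span; ``mask[i]`` is True where attended."""
    values: np.ndarray  # (W, 51)
    mask: np.ndarray    # (W,) bool

    @property
    def width(self) -> int:
        return self.values.shape[0]

    @property
    def center(self) -> int:
        return self.width // 2

    def copy(self) -> "ContextWindow":
        return ContextWindow(self.values.copy(), self.mask.copy())

    def refresh_mask(self) -> None:
        self.mask = np.any(self.values != 0.0, axis=1)

    def decode(self) -> str:
        """Residue string of present positions (presence flag == 1)."""
        out = []
        for i in range(self.width):
            if self.values[i, PRESENCE] == 1.0:
                hot = np.flatnonzero(self.values[i, :N_AA])
                out.append(AMINO_ACIDS[hot[0]] if hot.size else "X")
        return "".join(out)


def one_hot(residue: str) -> np.ndarray:
    v = np.zeros(N_AA)
    if residue != "X":
        v[AA_INDEX[residue]] = 1.0
    return v


def extract_window(protein: ProteinRecord, profile: ConservationProfile,
                   center: int, radius: int = DEFAULT_RADIUS) -> ContextWindow:
    """Encode the reference context window centered at residue ``center``.

    Raises ``IndexError`` when ``center`` falls outside the protein.
    """
    L = len(protein.sequence)
    if not 1 <= center <= L:
        raise IndexError(f"center {center} out of bounds for protein of length {L}")
    profile.check_against(protein)
    W = 2 * radius + 1
    values = np.zeros((W, N_CHANNELS))
    lo = max(1, center - radius)
    hi = min(L, center + radius)
    for pos in range(lo, hi + 1):
        w = pos - center + radius
        values[w, :N_AA] = one_hot(protein.sequence[pos - 1])
        values[w, N_AA:N_AA + N_PROFILE] = profile.matrix[pos - 1]
        values[w, PRESENCE] = 1.0
    win = ContextWindow(values, np.zeros(W, dtype=bool))
    win.refresh_mask()
    return win


def _check_ref(win: ContextWindow, edit: VariantEdit) -> None:
    """Validate that the window's residues match the edit's stated reference."""
    c = win.center
    for k, expected in enumerate(edit.ref_residues):
        w = c + k
        if w >= win.width:
            break  # span extends past the window; cannot check further
        if win.values[w, PRESENCE] != 1.0:
            raise ValueError(
                f"edit at position {edit.position + k} targets an absent residue")
        hot = np.flatnonzero(win.values[w, :N_AA])
        actual = AMINO_ACIDS[hot[0]] if hot.size else "X"
        if actual != expected:
            raise ValueError(
                f"reference mismatch at position {edit.position + k}: "
                f"window has {actual!r}, edit expects {expected!r}")


def _logical_delete(values: np.ndarray, rows: slice | np.ndarray) -> None:
    # Presence drops to 0; identity and conservation are retained so the
    # original sequence's conservation stays visible to the model.
    values[rows, PRESENCE] = 0.0


def apply_edit(ref_window: ContextWindow, edit: VariantEdit) -> ContextWindow:
    """Apply a protein-level edit to a reference window (window-local)."""
    win = ref_window.copy()
    v = win.values
    c = win.center
    W = win.width
    t = edit.edit_type

    if t is EditType.MISSENSE:
        _check_ref(win, edit)
        v[c, :N_AA] = one_hot(edit.alt_residues)
    elif t is EditType.DELETION:
        if not edit.ref_residues:
            raise ValueError("deletion needs a non-empty ref span")
        _check_ref(win, edit)
        end = min(c + len(edit.ref_residues), W)
        _logical_delete(v, slice(c, end))
    elif t in (EditType.INSERTION, EditType.STOP_LOSS):
        if not edit.alt_residues:
            raise ValueError(f"{t.value} needs inserted residues")
        ins = edit.alt_residues
        k = len(ins)
        # everything after the center shifts right; the tail falls off
        tail_src = v[c + 1: W - k].copy() if c + 1 < W - k else np.zeros((0, N_CHANNELS))
        n_new = min(k, W - c - 1)
        v[c + 1 + n_new:] = tail_src[: W - (c + 1 + n_new)]
        for j in range(n_new):
            row = c + 1 + j
            v[row] = 0.0
            v[row, :N_AA] = one_hot(ins[j])
            v[row, PRESENCE] = 1.0
    elif t is EditType.FRAMESHIFT:
        if edit.ref_residues:
            _check_ref(win, edit)
        pep = edit.alt_residues
        n_new = min(len(pep), W - c)
        for j in range(n_new):
            row = c + j
            v[row, :N_AA] = one_hot(pep[j])
            v[row, PRESENCE] = 1.0  # novel residue exists even past old end
        # residues after the novel stop are logically deleted
        stop_row = c + n_new
        if stop_row < W:
            was_present = ref_window.values[stop_row:, PRESENCE] == 1.0
            rows = np.flatnonzero(was_present) + stop_row
            _logical_delete(v, rows)
    elif t is EditType.STOP_GAIN:
        if edit.ref_residues:
            _check_ref(win, edit)
        was_present = ref_window.values[c:, PRESENCE] == 1.0
        rows = np.flatnonzero(was_present) + c
        _logical_delete(v, rows)
    else:  # pragma: no cover
        raise ValueError(f"unsupported edit type {t}")

    win.refresh_mask()
    return win


def window_center_for(edit: VariantEdit, protein_length: int) -> int:
    """Residue index on which to center the window for this edit.

    Stop-loss read-through peptides attach after the final residue, so their
    window centers on the last residue of the reference protein.
    """
    if edit.edit_type is EditType.STOP_LOSS:
        return protein_length
    return edit.position


def encode_variant(protein: ProteinRecord, profile: ConservationProfile,
                   edit: VariantEdit, radius: int = DEFAULT_RADIUS
                   ) -> tuple[ContextWindow, ContextWindow]:
    """Build the (reference, altered) window pair for one variant."""
    center = window_center_for(edit, len(protein.sequence))
    ref_win = extract_window(protein, profile, center, radius=radius)
    return ref_win, apply_edit(ref_win, edit)


def aggregate_site_feature(track: Sequence[float], edit: VariantEdit) -> float:
    """Collapse a per-residue score track to a single value for an edit.

    Multi-residue spans take the maximum over the affected span; insertions
    take the maximum of the two flanking residues; single-residue edits take
    the residue's own value.
    """
    track = np.asarray(track, dtype=float)
    L = track.shape[0]
    pos0 = edit.position - 1
    t = edit.edit_type
    if t in (EditType.INSERTION, EditType.STOP_LOSS):
        left = min(pos0, L - 1)
        right = min(pos0 + 1, L - 1)
        flank = track[[left, right]]
        if flank.size == 0:
            raise ValueError("empty flank for insertion")
        return float(np.max(flank))
    span = max(1, len(edit.ref_residues))
    lo, hi = pos0, min(pos0 + span, L)
    if hi <= lo:
        raise ValueError("edit span is empty or outside the track")
    return float(np.max(track[lo:hi]))


@dataclass
class StructuredFeatures:
    """The 12 per-variant numeric annotations fed to the structured branch."""
    gnomad_af: float = MISSING
    gnomad_hom_count: float = MISSING
    pli: float = MISSING
    prec: float = MISSING
    pnull: float = MISSING
    mis_z: float = MISSING
    lof_z: float = MISSING
    pext: float = MISSING
    ccr: float = MISSING
    gdi: float = MISSING
    rvis: float = MISSING
    gerp: float = MISSING

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "StructuredFeatures":
        vec = list(vec)
        if len(vec) != len(FEATURE_NAMES):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {len(vec)}")
        return cls(**dict(zip(FEATURE_NAMES, map(float, vec))))
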