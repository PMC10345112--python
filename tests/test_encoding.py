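"""Context-window construction and edit application, checked against an
independent record-list oracle that applies edits to the protein as a list
of (residue, profile-row, presence) records and rebuilds the window."""

import numpy as np
import pytest

from mendelrank.encoding import (
    AMINO_ACIDS,
    N_AA,
    N_CHANNELS,
    N_PROFILE,
    PRESENCE,
    ConservationProfile,
    EditType,
    ProteinRecord,
    VariantEdit,
    aggregate_site_feature,
    apply_edit,
    encode_variant,
    extract_window,
    one_hot,
    window_center_for,
)

RADIUS = 8


def make_protein(seq: str, seed: int = 0) -> tuple[ProteinRecord, ConservationProfile]:
    rng = np.random.default_rng(seed)
    p = ProteinRecord("TX1", "G1", seq)
    prof = ConservationProfile("TX1", rng.standard_normal((len(seq), N_PROFILE)))
    return p, prof


# ---------------------------------------------------------------------------
# independent oracle: protein as a list of residue records
# ---------------------------------------------------------------------------

def oracle_records(protein, profile):
    return [{"aa": protein.sequence[i], "prof": profile.matrix[i].copy(),
             "present": True} for i in range(len(protein.sequence))]


def oracle_apply(records, edit: VariantEdit):
    """Apply the edit to the record list; returns (records, center_index)."""
    records = [dict(r) for r in records]
    pos0 = edit.position - 1
    t = edit.edit_type
    if t is EditType.MISSENSE:
        records[pos0]["aa"] = edit.alt_residues
        center = pos0
    elif t is EditType.DELETION:
        for i in range(pos0, min(pos0 + len(edit.ref_residues), len(records))):
            records[i]["present"] = False
        center = pos0
    elif t is EditType.INSERTION:
        new = [{"aa": aa, "prof": np.zeros(N_PROFILE), "present": True}
               for aa in edit.alt_residues]
        records = records[: pos0 + 1] + new + records[pos0 + 1:]
        center = pos0
    elif t is EditType.STOP_LOSS:
        center = len(records) - 1
        new = [{"aa": aa, "prof": np.zeros(N_PROFILE), "present": True}
               for aa in edit.alt_residues]
        records = records + new
    elif t is EditType.FRAMESHIFT:
        pep = edit.alt_residues
        for j, aa in enumerate(pep):
            if pos0 + j < len(records):
                records[pos0 + j]["aa"] = aa
                records[pos0 + j]["present"] = True
            else:
                records.append({"aa": aa, "prof": np.zeros(N_PROFILE),
                                "present": True})
        for i in range(pos0 + len(pep), len(records)):
            records[i]["present"] = False
        center = pos0
    elif t is EditType.STOP_GAIN:
        for i in range(pos0, len(records)):
            records[i]["present"] = False
        center = pos0
    return records, center


def oracle_window(records, center, radius=RADIUS):
    W = 2 * radius + 1
    values = np.zeros((W, N_CHANNELS))
    for w in range(W):
        i = center - radius + w
        if 0 <= i < len(records):
            r = records[i]
            values[w, :N_AA] = one_hot(r["aa"])
            values[w, N_AA:N_AA + N_PROFILE] = r["prof"]
            values[w, PRESENCE] = 1.0 if r["present"] else 0.0
    mask = np.any(values != 0.0, axis=1)
    return values, mask


def random_edit(rng, protein):
    L = len(protein.sequence)
    t = list(EditType)[rng.integers(0, 6)]
    if t is EditType.STOP_LOSS:
        pep = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(1, 6)))
        return VariantEdit(t, L, "", pep)
    pos = int(rng.integers(1, L + 1))
    ref1 = protein.sequence[pos - 1]
    if t is EditType.MISSENSE:
        alt = str(rng.choice([a for a in AMINO_ACIDS if a != ref1]))
        return VariantEdit(t, pos, ref1, alt)
    if t is EditType.DELETION:
        span = int(rng.integers(1, min(5, L - pos + 1) + 1))
        return VariantEdit(t, pos, protein.sequence[pos - 1: pos - 1 + span], "")
    if t is EditType.INSERTION:
        pep = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(1, 5)))
        return VariantEdit(t, pos, "", pep)
    if t is EditType.FRAMESHIFT:
        pep = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(0, 15)))
        return VariantEdit(t, pos, ref1, pep)
    return VariantEdit(t, pos, ref1, "")


# ---------------------------------------------------------------------------
# extract_window
# ---------------------------------------------------------------------------

def test_interior_window_fully_unmasked():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=500))
    p, prof = make_protein(seq, seed=1)
    win = extract_window(p, prof, 250, radius=100)
    assert win.width == 201
    assert win.mask.all()


def test_window_near_start_masks_out_of_protein_positions():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=150))
    p, prof = make_protein(seq, seed=2)
    win = extract_window(p, prof, 10, radius=100)
    # residues -90..0 do not exist: the first 91 positions are zero + masked
    assert not win.mask[:91].any()
    assert np.all(win.values[:91] == 0.0)
    assert win.mask[91:].all()


def test_short_protein_window_has_exact_unmasked_count():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=50))
    p, prof = make_protein(seq, seed=3)
    win = extract_window(p, prof, 25, radius=100)
    # brute-force enumeration: residues 1..50 all fall inside +-100 of 25
    assert int(win.mask.sum()) == 50


def test_center_out_of_bounds_raises():
    p, prof = make_protein("ACDEF")
    with pytest.raises(IndexError):
        extract_window(p, prof, 6)
    with pytest.raises(IndexError):
        extract_window(p, prof, 0)


# ---------------------------------------------------------------------------
# apply_edit: targeted cases
# ---------------------------------------------------------------------------

def test_missense_changes_only_center_one_hot():
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=60))
    p, prof = make_protein(seq, seed=4)
    pos = 30
    edit = VariantEdit(EditType.MISSENSE, pos, seq[pos - 1],
                       "A" if seq[pos - 1] != "A" else "V")
    ref, alt = encode_variant(p, prof, edit, radius=RADIUS)
    c = ref.center
    # conservation + presence identical everywhere
    assert np.array_equal(ref.values[:, N_AA:], alt.values[:, N_AA:])
    # one-hot differs only at the center
    diff_rows = np.flatnonzero(
        np.any(ref.values[:, :N_AA] != alt.values[:, :N_AA], axis=1))
    assert diff_rows.tolist() == [c]
    assert alt.values[c, AMINO_ACIDS.index(edit.alt_residues)] == 1.0


def test_missense_ref_mismatch_names_position_and_residue():
    p, prof = make_protein("ACDEFGHIKLMNPQRST")
    wrong = "W"
    edit = VariantEdit(EditType.MISSENSE, 5, wrong, "A")
    with pytest.raises(ValueError, match="position 5"):
        encode_variant(p, prof, edit, radius=RADIUS)


def test_deletion_zeroes_presence_only_on_span():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=60))
    p, prof = make_protein(seq, seed=5)
    edit = VariantEdit(EditType.DELETION, 30, seq[29:31], "")
    ref, alt = encode_variant(p, prof, edit, radius=RADIUS)
    c = ref.center
    changed = np.flatnonzero(np.any(ref.values != alt.values, axis=1))
    assert changed.tolist() == [c, c + 1]
    assert alt.values[c, PRESENCE] == 0.0 and alt.values[c + 1, PRESENCE] == 0.0
    # identity and conservation of the deleted residues are retained
    assert np.array_equal(ref.values[c, :PRESENCE], alt.values[c, :PRESENCE])


def test_insertion_preserves_left_context_bitwise():
    rng = np.random.default_rng(6)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=300))
    p, prof = make_protein(seq, seed=6)
    edit = VariantEdit(EditType.INSERTION, 150, "", "KWN")
    ref, alt = encode_variant(p, prof, edit, radius=100)
    # everything through the center (positions 1..101) is bit-identical
    assert np.array_equal(ref.values[:101], alt.values[:101])
    # inserted residues carry zero conservation and presence 1
    ins = alt.values[101:104]
    assert np.all(ins[:, N_AA:N_AA + N_PROFILE] == 0.0)
    assert np.all(ins[:, PRESENCE] == 1.0)
    assert alt.width == ref.width == 201


def test_stop_gain_and_frameshift_keep_downstream_conservation():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=60))
    p, prof = make_protein(seq, seed=7)
    sg = VariantEdit(EditType.STOP_GAIN, 30, seq[29], "")
    ref, alt = encode_variant(p, prof, sg, radius=RADIUS)
    cons = slice(N_AA, N_AA + N_PROFILE)
    assert np.array_equal(ref.values[:, cons], alt.values[:, cons])
    assert np.all(alt.values[ref.center:, PRESENCE] == 0.0)

    fs = VariantEdit(EditType.FRAMESHIFT, 30, seq[29], "AWK")
    ref, alt = encode_variant(p, prof, fs, radius=RADIUS)
    assert np.array_equal(ref.values[:, cons], alt.values[:, cons])
    c = ref.center
    assert alt.decode()[:3] != ""  # novel peptide present at the center
    assert np.all(alt.values[c: c + 3, PRESENCE] == 1.0)
    assert np.all(alt.values[c + 3:, PRESENCE] == 0.0)


def test_unknown_residue_x_is_present_but_identity_free():
    p = ProteinRecord("TX1", "G1", "ACXEFGHIKL")
    prof = ConservationProfile("TX1", np.ones((10, N_PROFILE)))
    win = extract_window(p, prof, 3, radius=3)
    c = win.center
    assert np.all(win.values[c, :N_AA] == 0.0)
    assert win.values[c, PRESENCE] == 1.0
    assert win.mask[c]


# ---------------------------------------------------------------------------
# fuzzed oracle equivalence (round-trip invariant)
# ---------------------------------------------------------------------------

def test_apply_edit_matches_record_oracle_over_1000_fuzzed_edits():
    rng = np.random.default_rng(42)
    n_checked = {t: 0 for t in EditType}
    for trial in range(1000):
        L = int(rng.integers(5, 60))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        p, prof = make_protein(seq, seed=int(rng.integers(1 << 31)))
        edit = random_edit(rng, p)
        ref, alt = encode_variant(p, prof, edit, radius=RADIUS)
        records, center = oracle_apply(oracle_records(p, prof), edit)
        exp_values, exp_mask = oracle_window(records, center)
        assert np.array_equal(alt.values, exp_values), (
            f"trial {trial}: {edit} on length-{L} protein")
        assert np.array_equal(alt.mask, exp_mask)
        n_checked[edit.edit_type] += 1
    assert all(v > 50 for v in n_checked.values()), n_checked


def test_masked_iff_all_zero_for_all_edit_types():
    rng = np.random.default_rng(43)
    for _ in range(200):
        L = int(rng.integers(5, 50))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        p, prof = make_protein(seq, seed=int(rng.integers(1 << 31)))
        edit = random_edit(rng, p)
        ref, alt = encode_variant(p, prof, edit, radius=RADIUS)
        for win in (ref, alt):
            all_zero = ~np.any(win.values != 0.0, axis=1)
            assert np.array_equal(win.mask, ~all_zero)


def test_decoded_alt_window_is_prefix_slice_of_string_edit():
    """Decoding present residues of the altered window reproduces the string
    produced by plain string editing, aligned at the window's left edge."""
    rng = np.random.default_rng(44)
    for _ in range(500):
        L = int(rng.integers(5, 60))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        p, prof = make_protein(seq, seed=int(rng.integers(1 << 31)))
        edit = random_edit(rng, p)
        _, alt = encode_variant(p, prof, edit, radius=RADIUS)
        pos0 = edit.position - 1
        t = edit.edit_type
        if t is EditType.MISSENSE:
            edited = seq[:pos0] + edit.alt_residues + seq[pos0 + 1:]
        elif t is EditType.DELETION:
            edited = seq[:pos0] + seq[pos0 + len(edit.ref_residues):]
        elif t in (EditType.INSERTION, EditType.STOP_LOSS):
            at = pos0 + 1 if t is EditType.INSERTION else L
            edited = seq[:at] + edit.alt_residues + seq[at:]
        elif t is EditType.FRAMESHIFT:
            edited = seq[:pos0] + edit.alt_residues
        else:  # stop_gain
            edited = seq[:pos0]
        center = window_center_for(edit, L)
        left = max(0, center - 1 - RADIUS)
        decoded = alt.decode()
        assert edited[left: left + len(decoded)] == decoded, (edit, seq)


# ---------------------------------------------------------------------------
# aggregate_site_feature
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("edit,track,expected", [
    (VariantEdit(EditType.DELETION, 1, "ACD", ""), [0.2, 0.9, 0.4], 0.9),
    (VariantEdit(EditType.INSERTION, 1, "", "W"), [0.3, 0.7, 0.1], 0.7),
    (VariantEdit(EditType.MISSENSE, 2, "C", "W"), [0.1, 0.42, 0.8], 0.42),
    (VariantEdit(EditType.STOP_GAIN, 3, "D", ""), [0.1, 0.2, 0.33], 0.33),
])
def test_aggregate_site_feature_rules(edit, track, expected):
    assert aggregate_site_feature(track, edit) == pytest.approx(expected)


def test_aggregate_site_feature_rejects_out_of_track_span():
    with pytest.raises(ValueError):
        aggregate_site_feature([0.1, 0.2],
                               VariantEdit(EditType.MISSENSE, 3, "A", "V"))
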