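"""Compensatory base change (CBC) counting on aligned sequence-structure pairs.

A column pair qualifies as a shared pair when both records base-pair their
residues at exactly those alignment columns (through each record's own
gap-aware position map) and both pairings are canonical.  A full CBC
changes both partners; a hemi-CBC exactly one.  Counts can be restricted
to a half-open column window (the truncated-alignment, helix-wise
workflow); a pair belongs to the window of its 5' column, so windowed
counts over a partition sum to the global counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .energy import is_canonical_pair
from .fold import HelixDecomposition, decompose_helices
from .records import GAP, partner_array


@dataclass
class CBCDetail:
    col5: int
    col3: int
    pair1: tuple[str, str]
    pair2: tuple[str, str]
    category: str  # full | hemi | none


@dataclass
class CBCReport:
    shared_pairs: int
    full_cbc: int
    hemi_cbc: int
    details: list[CBCDetail] = field(default_factory=list)


def _col_maps(gapped_seq: str) -> tuple[list[int], dict[int, int]]:
    """col->ungapped index (-1 at gaps) and ungapped->col."""
    col2pos = []
    pos2col = {}
    pos = 0
    for c, ch in enumerate(gapped_seq):
        if ch == GAP:
            col2pos.append(-1)
        else:
            col2pos.append(pos)
            pos2col[pos] = c
            pos += 1
    return col2pos, pos2col


def shared_pairs(
    seq1: str, struct1: str, seq2: str, struct2: str
) -> list[tuple[int, int]]:
    """Column pairs base-paired (canonically) in both aligned records.

    ``seq1``/``seq2`` are gapped alignment rows; ``struct1``/``struct2``
    are each record's dot-bracket over its own ungapped positions.
    """
    if len(seq1) != len(seq2):
        raise ValueError(f"aligned rows differ in length: {len(seq1)} vs {len(seq2)}")
    out: list[tuple[int, int]] = []
    maps = []
    for seq, struct in ((seq1, struct1), (seq2, struct2)):
        ungapped = seq.replace(GAP, "")
        if len(struct) != len(ungapped):
            raise ValueError(
                f"structure length {len(struct)} != ungapped sequence length {len(ungapped)}"
            )
        col2pos, pos2col = _col_maps(seq)
        out_partner = [-1] * len(seq)
        partner = partner_array(struct)
        for pos, mate in enumerate(partner):
            if mate >= 0:
                out_partner[pos2col[pos]] = pos2col[mate]
        maps.append(out_partner)
    p1, p2 = maps
    shared: list[tuple[int, int]] = []
    for c in range(len(seq1)):
        c2 = p1[c]
        if c2 > c and p2[c] == c2:
            if is_canonical_pair(seq1[c], seq1[c2]) and is_canonical_pair(seq2[c], seq2[c2]):
                shared.append((c, c2))
    return shared


def count_cbcs(
    seq1: str,
    struct1: str,
    seq2: str,
    struct2: str,
    columns: tuple[int, int] | None = None,
) -> CBCReport:
    """Count full and hemi CBCs over the shared pairs of two aligned records.

    ``columns`` restricts to a half-open window on the 5' column.
    Symmetric in the two records.
    """
    pairs = shared_pairs(seq1, struct1, seq2, struct2)
    details: list[CBCDetail] = []
    full = hemi = 0
    for c5, c3 in pairs:
        if columns is not None and not (columns[0] <= c5 < columns[1]):
            continue
        a1, b1 = seq1[c5], seq1[c3]
        a2, b2 = seq2[c5], seq2[c3]
        if a1 != a2 and b1 != b2:
            cat = "full"
            full += 1
        elif a1 != a2 or b1 != b2:
            cat = "hemi"
            hemi += 1
        else:
            cat = "none"
        details.append(CBCDetail(c5, c3, (a1, b1), (a2, b2), cat))
    n_shared = len(details)
    return CBCReport(n_shared, full, hemi, details)


def count_cbcs_aligned(alignment, id_a: str, id_b: str, columns=None) -> CBCReport:
    """CBC report for two records of a :class:`SeqStructAlignment` by id."""
    ids = alignment.ids
    ia, ib = ids.index(id_a), ids.index(id_b)
    seq_a, _ = alignment.gapped_strings(ia)
    seq_b, _ = alignment.gapped_strings(ib)
    return count_cbcs(
        seq_a,
        alignment.codes[ia].dotbracket,
        seq_b,
        alignment.codes[ib].dotbracket,
        columns,
    )


def helix_windows(gapped_seq: str, struct: str) -> dict[str, tuple[int, int]]:
    """Project one record's helix domains through its gap map to column
    windows (helixI/helixII/helixIII when three domains exist, else
    helix1..helixN)."""
    decomp: HelixDecomposition = decompose_helices(struct)
    _, pos2col = _col_maps(gapped_seq)
    names = (
        ["helixI", "helixII", "helixIII"]
        if decomp.n_helices == 3
        else [f"helix{i+1}" for i in range(decomp.n_helices)]
    )
    out: dict[str, tuple[int, int]] = {}
    for name, (start, end, _np) in zip(names, decomp.domains):
        out[name] = (pos2col[start], pos2col[end - 1] + 1)
    return out
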