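"""The 12-letter sequence-structure alphabet and its scoring model.

Each position of a folded sequence is the cross product of its nucleotide
(A, C, G, U) and its structural state (unpaired '.', paired left '(',
paired right ')').  The fixed symbol order is
A., A(, A), C., C(, C), G., G(, G), U., U(, U) — i.e. index = 3*nt + state
with state order (., (, )).  Gaps are encoded as -1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import validate_dotbracket

NTS = "ACGU"
STATES = ".()"
SYMBOLS = tuple(f"{n}{s}" for n in NTS for s in STATES)
N_SYMBOLS = 12
GAP_CODE = -1


def symbol_index(nt: str, state: str) -> int:
    return 3 * NTS.index(nt) + STATES.index(state)


@dataclass
class Code12:
    """A sequence-structure string over the 12-letter alphabet."""

    codes: np.ndarray  # int8, values 0..11
    seq: str
    dotbracket: str

    def __len__(self) -> int:
        return len(self.codes)

    def symbols(self) -> list[str]:
        return [SYMBOLS[c] for c in self.codes]


def encode12(seq: str, dotbracket: str) -> Code12:
    """Position-wise composition of nucleotide and structural state.

    Bijective with (seq, dotbracket); length mismatch or invalid
    dot-bracket is an error.  Non-ACGU letters are not representable in the
    12-letter alphabet and are rejected.
    """
    if len(seq) != len(dotbracket):
        raise ValueError(
            f"sequence length {len(seq)} != structure length {len(dotbracket)}"
        )
    validate_dotbracket(dotbracket)
    codes = np.empty(len(seq), dtype=np.int8)
    for i, (n, s) in enumerate(zip(seq, dotbracket)):
        if n not in NTS:
            raise ValueError(f"letter {n!r} at position {i} not in the 12-letter alphabet")
        codes[i] = 3 * NTS.index(n) + STATES.index(s)
    return Code12(codes, seq, dotbracket)


def decode12(code: Code12 | np.ndarray) -> tuple[str, str]:
    codes = code.codes if isinstance(code, Code12) else code
    seq = "".join(NTS[c // 3] for c in codes)
    db = "".join(STATES[c % 3] for c in codes)
    return seq, db


@dataclass
class ScoreModel:
    """Symmetric 12x12 substitution scores with affine gap costs.

    A gap of length g costs ``gap_open + g * gap_extend`` (both negative).
    """

    S: np.ndarray
    gap_open: float = -6.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (12, 12):
            raise ValueError("scoring matrix must be 12x12")
        if not np.allclose(self.S, self.S.T):
            raise ValueError("scoring matrix must be symmetric")
        if np.any(np.diag(self.S)[:, None] < self.S):
            raise ValueError("diagonal must dominate each row")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


def default_score_model(
    match: float = 2.0,
    mismatch: float = -1.0,
    structure_bonus: float = 1.0,
    structure_penalty: float = -1.0,
    gap_open: float = -6.0,
    gap_extend: float = -1.0,
) -> ScoreModel:
    """Additive nucleotide + structure construction of the 12x12 matrix.

    S[(n1,s1),(n2,s2)] = (match if n1==n2 else mismatch)
                       + (structure_bonus if s1==s2 else structure_penalty).
    """
    if not match > mismatch:
        raise ValueError("match must exceed mismatch")
    if structure_bonus < 0 or structure_penalty > 0:
        raise ValueError("need structure_bonus >= 0 >= structure_penalty")
    S = np.empty((12, 12))
    for a in range(12):
        for b in range(12):
            nuc = match if a // 3 == b // 3 else mismatch
            struct = structure_bonus if a % 3 == b % 3 else structure_penalty
            S[a, b] = nuc + struct
    return ScoreModel(S, gap_open, gap_extend)


def load_score_matrix(path, gap_open: float = -6.0, gap_extend: float = -1.0) -> ScoreModel:
    """Load an arbitrary 12x12 whitespace-separated matrix (fixed symbol
    order A.,A(,A),C.,C(,C),G.,G(,G),U.,U(,U))."""
    S = np.loadtxt(path)
    return ScoreModel(S, gap_open, gap_extend)
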