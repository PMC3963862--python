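"""Reduced nearest-neighbour energy model for RNA secondary structure.

The model is deliberately small and fully declared: a symmetric 6x6
pair-on-pair stacking table, tabulated hairpin/bulge/internal loop
initiation penalties with Jacobson-Stockmayer log extrapolation, a linear
loop-asymmetry term, and an affine multiloop penalty.  Energies are
kcal/mol for the fixed 37 degC parameter set.  Allowed pairs are the six
canonical/wobble pairs; any position holding N or another ambiguity code
never pairs.

The same model is used by the dynamic-programming folder and by
:func:`energy_of_structure`, which scores an arbitrary nested structure by
loop decomposition; the two agree by construction, so exhaustive
enumeration of small structures is a valid independent oracle for the DP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

RT37 = 0.6156  # kcal/mol, 37 degC
NT_ORDER = "ACGU"
NT_INDEX = {c: i for i, c in enumerate(NT_ORDER)}
PAIR_NAMES = ("AU", "UA", "GC", "CG", "GU", "UG")

#: 5x5 lookup (A,C,G,U,other) -> pair index in PAIR_NAMES, -1 if not allowed
PAIR_TABLE = -np.ones((5, 5), dtype=np.int8)
for _k, (_a, _b) in enumerate(PAIR_NAMES):
    PAIR_TABLE[NT_INDEX[_a], NT_INDEX[_b]] = _k

# Symmetric stack table, kcal/mol, indexed by PAIR_NAMES order.
# Magnitudes follow the usual ordering: GC/CG stacks strongest, AU/UA
# intermediate, GU wobble weakest.
_STACK = np.array(
    [
        # AU     UA     GC     CG     GU     UG
        [-0.9, -1.1, -2.1, -2.2, -0.6, -1.4],  # AU
        [-1.1, -0.9, -2.1, -2.4, -1.0, -1.3],  # UA
        [-2.1, -2.1, -2.9, -3.4, -1.5, -2.5],  # GC
        [-2.2, -2.4, -3.4, -3.3, -1.4, -2.1],  # CG
        [-0.6, -1.0, -1.5, -1.4, -0.5, -0.6],  # GU
        [-1.4, -1.3, -2.5, -2.1, -0.6, -0.5],  # UG
    ]
)


def encode_seq(seq: str) -> np.ndarray:
    """Map a sequence string to int8 codes A=0 C=1 G=2 U=3, other=4."""
    out = np.full(len(seq), 4, dtype=np.int8)
    for i, c in enumerate(seq):
        out[i] = NT_INDEX.get(c, 4)
    return out


def _js_extend(table: list[float], start_len: int, max_len: int) -> np.ndarray:
    """Tabulate loop penalties with 1.75*RT*ln(l/l0) extrapolation."""
    arr = np.full(max_len + 1, np.inf)
    for l, v in enumerate(table):
        if l <= max_len:
            arr[l] = v
    base_len = len(table) - 1
    base = table[-1]
    for l in range(base_len + 1, max_len + 1):
        arr[l] = base + 1.75 * RT37 * math.log(l / base_len)
    if start_len > 0:
        arr[:start_len] = np.inf
    return arr


@dataclass(frozen=True)
class FoldParams:
    """Versioned parameter set for the reduced nearest-neighbour model."""

    stack: np.ndarray = field(default_factory=lambda: _STACK.copy())
    hairpin: np.ndarray = field(
        default_factory=lambda: _js_extend([0, 0, 0, 5.4, 5.6, 5.7], 3, 6000)
    )
    bulge: np.ndarray = field(
        default_factory=lambda: _js_extend([0, 3.8, 2.8, 3.2], 1, 6000)
    )
    internal: np.ndarray = field(
        default_factory=lambda: _js_extend([0, 0, 1.7, 2.0, 2.1, 2.3, 2.5], 2, 6000)
    )
    asym: float = 0.6  # per unpaired-length asymmetry unit
    asym_max: float = 3.0
    ml_close: float = 3.4  # multiloop closing penalty (a)
    ml_branch: float = 0.4  # per branch, closing pair included (b)
    ml_unpaired: float = 0.1  # per unpaired base in a multiloop (c)
    min_hairpin: int = 3
    max_loop: int = 30
    temperature_label: str = "37C"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.stack)):
            raise ValueError("stack energies must be finite")
        if self.min_hairpin < 1:
            raise ValueError("min_hairpin must be >= 1")


DEFAULT_PARAMS = FoldParams()


def pair_index(a: str, b: str) -> int:
    """Index of pair (a, b) in PAIR_NAMES, or -1 if not an allowed pair."""
    return int(PAIR_TABLE[NT_INDEX.get(a, 4), NT_INDEX.get(b, 4)])


def is_canonical_pair(a: str, b: str) -> bool:
    return pair_index(a, b) >= 0


def _interior_energy(
    p_outer: int, p_inner: int, n1: int, n2: int, params: FoldParams
) -> float:
    if n1 == 0 and n2 == 0:
        return float(params.stack[p_outer, p_inner])
    if n1 == 0 or n2 == 0:
        return float(params.bulge[n1 + n2])
    pen = min(params.asym_max, params.asym * abs(n1 - n2))
    return float(params.internal[n1 + n2]) + pen


def energy_of_structure(
    seq: str, pairs, params: FoldParams = DEFAULT_PARAMS, *, validate: bool = True
) -> float:
    """Free energy of a given nested structure by loop decomposition.

    Exterior-loop bases are free; each base pair closes exactly one loop
    (hairpin, stack/bulge/internal, or multiloop) whose energy is summed.
    """
    n = len(seq)
    s = encode_seq(seq)
    partner = np.full(n, -1, dtype=np.int64)
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    if validate:
        for i, j in pairs:
            if not (0 <= i < j < n):
                raise ValueError(f"pair ({i},{j}) out of range")
            if j - i <= params.min_hairpin:
                raise ValueError(f"pair ({i},{j}) violates min hairpin loop")
            if PAIR_TABLE[s[i], s[j]] < 0:
                raise ValueError(f"pair ({i},{j}) = {seq[i]}{seq[j]} not allowed")
        # nestedness
        stack: list[int] = []
        for i in range(n):
            if partner[i] > i:
                stack.append(partner[i])
            elif partner[i] >= 0:
                if not stack or stack[-1] != i:
                    raise ValueError("structure is not nested")
                stack.pop()

    total = 0.0
    for i, j in sorted(pairs):
        p = int(PAIR_TABLE[s[i], s[j]])
        # scan the loop closed by (i, j)
        children: list[tuple[int, int]] = []
        unpaired = 0
        k = i + 1
        while k < j:
            if partner[k] > k:
                children.append((k, int(partner[k])))
                k = int(partner[k]) + 1
            else:
                unpaired += 1
                k += 1
        if not children:
            total += float(params.hairpin[j - i - 1])
        elif len(children) == 1:
            (k1, l1) = children[0]
            total += _interior_energy(
                p, int(PAIR_TABLE[s[k1], s[l1]]), k1 - i - 1, j - l1 - 1, params
            )
        else:
            total += (
                params.ml_close
                + params.ml_branch * (len(children) + 1)
                + params.ml_unpaired * unpaired
            )
    return total


def enumerate_structures(seq: str, params: FoldParams = DEFAULT_PARAMS):
    """Yield every nested structure (as a tuple of pairs) of a short sequence.

    Intended as a brute-force oracle for the DP folder; exponential, use
    only for len(seq) <= ~14.
    """
    s = encode_seq(seq)
    n = len(s)
    min_hp = params.min_hairpin
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def structures(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        # all pair sets over region [i, j)
        if j - i <= min_hp:
            return ((),)
        out = []
        # position i unpaired
        out.extend(structures(i + 1, j))
        # i paired with k
        for k in range(i + min_hp + 1, j):
            if PAIR_TABLE[s[i], s[k]] >= 0:
                for inner in structures(i + 1, k):
                    for right in structures(k + 1, j):
                        out.append(((i, k),) + inner + right)
        return tuple(out)

    yield from structures(0, n)


def brute_force_mfe(seq: str, params: FoldParams = DEFAULT_PARAMS):
    """(energy, pairs) of the best structure by exhaustive enumeration."""
    best_e = 0.0
    best_pairs: tuple = ()
    for pairs in enumerate_structures(seq, params):
        e = energy_of_structure(seq, pairs, params, validate=False)
        if e < best_e - 1e-12:
            best_e = e
            best_pairs = pairs
    return best_e, sorted(best_pairs)
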