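"""Minimum-free-energy folding and common-core classification.

Zuker-style dynamic programming over the reduced nearest-neighbour model in
:mod:`its1kit.energy`: V(i,j) is the best energy of a structure closed by
pair (i,j); WM handles multiloop segments (>= 1 branch); W is the exterior
loop.  Interior loops are capped at ``max_loop`` unpaired bases, the
standard restriction.  Traceback is deterministic with a fixed preference
order (stacked pair > interior loop > multiloop > hairpin; exterior prefers
pairing with the leftmost opening), so identical input always yields an
identical dot-bracket.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .energy import (
    DEFAULT_PARAMS,
    PAIR_TABLE,
    FoldParams,
    encode_seq,
    energy_of_structure,
)
from .records import Record, dotbracket_from_pairs, partner_array

INF = 1e9
_TOL = 1e-6


@njit(cache=True)
def _fill(s, ptab, stack, hp, bulge, internal, asym, asym_max, a, b, c, min_hp, max_loop):
    n = s.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for span in range(n):
        for i in range(n - span):
            j = i + span
            if span > min_hp:
                p = ptab[s[i], s[j]]
                if p >= 0:
                    best = hp[span - 1]
                    # interior loops (stack / bulge / internal), capped size
                    for k in range(i + 1, j):
                        n1 = k - i - 1
                        if n1 > max_loop:
                            break
                        lmin = k + min_hp + 1
                        lo2 = j - 1 - (max_loop - n1)
                        if lo2 > lmin:
                            lmin = lo2
                        for l in range(j - 1, lmin - 1, -1):
                            if V[k, l] >= INF:
                                continue
                            n2 = j - l - 1
                            if n1 == 0 and n2 == 0:
                                e = V[k, l] + stack[p, ptab[s[k], s[l]]]
                            elif n1 == 0 or n2 == 0:
                                e = V[k, l] + bulge[n1 + n2]
                            else:
                                d = n1 - n2
                                if d < 0:
                                    d = -d
                                pen = asym * d
                                if pen > asym_max:
                                    pen = asym_max
                                e = V[k, l] + internal[n1 + n2] + pen
                            if e < best:
                                best = e
                    # multiloop: >= 2 branches inside
                    for m in range(i + 1, j - 1):
                        if WM[i + 1, m] < INF and WM[m + 1, j - 1] < INF:
                            e = a + b + WM[i + 1, m] + WM[m + 1, j - 1]
                            if e < best:
                                best = e
                    V[i, j] = best
            # WM: multiloop segment with >= 1 branch
            w = INF
            if V[i, j] < INF:
                w = V[i, j] + b
            if span >= 1:
                t = WM[i + 1, j] + c
                if t < w:
                    w = t
                t = WM[i, j - 1] + c
                if t < w:
                    w = t
                for m in range(i, j):
                    t = WM[i, m] + WM[m + 1, j]
                    if t < w:
                        w = t
            WM[i, j] = w
    W = np.zeros(n + 1)
    for e_ in range(1, n + 1):
        best = W[e_ - 1]
        for st in range(e_):
            if V[st, e_ - 1] < INF:
                t = W[st] + V[st, e_ - 1]
                if t < best:
                    best = t
        W[e_] = best
    return V, WM, W


@dataclass
class SecondaryStructure:
    """A nested secondary structure with its model energy (kcal/mol)."""

    seq: str
    dotbracket: str
    pairs: list[tuple[int, int]]
    energy: float

    def __post_init__(self) -> None:
        if len(self.dotbracket) != len(self.seq):
            raise ValueError("dot-bracket length != sequence length")


def _interior_e(p, pk, n1, n2, params):
    if n1 == 0 and n2 == 0:
        return float(params.stack[p, pk])
    if n1 == 0 or n2 == 0:
        return float(params.bulge[n1 + n2])
    return float(params.internal[n1 + n2]) + min(
        params.asym_max, params.asym * abs(n1 - n2)
    )


def _traceback(s, V, WM, W, params):
    n = s.shape[0]
    min_hp = params.min_hairpin
    max_loop = params.max_loop
    pairs: list[tuple[int, int]] = []

    def trace_v(i, j):
        pairs.append((i, j))
        p = PAIR_TABLE[s[i], s[j]]
        target = V[i, j]
        # 1. stack first (prefers maximally stacked helices)
        k, l = i + 1, j - 1
        if l - k > min_hp and V[k, l] < INF and PAIR_TABLE[s[k], s[l]] >= 0:
            if abs(V[k, l] + float(params.stack[p, PAIR_TABLE[s[k], s[l]]]) - target) < _TOL:
                trace_v(k, l)
                return
        # 2. other interior loops, small first in scan order
        for k in range(i + 1, j):
            n1 = k - i - 1
            if n1 > max_loop:
                break
            for l in range(j - 1, k + min_hp, -1):
                n2 = j - l - 1
                if n1 + n2 > max_loop or (n1 == 0 and n2 == 0):
                    continue
                if V[k, l] < INF and abs(
                    V[k, l] + _interior_e(p, PAIR_TABLE[s[k], s[l]], n1, n2, params) - target
                ) < _TOL:
                    trace_v(k, l)
                    return
        # 3. multiloop
        for m in range(i + 1, j - 1):
            if WM[i + 1, m] < INF and WM[m + 1, j - 1] < INF:
                if abs(
                    params.ml_close + params.ml_branch + WM[i + 1, m] + WM[m + 1, j - 1] - target
                ) < _TOL:
                    trace_wm(i + 1, m)
                    trace_wm(m + 1, j - 1)
                    return
        # 4. hairpin: nothing further to trace

    def trace_wm(i, j):
        target = WM[i, j]
        if V[i, j] < INF and abs(V[i, j] + params.ml_branch - target) < _TOL:
            trace_v(i, j)
            return
        for m in range(i, j):
            if WM[i, m] < INF and WM[m + 1, j] < INF and abs(
                WM[i, m] + WM[m + 1, j] - target
            ) < _TOL:
                trace_wm(i, m)
                trace_wm(m + 1, j)
                return
        if j > i and abs(WM[i + 1, j] + params.ml_unpaired - target) < _TOL:
            trace_wm(i + 1, j)
            return
        if j > i and abs(WM[i, j - 1] + params.ml_unpaired - target) < _TOL:
            trace_wm(i, j - 1)
            return
        raise AssertionError("WM traceback failed")  # pragma: no cover

    # exterior: scan right-to-left, preferring a pair with leftmost opening
    pos = n
    while pos > 0:
        chosen = False
        for st in range(pos):
            if V[st, pos - 1] < INF and abs(W[st] + V[st, pos - 1] - W[pos]) < _TOL:
                trace_v(st, pos - 1)
                pos = st
                chosen = True
                break
        if not chosen:
            pos -= 1
    return sorted(pairs)


def fold_mfe(seq: str, params: FoldParams = DEFAULT_PARAMS) -> SecondaryStructure:
    """Fold *seq* to its minimum-free-energy nested structure.

    Deterministic: identical input gives an identical dot-bracket.  Letters
    outside ACGU never pair.
    """
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    if n > 5000:
        raise ValueError("sequence longer than 5000 nt")
    s = encode_seq(seq)
    if n <= params.min_hairpin + 1:
        return SecondaryStructure(seq, "." * n, [], 0.0)
    V, WM, W = _fill(
        s,
        PAIR_TABLE,
        params.stack,
        params.hairpin,
        params.bulge,
        params.internal,
        params.asym,
        params.asym_max,
        params.ml_close,
        params.ml_branch,
        params.ml_unpaired,
        params.min_hairpin,
        params.max_loop,
    )
    pairs = _traceback(s, V, WM, W, params)
    energy = float(W[n])
    check = energy_of_structure(seq, pairs, params, validate=False)
    if abs(check - energy) > 1e-4:  # pragma: no cover - internal consistency
        raise AssertionError(
            f"traceback energy {check} disagrees with DP optimum {energy}"
        )
    return SecondaryStructure(seq, dotbracket_from_pairs(n, pairs), pairs, energy)


# ---------------------------------------------------------------------------
# helix decomposition and common-core classification


@dataclass
class HelixDecomposition:
    """Exterior-anchored helix domains of a structure.

    ``domains`` holds 0-based half-open spans plus the number of pairs in
    each; ``y_flags`` marks domains containing a multiloop (Y-shaped), which
    still count as a single helix.
    """

    domains: list[tuple[int, int, int]]
    inter_runs: list[int]
    flank5: int
    flank3: int
    y_flags: list[bool] = field(default_factory=list)

    @property
    def n_helices(self) -> int:
        return len(self.domains)


def decompose_helices(structure: SecondaryStructure | str) -> HelixDecomposition:
    """Split a structure into maximal exterior-loop-anchored paired domains."""
    db = structure.dotbracket if isinstance(structure, SecondaryStructure) else structure
    partner = partner_array(db)
    n = len(db)
    domains: list[tuple[int, int, int]] = []
    y_flags: list[bool] = []
    runs: list[int] = []
    i = 0
    run = 0
    while i < n:
        if partner[i] > i:
            runs.append(run)
            run = 0
            j = partner[i]
            n_pairs = sum(1 for k in range(i, j + 1) if partner[k] > k)
            # Y-shape: any pair inside with >= 2 directly nested children
            y = False
            for k in range(i, j + 1):
                if partner[k] > k:
                    children = 0
                    m = k + 1
                    while m < partner[k]:
                        if partner[m] > m:
                            children += 1
                            m = partner[m] + 1
                        else:
                            m += 1
                    if children >= 2:
                        y = True
                        break
            domains.append((i, j + 1, n_pairs))
            y_flags.append(y)
            i = j + 1
        else:
            run += 1
            i += 1
    runs.append(run)
    flank5 = runs[0] if runs else 0
    flank3 = runs[-1] if len(runs) > 1 else 0
    inter = runs[1:-1] if len(runs) > 2 else []
    if not domains:
        flank5, flank3, inter = n, 0, []
    return HelixDecomposition(domains, inter, flank5, flank3, y_flags)


@dataclass(frozen=True)
class CoreSpec:
    """Length constraints of the three-helix common core (nt spans)."""

    helixI_len: tuple[int, int] = (12, 35)
    helixII_len: tuple[int, int] = (115, 201)
    helixIII_len: tuple[int, int] = (8, 23)
    inter1: tuple[int, int] = (15, 28)
    inter2: tuple[int, int] = (10, 29)

    def __post_init__(self) -> None:
        for name in ("helixI_len", "helixII_len", "helixIII_len", "inter1", "inter2"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: empty range [{lo}, {hi}]")


DEFAULT_CORE = CoreSpec()


@dataclass
class CoreClassification:
    is_three_helix: bool
    is_core: bool
    violations: list[str]


def classify_core(
    decomp: HelixDecomposition, core_spec: CoreSpec = DEFAULT_CORE
) -> CoreClassification:
    """Classify a decomposition against the three-helix common core."""
    violations: list[str] = []
    three = decomp.n_helices == 3
    if not three:
        violations.append("n_helices")
        return CoreClassification(False, False, violations)
    spans = [end - start for start, end, _ in decomp.domains]
    checks = [
        ("helixI_len", spans[0], core_spec.helixI_len),
        ("helixII_len", spans[1], core_spec.helixII_len),
        ("helixIII_len", spans[2], core_spec.helixIII_len),
        ("inter1", decomp.inter_runs[0], core_spec.inter1),
        ("inter2", decomp.inter_runs[1], core_spec.inter2),
    ]
    for name, value, (lo, hi) in checks:
        if not (lo <= value <= hi):
            violations.append(name)
    return CoreClassification(True, not violations, violations)


# ---------------------------------------------------------------------------
# AT content


def at_content(record: Record) -> dict[str, float]:
    """A+U(T) fraction per annotated element plus the length-weighted overall.

    ``record.elements`` must partition the sequence; overlap or gap is an
    error.
    """
    if not record.elements:
        raise ValueError(f"record {record.id!r} has no element annotation")
    n = len(record.seq)
    covered = np.zeros(n, dtype=np.int64)
    out: dict[str, float] = {}
    at_total = 0
    for name, (start, end) in record.elements.items():
        if not (0 <= start < end <= n):
            raise ValueError(f"element {name!r}: bad span ({start}, {end})")
        covered[start:end] += 1
        sub = record.seq[start:end]
        at = sum(1 for c in sub if c in "AU")
        out[name] = at / (end - start)
        at_total += at
    if np.any(covered != 1):
        bad = int(np.argmax(covered != 1))
        kind = "overlap" if covered[bad] > 1 else "gap"
        raise ValueError(f"element spans do not partition the sequence ({kind} at {bad})")
    out["overall"] = at_total / n
    return out
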