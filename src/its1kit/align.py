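"""Pairwise and progressive alignment over the 12-letter alphabet.

Pairwise alignment is global Needleman-Wunsch/Gotoh with affine gaps
(a gap of length g costs gap_open + g*gap_extend) maximizing the 12x12
sequence-structure score.  Progressive alignment builds a Neighbor-Joining
guide tree on normalized pairwise distances and merges profiles with
sum-of-pairs column scoring.  Terminal gaps are penalized like internal
ones (a free-end-gaps switch exists on align_pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import GAP_CODE, Code12, ScoreModel, decode12, default_score_model, encode12
from .records import GAP, Record

_NEG = -1e30


def _gotoh(
    x: np.ndarray, y: np.ndarray, S: np.ndarray, go: float, ge: float,
    free_end_gaps: bool = False,
) -> tuple[float, list[tuple[int, int]]]:
    """Global affine alignment of two code vectors.

    Returns (score, ops) where ops are (i, j) pairs with -1 marking a gap.
    Deterministic traceback preference: diagonal > gap-in-y > gap-in-x.
    """
    n, m = len(x), len(y)
    M = np.full((n + 1, m + 1), _NEG)  # ends in a match/mismatch
    X = np.full((n + 1, m + 1), _NEG)  # ends with gap in y (consumes x)
    Y = np.full((n + 1, m + 1), _NEG)  # ends with gap in x (consumes y)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0 if free_end_gaps else go + i * ge
    for j in range(1, m + 1):
        Y[0, j] = 0.0 if free_end_gaps else go + j * ge
    for i in range(1, n + 1):
        Si = S[x[i - 1]]
        for j in range(1, m + 1):
            s = Si[y[j - 1]]
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            xgo = 0.0 if (free_end_gaps and j == m) else go + ge
            xge = 0.0 if (free_end_gaps and j == m) else ge
            X[i, j] = max(M[i - 1, j] + xgo, X[i - 1, j] + xge, Y[i - 1, j] + xgo)
            ygo = 0.0 if (free_end_gaps and i == n) else go + ge
            yge = 0.0 if (free_end_gaps and i == n) else ge
            Y[i, j] = max(M[i, j - 1] + ygo, Y[i, j - 1] + yge, X[i, j - 1] + ygo)
    score = max(M[n, m], X[n, m], Y[n, m])

    # traceback
    ops: list[tuple[int, int]] = []
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))  # 0=M,1=X,2=Y
    tol = 1e-9
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:  # border: switch to gap states
                state = 1 if i > 0 else 2
                continue
            ops.append((i - 1, j - 1))
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            target = M[i, j] - S[x[i - 1], y[j - 1]]
            state = next(k for k in range(3) if abs(prev[k] - target) < tol)
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append((i - 1, -1))
            if i == 1 and j == 0:
                break
            xgo = 0.0 if (free_end_gaps and j == m) else go + ge
            xge = 0.0 if (free_end_gaps and j == m) else ge
            if j == 0:
                xgo, xge = go + ge, ge
            if abs(X[i - 1, j] + xge - X[i, j]) < tol and (i > 1 or j == 0):
                state = 1
            elif j > 0 and abs(M[i - 1, j] + xgo - X[i, j]) < tol:
                state = 0
            elif j > 0 and abs(Y[i - 1, j] + xgo - X[i, j]) < tol:
                state = 2
            else:
                state = 1
            i -= 1
        else:
            ops.append((-1, j - 1))
            if j == 1 and i == 0:
                break
            ygo = 0.0 if (free_end_gaps and i == n) else go + ge
            yge = 0.0 if (free_end_gaps and i == n) else ge
            if i == 0:
                ygo, yge = go + ge, ge
            if abs(Y[i, j - 1] + yge - Y[i, j]) < tol and (j > 1 or i == 0):
                state = 2
            elif i > 0 and abs(M[i, j - 1] + ygo - Y[i, j]) < tol:
                state = 0
            elif i > 0 and abs(X[i, j - 1] + ygo - Y[i, j]) < tol:
                state = 1
            else:
                state = 2
            j -= 1
    ops.reverse()
    return float(score), ops


@dataclass
class PairwiseAlignment:
    score: float
    row1: np.ndarray  # codes with GAP_CODE at gaps
    row2: np.ndarray


def align_pair(
    code1: Code12, code2: Code12, model: ScoreModel | None = None,
    free_end_gaps: bool = False,
) -> PairwiseAlignment:
    """Optimal global sequence-structure alignment of two encoded records."""
    if len(code1) == 0 or len(code2) == 0:
        raise ValueError("cannot align empty codes")
    model = model or default_score_model()
    score, ops = _gotoh(
        code1.codes, code2.codes, model.S, model.gap_open, model.gap_extend,
        free_end_gaps,
    )
    r1 = np.array([code1.codes[i] if i >= 0 else GAP_CODE for i, _ in ops], dtype=np.int8)
    r2 = np.array([code2.codes[j] if j >= 0 else GAP_CODE for _, j in ops], dtype=np.int8)
    return PairwiseAlignment(score, r1, r2)


def self_score(code: Code12, model: ScoreModel) -> float:
    return float(model.S[code.codes, code.codes].sum())


@dataclass
class SeqStructAlignment:
    """A multiple sequence-structure alignment.

    ``rows[i]`` is the gapped 12-letter code row of record i (GAP_CODE at
    gaps); de-gapping row i recovers the original encoded record.
    """

    ids: list[str]
    rows: list[np.ndarray]
    codes: list[Code12]  # ungapped provenance, input order

    def __post_init__(self) -> None:
        ncol = len(self.rows[0])
        if any(len(r) != ncol for r in self.rows):
            raise ValueError("alignment rows have unequal length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def gapped_strings(self, i: int) -> tuple[str, str]:
        seq_chars, db_chars = [], []
        for c in self.rows[i]:
            if c == GAP_CODE:
                seq_chars.append(GAP)
                db_chars.append(GAP)
            else:
                seq_chars.append("ACGU"[c // 3])
                db_chars.append(".()"[c % 3])
        return "".join(seq_chars), "".join(db_chars)

    def to_records(self) -> list[Record]:
        out = []
        for i, rid in enumerate(self.ids):
            seq, db = self.gapped_strings(i)
            out.append(Record(id=rid, seq=seq, structure=db))
        return out


def _profile_merge(
    rows_a: list[np.ndarray], rows_b: list[np.ndarray], model: ScoreModel
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Align two profiles (lists of gapped rows) by sum-of-pairs Gotoh."""
    S, go, ge = model.S, model.gap_open, model.gap_extend
    A = np.stack(rows_a)
    B = np.stack(rows_b)
    n, m = A.shape[1], B.shape[1]

    # column pair scores: sum over non-gap residue pairs
    colscore = np.zeros((n, m))
    for a in A:
        for b in B:
            mask_a = a != GAP_CODE
            mask_b = b != GAP_CODE
            ia = np.where(mask_a)[0]
            ib = np.where(mask_b)[0]
            if len(ia) and len(ib):
                colscore[np.ix_(ia, ib)] += S[np.ix_(a[ia], b[ib])]

    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + i * ge
    for j in range(1, m + 1):
        Y[0, j] = go + j * ge
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + colscore[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] + go + ge, X[i - 1, j] + ge, Y[i - 1, j] + go + ge)
            Y[i, j] = max(M[i, j - 1] + go + ge, Y[i, j - 1] + ge, X[i, j - 1] + go + ge)
    # traceback
    i, j = n, m
    cols: list[tuple[int, int]] = []
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    tol = 1e-9
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            cols.append((i - 1, j - 1))
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            target = M[i, j] - colscore[i - 1, j - 1]
            state = next(k for k in range(3) if abs(prev[k] - target) < tol)
            i, j = i - 1, j - 1
        elif state == 1 or j == 0:
            cols.append((i - 1, -1))
            if j > 0 and abs(M[i - 1, j] + go + ge - X[i, j]) < tol:
                state = 0
            elif j > 0 and abs(Y[i - 1, j] + go + ge - X[i, j]) < tol:
                state = 2
            else:
                state = 1
            i -= 1
        else:
            cols.append((-1, j - 1))
            if i > 0 and abs(M[i, j - 1] + go + ge - Y[i, j]) < tol:
                state = 0
            elif i > 0 and abs(X[i, j - 1] + go + ge - Y[i, j]) < tol:
                state = 1
            else:
                state = 2
            j -= 1
    cols.reverse()
    new_a = [np.array([r[ci] if ci >= 0 else GAP_CODE for ci, _ in cols], dtype=np.int8) for r in rows_a]
    new_b = [np.array([r[cj] if cj >= 0 else GAP_CODE for _, cj in cols], dtype=np.int8) for r in rows_b]
    return new_a, new_b


def progressive_align(
    records: list[Record], model: ScoreModel | None = None
) -> SeqStructAlignment:
    """Progressive multiple alignment guided by an NJ tree.

    Pairwise distances are 1 - score/mean(self-scores); guide-tree ties
    break lexicographically by record id.  Profile merges use sum-of-pairs
    scoring with the pairwise gap costs.
    """
    from .phylo import nj  # local import to avoid a cycle

    if len(records) < 2:
        raise ValueError("need at least 2 records")
    for rec in records:
        if rec.structure is None:
            raise ValueError(f"record {rec.id!r} has no structure")
    model = model or default_score_model()
    order = sorted(range(len(records)), key=lambda i: records[i].id)
    codes = [encode12(records[i].seq, records[i].structure) for i in order]
    k = len(codes)
    selfs = [self_score(c, model) for c in codes]
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sc = align_pair(codes[i], codes[j], model).score
            denom = 0.5 * (selfs[i] + selfs[j])
            D[i, j] = D[j, i] = 1.0 - sc / denom if denom != 0 else 0.0

    if k == 2:
        aln = align_pair(codes[0], codes[1], model)
        merged = {0: [aln.row1], 1: [aln.row2]}
        members = {0: [0], 1: [1]}
        final_rows = [aln.row1, aln.row2]
        final_members = [0, 1]
    else:
        tree = nj(D, [records[i].id for i in order])
        # post-order merge following the guide tree
        profiles: dict[int, list[np.ndarray]] = {i: [codes[i].codes] for i in range(k)}
        member_lists: dict[int, list[int]] = {i: [i] for i in range(k)}
        label_to_idx = {records[i].id: n for n, i in enumerate(order)}

        def merge(node) -> int:
            if not node.children:
                return label_to_idx[node.label]
            child_ids = [merge(ch) for ch in node.children]
            cur = child_ids[0]
            for other in child_ids[1:]:
                ra, rb = _profile_merge(profiles[cur], profiles[other], model)
                profiles[cur] = ra + rb
                member_lists[cur] = member_lists[cur] + member_lists[other]
                del profiles[other], member_lists[other]
            return cur

        root_idx = merge(tree)
        final_rows = profiles[root_idx]
        final_members = member_lists[root_idx]

    # restore original record order
    ncol = len(final_rows[0])
    by_sorted_idx = {m: r for m, r in zip(final_members, final_rows)}
    rows_in_input_order: list[np.ndarray] = [None] * len(records)  # type: ignore
    codes_in_input_order: list[Code12] = [None] * len(records)  # type: ignore
    for pos_sorted, input_idx in enumerate(order):
        rows_in_input_order[input_idx] = by_sorted_idx[pos_sorted]
        codes_in_input_order[input_idx] = codes[pos_sorted]
    assert all(len(r) == ncol for r in rows_in_input_order)
    return SeqStructAlignment(
        ids=[r.id for r in records],
        rows=rows_in_input_order,
        codes=codes_in_input_order,
    )
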