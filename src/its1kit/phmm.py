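"""Ungapped-core profile HMMs for short conserved motifs.

Models are built from small gapped alignments (columns with > 50% gaps
become insert columns), scanned against sequences with a local
(Smith-Waterman-style entry/exit) Viterbi in log2-odds space, and assigned
E-values via seeded Monte-Carlo Gumbel calibration.  Entry and exit are
uniform over match states, in the spirit of Plan7 local alignment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.stats import gumbel_r

from .energy import NT_INDEX

NEG = -1e30


@dataclass(frozen=True)
class GumbelParams:
    mu: float
    lam: float

    def __post_init__(self) -> None:
        if not (self.lam > 0):
            raise ValueError("Gumbel lambda must be > 0")


@dataclass
class HmmHit:
    target_id: str
    start: int  # 0-based half-open target coordinates
    end: int
    bit_score: float
    evalue: float | None = None


@dataclass
class ProfileHMM:
    """Profile HMM with L match states over the RNA alphabet.

    ``match_emissions``: (L, 4) probability rows; ``transitions``: dict of
    per-position probability arrays (length L) for the seven allowed moves
    M->M, M->I, M->D, I->I, I->M, D->D, D->M, where index k holds the
    transition leaving position k (k = 0 is the begin state).
    """

    name: str
    L: int
    match_emissions: np.ndarray
    insert_emission: np.ndarray
    background: np.ndarray
    transitions: dict[str, np.ndarray]
    calibration: GumbelParams | None = None

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        for src, keys in (("M", ("MM", "MI", "MD")), ("I", ("II", "IM")), ("D", ("DD", "DM"))):
            tot = sum(self.transitions[k] for k in keys)
            if not np.allclose(tot, 1.0, atol=1e-9):
                raise ValueError(f"{src}-state transition rows must sum to 1")


def build_phmm(
    alignment: list[str], pseudocount: float = 0.1, name: str = "phmm"
) -> ProfileHMM:
    """Estimate a profile HMM from equal-length gapped rows.

    Match emissions are (count + pseudocount) / (total + 4*pseudocount);
    transitions are estimated the same way; the background is the pooled
    residue frequency over all columns.
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 alignment rows")
    rows = [r.upper().replace("T", "U") for r in alignment]
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("alignment rows have unequal lengths")
    nrow = len(rows)
    gap_frac = [sum(1 for r in rows if r[c] == "-") / nrow for c in range(ncol)]
    match_cols = [c for c in range(ncol) if gap_frac[c] <= 0.5]
    L = len(match_cols)
    if L == 0:
        raise ValueError("no match columns remain (all columns > 50% gaps)")

    emit = np.full((L, 4), pseudocount, dtype=float)
    bg = np.zeros(4, dtype=float)
    for r in rows:
        for c, ch in enumerate(r):
            if ch in NT_INDEX:
                bg[NT_INDEX[ch]] += 1.0
    if bg.sum() == 0:
        raise ValueError("alignment contains no ACGU residues")
    bg = (bg + pseudocount) / (bg.sum() + 4 * pseudocount)

    for k, c in enumerate(match_cols):
        for r in rows:
            ch = r[c]
            if ch in NT_INDEX:
                emit[k, NT_INDEX[ch]] += 1.0
    emit /= emit.sum(axis=1, keepdims=True)

    # transition counts from per-row state paths
    counts = {k: np.full(L, pseudocount, dtype=float) for k in ("MM", "MI", "MD", "II", "IM", "DD", "DM")}
    insert_between = {c: k for k, c in enumerate(match_cols)}  # match col -> position index
    for r in rows:
        # events: list of (kind, position k) in model order; begin == ("M", 0)
        events: list[tuple[str, int]] = [("M", 0)]
        pos = 0
        for c in range(ncol):
            if c in insert_between:
                pos = insert_between[c] + 1
                events.append(("M" if r[c] != "-" else "D", pos))
            elif r[c] != "-":
                events.append(("I", pos))
        prev_kind, prev_pos = events[0]
        for kind, pos_ in events[1:]:
            key = prev_kind + kind
            # transitions leave the source at its position index; moves out
            # of the final position (e.g. trailing inserts) are not modelled
            if key in counts and prev_pos < L:
                counts[key][prev_pos] += 1.0
            prev_kind, prev_pos = kind, pos_

    trans: dict[str, np.ndarray] = {}
    m_tot = counts["MM"] + counts["MI"] + counts["MD"]
    i_tot = counts["II"] + counts["IM"]
    d_tot = counts["DD"] + counts["DM"]
    with np.errstate(invalid="ignore"):
        for k in ("MM", "MI", "MD"):
            trans[k] = counts[k] / m_tot
        for k in ("II", "IM"):
            trans[k] = counts[k] / i_tot
        for k in ("DD", "DM"):
            trans[k] = counts[k] / d_tot
    if pseudocount == 0:
        # unanimous columns with no observed variation: make rows proper
        for grp, keys in ((m_tot, ("MM", "MI", "MD")), (i_tot, ("II", "IM")), (d_tot, ("DD", "DM"))):
            zero = grp == 0
            if np.any(zero):
                for k in keys:
                    trans[k] = np.where(zero, 1.0 if k in ("MM", "IM", "DM") else 0.0, trans[k])
    return ProfileHMM(
        name=name,
        L=L,
        match_emissions=emit,
        insert_emission=bg.copy(),
        background=bg,
        transitions=trans,
    )


@njit(cache=True)
def _viterbi_kernel(msc, lt_mm, lt_mi, lt_md, lt_ii, lt_im, lt_dd, lt_dm, entry, exit_):
    """Local Viterbi: returns (best_bits, start, end) of the best hit."""
    n, L = msc.shape
    VM = np.full(L + 1, NEG)
    VI = np.full(L + 1, NEG)
    SM = np.zeros(L + 1, np.int64)
    SI = np.zeros(L + 1, np.int64)
    best = NEG
    best_start = -1
    best_end = -1
    VD = np.full(L + 1, NEG)
    SD = np.zeros(L + 1, np.int64)
    for i in range(n):
        newVM = np.full(L + 1, NEG)
        newVI = np.full(L + 1, NEG)
        newSM = np.zeros(L + 1, np.int64)
        newSI = np.zeros(L + 1, np.int64)
        for k in range(1, L + 1):
            # entry anywhere (uniform over match states)
            sc = entry
            st = i
            t = VM[k - 1] + lt_mm[k - 1]
            if t > sc:
                sc = t
                st = SM[k - 1]
            t = VI[k - 1] + lt_im[k - 1]
            if t > sc:
                sc = t
                st = SI[k - 1]
            t = VD[k - 1] + lt_dm[k - 1]
            if t > sc:
                sc = t
                st = SD[k - 1]
            newVM[k] = sc + msc[i, k - 1]
            newSM[k] = st
            # insert after k (emits at background: score 0); no insert
            # state after the final match position in local mode
            if k < L:
                sc = VM[k] + lt_mi[k]
                st = SM[k]
                t = VI[k] + lt_ii[k]
                if t > sc:
                    sc = t
                    st = SI[k]
                newVI[k] = sc
                newSI[k] = st
        # deletes consume no residue: resolve within column i
        newVD = np.full(L + 1, NEG)
        newSD = np.zeros(L + 1, np.int64)
        for k in range(1, L + 1):
            sc = newVM[k - 1] + lt_md[k - 1]
            st = newSM[k - 1]
            t = newVD[k - 1] + lt_dd[k - 1]
            if t > sc:
                sc = t
                st = newSD[k - 1]
            newVD[k] = sc
            newSD[k] = st
        VM, VI, VD = newVM, newVI, newVD
        SM, SI, SD = newSM, newSI, newSD
        for k in range(1, L + 1):
            t = VM[k] + exit_
            if t > best:
                best = t
                best_start = SM[k]
                best_end = i + 1
    return best, best_start, best_end


def _log2_arrays(hmm: ProfileHMM):
    def lg(x):
        with np.errstate(divide="ignore"):
            return np.where(x > 0, np.log2(np.maximum(x, 1e-300)), NEG)

    t = hmm.transitions
    return tuple(lg(t[k]) for k in ("MM", "MI", "MD", "II", "IM", "DD", "DM"))


def _match_scores(hmm: ProfileHMM, seq: str) -> np.ndarray:
    """(n, L) log2-odds match emission scores; non-ACGU scores 0 (missing)."""
    n = len(seq)
    lodds = np.log2(hmm.match_emissions / hmm.background[None, :])
    msc = np.zeros((n, hmm.L))
    for i, ch in enumerate(seq):
        k = NT_INDEX.get(ch, -1)
        if k >= 0:
            msc[i] = lodds[:, k]
    return msc


def _best_hit(hmm: ProfileHMM, seq: str) -> tuple[float, int, int]:
    msc = _match_scores(hmm, seq)
    lts = _log2_arrays(hmm)
    entry = exit_ = -math.log2(hmm.L)
    return _viterbi_kernel(msc, *lts, entry, exit_)


def viterbi_scan(
    hmm: ProfileHMM, seq: str, min_bits: float = 0.0, target_id: str = ""
) -> list[HmmHit]:
    """Non-overlapping local hits above *min_bits*, best-first.

    Hits are found greedily: the best-scoring hit is taken, its span is
    masked, and the flanking segments are re-scanned.  Ties resolve to the
    leftmost start.
    """
    seq = seq.upper().replace("T", "U")
    if len(seq) < 1:
        raise ValueError("empty sequence")
    hits: list[HmmHit] = []

    def scan_segment(lo: int, hi: int) -> None:
        if hi - lo < 1:
            return
        score, s, e = _best_hit(hmm, seq[lo:hi])
        if s < 0 or score < min_bits:
            return
        ev = None
        if hmm.calibration is not None:
            ev = evalue(hmm, score)
        hits.append(HmmHit(target_id, lo + s, lo + e, float(score), ev))
        scan_segment(lo, lo + s)
        scan_segment(lo + e, hi)

    scan_segment(0, len(seq))
    hits.sort(key=lambda h: (-h.bit_score, h.start, h.target_id))
    return hits


def calibrate_evalue(
    hmm: ProfileHMM, decoy_count: int = 1000, decoy_length: int = 100, seed: int = 0
) -> GumbelParams:
    """Fit Gumbel (mu, lambda) to best-hit scores of background decoys.

    Seeded and reproducible; the fit is maximum likelihood via
    ``scipy.stats.gumbel_r``.
    """
    if decoy_count < 200:
        raise ValueError("decoy_count must be >= 200")
    rng = np.random.default_rng(seed)
    scores = np.empty(decoy_count)
    letters = np.array(list("ACGU"))
    for d in range(decoy_count):
        decoy = "".join(rng.choice(letters, size=decoy_length, p=hmm.background))
        scores[d], _, _ = _best_hit(hmm, decoy)
    loc, scale = gumbel_r.fit(scores)
    if scale <= 0 or not np.isfinite(scale):
        raise ValueError("degenerate Gumbel fit; increase decoy_count")
    params = GumbelParams(mu=float(loc), lam=float(1.0 / scale))
    hmm.calibration = params
    return params


def evalue(hmm: ProfileHMM, bit_score: float, n_targets: int = 1) -> float:
    """Expected number of >= bit_score hits in *n_targets* random targets."""
    if hmm.calibration is None:
        raise ValueError(f"HMM {hmm.name!r} is not calibrated")
    g = hmm.calibration
    e = n_targets * math.exp(-g.lam * (bit_score - g.mu))
    return float(min(max(e, 0.0), n_targets))


# ---------------------------------------------------------------------------
# serialization


def hmm_to_json(hmm: ProfileHMM) -> str:
    obj = {
        "name": hmm.name,
        "L": hmm.L,
        "match_emissions": hmm.match_emissions.tolist(),
        "insert_emission": hmm.insert_emission.tolist(),
        "background": hmm.background.tolist(),
        "transitions": {k: v.tolist() for k, v in hmm.transitions.items()},
        "calibration": (
            {"mu": hmm.calibration.mu, "lambda": hmm.calibration.lam}
            if hmm.calibration
            else None
        ),
    }
    return json.dumps(obj, indent=1)


def hmm_from_json(text: str) -> ProfileHMM:
    obj = json.loads(text)
    cal = obj.get("calibration")
    return ProfileHMM(
        name=obj["name"],
        L=obj["L"],
        match_emissions=np.asarray(obj["match_emissions"], dtype=float),
        insert_emission=np.asarray(obj["insert_emission"], dtype=float),
        background=np.asarray(obj["background"], dtype=float),
        transitions={k: np.asarray(v, dtype=float) for k, v in obj["transitions"].items()},
        calibration=GumbelParams(cal["mu"], cal["lambda"]) if cal else None,
    )


def save_hmm(hmm: ProfileHMM, path) -> None:
    with open(path, "w") as fh:
        fh.write(hmm_to_json(hmm))


def load_hmm(path) -> ProfileHMM:
    with open(path) as fh:
        return hmm_from_json(fh.read())
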