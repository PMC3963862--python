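"""Profile HMM construction, Viterbi scanning and E-value calibration."""

import math

import numpy as np
import pytest

from its1kit.phmm import (
    ProfileHMM,
    build_phmm,
    calibrate_evalue,
    evalue,
    hmm_from_json,
    hmm_to_json,
    viterbi_scan,
    _best_hit,
)


class TestBuild:
    def test_unanimous_columns_give_indicator_emissions(self):
        hmm = build_phmm(["ACGU"] * 3, pseudocount=0.0)
        assert np.allclose(hmm.match_emissions, np.eye(4))

    def test_pseudocount_smoothing_hand_computed(self):
        # 2 rows {A, C}, pseudocount 1: (1+1)/(2+4) vs (0+1)/(2+4)
        hmm = build_phmm(["A", "C"], pseudocount=1.0)
        assert np.allclose(hmm.match_emissions[0], [2 / 6, 2 / 6, 1 / 6, 1 / 6])

    def test_half_gap_column_is_still_a_match_state(self):
        # gap fraction exactly 0.5 is not > 0.5
        hmm = build_phmm(["A-", "AC"], pseudocount=0.5)
        assert hmm.L == 2

    def test_majority_gap_column_becomes_insert(self):
        hmm = build_phmm(["A--", "AC-", "A--", "A--"], pseudocount=0.5)
        assert hmm.L == 1

    def test_all_gap_error(self):
        with pytest.raises(ValueError):
            build_phmm(["-", "-", "-"], pseudocount=0.5)

    def test_rows_normalized(self):
        hmm = build_phmm(["ACGU", "AGGU", "ACGU"], pseudocount=0.1)
        assert np.allclose(hmm.match_emissions.sum(axis=1), 1.0)
        for keys in (("MM", "MI", "MD"), ("II", "IM"), ("DD", "DM")):
            tot = sum(hmm.transitions[k] for k in keys)
            assert np.allclose(tot, 1.0)


class TestScan:
    def test_planted_exact_match_found_at_exact_coordinates(self):
        hmm = build_phmm(["ACGUACGUAC"] * 3)
        hits = viterbi_scan(hmm, "GGGGACGUACGUACGGGG", min_bits=0.0)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (4, 14)
        assert hits[0].bit_score > 0

    def test_background_sequence_has_no_hit(self):
        hmm = build_phmm(["ACGUACGUAC"] * 3)
        assert viterbi_scan(hmm, "G" * 40, min_bits=0.0) == []

    def test_substitution_lowers_score_by_emission_delta(self):
        # mid-motif substitution: the full-span alignment stays optimal, so
        # the score drop equals the emission log-odds delta at that column
        motif = "ACGUACGUACGUAC"
        hmm = build_phmm([motif] * 3)
        target = "gggg" + motif + "gggg"
        mutated_t = target[: 4 + 7] + "A" + target[4 + 8 :]  # U -> A at column 7
        exact = viterbi_scan(hmm, target, min_bits=0.0)[0]
        mutated = viterbi_scan(hmm, mutated_t, min_bits=0.0)[0]
        assert mutated.bit_score < exact.bit_score
        assert (mutated.start, mutated.end) == (exact.start, exact.end)
        lodds = np.log2(hmm.match_emissions / hmm.background[None, :])
        delta = lodds[7, 3] - lodds[7, 0]
        assert exact.bit_score - mutated.bit_score == pytest.approx(delta, abs=1e-6)

    def test_two_planted_copies_give_two_nonoverlapping_hits(self):
        hmm = build_phmm(["ACGUACGUAC"] * 3)
        hits = viterbi_scan(hmm, "gACGUACGUACggggACGUACGUACg", min_bits=1.0)
        assert len(hits) == 2
        spans = sorted((h.start, h.end) for h in hits)
        assert spans == [(1, 11), (15, 25)]


def _enumerate_local_score(hmm: ProfileHMM, seq: str) -> float:
    """Brute-force max over all local alignments (entry at any match state,
    exit at any match state, M/I/D moves between); oracle for the Viterbi."""
    from its1kit.energy import NT_INDEX

    L = hmm.L
    t = {k: np.log2(np.maximum(v, 1e-300)) for k, v in hmm.transitions.items()}
    lodds = np.log2(hmm.match_emissions / hmm.background[None, :])
    entry = exit_ = -math.log2(L)
    n = len(seq)
    best = -math.inf

    def walk(state, k, i, score):
        """state at model position k having consumed seq[:i]."""
        nonlocal best
        if state == "M":
            best = max(best, score + exit_)
        if state == "M" and k < L and i < n:
            walk("M", k + 1, i + 1, score + t["MM"][k] + lodds[k, NT_INDEX[seq[i + 0]]])
        if state == "M" and k < L:
            walk("D", k + 1, i, score + t["MD"][k])
            if i < n:
                walk("I", k, i + 1, score + t["MI"][k])
        if state == "I" and k < L and i < n:
            walk("M", k + 1, i + 1, score + t["IM"][k] + lodds[k, NT_INDEX[seq[i]]])
            walk("I", k, i + 1, score + t["II"][k])
        if state == "D" and k < L:
            walk("M", k + 1, i + 1, score + t["DM"][k] + lodds[k, NT_INDEX[seq[i]]]) if i < n else None
            walk("D", k + 1, i, score + t["DD"][k])

    for start in range(n):
        for k0 in range(1, L + 1):
            walk("M", k0, start + 1, entry + lodds[k0 - 1, NT_INDEX[seq[start]]])
    return best


def test_viterbi_equals_exhaustive_path_enumeration():
    """DP local score equals brute-force max over all alignments (L<=4, n<=8)."""
    rng = np.random.default_rng(8)
    letters = np.array(list("ACGU"))
    for trial in range(6):
        ncols = int(rng.integers(2, 5))
        rows = ["".join(rng.choice(letters, ncols)) for _ in range(3)]
        hmm = build_phmm(rows, pseudocount=0.3)
        seq = "".join(rng.choice(letters, int(rng.integers(2, 9))))
        dp_score, _, _ = _best_hit(hmm, seq)
        brute = _enumerate_local_score(hmm, seq)
        assert dp_score == pytest.approx(brute, abs=1e-9)


class TestEvalue:
    def test_calibration_is_seed_reproducible(self):
        hmm = build_phmm(["ACGUACGUAC"] * 3)
        g1 = calibrate_evalue(hmm, decoy_count=200, decoy_length=60, seed=5)
        g2 = calibrate_evalue(hmm, decoy_count=200, decoy_length=60, seed=5)
        assert g1 == g2

    def test_evalue_at_mu_is_n_targets(self):
        hmm = build_phmm(["ACGUACGUAC"] * 3)
        g = calibrate_evalue(hmm, decoy_count=200, decoy_length=60, seed=5)
        assert evalue(hmm, g.mu, n_targets=1) == pytest.approx(1.0)

    def test_evalue_monotone_decreasing_and_bounded(self):
        hmm = build_phmm(["ACGUACGUAC"] * 3)
        calibrate_evalue(hmm, decoy_count=200, decoy_length=60, seed=5)
        scores = np.linspace(-5, 40, 30)
        es = [evalue(hmm, s) for s in scores]
        assert all(a >= b for a, b in zip(es, es[1:]))
        assert all(0 <= e <= 1 for e in es)
        assert evalue(hmm, 1e6) == pytest.approx(0.0)

    def test_too_few_decoys_rejected(self):
        hmm = build_phmm(["ACGUACGUAC"] * 3)
        with pytest.raises(ValueError):
            calibrate_evalue(hmm, decoy_count=50)


def test_json_serialization_roundtrip():
    hmm = build_phmm(["ACGUACGUAC"] * 3)
    calibrate_evalue(hmm, decoy_count=200, decoy_length=60, seed=5)
    back = hmm_from_json(hmm_to_json(hmm))
    assert back.L == hmm.L
    assert np.allclose(back.match_emissions, hmm.match_emissions)
    assert back.calibration == hmm.calibration
    # behaviourally identical
    s1, _, _ = _best_hit(hmm, "GGGGACGUACGUACGGGG")
    s2, _, _ = _best_hit(back, "GGGGACGUACGUACGGGG")
    assert s1 == pytest.approx(s2)
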