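"""12-letter encoding and sequence-structure alignment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from its1kit.align import _gotoh, align_pair, progressive_align
from its1kit.alphabet import (
    GAP_CODE,
    SYMBOLS,
    ScoreModel,
    decode12,
    default_score_model,
    encode12,
)
from its1kit.records import Record
from its1kit.simulate import simulate_its1


class TestEncode:
    def test_basic_composition(self):
        c = encode12("AC", "()")
        assert c.symbols() == ["A(", "C)"]

    def test_all_unpaired(self):
        c = encode12("ACGU", "....")
        assert [s[1] for s in c.symbols()] == ["."] * 4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            encode12("ACG", "....")

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_encode_decode_identity_on_folded_records(self, seed):
        from its1kit.fold import fold_mfe

        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGU"), int(rng.integers(4, 30))))
        db = fold_mfe(seq).dotbracket
        assert decode12(encode12(seq, db)) == (seq, db)


class TestScoreModel:
    def test_additive_construction_values(self):
        m = default_score_model()
        iA_paired = SYMBOLS.index("A(")
        iA_un = SYMBOLS.index("A.")
        assert m.S[iA_paired, iA_paired] == 3.0  # match + bonus
        assert m.S[iA_paired, iA_un] == 1.0  # match + penalty

    def test_symmetric_all_entries(self):
        m = default_score_model()
        assert np.array_equal(m.S, m.S.T)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            default_score_model(match=1.0, mismatch=2.0)
        with pytest.raises(ValueError):
            ScoreModel(np.zeros((4, 4)))


def _brute_force_best(x, y, S, go, ge):
    """Exhaustive optimal affine alignment score: gap of length g costs
    go + g*ge.  Oracle for the Gotoh DP, lengths <= 6."""
    best = -np.inf
    n, m = len(x), len(y)

    def rec(i, j, ops):
        nonlocal best
        if i == n and j == m:
            sc, run = 0.0, None
            for a, b in ops:
                if a >= 0 and b >= 0:
                    sc += S[x[a], y[b]]
                    run = None
                elif a >= 0:
                    sc += (go + ge) if run != "x" else ge
                    run = "x"
                else:
                    sc += (go + ge) if run != "y" else ge
                    run = "y"
            best = max(best, sc)
            return
        if i < n and j < m:
            rec(i + 1, j + 1, ops + [(i, j)])
        if i < n:
            rec(i + 1, j, ops + [(i, -1)])
        if j < m:
            rec(i, j + 1, ops + [(-1, j)])

    rec(0, 0, [])
    return best


class TestAlignPair:
    def test_identical_codes_score_and_no_gaps(self):
        m = default_score_model()
        c = encode12("GGGAAACCC", "(((...)))")
        a = align_pair(c, c, m)
        assert a.score == pytest.approx(9 * 3.0)
        assert GAP_CODE not in a.row1 and GAP_CODE not in a.row2

    def test_single_overhang_costs_open_plus_extend(self):
        m = default_score_model()
        a = align_pair(encode12("AC", "()"), encode12("ACA", "()."), m)
        assert a.score == pytest.approx(2 * 3.0 + m.gap_open + m.gap_extend)

    def test_score_symmetric_under_exchange(self):
        m = default_score_model()
        rng = np.random.default_rng(6)
        for _ in range(10):
            from its1kit.fold import fold_mfe

            s1 = "".join(rng.choice(list("ACGU"), int(rng.integers(4, 15))))
            s2 = "".join(rng.choice(list("ACGU"), int(rng.integers(4, 15))))
            c1 = encode12(s1, fold_mfe(s1).dotbracket)
            c2 = encode12(s2, fold_mfe(s2).dotbracket)
            assert align_pair(c1, c2, m).score == pytest.approx(
                align_pair(c2, c1, m).score
            )

    def test_matches_brute_force_on_short_codes(self):
        """Gotoh equals exhaustive enumeration for code lengths <= 6."""
        m = default_score_model()
        rng = np.random.default_rng(7)
        for _ in range(60):
            x = rng.integers(0, 12, int(rng.integers(1, 7)))
            y = rng.integers(0, 12, int(rng.integers(1, 7)))
            sc, _ = _gotoh(x, y, m.S, m.gap_open, m.gap_extend)
            assert sc == pytest.approx(_brute_force_best(x, y, m.S, m.gap_open, m.gap_extend))

    def test_traceback_rows_degap_to_inputs(self):
        m = default_score_model()
        c1 = encode12("GGGAAACCC", "(((...)))")
        c2 = encode12("GGGAAAACCC", "(((....)))")
        a = align_pair(c1, c2, m)
        assert list(a.row1[a.row1 != GAP_CODE]) == list(c1.codes)
        assert list(a.row2[a.row2 != GAP_CODE]) == list(c2.codes)


class TestProgressive:
    def test_identical_records_align_without_gaps(self):
        recs = [
            Record(id=f"r{i}", seq="GGGAAACCC", structure="(((...)))") for i in range(3)
        ]
        aln = progressive_align(recs)
        assert aln.n_cols == 9
        assert all(GAP_CODE not in row for row in aln.rows)

    def test_single_extra_unpaired_base_gives_one_gap_column(self):
        recs = [
            Record(id="a", seq="GGGAAACCC", structure="(((...)))"),
            Record(id="b", seq="GGGAAAACCC", structure="(((....)))"),
        ]
        aln = progressive_align(recs)
        assert aln.n_cols == 10
        assert sum(1 for c in aln.rows[0] if c == GAP_CODE) == 1

    def test_rows_degap_to_original_records(self):
        recs = [simulate_its1(seed=s, rec_id=f"r{s}") for s in (3, 4, 5)]
        recs = [
            Record(id=r.id, seq=r.seq, structure=r.structure) for r in recs
        ]
        aln = progressive_align(recs)
        assert len(aln.rows) == len(recs)
        for i, rec in enumerate(recs):
            seq, db = aln.gapped_strings(i)
            assert seq.replace("-", "") == rec.seq
            assert db.replace("-", "") == rec.structure

    def test_k_copies_pairwise_score_identity(self):
        """k identical records: every induced pair scores n*(match+bonus)."""
        m = default_score_model()
        rec = Record(id="x", seq="GGGAAACCC", structure="(((...)))")
        recs = [Record(id=f"x{i}", seq=rec.seq, structure=rec.structure) for i in range(4)]
        aln = progressive_align(recs, m)
        n = len(rec.seq)
        total = 0.0
        for i, j in itertools.combinations(range(4), 2):
            total += m.S[aln.rows[i], aln.rows[j]].sum()
        assert total == pytest.approx(4 * 3 / 2 * n * 3.0)

    def test_record_without_structure_rejected(self):
        recs = [
            Record(id="a", seq="GGGAAACCC", structure="(((...)))"),
            Record(id="b", seq="GGGAAACCC"),
        ]
        with pytest.raises(ValueError, match="structure"):
            progressive_align(recs)
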