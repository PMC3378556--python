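import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_force_apc, brute_force_omes
from rnacov import (Alignment, ScoreMatrix, column_profile, mip, mixy,
                    n_unordered_pairs, omes, pair_state_table, zscores)


def make_alignment(columns: list[str]) -> Alignment:
    """Build an alignment from per-column strings (sequences are rows)."""
    n = len(columns[0])
    rows = ["".join(col[k] for col in columns) for k in range(n)]
    return Alignment([f"s{k}" for k in range(n)], rows)


class TestColumnProfile:
    @pytest.mark.parametrize("column, expected", [
        ("AAAA", 0.0),                 # single state
        ("AAGG", 1.0),                 # two equiprobable states
        ("ACGU", 2.0),                 # four equiprobable states
        ("AA--", 1.0),                 # gap counts as a state
    ])
    def test_entropy_closed_forms(self, column, expected):
        aln = make_alignment([column, "A" * len(column)])
        prof = column_profile(aln, 1)
        assert prof.entropy == pytest.approx(expected, abs=1e-12)

    def test_ambiguity_excluded_from_denominator(self):
        # N removed entirely: remaining A,A,G,G -> 1 bit
        aln = make_alignment(["AAGGN", "AAAAA"])
        prof = column_profile(aln, 1)
        assert prof.entropy == pytest.approx(1.0)
        assert prof.ambiguous_freq == pytest.approx(0.2)

    def test_empty_effective_column(self):
        aln = make_alignment(["NN", "AA"])
        prof = column_profile(aln, 1)
        assert prof.entropy == 0.0
        assert all(v == 0.0 for v in prof.freqs.values())

    def test_inverted_conservation(self):
        aln = make_alignment(["ACGU", "AAAA"])
        assert column_profile(aln, 1).inverted_conservation() == pytest.approx(0.0)


class TestPairStateTable:
    def test_direct_counts(self, tiny_alignment):
        table = pair_state_table(tiny_alignment, 1, 2)
        assert table.n_effective == 4
        assert table.pair_type_freqs() == {"A:U": 0.5, "G:C": 0.5}
        assert table.marginal_x[0] == pytest.approx(0.5)  # Pr(A_x)

    def test_ambiguous_row_excluded(self):
        aln = Alignment(["a", "b", "c"], ["AU", "NU", "GC"])
        table = pair_state_table(aln, 1, 2)
        assert table.n_effective == 2

    def test_transpose_symmetry(self, tiny_alignment):
        t12 = pair_state_table(tiny_alignment, 1, 2)
        t21 = pair_state_table(tiny_alignment, 2, 1)
        assert np.array_equal(t12.counts, t21.counts.T)


class TestMixy:
    def test_two_coupled_states_one_bit(self, tiny_alignment):
        table = pair_state_table(tiny_alignment, 1, 2)
        assert mixy(table) == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_zero(self):
        aln = make_alignment(["AAAA", "ACGU"])
        assert mixy(pair_state_table(aln, 1, 2)) == pytest.approx(0.0, abs=1e-12)

    def test_four_coupled_states_two_bits(self):
        aln = make_alignment(["AUGC", "UACG"])
        assert mixy(pair_state_table(aln, 1, 2)) == pytest.approx(2.0, abs=1e-12)

    def test_uninformative_pair_raises(self):
        aln = Alignment(["a", "b", "c"], ["AU", "N-", "-N"])
        with pytest.raises(ValueError):
            mixy(pair_state_table(aln, 1, 2))

    @given(st.lists(st.sampled_from("ACGU-"), min_size=4, max_size=24),
           st.lists(st.sampled_from("ACGU-"), min_size=4, max_size=24))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_min_marginal_entropy_and_symmetric(self, colx, coly):
        # the information bound MI <= min(H) holds on the joint support:
        # marginals of the pair table, nucleotides only
        n = min(len(colx), len(coly))
        aln = make_alignment(["".join(colx[:n]), "".join(coly[:n])])
        table = pair_state_table(aln, 1, 2)
        if table.n_effective < 2:
            return
        mi = mixy(table)
        hx = -sum(p * math.log2(p) for p in table.marginal_x if p > 0)
        hy = -sum(p * math.log2(p) for p in table.marginal_y if p > 0)
        assert -1e-12 <= mi <= min(hx, hy) + 1e-9
        assert mi == pytest.approx(mixy(pair_state_table(aln, 2, 1)))


class TestOmes:
    def test_perfect_independence_zero(self):
        # every observed count equals its expectation exactly
        aln = make_alignment(["AAGG", "AGAG"])
        assert omes(pair_state_table(aln, 1, 2)) == pytest.approx(0.0)

    def test_two_type_table_equals_oracle(self, tiny_alignment):
        table = pair_state_table(tiny_alignment, 1, 2)
        expected = brute_force_omes([("A", "U"), ("A", "U"),
                                     ("G", "C"), ("G", "C")])
        assert expected == pytest.approx(1.0)
        assert omes(table) == pytest.approx(expected, abs=1e-12)

    def test_doubling_counts_doubles_score(self):
        pairs = [("A", "U"), ("A", "U"), ("G", "C"), ("G", "U")]
        aln1 = make_alignment(["".join(a for a, _ in pairs),
                               "".join(b for _, b in pairs)])
        aln2 = make_alignment(["".join(a for a, _ in pairs * 2),
                               "".join(b for _, b in pairs * 2)])
        s1 = omes(pair_state_table(aln1, 1, 2))
        s2 = omes(pair_state_table(aln2, 1, 2))
        assert s2 == pytest.approx(2 * s1, abs=1e-12)
        assert s1 == pytest.approx(brute_force_omes(pairs), abs=1e-12)


class TestMip:
    def test_uniform_matrix_gives_zero_mip(self):
        # constant MIxy -> APC equals the constant, every MIp exactly 0,
        # and the Z-score is undefined (sd = 0)
        values = {(i, j): 0.7 for i in range(1, 5) for j in range(i + 1, 5)}
        sm = ScoreMatrix("MIxy", values)
        mip_sm = mip(sm)
        assert all(s == pytest.approx(0.0, abs=1e-12) for _, s in mip_sm.items())
        with pytest.raises(ValueError, match="Z-score"):
            zscores(mip_sm)
        apc = brute_force_apc(values)
        assert all(abs(v) < 1e-12 for v in apc.values())

    def test_matches_brute_force_apc(self):
        rng = np.random.default_rng(7)
        mi_values = {}
        sm = ScoreMatrix("MIxy")
        for i in range(1, 11):
            for j in range(i + 1, 11):
                v = float(rng.uniform(0, 2))
                mi_values[(i, j)] = v
                sm.set(i, j, v)
        mip_sm = mip(sm)
        z_sm = zscores(mip_sm)
        expected = brute_force_apc(mi_values)
        for pair, v in expected.items():
            assert mip_sm.get(*pair) == pytest.approx(v, abs=1e-12)
        zs = np.array([s for _, s in z_sm.items()])
        assert zs.mean() == pytest.approx(0.0, abs=1e-9)
        assert zs.std() == pytest.approx(1.0, abs=1e-9)

    def test_four_column_toy_hand_computed(self):
        # 6 pairwise MIxy values; APC computed by hand with the oracle
        # before freezing: MIp(1,2) = 1.0 - (0.6*0.5)/0.45 = 0.33333...
        values = {(1, 2): 1.0, (1, 3): 0.5, (1, 4): 0.3,
                  (2, 3): 0.2, (2, 4): 0.3, (3, 4): 0.4}
        sm = ScoreMatrix("MIxy", values)
        mip_sm = mip(sm)
        assert mip_sm.get(1, 2) == pytest.approx(1.0 - 0.6 * 0.5 / 0.45,
                                                 abs=1e-12)
        expected = brute_force_apc(values)
        for pair, v in expected.items():
            assert mip_sm.get(*pair) == pytest.approx(v, abs=1e-12)


class TestScoreMatrix:
    def test_symmetry_and_no_self_pairs(self):
        sm = ScoreMatrix("x")
        sm.set(5, 2, 1.5)
        assert sm.get(2, 5) == 1.5
        assert (5, 2) in sm
        with pytest.raises(ValueError):
            sm.set(3, 3, 1.0)

    def test_ranked_partners_order_and_ties(self):
        sm = ScoreMatrix("x")
        sm.set(1, 2, 0.9)
        sm.set(1, 3, 0.9)
        sm.set(1, 4, 0.1)
        assert sm.ranked_partners(1) == [(2, 0.9), (3, 0.9), (4, 0.1)]


def test_pair_enumeration_for_wide_alignment():
    assert n_unordered_pairs(3236) == 5_234_230
    assert n_unordered_pairs(2) == 1
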