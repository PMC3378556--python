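import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_force_purity
from rnacov import (Alignment, PECResult, ReferenceStructure, ScoreMatrix,
                    base_center_distance, build_position_map,
                    canonical_fraction, evaluate_calls, helix_extend,
                    neighbor_effects, purity_from_counts,
                    read_reference_structure)
from rnacov.pec import EventCount


def alignment_from_columns(columns: list[str]) -> Alignment:
    n = len(columns[0])
    rows = ["".join(col[k] for col in columns) for k in range(n)]
    return Alignment([f"s{k}" for k in range(n)], rows)


class TestHelixExtend:
    def make_alignment(self):
        # 10 columns x 8 sequences; helix at (3,8),(4,7) all canonical;
        # (5,6) only 50% canonical; flanks (2,9) random non-canonical
        cols = [
            "AAAAAAAA",   # 1
            "ACGUACGU",   # 2 random
            "GGGGCCCC",   # 3 pairs col 8
            "AAAAUUUU",   # 4 pairs col 7
            "AAAAAAAA",   # 5: A:A with col 6 half the time
            "UUUUGGGG",   # 6: A:U x4 then A:G x4 -> 50% canonical
            "UUUUAAAA",   # 7
            "CCCCGGGG",   # 8
            "ACGUACGU",   # 9 random
            "AAAAAAAA",   # 10
        ]
        return alignment_from_columns(cols)

    def test_outward_extension_until_failure(self):
        aln = self.make_alignment()
        res = helix_extend(aln, [(4, 7)], 0.85)
        ext = {e.pair for e in res.extended_pairs}
        assert (3, 8) in ext          # 100% canonical, added
        assert (2, 9) not in ext      # random columns fail threshold
        assert (5, 6) not in ext      # 50% canonical, inward stops

    def test_every_extension_meets_threshold_post_hoc(self):
        aln = self.make_alignment()
        res = helix_extend(aln, [(4, 7)], 0.85)
        for e in res.extended_pairs:
            assert canonical_fraction(aln, *e.pair) >= 0.85
            assert e.canonical_fraction == pytest.approx(
                canonical_fraction(aln, *e.pair))

    def test_extension_stops_at_alignment_edge(self):
        aln = alignment_from_columns(["GGCC", "CCGG"])
        res = helix_extend(aln, [(1, 2)], 0.85)
        assert res.extended_pairs == []

    def test_nucleation_pairs_not_readded(self):
        aln = self.make_alignment()
        res = helix_extend(aln, [(3, 8), (4, 7)], 0.85)
        ext = {e.pair for e in res.extended_pairs}
        assert ext.isdisjoint({(3, 8), (4, 7)})

    def test_85_percent_boundary(self):
        # outward from (3,4): first step (2,5) is 17/20 = 85% canonical
        # (accepted, inclusive threshold); next step (1,6) is 16/20 = 80%
        # (rejected, extension stops)
        aln = alignment_from_columns([
            "G" * 20,                # 1
            "G" * 20,                # 2
            "A" * 20,                # 3 nucleation 5'
            "U" * 20,                # 4 nucleation 3'
            "C" * 17 + "A" * 3,      # 5
            "C" * 16 + "A" * 4,      # 6
        ])
        res = helix_extend(aln, [(3, 4)], 0.85)
        ext = {e.pair for e in res.extended_pairs}
        assert (2, 5) in ext
        assert (1, 6) not in ext

    def test_recovers_planted_invariant_flanks(self, fitted_default):
        model, results, truth = fitted_default
        res = helix_extend(model.alignment, results.calls["CPE"], 0.85)
        flanks = {p for b in truth.helix_blocks for p in b.invariant_pairs}
        ext = {e.pair for e in res.extended_pairs}
        assert len(ext & flanks) / len(flanks) >= 0.9


class TestPurity:
    @pytest.mark.parametrize("counts", [
        {"A:U": 10, "G:C": 5, "U:A": 3, "C:G": 2},
        {"A:A": 1, "G:G": 1, "C:C": 1, "U:U": 1},
        {"A:U": 3, "G:G": 7},
        {"A:G": 4, "G:A": 6},
        {"A:C": 1, "G:U": 9},
    ])
    def test_fully_covarying_sets_score_one(self, counts):
        res = purity_from_counts(counts)
        assert res.purity == pytest.approx(1.0)

    def test_one_nucleotide_dominated_table(self):
        res = purity_from_counts(
            {"A:A": 0.4, "A:G": 0.3, "A:C": 0.2, "A:U": 0.1}
        )
        # every type shares the 5' A: only the top type is accepted
        assert res.purity == pytest.approx(0.4)
        assert res.accepted_types == ["A:A"]
        assert res.purity == pytest.approx(
            brute_force_purity({"A:A": 0.4, "A:G": 0.3,
                                "A:C": 0.2, "A:U": 0.1}))

    def test_wobble_credited_in_gu_plus(self):
        res = purity_from_counts({"A:U": 0.5, "G:C": 0.3, "G:U": 0.2})
        assert res.purity == pytest.approx(0.8)
        assert res.gu_plus_purity == pytest.approx(1.0)

    def test_gu_blocks_noncanonical_even_in_gu_plus(self):
        res = purity_from_counts({"G:U": 0.5, "G:A": 0.5})
        assert res.purity == pytest.approx(0.5)
        assert res.gu_plus_purity == pytest.approx(0.5)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            purity_from_counts({})

    @given(st.dictionaries(
        st.sampled_from([f"{a}:{b}" for a in "ACGU" for b in "ACGU"]),
        st.integers(min_value=1, max_value=50),
        min_size=1, max_size=16,
    ))
    @settings(max_examples=200, deadline=None)
    def test_gu_plus_at_least_purity_and_bounds(self, counts):
        res = purity_from_counts(counts)
        assert 0.0 < res.purity <= 1.0
        assert res.purity <= res.gu_plus_purity <= 1.0
        assert res.purity == pytest.approx(brute_force_purity(counts))


class TestDistances:
    def make_structure(self, centers):
        return ReferenceStructure("ref", base_centers=centers)

    def test_identical_centers_zero(self):
        s = self.make_structure({1: np.zeros(3), 2: np.zeros(3)})
        assert base_center_distance(s, 1, 2) == pytest.approx(0.0)

    def test_three_four_five(self):
        s = self.make_structure({1: np.array([0.0, 0.0, 0.0]),
                                 2: np.array([3.0, 4.0, 0.0])})
        assert base_center_distance(s, 1, 2) == pytest.approx(5.0)

    def test_missing_position_returns_none(self):
        s = self.make_structure({1: np.zeros(3)})
        assert base_center_distance(s, 1, 99) is None

    def test_no_coordinates_raises(self):
        s = ReferenceStructure("ref")
        with pytest.raises(ValueError):
            base_center_distance(s, 1, 2)

    def test_toy_pdb_matches_hand_calculation(self, tmp_path):
        # G edge atoms (N1,N2,O6) all at origin; C edge atoms (N3,O2,N4)
        # all at (3,4,0): centers 5.0 Angstroms apart
        def atom(serial, name, resname, resseq, x, y, z):
            return (f"ATOM  {serial:5d}  {name:<3s}{resname:>3s} A"
                    f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"  1.00  0.00           {name[0]}\n")

        pdb = tmp_path / "toy.pdb"
        pdb.write_text(
            atom(1, "N1", "G", 1, 0, 0, 0)
            + atom(2, "N2", "G", 1, 0, 0, 0)
            + atom(3, "O6", "G", 1, 0, 0, 0)
            + atom(4, "N3", "C", 2, 3, 4, 0)
            + atom(5, "O2", "C", 2, 3, 4, 0)
            + atom(6, "N4", "C", 2, 3, 4, 0)
            + "END\n"
        )
        bpseq = tmp_path / "toy.bpseq"
        bpseq.write_text("1 G 2\n2 C 1\n")
        ref = read_reference_structure(bpseq, "ref", pdb=pdb)
        assert base_center_distance(ref, 1, 2) == pytest.approx(5.0)


class TestNeighborEffects:
    def make_pec_result(self, entries, events):
        sm = ScoreMatrix("CPE", entries)
        counts = {tuple(sorted(p)): EventCount(*ev)
                  for p, ev in events.items()}
        return PECResult(sm, counts)

    def base_case(self, cpe_12=0.3, events_12=(4, 8)):
        # columns 1 and 2 each have two partners with near-equal CPE
        entries = {(1, 2): cpe_12, (1, 3): 0.29, (2, 4): 0.28,
                   (3, 4): 0.05}
        events = {(1, 2): events_12, (1, 3): (3, 7), (2, 4): (3, 7),
                  (3, 4): (1, 9)}
        return self.make_pec_result(entries, events)

    def test_all_criteria_met_flags_pair(self):
        res = self.base_case()
        effects = neighbor_effects(res, [], ratio_min=0.85,
                                   cpe_min=0.25, events_min=10)
        pairs = {e.pair for e in effects}
        assert (1, 2) in pairs
        e = next(e for e in effects if e.pair == (1, 2))
        assert e.nbest_ratio >= 0.85 and e.total_events == 12

    def test_low_cpe_not_flagged(self):
        # events give CPE 2/12 < 0.25 although ratios and totals qualify
        res = self.base_case(events_12=(2, 10))
        effects = neighbor_effects(res, [], cpe_min=0.25)
        assert all(e.pair != (1, 2) for e in effects)

    def test_low_ratio_not_flagged(self):
        entries = {(1, 2): 0.5, (1, 3): 0.1, (2, 4): 0.1}
        events = {(1, 2): (25, 25), (1, 3): (1, 9), (2, 4): (1, 9)}
        res = self.make_pec_result(entries, events)
        effects = neighbor_effects(res, [], ratio_min=0.85)
        assert effects == []

    def test_too_few_events_not_flagged(self):
        res = self.base_case(events_12=(3, 6))
        effects = neighbor_effects(res, [], events_min=10)
        assert all(e.pair != (1, 2) for e in effects)

    def test_called_pairs_excluded(self):
        res = self.base_case()
        effects = neighbor_effects(res, [(1, 2)])
        assert all(e.pair != (1, 2) for e in effects)

    def test_distance_and_class_annotation(self):
        res = self.base_case()
        aln = Alignment(["ref", "o"], ["AUGC", "AUGC"])
        pm = build_position_map(aln, "ref")
        structure = ReferenceStructure(
            "ref", pairs={(1, 2)}, pair_class={(1, 2): "tertiary"},
            base_centers={1: np.zeros(3), 2: np.array([0.0, 0.0, 2.0])},
        )
        effects = neighbor_effects(res, [], structure=structure,
                                   position_map=pm)
        e = next(e for e in effects if e.pair == (1, 2))
        assert e.distance == pytest.approx(2.0)
        assert e.h_bonded_class == "tertiary"


class TestEvaluateCalls:
    def setup_refs(self):
        aln = Alignment(["ref", "o"], ["AU-GC", "AUCGC"])
        pm = build_position_map(aln, "ref")
        structure = ReferenceStructure(
            "ref", pairs={(1, 4)}, pair_class={(1, 4): "secondary"},
        )
        return pm, structure

    def test_tp_fp_and_unmappable(self):
        pm, structure = self.setup_refs()
        # columns (1,5)->positions (1,4): TP; (2,4)->(2,3): FP;
        # (3,4): column 3 is reference-gapped -> unmappable
        report = evaluate_calls([(1, 5), (2, 4), (3, 4)], pm, structure)
        assert report.n_true_positive == 1
        assert report.n_false_positive == 1
        assert report.n_unmappable == 1
        assert report.calls[0].pair_class == "secondary"

    def test_curve_ends_at_overall_precision(self):
        pm, structure = self.setup_refs()
        report = evaluate_calls([(1, 5), (2, 4)], pm, structure)
        assert report.precision_curve[-1] == (2, pytest.approx(0.5))
        assert report.precision == pytest.approx(0.5)
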