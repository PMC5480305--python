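"""Pathway barrier functional and the low-barrier constructors."""

import itertools

import pytest

from switchlock.design import DesignParams, initial_structure, region_map_of, \
    target_structure
from switchlock.energy import ARC, STACK
from switchlock.pathway import (Move, Pathway, PathwayError, barrier_of_trace,
                                construct_low_barrier_pathway_4,
                                construct_low_barrier_pathway_8,
                                expected_barrier_4, expected_barrier_8,
                                reconfigure_switch, unlock_band, read_pathway,
                                write_pathway)


def brute_barrier(trace):
    return max(trace[i] - trace[j]
               for i in range(len(trace)) for j in range(i, len(trace)))


class TestBarrierFunctional:
    @pytest.mark.parametrize("trace,want", [
        ([5, 4, 3, 4, 5], 2),
        ([3, 3, 3], 0),
        ([3, 4, 5, 4, 3, 2], 3),
        ([0, 5, 1, 6, 0], 6),
    ])
    def test_against_all_pairs(self, trace, want):
        assert barrier_of_trace(trace) == want == brute_barrier(trace)

    def test_single_point(self):
        assert barrier_of_trace([7]) == 0


class TestPathwayChecks:
    def test_removing_absent_arc_rejected(self, tiny_design):
        params, seq, _ = tiny_design
        with pytest.raises(PathwayError):
            Pathway(seq, initial_structure(params), [Move("remove", (0, 3))])

    def test_crossing_addition_rejected(self, tiny_design):
        params, seq, _ = tiny_design
        # (1,3) is U·A, complementary, but crosses the switch arc (0,2)
        with pytest.raises(PathwayError):
            Pathway(seq, initial_structure(params), [Move("add", (1, 3))])

    def test_reversal_is_valid_and_swaps_endpoints(self):
        p = construct_low_barrier_pathway_8(DesignParams(1, 4, 2))
        r = p.reversed()
        assert r.start.arc_set() == p.end.arc_set()
        assert r.end.arc_set() == p.start.arc_set()
        assert r.validate_all() == []


class TestReconfigureSwitch:
    @pytest.mark.parametrize("k,A", [(1, 2), (2, 4), (3, 6)])
    def test_move_count_2k_Aminus1(self, k, A):
        params = DesignParams(k, A, 2)
        moves = reconfigure_switch(initial_structure(params), "left_to_right",
                                   params)
        assert len(moves) == 2 * k * (A - 1)

    def test_subpathway_barrier_k_plus_1(self):
        params = DesignParams(2, 4, 2)
        seq, _ = region_map_of(params)
        start = initial_structure(params)
        moves = reconfigure_switch(start, "left_to_right", params)
        p = Pathway(seq, start, moves)
        assert p.barrier(ARC) == params.k + 1 == 3

    def test_requires_pure_position(self):
        params = DesignParams(1, 4, 2)
        start = initial_structure(params)
        broken = start.without_arc(start.arcs[0])
        with pytest.raises(PathwayError):
            reconfigure_switch(broken, "left_to_right", params)


class TestUnlockBand:
    @pytest.mark.parametrize("k,A", [(1, 2), (2, 4)])
    def test_move_count_2kA_plus_4k(self, k, A):
        params = DesignParams(k, A, 2)
        moves = unlock_band(initial_structure(params), 1, params)
        assert len(moves) == 2 * k * A + 4 * k

    def test_k_trans_arcs_formed_and_removed(self):
        params = DesignParams(3, 4, 2)
        moves = unlock_band(initial_structure(params), 1, params)
        n_switch = 2 * params.k * params.A
        trans_added = [m for m in moves
                       if m.op == "add" and m.arc[0] < n_switch <= m.arc[1]]
        trans_removed = [m for m in moves
                         if m.op == "remove" and m.arc[0] < n_switch <= m.arc[1]]
        assert len(trans_added) == len(trans_removed) == params.k

    def test_center_band_fully_removed(self):
        params = DesignParams(2, 4, 2)
        start = initial_structure(params)
        moves = unlock_band(start, 1, params)
        s = start
        for m in moves:
            s = s.with_arc(m.arc) if m.op == "add" else s.without_arc(m.arc)
        _, rmap = region_map_of(params)
        l1, r1 = rmap["l1"], rmap["r1"]
        assert not any(l1.start <= i < l1.end and r1.start <= j < r1.end
                       for i, j in s.arcs)

    def test_out_of_order_unlock_rejected(self):
        params = DesignParams(1, 4, 2)
        with pytest.raises(PathwayError):
            unlock_band(initial_structure(params), 2, params)


GRID_8 = [(k, A, B) for k, A, B in
          itertools.product((1, 2, 3), (2, 4, 6), (2, 4))]


class TestConstructor8:
    @pytest.mark.parametrize("k,A,B", GRID_8)
    def test_length_barrier_endpoints(self, k, A, B):
        params = DesignParams(k, A, B)
        p = construct_low_barrier_pathway_8(params)
        assert len(p) == 2 * k * (A * B + A + 2 * B - 1)
        assert p.barrier(ARC) == expected_barrier_8(params)
        assert p.start.arc_set() == initial_structure(params).arc_set()
        assert p.end.arc_set() == target_structure(params).arc_set()

    def test_every_structure_validates(self):
        p = construct_low_barrier_pathway_8(DesignParams(2, 4, 4))
        assert p.validate_all() == []

    def test_ac_range_consistent_with_barrier(self):
        # max AC along the pathway is MAC, min is MAC - (k+1), both attained
        params = DesignParams(2, 4, 2)
        p = construct_low_barrier_pathway_8(params)
        trace = p.energies(ARC)
        mac = (params.A - 1) * params.k + 2 * params.k * params.B
        assert max(trace) == mac
        assert min(trace) == mac - (params.k + 1)

    def test_barrier_k1_A2_is_k(self):
        # degenerate switch: one band pair, no branch migration subphase
        p = construct_low_barrier_pathway_8(DesignParams(3, 2, 2))
        assert p.barrier(ARC) == 3


GRID_4 = [(2, 2, 2), (2, 4, 2), (2, 4, 4), (4, 4, 2), (4, 2, 2)]


class TestConstructor4:
    @pytest.mark.parametrize("k,A,B", GRID_4)
    def test_length_barrier_endpoints(self, k, A, B):
        params = DesignParams(k, A, B, "four_letter_prime")
        p = construct_low_barrier_pathway_4(params)
        assert len(p) == (2 * k * (A - 1) + 6 * k + 3) * B + 2 * k * (A - 1)
        assert p.barrier(STACK) == expected_barrier_4(params)
        assert p.start.arc_set() == initial_structure(params).arc_set()
        assert p.end.arc_set() == target_structure(params).arc_set()

    def test_length_formula_instance(self):
        p = construct_low_barrier_pathway_4(DesignParams(2, 2, 2, "four_letter_prime"))
        assert len(p) == (2 * 2 * 1 + 12 + 3) * 2 + 4 == 42

    def test_per_band_lock_budget_6k_plus_3(self):
        # moves per unlock beyond the embedded switch reconfiguration
        params = DesignParams(2, 4, 2, "four_letter_prime")
        k, A = params.k, params.A
        moves = unlock_band(initial_structure(params), 1, params)
        assert len(moves) - 2 * k * (A - 1) == 6 * k + 3
        # decomposition: (2k+1) center removals, k trans adds, k trans
        # removals, (k+1)+(k+1) replacement-band additions
        n_switch = 2 * k * A
        lock_moves = moves[2 * k * (A - 1):]
        removals = [m for m in lock_moves if m.op == "remove"]
        additions = [m for m in lock_moves if m.op == "add"]
        trans = [m for m in lock_moves if m.arc[0] < n_switch <= m.arc[1]]
        assert len(removals) == (2 * k + 1) + k
        assert len(additions) == k + 2 * (k + 1)
        assert len(trans) == 2 * k

    def test_every_structure_validates(self):
        p = construct_low_barrier_pathway_4(DesignParams(2, 4, 2, "four_letter_prime"))
        assert p.validate_all() == []


class TestPathwayFiles:
    def test_round_trip(self, tmp_path):
        p = construct_low_barrier_pathway_8(DesignParams(1, 2, 2))
        path = tmp_path / "p.db"
        write_pathway(path, p)
        back = read_pathway(path)
        assert len(back) == len(p)
        assert back.barrier(ARC) == p.barrier(ARC)
        assert back.end.arc_set() == p.end.arc_set()
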