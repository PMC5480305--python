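"""The 8->4 letter map, eccentricity dialects, and the Map' identity."""

import numpy as np
import pytest

from switchlock.design import DesignParams, Sequence, build_switch_lock, \
    initial_structure
from switchlock.fourmap import (classify_arc, classify_stack,
                                eccentricity_report, map_sequence,
                                map_structure, prime_mapping)
from switchlock.landscape import random_structure
from switchlock.structure import SecondaryStructure, validate


@pytest.fixture(scope="module")
def mapped_222():
    params = DesignParams(2, 2, 2)
    seq8, rmap8 = build_switch_lock(params)
    return map_sequence(seq8, rmap8)


class TestMapSequence:
    def test_acgu_regions_widen_by_one(self):
        m = map_sequence(Sequence("CC", "eight"))
        assert m.seq4.symbols == "CCC"

    def test_x_region_becomes_alternating_CA(self):
        m = map_sequence(Sequence("XX", "eight"))
        assert m.seq4.symbols == "CAC"

    def test_length_n_plus_r(self, mapped_222):
        n8 = len(mapped_222.seq8)
        assert len(mapped_222.seq4) == n8 + mapped_222.region_count

    def test_mapped_x_y_are_reverse_complementary(self):
        from switchlock.alphabet import COMPLEMENT
        mx = map_sequence(Sequence("XXXX", "eight")).seq4.symbols
        my = map_sequence(Sequence("YYYY", "eight")).seq4.symbols
        assert mx == "".join(COMPLEMENT[c] for c in reversed(my))

    def test_mapped_p_q_are_reverse_complementary(self):
        # even-width regions map to odd alternating runs, which pair exactly;
        # this is why the prime design insists on even k
        from switchlock.alphabet import COMPLEMENT
        mp = map_sequence(Sequence("PP", "eight")).seq4.symbols
        mq = map_sequence(Sequence("QQ", "eight")).seq4.symbols
        assert mp == "AGA" and mq == "UCU"
        assert mp == "".join(COMPLEMENT[c] for c in reversed(mq))


class TestClassification:
    def test_G_to_X_region_arc_is_eccentric(self, mapped_222):
        m = mapped_222
        g = next(r for r in m.regions if r.symbol == "G")
        x = next(r for r in m.regions if r.symbol == "X")
        # a C inside the mapped X run can pair a G of a G-region
        c_pos = next(p for p in range(x.start4, x.end4)
                     if m.seq4.symbols[p] == "C")
        assert classify_arc((g.start4, c_pos), m) == "eccentric"

    def test_C_to_G_region_arc_is_normal(self, mapped_222):
        m = mapped_222
        c = next(r for r in m.regions if r.symbol == "C")
        g = next(r for r in m.regions if r.symbol == "G" and r.start4 > c.start4)
        assert classify_arc((c.start4, g.end4 - 1), m) == "normal"

    def test_boundary_stack_eccentric_in_generic_dialect(self):
        params = DesignParams(2, 4, 2, "four_letter_prime")
        m = prime_mapping(params)
        init = initial_structure(params)
        # junction stack between two switch bands straddles L/R boundaries
        k, A = params.k, params.A
        junction = next((i, j) for i, j in init.arcs
                        if init.partner(i + 1) == j - 1
                        and m.region_at4(i) is not m.region_at4(i + 1))
        assert classify_stack(junction, m, "generic") == "eccentric"
        assert classify_stack(junction, m, "prime") == "normal"

    def test_interior_stack_normal_in_both_dialects(self, mapped_222):
        m = mapped_222
        c = next(r for r in m.regions if r.symbol == "C" and r.end4 - r.start4 > 2)
        g = next(r for r in m.regions if r.symbol == "G" and r.end4 - r.start4 > 2)
        stack = (c.start4, g.end4 - 1)  # with (start+1, end-2) inside
        for dialect in ("generic", "prime"):
            assert classify_stack(stack, m, dialect) == "normal"


class TestMapStructureIdentity:
    """AC(Map'(S')) = SAC(S') - E on random valid structures; E <= r - 1."""

    def test_thousand_random_structures(self, mapped_222):
        m = mapped_222
        rng = np.random.default_rng(42)
        for _ in range(1000):
            s = random_structure(m.seq4, rng)
            rep = eccentricity_report(s, m, "generic")
            mapped = map_structure(s, m, "generic")
            assert mapped.arc_count() == s.stacked_pair_count() - rep.E
            assert rep.E <= rep.r - 1
            assert validate(mapped, m.seq8) == []

    def test_every_eccentric_stack_uses_a_boundary(self, mapped_222):
        # generic dialect: an eccentric stack always straddles a boundary
        m = mapped_222
        rng = np.random.default_rng(7)
        boundaries = {r.end4 for r in m.regions}
        seen = 0
        for _ in range(300):
            s = random_structure(m.seq4, rng)
            for (i, j) in eccentricity_report(s, m, "generic").eccentric_stacks:
                seen += 1
                assert (i + 1 in boundaries) or (j in boundaries)
        assert seen > 0  # the census actually exercised eccentric stacks

    def test_zero_eccentric_gives_exact_equality(self, mapped_222):
        m = mapped_222
        # a single clean in-band stack: no eccentricity, AC == SAC
        c = next(r for r in m.regions if r.symbol == "C" and r.end4 - r.start4 > 2)
        g = next(r for r in m.regions if r.symbol == "G" and r.end4 - r.start4 > 2
                 and r.start4 > c.start4)
        s = SecondaryStructure(len(m.seq4),
                               ((c.start4, g.end4 - 1), (c.start4 + 1, g.end4 - 2)))
        rep = eccentricity_report(s, m, "generic")
        assert rep.E == 0
        assert map_structure(s, m, "generic").arc_count() == s.stacked_pair_count()


class TestPrimeMapping:
    def test_prime_initial_maps_onto_eight_letter_initial(self):
        """Map' recovers the 8-letter initial structure up to the innermost
        switch arc (a helix of m arcs has m-1 stacks)."""
        params4 = DesignParams(2, 4, 2, "four_letter_prime")
        params8 = DesignParams(2, 4, 2)
        m = prime_mapping(params4)
        s4 = initial_structure(params4)
        mapped = map_structure(s4, m)  # prime dialect by default
        init8 = initial_structure(params8)
        missing = init8.arc_set() - mapped.arc_set()
        assert mapped.arc_set() <= init8.arc_set()
        assert len(missing) == 1
        # the one missing arc is the innermost intra-switch arc
        ((i, j),) = missing
        n_switch = 2 * params8.k * params8.A
        assert j < n_switch
        assert eccentricity_report(s4, m).E == 0
        assert mapped.arc_count() == s4.stacked_pair_count()

    def test_prime_lock_bands_map_exactly(self):
        params4 = DesignParams(2, 2, 2, "four_letter_prime")
        params8 = DesignParams(2, 2, 2)
        m = prime_mapping(params4)
        mapped = map_structure(initial_structure(params4), m)
        init8 = initial_structure(params8)
        n_switch = 2 * params8.k * params8.A
        lock8 = {a for a in init8.arcs if a[0] >= n_switch}
        lock_mapped = {a for a in mapped.arcs if a[0] >= n_switch}
        assert lock_mapped == lock8
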