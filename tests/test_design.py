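"""Sequence families, region decompositions and designed structures."""

import pytest

from switchlock.alphabet import complementary
from switchlock.design import (DesignParams, ParameterError, build_lock,
                               build_switch, build_switch_lock,
                               build_switch_lock_prime, initial_structure,
                               region_map_of, target_structure, read_fasta,
                               write_fasta)
from switchlock.structure import validate

from conftest import SMALL_GRID


class TestSwitch:
    def test_printed_A6_template_at_k1(self):
        assert build_switch(1, 6).symbols == "GUGUGUCACACA"

    def test_regex_expansion(self):
        assert build_switch(2, 2).symbols == "GGUUCCAA"

    @pytest.mark.parametrize("k,A", [(1, 2), (3, 6), (5, 8)])
    def test_length_2kA(self, k, A):
        assert len(build_switch(k, A)) == 2 * k * A

    @pytest.mark.parametrize("k,A", [(0, 2), (1, 3), (1, 0), (-1, 4)])
    def test_rejects_bad_parameters(self, k, A):
        with pytest.raises(ParameterError):
            build_switch(k, A)


class TestLock:
    def test_printed_B4_expansion(self):
        k = 2
        want = ("X" * k) * 4 \
            + ("C" * 2 * k + "Y" * k + "A" * 2 * k + "Y" * k) * 2 \
            + ("P" * k + "U" * 2 * k + "P" * k + "G" * 2 * k) * 2 \
            + ("Q" * k) * 4
        assert build_lock(k, 4).symbols == want

    def test_forced_expansion_k1_B2(self):
        assert build_lock(1, 2).symbols == "XXCCYAAYPUUPGGQQ"

    def test_length_8kB(self):
        assert len(build_lock(2, 4)) == 64

    def test_rejects_odd_B(self):
        with pytest.raises(ParameterError):
            build_lock(1, 3)


class TestSwitchLock:
    def test_concatenation_k1(self, tiny_design):
        _, seq, _ = tiny_design
        assert seq.symbols == "GUCA" + "XXCCYAAYPUUPGGQQ"

    @pytest.mark.parametrize("k,A,B", [(2, 4, 2), (1, 2, 2), (3, 8, 6)])
    def test_length_formula(self, k, A, B):
        params = DesignParams(k, A, B)
        seq, _ = build_switch_lock(params)
        assert len(seq) == 2 * k * A + 8 * k * B == params.length

    def test_region_r1_is_G_of_width_2k(self, tiny_design):
        _, seq, rmap = tiny_design
        r1 = rmap["r1"]
        assert r1.symbol == "G" and r1.width == 2
        assert seq.symbols[r1.start:r1.end] == "GG"

    @pytest.mark.parametrize("k,A,B", SMALL_GRID)
    def test_region_map_tiles_and_counts(self, k, A, B):
        seq, rmap = build_switch_lock(DesignParams(k, A, B))
        assert rmap.tiles()
        assert rmap.length() == len(seq)
        assert len(rmap) == 2 * A + 6 * B
        # every region is a maximal run of one symbol
        for r in rmap:
            assert set(seq.symbols[r.start:r.end]) == {r.symbol}

    def test_rightmost_base_indexing(self, tiny_design):
        _, _, rmap = tiny_design
        # R_{a,i} is the i-th rightmost base; L_{a,i} the i-th leftmost
        assert rmap["R1"].base(1) == rmap["R1"].end - 1
        assert rmap["L1"].base(1) == rmap["L1"].start


class TestPrimeDesign:
    def test_x_region_content_k2(self):
        seq, rmap = build_switch_lock_prime(DesignParams(2, 2, 2, "four_letter_prime"))
        x1 = rmap["x1"]
        assert seq.symbols[x1.start:x1.end] == "CAC"

    def test_length_formula(self):
        params = DesignParams(2, 2, 2, "four_letter_prime")
        assert params.length == 52
        seq, _ = build_switch_lock_prime(params)
        assert len(seq) == 52

    @pytest.mark.parametrize("k,A,B", [(2, 2, 2), (2, 4, 2), (4, 4, 4), (6, 2, 2)])
    def test_region_widths(self, k, A, B):
        _, rmap = build_switch_lock_prime(DesignParams(k, A, B, "four_letter_prime"))
        assert rmap["l1"].width == 2 * k + 1 == rmap["r1"].width
        for kind in "xypq":
            assert rmap[f"{kind}1"].width == k + 1
        assert rmap["L1"].width == k  # the switch is not widened

    def test_odd_k_rejected(self):
        with pytest.raises(ParameterError):
            DesignParams(3, 2, 2, "four_letter_prime")


class TestDesignedStructures:
    def test_tiny_initial_arcs(self, tiny_design):
        params, _, _ = tiny_design
        init = initial_structure(params)
        # L1·R2 in the switch; l1·r1 and l2·r2 bands in the lock
        assert init.arc_set() == {(0, 2), (6, 17), (7, 16), (9, 14), (10, 13)}
        assert init.arc_count() == (params.A - 1) * params.k + 2 * params.k * params.B

    @pytest.mark.parametrize("k,A,B,alphabet", [
        (k, A, B, alphabet)
        for alphabet in ("eight_letter", "four_letter_prime")
        for k, A, B in SMALL_GRID
        if alphabet == "eight_letter" or k % 2 == 0  # prime design: even k
    ])
    def test_structures_validate_on_grid(self, k, A, B, alphabet):
        params = DesignParams(k, A, B, alphabet)
        seq, rmap = region_map_of(params)
        for s in (initial_structure(params), target_structure(params)):
            assert validate(s, seq) == []
            # every arc joins complementary regions
            for i, j in s.arcs:
                assert complementary(rmap.region_at(i).symbol,
                                     rmap.region_at(j).symbol, "eight")

    @pytest.mark.parametrize("k,A,B", SMALL_GRID)
    def test_initial_and_target_share_no_switch_arcs(self, k, A, B):
        params = DesignParams(k, A, B)
        init, tgt = initial_structure(params), target_structure(params)
        n_switch = 2 * k * A
        left = {a for a in init.arcs if a[1] < n_switch}
        right = {a for a in tgt.arcs if a[1] < n_switch}
        assert left and right and not left & right

    def test_equal_arc_counts(self):
        params = DesignParams(2, 4, 4)
        assert initial_structure(params).arc_count() == \
            target_structure(params).arc_count()

    def test_prime_band_arc_counts(self):
        params = DesignParams(2, 2, 2, "four_letter_prime")
        init, tgt = initial_structure(params), target_structure(params)
        k, A, B = params.k, params.A, params.B
        assert init.arc_count() == (A - 1) * k + (2 * k + 1) * B
        assert tgt.arc_count() == (A - 1) * k + 2 * (k + 1) * B


class TestFasta:
    def test_round_trip_eight_letter(self, tmp_path, tiny_design):
        _, seq, _ = tiny_design
        path = tmp_path / "seq.fa"
        write_fasta(path, seq)
        back = read_fasta(path)
        assert back.symbols == seq.symbols and back.alphabet == "eight"
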