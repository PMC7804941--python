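"""Motif notation parsing and sequence scanning."""

import pytest
from hypothesis import given, settings, strategies as st

from degradome.motifs import (
    GapBounds,
    MotifParseError,
    clean_sequence,
    match_architecture,
    parse_architecture,
    parse_motif,
    scan,
)

from .conftest import random_protein
from .oracle import brute_force_scan

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestParsing:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("HEXXH", ["H", "E", "*", "*", "H"]),
            ("GXSXX(T/S/G)", ["G", "*", "S", "*", "*", "GST"]),
            ("A", ["A"]),
            ("NEXXT/A", ["N", "E", "*", "*", "AT"]),
            ("P/GXXD", ["GP", "*", "*", "D"]),
            ("H(Q/E)XXHXXGXXH/D", ["H", "EQ", "*", "*", "H", "*", "*", "G",
                                   "*", "*", "DH"]),
        ],
    )
    def test_residue_patterns(self, text, expected):
        pat = parse_motif(text)
        got = [
            "*" if e.is_wildcard else "".join(sorted(e.residues))
            for e in pat.elements
        ]
        assert got == expected

    @pytest.mark.parametrize(
        "text, gaps",
        [
            ("HXXGHXXGX_3-8_H", [(3, 8)]),
            ("HXXEHX_76_EXXV/H", [(76, 76)]),
            ("EX_nHXHX_10D", [(1, 100), (10, 10)]),
            ("HGX_39_TC", [(39, 39)]),
        ],
    )
    def test_gap_bounds(self, text, gaps):
        pat = parse_motif(text)
        got = [(e.min_gap, e.max_gap) for e in pat.elements if e.kind == "gap"]
        assert got == gaps

    def test_xn_bound_is_configurable(self):
        pat = parse_motif("EX_nH", xn_max=7)
        gap = [e for e in pat.elements if e.kind == "gap"][0]
        assert (gap.min_gap, gap.max_gap) == (1, 7)

    @pytest.mark.parametrize("bad", ["", "X_8-3_H", "H(Q/)H", "h+j", "(/)"])
    def test_malformed_input_raises(self, bad):
        with pytest.raises(MotifParseError):
            parse_motif(bad)

    def test_ideographic_comma_is_component_separator(self):
        comps = parse_architecture("D(D/T)G、GXSXX(T/S/G)")
        assert [c.source_text for c in comps] == ["D(D/T)G", "GXSXX(T/S/G)"]

    @pytest.mark.parametrize(
        "text",
        ["HEXXH", "GXSXX(T/S/G)", "HXXGHXXGX_3-8_H", "NEXXT/A",
         "(S/G/A)HXDXV", "EX_nHXHX_10D", "EE"],
    )
    def test_render_round_trip_is_idempotent(self, text):
        pat = parse_motif(text)
        once = pat.render()
        assert parse_motif(once).render() == once


class TestScan:
    def test_simple_match_coordinates(self):
        hits = scan("MHEAAHK", parse_motif("HEXXH"))
        assert [(m.start, m.end, m.matched_text) for m in hits] == [
            (2, 6, "HEAAH")
        ]

    def test_truncated_motif_is_no_match(self):
        assert scan("MHEAH", parse_motif("HEXXH")) == []

    def test_empty_sequence_gives_empty_list(self):
        assert scan("", parse_motif("HEXXH")) == []

    def test_nonstandard_codes_match_only_wildcards(self):
        # B at a fixed position blocks the match ...
        assert scan("HBAAH", parse_motif("HEXXH")) == []
        # ... but B at a wildcard position is tolerated
        hits = scan("HEBBH", parse_motif("HEXXH"))
        assert [(m.start, m.end) for m in hits] == [(1, 5)]

    def test_gap_and_stop_symbols_are_stripped_with_warning(self):
        with pytest.warns(UserWarning):
            assert clean_sequence("he-xx*h") == "HEXXH"

    def test_case_is_normalized(self):
        assert [m.matched_text for m in scan("mheaahk", parse_motif("HEXXH"))] \
            == ["HEAAH"]

    def test_overlapping_starts_are_all_reported(self):
        hits = scan("HHHH", parse_motif("HH"))
        assert [(m.start, m.end) for m in hits] == [(1, 2), (2, 3), (3, 4)]

    def test_gapped_match_prefers_shortest_gap(self):
        # gap 1-3 before the final H: the 1-gap assignment must win
        hits = scan("AHX_1-3_H".replace("A", "") and "HAHAH",
                    parse_motif("HX_1-3_H"))
        assert (hits[0].start, hits[0].end) == (1, 3)

    def test_matches_equal_brute_force_on_random_sequences(self, rng):
        patterns = [
            parse_motif(t)
            for t in ("HEXXH", "GXSXX(T/S/G)", "HXXGHXXGX_3-8_H", "DTG",
                      "NEXXT/A", "HGX_5-9_TC", "D(D/T)G")
        ]
        for _ in range(40):
            seq = random_protein(rng, int(rng.integers(30, 300)))
            for pat in patterns:
                got = [(m.start, m.end, m.matched_text)
                       for m in scan(seq, pat)]
                assert got == brute_force_scan(seq, pat), pat.source_text

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet=AA, min_size=0, max_size=120),
        lo=st.integers(0, 4),
        extra=st.integers(0, 5),
    )
    def test_gapped_scan_matches_oracle_property(self, seq, lo, extra):
        pat = parse_motif(f"HX_{lo}-{lo + extra}_G")
        got = [(m.start, m.end, m.matched_text) for m in scan(seq, pat)]
        assert got == brute_force_scan(seq, pat)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet=AA, min_size=5, max_size=100),
        lo=st.integers(0, 3),
        hi1=st.integers(0, 4),
        widen=st.integers(0, 4),
    )
    def test_widening_gap_never_loses_match_starts(self, seq, lo, hi1, widen):
        narrow = parse_motif(f"HX_{lo}-{lo + hi1}_G")
        wide = parse_motif(f"HX_{lo}-{lo + hi1 + widen}_G")
        starts_narrow = {m.start for m in scan(seq, narrow)}
        starts_wide = {m.start for m in scan(seq, wide)}
        assert starts_narrow <= starts_wide

    def test_determinism(self, rng):
        seq = random_protein(rng, 200)
        pat = parse_motif("HXXGHXXGX_3-8_H")
        assert scan(seq, pat) == scan(seq, pat)


class TestArchitecture:
    def test_ordered_components_both_found(self):
        comps = parse_architecture("DTG + DSG")
        arch = match_architecture("AAADTGAAAAAAAAAADSGAAA", comps)
        assert arch.n_matched == 2
        coords = [(m.start, m.end) for _, m in arch.component_matches]
        assert coords == [(4, 6), (17, 19)]

    def test_order_is_never_relaxed(self):
        # reversed component order: only the first (DSG) can be placed, and
        # no DTG exists downstream of it
        comps = parse_architecture("DSG + DTG")
        arch = match_architecture("AAADTGAAAAAAAAAADSGAAA", comps)
        placed = [(i, (m.start, m.end) if m else None)
                  for i, m in arch.component_matches]
        assert placed == [(0, (17, 19)), (1, None)]
        assert arch.n_matched == 1

    def test_absent_component_recorded_not_raised(self):
        comps = parse_architecture("DTG + WWW")
        arch = match_architecture("AAADTGAAA", comps)
        assert arch.n_matched == 1
        assert arch.component_matches[1][1] is None

    def test_components_never_overlap(self):
        comps = parse_architecture("HH + HH")
        arch = match_architecture("AHHHHA", comps)
        spans = [(m.start, m.end) for _, m in arch.component_matches if m]
        assert spans == [(2, 3), (4, 5)]

    def test_min_inter_gap_enforced(self):
        comps = parse_architecture("HH + HH")
        arch = match_architecture("AHHHHA", comps, inter_gap=GapBounds(2, None))
        assert arch.n_matched == 1

    def test_needs_at_least_one_component(self):
        with pytest.raises(ValueError):
            match_architecture("AAAA", [])

    def test_catalytic_specificity_counts_catalytic_components_only(self):
        comps = parse_architecture("DTG + Y")
        arch = match_architecture(
            "AADTGAAYAA", comps, roles=["catalytic", "accessory"]
        )
        assert arch.n_catalytic_matched == 1
        assert arch.specificity == 4
        assert arch.catalytic_specificity == 3
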