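"""Match-pattern construction, profiling and the triplet geometry identity."""

import numpy as np
import pytest

from recascan.patterns import (
    AlignedPair,
    AlignmentError,
    AlphabetError,
    PatternSpecError,
    longest_match_run,
    make_pattern,
    panel_catalog,
    profile_from_pair,
    sequences_from_pattern,
    triplet_geometry,
)


class TestProfileFromPair:
    def test_identical_sequences_match_everywhere(self):
        seq = "ACGTACGTACGTACGTACGT"
        pat = profile_from_pair(AlignedPair("id", seq, seq))
        assert pat.matches == 20 and pat.mismatches == 0

    def test_transversion_at_every_position_gives_zero_matches(self):
        a = "ACGTACGTACGTACGTACGT"
        b = a.translate(str.maketrans("ACGT", "CAAC"))
        pat = profile_from_pair(AlignedPair("het", a, b))
        assert pat.matches == 0

    def test_case_and_uracil_insensitive(self):
        pat = profile_from_pair(AlignedPair("rna", "acgu", "ACGT"))
        assert pat.matches == 4

    def test_ambiguity_base_counts_as_mismatch(self):
        pat = profile_from_pair(AlignedPair("amb", "ANNT", "ANNT"))
        assert pat.mismatch_positions == (2, 3)

    def test_match_count_symmetric_in_sequence_order(self):
        a, b = "ACGTACGTAC", "AGGTACGAAC"
        fwd = profile_from_pair(AlignedPair("f", a, b))
        rev = profile_from_pair(AlignedPair("r", b, a))
        assert fwd.matches == rev.matches

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            AlignedPair("bad", "ACGT", "ACG")

    def test_gap_and_invalid_characters_rejected(self):
        with pytest.raises(AlphabetError):
            AlignedPair("gap", "AC-T", "ACGT")

    def test_five_match_background_pair(self, catalog):
        # a synthetic realization of the 5/20 distributed-match pattern
        pair = sequences_from_pattern(catalog["pcDNA3"], seed=11)
        assert profile_from_pair(pair).matches == 5

    def test_sequences_from_pattern_round_trips_any_catalog_entry(self, catalog):
        for name, pat in catalog.items():
            back = profile_from_pair(sequences_from_pattern(pat, seed=1))
            assert np.array_equal(back.is_match, pat.is_match), name


class TestLongestMatchRun:
    @pytest.mark.parametrize(
        "name, expected_m",
        [
            ("tr 3'", 17),
            ("tr 5'", 17),
            ("tr c3'", 14),
            ("tr c5'", 14),
            ("tr m", 9),
            ("3i", 5),
            ("1+2", 10),
            ("2+1", 8),
            ("hom", 20),
            ("het", 0),
        ],
    )
    def test_panel_longest_runs(self, catalog, name, expected_m):
        assert longest_match_run(catalog[name]) == expected_m


class TestTripletGeometry:
    def test_terminal_triplet_has_k2_m17(self, catalog):
        geom = triplet_geometry(catalog["tr 5'"])
        assert (geom.center, geom.k, geom.m) == (2, 2, 17)

    def test_central_triplet_has_k10_m9(self, catalog):
        geom = triplet_geometry(catalog["tr m"])
        assert (geom.center, geom.k, geom.m) == (11, 10, 9)

    def test_triplet_centered_at_5_has_m14(self, catalog):
        geom = triplet_geometry(catalog["tr c5'"])
        assert (geom.center, geom.k, geom.m) == (5, 5, 14)

    def test_m_equals_19_minus_k_for_every_center(self):
        # exhaustive over all 18 admissible centers of a 20-mer
        for center in range(2, 20):
            pat = make_pattern("tr", 20, triplet_center=center)
            geom = triplet_geometry(pat)
            assert geom.m == 19 - geom.k == longest_match_run(pat)

    def test_non_triplet_pattern_rejected(self, catalog):
        with pytest.raises(PatternSpecError):
            triplet_geometry(catalog["3i"])


class TestMakePattern:
    def test_triplet_center_places_three_mismatches(self):
        pat = make_pattern("t", 20, triplet_center=11)
        assert pat.mismatch_positions == (10, 11, 12)

    def test_explicit_mismatch_list(self):
        pat = make_pattern("e", 20, mismatch_positions={3, 9, 14, 17})
        assert pat.matches == 16

    def test_random_pattern_is_seed_reproducible(self):
        a = make_pattern("r", 20, random_matches=5, seed=42)
        b = make_pattern("r", 20, random_matches=5, seed=42)
        assert a == b and a.matches == 5

    def test_out_of_range_positions_rejected(self):
        with pytest.raises(PatternSpecError):
            make_pattern("bad", 20, mismatch_positions=[0, 5])
        with pytest.raises(PatternSpecError):
            make_pattern("bad", 20, mismatch_positions=[5, 21])

    def test_conflicting_specs_rejected(self):
        with pytest.raises(PatternSpecError):
            make_pattern("bad", 20, triplet_center=5, all_match=True)


class TestPanelCatalog:
    def test_match_totals_honor_name_claims(self, catalog):
        expected = {
            "hom": 20,
            "het": 0,
            "mis4": 16,
            "mis5 3'": 15,
            "mis5 5'": 15,
            "mis6a": 14,
            "mis6b": 14,
            "12/20": 12,
            "10/20": 10,
            "5/20": 5,
            "pcDNA3": 5,
        }
        for name, total in expected.items():
            assert catalog[name].matches == total, name
        for name in ("tr 3'", "tr 5'", "tr m", "tr c3'", "tr c5'", "3i", "1+2", "2+1"):
            assert catalog[name].matches == 17, name

    def test_3i_mismatches_isolated_and_evenly_spaced(self, catalog):
        assert catalog["3i"].mismatch_positions == (6, 12, 18)

    def test_every_pattern_is_20nt(self, catalog):
        assert all(pat.n == 20 for pat in catalog.values())

    def test_overrides_replace_default_positions(self):
        panel = panel_catalog({"mis4": [1, 2, 3, 4]})
        assert panel["mis4"].mismatch_positions == (1, 2, 3, 4)
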