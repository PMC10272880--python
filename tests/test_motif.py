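"""Degenerate consensus scoring, rendering, scanning, and discovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulonmap import (
    LLDR_BOX,
    ValidationError,
    discover_consensus,
    information_content,
    is_palindromic,
    parse_consensus,
    pfm_from_sites,
    render_match,
    revcomp,
    scan_region,
    score_match,
)
from regulonmap.motif import _BASES
from regulonmap.reference_sites import REFERENCE_SITES
from regulonmap.synthetic import simulate_dataset

seventeen_mers = st.text(alphabet="ACGT", min_size=17, max_size=17)


class TestParseConsensus:
    def test_lldr_box_dimensions(self, lldr_box):
        assert lldr_box.width == 17
        assert lldr_box.informative_count == 14
        assert lldr_box.informative_positions == tuple(
            i for i in range(17) if i not in (2, 8, 14)
        )

    def test_all_n_pattern_has_no_informative_positions(self):
        assert parse_consensus("nnnn").informative_count == 0

    def test_illegal_character_reported_with_position(self):
        with pytest.raises(ValidationError, match="position 3"):
            parse_consensus("AAxT")

    def test_case_and_N_normalisation(self):
        assert parse_consensus("aAntGgN").pattern == "AAnTGGn"


class TestPalindromy:
    def test_lldr_box_is_palindromic(self, lldr_box):
        assert is_palindromic(lldr_box)

    def test_homopolymer_is_not(self):
        assert not is_palindromic(parse_consensus("AAAA"))

    def test_self_reverse_complement_is(self):
        assert is_palindromic(parse_consensus("ACGT"))


class TestScoreAndRender:
    # catalogued box sequences with their published conservation scores
    @pytest.mark.parametrize(
        "seq,expected",
        [("AGGAGGTCTGACCACTT", 12), ("CTTTCGCCAGACCAAAG", 8),
         ("TTTTGGTCCTACCAAAT", 10), ("CACTGGTCTGATTTCTA", 9)],
    )
    def test_catalogued_scores(self, lldr_box, seq, expected):
        assert score_match(seq, lldr_box) == (expected, 14)

    def test_pattern_own_string_scores_full(self, lldr_box):
        assert score_match(lldr_box.pattern.replace("n", "A"), lldr_box) == (14, 14)

    def test_length_mismatch_rejected(self, lldr_box):
        with pytest.raises(ValidationError):
            score_match("ACGT", lldr_box)

    @pytest.mark.parametrize(
        "seq,rendered",
        [("TTTTGGTCCTACCAAAT", "tttTGGTCctACCAaaT"),
         ("CACTGGTCTGATTTCTA", "cAcTGGTCtGAtttcTa")],
    )
    def test_catalogued_renderings(self, lldr_box, seq, rendered):
        assert render_match(seq, lldr_box) == rendered

    def test_all_mismatch_renders_lowercase(self, lldr_box):
        seq = "".join("C" if c in ("A", "n") else "A" for c in lldr_box.pattern)
        assert render_match(seq, lldr_box) == seq.lower()

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(seq=seventeen_mers)
    def test_uppercase_count_equals_score(self, lldr_box, seq):
        rendered = render_match(seq, lldr_box)
        assert sum(c.isupper() for c in rendered) == score_match(seq, lldr_box)[0]

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(seq=seventeen_mers)
    def test_palindromic_score_invariant_under_revcomp(self, lldr_box, seq):
        assert score_match(seq, lldr_box) == score_match(revcomp(seq), lldr_box)


class TestScanRegion:
    def test_single_perfect_box_found_at_its_offset(self, lldr_box):
        rng = np.random.default_rng(0)
        bg = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120)])
        box = "AAATGGTCAGACCAATT"
        region = bg[:40] + box + bg[40:]
        top = scan_region(region, lldr_box, top_k=1)[0]
        assert (top.offset, top.score) == (40, 14)

    def test_two_planted_boxes_ranked_by_score(self, lldr_box):
        rng = np.random.default_rng(1)
        bg = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
        perfect = "AAATGGTCAGACCAATT"
        two_off = "AACTTGTCAGACCACAT"  # mismatches at informative positions 5 and 16
        assert score_match(two_off, lldr_box)[0] == 12
        region = bg[:20] + perfect + bg[20:53] + two_off + bg[53:]
        matches = scan_region(region, lldr_box, top_k=2)
        assert [(m.offset, m.score) for m in matches] == [(20, 14), (70, 12)]

    def test_reverse_complement_region_gives_same_scores(self, lldr_box):
        rng = np.random.default_rng(2)
        region = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        fwd = sorted(m.score for m in scan_region(region, lldr_box, top_k=3))
        rev = sorted(m.score for m in scan_region(revcomp(region), lldr_box, top_k=3))
        assert fwd == rev

    def test_short_region_rejected(self, lldr_box):
        with pytest.raises(ValidationError):
            scan_region("ACGT", lldr_box)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(region=st.text(alphabet="ACGT", min_size=17, max_size=200))
    def test_rank_one_equals_brute_force_argmax(self, lldr_box, region):
        top = scan_region(region, lldr_box, top_k=1)[0]
        best = max(
            max(score_match(region[o : o + 17], lldr_box)[0],
                score_match(revcomp(region[o : o + 17]), lldr_box)[0])
            for o in range(len(region) - 16)
        )
        assert top.score == best


class TestInformationContent:
    def test_fully_conserved_column_is_two_bits(self):
        pfm = pfm_from_sites(["A", "A", "A", "A"])
        assert information_content(pfm)[0] == pytest.approx(2.0)

    def test_uniform_column_is_zero_bits(self):
        pfm = pfm_from_sites(["A", "C", "G", "T"])
        assert information_content(pfm)[0] == pytest.approx(0.0)

    def test_mixed_column_matches_closed_form(self):
        pfm = pfm_from_sites(["A"] * 12 + ["G"] * 4)
        expected = 2 + 0.75 * np.log2(0.75) + 0.25 * np.log2(0.25)
        assert information_content(pfm)[0] == pytest.approx(expected)

    def test_empty_pfm_rejected(self):
        with pytest.raises(ValidationError):
            pfm_from_sites([])


class TestDiscoverConsensus:
    def test_pure_repeats_of_a_perfect_box_converge(self, lldr_box):
        box = "AAATGGTCAGACCAATT"
        regions = [box * 3] * 4
        found, pfm = discover_consensus(regions, width=17)
        assert found.pattern == box
        assert pfm.n_sites == 4

    def test_fewer_than_two_regions_rejected(self):
        with pytest.raises(ValidationError):
            discover_consensus(["A" * 40], width=17)

    def test_modal_bases_of_catalogued_boxes_match_lldr_box(self, lldr_box):
        # majority-count oracle over the 16 catalogued site sequences
        seqs = [b.sequence for s in REFERENCE_SITES for b in s.boxes]
        pfm = pfm_from_sites(seqs)
        modal = "".join(_BASES[int(np.argmax(row))] for row in pfm.counts)
        for i in lldr_box.informative_positions:
            assert modal[i] == lldr_box.pattern[i]

    def test_recovers_planted_box_from_synthetic_regions(self, lldr_box):
        genome, truth, _ = simulate_dataset(seed=33, n_sites=8, mismatches=2,
                                            amplitude=10.0)
        regions = [genome.subsequence(s.position - 250, s.position + 250)
                   for s in truth.sites]
        found, pfm = discover_consensus(regions, width=17, palindromic=True,
                                        seed=33)
        for i in lldr_box.informative_positions:
            assert found.pattern[i] == lldr_box.pattern[i]
        # the recovered PFM is strongly informative at informative positions
        bits = information_content(pfm)
        assert np.mean([bits[i] for i in lldr_box.informative_positions]) > 1.0
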