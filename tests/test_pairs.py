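"""Adjacent-pair calling: distance formula, spacing window, summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fbescan.motifs import ElementMatch, scan_sequence
from fbescan.pairs import find_adjacent_pairs, pair_distance, summarize_pairs
from fbescan.records import PeakRecord


def _match(peak="p", cls="FBE_canonical", start=0, length=9):
    return ElementMatch(peak, cls, start, length, "N" * length)


class TestPairDistance:
    def test_gld1_core_elements(self, gld1_rna):
        e5, e3 = scan_sequence(gld1_rna, peak_id="gld1")
        assert (e5.start, e3.start) == (4, 18)
        assert pair_distance(e5, e3) == 5

    def test_gld1_extended_elements_three_nt_apart(self, gld1_rna):
        # the full elements with their upstream-C context are 3 nt apart
        a = gld1_rna.find("CAUGUGCCAUA")
        b = gld1_rna.find("CAUGUUGCCAUU")
        e5 = ElementMatch("gld1", "FBEa_ext", a, 11, gld1_rna[a : a + 11])
        e3 = ElementMatch("gld1", "FBEastar_ext", b, 12, gld1_rna[b : b + 12])
        assert (a, b) == (2, 16)
        assert pair_distance(e5, e3) == 3

    def test_minimal_gap(self):
        e5 = _match(start=0, length=9)
        e3 = _match(start=10)
        assert pair_distance(e5, e3) == 1

    def test_cross_peak_rejected(self):
        with pytest.raises(ValueError, match="different peaks"):
            pair_distance(_match(peak="a"), _match(peak="b", start=15))


class TestFindAdjacentPairs:
    def test_gld1_yields_one_pair(self, gld1_rna):
        pairs = find_adjacent_pairs(scan_sequence(gld1_rna, peak_id="gld1"))
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.element_5p.fbe_class, p.element_3p.fbe_class) == (
            "FBE_canonical",
            "FBEastar_B",
        )
        assert p.distance == 5

    def test_window_excludes_distant_canonicals(self):
        ms = [_match(start=0), _match(start=9 + 25)]  # 25 nt apart
        assert find_adjacent_pairs(ms) == []

    def test_no_canonical_no_pair(self):
        ms = [
            _match(cls="FBEastar_A", start=0, length=9),
            _match(cls="FBEastar_B", start=14, length=10),
        ]
        assert find_adjacent_pairs(ms) == []

    def test_two_canonicals_may_pair(self):
        ms = [_match(start=0), _match(start=12)]
        pairs = find_adjacent_pairs(ms)
        assert len(pairs) == 1 and pairs[0].distance == 3
        assert pairs[0].second_class == "FBE_canonical"

    def test_anchor_may_be_three_prime(self):
        ms = [_match(cls="cFBE", start=0, length=8), _match(start=11)]
        pairs = find_adjacent_pairs(ms)
        assert len(pairs) == 1
        assert pairs[0].element_3p.fbe_class == "FBE_canonical"
        assert pairs[0].second_class == "cFBE"

    def test_shared_start_deduplicated_keeping_canonical_anchor(self):
        # two classes match at start 0; only one pair per (start_5p, start_3p)
        ms = [
            _match(cls="FBEastar_A", start=0, length=9),
            _match(cls="FBE_canonical", start=0, length=9),
            _match(cls="cFBE", start=14, length=8),
        ]
        pairs = find_adjacent_pairs(ms)
        assert len(pairs) == 1
        assert pairs[0].element_5p.fbe_class == "FBE_canonical"

    def test_empty_input(self):
        assert find_adjacent_pairs([]) == []

    @given(
        starts=st.lists(st.integers(0, 150), min_size=0, max_size=8, unique=True),
        classes=st.lists(
            st.sampled_from(["FBE_canonical", "cFBE", "FBEastar_A", "FBEastar_B"]),
            min_size=8,
            max_size=8,
        ),
    )
    @settings(max_examples=200)
    def test_returned_pairs_respect_all_rules(self, starts, classes):
        lengths = {"FBE_canonical": 9, "cFBE": 8, "FBEastar_A": 9, "FBEastar_B": 10}
        ms = [
            _match(cls=c, start=s, length=lengths[c])
            for s, c in zip(starts, classes)
        ]
        pairs = find_adjacent_pairs(ms)
        seen = set()
        for p in pairs:
            assert p.element_5p.start < p.element_3p.start
            assert p.distance == p.element_3p.start - p.element_5p.start - p.element_5p.length
            assert 1 <= p.distance <= 20
            assert "FBE_canonical" in (p.element_5p.fbe_class, p.element_3p.fbe_class)
            key = (p.peak_id, p.element_5p.start, p.element_3p.start)
            assert key not in seen  # each unordered pair reported once
            seen.add(key)

    def test_order_invariance(self, rng):
        lengths = {"FBE_canonical": 9, "cFBE": 8, "FBEastar_A": 9, "FBEastar_B": 10}
        names = list(lengths)
        ms = [
            _match(
                peak=f"p{int(rng.integers(3))}",
                cls=(c := names[int(rng.integers(4))]),
                start=int(rng.integers(0, 120)),
                length=lengths[c],
            )
            for _ in range(30)
        ]
        a = find_adjacent_pairs(ms)
        b = find_adjacent_pairs(list(reversed(ms)))
        assert a == b


class TestSummarize:
    def _peaks(self):
        return [
            PeakRecord("A", gene_id="g1", region="3'UTR"),
            PeakRecord("B", gene_id="g1", region="3'UTR"),
            PeakRecord("C", gene_id="g2", region="5'UTR"),
        ]

    def _pair(self, peak, s5=0, s3=12):
        e5 = _match(peak=peak, start=s5)
        e3 = _match(peak=peak, cls="cFBE", start=s3, length=8)
        return find_adjacent_pairs([e5, e3])[0]

    def test_peak_level_dedup(self):
        pairs = [self._pair("A"), self._pair("A", s5=30, s3=42), self._pair("B")]
        s = summarize_pairs(self._peaks(), pairs)
        assert s.n_peaks_with_pairs == 2

    def test_gene_dedup(self):
        s = summarize_pairs(self._peaks(), [self._pair("A"), self._pair("B")])
        assert s.n_unique_genes == 1
        assert s.region_breakdown == {"3'UTR": 2}
        assert s.class_breakdown == {"cFBE": 2}

    def test_unknown_peak_rejected(self):
        with pytest.raises(KeyError):
            summarize_pairs(self._peaks(), [self._pair("Z")])
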