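"""Adjacent FBE pair calling within CLIP peaks.

Two elements in the same peak form an adjacent pair when the gap between
them, defined as

    distance = start(3'-most) - start(5'-most) - length(5'-most)

(i.e. the number of bases strictly between the motifs), lies within a
configurable window (default 1-20 nt) and at least one member is a canonical
FBE.  The canonical anchor may sit on either side of the second element.
Headline counts are per peak, deduplicated by peak id, with unique genes
counted over peaks carrying at least one pair.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from fbescan.motifs import CANONICAL, ElementMatch
from fbescan.records import PeakRecord

__all__ = [
    "AdjacentPair",
    "PairSummary",
    "pair_distance",
    "find_adjacent_pairs",
    "summarize_pairs",
]


@dataclass(frozen=True)
class AdjacentPair:
    """An ordered (5' then 3') pair of FBE matches within one peak."""

    peak_id: str
    element_5p: ElementMatch
    element_3p: ElementMatch
    distance: int

    @property
    def second_class(self) -> str:
        """Class of the non-anchor element (canonical if both are canonical)."""
        if self.element_5p.fbe_class == CANONICAL:
            return self.element_3p.fbe_class
        return self.element_5p.fbe_class


@dataclass(frozen=True)
class PairSummary:
    n_peaks_with_pairs: int
    n_unique_genes: int
    region_breakdown: dict[str, int]
    class_breakdown: dict[str, int]


def pair_distance(e5: ElementMatch, e3: ElementMatch) -> int:
    """Number of bases between two element matches from the same peak.

    May be zero or negative for abutting or overlapping matches; callers
    filter on the spacing window.
    """
    if e5.peak_id != e3.peak_id:
        raise ValueError(
            f"matches from different peaks: {e5.peak_id!r} vs {e3.peak_id!r}"
        )
    if e5.start >= e3.start:
        raise ValueError("element_5p must start strictly before element_3p")
    return e3.start - e5.start - e5.length


def _anchor_rank(e5: ElementMatch, e3: ElementMatch) -> tuple:
    # prefer a canonical 5' anchor, then a canonical 3' anchor, then stable
    # alphabetical class order so deduplication is deterministic
    return (
        e5.fbe_class != CANONICAL,
        e3.fbe_class != CANONICAL,
        e5.fbe_class,
        e3.fbe_class,
    )


def find_adjacent_pairs(
    matches: Iterable[ElementMatch],
    min_gap: int = 1,
    max_gap: int = 20,
) -> list[AdjacentPair]:
    """Call adjacent FBE pairs from scanner output.

    Every pair of matches within one peak whose spacing satisfies
    ``min_gap <= distance <= max_gap`` and that includes at least one
    canonical FBE is returned.  Two canonical elements may pair with each
    other.  When the same start position matches several classes, one pair is
    reported per (peak, start_5p, start_3p), keeping the class combination
    with a canonical anchor (5'-anchored preferred).  Output order is
    (peak_id, start_5p, start_3p).
    """
    if not (1 <= min_gap <= max_gap):
        raise ValueError(f"require 1 <= min_gap <= max_gap, got ({min_gap}, {max_gap})")

    by_peak: dict[str, list[ElementMatch]] = defaultdict(list)
    for m in matches:
        by_peak[m.peak_id].append(m)

    pairs: list[AdjacentPair] = []
    for peak_id in sorted(by_peak):
        ms = sorted(by_peak[peak_id], key=lambda m: (m.start, m.fbe_class))
        best: dict[tuple[int, int], AdjacentPair] = {}
        for i, e5 in enumerate(ms):
            for e3 in ms[i + 1 :]:
                if e3.start <= e5.start:
                    continue
                if e5.fbe_class != CANONICAL and e3.fbe_class != CANONICAL:
                    continue
                d = pair_distance(e5, e3)
                if not (min_gap <= d <= max_gap):
                    continue
                key = (e5.start, e3.start)
                cand = AdjacentPair(peak_id, e5, e3, d)
                prev = best.get(key)
                if prev is None or _anchor_rank(e5, e3) < _anchor_rank(
                    prev.element_5p, prev.element_3p
                ):
                    best[key] = cand
        pairs.extend(best[k] for k in sorted(best))
    return pairs


def summarize_pairs(
    peaks: Sequence[PeakRecord] | Mapping[str, PeakRecord],
    pairs: Sequence[AdjacentPair],
) -> PairSummary:
    """Peak-level summary of adjacent-pair calls.

    Each peak is counted at most once no matter how many pairs it contains;
    unique genes are counted over the peaks with at least one pair; the
    region breakdown uses peak metadata; the class breakdown counts the
    second (non-anchor) element class once per pair.
    """
    if isinstance(peaks, Mapping):
        by_id = dict(peaks)
    else:
        by_id = {p.peak_id: p for p in peaks}

    unknown = sorted({p.peak_id for p in pairs} - set(by_id))
    if unknown:
        raise KeyError(f"pairs reference unknown peaks: {unknown}")

    peak_ids = sorted({p.peak_id for p in pairs})
    genes = {by_id[pid].gene_id for pid in peak_ids}
    regions = Counter(by_id[pid].region for pid in peak_ids)
    classes = Counter(p.second_class for p in pairs)
    return PairSummary(
        n_peaks_with_pairs=len(peak_ids),
        n_unique_genes=len(genes),
        region_breakdown=dict(regions),
        class_breakdown=dict(classes),
    )
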