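"""Degenerate FBE patterns and exact-match scanning of RNA sequences.

FBF binding elements come in four flavors, all anchored by a 5' UGU
trinucleotide:

========================  ============  ======
class                     pattern       length
========================  ============  ======
``FBE_canonical``         ``UGURnnAUn``   9 nt
``cFBE`` (compact)        ``UGURnAUn``    8 nt
``FBEastar_A``            ``UGUYRnAUn``   9 nt
``FBEastar_B``            ``UGUnRnnAUn`` 10 nt
========================  ============  ======

where R = A/G (purine), Y = C/U (pyrimidine) and n = any nucleotide.  The
two FBEa*-like patterns describe non-canonical elements in which the base
after the UGU is flipped away from the protein's RNA-binding surface.
Matching is exact (no mismatches) on the sense strand; all classes are
scanned independently and overlapping matches are all reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "IUPAC_SETS",
    "FBEClass",
    "FBE_CLASSES",
    "ElementMatch",
    "MalformedSequenceError",
    "normalize_sequence",
    "scan_sequence",
]

#: Expansion of the degenerate alphabet used in FBE patterns.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "n": frozenset("ACGU"),
}


class MalformedSequenceError(ValueError):
    """Raised when a nucleotide sequence contains a non-ACGTU symbol."""


@dataclass(frozen=True)
class FBEClass:
    """One degenerate FBE pattern.

    Attributes
    ----------
    name:
        Class identifier (e.g. ``"FBE_canonical"``).
    pattern:
        Pattern string over ``{U, G, A, C, R, Y, n}``.
    """

    name: str
    pattern: str

    def __post_init__(self) -> None:
        bad = set(self.pattern) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"pattern {self.pattern!r} uses unknown symbols {sorted(bad)}")
        if not self.pattern.startswith("UGU"):
            raise ValueError(f"FBE patterns start with UGU, got {self.pattern!r}")

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def position_sets(self) -> tuple[frozenset[str], ...]:
        return tuple(IUPAC_SETS[c] for c in self.pattern)

    def matches(self, window: str) -> bool:
        """Exact character-class match of ``window`` against this pattern."""
        if len(window) != self.length:
            return False
        return all(base in allowed for base, allowed in zip(window, self.position_sets))


#: The four FBE classes, keyed by name.
FBE_CLASSES: dict[str, FBEClass] = {
    c.name: c
    for c in (
        FBEClass("FBE_canonical", "UGURnnAUn"),
        FBEClass("cFBE", "UGURnAUn"),
        FBEClass("FBEastar_A", "UGUYRnAUn"),
        FBEClass("FBEastar_B", "UGUnRnnAUn"),
    )
}

CANONICAL = "FBE_canonical"


@dataclass(frozen=True)
class ElementMatch:
    """One FBE hit inside a peak sequence.

    ``start`` is a 0-based offset; written reports convert to 1-based
    inclusive coordinates.  ``matched`` is the matching slice of the peak
    sequence, i.e. ``seq[start:start + length]``.
    """

    peak_id: str
    fbe_class: str
    start: int
    length: int
    matched: str


_VALID = set("ACGTU")


def normalize_sequence(raw: str) -> str:
    """Uppercase ``raw`` and map T to U, validating the alphabet.

    DNA-alphabet input (as found in FASTA exports of peak sequences) is
    accepted unchanged in meaning; any symbol outside A/C/G/T/U raises
    :class:`MalformedSequenceError` naming the 0-based offending position.
    """
    up = raw.upper()
    for i, ch in enumerate(up):
        if ch not in _VALID:
            raise MalformedSequenceError(
                f"invalid nucleotide {raw[i]!r} at position {i}: expected A/C/G/T/U"
            )
    return up.replace("T", "U")


def scan_sequence(
    seq: str,
    classes: Iterable[FBEClass] | None = None,
    peak_id: str = "",
) -> list[ElementMatch]:
    """Report every exact FBE match in a normalized RNA sequence.

    Each class is scanned independently at every start position; overlapping
    matches, and multiple classes matching at the same start, are all
    reported.  Output is sorted by (start, class name) and is deterministic.
    A sequence shorter than a pattern simply yields no matches for that
    class.

    Parameters
    ----------
    seq:
        RNA sequence (uppercase ACGU, see :func:`normalize_sequence`).
    classes:
        FBE classes to scan; defaults to all four.
    peak_id:
        Identifier stamped on each match.
    """
    if classes is None:
        classes = FBE_CLASSES.values()
    classes = list(classes)
    if not classes:
        raise ValueError("classes must be non-empty")

    hits: list[ElementMatch] = []
    n = len(seq)
    for cls in classes:
        L = cls.length
        sets = cls.position_sets
        for start in range(n - L + 1):
            window = seq[start : start + L]
            if all(b in allowed for b, allowed in zip(window, sets)):
                hits.append(ElementMatch(peak_id, cls.name, start, L, window))
    hits.sort(key=lambda m: (m.start, m.fbe_class))
    return hits


def scan_many(
    sequences: dict[str, str] | Sequence[tuple[str, str]],
    classes: Iterable[FBEClass] | None = None,
) -> list[ElementMatch]:
    """Scan a collection of (peak_id, sequence) pairs; concatenated output."""
    items = sequences.items() if isinstance(sequences, dict) else sequences
    out: list[ElementMatch] = []
    for peak_id, seq in items:
        out.extend(scan_sequence(seq, classes=classes, peak_id=peak_id))
    return out
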