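"""Shared fixtures and the independent brute-force motif oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

# The 29-nt gld-1 3'UTR fragment carrying the tandem FBEa and FBEa* sites,
# as used in the gel-shift and SEC-MALS experiments.
GLD1_TANDEM_RNA = "AUCAUGUGCCAUACAUCAUGUUGCCAUUU"

# Independent oracle: its own copy of the element definitions, expanded to
# per-position character sets, checked window by window.  Kept free of any
# import from fbescan.motifs internals so it cannot inherit a scanner bug.
_ORACLE_PATTERNS = {
    "FBE_canonical": "UGURnnAUn",
    "cFBE": "UGURnAUn",
    "FBEastar_A": "UGUYRnAUn",
    "FBEastar_B": "UGUnRnnAUn",
}
_ORACLE_SETS = {"R": "AG", "Y": "CU", "n": "ACGU", "A": "A", "C": "C", "G": "G", "U": "U"}


def oracle_scan(seq: str) -> set[tuple[str, int]]:
    """Every (class, 0-based start) whose window matches, by direct checking."""
    hits = set()
    for name, pattern in _ORACLE_PATTERNS.items():
        L = len(pattern)
        for start in range(len(seq) - L + 1):
            if all(seq[start + i] in _ORACLE_SETS[pattern[i]] for i in range(L)):
                hits.add((name, start))
    return hits


def oracle_rematch(fbe_class: str, matched: str) -> bool:
    pattern = _ORACLE_PATTERNS[fbe_class]
    return len(matched) == len(pattern) and all(
        b in _ORACLE_SETS[p] for b, p in zip(matched, pattern)
    )


@pytest.fixture
def gld1_rna() -> str:
    return GLD1_TANDEM_RNA


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
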