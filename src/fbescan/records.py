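"""Shared peak record container."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PeakRecord"]


@dataclass(frozen=True)
class PeakRecord:
    """One CLIP peak: sequence plus metadata.

    Heights are peak occupancies in FPKM (fragments per kilobase mapped) from
    eCLIP of wild-type FBF-2 and, optionally, of the partnership-defective
    Y479A variant.
    """

    peak_id: str
    gene_id: str = ""
    region: str = ""
    sequence: str = ""
    wt_height: float = 0.0
    y479a_height: float | None = None

    def __post_init__(self) -> None:
        if self.wt_height < 0:
            raise ValueError(f"peak {self.peak_id}: negative wt_height")
        if self.y479a_height is not None and self.y479a_height < 0:
            raise ValueError(f"peak {self.peak_id}: negative y479a_height")
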