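"""Amplicon geometry bookkeeping for Sanger confirmation design.

Given the genomic footprints of a gene-specific primer pair (with optional
universal-sequencing tails, e.g. 18-base M13 tails on the 5' ends), compute
the amplicon length and check that the nucleotide of interest is flanked.
Coordinates are 1-based inclusive positions on one assembly; no sequence
retrieval or thermodynamics — that is primer-design territory.
"""

from __future__ import annotations

from dataclasses import dataclass

# universal M13 sequencing tails commonly appended to gene-specific primers
M13_FORWARD_TAIL = "TGTAAAACGACGGCCAGT"
M13_REVERSE_TAIL = "CAGGAAACAGCTATGACC"


class PrimerDesignError(ValueError):
    """Geometrically invalid primer pair (e.g. overlapping footprints)."""


@dataclass(frozen=True)
class PrimerPair:
    """Genomic footprints of a primer pair, orientation-free.

    Each primer is given by its two 1-based end coordinates in either
    order (reverse primers are naturally written 5'→3' on the minus
    strand, i.e. descending). Tail lengths count non-genomic 5' bases.
    """

    forward: tuple[int, int]
    reverse: tuple[int, int]
    forward_tail: int = 0
    reverse_tail: int = 0

    def __post_init__(self) -> None:
        if self.forward_tail < 0 or self.reverse_tail < 0:
            raise ValueError("tail lengths must be non-negative")
        f_lo, f_hi = sorted(self.forward)
        r_lo, r_hi = sorted(self.reverse)
        if f_lo <= r_hi and r_lo <= f_hi:
            raise PrimerDesignError(
                f"primer footprints overlap: {self.forward} vs {self.reverse}"
            )

    def _spans(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """(left, right) primer spans as sorted (lo, hi) pairs."""
        f, r = sorted(self.forward), sorted(self.reverse)
        return (f, r) if f[0] < r[0] else (r, f)


def amplicon_length(pair: PrimerPair) -> int:
    """Amplicon length in bases, tails included.

    The genomic span is outer-edge to outer-edge (max coordinate − min
    coordinate + 1); non-genomic tails extend the product on both ends.
    Invariant to swapping forward/reverse and to coordinate order within
    each primer.
    """
    coords = (*pair.forward, *pair.reverse)
    return (max(coords) - min(coords) + 1) + pair.forward_tail + pair.reverse_tail


def contains_target(pair: PrimerPair, target_pos: int) -> bool:
    """True iff the target lies strictly between the primer footprints.

    A target inside a primer footprint is not usable for confirmation (the
    base would be dictated by the primer), hence 'strictly between the
    inner boundaries'.
    """
    left, right = pair._spans()
    return left[1] < target_pos < right[0]
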