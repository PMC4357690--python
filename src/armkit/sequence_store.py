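"""Soft-masked genome access, target-region extraction and repeat fractions.

The genome is a soft-masked FASTA: lowercase marks repeat-derived bases (as
produced by RepeatMasker-style tools); hard-masked ``N`` runs count as repeat
as well and are additionally forbidden primer positions downstream.  Random
access goes through pyfaidx (.fai-style index, built on first open).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pyfaidx import Fasta

log = logging.getLogger(__name__)

DEFAULT_FLANK = 3000


@dataclass(frozen=True)
class MaskedSequence:
    chrom: str
    start: int
    end: int
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) != self.end - self.start:
            raise ValueError("sequence length does not match interval")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class TargetRegion:
    """An exon or projection plus clipped flanking sequence."""

    chrom: str
    focus_start: int
    focus_end: int
    flank_size: int
    start: int
    end: int
    sequence: MaskedSequence

    @property
    def length(self) -> int:
        return self.end - self.start


class SequenceStore:
    """Random-access reader over an indexed soft-masked FASTA."""

    def __init__(self, fasta_path: str | Path):
        self.path = Path(fasta_path)
        self._fasta = Fasta(
            str(self.path), as_raw=True, sequence_always_upper=False
        )

    def chroms(self) -> list[str]:
        return list(self._fasta.keys())

    def chrom_length(self, chrom: str) -> int:
        if chrom not in self._fasta:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> MaskedSequence:
        """Exact case-preserving sub-sequence; out-of-bounds requests clipped."""
        length = self.chrom_length(chrom)
        cstart, cend = max(0, start), min(length, end)
        if (cstart, cend) != (start, end):
            log.info(
                "fetch %s:[%d,%d) clipped to [%d,%d)", chrom, start, end, cstart, cend
            )
        if cend <= cstart:
            return MaskedSequence(chrom, cstart, cstart, "")
        bases = str(self._fasta[chrom][cstart:cend])
        return MaskedSequence(chrom, cstart, cend, bases)

    def target_region(
        self,
        chrom: str,
        focus_start: int,
        focus_end: int,
        flank_size: int = DEFAULT_FLANK,
    ) -> TargetRegion:
        """Focus feature extended by ``flank_size`` each side, clipped to the chromosome."""
        seq = self.fetch(chrom, focus_start - flank_size, focus_end + flank_size)
        return TargetRegion(
            chrom, focus_start, focus_end, flank_size, seq.start, seq.end, seq
        )


def repeat_fraction(seq: str | MaskedSequence) -> float:
    """Fraction of repeat-derived positions: lowercase plus (hard-masked) N.

    Invariant under reverse complement.  Undefined (raises) on an empty
    sequence.
    """
    bases = seq.bases if isinstance(seq, MaskedSequence) else seq
    if not bases:
        raise ValueError("repeat fraction undefined for empty sequence")
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    masked = (arr >= 97) | (arr == ord("N"))  # lowercase ascii or 'N'
    return float(masked.sum()) / len(arr)
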