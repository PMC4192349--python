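"""Genomic interval primitives and gene models.

Coordinates are 1-based with an inclusive ``start`` and an exclusive
``end``, so ``length == end - start``.  This is the convention used by
the curated region table, whose printed ``start..end`` pairs satisfy
exactly that arithmetic; BED I/O (:mod:`hetrseq.io`) converts to and
from BED's 0-based half-open frame explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

_STRANDS = ("+", "-", ".")
_FLIP = {"+": "-", "-": "+", ".": "."}


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """Half-open interval on a named replicon.

    Parameters
    ----------
    replicon : str
        Name of the chromosome or plasmid.
    start : int
        1-based inclusive start position.
    end : int
        Exclusive end position; ``end >= start``.
    strand : str
        ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    replicon: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomeInterval") -> bool:
        """True if the two intervals share at least one base."""
        return (
            self.replicon == other.replicon
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def reflected(self, replicon_length: int) -> "GenomeInterval":
        """Mirror image under reversal of the replicon.

        Position ``p`` maps to ``L - p + 1``; strands flip.  Used to check
        that annotation logic is strand-symmetric.
        """
        return GenomeInterval(
            self.replicon,
            replicon_length - self.end + 2,
            replicon_length - self.start + 2,
            _FLIP[self.strand],
        )


def interval_length(iv: GenomeInterval) -> int:
    """Length in base pairs (``end - start``)."""
    return iv.length


def reflect_position(position: int, replicon_length: int) -> int:
    return replicon_length - position + 1


@dataclass(frozen=True)
class GeneModel:
    """A gene (ORF) with an optional 5' untranslated region.

    The 5'UTR, when present, abuts the translational start on the coding
    strand: its end equals the gene start for a plus-strand gene, and its
    start equals the gene end for a minus-strand gene.
    """

    gene_id: str
    interval: GenomeInterval
    utr5: Optional[GenomeInterval] = None

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} requires a stranded interval")
        if self.utr5 is not None:
            ok = (
                self.utr5.end == self.interval.start
                if self.strand == "+"
                else self.utr5.start == self.interval.end
            )
            if not ok:
                raise ValueError(
                    f"5'UTR of {self.gene_id} does not abut the gene start"
                )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def start_codon_pos(self) -> int:
        """Position of the 5'-most coding base (the translational start)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    def reflected(self, replicon_length: int) -> "GeneModel":
        return GeneModel(
            self.gene_id,
            self.interval.reflected(replicon_length),
            None if self.utr5 is None else self.utr5.reflected(replicon_length),
        )
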