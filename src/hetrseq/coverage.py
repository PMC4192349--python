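"""Strand-aware coverage tracks built from aligned-read intervals."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .intervals import GenomeInterval

MODES = ("read_start", "read_body")


@dataclass
class CoverageTrack:
    """Per-position depth along one replicon.

    ``values[i]`` is the depth at 1-based position ``i + 1``.  In
    ``read_start`` mode each read increments only its 5' position
    (start on the plus strand, last base on the minus strand), so the
    track sums to the number of reads; in ``read_body`` mode every
    covered position is incremented, so the track sums to the number of
    aligned bases.
    """

    replicon: str
    strand: str  # '+', '-', or '.' when both strands are pooled
    mode: str
    values: np.ndarray

    def total(self) -> int:
        return int(self.values.sum())


def five_prime_positions(alignments: Sequence[GenomeInterval]) -> np.ndarray:
    """1-based 5' end of each read: start on '+', end - 1 on '-'."""
    return np.array(
        [a.start if a.strand == "+" else a.end - 1 for a in alignments],
        dtype=np.int64,
    )


def build_coverage(
    alignments: Iterable[GenomeInterval],
    replicon_length: int,
    strand_filter: Optional[str] = None,
    mode: str = "read_start",
    replicon: Optional[str] = None,
) -> CoverageTrack:
    """Accumulate a coverage track from aligned reads on one replicon.

    Parameters
    ----------
    alignments
        Stranded read intervals, all on the same replicon.
    replicon_length
        Length of the replicon in bp.
    strand_filter
        If ``'+'`` or ``'-'``, only reads on that strand contribute.
    mode
        ``'read_start'`` or ``'read_body'``.
    """
    if mode not in MODES:
        raise ValueError(f"unknown coverage mode {mode!r}")
    records = [a for a in alignments if strand_filter is None or a.strand == strand_filter]
    name = replicon
    for a in records:
        if name is None:
            name = a.replicon
        elif a.replicon != name:
            raise ValueError(f"mixed replicons: {a.replicon!r} vs {name!r}")
        if a.start < 1 or a.end > replicon_length + 1:
            raise ValueError(f"alignment {a} outside replicon bounds (L={replicon_length})")
    values = np.zeros(replicon_length, dtype=np.int64)
    if records:
        if mode == "read_start":
            pos = five_prime_positions(records)
            values += np.bincount(pos - 1, minlength=replicon_length)
        else:
            delta = np.zeros(replicon_length + 1, dtype=np.int64)
            starts = np.array([a.start for a in records], dtype=np.int64) - 1
            ends = np.array([a.end for a in records], dtype=np.int64) - 1
            np.add.at(delta, starts, 1)
            np.add.at(delta, ends, -1)
            values += np.cumsum(delta[:-1])
    return CoverageTrack(name or "", strand_filter or ".", mode, values)
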