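"""Position-weight-matrix scanning and consensus-motif construction.

A :class:`PWM` stores per-position base probabilities and a 0-order
background.  Sequences are scored as background-relative log-odds in
bits; the score p-value P(score(K) >= s) for a background-random k-mer
K is computed exactly (up to a discretization grid) by convolving the
per-column score distributions, as done by exact-p-value motif scanners.
Scanning reports every position/strand whose p-value passes a fixed
threshold; the matched sequences can then be stacked, without gaps, into
a consensus motif with per-column information content and an IUPAC
rendering whose case encodes conservation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .intervals import GenomeInterval

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

IUPAC_BASES: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_CODE_FOR_BASES = {frozenset(v): k for k, v in IUPAC_BASES.items()}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

#: score-discretization grid in bits; p-value error is bounded by width * grid
GRID = 1e-3

_PROB_FLOOR = 1e-12  # zero-probability cells score log2(floor/bg), not -inf


def reverse_complement(seq: str) -> str:
    """Reverse complement (IUPAC-aware, case-preserving). An involution."""
    return seq.translate(_COMPLEMENT)[::-1]


def composition(seq: str) -> np.ndarray:
    """0-order base composition of a sequence (the default scanning
    background: the whole genome's composition, since individual scanned
    regions are short)."""
    codes = encode(seq.upper())
    counts = np.bincount(codes[codes >= 0], minlength=4).astype(float)
    if counts.sum() == 0:
        raise ValueError("sequence contains no ACGT letters")
    return counts / counts.sum()


def encode(seq: str) -> np.ndarray:
    """Map a sequence to base indices; letters outside ACGT become -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        mask = np.frombuffer(seq.encode("ascii"), dtype="S1") == base.encode()
        out[mask] = idx
    return out


class PWM:
    """Position probability matrix with background and log-odds scoring.

    Parameters
    ----------
    probs : array (width, 4)
        Per-position probabilities over A, C, G, T; each row sums to 1.
    background : array (4,), optional
        0-order background; defaults to uniform.
    """

    def __init__(self, probs, background=None, name: str = "motif"):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("probs must have shape (width, 4) with width >= 1")
        if (probs < -1e-12).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1")
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        if background.shape != (4,) or not np.isclose(background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must be 4 probabilities summing to 1")
        self.probs = probs
        self.background = background
        self.name = name
        self._tails: Dict[float, Tuple[int, np.ndarray]] = {}

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, counts, pseudocount: float = 0.25, background=None,
                    name: str = "motif") -> "PWM":
        """Build from a position count matrix, adding a background-weighted
        pseudocount."""
        counts = np.asarray(counts, dtype=float)
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        total = counts.sum(axis=1, keepdims=True)
        probs = (counts + pseudocount * background) / (total + pseudocount)
        return cls(probs, background, name=name)

    def log_odds(self) -> np.ndarray:
        """Per-position log2(p / background) matrix in bits."""
        p = np.clip(self.probs, _PROB_FLOOR, None)
        return np.log2(p / self.background)

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1], self.background[::-1], name=self.name)

    # -- exact score distribution ------------------------------------------

    def _int_matrix(self, grid: float = GRID) -> np.ndarray:
        return np.rint(self.log_odds() / grid).astype(np.int64)

    def _tail(self, grid: float = GRID) -> Tuple[int, np.ndarray]:
        """(offset, tail) with tail[j] = P(int score >= offset + j) under
        the background, by dynamic-programming convolution over columns."""
        if grid not in self._tails:
            M = self._int_matrix(grid)
            mins = M.min(axis=1)
            cur = np.array([1.0])
            for i in range(self.width):
                span = int(M[i].max() - mins[i])
                new = np.zeros(len(cur) + span)
                for b in range(4):
                    shift = int(M[i, b] - mins[i])
                    new[shift:shift + len(cur)] += self.background[b] * cur
                cur = new
            tail = np.cumsum(cur[::-1])[::-1]
            self._tails[grid] = (int(mins.sum()), tail)
        return self._tails[grid]

    def min_int_score(self, p_threshold: float, grid: float = GRID) -> Optional[int]:
        """Smallest integer score whose tail probability is <= p_threshold,
        or None if no achievable score passes."""
        offset, tail = self._tail(grid)
        passing = np.flatnonzero(tail <= p_threshold)
        if passing.size == 0:
            return None
        return offset + int(passing[0])


def seed_to_pwm(iupac_seed: str, strong_weight: float = 0.91,
                weak_weight: float = 0.55, background=None) -> PWM:
    """Turn a case-annotated IUPAC string into a PWM.

    Uppercase letters mark strongly conserved positions and receive
    ``strong_weight`` total probability (spread over the letter's bases);
    lowercase letters receive ``weak_weight``; the remainder is uniform
    over the other bases.  ``N`` columns equal the background.
    """
    if not iupac_seed:
        raise ValueError("empty seed")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    cols = []
    for ch in iupac_seed:
        bases = IUPAC_BASES.get(ch.upper())
        if bases is None:
            raise ValueError(f"invalid IUPAC letter {ch!r}")
        if ch.upper() == "N":
            cols.append(background.copy())
            continue
        weight = strong_weight if ch.isupper() else weak_weight
        col = np.full(4, (1.0 - weight) / (4 - len(bases)))
        for b in bases:
            col[_BASE_INDEX[b]] = weight / len(bases)
        cols.append(col)
    return PWM(np.array(cols), background, name=iupac_seed)


def log_odds_score(pwm: PWM, kmer: str) -> float:
    """Log-odds score of one k-mer in bits; rejects ambiguity codes."""
    if len(kmer) != pwm.width:
        raise ValueError(f"kmer length {len(kmer)} != PWM width {pwm.width}")
    codes = encode(kmer.upper())
    if (codes < 0).any():
        raise ValueError(f"non-ACGT character in kmer {kmer!r}")
    lo = pwm.log_odds()
    return float(lo[np.arange(pwm.width), codes].sum())


def score_pvalue(pwm: PWM, score: float, grid: float = GRID) -> float:
    """P(score(K) >= score) for a background-random k-mer K.

    Computed from the discretized exact distribution; the absolute error
    in score placement is bounded by ``width * grid`` bits.
    """
    offset, tail = pwm._tail(grid)
    idx = int(round(score / grid)) - offset
    if idx <= 0:
        return 1.0
    if idx >= len(tail):
        return 0.0
    return float(tail[idx])


@dataclass(frozen=True)
class MotifHit:
    """A scan match; coordinates always refer to the forward strand and
    ``matched_sequence`` is strand-corrected (reverse-complemented for
    minus-strand hits)."""

    interval: GenomeInterval
    matched_sequence: str
    score: float  # bits
    p_value: float

    @property
    def strand(self) -> str:
        return self.interval.strand


def scan_sequence(seq: str, pwm: PWM, p_threshold: float = 1e-4,
                  replicon: str = "chr", offset: int = 0,
                  grid: float = GRID) -> List[MotifHit]:
    """Scan both strands of ``seq`` and return hits with p <= threshold.

    ``offset`` shifts reported coordinates: position 1 of ``seq`` is
    genome position ``offset + 1``.  When both strands pass at the same
    offset (a palindromic tie) only the better-scoring orientation is
    kept, plus strand winning ties.
    """
    w = pwm.width
    seq = seq.upper()
    n = len(seq)
    if n < w:
        return []
    codes = encode(seq)
    valid = codes >= 0
    codes_safe = np.where(valid, codes, 0)
    npos = n - w + 1
    ok = np.ones(npos, dtype=bool)
    for i in range(w):
        ok &= valid[i:i + npos]

    by_offset: Dict[int, MotifHit] = {}
    for strand, mat_pwm in (("+", pwm), ("-", pwm.reverse_complement())):
        smin = mat_pwm.min_int_score(p_threshold, grid)
        if smin is None:
            continue
        M = mat_pwm._int_matrix(grid)
        scores = np.zeros(npos, dtype=np.int64)
        for i in range(w):
            scores += M[i, codes_safe[i:i + npos]]
        t_off, tail = mat_pwm._tail(grid)
        for j in np.flatnonzero(ok & (scores >= smin)):
            j = int(j)
            sub = seq[j:j + w]
            hit = MotifHit(
                interval=GenomeInterval(replicon, offset + j + 1, offset + j + 1 + w, strand),
                matched_sequence=sub if strand == "+" else reverse_complement(sub),
                score=float(scores[j]) * grid,
                p_value=float(tail[int(scores[j]) - t_off]),
            )
            prev = by_offset.get(j)
            # plus strand is scanned first, so an equal-scoring minus-strand
            # (palindromic) tie never displaces it
            if prev is None or hit.score > prev.score + 1e-12:
                by_offset[j] = hit
    return [by_offset[j] for j in sorted(by_offset)]


def scan_regions(regions, genome: Union[str, Dict[str, str]], pwm: PWM,
                 p_threshold: float = 1e-4) -> Tuple[List[List[MotifHit]], Dict[str, int]]:
    """Scan each region's sequence; returns per-region hit lists and a
    summary with ``n_regions``, ``n_regions_with_hit`` and ``n_hits``."""
    hits_by_region: List[List[MotifHit]] = []
    for region in regions:
        iv = region.interval if hasattr(region, "interval") else region
        seq = genome[iv.replicon] if isinstance(genome, dict) else genome
        sub = seq[iv.start - 1:iv.end - 1]
        hits_by_region.append(
            scan_sequence(sub, pwm, p_threshold, replicon=iv.replicon, offset=iv.start - 1)
        )
    summary = {
        "n_regions": len(hits_by_region),
        "n_regions_with_hit": sum(1 for h in hits_by_region if h),
        "n_hits": sum(len(h) for h in hits_by_region),
    }
    return hits_by_region, summary


@dataclass
class ConsensusResult:
    """Consensus motif built from an ungapped stack of matched sites."""

    pwm: PWM
    iupac: str
    per_column_ic: np.ndarray  # bits
    n_sites: int


def build_consensus(hits: Sequence[Union[MotifHit, str]], background=None,
                    pseudocount: float = 0.25) -> ConsensusResult:
    """Stack strand-corrected matched sequences into a consensus motif.

    Per-column information content is computed from the raw site
    frequencies relative to the background (2 bits maximum for a uniform
    background); the IUPAC letter for a column is the minimal code
    covering every base at frequency >= 0.25, uppercased when the column
    carries at least 1 bit.
    """
    seqs = [h.matched_sequence if isinstance(h, MotifHit) else h for h in hits]
    if not seqs:
        raise ValueError("cannot build a consensus from zero sites")
    w = len(seqs[0])
    if any(len(s) != w for s in seqs):
        raise ValueError("matched sequences have unequal lengths")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    counts = np.zeros((w, 4))
    for s in seqs:
        codes = encode(s.upper())
        if (codes < 0).any():
            raise ValueError(f"non-ACGT character in site {s!r}")
        counts[np.arange(w), codes] += 1
    n = len(seqs)
    freqs = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log2(freqs / background), 0.0)
    ic = terms.sum(axis=1)
    letters = []
    for i in range(w):
        covered = frozenset(ALPHABET[b] for b in range(4) if freqs[i, b] >= 0.25)
        if not covered:  # only possible through ties below 0.25; fall back to argmax
            covered = frozenset(ALPHABET[int(np.argmax(freqs[i]))])
        code = _CODE_FOR_BASES[covered]
        letters.append(code.upper() if ic[i] >= 1.0 else code.lower())
    pwm = PWM.from_counts(counts, pseudocount=pseudocount, background=background,
                          name="consensus")
    return ConsensusResult(pwm=pwm, iupac="".join(letters), per_column_ic=ic, n_sites=n)


# ---------------------------------------------------------------------------
# MEME minimal text format

def write_meme(pwm: PWM, path, name: Optional[str] = None, nsites: int = 20) -> None:
    name = name or pwm.name
    bg = pwm.background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.6f} C {bg[1]:.6f} G {bg[2]:.6f} T {bg[3]:.6f}\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {nsites} E= 0\n"
        )
        for row in pwm.probs:
            fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")


def read_meme(path) -> PWM:
    """Read the first motif from a MEME minimal-format file."""
    background = np.full(4, 0.25)
    rows: List[List[float]] = []
    name = "motif"
    width = None
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    for line in lines:
        line = line.strip()
        if line.startswith("Background letter frequencies"):
            freq_line = next(lines).split()
            background = np.array([float(freq_line[i]) for i in (1, 3, 5, 7)])
        elif line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) > 1:
                name = parts[1]
        elif line.startswith("letter-probability matrix"):
            fields = line.split()
            if "w=" in fields:
                width = int(fields[fields.index("w=") + 1])
        elif line and width is not None and len(rows) < width:
            vals = [float(x) for x in line.split()]
            if len(vals) == 4:
                rows.append(vals)
    if width is None or len(rows) != width:
        raise ValueError(f"{path}: no complete letter-probability matrix found")
    return PWM(np.array(rows), background, name=name)
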