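"""Windowed Poisson peak calling against a control library.

The genome is tiled with non-overlapping windows (100 bp by default).
For each window the IP read-start count ``k_ip`` is tested against a
Poisson null whose rate comes from the library-size-scaled control
count, floored by the genome-wide control rate and by a pseudocount:

    lambda = max(eps, s * k_ctrl, s * mean(k_ctrl)),   s = n_ip / n_ctrl

The global floor keeps the plug-in control estimate from going
anti-conservative in windows where the control count fluctuates low; it
is a single genome-wide rate, not a local background model, and can be
disabled.  Upper-tail p-values P(X >= k_ip) are screened with the
Benjamini-Hochberg step-up at the requested false discovery rate, and
adjacent significant windows are merged into peaks.

Replicate consistency follows the study design: the IP reads are split
at random into three technical replicates, the identical analysis runs
on each, and full-data peaks are kept only when they overlap peaks in at
least two of the three replicate calls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .coverage import CoverageTrack, build_coverage, five_prime_positions
from .intervals import GenomeInterval


@dataclass
class CallerParams:
    """Peak-caller settings; the defaults are the study's stated
    parameters (100-bp window, 5% FDR) plus this implementation's
    explicit choices."""

    window: int = 100
    fdr_q: float = 0.05
    pseudocount: float = 0.5
    merge_gap: int = 1  # max non-significant windows bridged when merging
    min_ip_reads: int = 1  # windows with fewer IP reads are not tested
    global_lambda_floor: bool = True

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class WindowStat:
    interval: GenomeInterval
    k_ip: int
    k_ctrl: int
    lam: float
    p_value: float
    significant: bool


@dataclass
class Peak:
    """A merged run of significant windows."""

    interval: GenomeInterval
    k_ip: int
    k_ctrl_norm: float
    fold_enrichment: float
    min_p: float
    summit: int
    support: Optional[int] = None  # replicate support, set by consensus_peaks


def window_counts(
    track: CoverageTrack, window: int
) -> List[Tuple[GenomeInterval, int]]:
    """Counts over consecutive non-overlapping windows tiling the
    replicon (the final window may be truncated)."""
    if window <= 0:
        raise ValueError("window must be positive")
    L = len(track.values)
    edges = np.arange(0, L, window)
    counts = np.add.reduceat(track.values, edges)
    return [
        (
            GenomeInterval(track.replicon, int(e) + 1, int(min(e + window, L)) + 1),
            int(c),
        )
        for e, c in zip(edges, counts)
    ]


def normalization_factor(n_ip: int, n_ctrl: int) -> float:
    """Library-size scaling s = n_ip / n_ctrl."""
    if n_ctrl <= 0:
        raise ValueError("control library size must be positive")
    if n_ip < 0:
        raise ValueError("IP library size must be >= 0")
    return n_ip / n_ctrl


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam), via the survival function (stable
    in the far tail)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def bh_select(p_values: Sequence[float], q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject all p <= p_(i*) where
    i* = max{i : p_(i) <= i q / m}.  Returns a boolean mask."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    selected = np.zeros(m, dtype=bool)
    if m == 0:
        return selected
    order = np.argsort(p, kind="stable")
    below = p[order] <= (np.arange(1, m + 1) * q) / m
    if not below.any():
        return selected
    k_star = int(np.flatnonzero(below)[-1])
    selected[order[: k_star + 1]] = True
    return selected


def _group_reads(reads: Iterable[GenomeInterval]) -> Dict[str, List[GenomeInterval]]:
    grouped: Dict[str, List[GenomeInterval]] = {}
    for r in reads:
        grouped.setdefault(r.replicon, []).append(r)
    return grouped


def call_peaks(
    ip_reads: Sequence[GenomeInterval],
    ctrl_reads: Sequence[GenomeInterval],
    params: CallerParams,
    replicon_lengths: Dict[str, int],
) -> List[Peak]:
    """Call enriched peaks on every replicon.

    An empty IP read set yields an empty result; an empty control is an
    error (the test has no background estimate without it).
    """
    if not ip_reads:
        return []
    if not ctrl_reads:
        raise ValueError("control read set is empty")
    s = normalization_factor(len(ip_reads), len(ctrl_reads))
    ip_by_rep = _group_reads(ip_reads)
    ctrl_by_rep = _group_reads(ctrl_reads)
    peaks: List[Peak] = []
    for rep in sorted(replicon_lengths):
        L = replicon_lengths[rep]
        ip_rep = ip_by_rep.get(rep, [])
        if not ip_rep:
            continue
        ip_start = build_coverage(ip_rep, L, mode="read_start", replicon=rep)
        ctrl_start = build_coverage(ctrl_by_rep.get(rep, []), L, mode="read_start", replicon=rep)
        edges = np.arange(0, L, params.window)
        k_ip = np.add.reduceat(ip_start.values, edges)
        k_ctrl = np.add.reduceat(ctrl_start.values, edges)

        lam = s * k_ctrl.astype(float)
        if params.global_lambda_floor:
            lam = np.maximum(lam, s * float(k_ctrl.mean()))
        lam = np.maximum(lam, params.pseudocount)

        tested = k_ip >= params.min_ip_reads
        p = np.ones(k_ip.size)
        p[tested] = stats.poisson.sf(k_ip[tested] - 1, lam[tested])
        significant = np.zeros(k_ip.size, dtype=bool)
        if tested.any():
            significant[tested] = bh_select(p[tested], params.fdr_q)
        if not significant.any():
            continue

        body = build_coverage(ip_rep, L, mode="read_body", replicon=rep).values
        sig_idx = np.flatnonzero(significant)
        breaks = np.flatnonzero(np.diff(sig_idx) > params.merge_gap + 1)
        groups = np.split(sig_idx, breaks + 1)
        for grp in groups:
            i0, i1 = int(grp[0]), int(grp[-1])
            span_start = i0 * params.window + 1
            span_end = min((i1 + 1) * params.window, L) + 1
            K_ip = int(k_ip[i0:i1 + 1].sum())
            K_ctrl_norm = float(s * k_ctrl[i0:i1 + 1].sum())
            fold = K_ip / max(params.pseudocount, K_ctrl_norm)
            sl = body[span_start - 1:span_end - 1]
            summit = span_start + int(np.argmax(sl))
            peaks.append(
                Peak(
                    interval=GenomeInterval(rep, span_start, span_end),
                    k_ip=K_ip,
                    k_ctrl_norm=K_ctrl_norm,
                    fold_enrichment=float(fold),
                    min_p=float(p[grp].min()),
                    summit=summit,
                )
            )
    return peaks


def split_replicates(
    reads: Sequence[GenomeInterval], n_splits: int = 3, seed: int = 0
) -> List[List[GenomeInterval]]:
    """Randomly partition reads into ``n_splits`` technical replicates
    (multinomial with equal probabilities; every read lands in exactly
    one subset)."""
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    rng = np.random.default_rng(seed)
    assignment = rng.integers(0, n_splits, size=len(reads))
    subsets: List[List[GenomeInterval]] = [[] for _ in range(n_splits)]
    for read, a in zip(reads, assignment):
        subsets[int(a)].append(read)
    return subsets


def consensus_peaks(
    peaks: Sequence[Peak],
    replicate_peak_sets: Sequence[Sequence[Peak]],
    min_support: int = 2,
) -> List[Peak]:
    """Keep full-data peaks that overlap (>= 1 bp) a peak in at least
    ``min_support`` of the replicate peak sets; record the support."""
    if min_support > len(replicate_peak_sets):
        raise ValueError("min_support exceeds the number of replicate sets")
    kept: List[Peak] = []
    for pk in peaks:
        support = sum(
            1
            for rep_set in replicate_peak_sets
            if any(pk.interval.overlaps(q.interval) for q in rep_set)
        )
        if support >= min_support:
            kept.append(replace(pk, support=support))
    return kept


def call_peaks_with_replicates(
    ip_reads: Sequence[GenomeInterval],
    ctrl_reads: Sequence[GenomeInterval],
    params: CallerParams,
    replicon_lengths: Dict[str, int],
    n_splits: int = 3,
    min_support: int = 2,
    seed: int = 0,
) -> Tuple[List[Peak], List[Peak], List[List[Peak]]]:
    """Full-data call plus the replicate-consistency screen.

    Returns ``(consensus, full_call, replicate_calls)``.
    """
    full = call_peaks(ip_reads, ctrl_reads, params, replicon_lengths)
    subsets = split_replicates(ip_reads, n_splits=n_splits, seed=seed)
    rep_calls = [
        call_peaks(sub, ctrl_reads, params, replicon_lengths) if sub else []
        for sub in subsets
    ]
    return consensus_peaks(full, rep_calls, min_support), full, rep_calls
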