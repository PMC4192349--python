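"""Biological curation of called peaks.

Reproduces, as explicit configurable filters, the by-eye screen applied
to raw ChIP peaks: at least 3-fold read enrichment over the control, a
twin-peak (strand-offset) read-start morphology, a misregulated
neighbouring gene in the hetR-null mutant, and a promoter-proximal
location (within 500 bp upstream of an ORF, downstream of a potential
TSS, or inside an annotated 5'UTR).  Every annotated peak carries an
audit of which filters it passed, so the funnel from raw to curated
regions can be reconstructed exactly.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .coverage import CoverageTrack
from .intervals import GeneModel, GenomeInterval
from .io import TSS
from .peaks import Peak
from .tables import CuratedRegion, ExpressionRecord, FoldChange, Proximity


@dataclass
class CurationParams:
    fold_threshold: float = 3.0
    smoothing: int = 25  # moving-average width for read-start tracks, bp
    min_shift: int = 20
    max_shift: int = 400  # 2x the default mean fragment length
    c_min: float = 0.5  # minimum strand cross-correlation
    min_reads_per_strand: int = 10
    upstream_limit: int = 500
    tss_assign_limit: int = 1000  # max TSS-to-start-codon distance
    misreg_min_fold: float = 1.5
    require_fold: bool = True
    require_twin: bool = True
    require_misregulation: bool = True
    require_proximity: bool = True


@dataclass
class TwinPeakResult:
    plus_summit: int
    minus_summit: int
    shift: int  # minus_summit - plus_summit
    correlation_score: float  # NaN when a strand lacks reads
    is_twin: bool


@dataclass
class RegionAnnotation:
    peak: Peak
    gene_left: Optional[GeneModel]
    gene_right: Optional[GeneModel]
    proximity_left: Proximity
    proximity_right: Proximity
    misregulated_left: Optional[bool]
    misregulated_right: Optional[bool]


def fold_filter(peak: Peak, threshold: float = 3.0) -> bool:
    """True iff the peak's fold enrichment reaches the threshold
    (boundary inclusive)."""
    return peak.fold_enrichment >= threshold


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values.astype(float)
    kernel = np.ones(width) / width
    return np.convolve(values.astype(float), kernel, mode="same")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or x.std() == 0.0 or y.std() == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def twin_peak_score(
    peak: Peak,
    plus_track: CoverageTrack,
    minus_track: CoverageTrack,
    params: CurationParams = CurationParams(),
) -> TwinPeakResult:
    """Score the strand-offset read-start signature of point binding.

    Summits are the argmax of the smoothed per-strand read-start density
    within the peak; the correlation score is the best Pearson
    correlation between the plus track and the minus track shifted back
    by d over d in [min_shift, max_shift].  A peak is a twin peak when
    the summit shift is positive (minus summit downstream of plus
    summit), at most max_shift, and the correlation reaches c_min.
    Peaks with too few reads on either strand are rejected with a NaN
    score.
    """
    L = len(plus_track.values)
    lo = max(peak.interval.start - params.max_shift, 1)
    hi = min(peak.interval.end + params.max_shift, L + 1)
    pv = plus_track.values[lo - 1:hi - 1]
    mv = minus_track.values[lo - 1:hi - 1]
    sp = _smooth(pv, params.smoothing)
    sm = _smooth(mv, params.smoothing)
    a = peak.interval.start - lo
    b = peak.interval.end - lo
    plus_summit = lo + a + int(np.argmax(sp[a:b]))
    minus_summit = lo + a + int(np.argmax(sm[a:b]))
    shift = minus_summit - plus_summit
    if int(pv.sum()) < params.min_reads_per_strand or int(mv.sum()) < params.min_reads_per_strand:
        return TwinPeakResult(plus_summit, minus_summit, shift, math.nan, False)
    best = -1.0
    for d in range(params.min_shift, params.max_shift + 1):
        if d >= sp.size:
            break
        best = max(best, _pearson(sp[: sp.size - d], sm[d:]))
    is_twin = 0 < shift <= params.max_shift and best >= params.c_min
    return TwinPeakResult(plus_summit, minus_summit, shift, best, is_twin)


def classify_proximity(
    peak_interval: GenomeInterval,
    gene: GeneModel,
    tss_list: Sequence[TSS],
    upstream_limit: int = 500,
    tss_assign_limit: int = 1000,
) -> Proximity:
    """Assign a peak-to-gene proximity category on the gene's coding strand.

    Not applicable when the peak lies entirely 3' of the gene;
    downstream-of-TSS when the peak sits wholly between a TSS assigned
    to the gene and its start codon; within-500-bp-upstream when the
    peak overlaps the upstream window; beyond-500-bp-upstream otherwise.
    All conditions are mirror-symmetric under genome reflection.
    """
    piv = peak_interval
    if gene.strand == "+":
        gs = gene.interval.start
        if piv.start >= gene.interval.end:
            return Proximity.NOT_APPLICABLE
        cands = [
            t.position
            for t in tss_list
            if t.strand == "+" and t.position < gs and gs - t.position <= tss_assign_limit
        ]
        if cands:
            t = max(cands)  # nearest upstream TSS
            if piv.start > t and piv.end <= gs:
                return Proximity.DOWNSTREAM_OF_TSS
        if piv.start < gs and piv.end > gs - upstream_limit:
            return Proximity.WITHIN_500BP_UPSTREAM
        return Proximity.BEYOND_500BP_UPSTREAM
    else:
        ge = gene.interval.end  # exclusive; the 5' base is ge - 1
        if piv.end <= gene.interval.start:
            return Proximity.NOT_APPLICABLE
        cands = [
            t.position
            for t in tss_list
            if t.strand == "-" and t.position >= ge and t.position - (ge - 1) <= tss_assign_limit
        ]
        if cands:
            t = min(cands)
            if piv.end <= t and piv.start >= ge:
                return Proximity.DOWNSTREAM_OF_TSS
        if piv.end > ge and piv.start < ge + upstream_limit:
            return Proximity.WITHIN_500BP_UPSTREAM
        return Proximity.BEYOND_500BP_UPSTREAM


def annotate_region(
    peak: Peak,
    genes: Sequence[GeneModel],
    tss_list: Sequence[TSS],
    upstream_limit: int = 500,
    tss_assign_limit: int = 1000,
) -> RegionAnnotation:
    """Find the flanking gene on each side of the peak and classify the
    peak's proximity to each.  ``genes`` must be sorted by start."""
    if not genes:
        raise ValueError("empty gene list")
    starts = [g.interval.start for g in genes]
    i = bisect_right(starts, peak.interval.start)
    gene_left = genes[i - 1] if i > 0 else None
    gene_right = genes[i] if i < len(genes) else None
    prox_left = (
        classify_proximity(peak.interval, gene_left, tss_list, upstream_limit, tss_assign_limit)
        if gene_left
        else Proximity.NOT_APPLICABLE
    )
    prox_right = (
        classify_proximity(peak.interval, gene_right, tss_list, upstream_limit, tss_assign_limit)
        if gene_right
        else Proximity.NOT_APPLICABLE
    )
    return RegionAnnotation(peak, gene_left, gene_right, prox_left, prox_right, None, None)


def misregulation_flag(
    gene_id: str,
    expression: Dict[str, ExpressionRecord],
    min_fold: float = 1.5,
) -> Optional[bool]:
    """True iff |signed fold| >= min_fold at 0 h or 6 h.

    Sentinel fold changes are indeterminate: if no timepoint passes but
    any is a sentinel, the result is None (the peak is not excluded on
    their account).  The ``n / 0`` sentinel counts as infinite magnitude
    and always passes.
    """
    rec = expression.get(gene_id)
    if rec is None:
        return None
    mags = [rec.fc_0h.magnitude, rec.fc_6h.magnitude]
    if any(m is not None and m >= min_fold for m in mags):
        return True
    if any(m is None for m in mags):
        return None
    return False


_QUALIFYING = (Proximity.WITHIN_500BP_UPSTREAM, Proximity.DOWNSTREAM_OF_TSS)


def _fc_for(gene: Optional[GeneModel], expression: Dict[str, ExpressionRecord]) -> FoldChange:
    if gene is None or gene.gene_id not in expression:
        return FoldChange("na")
    return expression[gene.gene_id].fc_6h


def curate_regions(
    peaks: Sequence[Peak],
    plus_track: CoverageTrack,
    minus_track: CoverageTrack,
    genes: Sequence[GeneModel],
    tss_list: Sequence[TSS],
    expression: Sequence[ExpressionRecord],
    params: CurationParams = CurationParams(),
    keep_all: bool = False,
) -> List[CuratedRegion]:
    """Run every curation filter over the called peaks.

    A peak is retained when (subject to each filter's enable flag) its
    fold enrichment passes, it shows twin-peak morphology, at least one
    flanking gene is misregulated in the mutant (indeterminate evidence
    does not exclude), and it is promoter-proximal to at least one
    flanking gene or overlaps an annotated 5'UTR.  With ``keep_all`` the
    rejected records are returned too; each record's ``audit`` maps
    filter name to outcome.
    """
    expr_map = {r.gene_id: r for r in expression}
    out: List[CuratedRegion] = []
    for idx, pk in enumerate(peaks):
        ann = annotate_region(pk, genes, tss_list, params.upstream_limit, params.tss_assign_limit)
        fold_ok = fold_filter(pk, params.fold_threshold)
        twin = twin_peak_score(pk, plus_track, minus_track, params)
        mis_l = (
            misregulation_flag(ann.gene_left.gene_id, expr_map, params.misreg_min_fold)
            if ann.gene_left
            else None
        )
        mis_r = (
            misregulation_flag(ann.gene_right.gene_id, expr_map, params.misreg_min_fold)
            if ann.gene_right
            else None
        )
        defined = [m for m in (mis_l, mis_r) if m is not None]
        mis_ok = (True in defined) or not defined  # sentinels don't exclude
        utr_ok = any(
            g is not None and g.utr5 is not None and pk.interval.overlaps(g.utr5)
            for g in (ann.gene_left, ann.gene_right)
        )
        prox_ok = (
            ann.proximity_left in _QUALIFYING
            or ann.proximity_right in _QUALIFYING
            or utr_ok
        )
        audit = {
            "fold": fold_ok,
            "twin": twin.is_twin,
            "misregulation": mis_ok,
            "proximity": prox_ok,
        }
        retained = (
            (fold_ok or not params.require_fold)
            and (twin.is_twin or not params.require_twin)
            and (mis_ok or not params.require_misregulation)
            and (prox_ok or not params.require_proximity)
        )
        audit["retained"] = retained
        if retained or keep_all:
            out.append(
                CuratedRegion(
                    interval=pk.interval,
                    gene_left=ann.gene_left.gene_id if ann.gene_left else None,
                    fc_left=_fc_for(ann.gene_left, expr_map),
                    gene_right=ann.gene_right.gene_id if ann.gene_right else None,
                    fc_right=_fc_for(ann.gene_right, expr_map),
                    proximity_left=ann.proximity_left,
                    proximity_right=ann.proximity_right,
                    has_binding_site=False,
                    region_id=f"region_{idx:03d}",
                    audit=audit,
                )
            )
    return out
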