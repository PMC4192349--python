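"""Synthetic sequencing-design simulator.

Generates bacterial-scale genomes with planted transcription-factor
binding sites, gene models with transcription start sites, IP and
control read alignments with sonication-fragment twin-peak geometry,
and WT vs mutant expression tables — everything the downstream peak
calling, curation, motif and enrichment stages consume, with a known
ground truth.

The fragment model: a pulled-down fragment is centered on the bound
site (with Gaussian jitter of one fragment-length standard deviation)
or uniformly on the genome for background; its length is Gaussian,
truncated below the read length; the sequenced read covers the
fragment's 5'-most ``read_length`` bases on a uniformly chosen strand.
This places plus-strand read starts about half a fragment length
upstream of the site and minus-strand read ends the same distance
downstream — the strand-offset "twin peak" signature of point-source
binding that the curation stage detects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .intervals import GeneModel, GenomeInterval
from .io import TSS
from .motifs import PWM, reverse_complement, seed_to_pwm
from .tables import ExpressionRecord, FoldChange

_BASES = np.frombuffer(b"ACGT", dtype="S1")

RngOrSeed = Union[int, np.random.Generator]


def _as_rng(seed: RngOrSeed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimConfig:
    """Parameters of one simulated sequencing experiment.

    Defaults are a scaled-down rendition of the study design: a
    bacterial-scale (1 Mb) genome at 41.2% GC, 40-bp single-end reads,
    ~200-bp sonication fragments, 30 planted sites at 10x enrichment,
    and 200k reads per sample.
    """

    genome_length: int = 1_000_000
    gc_fraction: float = 0.412
    n_sites: int = 30
    n_reads_ip: int = 200_000
    n_reads_control: int = 200_000
    read_length: int = 40
    fragment_mean: float = 200.0
    fragment_sd: float = 40.0
    enrichment_ratio: float = 10.0
    n_genes: int = 300
    seed: int = 0
    min_site_spacing: int = 2_000
    replicon: str = "chr"

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        for name in ("n_sites", "n_reads_ip", "n_reads_control", "n_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must not exceed fragment_mean")
        if self.fragment_sd < 0:
            raise ValueError("fragment_sd must be >= 0")
        if self.enrichment_ratio < 1.0:
            raise ValueError("enrichment_ratio must be >= 1")

    @property
    def site_fraction(self) -> float:
        """Fraction of IP fragments drawn at planted sites.

        Chosen so the fragment rate over a site's footprint (one mean
        fragment length) is ``enrichment_ratio`` times background;
        capped at 1.
        """
        if self.n_sites == 0:
            return 0.0
        p = (
            self.n_sites
            * (self.enrichment_ratio - 1.0)
            * self.fragment_mean
            / self.genome_length
        )
        return min(1.0, max(0.0, p))


@dataclass
class TruthSet:
    """Ground truth of one simulated experiment."""

    planted_sites: List[GenomeInterval] = field(default_factory=list)
    site_sequences: List[str] = field(default_factory=list)
    gene_models: List[GeneModel] = field(default_factory=list)
    tss: List[TSS] = field(default_factory=list)
    expression: List[ExpressionRecord] = field(default_factory=list)
    hetr_dependent: Set[str] = field(default_factory=set)


def simulate_genome(length: int, gc: float, seed: RngOrSeed) -> str:
    """I.i.d. random genome with P(G) = P(C) = gc / 2."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = _as_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def sample_pwm_sites(pwm: PWM, n: int, rng: np.random.Generator) -> List[str]:
    """Draw ``n`` strings column-i.i.d. from the PWM probabilities."""
    w = pwm.width
    out = np.empty((n, w), dtype="S1")
    u = rng.random((n, w))
    for i in range(w):
        cum = np.cumsum(pwm.probs[i])
        idx = np.minimum(np.searchsorted(cum, u[:, i], side="right"), 3)
        out[:, i] = _BASES[idx]
    return [row.tobytes().decode("ascii") for row in out]


def _insert_site(genome: bytearray, seq: str, start0: int, strand: str) -> None:
    placed = seq if strand == "+" else reverse_complement(seq)
    genome[start0:start0 + len(seq)] = placed.encode("ascii")


def plant_sites(
    genome: str,
    pwm: PWM,
    n_sites: int,
    min_spacing: int = 2_000,
    seed: RngOrSeed = 0,
    replicon: str = "chr",
) -> Tuple[str, TruthSet]:
    """Write ``n_sites`` PWM samples into the genome at random,
    non-overlapping positions (uniform placement with guaranteed
    spacing); strands are chosen uniformly.

    Returns the modified genome and a truth set whose
    ``site_sequences`` are the PWM-frame (plus-orientation) samples.
    """
    w = pwm.width
    L = len(genome)
    if n_sites == 0:
        return genome, TruthSet()
    slack = L - n_sites * (w + min_spacing)
    if slack < 0:
        raise ValueError(
            f"cannot place {n_sites} sites of width {w} with spacing {min_spacing} in {L} bp"
        )
    rng = _as_rng(seed)
    offsets = np.sort(rng.integers(0, slack + 1, size=n_sites))
    starts0 = offsets + np.arange(n_sites) * (w + min_spacing)
    strands = np.where(rng.random(n_sites) < 0.5, "+", "-")
    seqs = sample_pwm_sites(pwm, n_sites, rng)
    garr = bytearray(genome.encode("ascii"))
    truth = TruthSet()
    for i in range(n_sites):
        _insert_site(garr, seqs[i], int(starts0[i]), str(strands[i]))
        truth.planted_sites.append(
            GenomeInterval(replicon, int(starts0[i]) + 1, int(starts0[i]) + 1 + w, str(strands[i]))
        )
        truth.site_sequences.append(seqs[i])
    return garr.decode("ascii"), truth


def simulate_reads(
    genome_length: int,
    truth: TruthSet,
    cfg: SimConfig,
    enriched: bool = True,
    seed: Optional[RngOrSeed] = None,
    site_probability: Optional[float] = None,
) -> List[GenomeInterval]:
    """Simulate aligned single-end reads for one sample.

    With ``enriched=True`` a fraction of fragments (``cfg.site_fraction``
    unless overridden) is centered on planted sites; the control sample
    is pure background.  Reads overhanging the genome ends are redrawn,
    so the output count always equals the requested count.  Output is
    sorted by start coordinate.
    """
    n = cfg.n_reads_ip if enriched else cfg.n_reads_control
    if seed is None:
        seed = np.random.default_rng([cfg.seed, int(enriched)])
    rng = _as_rng(seed)
    L = genome_length
    rl = cfg.read_length
    site_centers = (
        np.array([iv.midpoint for iv in truth.planted_sites], dtype=float)
        if (enriched and truth.planted_sites)
        else np.empty(0)
    )
    p_site = site_probability if site_probability is not None else cfg.site_fraction
    if not enriched or site_centers.size == 0:
        p_site = 0.0

    starts = np.empty(n, dtype=np.int64)
    plus = np.empty(n, dtype=bool)
    todo = np.arange(n)
    while todo.size:
        m = todo.size
        centers = rng.uniform(1.0, L + 1.0, m)
        if p_site > 0:
            from_site = rng.random(m) < p_site
            k = int(from_site.sum())
            if k:
                idx = rng.integers(0, site_centers.size, k)
                centers[from_site] = site_centers[idx] + rng.normal(0.0, cfg.fragment_sd, k)
        flen = rng.normal(cfg.fragment_mean, cfg.fragment_sd, m)
        bad = flen < rl
        while bad.any():  # truncated-Gaussian fragment length
            flen[bad] = rng.normal(cfg.fragment_mean, cfg.fragment_sd, int(bad.sum()))
            bad = flen < rl
        flen_i = np.rint(flen).astype(np.int64)
        left = np.rint(centers - flen / 2.0).astype(np.int64)
        right = left + flen_i  # fragment occupies [left, right)
        is_plus = rng.random(m) < 0.5
        rstart = np.where(is_plus, left, right - rl)
        rend = rstart + rl
        keep = (rstart >= 1) & (rend <= L + 1)
        starts[todo[keep]] = rstart[keep]
        plus[todo[keep]] = is_plus[keep]
        todo = todo[~keep]

    order = np.argsort(starts, kind="stable")
    rep = cfg.replicon
    return [
        GenomeInterval(rep, int(starts[i]), int(starts[i]) + rl, "+" if plus[i] else "-")
        for i in order
    ]


def simulate_gene_models(
    genome_length: int,
    n_genes: int,
    seed: RngOrSeed = 0,
    replicon: str = "chr",
    gene_length: int = 900,
    tss_offset_range: Tuple[int, int] = (30, 150),
    utr_fraction: float = 0.5,
) -> Tuple[List[GeneModel], List[TSS]]:
    """Evenly pitched gene models with random strands, a TSS a short
    distance upstream of each start codon, and 5'UTRs for a fraction of
    genes."""
    rng = _as_rng(seed)
    if n_genes == 0:
        return [], []
    pitch = genome_length // (n_genes + 1)
    margin = tss_offset_range[1] + 50
    if pitch <= gene_length + 2 * margin:
        raise ValueError("genome too short for the requested gene count")
    genes: List[GeneModel] = []
    tss_list: List[TSS] = []
    for i in range(n_genes):
        s = i * pitch + margin + 1
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomeInterval(replicon, s, s + gene_length, strand)
        offset = int(rng.integers(tss_offset_range[0], tss_offset_range[1] + 1))
        has_utr = rng.random() < utr_fraction
        if strand == "+":
            t = iv.start - offset
            utr5 = GenomeInterval(replicon, t, iv.start, "+") if has_utr else None
        else:
            t = iv.end - 1 + offset
            utr5 = GenomeInterval(replicon, iv.end, t + 1, "-") if has_utr else None
        genes.append(GeneModel(f"gene{i:04d}", iv, utr5))
        tss_list.append(TSS(replicon, t, strand))
    return genes, tss_list


def rpkm(read_count: int, gene_length: int, total_mapped: int) -> float:
    """Reads per kilobase of gene model per million mapped reads."""
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if read_count < 0:
        raise ValueError("read_count must be >= 0")
    return read_count / ((gene_length / 1_000.0) * (total_mapped / 1_000_000.0))


def signed_fold_change(
    wt_reads: int,
    mut_reads: int,
    gene_length: int,
    total_mapped_wt: int,
    total_mapped_mut: int,
    low_coverage_reads: int = 10,
) -> FoldChange:
    """Signed RPKM fold change with the sentinel conventions.

    Negative means lower in the mutant; equal abundances give +1.  Both
    samples below the coverage floor give ``Low coverage``; a positive WT
    count with zero mutant reads gives the ``n / 0`` sentinel.
    """
    if wt_reads < low_coverage_reads and mut_reads < low_coverage_reads:
        return FoldChange("low_coverage")
    if mut_reads == 0:
        return FoldChange("zero_mutant", wt_reads=wt_reads)
    wt = rpkm(wt_reads, gene_length, total_mapped_wt)
    mut = rpkm(mut_reads, gene_length, total_mapped_mut)
    if wt == 0.0:
        return FoldChange("low_coverage")
    if mut >= wt:
        return FoldChange("value", value=mut / wt)
    return FoldChange("value", value=-(wt / mut))


def simulate_expression(
    genes: Sequence[GeneModel],
    hetr_dependent: Set[str],
    effect: float = 8.0,
    noise_cv: float = 0.1,
    seed: RngOrSeed = 0,
    base_mean_reads: float = 200.0,
    base_log_sd: float = 0.5,
    total_mapped: int = 1_000_000,
    low_coverage_reads: int = 10,
) -> Tuple[List[ExpressionRecord], Dict[str, Dict[str, Tuple[float, float]]]]:
    """WT and mutant read counts per gene at 0 h and 6 h, reduced to
    signed RPKM fold changes.

    Genes in ``hetr_dependent`` have mutant abundance divided by
    ``effect``; multiplicative Gaussian noise with coefficient of
    variation ``noise_cv`` perturbs every measurement.  Returns the
    records and the per-gene truth of expected (WT, mutant) reads.
    """
    if effect < 1.0:
        raise ValueError("effect must be >= 1")
    rng = _as_rng(seed)
    records: List[ExpressionRecord] = []
    truth: Dict[str, Dict[str, Tuple[float, float]]] = {}
    for gene in genes:
        base = float(base_mean_reads * rng.lognormal(0.0, base_log_sd))
        dep = gene.gene_id in hetr_dependent
        truth[gene.gene_id] = {}
        fcs = {}
        for tp in ("0h", "6h"):
            wt_expected = base
            mut_expected = base / effect if dep else base
            truth[gene.gene_id][tp] = (wt_expected, mut_expected)
            noise = rng.normal(1.0, noise_cv, 2) if noise_cv > 0 else np.ones(2)
            wt_reads = max(0, int(round(wt_expected * max(0.0, noise[0]))))
            mut_reads = max(0, int(round(mut_expected * max(0.0, noise[1]))))
            fcs[tp] = signed_fold_change(
                wt_reads, mut_reads, gene.interval.length, total_mapped, total_mapped,
                low_coverage_reads=low_coverage_reads,
            )
        records.append(ExpressionRecord(gene.gene_id, fcs["0h"], fcs["6h"]))
    return records, truth


# ---------------------------------------------------------------------------
# Full-study construction

DEFAULT_SEED_SITE = "GGGTCTAgCCCagCA"


@dataclass
class StudyData:
    """One complete simulated study: genome, truth, reads, annotations."""

    config: SimConfig
    genome: str
    truth: TruthSet
    reads_ip: List[GenomeInterval]
    reads_control: List[GenomeInterval]
    site_pwm: PWM
    regulatory_sites: List[int]  # indices into truth.planted_sites
    decoy_sites: List[int]
    annotations: Dict[str, set]


CATEGORIES = (
    "heterocyst differentiation",
    "transposon related functions",
    "transcription",
    "adaptations and atypical conditions",
    "unknown",
)
_CATEGORY_PROBS = (0.05, 0.08, 0.10, 0.12, 0.65)


def simulate_study(
    cfg: SimConfig,
    n_regulatory: int = 10,
    n_decoy: int = 5,
    effect: float = 8.0,
    noise_cv: float = 0.1,
    site_pwm: Optional[PWM] = None,
    target_category_prob: float = 0.8,
) -> StudyData:
    """Build a full synthetic study with sites planted upstream of genes.

    ``n_regulatory`` sites sit 100-300 bp upstream of genes whose mutant
    expression is reduced ``effect``-fold (they pass every curation
    filter); ``n_decoy`` sites have identical geometry and enrichment but
    sit upstream of unaffected genes, so they fail exactly the
    misregulation filter.  Gene functional categories are drawn from
    genome-wide proportions, with regulatory target genes preferentially
    labelled "heterocyst differentiation" so the enrichment stage has a
    planted signal.
    """
    if site_pwm is None:
        site_pwm = seed_to_pwm(DEFAULT_SEED_SITE)
    ss = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(child) for child in ss.spawn(6)]
    L = cfg.genome_length
    genome = simulate_genome(L, cfg.gc_fraction, rngs[0])
    genes, tss_list = simulate_gene_models(L, cfg.n_genes, rngs[1], replicon=cfg.replicon)

    n_targets = n_regulatory + n_decoy
    if n_targets > len(genes):
        raise ValueError("more target sites than genes")
    stride = max(1, len(genes) // max(1, n_targets))
    # offset by stride // 2 so the first target is never the first gene,
    # whose upstream region may run off the genome start
    target_idx = [min(i * stride + stride // 2, len(genes) - 1) for i in range(n_targets)]
    if len(set(target_idx)) != n_targets:
        raise ValueError("too many target sites for the gene count")
    rngs[2].shuffle(target_idx)
    w = site_pwm.width
    garr = bytearray(genome.encode("ascii"))
    truth = TruthSet(gene_models=genes, tss=tss_list)
    site_seqs = sample_pwm_sites(site_pwm, n_targets, rngs[2])
    regulatory_sites: List[int] = []
    decoy_sites: List[int] = []
    hetr_dependent: Set[str] = set()
    for k, gi in enumerate(target_idx):
        gene = genes[gi]
        d = int(rngs[2].integers(100, 301))  # site-to-start-codon distance
        if gene.strand == "+":
            start1 = gene.interval.start - d - w
        else:
            start1 = gene.interval.end + d
        strand = "+" if rngs[2].random() < 0.5 else "-"
        _insert_site(garr, site_seqs[k], start1 - 1, strand)
        truth.planted_sites.append(GenomeInterval(cfg.replicon, start1, start1 + w, strand))
        truth.site_sequences.append(site_seqs[k])
        if k < n_regulatory:
            regulatory_sites.append(k)
            hetr_dependent.add(gene.gene_id)
        else:
            decoy_sites.append(k)
    genome = garr.decode("ascii")

    expression, _expr_truth = simulate_expression(
        genes, hetr_dependent, effect=effect, noise_cv=noise_cv, seed=rngs[3]
    )
    truth.expression = expression
    truth.hetr_dependent = hetr_dependent

    reads_ip = simulate_reads(L, truth, cfg, enriched=True, seed=rngs[4])
    reads_control = simulate_reads(L, truth, cfg, enriched=False, seed=rngs[4])

    annotations: Dict[str, set] = {}
    for gene in genes:
        if gene.gene_id in hetr_dependent and rngs[5].random() < target_category_prob:
            cat = CATEGORIES[0]
        else:
            cat = CATEGORIES[int(rngs[5].choice(len(CATEGORIES), p=_CATEGORY_PROBS))]
        annotations[gene.gene_id] = {cat}

    return StudyData(
        config=cfg,
        genome=genome,
        truth=truth,
        reads_ip=reads_ip,
        reads_control=reads_control,
        site_pwm=site_pwm,
        regulatory_sites=regulatory_sites,
        decoy_sites=decoy_sites,
        annotations=annotations,
    )
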