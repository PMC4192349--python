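"""Shared fixtures: seeded end-to-end simulations reused across tests."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pytest
from hypothesis import settings

from hetrseq import (
    CallerParams,
    CurationParams,
    PWM,
    SimConfig,
    StudyData,
    TruthSet,
    build_coverage,
    call_peaks_with_replicates,
    curate_regions,
    plant_sites,
    seed_to_pwm,
    simulate_genome,
    simulate_reads,
    simulate_study,
)
from hetrseq.motifs import composition

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

GENOME_BACKGROUND = np.array([0.294, 0.206, 0.206, 0.294])  # GC = 0.412


@dataclass
class RecoveryRun:
    """Default-scale simulation: 1 Mb genome, 30 planted sites at 10x
    enrichment, 200k reads per sample, full peak calling with the
    replicate-consistency screen."""

    config: SimConfig
    genome: str
    truth: TruthSet
    pwm: PWM
    reads_ip: list
    reads_control: list
    peaks: list  # replicate-consistent
    full_peaks: list


@pytest.fixture(scope="session")
def recovery_run() -> RecoveryRun:
    master = 1
    ss = np.random.SeedSequence(master)
    rngs = [np.random.default_rng(c) for c in ss.spawn(5)]
    cfg = SimConfig(seed=master)
    pwm = seed_to_pwm("GGGTCTAgCCCagCA", background=GENOME_BACKGROUND)
    genome = simulate_genome(cfg.genome_length, cfg.gc_fraction, rngs[0])
    genome, truth = plant_sites(genome, pwm, cfg.n_sites, seed=rngs[1])
    reads_ip = simulate_reads(cfg.genome_length, truth, cfg, enriched=True, seed=rngs[2])
    reads_control = simulate_reads(cfg.genome_length, truth, cfg, enriched=False, seed=rngs[3])
    peaks, full, _ = call_peaks_with_replicates(
        reads_ip, reads_control, CallerParams(), {cfg.replicon: cfg.genome_length}, seed=master
    )
    return RecoveryRun(cfg, genome, truth, pwm, reads_ip, reads_control, peaks, full)


@dataclass
class StudyRun:
    """Gene-anchored study: 10 regulatory sites upstream of mutant-
    misregulated genes plus 5 decoys constructed to fail exactly the
    misregulation filter, with peaks called and tracks built."""

    study: StudyData
    peaks: list
    full_peaks: list
    plus_track: object
    minus_track: object
    params: CurationParams


@pytest.fixture(scope="session")
def study_run() -> StudyRun:
    cfg = SimConfig(seed=7)
    study = simulate_study(cfg, n_regulatory=10, n_decoy=5)
    L = cfg.genome_length
    peaks, full, _ = call_peaks_with_replicates(
        study.reads_ip, study.reads_control, CallerParams(), {cfg.replicon: L}, seed=7
    )
    plus = build_coverage(study.reads_ip, L, strand_filter="+", replicon=cfg.replicon)
    minus = build_coverage(study.reads_ip, L, strand_filter="-", replicon=cfg.replicon)
    return StudyRun(study, peaks, full, plus, minus, CurationParams())


@pytest.fixture(scope="session")
def curated_study(study_run) -> Dict[str, object]:
    regions = curate_regions(
        study_run.peaks,
        study_run.plus_track,
        study_run.minus_track,
        study_run.study.truth.gene_models,
        study_run.study.truth.tss,
        study_run.study.truth.expression,
        study_run.params,
    )
    all_regions = curate_regions(
        study_run.peaks,
        study_run.plus_track,
        study_run.minus_track,
        study_run.study.truth.gene_models,
        study_run.study.truth.tss,
        study_run.study.truth.expression,
        study_run.params,
        keep_all=True,
    )
    return {"retained": regions, "all": all_regions}
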