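"""End-to-end orchestration: simulate -> call peaks -> curate -> scan
motifs -> build consensus -> category enrichment.

One seed fans out to per-stage sub-seeds through a fixed
``numpy.random.SeedSequence`` derivation, so a run is reproducible as a
whole and each stage is reproducible on its own.  The run manifest
records the configuration snapshot, the per-stage record counts (the
funnel), and every output path.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import yaml

from . import __version__
from .curate import CurationParams, curate_regions
from .coverage import build_coverage
from .enrich import category_fold_enrichment, flag_enriched
from .io import BedRecord, write_bed, write_fasta, write_gene_models, write_peaks, write_tss
from .motifs import build_consensus, composition, scan_regions, seed_to_pwm, write_meme
from .peaks import CallerParams, call_peaks_with_replicates
from .simulate import DEFAULT_SEED_SITE, SimConfig, simulate_study
from .tables import write_category_annotations, write_expression_table, write_region_table

logger = logging.getLogger("hetrseq")

PathLike = Union[str, Path]

DEFAULT_CONFIG: Dict[str, dict] = {
    "sim": {
        "genome_length": 1_000_000,
        "gc_fraction": 0.412,
        "n_reads_ip": 200_000,
        "n_reads_control": 200_000,
        "read_length": 40,
        "fragment_mean": 200.0,
        "fragment_sd": 40.0,
        "enrichment_ratio": 10.0,
        "n_genes": 300,
        "n_regulatory": 10,
        "n_decoy": 5,
        "effect": 8.0,
        "noise_cv": 0.1,
    },
    "caller": {
        "window": 100,
        "fdr_q": 0.05,
        "pseudocount": 0.5,
        "merge_gap": 1,
        "min_ip_reads": 1,
        "n_splits": 3,
        "min_support": 2,
    },
    "curation": {
        "fold_threshold": 3.0,
        "smoothing": 25,
        "min_shift": 20,
        "max_shift": 400,
        "c_min": 0.5,
        "min_reads_per_strand": 10,
        "upstream_limit": 500,
        "misreg_min_fold": 1.5,
    },
    "motif": {
        "seed_site": DEFAULT_SEED_SITE,
        "strong_weight": 0.91,
        "weak_weight": 0.55,
        "p_threshold": 1e-4,
        "consensus_pseudocount": 0.25,
    },
    "enrich": {"min_fold": 3.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: Optional[PathLike] = None) -> Dict[str, dict]:
    """Defaults, optionally overridden by a YAML file with the same
    section structure."""
    config = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping")
        config = _merge(config, user)
    return config


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    version: str
    seed: int
    config: Dict[str, dict]
    counts: Dict[str, int] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)

    def to_json(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _stage_seed(master: int, stage: int) -> int:
    """Deterministic per-stage integer sub-seed (< 2**31)."""
    ss = np.random.SeedSequence(master, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2**31))


def run_all(
    outdir: PathLike,
    seed: int,
    config: Optional[Dict[str, dict]] = None,
) -> RunManifest:
    """Execute every stage on a fresh simulated study and write all
    artifacts plus a manifest into ``outdir``."""
    config = config if config is not None else load_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, seed=seed, config=config)
    counts = manifest.counts
    outputs = manifest.outputs

    def _emit(name: str, filename: str) -> Path:
        outputs[name] = filename
        return outdir / filename

    stage = "simulate"
    try:
        sim_cfg_dict = dict(config["sim"])
        n_regulatory = sim_cfg_dict.pop("n_regulatory", 10)
        n_decoy = sim_cfg_dict.pop("n_decoy", 5)
        effect = sim_cfg_dict.pop("effect", 8.0)
        noise_cv = sim_cfg_dict.pop("noise_cv", 0.1)
        mcfg = config["motif"]
        pwm = seed_to_pwm(mcfg["seed_site"], mcfg["strong_weight"], mcfg["weak_weight"])
        cfg = SimConfig(seed=_stage_seed(seed, 0), n_sites=n_regulatory + n_decoy,
                        **sim_cfg_dict)
        study = simulate_study(cfg, n_regulatory=n_regulatory, n_decoy=n_decoy,
                               effect=effect, noise_cv=noise_cv, site_pwm=pwm)
        L = cfg.genome_length
        write_fasta({cfg.replicon: study.genome}, _emit("genome", "genome.fasta"))
        write_bed(
            [
                BedRecord(iv, f"site_{i}", 0.0)
                for i, iv in enumerate(study.truth.planted_sites)
            ],
            _emit("truth_sites", "sites_truth.bed"),
        )
        write_bed(study.reads_ip, _emit("reads_ip", "reads_ip.bed"))
        write_bed(study.reads_control, _emit("reads_control", "reads_control.bed"))
        write_gene_models(study.truth.gene_models, _emit("genes", "genes.gff3"))
        write_tss(study.truth.tss, _emit("tss", "tss.tsv"))
        write_expression_table(study.truth.expression, _emit("expression", "expression.tsv"))
        write_category_annotations(study.annotations, _emit("annotations", "annotations.tsv"))
        counts["planted_sites"] = len(study.truth.planted_sites)
        counts["reads_ip"] = len(study.reads_ip)
        counts["reads_control"] = len(study.reads_control)
        logger.info("simulate: %d sites, %d IP reads, %d control reads",
                    counts["planted_sites"], counts["reads_ip"], counts["reads_control"])

        stage = "callpeaks"
        ccfg = dict(config["caller"])
        n_splits = ccfg.pop("n_splits", 3)
        min_support = ccfg.pop("min_support", 2)
        params = CallerParams(**ccfg)
        peaks, full_peaks, _reps = call_peaks_with_replicates(
            study.reads_ip, study.reads_control, params, {cfg.replicon: L},
            n_splits=n_splits, min_support=min_support, seed=_stage_seed(seed, 1),
        )
        write_peaks(peaks, _emit("peaks", "peaks.tsv"))
        counts["peaks_called"] = len(full_peaks)
        counts["peaks_replicate_consistent"] = len(peaks)
        logger.info("callpeaks: %d called, %d replicate-consistent",
                    len(full_peaks), len(peaks))

        stage = "curate"
        cur_params = CurationParams(**config["curation"])
        plus = build_coverage(study.reads_ip, L, strand_filter="+", replicon=cfg.replicon)
        minus = build_coverage(study.reads_ip, L, strand_filter="-", replicon=cfg.replicon)
        regions = curate_regions(
            peaks, plus, minus, study.truth.gene_models, study.truth.tss,
            study.truth.expression, cur_params,
        )
        counts["curated_regions"] = len(regions)
        logger.info("curate: %d regions retained", len(regions))

        stage = "motif"
        # scan against the whole-genome 0-order composition
        scan_pwm = seed_to_pwm(
            mcfg["seed_site"], mcfg["strong_weight"], mcfg["weak_weight"],
            background=composition(study.genome),
        )
        hits_by_region, summary = scan_regions(
            regions, study.genome, scan_pwm, mcfg["p_threshold"]
        )
        for region, hits in zip(regions, hits_by_region):
            region.has_binding_site = bool(hits)
        write_region_table(regions, _emit("regions", "regions.tsv"))
        all_hits = [h for hits in hits_by_region for h in hits]
        with open(_emit("hits", "hits.tsv"), "w") as fh:
            fh.write("region_id\tstart\tend\tstrand\tscore\tp_value\tmatched_sequence\n")
            for region, hits in zip(regions, hits_by_region):
                for h in hits:
                    fh.write(
                        f"{region.region_id}\t{h.interval.start}\t{h.interval.end}\t"
                        f"{h.strand}\t{h.score:.4f}\t{h.p_value:.3e}\t{h.matched_sequence}\n"
                    )
        counts["regions_with_binding_site"] = summary["n_regions_with_hit"]
        counts["motif_hits"] = summary["n_hits"]
        if all_hits:
            consensus = build_consensus(
                all_hits, background=scan_pwm.background,
                pseudocount=mcfg["consensus_pseudocount"],
            )
            write_meme(consensus.pwm, _emit("consensus", "consensus.meme"),
                       name="consensus", nsites=consensus.n_sites)
            counts["consensus_width"] = consensus.pwm.width
        else:
            counts["consensus_width"] = 0
        logger.info("motif: %d hits in %d/%d regions", summary["n_hits"],
                    summary["n_regions_with_hit"], len(regions))

        stage = "enrich"
        hit_genes = sorted(
            {g for r in regions for g in (r.gene_left, r.gene_right) if g is not None}
        )
        genome_genes = [g.gene_id for g in study.truth.gene_models]
        if hit_genes:
            table = category_fold_enrichment(hit_genes, study.annotations, genome_genes)
            table.to_csv(_emit("enrichment", "enrichment.tsv"), sep="\t", index=False)
            counts["enriched_categories"] = len(
                flag_enriched(table, config["enrich"]["min_fold"])
            )
        else:
            counts["enriched_categories"] = 0

        # truth-aware recall: consensus peaks covering planted site centers
        recovered = sum(
            1
            for iv in study.truth.planted_sites
            if any(p.interval.contains(iv.midpoint) for p in peaks)
        )
        counts["planted_sites_recovered"] = recovered
    except Exception as exc:
        manifest.counts["failed_stage"] = stage  # type: ignore[assignment]
        manifest.to_json(outdir / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    outputs["manifest"] = "manifest.json"
    manifest.to_json(outdir / "manifest.json")
    return manifest
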