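"""Synthetic-data generator: composition, planting, read geometry,
expression truth."""

import math

import numpy as np
import pytest
from scipy import stats

from hetrseq import (
    GenomeInterval,
    SimConfig,
    plant_sites,
    rpkm,
    seed_to_pwm,
    simulate_expression,
    simulate_gene_models,
    simulate_genome,
    simulate_reads,
    simulate_study,
)
from hetrseq.coverage import five_prime_positions
from hetrseq.motifs import reverse_complement
from hetrseq.simulate import TruthSet, signed_fold_change

CONSENSUS = "GGGTCTAGCCCAGCA"


def deterministic_pwm():
    probs = np.zeros((len(CONSENSUS), 4))
    for i, b in enumerate(CONSENSUS):
        probs[i, "ACGT".index(b)] = 1.0
    from hetrseq import PWM

    return PWM(probs)


class TestSimulateGenome:
    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome(0, 0.5, 1)

    def test_gc_bounds_enforced(self):
        with pytest.raises(ValueError):
            simulate_genome(100, 1.5, 1)

    def test_zero_gc_gives_at_only(self):
        seq = simulate_genome(10_000, 0.0, 2)
        assert set(seq) <= {"A", "T"}

    def test_gc_fraction_within_three_standard_errors(self):
        n, gc = 1_000_000, 0.412
        seq = simulate_genome(n, gc, 3)
        observed = (seq.count("G") + seq.count("C")) / n
        se = math.sqrt(gc * (1 - gc) / n)
        assert abs(observed - gc) <= 3 * se

    def test_deterministic_for_fixed_seed(self):
        assert simulate_genome(5_000, 0.4, 9) == simulate_genome(5_000, 0.4, 9)


class TestPlantSites:
    def test_zero_sites_is_identity(self):
        genome = simulate_genome(10_000, 0.5, 1)
        out, truth = plant_sites(genome, deterministic_pwm(), 0)
        assert out == genome
        assert truth.planted_sites == []

    def test_deterministic_pwm_plants_consensus_exactly(self):
        genome = simulate_genome(50_000, 0.5, 1)
        out, truth = plant_sites(genome, deterministic_pwm(), 5, seed=2)
        assert len(truth.planted_sites) == 5
        for iv in truth.planted_sites:
            sub = out[iv.start - 1:iv.end - 1]
            if iv.strand == "-":
                sub = reverse_complement(sub)
            assert sub == CONSENSUS

    def test_planted_sites_do_not_overlap_and_fit_genome(self):
        genome = simulate_genome(200_000, 0.4, 1)
        _, truth = plant_sites(genome, seed_to_pwm("GGGTCTAgCCCagCA"), 30, seed=3)
        sites = sorted(truth.planted_sites, key=lambda iv: iv.start)
        assert all(a.end <= b.start for a, b in zip(sites, sites[1:]))
        assert sites[0].start >= 1 and sites[-1].end <= len(genome) + 1

    def test_column_frequencies_match_pwm(self):
        # chi-square goodness of fit per column over 300 planted strings
        pwm = seed_to_pwm("GGGTCTAgCCCagCA")
        genome = simulate_genome(900_000, 0.4, 1)
        _, truth = plant_sites(genome, pwm, 300, min_spacing=100, seed=4)
        stack = np.array([[c for c in s] for s in truth.site_sequences])
        for col in range(pwm.width):
            counts = np.array([(stack[:, col] == b).sum() for b in "ACGT"])
            expected = pwm.probs[col] * 300
            keep = expected > 0.5
            chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
            dof = keep.sum() - 1
            assert stats.chi2.sf(chi2, dof) > 1e-4, f"column {col}"

    def test_infeasible_packing_rejected(self):
        genome = "A" * 1000
        with pytest.raises(ValueError):
            plant_sites(genome, deterministic_pwm(), 10, min_spacing=500)


class TestSimulateReads:
    def test_zero_reads(self):
        cfg = SimConfig(genome_length=10_000, n_sites=0, n_reads_ip=0, n_reads_control=0)
        assert simulate_reads(cfg.genome_length, TruthSet(), cfg, enriched=True) == []

    def test_deterministic_twin_geometry(self):
        # one site, all fragments site-derived, zero length spread
        cfg = SimConfig(genome_length=10_000, n_sites=1, n_reads_ip=500,
                        n_reads_control=0, fragment_sd=0.0, seed=5)
        site = GenomeInterval("chr", 4993, 5008, "+")  # midpoint 5000
        truth = TruthSet(planted_sites=[site], site_sequences=["G" * 15])
        reads = simulate_reads(cfg.genome_length, truth, cfg, enriched=True,
                               site_probability=1.0)
        center = site.midpoint
        for r in reads:
            if r.strand == "+":
                assert r.start == round(center - cfg.fragment_mean / 2)
            else:
                assert r.end == round(center + cfg.fragment_mean / 2)

    def test_twin_peak_separation_matches_fragment_mean(self):
        # histogram oracle: strand-specific 5'-end density maxima are
        # separated by about one mean fragment length
        cfg = SimConfig(genome_length=50_000, n_sites=1, n_reads_ip=20_000,
                        n_reads_control=0, seed=6)
        site = GenomeInterval("chr", 24993, 25008, "+")
        truth = TruthSet(planted_sites=[site], site_sequences=["G" * 15])
        reads = simulate_reads(cfg.genome_length, truth, cfg, enriched=True,
                               site_probability=1.0)
        plus = [r for r in reads if r.strand == "+"]
        minus = [r for r in reads if r.strand == "-"]
        hp, edges = np.histogram(five_prime_positions(plus), bins=np.arange(0, 50_001, 25))
        hm, _ = np.histogram(five_prime_positions(minus), bins=np.arange(0, 50_001, 25))
        sep = edges[np.argmax(hm)] - edges[np.argmax(hp)]
        assert abs(sep - cfg.fragment_mean) <= 50

    def test_conservation_and_bounds(self):
        cfg = SimConfig(genome_length=20_000, n_sites=0, n_reads_ip=5_000,
                        n_reads_control=5_000, seed=7)
        reads = simulate_reads(cfg.genome_length, TruthSet(), cfg, enriched=False)
        assert len(reads) == 5_000
        assert all(1 <= r.start and r.end <= cfg.genome_length + 1 for r in reads)
        starts = [r.start for r in reads]
        assert starts == sorted(starts)

    def test_determinism(self):
        cfg = SimConfig(genome_length=20_000, n_sites=0, n_reads_ip=2_000,
                        n_reads_control=0, seed=8)
        a = simulate_reads(cfg.genome_length, TruthSet(), cfg, enriched=True)
        b = simulate_reads(cfg.genome_length, TruthSet(), cfg, enriched=True)
        assert a == b

    def test_control_window_counts_are_poisson_dispersed(self):
        # dispersion test over 1000 windows: (n-1) * var/mean ~ chi2(n-1)
        cfg = SimConfig(genome_length=100_000, n_sites=0, n_reads_ip=0,
                        n_reads_control=50_000, seed=9)
        reads = simulate_reads(cfg.genome_length, TruthSet(), cfg, enriched=False)
        counts = np.bincount(
            (five_prime_positions(reads) - 1) // 100, minlength=1000
        )[:1000]
        ratio = counts.var(ddof=1) / counts.mean()
        statistic = (counts.size - 1) * ratio
        p = 2 * min(
            stats.chi2.sf(statistic, counts.size - 1),
            stats.chi2.cdf(statistic, counts.size - 1),
        )
        assert p > 0.001


class TestExpression:
    def _genes(self, n):
        genes, _ = simulate_gene_models(10_000 * n, n, seed=11)
        return genes

    def test_no_effect_no_noise_gives_unit_folds(self):
        genes = self._genes(20)
        records, _ = simulate_expression(genes, set(), effect=1.0, noise_cv=0.0, seed=1)
        assert all(r.fc_0h.value == 1.0 and r.fc_6h.value == 1.0 for r in records)

    def test_effect_recovery_within_ten_percent(self):
        genes = self._genes(200)
        dependent = {g.gene_id for g in genes[:100]}
        records, _ = simulate_expression(genes, dependent, effect=8.0, noise_cv=0.1, seed=2)
        mags = [
            r.fc_6h.magnitude
            for r in records
            if r.gene_id in dependent and r.fc_6h.kind == "value"
        ]
        assert len(mags) > 80
        assert abs(np.mean(mags) - 8.0) / 8.0 <= 0.10

    def test_dependent_genes_are_down_in_mutant(self):
        genes = self._genes(50)
        dependent = {g.gene_id for g in genes[:25]}
        records, _ = simulate_expression(genes, dependent, effect=8.0, noise_cv=0.05, seed=3)
        for r in records:
            if r.gene_id in dependent and r.fc_6h.kind == "value":
                assert r.fc_6h.value < 0

    def test_zero_mutant_reads_serialize_with_sentinel(self):
        fc = signed_fold_change(11, 0, gene_length=900, total_mapped_wt=10**6,
                                total_mapped_mut=10**6)
        assert fc.kind == "zero_mutant"
        assert fc.format() == "11 / 0"
        assert fc.magnitude == math.inf


class TestRpkm:
    def test_unit_case(self):
        assert rpkm(100, 1000, 10**6) == 100.0

    def test_zero_reads(self):
        assert rpkm(0, 1000, 10**6) == 0.0

    def test_matches_direct_arithmetic(self):
        assert rpkm(37, 1234, 3_500_000) == pytest.approx(37 / (1.234 * 3.5))

    @pytest.mark.parametrize("length,total", [(0, 10**6), (1000, 0)])
    def test_degenerate_inputs_rejected(self, length, total):
        with pytest.raises(ValueError):
            rpkm(10, length, total)


class TestStudyConstruction:
    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(read_length=300, fragment_mean=200)
        with pytest.raises(ValueError):
            SimConfig(enrichment_ratio=0.5)

    def test_truth_sites_lie_upstream_of_target_genes(self, study_run):
        study = study_run.study
        genes = {g.gene_id: g for g in study.truth.gene_models}
        dependent_genes = [genes[g] for g in study.truth.hetr_dependent]
        for k in study.regulatory_sites:
            site = study.truth.planted_sites[k]
            near = [
                g for g in dependent_genes
                if (g.strand == "+" and 0 < g.interval.start - site.end <= 300)
                or (g.strand == "-" and 0 < site.start - g.interval.end <= 300)
            ]
            assert near, f"site {k} has no dependent gene just downstream"

    def test_planted_site_sequences_appear_in_genome(self, study_run):
        study = study_run.study
        for iv, seq in zip(study.truth.planted_sites, study.truth.site_sequences):
            sub = study.genome[iv.start - 1:iv.end - 1]
            if iv.strand == "-":
                sub = reverse_complement(sub)
            assert sub == seq
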