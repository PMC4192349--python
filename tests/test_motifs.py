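"""PWM construction, log-odds scoring, exact p-values, scanning, and
consensus building."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hetrseq import (
    HETR_SITE_SEED,
    PWM,
    build_consensus,
    log_odds_score,
    reverse_complement,
    scan_regions,
    scan_sequence,
    score_pvalue,
    seed_to_pwm,
    simulate_genome,
)
from hetrseq.intervals import GenomeInterval
from hetrseq.motifs import GRID, composition, read_meme, write_meme

DNA = st.text(alphabet="ACGT", max_size=60)


def random_pwm(rng, width):
    probs = rng.dirichlet(np.ones(4), size=width)
    return PWM(probs)


def enumeration_tail(pwm, score):
    """Brute-force oracle: exact P(score(K) >= s) by enumerating all 4^w
    k-mers with float (non-discretized) log-odds scores."""
    w = pwm.width
    lo = pwm.log_odds()
    total = 0.0
    for kmer in itertools.product(range(4), repeat=w):
        s = sum(lo[i, b] for i, b in enumerate(kmer))
        if s >= score:
            total += math.prod(pwm.background[b] for b in kmer)
    return total


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGT", "ACGT"),
        ("", ""),
        ("GAGGGGTCTAACCCCTC", "GAGGGGTTAGACCCCTC"),
    ])
    def test_known_values(self, seq, expected):
        # expectation computed with an independent character-wise oracle
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        assert "".join(comp[c] for c in reversed(seq)) == expected
        assert reverse_complement(seq) == expected

    @given(seq=DNA)
    def test_involution_and_length(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq
        assert len(reverse_complement(seq)) == len(seq)


class TestSeedToPwm:
    def test_strong_uppercase_column(self):
        pwm = seed_to_pwm("G", strong_weight=0.91)
        assert pwm.probs[0].tolist() == pytest.approx([0.03, 0.03, 0.91, 0.03])

    def test_seed_width(self):
        assert seed_to_pwm(HETR_SITE_SEED).width == 15

    def test_n_column_equals_background(self):
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        pwm = seed_to_pwm("N", background=bg)
        assert pwm.probs[0].tolist() == bg.tolist()

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError):
            seed_to_pwm("GXG")

    def test_lowercase_weak_column(self):
        pwm = seed_to_pwm("g", weak_weight=0.55)
        assert pwm.probs[0, 2] == pytest.approx(0.55)
        assert pwm.probs[0].sum() == pytest.approx(1.0)


class TestLogOddsScore:
    def test_deterministic_g_columns(self):
        probs = np.zeros((3, 4))
        probs[:, 2] = 1.0
        pwm = PWM(probs)
        assert log_odds_score(pwm, "GGG") == pytest.approx(3 * math.log2(4), abs=1e-6)

    def test_uniform_pwm_scores_zero(self):
        pwm = PWM(np.full((4, 4), 0.25))
        assert log_odds_score(pwm, "ACGT") == pytest.approx(0.0)

    def test_matches_independent_scorer(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            w = int(rng.integers(2, 12))
            pwm = random_pwm(rng, w)
            kmer = "".join("ACGT"[i] for i in rng.integers(0, 4, w))
            # second, independently coded scorer
            expected = 0.0
            for i, c in enumerate(kmer):
                b = "ACGT".index(c)
                expected += math.log2(pwm.probs[i, b] / pwm.background[b])
            assert log_odds_score(pwm, kmer) == pytest.approx(expected, abs=1e-9)

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError):
            log_odds_score(seed_to_pwm("GG"), "GN")


class TestScorePvalue:
    def test_below_minimum_is_one(self):
        pwm = random_pwm(np.random.default_rng(1), 5)
        assert score_pvalue(pwm, -1e6) == 1.0

    def test_above_maximum_is_zero(self):
        pwm = random_pwm(np.random.default_rng(2), 5)
        assert score_pvalue(pwm, 1e6) == 0.0

    def test_non_increasing_in_score(self):
        pwm = random_pwm(np.random.default_rng(3), 6)
        scores = np.linspace(-20, 12, 80)
        ps = [score_pvalue(pwm, s) for s in scores]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("width", [3, 5])
    def test_matches_enumeration_within_grid(self, width):
        rng = np.random.default_rng(width)
        pwm = random_pwm(rng, width)
        slack = width * GRID
        lo = pwm.log_odds()
        for q in np.linspace(lo.min(axis=1).sum(), lo.max(axis=1).sum(), 9):
            dp = score_pvalue(pwm, q)
            upper = enumeration_tail(pwm, q - slack - 1e-9)
            lower = enumeration_tail(pwm, q + slack + 1e-9)
            assert lower - 1e-12 <= dp <= upper + 1e-12


class TestScan:
    def test_planted_consensus_recovered(self):
        rng = np.random.default_rng(7)
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        site = "GGGTCTAGCCCAGCA"
        seq = flank + site + flank
        hits = scan_sequence(seq, seed_to_pwm(HETR_SITE_SEED), 1e-4)
        assert any(h.matched_sequence == site for h in hits)
        best = max(hits, key=lambda h: h.score)
        assert best.interval.start == len(flank) + 1

    def test_reverse_complement_gives_mirrored_minus_hit(self):
        rng = np.random.default_rng(8)
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        site = "GGGTCTAGCCCAGCA"
        seq = flank + site + flank
        pwm = seed_to_pwm(HETR_SITE_SEED)
        fwd = scan_sequence(seq, pwm, 1e-4)
        rev = scan_sequence(reverse_complement(seq), pwm, 1e-4)
        L = len(seq)
        fwd_set = {(h.interval.start, h.interval.end, h.strand, h.matched_sequence) for h in fwd}
        mirrored = {
            (L - h.interval.end + 2, L - h.interval.start + 2,
             "+" if h.strand == "-" else "-", h.matched_sequence)
            for h in rev
        }
        assert fwd_set == mirrored

    def test_hopeless_sequence_has_no_hits(self):
        assert scan_sequence("A" * 300, seed_to_pwm("GGGGGGGG"), 1e-4) == []

    def test_sequence_shorter_than_width_is_empty(self):
        assert scan_sequence("ACG", seed_to_pwm(HETR_SITE_SEED), 1e-4) == []

    def test_scan_regions_zero_and_two_site_cases(self):
        pwm = seed_to_pwm(HETR_SITE_SEED)
        _, empty_summary = scan_regions([], "ACGT" * 100, pwm)
        assert empty_summary == {"n_regions": 0, "n_regions_with_hit": 0, "n_hits": 0}
        rng = np.random.default_rng(9)
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        site = "GGGTCTAGCCCAGCA"
        seq = flank + site + flank + site + flank
        region = GenomeInterval("chr", 1, len(seq) + 1)
        hits_by, summary = scan_regions([region], seq, pwm)
        assert summary["n_regions_with_hit"] == 1
        assert len(hits_by[0]) == 2

    def test_core_pattern_constraint_on_passing_kmers(self):
        # structural constraint of the binding site: a G-triplet then a
        # C-triplet; every k-mer passing p <= 1e-4 against the width-8
        # sub-motif GGGtcTAg must open with the GGG
        sub = seed_to_pwm("GGGTCTAg")
        smin = sub.min_int_score(1e-4)
        M = sub._int_matrix()
        passing = []
        for kmer in itertools.product(range(4), repeat=8):
            s = sum(M[i, b] for i, b in enumerate(kmer))
            if s >= smin:
                passing.append(kmer)
        assert passing
        for kmer in passing:
            assert kmer[0] == kmer[1] == kmer[2] == 2  # G at seed positions 1-3


class TestConsensus:
    def test_degenerate_stack(self):
        site = "GGGTCTAGCCCAGCA"
        result = build_consensus([site] * 30)
        assert result.iupac == site
        assert np.allclose(result.per_column_ic, 2.0)
        assert result.n_sites == 30

    def test_half_half_column_is_R_with_one_bit(self):
        result = build_consensus(["A", "A", "G", "G"])
        assert result.iupac == "R"  # exactly 1 bit: the inclusive uppercase boundary
        assert result.per_column_ic[0] == pytest.approx(1.0)

    def test_sampled_sites_recover_generating_pwm(self):
        from hetrseq.simulate import sample_pwm_sites

        pwm = seed_to_pwm(HETR_SITE_SEED)
        rng = np.random.default_rng(10)
        sites = sample_pwm_sites(pwm, 59, rng)
        result = build_consensus(sites)
        corr = np.corrcoef(result.pwm.probs.ravel(), pwm.probs.ravel())[0, 1]
        assert corr >= 0.9
        assert result.iupac[:3].upper() == "GGG"
        assert result.iupac[8:11].upper() == "CCC"

    def test_upstream_A_is_recovered_when_planted(self):
        # consensus built from sites with a conserved A two bases 5' of
        # the G-triplet renders that A
        pwm = seed_to_pwm("AnGGGTCTAgCCCagCA")
        rng = np.random.default_rng(11)
        from hetrseq.simulate import sample_pwm_sites

        result = build_consensus(sample_pwm_sites(pwm, 59, rng))
        assert result.iupac[0].upper() == "A"
        assert result.iupac[2:5].upper() == "GGG"

    def test_empty_hit_list_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([])


class TestMemeFormat:
    def test_roundtrip(self, tmp_path):
        pwm = seed_to_pwm(HETR_SITE_SEED, background=np.array([0.294, 0.206, 0.206, 0.294]))
        path = tmp_path / "motif.meme"
        write_meme(pwm, path, name="hetr_site", nsites=59)
        back = read_meme(path)
        assert back.width == pwm.width
        assert np.allclose(back.probs, pwm.probs, atol=1e-5)
        assert np.allclose(back.background, pwm.background, atol=1e-5)


class TestComposition:
    def test_counts_gc(self):
        assert composition("GGCCAATT").tolist() == [0.25, 0.25, 0.25, 0.25]

    def test_simulated_genome_composition_near_target(self):
        seq = simulate_genome(200_000, 0.412, 12)
        bg = composition(seq)
        assert bg[1] + bg[2] == pytest.approx(0.412, abs=0.01)
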