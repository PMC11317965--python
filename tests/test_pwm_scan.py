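"""Log-odds scoring, exact p-value DP, both-strand scanning, word counting."""

import itertools

import numpy as np
import pytest

from conftest import random_genome, random_pwm
from doublebox.io_core import Genome, reverse_complement
from doublebox.motif_model import BASE_INDEX, PWM, build_pwm, make_double_pwm
from doublebox.pwm_scan import (ScoreDistribution, best_local_pvalue,
                                count_exact, log_odds, scan,
                                score_distribution)
from doublebox.reference import DNAA_BOX_CONSENSUS

UNIFORM = np.full(4, 0.25)


def consensus_pwm(pseudocount=0.0):
    """Near-deterministic PWM for the 9-mer box, uniform background."""
    return build_pwm([DNAA_BOX_CONSENSUS] * 2, pseudocount=pseudocount,
                     background=UNIFORM)


def enumerate_binned_tail(dist: ScoreDistribution, background: np.ndarray):
    """Brute-force oracle: bin every k-mer with the DP's own column bins and
    accumulate background weights into a tail distribution."""
    width = dist.column_bins.shape[0]
    tails = {}
    for kmer in itertools.product(range(4), repeat=width):
        score = int(sum(dist.column_bins[i, b] for i, b in enumerate(kmer)))
        weight = float(np.prod([background[b] for b in kmer]))
        tails[score] = tails.get(score, 0.0) + weight
    scores = sorted(tails, reverse=True)
    acc, tail = 0.0, {}
    for s in scores:
        acc += tails[s]
        tail[s] = acc
    return tail


class TestLogOdds:
    def test_uniform_pwm_scores_zero(self):
        pwm = PWM(np.full((4, 4), 0.25), UNIFORM)
        assert log_odds(pwm, "ACGT") == pytest.approx(0.0)

    def test_consensus_certain_pwm_scores_18_bits(self):
        assert log_odds(consensus_pwm(), DNAA_BOX_CONSENSUS) == pytest.approx(
            9 * np.log2(4))

    def test_two_column_hand_example(self):
        probs = np.array([[0.5, 0.5, 0.0, 0.0], [1.0, 0.0, 0.0, 0.0]])
        pwm = PWM(probs, UNIFORM)
        assert log_odds(pwm, "CA") == pytest.approx(np.log2(2) + np.log2(4))

    def test_length_mismatch_and_n_rejected(self):
        pwm = consensus_pwm()
        with pytest.raises(ValueError, match="length"):
            log_odds(pwm, "ACGT")
        with pytest.raises(ValueError, match="N"):
            log_odds(pwm, "TTATCCACN")


class TestScoreDistribution:
    def test_single_column_max_probability(self):
        probs = np.array([[0.7, 0.1, 0.1, 0.1]])
        dist = score_distribution(PWM(probs, UNIFORM))
        assert dist.pvalue_of_bin(dist.max_bin) == pytest.approx(0.25)

    def test_minimum_score_has_total_mass(self):
        dist = score_distribution(consensus_pwm(0.1))
        assert dist.pvalue_of_bin(dist.min_bin) == pytest.approx(1.0)

    def test_tail_non_increasing_and_mass_sums_to_one(self):
        rng = np.random.default_rng(0)
        dist = score_distribution(random_pwm(rng, 5))
        assert np.all(np.diff(dist.tail) <= 1e-15)
        assert dist.probabilities.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("bg", [UNIFORM, np.array([0.4, 0.1, 0.1, 0.4])])
    def test_dp_matches_exhaustive_enumeration(self, seed, bg):
        rng = np.random.default_rng(seed)
        width = int(rng.integers(2, 7))
        pwm = PWM(random_pwm(rng, width).probs, bg)
        dist = score_distribution(pwm)
        oracle = enumerate_binned_tail(dist, bg)
        for score, expected in oracle.items():
            assert dist.pvalue_of_bin(score) == pytest.approx(expected, abs=1e-9)


class TestScan:
    def test_double_box_genome_hit_at_start_one(self):
        single = build_pwm(["A" + DNAA_BOX_CONSENSUS + "G"] * 2,
                           pseudocount=0.5, background=UNIFORM)
        double = make_double_pwm(single, spacing=3)
        genome = Genome("g", double.consensus())
        hits = scan(genome, double, p_max=1e-4, background=UNIFORM)
        assert any(h.start == 1 and h.strand == "+" for h in hits)
        top = [h for h in hits if h.start == 1 and h.strand == "+"][0]
        dist = score_distribution(PWM(double.probs, UNIFORM))
        assert top.p_value == pytest.approx(dist.pvalue(top.score), rel=1e-6)

    def test_poly_a_genome_has_no_hits(self):
        genome = Genome("g", "A" * 200)
        pwm = build_pwm(["C" + DNAA_BOX_CONSENSUS + "C"] * 2, pseudocount=0.5,
                        background=UNIFORM)
        assert scan(genome, pwm, p_max=1e-4, background=UNIFORM) == []

    def test_genome_shorter_than_motif(self):
        genome = Genome("g", "ACGT")
        pwm = consensus_pwm(0.1)
        assert scan(genome, pwm) == []

    def test_windows_containing_n_are_skipped(self):
        seq = DNAA_BOX_CONSENSUS + "N" + DNAA_BOX_CONSENSUS
        genome = Genome("g", seq)
        pwm = consensus_pwm(0.1)
        hits = scan(genome, pwm, p_max=1e-3, background=UNIFORM)
        starts = {h.start for h in hits if h.strand == "+"}
        assert starts == {1, 11}  # no window spanning the N is reported

    @pytest.mark.parametrize("seed", range(10))
    def test_strand_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        genome = random_genome(rng, 500)
        pwm = random_pwm(rng, 6, sharpness=0.3)
        fwd = scan(genome, pwm, p_max=0.01)
        rev = scan(Genome("g", reverse_complement(genome.sequence)), pwm,
                   p_max=0.01)
        fwd_key = sorted((h.score, h.p_value) for h in fwd)
        rev_key = sorted((h.score, h.p_value) for h in rev)
        assert len(fwd_key) == len(rev_key)
        for (s1, p1), (s2, p2) in zip(fwd_key, rev_key):
            assert s1 == pytest.approx(s2, abs=1e-9)
            assert p1 == pytest.approx(p2, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_hit_sets_nested_in_p_max(self, seed):
        rng = np.random.default_rng(100 + seed)
        genome = random_genome(rng, 1000)
        pwm = random_pwm(rng, 7, sharpness=0.3)
        loose = {(h.start, h.strand) for h in scan(genome, pwm, p_max=1e-2)}
        tight = {(h.start, h.strand) for h in scan(genome, pwm, p_max=1e-3)}
        assert tight <= loose

    @pytest.mark.parametrize("seed", range(3))
    def test_scan_equals_brute_force(self, seed):
        rng = np.random.default_rng(200 + seed)
        genome = random_genome(rng, 300)
        pwm = random_pwm(rng, 5, sharpness=0.4)
        p_max = 0.02
        hits = {(h.start, h.strand): h.p_value
                for h in scan(genome, pwm, p_max=p_max)}
        # brute force: bin every window with the DP's bins, both strands
        from doublebox.motif_model import estimate_background

        bg = estimate_background(genome.sequence)
        expected = {}
        for strand, matrix in (("+", pwm), ("-", pwm.reverse_complement())):
            matrix = PWM(matrix.probs, bg)
            dist = score_distribution(matrix)
            oracle = enumerate_binned_tail(dist, bg)
            for pos in range(genome.length - pwm.width + 1):
                kmer = genome.sequence[pos:pos + pwm.width]
                score = int(sum(dist.column_bins[i, BASE_INDEX[c]]
                                for i, c in enumerate(kmer)))
                attained = [s for s in oracle if s >= score]
                p = oracle[min(attained)] if attained else 0.0
                if p <= p_max:
                    expected[(pos + 1, strand)] = p
        assert set(hits) == set(expected)
        for k in hits:
            assert hits[k] == pytest.approx(expected[k], rel=1e-9)


class TestCountExact:
    @pytest.mark.parametrize("seq,word,expected", [
        ("TTATCCACA", "TTATCCACA", 1),
        ("TGTGGATAA", "TTATCCACA", 1),   # reverse-strand instance
        ("AAAA", "AA", 3),               # overlapping forward occurrences
        ("CCCC", "AA", 0),
    ])
    def test_examples(self, seq, word, expected):
        assert count_exact(Genome("g", seq), word) == expected

    def test_empty_word_rejected(self):
        with pytest.raises(ValueError):
            count_exact(Genome("g", "ACGT"), "")


class TestBestLocalPvalue:
    def test_planted_site_beats_background(self):
        rng = np.random.default_rng(0)
        genome = random_genome(rng, 400)
        seq = (genome.sequence[:200] + DNAA_BOX_CONSENSUS
               + genome.sequence[209:])
        genome = Genome("g", seq)
        pwm = consensus_pwm(0.1)
        at_site = best_local_pvalue(genome, pwm, 199, 203)
        elsewhere = best_local_pvalue(genome, pwm, 20, 24)
        assert at_site < 1e-4 < elsewhere
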