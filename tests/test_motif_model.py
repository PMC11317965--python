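"""PWM construction, de-novo discovery, double-box composition, MEME I/O."""

import numpy as np
import pytest

from doublebox.io_core import reverse_complement
from doublebox.motif_model import (PWM, SiteAlignment, build_pwm,
                                   count_consensus_matches, discover_motif,
                                   estimate_background, make_double_pwm,
                                   read_meme, write_meme)
from doublebox.reference import DNAA_BOX_CONSENSUS

UNIFORM = np.full(4, 0.25)


def planted_windows(rng, n=16, length=101, motif=DNAA_BOX_CONSENSUS):
    wins = []
    for _ in range(n):
        w = "".join("ACGT"[j] for j in rng.integers(4, size=length))
        off = int(rng.integers(0, length - len(motif)))
        wins.append(w[:off] + motif + w[off + len(motif):])
    return wins


class TestConsensusMatches:
    @pytest.mark.parametrize("site,expected", [
        ("TTACGCACA", 7),     # purH upstream box
        ("TTATCCACA", 9),     # perfect match
        ("GGGGGGGGG", 0),     # consensus contains no G
        ("ttatccaca", 9),     # case-insensitive
    ])
    def test_examples(self, site, expected):
        assert count_consensus_matches(site) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            count_consensus_matches("TTAT")


class TestBuildPwm:
    def test_unanimous_sites_no_pseudocount(self):
        pwm = build_pwm(["AAAA", "AAAA"], pseudocount=0)
        np.testing.assert_allclose(pwm.probs[:, 0], 1.0)

    def test_even_split(self):
        pwm = build_pwm(["AAAA", "CCCC"], pseudocount=0)
        np.testing.assert_allclose(pwm.probs[:, 0], 0.5)
        np.testing.assert_allclose(pwm.probs[:, 1], 0.5)

    def test_pseudocount_hand_arithmetic(self):
        # (count + pc*bg) / (n + pc) with sites {AA, AC}, pc=1, uniform bg
        pwm = build_pwm(["AA", "AC"], pseudocount=1, background=UNIFORM)
        np.testing.assert_allclose(pwm.probs[1],
                                   [1.25 / 3, 1.25 / 3, 0.25 / 3, 0.25 / 3])

    def test_column_sums_are_one(self):
        pwm = build_pwm(["ACGT", "AAAA", "ACGG"], pseudocount=0.1)
        np.testing.assert_allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("sites,err", [
        ([], "empty"), (["AA"], "at least 2"), (["AA", "ACG"], "ragged"),
    ])
    def test_bad_alignments_rejected(self, sites, err):
        with pytest.raises(ValueError, match=err):
            build_pwm(sites)

    def test_converges_to_source_pwm_with_more_sites(self):
        # KL(source || estimate) decreases as sites accumulate
        rng = np.random.default_rng(0)
        source = rng.dirichlet(np.ones(4), size=6)
        divergences = []
        for n in (10, 100, 1000):
            sites = ["".join("ACGT"[rng.choice(4, p=source[i])]
                             for i in range(6)) for _ in range(n)]
            est = build_pwm(sites, pseudocount=0).probs
            with np.errstate(divide="ignore", invalid="ignore"):
                kl = np.nansum(source * np.log2(source / np.clip(est, 1e-12, None)))
            divergences.append(kl)
        assert divergences[0] > divergences[1] > divergences[2]


class TestDiscoverMotif:
    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_planted_consensus(self, seed):
        rng = np.random.default_rng(seed)
        pwm, alignment = discover_motif(planted_windows(rng), width=11)
        core = pwm.consensus()[pwm.core_offset:pwm.core_offset + 9]
        assert DNAA_BOX_CONSENSUS in (core, reverse_complement(core))
        assert len(alignment.sites) >= 12  # most of the 16 plants found

    def test_random_windows_score_below_planted(self):
        rng = np.random.default_rng(3)
        planted_pwm, _ = discover_motif(planted_windows(rng), width=11)
        rng2 = np.random.default_rng(4)
        random_wins = ["".join("ACGT"[j] for j in rng2.integers(4, size=101))
                       for _ in range(16)]
        random_pwm, _ = discover_motif(random_wins, width=11)
        assert random_pwm.information_content() < planted_pwm.information_content()

    def test_width_exceeding_window_rejected(self):
        with pytest.raises(ValueError, match="width"):
            discover_motif(["ACGT"] * 4, width=10)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="no informative motif"):
            discover_motif(["A" * 50] * 8, width=11)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            discover_motif(["ACGTACGTACGT"] * 3, width=4)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(5)
        wins = planted_windows(rng)
        fwd, _ = discover_motif(wins, width=11)
        rev, _ = discover_motif([reverse_complement(w) for w in wins], width=11)
        assert abs(fwd.information_content() - rev.information_content()) < 1e-6


class TestMakeDoublePwm:
    def single(self, flank="A"):
        sites = [flank + DNAA_BOX_CONSENSUS + flank] * 4
        return build_pwm(sites, pseudocount=0.2, background=UNIFORM)

    def test_spacing_two_geometry(self):
        d = make_double_pwm(self.single(), spacing=2)
        assert d.width == 22 and d.core_spacing == 2

    def test_spacing_three_geometry_and_background_column(self):
        d = make_double_pwm(self.single(), spacing=3)
        assert d.width == 23 and d.core_spacing == 3
        np.testing.assert_allclose(d.probs[11], d.background)

    def test_consensus_cores_at_expected_offsets(self):
        d = make_double_pwm(self.single(), spacing=3)
        consensus = d.consensus()
        assert consensus[1:10] == DNAA_BOX_CONSENSUS
        assert consensus[13:22] == DNAA_BOX_CONSENSUS

    def test_column_sums_and_information_content(self):
        s = self.single()
        for spacing in (2, 3):
            d = make_double_pwm(s, spacing=spacing)
            np.testing.assert_allclose(d.probs.sum(axis=1), 1.0, atol=1e-9)
            assert d.information_content() == pytest.approx(
                2 * s.information_content(), abs=1e-9)

    def test_unsupported_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing 5"):
            make_double_pwm(self.single(), spacing=5)

    def test_double_of_double_rejected(self):
        d = make_double_pwm(self.single(), spacing=2)
        with pytest.raises(ValueError, match="already"):
            make_double_pwm(d, spacing=2)


class TestMemeFormat:
    def test_round_trip(self, tmp_path):
        sites = ["A" + DNAA_BOX_CONSENSUS + "C"] * 3 + ["G" + DNAA_BOX_CONSENSUS + "T"]
        pwm = build_pwm(sites, background=np.array([0.3, 0.2, 0.2, 0.3]),
                        name="single_box")
        p = tmp_path / "motif.meme"
        write_meme(pwm, p)
        back = read_meme(p)[0]
        assert back.name == "single_box" and back.width == pwm.width
        np.testing.assert_allclose(back.probs, pwm.probs, atol=1e-5)
        np.testing.assert_allclose(back.background, pwm.background, atol=1e-5)

    def test_multiple_motifs(self, tmp_path):
        s = build_pwm(["A" + DNAA_BOX_CONSENSUS + "C"] * 2, background=UNIFORM)
        d = make_double_pwm(s, spacing=3)
        p = tmp_path / "m.meme"
        write_meme([s, d], p)
        motifs = read_meme(p)
        assert [m.width for m in motifs] == [11, 23]

    def test_missing_motifs_rejected(self, tmp_path):
        p = tmp_path / "empty.meme"
        p.write_text("MEME version 4\n")
        with pytest.raises(ValueError, match="no motifs"):
            read_meme(p)


def test_estimate_background_strand_averaged():
    bg = estimate_background("AAAA", both_strands=True)
    np.testing.assert_allclose(bg, [0.5, 0, 0, 0.5])
    bg1 = estimate_background("AAAA", both_strands=False)
    np.testing.assert_allclose(bg1, [1, 0, 0, 0])
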