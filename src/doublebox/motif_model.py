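"""Single- and double-box PWM models.

Builds a position weight matrix for the single DnaA box from aligned sites or
by de-novo discovery (a seeded expectation-maximization finder in the spirit
of MEME's any-number-of-repetitions mode), and composes double-box PWMs by
tandem concatenation: two box cores separated by 2 bp (plain concatenation of
a width-11 single-box matrix) or 3 bp (concatenation with one background
column inserted between the halves).
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_core import reverse_complement
from .reference import DNAA_BOX_CONSENSUS

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNIFORM_BACKGROUND = np.full(4, 0.25)

CORE_WIDTH = 9  # the DnaA box is a 9-mer


@dataclass
class PWM:
    """Position weight matrix: per-column base probabilities plus background.

    ``probs`` is a (width, 4) array in A,C,G,T order.  ``core_offset`` is the
    0-based start of the 9-mer box core within the motif; ``core_spacing`` is
    set only on double-box PWMs and records the gap (bp) between the two cores.
    """

    probs: np.ndarray
    background: np.ndarray
    core_offset: int = 0
    core_spacing: int | None = None
    name: str = "motif"
    nsites: int = 0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be a (width, 4) matrix")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every PWM column must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def is_double(self) -> bool:
        return self.core_spacing is not None

    def consensus(self) -> str:
        """Highest-probability base per column (ties broken A<C<G<T)."""
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    def information_content(self) -> float:
        """Total information content in bits relative to the background."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.probs * np.log2(self.probs / self.background[None, :])
        return float(np.nansum(terms))

    def reverse_complement(self) -> "PWM":
        rc_probs = self.probs[::-1, ::-1].copy()
        rc_bg = self.background[::-1].copy()
        return PWM(rc_probs, rc_bg, core_offset=self.width - self.core_offset - CORE_WIDTH,
                   core_spacing=self.core_spacing, name=self.name + "_rc",
                   nsites=self.nsites)


@dataclass
class SiteAlignment:
    """Equal-length aligned motif occurrences with their source coordinates."""

    sites: list[str]
    coordinates: list[tuple[int, int, str]] = field(default_factory=list)
    # (window index, 0-based offset in window, strand)

    def __post_init__(self) -> None:
        if self.sites:
            w = len(self.sites[0])
            for s in self.sites:
                if len(s) != w:
                    raise ValueError("ragged alignment")
                if any(c not in BASE_INDEX for c in s):
                    raise ValueError(f"illegal character in site {s!r}")

    @property
    def width(self) -> int:
        return len(self.sites[0]) if self.sites else 0


def count_consensus_matches(site: str, consensus: str = DNAA_BOX_CONSENSUS) -> int:
    """Number of positions at which ``site`` matches the box consensus."""
    site, consensus = site.upper(), consensus.upper()
    if len(site) != len(consensus):
        raise ValueError(
            f"length mismatch: site {len(site)} vs consensus {len(consensus)}"
        )
    return sum(a == b for a, b in zip(site, consensus))


def estimate_background(sequences: list[str] | str,
                        both_strands: bool = True) -> np.ndarray:
    """0-order base frequencies; strand-averaged so A=T and C=G when asked."""
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = np.zeros(4)
    for seq in sequences:
        for b, n in Counter(seq.upper()).items():
            if b in BASE_INDEX:
                counts[BASE_INDEX[b]] += n
    if counts.sum() == 0:
        return UNIFORM_BACKGROUND.copy()
    if both_strands:
        counts = counts + counts[::-1]
    return counts / counts.sum()


def build_pwm(sites: SiteAlignment | list[str], pseudocount: float = 0.1,
              background: np.ndarray | None = None, name: str = "motif") -> PWM:
    """Estimate a PWM from aligned sites.

    probs[i][b] = (count(b at i) + pseudocount * background[b]) / (n + pseudocount);
    the pseudocount mass is distributed by the background composition.  The
    core offset is placed on the 9 contiguous columns of highest information.
    """
    if isinstance(sites, list):
        sites = SiteAlignment(sites=sites)
    n = len(sites.sites)
    if n == 0:
        raise ValueError("empty alignment")
    if n < 2:
        raise ValueError("need at least 2 sites to build a PWM")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    width = sites.width
    counts = np.zeros((width, 4))
    for s in sites.sites:
        for i, c in enumerate(s.upper()):
            counts[i, BASE_INDEX[c]] += 1
    probs = (counts + pseudocount * bg[None, :]) / (n + pseudocount)
    pwm = PWM(probs, bg, name=name, nsites=n)
    pwm.core_offset = _locate_core(pwm)
    return pwm


def _locate_core(pwm: PWM, core_width: int = CORE_WIDTH) -> int:
    """0-based offset of the highest-information contiguous core window."""
    if pwm.width <= core_width:
        return 0
    with np.errstate(divide="ignore", invalid="ignore"):
        col_ic = np.nansum(
            pwm.probs * np.log2(pwm.probs / pwm.background[None, :]), axis=1)
    window_ic = np.convolve(col_ic, np.ones(core_width), mode="valid")
    return int(np.argmax(window_ic))


# ---------------------------------------------------------------------------
# De-novo discovery (seeded EM, any number of repetitions per window)

def _canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return min(kmer, rc)


def _hamming_neighbour_counts(kmers: list[str], radius: int = 2) -> Counter:
    """Occurrence counts smeared over the Hamming ball of each observed k-mer.

    Gives every candidate seed the number of observed occurrences within
    ``radius`` mismatches, so occurrences of a planted motif that differ only
    in flanking positions reinforce a common seed.
    """
    counts: Counter = Counter()
    for kmer in kmers:
        counts[kmer] += 1
        if radius >= 1:
            for i in range(len(kmer)):
                for b in BASES:
                    if b != kmer[i]:
                        counts[kmer[:i] + b + kmer[i + 1:]] += 1
        if radius >= 2:
            for i, j in itertools.combinations(range(len(kmer)), 2):
                for bi in BASES:
                    if bi == kmer[i]:
                        continue
                    for bj in BASES:
                        if bj == kmer[j]:
                            continue
                        counts[kmer[:i] + bi + kmer[i + 1:j] + bj + kmer[j + 1:]] += 1
    return counts


def _seed_pwm(seed: str, background: np.ndarray, match_prob: float = 0.7) -> np.ndarray:
    probs = np.tile((1 - match_prob) / 3, (len(seed), 4))
    for i, c in enumerate(seed):
        probs[i, :] = (1 - match_prob) / 3
        probs[i, BASE_INDEX[c]] = match_prob
    return probs


def discover_motif(windows: list[str], width: int = 11, n_seeds: int = 5,
                   seed: int = 0, pseudocount: float = 0.1,
                   max_iter: int = 200, tol: float = 1e-6,
                   background: np.ndarray | None = None
                   ) -> tuple[PWM, SiteAlignment]:
    """Find the most enriched width-mer motif in a set of sequence windows.

    Candidate seeds are the most over-represented width-mers (both strands,
    occurrences pooled over a 2-mismatch Hamming ball, canonical-orientation
    deduplicated, ties broken lexicographically).  Each seed initializes a
    two-component (motif vs. 0-order background) mixture allowing any number
    of occurrences per window, refined by EM until the information content
    stabilizes.  The refined seed with the largest total information content
    (per-motif information times expected occurrence count) wins.  The
    procedure is deterministic for fixed inputs; ``seed`` is accepted for
    interface uniformity.
    """
    del seed  # no stochastic step: seeding and EM are deterministic
    if len(windows) < 4:
        raise ValueError("need at least 4 windows for motif discovery")
    windows = [w.upper() for w in windows]
    if any(width > len(w) for w in windows):
        raise ValueError("motif width exceeds window length")
    distinct = set("".join(windows)) & set(BASES)
    if len(distinct) <= 1:
        raise ValueError("no informative motif: degenerate input")

    bg = estimate_background(windows) if background is None else np.asarray(background, float)
    bg = np.clip(bg, 1e-6, None)
    bg = bg / bg.sum()

    # candidate sites: every clean width-mer on both strands of every window
    site_kmers: list[str] = []
    site_coords: list[tuple[int, int, str]] = []
    for wi, win in enumerate(windows):
        for off in range(len(win) - width + 1):
            kmer = win[off:off + width]
            if "N" in kmer:
                continue
            site_kmers.append(kmer)
            site_coords.append((wi, off, "+"))
            site_kmers.append(reverse_complement(kmer))
            site_coords.append((wi, off, "-"))
    if not site_kmers:
        raise ValueError("no informative motif: no scorable windows")

    ball_counts = _hamming_neighbour_counts(site_kmers)
    observed = {}
    for kmer in set(site_kmers):
        canon = _canonical(kmer)
        observed[canon] = max(observed.get(canon, 0), ball_counts[kmer],
                              ball_counts.get(reverse_complement(kmer), 0))
    seeds = sorted(observed, key=lambda k: (-observed[k], k))[:n_seeds]

    encoded = np.array([[BASE_INDEX[c] for c in kmer] for kmer in site_kmers])
    log_bg_site = np.log(bg)[encoded].sum(axis=1)

    best = None
    for seed_kmer in seeds:
        probs = _seed_pwm(seed_kmer, bg)
        gamma = 1.0 / max(len(w) for w in windows)
        prev_ic = -np.inf
        for _ in range(max_iter):
            log_motif = np.log(probs)[np.arange(width)[None, :], encoded].sum(axis=1)
            lr = np.exp(np.clip(log_motif - log_bg_site, -500, 500))
            z = gamma * lr / (gamma * lr + (1 - gamma))
            total_z = z.sum()
            counts = np.zeros((width, 4))
            for b in range(4):
                counts[:, b] = (z[:, None] * (encoded == b)).sum(axis=0)
            probs = (counts + pseudocount * bg[None, :]) / (total_z + pseudocount)
            gamma = min(max(total_z / len(site_kmers), 1e-9), 0.5)
            with np.errstate(divide="ignore", invalid="ignore"):
                ic = float(np.nansum(probs * np.log2(probs / bg[None, :])))
            if abs(ic - prev_ic) < tol:
                break
            prev_ic = ic
        objective = ic * total_z
        if (best is None or objective > best[0]
                or (objective == best[0] and seed_kmer < best[1])):
            best = (objective, seed_kmer, probs, z)

    _, _, probs, z = best
    pwm = PWM(probs, bg, name="discovered", nsites=int(round(z.sum())))
    pwm.core_offset = _locate_core(pwm)

    hard = np.flatnonzero(z > 0.5)
    # keep one orientation per genomic site (the better-scoring strand)
    chosen: dict[tuple[int, int], int] = {}
    for idx in hard:
        locus = site_coords[idx][:2]
        if locus not in chosen or z[idx] > z[chosen[locus]]:
            chosen[locus] = idx
    picked = sorted(chosen.values())
    alignment = SiteAlignment(sites=[site_kmers[i] for i in picked],
                              coordinates=[site_coords[i] for i in picked])
    return pwm, alignment


# ---------------------------------------------------------------------------
# Double-box composition

def make_double_pwm(single: PWM, spacing: int) -> PWM:
    """Compose a double-box PWM from a single-box PWM.

    With flank width f = (width - 9) / 2 on each side of the core, plain
    tandem concatenation yields cores 2f bp apart and concatenation with one
    background-distributed spacer column yields 2f+1 bp.  For the canonical
    width-11 single box (f = 1) these are the 2 bp and 3 bp double boxes.
    """
    if single.is_double:
        raise ValueError("input PWM is already a double-box PWM")
    if (single.width - CORE_WIDTH) % 2 != 0 or single.width < CORE_WIDTH:
        raise ValueError(
            f"single PWM width {single.width} has no symmetric flanks around a 9-mer core"
        )
    flank = (single.width - CORE_WIDTH) // 2
    if spacing == 2 * flank:
        probs = np.vstack([single.probs, single.probs])
    elif spacing == 2 * flank + 1:
        probs = np.vstack([single.probs, single.background[None, :], single.probs])
    else:
        raise ValueError(
            f"spacing {spacing} unsupported for flank {flank}: "
            f"supported spacings are {2 * flank} and {2 * flank + 1}"
        )
    return PWM(probs, single.background.copy(), core_offset=flank,
               core_spacing=spacing, name=f"{single.name}_double{spacing}",
               nsites=single.nsites)


# ---------------------------------------------------------------------------
# MEME minimal motif format

def write_meme(pwms: PWM | list[PWM], path: str | Path) -> None:
    """Serialize PWMs in MEME minimal motif format."""
    if isinstance(pwms, PWM):
        pwms = [pwms]
    bg = pwms[0].background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.6f}" for b, p in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= {max(pwm.nsites, 1)} E= 0\n")
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list[PWM]:
    """Parse motifs from a MEME minimal format file."""
    bg = UNIFORM_BACKGROUND.copy()
    pwms: list[PWM] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            bg = np.array([freq.get(b, 0.25) for b in BASES])
            bg = bg / bg.sum()
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1] if len(line.split()) > 1 else f"motif{len(pwms) + 1}"
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                i += 1
            header = lines[i].strip()
            w = int(_meme_field(header, "w"))
            nsites = int(float(_meme_field(header, "nsites", "1")))
            rows = []
            i += 1
            while len(rows) < w:
                toks = lines[i].split()
                rows.append([float(t) for t in toks[:4]])
                i += 1
            probs = np.array(rows)
            probs = probs / probs.sum(axis=1, keepdims=True)
            pwm = PWM(probs, bg.copy(), name=name, nsites=nsites)
            pwm.core_offset = _locate_core(pwm)
            pwms.append(pwm)
            continue
        i += 1
    if not pwms:
        raise ValueError(f"no motifs found in {path}")
    return pwms


def _meme_field(header: str, key: str, default: str | None = None) -> str:
    toks = header.replace("=", "= ").split()
    for j, t in enumerate(toks):
        if t == f"{key}=":
            return toks[j + 1]
    if default is not None:
        return default
    raise ValueError(f"field {key}= missing from {header!r}")
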