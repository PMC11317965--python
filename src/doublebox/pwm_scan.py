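"""Genome scanning against a PWM with exact p-values.

Scores every window on both strands with the log-odds (bits) scoring rule and
converts scores to p-values using the exact distribution of the discretized
score of a background-drawn k-mer, computed by positionwise convolution
(dynamic programming) over per-column score contributions — the same
machinery FIMO uses.  Hits at or below the p-value threshold are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import Genome, reverse_complement
from .motif_model import BASES, BASE_INDEX, PWM, estimate_background

# log-odds of a zero-probability base is clamped here (bits); only reachable
# when a PWM was built with pseudocount 0
MIN_COLUMN_SCORE_BITS = -64.0

_N_SENTINEL = np.int64(-(1 << 40))  # poisons any window containing N


@dataclass
class MotifHit:
    """One scored PWM match on the forward coordinate system.

    ``start`` is the 1-based coordinate of the leftmost matched base on the
    forward strand regardless of hit strand.
    """

    start: int
    strand: str
    matched_sequence: str
    score: float            # log-odds, bits
    p_value: float
    motif_id: str
    rank: int | None = None

    @property
    def end(self) -> int:
        return self.start + len(self.matched_sequence) - 1


class ScoreDistribution:
    """Exact distribution of the discretized background log-odds score.

    Column scores are floored to ``granularity``-bit bins; the distribution
    of the width-column sum under the 0-order background is built by
    convolving columns.  ``tail(bin)`` is P(score >= bin), non-increasing.
    """

    def __init__(self, pwm: PWM, granularity: float = 0.001,
                 background: np.ndarray | None = None) -> None:
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        bg = pwm.background if background is None else np.asarray(background, float)
        bg = bg / bg.sum()
        with np.errstate(divide="ignore"):
            ratio = np.log2(pwm.probs / bg[None, :])
        ratio = np.maximum(ratio, MIN_COLUMN_SCORE_BITS)
        self.granularity = float(granularity)
        self.column_bins = np.floor(ratio / granularity).astype(np.int64)  # (w, 4)
        dist = np.array([1.0])
        cur_min = 0
        for col in range(pwm.width):
            cbins = self.column_bins[col]
            cmin, cmax = int(cbins.min()), int(cbins.max())
            new = np.zeros(len(dist) + (cmax - cmin))
            for b in range(4):
                off = int(cbins[b]) - cmin
                new[off:off + len(dist)] += bg[b] * dist
            dist = new
            cur_min += cmin
        self.min_bin = cur_min
        self.probabilities = dist / dist.sum()
        self.tail = np.cumsum(self.probabilities[::-1])[::-1]

    @property
    def max_bin(self) -> int:
        return self.min_bin + len(self.probabilities) - 1

    def pvalue_of_bin(self, score_bin: int) -> float:
        idx = score_bin - self.min_bin
        if idx < 0:
            return 1.0
        if idx >= len(self.tail):
            return float(self.tail[-1])
        return float(self.tail[idx])

    def pvalue(self, score_bits: float) -> float:
        """P(background score >= score), conservative to one bin."""
        return self.pvalue_of_bin(int(np.floor(score_bits / self.granularity)))

    def threshold_bin(self, p_max: float) -> int | None:
        """Smallest score bin whose tail probability is <= p_max."""
        idx = np.searchsorted(-self.tail, -p_max, side="left")
        if idx >= len(self.tail):
            return None
        return self.min_bin + int(idx)


def log_odds(pwm: PWM, kmer: str) -> float:
    """Log-odds score (bits) of ``kmer`` under ``pwm`` vs. its background."""
    kmer = kmer.upper()
    if len(kmer) != pwm.width:
        raise ValueError(f"kmer length {len(kmer)} != motif width {pwm.width}")
    if "N" in kmer:
        raise ValueError("cannot score a window containing N")
    total = 0.0
    for i, c in enumerate(kmer):
        p = pwm.probs[i, BASE_INDEX[c]]
        b = pwm.background[BASE_INDEX[c]]
        total += max(np.log2(p / b) if p > 0 else -np.inf, MIN_COLUMN_SCORE_BITS)
    return float(total)


def score_distribution(pwm: PWM, granularity: float = 0.001,
                       background: np.ndarray | None = None) -> ScoreDistribution:
    return ScoreDistribution(pwm, granularity=granularity, background=background)


def _encode(sequence: str) -> np.ndarray:
    codes = np.full(len(sequence), 4, dtype=np.int8)  # 4 = N/other
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    for base, idx in BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _window_score_bins(codes: np.ndarray, column_bins: np.ndarray) -> np.ndarray:
    """Discretized score of every window; windows containing N are poisoned."""
    w = column_bins.shape[0]
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64)
    lut = np.hstack([column_bins, np.full((w, 1), _N_SENTINEL)])  # (w, 5)
    scores = np.zeros(n_win, dtype=np.int64)
    for col in range(w):
        scores += lut[col][codes[col:col + n_win]]
    return scores


def scan(genome: Genome, pwm: PWM, p_max: float = 0.0001,
         background: np.ndarray | None = None,
         granularity: float = 0.001) -> list[MotifHit]:
    """Report PWM matches on both strands with p-value <= ``p_max``.

    The background defaults to the strand-averaged 0-order composition of the
    scanned genome; the same background drives both the log-odds scores and
    the exact p-value distribution.  Windows containing N are never scored.
    Output is sorted by start coordinate, then strand (+ before -).
    """
    if pwm.width > genome.length:
        return []
    bg = (estimate_background(genome.sequence, both_strands=True)
          if background is None else np.asarray(background, float))
    bg = bg / bg.sum()
    codes = _encode(genome.sequence)

    hits: list[MotifHit] = []
    for strand, matrix in (("+", pwm), ("-", pwm.reverse_complement())):
        matrix = PWM(matrix.probs, bg, name=pwm.name)
        dist = ScoreDistribution(matrix, granularity=granularity)
        thr = dist.threshold_bin(p_max)
        if thr is None:
            continue
        scores = _window_score_bins(codes, dist.column_bins)
        for pos in np.flatnonzero(scores >= thr):
            window = genome.sequence[pos:pos + pwm.width]
            seq = window if strand == "+" else reverse_complement(window)
            hits.append(MotifHit(
                start=int(pos) + 1,
                strand=strand,
                matched_sequence=seq,
                score=float(scores[pos]) * granularity,
                p_value=dist.pvalue_of_bin(int(scores[pos])),
                motif_id=pwm.name,
            ))
    hits.sort(key=lambda h: (h.start, 0 if h.strand == "+" else 1))
    return hits


def best_local_pvalue(genome: Genome, pwm: PWM, start_lo: int, start_hi: int,
                      background: np.ndarray | None = None,
                      granularity: float = 0.001) -> float:
    """Smallest p-value over both strands for windows starting in a range.

    Evaluates the PWM at every alignment whose leftmost base falls in
    ``[start_lo, start_hi]`` (1-based), e.g. the footprint of a known site,
    and returns the best p-value found.  Windows containing N score 1.0.
    """
    bg = (estimate_background(genome.sequence, both_strands=True)
          if background is None else np.asarray(background, float))
    bg = bg / bg.sum()
    best = 1.0
    for matrix in (pwm, pwm.reverse_complement()):
        matrix = PWM(matrix.probs, bg, name=pwm.name)
        dist = ScoreDistribution(matrix, granularity=granularity)
        for start in range(max(start_lo, 1), start_hi + 1):
            if start + pwm.width - 1 > genome.length:
                continue
            window = genome.sequence[start - 1:start - 1 + pwm.width]
            if "N" in window:
                continue
            bins = int(sum(dist.column_bins[i, BASE_INDEX[c]]
                           for i, c in enumerate(window)))
            best = min(best, dist.pvalue_of_bin(bins))
    return best


def count_exact(genome: Genome, word: str) -> int:
    """Count overlapping occurrences of ``word`` on both strands.

    Forward-strand occurrences of the word plus forward-strand occurrences of
    its reverse complement.
    """
    if not word:
        raise ValueError("word must be non-empty")
    word = word.upper()

    def overlapping(hay: str, needle: str) -> int:
        count = start = 0
        while True:
            i = hay.find(needle, start)
            if i < 0:
                return count
            count += 1
            start = i + 1

    total = overlapping(genome.sequence, word)
    rc = reverse_complement(word)
    total += overlapping(genome.sequence, rc)
    return total
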