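"""Sequence/coordinate primitives and readers/writers for the standard formats.

Coordinate convention: all internal coordinates are 1-based inclusive, so
published genome coordinates can be used verbatim.  Conversion to the 0-based
half-open convention happens only at the BED/bedGraph boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_ILLEGAL_RE = re.compile(r"[^ACGTN]")


@dataclass
class Genome:
    """A single replicon: name, upper-case sequence over {A,C,G,T,N}."""

    name: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        m = _ILLEGAL_RE.search(self.sequence)
        if m:
            raise ValueError(
                f"illegal character {m.group()!r} at position {m.start() + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CoverageTrack:
    """Per-base normalized read depth for one sample.

    ``values[i-1]`` is the depth at 1-based genome position ``i``.
    ``normalization_factor`` is the multiplier that was applied to the raw
    depths (1.0 for unnormalized tracks).
    """

    genome_name: str
    values: np.ndarray
    normalization_factor: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")
        if self.normalization_factor <= 0:
            raise ValueError("normalization_factor must be positive")

    @property
    def length(self) -> int:
        return self.values.size

    def normalized(self, target_sum: float | None = None) -> "CoverageTrack":
        """Rescale so the track sums to ``target_sum`` (default: track length).

        Makes replicate averaging well-defined: every normalized track carries
        the same total library-size mass, so the mean normalized depth is 1.
        """
        if target_sum is None:
            target_sum = float(self.length)
        total = float(self.values.sum())
        if total == 0:
            return CoverageTrack(self.genome_name, self.values.copy(), 1.0)
        factor = target_sum / total
        return CoverageTrack(self.genome_name, self.values * factor,
                             self.normalization_factor * factor)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval with optional strand."""

    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> Genome:
    """Read a single-record FASTA file into a :class:`Genome`.

    Genome input must contain exactly one record; the record name is the
    first whitespace-delimited token of the header.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ValueError(f"multiple records in {path}; expected one genome")
    rec = records[0]
    if len(rec.seq) == 0:
        raise ValueError(f"empty record in {path}")
    return Genome(name=rec.id, sequence=str(rec.seq))


def write_fasta(genome: Genome, path: str | Path, line_width: int = 70) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    del line_width  # SeqIO wraps at 60; parameter kept for API stability


# ---------------------------------------------------------------------------
# Sequence operations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    seq = seq.upper()
    m = _ILLEGAL_RE.search(seq)
    if m:
        raise ValueError(
            f"illegal character {m.group()!r} at position {m.start() + 1}"
        )
    return seq.translate(_COMPLEMENT)[::-1]


def extract_window(genome: Genome, centre: int, width: int,
                   allow_wrap: bool = False) -> str:
    """Extract a ``width``-bp window with ``centre`` at its middle base.

    ``width`` must be odd.  On a circular genome the window may wrap around
    the origin when ``allow_wrap`` is set; on a linear genome (or without
    opting in) an out-of-range window is an error.
    """
    if width % 2 != 1 or width < 1:
        raise ValueError("window width must be odd and positive")
    if not 1 <= centre <= genome.length:
        raise ValueError(f"centre {centre} outside genome of length {genome.length}")
    half = width // 2
    start = centre - half  # 1-based
    end = centre + half
    if start < 1 or end > genome.length:
        if not (genome.circular and allow_wrap):
            raise ValueError(
                f"window [{start}, {end}] out of range on linear genome"
            )
        n = genome.length
        idx = [(p - 1) % n for p in range(start, end + 1)]
        return "".join(genome.sequence[i] for i in idx)
    return genome.sequence[start - 1:end]


# ---------------------------------------------------------------------------
# bedGraph / BED / TSV

def read_bedgraph(path: str | Path, genome_length: int,
                  genome_name: str | None = None) -> CoverageTrack:
    """Expand a bedGraph file to a per-base :class:`CoverageTrack`.

    bedGraph intervals are 0-based half-open; positions absent from the file
    get value 0.  Overlapping intervals, negative values and coordinates
    beyond the genome length are rejected.
    """
    values = np.zeros(genome_length, dtype=float)
    seen_name = genome_name
    covered_until = -1  # exclusive bedGraph end of the previous interval
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if seen_name is None:
                seen_name = chrom
            elif chrom != seen_name:
                raise ValueError(f"{path}:{lineno}: multiple chromosomes not supported")
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage value")
            if start < 0 or end > genome_length or start >= end:
                raise ValueError(f"{path}:{lineno}: interval [{start}, {end}) out of range")
            if start < covered_until:
                raise ValueError(f"{path}:{lineno}: overlapping intervals")
            covered_until = max(covered_until, end)
            values[start:end] = value
    return CoverageTrack(genome_name=seen_name or "genome", values=values)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a per-base track as run-length-compressed bedGraph (zeros omitted)."""
    v = track.values
    with open(path, "w") as fh:
        if v.size:
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [v.size]))
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{track.genome_name}\t{s}\t{e}\t{v[s]:.6g}\n")


def write_bed(intervals: list[GenomicInterval], path: str | Path,
              genome_name: str = "genome", scores: list[float] | None = None) -> None:
    """Write intervals as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for i, iv in enumerate(intervals):
            score = scores[i] if scores is not None else 0
            name = iv.name or f"iv{i + 1}"
            fh.write(f"{genome_name}\t{iv.start - 1}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            start, end = int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(start=start + 1, end=end, strand=strand, name=name))
    return out


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Tab-delimited output with a commented header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, table.columns)) + "\n")
        table.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
        return pd.read_csv(fh, sep="\t", names=header)
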