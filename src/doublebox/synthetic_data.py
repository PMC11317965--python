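"""Synthetic genomes and ChIP/control coverage with planted DnaA boxes.

Plants single boxes (the 9-mer consensus with a chosen number of mismatches)
and double boxes (two 9-mer cores separated by a spacer of 2, 3 or a
perturbed number of bases) at known coordinates in an i.i.d. background
genome, then simulates replicate ChIP and control coverage: negative-binomial
noise everywhere, plus a Gaussian-shaped enrichment bump over each plant in
the ChIP tracks whose height is the plant's strength.  The recorded truth
lets every downstream stage be tested against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (CoverageTrack, Genome, GenomicInterval, reverse_complement,
                      write_bed, write_bedgraph, write_fasta, write_tsv)
from .reference import DNAA_BOX_CONSENSUS

BASES = "ACGT"


@dataclass(frozen=True)
class PlantSpec:
    """One planted site: where, what kind, how degenerate, how enriched.

    ``strength`` is the relative enrichment multiplier used by the coverage
    simulation (bump height = strength x background mean).  For ``single``
    plants only ``mismatches_upstream`` is used; 9 mismatches turn the box
    into an unrelated sequence (an enriched-but-motifless site).
    """

    centre: int
    kind: str  # {"single", "double"}
    strength: float
    spacing: int | None = None  # double only: bp between the two 9-mer cores
    mismatches_upstream: int = 0
    mismatches_downstream: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.kind not in {"single", "double"}:
            raise ValueError(f"unknown plant kind {self.kind!r}")
        if self.kind == "double" and (self.spacing is None or self.spacing < 0):
            raise ValueError("double plants need a non-negative spacing")
        if not 0 <= self.mismatches_upstream <= 9:
            raise ValueError("mismatches_upstream must be in 0..9")
        if not 0 <= self.mismatches_downstream <= 9:
            raise ValueError("mismatches_downstream must be in 0..9")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be + or -")
        if self.strength <= 0:
            raise ValueError("strength must be positive")

    @property
    def footprint(self) -> int:
        if self.kind == "single":
            return 9
        return 9 + int(self.spacing) + 9

    @property
    def start(self) -> int:
        """1-based leftmost coordinate of the planted site."""
        return self.centre - (self.footprint - 1) // 2

    @property
    def end(self) -> int:
        return self.start + self.footprint - 1


@dataclass(frozen=True)
class RealizedPlant:
    """A plant together with the sequence actually embedded in the genome."""

    spec: PlantSpec
    sequence: str  # forward-strand sequence occupying [start, end]

    @property
    def start(self) -> int:
        return self.spec.start

    @property
    def end(self) -> int:
        return self.spec.end


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic genome."""

    plants: list[RealizedPlant]
    seed: int

    def strong(self, min_strength: float) -> list[RealizedPlant]:
        return [p for p in self.plants if p.spec.strength >= min_strength]


def _mutate_box(box: str, n_mismatches: int, rng: np.random.Generator) -> str:
    """Introduce exactly ``n_mismatches`` substitutions at distinct positions."""
    if n_mismatches == 0:
        return box
    positions = rng.choice(len(box), size=n_mismatches, replace=False)
    out = list(box)
    for p in positions:
        alternatives = [b for b in BASES if b != out[p]]
        out[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _realize_site(spec: PlantSpec, rng: np.random.Generator) -> str:
    upstream = _mutate_box(DNAA_BOX_CONSENSUS, spec.mismatches_upstream, rng)
    if spec.kind == "single":
        site = upstream
    else:
        spacer = "".join(BASES[i] for i in rng.integers(4, size=int(spec.spacing)))
        downstream = _mutate_box(DNAA_BOX_CONSENSUS, spec.mismatches_downstream, rng)
        site = upstream + spacer + downstream
    if spec.strand == "-":
        site = reverse_complement(site)
    return site


def generate_genome(length: int, gc_fraction: float, plants: list[PlantSpec],
                    seed: int, name: str = "synthetic") -> tuple[Genome, SyntheticTruth]:
    """Draw an i.i.d. background genome and embed the planted sites.

    Deterministic given ``seed``; plant realization and background use
    separate substreams so adding plants does not reshuffle the background.
    """
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    spans = sorted((p.start, p.end) for p in plants)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping plants at [{s1},{e1}] and [{s2},{e2}]")
    for p in plants:
        if p.start < 1 or p.end > length:
            raise ValueError(f"plant at centre {p.centre} outside genome of length {length}")

    bg_rng = np.random.default_rng([seed, 0])
    probs = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                      gc_fraction / 2, (1 - gc_fraction) / 2])
    seq = np.array(list(BASES))[bg_rng.choice(4, size=length, p=probs)]

    realized: list[RealizedPlant] = []
    for i, spec in enumerate(sorted(plants, key=lambda p: p.centre)):
        plant_rng = np.random.default_rng([seed, 1, i])
        site = _realize_site(spec, plant_rng)
        seq[spec.start - 1:spec.end] = list(site)
        realized.append(RealizedPlant(spec=spec, sequence=site))

    genome = Genome(name=name, sequence="".join(seq))
    return genome, SyntheticTruth(plants=realized, seed=seed)


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray,
                       dispersion: float) -> np.ndarray:
    """NB draw parameterized by mean and dispersion (var = m + d*m^2)."""
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p).astype(float)


def generate_coverage(genome: Genome, truth: SyntheticTruth,
                      background_mean: float = 10.0, dispersion: float = 0.2,
                      peak_width_sd: float = 75.0, replicates: int = 2,
                      seed: int | None = None,
                      ) -> tuple[list[CoverageTrack], list[CoverageTrack]]:
    """Simulate replicate ChIP and control coverage tracks.

    Control tracks are NB noise around ``background_mean``.  ChIP tracks add
    a Gaussian bump of height ``strength * background_mean`` and standard
    deviation ``peak_width_sd`` over every plant.  Tracks are depth-
    normalized so each sums to the genome length (mean normalized depth 1).
    """
    if background_mean <= 0 or dispersion <= 0:
        raise ValueError("background_mean and dispersion must be positive")
    if seed is None:
        seed = truth.seed
    L = genome.length
    enrichment = np.zeros(L)
    positions = np.arange(L)
    for plant in truth.plants:
        c = plant.spec.centre - 1
        lo = max(0, int(c - 5 * peak_width_sd))
        hi = min(L, int(c + 5 * peak_width_sd) + 1)
        x = positions[lo:hi] - c
        enrichment[lo:hi] += plant.spec.strength * np.exp(-x * x / (2 * peak_width_sd ** 2))
    chip_mean = background_mean * (1.0 + enrichment)
    control_mean = np.full(L, background_mean)

    chip_tracks, control_tracks = [], []
    for r in range(replicates):
        chip_rng = np.random.default_rng([seed, 10, r])
        ctrl_rng = np.random.default_rng([seed, 20, r])
        chip = CoverageTrack(genome.name, _negative_binomial(chip_rng, chip_mean, dispersion))
        ctrl = CoverageTrack(genome.name, _negative_binomial(ctrl_rng, control_mean, dispersion))
        chip_tracks.append(chip.normalized())
        control_tracks.append(ctrl.normalized())
    return chip_tracks, control_tracks


# ---------------------------------------------------------------------------
# Fixture profiles

def _strong_roster() -> list[tuple[str, int | None, int, int, str, float]]:
    """(kind, spacing, mm_up, mm_down, strand, strength) for region-forming
    plants: double boxes at 2/3 bp spacing (consensus and one-imperfect-box
    variants) plus one enriched motifless site."""
    return [
        ("double", 3, 0, 0, "+", 10.0),
        ("double", 3, 0, 0, "-", 10.0),
        ("double", 2, 0, 0, "+", 10.0),
        ("double", 2, 0, 0, "-", 10.0),
        ("double", 3, 2, 0, "+", 8.0),
        ("double", 3, 2, 0, "-", 8.0),
        ("double", 3, 2, 0, "+", 8.0),
        ("double", 2, 2, 0, "+", 8.0),
        ("double", 2, 2, 0, "-", 8.0),
        ("double", 3, 0, 2, "+", 6.0),
        ("double", 3, 0, 2, "-", 6.0),
        ("double", 2, 0, 2, "+", 6.0),
        ("single", None, 9, 0, "+", 8.0),   # enriched, no box (dnaN-like)
        ("double", 3, 0, 0, "+", 5.0),
        ("double", 2, 0, 0, "-", 5.0),
    ]


def _weak_roster() -> list[tuple[str, int | None, int, int, str, float]]:
    """Sub-threshold plants: spacing mutants of the purH-like arrangement
    (one 7/9 box, one perfect box, spacer widened to 4 bp), doubly-mutated
    doubles, and unbound single boxes (consensus boxes exist genome-wide
    without ChIP enrichment, as observed in vivo)."""
    return [
        ("double", 4, 2, 0, "+", 1.0),
        ("double", 4, 2, 0, "-", 1.0),
        ("double", 3, 2, 2, "+", 1.0),
        ("double", 3, 2, 2, "-", 1.0),
        ("double", 2, 2, 2, "+", 1.0),
        ("single", None, 0, 0, "+", 1.0),
        ("single", None, 0, 0, "-", 1.0),
        ("single", None, 0, 0, "+", 1.0),
        ("single", None, 1, 0, "+", 1.0),
        ("single", None, 1, 0, "-", 1.0),
        ("single", None, 2, 0, "+", 0.5),
        ("single", None, 2, 0, "-", 0.5),
        ("single", None, 0, 0, "+", 0.5),
        ("single", None, 0, 0, "-", 0.5),
        ("double", 4, 2, 0, "+", 0.5),
    ]


PROFILES = {
    "small": {"length": 50_000, "gc_fraction": 0.5,
              "roster": _strong_roster()[:5] + _weak_roster()[:3]},
    "paper-like": {"length": 500_000, "gc_fraction": 0.5,
                   "roster": _strong_roster() + _weak_roster()},
}


def profile_plants(profile: str, seed: int) -> tuple[int, float, list[PlantSpec]]:
    """Lay out the profile's plant roster at jittered, well-separated centres."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    cfg = PROFILES[profile]
    roster = cfg["roster"]
    length = cfg["length"]
    rng = np.random.default_rng([seed, 2])
    n = len(roster)
    margin = 2_000
    pitch = (length - 2 * margin) / max(n - 1, 1)
    order = rng.permutation(n)
    plants = []
    for slot, idx in enumerate(order):
        kind, spacing, mm_up, mm_down, strand, strength = roster[idx]
        jitter = int(rng.integers(int(-pitch // 4), int(pitch // 4) + 1))
        centre = int(margin + slot * pitch) + jitter
        centre = min(max(centre, margin), length - margin)
        plants.append(PlantSpec(centre=centre, kind=kind, spacing=spacing,
                                mismatches_upstream=mm_up,
                                mismatches_downstream=mm_down,
                                strand=strand, strength=strength))
    return length, cfg["gc_fraction"], plants


@dataclass
class Fixture:
    """A generated dataset, in memory and (optionally) on disk."""

    genome: Genome
    truth: SyntheticTruth
    chip_tracks: list[CoverageTrack]
    control_tracks: list[CoverageTrack]
    paths: dict = field(default_factory=dict)


def make_dataset(profile: str, seed: int, **coverage_kwargs) -> Fixture:
    """Generate a profile dataset in memory."""
    length, gc, plants = profile_plants(profile, seed)
    genome, truth = generate_genome(length, gc, plants, seed=seed)
    chip, ctrl = generate_coverage(genome, truth, **coverage_kwargs)
    return Fixture(genome=genome, truth=truth, chip_tracks=chip, control_tracks=ctrl)


def truth_table(truth: SyntheticTruth) -> pd.DataFrame:
    rows = []
    for p in truth.plants:
        s = p.spec
        rows.append({"centre": s.centre, "start": s.start, "end": s.end,
                     "kind": s.kind, "spacing": s.spacing if s.spacing is not None else "",
                     "mismatches_upstream": s.mismatches_upstream,
                     "mismatches_downstream": s.mismatches_downstream,
                     "strand": s.strand, "strength": s.strength,
                     "sequence": p.sequence})
    return pd.DataFrame(rows)


def make_fixture(profile: str, seed: int, out_dir: str | Path,
                 **coverage_kwargs) -> Fixture:
    """Generate a profile dataset and write it to ``out_dir``.

    Emits genome FASTA, two ChIP and two control bedGraph tracks, and the
    ground truth as BED6 + TSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = make_dataset(profile, seed, **coverage_kwargs)
    paths = {"genome": out / "genome.fa"}
    write_fasta(fx.genome, paths["genome"])
    for label, tracks in (("chip", fx.chip_tracks), ("control", fx.control_tracks)):
        for i, track in enumerate(tracks, 1):
            p = out / f"{label}_{i}.bedgraph"
            write_bedgraph(track, p)
            paths[f"{label}_{i}"] = p
    intervals = [GenomicInterval(start=p.start, end=p.end, strand=p.spec.strand,
                                 name=f"{p.spec.kind}{p.spec.spacing or ''}")
                 for p in fx.truth.plants]
    paths["truth_bed"] = out / "truth.bed"
    write_bed(intervals, paths["truth_bed"], genome_name=fx.genome.name,
              scores=[p.spec.strength for p in fx.truth.plants])
    paths["truth_tsv"] = out / "truth.tsv"
    write_tsv(truth_table(fx.truth), paths["truth_tsv"])
    fx.paths = paths
    return fx
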