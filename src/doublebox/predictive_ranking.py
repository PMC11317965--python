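"""Rank motif hits, associate them with bound regions, build recovery curves.

The predictive-power comparison: hits from one or more scans are pooled and
ranked by score (best first); each bound region is assigned the lowest-rank
hit within 100 bp of its centre; the recovery curve then gives, for every
rank r, how many regions have a hit of rank r or better.  A motif whose
curve rises faster is the better predictor of in-vivo binding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pwm_scan import MotifHit
from .region_caller import BoundRegion


@dataclass
class RegionAssociation:
    """The best-ranked hit near one region (or none)."""

    region: BoundRegion
    best_hit: MotifHit | None = None
    best_rank: int | None = None


@dataclass
class RecoveryCurve:
    """Cumulative recovery of bound regions as a function of hit rank."""

    motif_label: str
    counts: np.ndarray     # counts[r-1] = #regions with best_rank <= r
    n_regions: int

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, len(self.counts) + 1)

    @property
    def fractions(self) -> np.ndarray:
        if self.n_regions == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.n_regions

    def count_at(self, rank: int) -> int:
        """Regions recovered at rank <= ``rank`` (curve extended flat)."""
        if len(self.counts) == 0 or rank < 1:
            return 0
        return int(self.counts[min(rank, len(self.counts)) - 1])

    def rank_reaching(self, fraction: float) -> int | None:
        """Smallest rank at which the curve reaches ``fraction``; None if never."""
        if self.n_regions == 0:
            return None
        needed = fraction * self.n_regions
        idx = np.flatnonzero(self.counts >= needed - 1e-12)
        return int(idx[0]) + 1 if idx.size else None

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"rank": self.ranks, "count": self.counts,
                             "fraction": self.fractions})


def rank_hits(*hit_lists: list[MotifHit]) -> list[MotifHit]:
    """Pool hit lists, deduplicate identical loci, and assign ranks.

    Duplicates share (start, strand, motif_id); the higher-scoring entry is
    kept.  Sorting: score descending, ties by p-value ascending, then start
    ascending, then strand (+ before -).  Ranks are 1..n.
    """
    best: dict[tuple[int, str, str], MotifHit] = {}
    for hits in hit_lists:
        for h in hits:
            key = (h.start, h.strand, h.motif_id)
            if key not in best or h.score > best[key].score:
                best[key] = h
    ranked = sorted(best.values(),
                    key=lambda h: (-h.score, h.p_value, h.start,
                                   0 if h.strand == "+" else 1))
    out = []
    for i, h in enumerate(ranked, 1):
        out.append(MotifHit(start=h.start, strand=h.strand,
                            matched_sequence=h.matched_sequence, score=h.score,
                            p_value=h.p_value, motif_id=h.motif_id, rank=i))
    return out


def _hit_distance(hit: MotifHit, centre: int, reference: str) -> int:
    if reference == "nearest":
        if centre < hit.start:
            return hit.start - centre
        if centre > hit.end:
            return centre - hit.end
        return 0
    if reference == "start":
        return abs(hit.start - centre)
    if reference == "midpoint":
        return abs((hit.start + hit.end) // 2 - centre)
    raise ValueError(f"unknown reference point {reference!r}")


def associate(ranked_hits: list[MotifHit], regions: list[BoundRegion],
              within: float = 100, reference: str = "nearest"
              ) -> list[RegionAssociation]:
    """Assign each region the lowest-rank hit within ``within`` bp of its centre.

    Distance is measured from the hit's nearest base (configurable to the
    hit start or midpoint).  Regions with no eligible hit get none.
    """
    if any(h.rank is None for h in ranked_hits):
        raise ValueError("hits must be ranked first")
    associations = []
    for region in regions:
        best = None
        for h in ranked_hits:
            if _hit_distance(h, region.centre, reference) <= within:
                if best is None or h.rank < best.rank:
                    best = h
        associations.append(RegionAssociation(
            region=region, best_hit=best,
            best_rank=best.rank if best else None))
    return associations


def recovery_curve(associations: list[RegionAssociation], n_total_hits: int,
                   motif_label: str = "motif") -> RecoveryCurve:
    """Cumulative count of regions recovered at each rank 1..n_total_hits."""
    best_ranks = np.sort([a.best_rank for a in associations
                          if a.best_rank is not None])
    ranks = np.arange(1, n_total_hits + 1)
    counts = np.searchsorted(best_ranks, ranks, side="right")
    return RecoveryCurve(motif_label=motif_label, counts=counts,
                         n_regions=len(associations))


def compare_motifs(curve_a: RecoveryCurve, curve_b: RecoveryCurve,
                   rank_cap: int | None = None) -> dict:
    """Summarize two recovery curves over the same region set.

    Reports the rank at which each curve reaches 50/80/100 % recovery, the
    per-rank difference (b - a) up to ``rank_cap`` (default: longer curve,
    shorter curve extended flat), the area between the curves, and whether
    ``curve_b`` dominates (is >= at every rank).
    """
    if curve_a.n_regions != curve_b.n_regions:
        raise ValueError("curves cover different region sets")
    if rank_cap is None:
        rank_cap = max(len(curve_a.counts), len(curve_b.counts))
    a = np.array([curve_a.count_at(r) for r in range(1, rank_cap + 1)])
    b = np.array([curve_b.count_at(r) for r in range(1, rank_cap + 1)])
    diff = b - a
    summary = {
        "n_regions": curve_a.n_regions,
        "labels": (curve_a.motif_label, curve_b.motif_label),
        "area_between": float(diff.sum()),
        "b_dominates": bool(np.all(diff >= 0)),
        "max_abs_difference": int(np.max(np.abs(diff))) if rank_cap else 0,
    }
    for frac, tag in ((0.5, "50"), (0.8, "80"), (1.0, "100")):
        summary[f"rank{tag}_{curve_a.motif_label}"] = curve_a.rank_reaching(frac)
        summary[f"rank{tag}_{curve_b.motif_label}"] = curve_b.rank_reaching(frac)
    return summary


def hits_table(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "motif_id": h.motif_id, "start": h.start, "stop": h.end,
        "strand": h.strand, "score": h.score, "p_value": h.p_value,
        "matched_sequence": h.matched_sequence,
        "rank": h.rank if h.rank is not None else "",
    } for h in hits])


def associations_table(associations: list[RegionAssociation]) -> pd.DataFrame:
    rows = []
    for a in associations:
        rows.append({
            "region_centre": a.region.centre,
            "label": a.region.label,
            "relative_coverage": a.region.relative_coverage,
            "best_rank": a.best_rank if a.best_rank is not None else "",
            "best_hit_start": a.best_hit.start if a.best_hit else "",
            "best_hit_strand": a.best_hit.strand if a.best_hit else "",
            "best_hit_score": a.best_hit.score if a.best_hit else "",
        })
    return pd.DataFrame(rows)


def plot_curves(curves: list[RecoveryCurve], path: str, rank_cap: int = 200) -> None:
    """Draw cumulative recovery curves (rank vs. regions recovered)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for curve in curves:
        r = np.arange(1, rank_cap + 1)
        ax.step(r, [curve.count_at(x) for x in r], where="post",
                label=curve.motif_label)
    ax.set_xlabel("rank of genomic region")
    ax.set_ylabel("DnaA-bound regions recovered")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
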