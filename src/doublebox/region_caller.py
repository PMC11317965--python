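"""Call DnaA-bound regions from replicate ChIP/control coverage.

Pipeline: detect point peaks in the smoothed ChIP/control ratio (or accept a
user-supplied peak list), single-linkage merge peaks closer than 100 bp into
candidate bound regions, score each region as the mean normalized ChIP
coverage over a 201 bp window centred on the region centre divided by the
same quantity for the control, and discard regions scoring below 3 or lying
in excluded (e.g. repetitive) intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .io_core import CoverageTrack, GenomicInterval


@dataclass(frozen=True)
class Peak:
    """A point-location ChIP-seq peak."""

    position: int  # 1-based
    source: str = "detected"


@dataclass
class BoundRegion:
    """A called DnaA-bound locus."""

    centre: int
    member_peaks: list[Peak]
    relative_coverage: float | None = None
    label: str = ""
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if not self.member_peaks:
            raise ValueError("a region needs at least one member peak")
        self.member_peaks = sorted(self.member_peaks, key=lambda p: p.position)


def _mean_track(tracks: list[CoverageTrack]) -> np.ndarray:
    if not tracks:
        raise ValueError("need at least one track")
    lengths = {t.length for t in tracks}
    if len(lengths) != 1:
        raise ValueError("tracks have differing lengths")
    return np.mean([t.values for t in tracks], axis=0)


def detect_peaks(chip_tracks: list[CoverageTrack],
                 control_tracks: list[CoverageTrack],
                 min_fold: float = 2.5, min_separation: int = 100,
                 smooth_sd: float = 50.0,
                 pseudocount: float = 0.25) -> list[Peak]:
    """Local maxima of smoothed ChIP/control ratio exceeding ``min_fold``.

    A simple stand-in peak detector: the replicate-averaged tracks are
    Gaussian-smoothed, their ratio (with a pseudocount in the denominator)
    thresholded at ``min_fold``, and maxima thinned so no two retained peaks
    are closer than ``min_separation`` bp (higher peaks win).  Deterministic.
    """
    if min_fold <= 1:
        raise ValueError("min_fold must exceed 1")
    chip = gaussian_filter1d(_mean_track(chip_tracks), smooth_sd)
    control = gaussian_filter1d(_mean_track(control_tracks), smooth_sd)
    ratio = chip / (control + pseudocount)
    idx, _ = find_peaks(ratio, height=min_fold, distance=max(min_separation, 1))
    return [Peak(position=int(i) + 1) for i in idx]


def aggregate_peaks(peaks: list[Peak], max_gap: int = 100) -> list[BoundRegion]:
    """Single-linkage merge of peaks closer than ``max_gap`` (strict).

    The region centre is the midpoint of the first and last member peak,
    rounded half up.  Returns unscored regions.
    """
    if not peaks:
        return []
    peaks = sorted(peaks, key=lambda p: p.position)
    regions: list[BoundRegion] = []
    members = [peaks[0]]
    for peak in peaks[1:]:
        if peak.position - members[-1].position < max_gap:
            members.append(peak)
        else:
            regions.append(_close_region(members))
            members = [peak]
    regions.append(_close_region(members))
    return regions


def _close_region(members: list[Peak]) -> BoundRegion:
    first, last = members[0].position, members[-1].position
    centre = (first + last + 1) // 2  # round half up
    return BoundRegion(centre=centre, member_peaks=list(members))


def score_region(region: BoundRegion, chip_tracks: list[CoverageTrack],
                 control_tracks: list[CoverageTrack], window: int = 201,
                 pseudocount: float = 0.25) -> BoundRegion:
    """Coverage relative to control over a ``window``-bp window at the centre.

    Mean of the replicate-averaged normalized ChIP coverage over the window,
    divided by the same quantity for the control plus a small pseudocount
    (guards against zero control coverage).
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    chip = _mean_track(chip_tracks)
    control = _mean_track(control_tracks)
    half = window // 2
    lo = region.centre - half - 1  # 0-based inclusive
    hi = region.centre + half      # 0-based exclusive
    if lo < 0 or hi > len(chip):
        raise ValueError(f"window around centre {region.centre} out of range")
    chip_mean = float(chip[lo:hi].mean())
    control_mean = float(control[lo:hi].mean())
    region.relative_coverage = chip_mean / (control_mean + pseudocount)
    return region


def filter_regions(regions: list[BoundRegion], min_ratio: float = 3.0,
                   exclusion: list[GenomicInterval] = ()) -> list[BoundRegion]:
    """Flag regions below ``min_ratio`` (strict) or inside excluded intervals.

    All regions are returned; dropped ones carry ``excluded=True`` with a
    reason.  A ratio exactly equal to ``min_ratio`` is retained.
    """
    out = []
    for region in regions:
        if region.relative_coverage is None:
            raise ValueError("regions must be scored before filtering")
        if region.relative_coverage < min_ratio:
            region.excluded = True
            region.exclusion_reason = (
                f"relative coverage {region.relative_coverage:.3g} < {min_ratio:g}")
        else:
            for iv in exclusion:
                if iv.contains(region.centre):
                    region.excluded = True
                    region.exclusion_reason = (
                        f"centre in excluded interval [{iv.start}, {iv.end}]"
                        + (f" ({iv.name})" if iv.name else ""))
                    break
        out.append(region)
    return out


def retained(regions: list[BoundRegion]) -> list[BoundRegion]:
    return [r for r in regions if not r.excluded]
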