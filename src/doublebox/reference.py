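"""Curated reference data for the E. coli MG1655 DnaA system.

The DnaA box consensus and the ChIP-seq-derived table of DnaA-bound regions
(NC_000913.2 coordinates, associated locus, coverage relative to control, and
the mixed-case double-box annotation: upper-case bases are the two 9-mer box
cores, lower-case bases are flanks and the inter-box spacer).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

DNAA_BOX_CONSENSUS = "TTATCCACA"

_ANNOT_RE = re.compile(r"^[acgt]*([ACGT]{9})([acgt]+)([ACGT]{9})[acgt]*$")


@dataclass(frozen=True)
class DoubleBoxAnnotation:
    """A parsed double DnaA box: two 9-mer cores and the spacer between them."""

    upstream_box: str
    spacer: str
    downstream_box: str

    @property
    def spacing(self) -> int:
        """Number of base pairs between the two 9-mer cores."""
        return len(self.spacer)


def parse_double_box(annotation: str) -> DoubleBoxAnnotation:
    """Parse a mixed-case double-box string (cores upper-case, spacer lower).

    Example: ``tTTACGCACAgagTTATCCACAa`` -> boxes TTACGCACA / TTATCCACA
    separated by a 3 bp spacer.
    """
    m = _ANNOT_RE.match(annotation)
    if m is None:
        raise ValueError(f"not a double-box annotation: {annotation!r}")
    return DoubleBoxAnnotation(upstream_box=m.group(1),
                               spacer=m.group(2).upper(),
                               downstream_box=m.group(3))


@dataclass(frozen=True)
class KnownBoundRegion:
    """One ChIP-seq DnaA-bound region of E. coli MG1655."""

    coordinate: int           # NC_000913.2, 1-based
    locus: str
    relative_coverage: float  # ChIP coverage / control coverage, 201 bp window
    double_box: str | None    # mixed-case annotation; None if no double box found


KNOWN_BOUND_REGIONS: tuple[KnownBoundRegion, ...] = (
    KnownBoundRegion(813331, "DARS1", 16, "cTAATACACAtggTTATCCACAg"),
    KnownBoundRegion(1144772, "rne", 5, "tTTATCACCCgcTTACTCACAg"),
    KnownBoundRegion(2344805, "nrdA", 14, "gTTATCCACAaagTTATGCACTt"),
    KnownBoundRegion(2969124, "DARS2", 78, "gTTCTTCACAactCTATCCACAg"),
    KnownBoundRegion(2969306, "DARS2", 199, "gTTCTTCACAactCTATCCACAg"),
    KnownBoundRegion(2969501, "DARS2", 213, "tCTTACACCAtgTTATCCACAg"),
    KnownBoundRegion(3600944, "rpoH", 4, "tTTATCCACAagTTCAATGCAa"),
    KnownBoundRegion(3882238, "dnaN", 5, None),
    KnownBoundRegion(3883968, "dnaA", 5, "tTTATCCACAggaCTTTCCAGAa"),
    KnownBoundRegion(3925806, "oriC", 218, "cTTCCTGACAgagTTATCCACAg"),
    KnownBoundRegion(3925943, "oriC", 174, "cTTCCTGACAgagTTATCCACAg"),
    KnownBoundRegion(3926498, "mioC", 25, "tTTAATCCCAtacTTTTCCACAg"),
    KnownBoundRegion(4046831, "polA", 123, "tTTATGCACAaagTTATCCACAt"),
    KnownBoundRegion(4207740, "purH", 124, "tTTACGCACAgagTTATCCACAa"),
    KnownBoundRegion(4392740, "datA", 213, "cTTGTAAACAgagTTATCCACAg"),
    KnownBoundRegion(4462739, "nrdD", 62, "tTTAAGAACAggTTATCCACAg"),
)
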