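"""Mapping short Y-linked markers and testing their MSY enrichment.

Sex-linked markers from a related species are short (tens of bp).  Each
is searched near-exactly against both strands of the genome; markers with
one genomic location are informative, and the question is whether those
unique locations co-locate with the detected male-specific region more
often than chance.  Chance is modelled by a 2x2 contingency table of
unique hits inside/outside the MSY against the genomic extent (in
coverage bins) inside/outside, tested with a two-sided Fisher exact test.
The length-proportional bin background is an explicit modelling choice —
markers could also be tested against gene counts or raw bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .coverage import DEFAULT_BIN_SIZE, MsyCall

__all__ = ["MarkerHit", "EnrichmentResult", "map_markers", "fisher_exact", "msy_enrichment"]

logger = logging.getLogger(__name__)

_BASE_ORD = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class MarkerHit:
    """Mapping outcome for one marker sequence."""

    marker_id: str
    length: int
    status: str  # unique | multi | unmapped
    locations: list[tuple[str, int, int]]  # (chrom, start, end), 0-based half-open

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("marker length must be positive")
        if self.status == "unique" and len(self.locations) != 1:
            raise ValueError("unique hit must have exactly one location")


@dataclass
class EnrichmentResult:
    table: list[list[int]]  # [[hits_in, hits_out], [units_in, units_out]]
    p_value: float
    unit: str
    n_unique: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def map_markers(
    markers: dict[str, str],
    genome: dict[str, str],
    max_mismatch_rate: float = 0.05,
) -> list[MarkerHit]:
    """Find all near-exact occurrences of each marker, both strands.

    A placement qualifies when its mismatch count is at most
    ``floor(max_mismatch_rate * length)``.  Overlapping forward/reverse
    placements at the same interval are merged; 0 placements => unmapped,
    1 => unique, >=2 => multi.
    """
    if not markers:
        raise ValueError("no marker sequences supplied")
    enc_genome = {c: _encode(s) for c, s in genome.items()}
    hits = []
    for mid in sorted(markers):
        seq = markers[mid].upper()
        L = len(seq)
        max_mm = int(max_mismatch_rate * L)
        locations: set[tuple[str, int, int]] = set()
        for strand_seq in (seq, seq.translate(_COMP)[::-1]):
            m = _encode(strand_seq)
            for chrom, g in enc_genome.items():
                n = len(g) - L + 1
                if n <= 0:
                    continue
                mismatches = np.zeros(n, dtype=np.int32)
                for j in range(L):
                    mismatches += g[j : j + n] != m[j]
                for pos in np.flatnonzero(mismatches <= max_mm):
                    locations.add((chrom, int(pos), int(pos) + L))
        locs = sorted(locations)
        status = "unmapped" if not locs else ("unique" if len(locs) == 1 else "multi")
        hits.append(MarkerHit(marker_id=mid, length=L, status=status, locations=locs))
    return hits


def fisher_exact(table: list[list[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    p is the sum of hypergeometric probabilities, at fixed margins, of
    every table as or less probable than the observed one (with a small
    relative tolerance on the comparison, as in R's fisher.test).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    row1, col1 = a + b, a + c
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    include = pmf <= p_obs * (1 + 1e-7)
    if include.all():
        return 1.0  # observed table is modal; every table is as/less probable
    return min(float(pmf[include].sum()), 1.0)


def msy_enrichment(
    hits: list[MarkerHit],
    msy: MsyCall,
    chrom_lengths: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    unit: str = "bin",
) -> EnrichmentResult:
    """Fisher test of unique marker hits inside vs outside the MSY call.

    Background units are coverage bins (``unit="bin"``, the scan's own
    resolution) or base pairs (``unit="bp"``); either way the second row
    of the table is the genomic extent inside/outside the MSY.
    """
    unique = [h for h in hits if h.status == "unique"]
    if not unique:
        raise ValueError("no unique marker hits to test")
    in_msy = out_msy = 0
    for h in unique:
        chrom, start, end = h.locations[0]
        if chrom == msy.chrom and start >= msy.start and end <= msy.end:
            in_msy += 1
        else:
            out_msy += 1
    if unit == "bin":
        total_units = sum(-(-length // bin_size) for length in chrom_lengths.values())
        units_in = -(-(msy.end - msy.start) // bin_size)
    elif unit == "bp":
        total_units = sum(chrom_lengths.values())
        units_in = msy.end - msy.start
    else:
        raise ValueError("unit must be 'bin' or 'bp'")
    table = [[in_msy, out_msy], [units_in, total_units - units_in]]
    return EnrichmentResult(
        table=table,
        p_value=fisher_exact(table),
        unit=unit,
        n_unique=len(unique),
    )
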