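"""Binned sexed read-depth profiles and half-coverage (MSY) segmentation.

A male-specific Y region is hemizygous: males carry one copy where
females carry two, so after per-sex depth normalization the male:female
ratio drops to ~0.5 over the region and stays at ~1.0 elsewhere.  The
scan bins depth along each chromosome (default 100 kb bins), normalizes
each sex by its genome-wide median bin depth, and reports maximal runs
of bins whose normalized ratio sits in a band around 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CoverageProfile", "MsyCall", "bin_depth", "build_profiles", "detect_half_coverage"]

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 100_000
DEFAULT_BAND = (0.35, 0.65)


@dataclass
class CoverageProfile:
    """Per-bin male and female depth along one chromosome.

    Bins are 0-based half-open and tile the chromosome; the last bin may
    be short.  ``ratio`` is (male/median_male) / (female/median_female),
    NaN where the female depth is zero (hemizygosity is undefined there).
    """

    chrom: str
    bin_size: int
    length: int
    male_depth: np.ndarray
    female_depth: np.ndarray
    ratio: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_bins(self) -> int:
        return len(self.male_depth)

    def bin_bounds(self, i: int) -> tuple[int, int]:
        return i * self.bin_size, min((i + 1) * self.bin_size, self.length)

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(self.n_bins) * self.bin_size
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": starts,
                "end": np.minimum(starts + self.bin_size, self.length),
                "male_depth": self.male_depth,
                "female_depth": self.female_depth,
                "ratio": self.ratio,
            }
        )


@dataclass
class MsyCall:
    """A detected half-coverage segment."""

    chrom: str
    start: int
    end: int
    mean_ratio: float
    n_bins: int
    n_gametologs: int | None = None


def _per_base_depth(reads: pd.DataFrame, length: int) -> np.ndarray:
    diff = np.zeros(length + 1, dtype=np.float64)
    starts = np.clip(reads["start"].to_numpy(dtype=np.int64), 0, length)
    ends = np.clip(reads["end"].to_numpy(dtype=np.int64), 0, length)
    np.add.at(diff, starts, 1.0)
    np.add.at(diff, ends, -1.0)
    return np.cumsum(diff[:-1])


def bin_depth(reads: pd.DataFrame, length: int, bin_size: int = DEFAULT_BIN_SIZE) -> np.ndarray:
    """Mean depth per bin: read-base overlap divided by the bin width."""
    if length <= 0 or bin_size <= 0:
        raise ValueError("length and bin_size must be positive")
    depth = _per_base_depth(reads, length)
    n_bins = -(-length // bin_size)
    padded = np.zeros(n_bins * bin_size)
    padded[:length] = depth
    sums = padded.reshape(n_bins, bin_size).sum(axis=1)
    widths = np.full(n_bins, bin_size, dtype=float)
    widths[-1] = length - (n_bins - 1) * bin_size
    return sums / widths


def build_profiles(
    male_reads: pd.DataFrame,
    female_reads: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> list[CoverageProfile]:
    """Bin both sexes over every chromosome and attach normalized ratios.

    Normalization divides each sex by its median bin depth across the
    whole genome, making calls invariant to global sequencing-effort
    differences between the libraries.
    """
    profiles = []
    for chrom, length in chrom_lengths.items():
        m = bin_depth(male_reads[male_reads["chrom"] == chrom], length, bin_size)
        f = bin_depth(female_reads[female_reads["chrom"] == chrom], length, bin_size)
        profiles.append(CoverageProfile(chrom, bin_size, length, m, f))
    med_m = float(np.median(np.concatenate([p.male_depth for p in profiles])))
    med_f = float(np.median(np.concatenate([p.female_depth for p in profiles])))
    for p in profiles:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            norm_m = p.male_depth / med_m if med_m > 0 else np.full(p.n_bins, np.nan)
            norm_f = p.female_depth / med_f if med_f > 0 else np.full(p.n_bins, np.nan)
            ratio = norm_m / norm_f
        ratio[p.female_depth == 0] = np.nan
        p.ratio = ratio
    return profiles


def detect_half_coverage(
    profile: CoverageProfile,
    band: tuple[float, float] = DEFAULT_BAND,
    min_bins: int = 3,
    max_gap: int = 1,
) -> list[MsyCall]:
    """Segment maximal runs of in-band bins into MSY calls.

    Runs of consecutive bins with ratio inside ``band`` are merged across
    at most ``max_gap`` interior off-band (or ratio-undefined) bins, and
    reported when they contain at least ``min_bins`` in-band bins.
    Autosomal background (ratio near 1) is never called.
    """
    if profile.n_bins < min_bins:
        raise ValueError(f"profile has {profile.n_bins} bins; need >= {min_bins}")
    ratio = profile.ratio
    if np.all(profile.female_depth == 0):
        warnings.warn(f"{profile.chrom}: female depth is zero everywhere; no calls possible")
        return []
    lo, hi = band
    inband = np.flatnonzero((ratio >= lo) & (ratio <= hi))
    if inband.size == 0:
        return []
    # group in-band bins, bridging interior gaps of <= max_gap bins
    groups: list[list[int]] = [[int(inband[0])]]
    for b in inband[1:]:
        if b - groups[-1][-1] - 1 <= max_gap:
            groups[-1].append(int(b))
        else:
            groups.append([int(b)])
    calls = []
    for g in groups:
        if len(g) < min_bins:
            continue
        start = g[0] * profile.bin_size
        end = min((g[-1] + 1) * profile.bin_size, profile.length)
        mean_ratio = float(np.nanmean(ratio[g[0] : g[-1] + 1]))
        calls.append(MsyCall(profile.chrom, start, end, mean_ratio, len(g)))
    return calls
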