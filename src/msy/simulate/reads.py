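"""Sexed read simulation: uniform-coverage, error-free by default.

Females sample reads from two copies of the X haplotype; males from one
X and one Y copy.  Because the Y haplotype is heavily diverged inside
the MSY, male reads drawn there cannot be placed on the X-coordinate
reference — which is exactly what produces the half-coverage signal the
scan looks for.  The placement table emitted alongside the FASTQ
emulates a strict (near-exact) aligner: every read is placed at its true
origin except male Y-haplotype reads overlapping the MSY.

Read names encode the simulation truth:
``<sex>_<kind>_<haplotype>_<chrom>_<start>_<serial>``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..subtraction import revcomp
from .genome import SimulatedGenome

__all__ = ["simulate_reads", "simulate_placed_reads"]

_QUAL = "I"


def _mutate_read(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    for pos in np.flatnonzero(rng.random(len(arr)) < error_rate):
        arr[pos] = "ACGT"[("ACGT".index(arr[pos]) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


def _reads_from_sequence(
    label: str,
    seq: str,
    n_reads: int,
    read_length: int,
    error_rate: float,
    rng: np.random.Generator,
    serial_start: int,
) -> list[tuple[str, int, str]]:
    """(title, start, read sequence) tuples with uniform start positions."""
    starts = rng.integers(0, len(seq) - read_length + 1, size=n_reads)
    flips = rng.random(n_reads) < 0.5
    out = []
    for i, (start, flip) in enumerate(zip(starts, flips)):
        r = seq[start : start + read_length]
        r = _mutate_read(r, error_rate, rng)
        if flip:
            r = revcomp(r)
        out.append((f"{label}_{start}_{serial_start + i}", int(start), r))
    return out


def simulate_reads(
    genome: SimulatedGenome,
    sex: str,
    kind: str,
    depth: float,
    read_length: int = 100,
    seed: int = 0,
    error_rate: float = 0.0,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame | None]:
    """Simulate one sexed library at ``depth``-fold coverage.

    DNA libraries sample the two haplotypes of the given sex at half the
    total depth each and return a placement table (chrom, start, end) for
    the reads a strict aligner would place on the X-coordinate reference.
    RNA libraries sample each of the sex's transcripts at ``depth``-fold
    and return no placement table.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    if kind not in ("DNA", "RNA"):
        raise ValueError(f"unknown kind {kind!r}")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    spec = genome.spec
    reads: list[tuple[str, str, str]] = []
    qual = _QUAL * read_length

    if kind == "RNA":
        transcripts = genome.female_transcriptome if sex == "female" else genome.male_transcripts
        short = min(len(s) for s in transcripts.values())
        if read_length > short:
            raise ValueError(f"read_length {read_length} exceeds shortest transcript ({short})")
        for tid in transcripts:
            seq = transcripts[tid]
            n = max(1, round(depth * len(seq) / read_length))
            for title, _start, r in _reads_from_sequence(
                f"{sex}_RNA_T_{tid}", seq, n, read_length, error_rate, rng, 0
            ):
                reads.append((title, r, qual))
        return reads, None

    short = min(spec.chrom_lengths.values())
    if read_length > short:
        raise ValueError(f"read_length {read_length} exceeds shortest chromosome ({short})")
    haplotypes = (
        [("X1", genome.x_haplotype), ("X2", genome.x_haplotype)]
        if sex == "female"
        else [("X1", genome.x_haplotype), ("Y", genome.y_haplotype)]
    )
    msy_start, msy_end = spec.msy_interval
    placement_rows = []
    for hap_name, hap in haplotypes:
        for chrom, seq in hap.items():
            n = round((depth / 2.0) * len(seq) / read_length)
            for title, start, r in _reads_from_sequence(
                f"{sex}_DNA_{hap_name}_{chrom}", seq, n, read_length, error_rate, rng, 0
            ):
                reads.append((title, r, qual))
                in_msy = (
                    hap_name == "Y"
                    and chrom == spec.msy_chrom
                    and start < msy_end
                    and start + read_length > msy_start
                )
                if not in_msy:
                    placement_rows.append((chrom, start, start + read_length))
    placement = pd.DataFrame(placement_rows, columns=["chrom", "start", "end"])
    return reads, placement


def simulate_placed_reads(
    chrom_lengths: dict[str, int],
    sex: str,
    depth: float = 20.0,
    read_length: int = 100,
    msy_chrom: str | None = None,
    msy_interval: tuple[int, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Placement table only (no sequences) — the fast path for coverage scans.

    Equivalent to the placement output of :func:`simulate_reads` for a
    genome whose MSY is at ``msy_interval``: male Y-haplotype reads
    overlapping the interval are unplaceable and dropped.  With
    ``msy_interval=None`` the genome has no MSY (specificity control).
    """
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for hap in range(2):
        is_y = sex == "male" and hap == 1
        for chrom, length in chrom_lengths.items():
            n = round((depth / 2.0) * length / read_length)
            starts = rng.integers(0, length - read_length + 1, size=n)
            if is_y and msy_interval is not None and chrom == msy_chrom:
                lo, hi = msy_interval
                keep = (starts + read_length <= lo) | (starts >= hi)
                starts = starts[keep]
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": starts + read_length}
                )
            )
    return pd.concat(rows, ignore_index=True)
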