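"""Diploid genome with a planted male-specific region of known age.

The genome comes as two haplotypes over the same coordinate system:

* the X haplotype — what females carry in two copies;
* the Y haplotype — identical to X everywhere except inside the planted
  MSY interval, where it carries (a) Y gametolog copies of the genes
  annotated there, diverged from their X copies under the synonymous
  clock, and (b) Y-specific genes with no X counterpart at all
  (Y-acquired content), whose sequence is novel.

Gametologs exercise the pairing/dating stages; the Y-specific genes
exercise the subtraction stage, whose any-shared-k-mer filter cannot by
construction retain reads from regions conserved over a whole k-mer
between X and Y.  Truth files (MSY BED, gene table, marker table) are
emitted alongside and always derived from the same sequences.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .. import io as msy_io
from ..clock import codon_string
from .gametologs import ClockSimSpec, simulate_gametolog_pair

__all__ = ["GenomeSpec", "SimulatedGenome", "simulate_genome"]

_TAIL_RESERVE = 20_000  # intergenic tail kept gene-free for marker duplications


@dataclass(frozen=True)
class GenomeSpec:
    """Everything needed to simulate the genome, with its planted truth."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 500_000, "chr5": 1_000_000}
    )
    msy_chrom: str = "chr5"
    msy_interval: tuple[int, int] = (400_000, 700_000)
    n_gametolog_genes: int = 14
    n_y_specific_genes: int = 6
    n_autosomal_genes: int = 16
    gene_length_codons: int = 300
    gc_content: float = 0.42
    clock: ClockSimSpec = field(default_factory=lambda: ClockSimSpec(true_age=116.0))
    n_markers_in_msy: int = 4
    n_markers_outside: int = 1
    n_markers_multi: int = 2
    n_markers_unmapped: int = 2
    marker_length_range: tuple[int, int] = (17, 70)
    seed: int = 0

    def __post_init__(self):
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("all chromosome lengths must be positive")
        if self.msy_chrom not in self.chrom_lengths:
            raise ValueError(f"msy_chrom {self.msy_chrom!r} not in chrom_lengths")
        start, end = self.msy_interval
        if not (0 <= start < end <= self.chrom_lengths[self.msy_chrom]):
            raise ValueError(
                f"msy_interval {self.msy_interval} invalid or empty on "
                f"{self.msy_chrom} (length {self.chrom_lengths[self.msy_chrom]})"
            )
        if self.n_gametolog_genes < 1:
            raise ValueError("n_gametolog_genes must be >= 1")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")


@dataclass
class SimulatedGenome:
    """The simulated sequences plus every planted-truth annotation."""

    spec: GenomeSpec
    x_haplotype: dict[str, str]
    y_haplotype: dict[str, str]
    genes: pd.DataFrame  # gene_id, chrom, start, end, haplotype, kind
    female_transcriptome: dict[str, str]
    male_transcripts: dict[str, str]
    x_cds: dict[str, str]  # gene -> X gametolog CDS
    y_cds: dict[str, str]  # gene -> Y gametolog CDS
    orthologs: dict[str, dict[str, str]]  # gene -> taxon -> CDS (X, Y + outgroups)
    y_specific: dict[str, str]
    markers: dict[str, str]
    marker_truth: pd.DataFrame  # marker_id, planted_status

    @property
    def msy_truth(self) -> tuple[str, int, int]:
        return (self.spec.msy_chrom, *self.spec.msy_interval)

    def annotation(self) -> pd.DataFrame:
        """gene_id -> X-coordinate location table (for synteny checks)."""
        ann = self.genes[self.genes["haplotype"] == "X"]
        return ann[["gene_id", "chrom", "start", "end"]].reset_index(drop=True)

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        msy_io.write_fasta(self.x_haplotype, os.path.join(outdir, "genome_X.fa"))
        msy_io.write_fasta(self.y_haplotype, os.path.join(outdir, "genome_Y.fa"))
        msy_io.write_fasta(
            self.female_transcriptome, os.path.join(outdir, "female_transcriptome.fa")
        )
        msy_io.write_fasta(self.male_transcripts, os.path.join(outdir, "male_transcripts.fa"))
        msy_io.write_fasta(self.y_cds, os.path.join(outdir, "y_cds.fa"))
        msy_io.write_fasta(self.x_cds, os.path.join(outdir, "x_cds.fa"))
        msy_io.write_fasta(self.markers, os.path.join(outdir, "markers.fa"))
        for gene, seqs in self.orthologs.items():
            msy_io.write_fasta(seqs, os.path.join(outdir, f"orthologs_{gene}.fa"))
        msy_io.write_bed(
            [(self.spec.msy_chrom, *self.spec.msy_interval, "MSY")],
            os.path.join(outdir, "msy_truth.bed"),
        )
        self.genes.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
        self.marker_truth.to_csv(os.path.join(outdir, "marker_truth.tsv"), sep="\t", index=False)


def _random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(bases, size=length, p=p).tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute a ``rate`` fraction of positions with a different base."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    idx = {b: i for i, b in enumerate(bases)}
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    shifts = rng.integers(1, 4, size=hit.size)
    for pos, shift in zip(hit, shifts):
        arr[pos] = bases[(idx[arr[pos]] + shift) % 4]
    return arr.tobytes().decode()


def _allocate(
    regions: list[tuple[str, int, int]],
    n_genes: int,
    gene_bp: int,
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Place genes left to right across regions with random intergenic gaps."""
    placements = []
    cursors = {i: r[1] for i, r in enumerate(regions)}
    i = 0
    attempts = 0
    while len(placements) < n_genes:
        if attempts > 10 * n_genes * max(len(regions), 1):
            raise ValueError("cannot place genes: regions too small for the gene content")
        attempts += 1
        chrom, r_start, r_end = regions[i % len(regions)]
        cur = cursors[i % len(regions)] + int(rng.integers(200, 2000))
        if cur + gene_bp <= r_end - _TAIL_RESERVE:
            placements.append((chrom, cur, cur + gene_bp))
            cursors[i % len(regions)] = cur + gene_bp
        i += 1
    return placements


def simulate_genome(spec: GenomeSpec) -> SimulatedGenome:
    """Build the two haplotypes, transcript sets, markers and truth tables."""
    rng = np.random.default_rng(spec.seed)
    gene_bp = spec.gene_length_codons * 3

    x_hap = {c: _random_dna(l, spec.gc_content, rng) for c, l in spec.chrom_lengths.items()}

    # duplicated segments for multi-mapping markers, planted in both
    # haplotypes before any genes so gene sequence is never disturbed
    chroms = list(spec.chrom_lengths)
    markers: dict[str, str] = {}
    truth_rows = []
    lo_len, hi_len = spec.marker_length_range
    for m in range(spec.n_markers_multi):
        length = int(rng.integers(lo_len, hi_len + 1))
        src_chrom = chroms[m % len(chroms)]
        dst_chrom = chroms[(m + 1) % len(chroms)]
        src_pos = spec.chrom_lengths[src_chrom] - _TAIL_RESERVE + 100 + 200 * m
        dst_pos = spec.chrom_lengths[dst_chrom] - _TAIL_RESERVE + 5_000 + 200 * m
        segment = x_hap[src_chrom][src_pos : src_pos + length]
        s = x_hap[dst_chrom]
        x_hap[dst_chrom] = s[:dst_pos] + segment + s[dst_pos + length :]
        markers[f"marker_multi_{m:02d}"] = segment
        truth_rows.append((f"marker_multi_{m:02d}", "multi"))

    msy_start, msy_end = spec.msy_interval

    # gene placement: autosomal genes outside the MSY, MSY genes inside
    outside_regions = []
    for chrom, length in spec.chrom_lengths.items():
        if chrom == spec.msy_chrom:
            if msy_start > 0:
                outside_regions.append((chrom, 0, msy_start))
            if msy_end < length:
                outside_regions.append((chrom, msy_end, length))
        else:
            outside_regions.append((chrom, 0, length))
    auto_loci = _allocate(outside_regions, spec.n_autosomal_genes, gene_bp, rng)
    n_msy_genes = spec.n_gametolog_genes + spec.n_y_specific_genes
    msy_loci = _allocate_msy(spec, n_msy_genes, gene_bp, rng)

    # The Y haplotype matches X outside the MSY.  Inside it the backbone is
    # heavily diverged (degenerate/rearranged in real MSYs), so that no
    # male MSY read can be confused with the X-coordinate reference.
    y_hap = dict(x_hap)
    y_msy_backbone = _mutate(x_hap[spec.msy_chrom][msy_start:msy_end], 0.15, rng)
    y_hap[spec.msy_chrom] = (
        x_hap[spec.msy_chrom][:msy_start] + y_msy_backbone + x_hap[spec.msy_chrom][msy_end:]
    )
    gene_rows = []
    female_tx: dict[str, str] = {}
    male_tx: dict[str, str] = {}
    x_cds: dict[str, str] = {}
    y_cds: dict[str, str] = {}
    orthologs: dict[str, dict[str, str]] = {}
    y_specific: dict[str, str] = {}

    def _paste(hap: dict[str, str], chrom: str, start: int, seq: str) -> None:
        s = hap[chrom]
        hap[chrom] = s[:start] + seq + s[start + len(seq) :]

    for i, (chrom, start, end) in enumerate(auto_loci):
        gid = f"auto_{i:02d}"
        seq = x_hap[chrom][start:end]
        gene_rows.append((gid, chrom, start, end, "X", "autosomal"))
        female_tx[gid] = seq
        male_tx[gid] = seq

    clock_rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    for g in range(spec.n_gametolog_genes):
        gid = f"gam_{g:02d}"
        chrom, start, end = msy_loci[g]
        seqs = simulate_gametolog_pair(spec.clock, spec.gene_length_codons, clock_rng)
        ortho = {t: codon_string(arr) for t, arr in seqs.items()}
        orthologs[gid] = ortho
        x_seq, y_seq = ortho["X"], ortho["Y"]
        _paste(x_hap, chrom, start, x_seq)
        _paste(y_hap, chrom, start, y_seq)
        gene_rows.append((f"{gid}_X", chrom, start, end, "X", "x_gametolog"))
        gene_rows.append((f"{gid}_Y", chrom, start, end, "Y", "y_gametolog"))
        x_cds[f"{gid}_X"] = x_seq
        y_cds[f"{gid}_Y"] = y_seq
        female_tx[f"{gid}_X"] = x_seq
        male_tx[f"{gid}_X"] = x_seq
        male_tx[f"{gid}_Y"] = y_seq

    for s in range(spec.n_y_specific_genes):
        gid = f"yspec_{s:02d}"
        chrom, start, end = msy_loci[spec.n_gametolog_genes + s]
        seq = _random_dna(end - start, spec.gc_content, rng)
        _paste(y_hap, chrom, start, seq)
        gene_rows.append((gid, chrom, start, end, "Y", "y_specific"))
        y_specific[gid] = seq
        male_tx[gid] = seq

    # Y haplotype equals X outside the MSY by construction; the multi-marker
    # duplications above touched both haplotypes through the shared copy
    for chrom in y_hap:
        if chrom != spec.msy_chrom:
            y_hap[chrom] = x_hap[chrom]
        else:
            y_hap[chrom] = (
                x_hap[chrom][:msy_start] + y_hap[chrom][msy_start:msy_end] + x_hap[chrom][msy_end:]
            )

    # unique markers sampled from the reference (X) chromosomes
    for m in range(spec.n_markers_in_msy):
        length = int(rng.integers(lo_len, hi_len + 1))
        pos = int(rng.integers(msy_start, msy_end - length + 1))
        markers[f"marker_msy_{m:02d}"] = x_hap[spec.msy_chrom][pos : pos + length]
        truth_rows.append((f"marker_msy_{m:02d}", "unique_in_msy"))
    other_chroms = [c for c in chroms if c != spec.msy_chrom] or [spec.msy_chrom]
    for m in range(spec.n_markers_outside):
        length = int(rng.integers(lo_len, hi_len + 1))
        chrom = other_chroms[m % len(other_chroms)]
        pos = int(rng.integers(0, spec.chrom_lengths[chrom] - _TAIL_RESERVE - length))
        markers[f"marker_out_{m:02d}"] = x_hap[chrom][pos : pos + length]
        truth_rows.append((f"marker_out_{m:02d}", "unique_outside"))
    for m in range(spec.n_markers_unmapped):
        length = int(rng.integers(max(lo_len, 30), hi_len + 1))
        markers[f"marker_unmapped_{m:02d}"] = _random_dna(length, spec.gc_content, rng)
        truth_rows.append((f"marker_unmapped_{m:02d}", "unmapped"))

    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "haplotype", "kind"]
    )
    marker_truth = pd.DataFrame(truth_rows, columns=["marker_id", "planted_status"])
    return SimulatedGenome(
        spec=spec,
        x_haplotype=x_hap,
        y_haplotype=y_hap,
        genes=genes,
        female_transcriptome=female_tx,
        male_transcripts=male_tx,
        x_cds=x_cds,
        y_cds=y_cds,
        orthologs=orthologs,
        y_specific=y_specific,
        markers=markers,
        marker_truth=marker_truth,
    )


def _allocate_msy(
    spec: GenomeSpec, n_genes: int, gene_bp: int, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Evenly spread the MSY gene content across the planted interval."""
    start, end = spec.msy_interval
    span = end - start
    if n_genes * (gene_bp + 400) > span:
        raise ValueError("msy_interval too small for the requested gene content")
    slot = span // n_genes
    placements = []
    for i in range(n_genes):
        lo = start + i * slot
        jitter = int(rng.integers(100, max(101, slot - gene_bp - 100)))
        placements.append((spec.msy_chrom, lo + jitter, lo + jitter + gene_bp))
    return placements
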