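"""Shared fixtures: a small simulated genome with sexed reads.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import pytest

from msy.simulate import ClockSimSpec, GenomeSpec, simulate_genome, simulate_reads

SMALL_SPEC = GenomeSpec(
    chrom_lengths={"chr1": 120_000, "chr5": 200_000},
    msy_chrom="chr5",
    msy_interval=(60_000, 140_000),
    n_gametolog_genes=4,
    n_y_specific_genes=3,
    n_autosomal_genes=8,
    gene_length_codons=200,
    clock=ClockSimSpec(true_age=116.0),
    seed=11,
)


@pytest.fixture(scope="session")
def small_genome():
    return simulate_genome(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_reads(small_genome):
    """(male_rna, male_dna, female_dna, male_placement, female_placement)."""
    male_rna, _ = simulate_reads(small_genome, "male", "RNA", 30, seed=21)
    male_dna, placed_m = simulate_reads(small_genome, "male", "DNA", 20, seed=22)
    female_dna, placed_f = simulate_reads(small_genome, "female", "DNA", 20, seed=23)
    return male_rna, male_dna, female_dna, placed_m, placed_f
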