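"""Synthetic-data generators: determinism, planted-truth consistency."""

from __future__ import annotations

import numpy as np
import pytest

from msy.clock import codon_string, ng86_ds
from msy.simulate import (
    ClimateSimSpec,
    ClockSimSpec,
    GenomeSpec,
    simulate_climate,
    simulate_gametolog_pair,
    simulate_genome,
    simulate_placed_reads,
    simulate_reads,
)
from msy.subtraction import canonical_kmers

from conftest import SMALL_SPEC


class TestGenomeSpecValidation:
    def test_empty_msy_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(
                chrom_lengths={"c": 100_000}, msy_chrom="c", msy_interval=(5_000, 5_000)
            )

    def test_interval_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(
                chrom_lengths={"c": 100_000}, msy_chrom="c", msy_interval=(50_000, 200_000)
            )

    def test_unknown_msy_chrom_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(chrom_lengths={"c": 100_000}, msy_chrom="zz")

    def test_zero_gametologs_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(
                chrom_lengths={"c": 500_000},
                msy_chrom="c",
                msy_interval=(100_000, 400_000),
                n_gametolog_genes=0,
            )


class TestSimulatedGenome:
    def test_deterministic_under_seed(self):
        a = simulate_genome(SMALL_SPEC)
        b = simulate_genome(SMALL_SPEC)
        assert a.x_haplotype == b.x_haplotype
        assert a.y_haplotype == b.y_haplotype
        assert a.genes.equals(b.genes)
        assert a.markers == b.markers

    def test_y_equals_x_outside_msy(self, small_genome):
        spec = small_genome.spec
        start, end = spec.msy_interval
        for chrom in spec.chrom_lengths:
            x, y = small_genome.x_haplotype[chrom], small_genome.y_haplotype[chrom]
            if chrom != spec.msy_chrom:
                assert x == y
            else:
                assert x[:start] == y[:start] and x[end:] == y[end:]
                assert x[start:end] != y[start:end]

    def test_annotation_lists_requested_gene_pairs(self, small_genome):
        spec = small_genome.spec
        gam_x = small_genome.genes.query("kind == 'x_gametolog'")
        gam_y = small_genome.genes.query("kind == 'y_gametolog'")
        assert len(gam_x) == len(gam_y) == spec.n_gametolog_genes
        start, end = spec.msy_interval
        for df in (gam_x, gam_y):
            assert (df["chrom"] == spec.msy_chrom).all()
            assert (df["start"] >= start).all() and (df["end"] <= end).all()

    def test_gametolog_identity_in_pairing_window(self, small_genome):
        for gid, x_seq in small_genome.x_cds.items():
            y_seq = small_genome.y_cds[gid.replace("_X", "_Y")]
            ident = sum(a == b for a, b in zip(x_seq, y_seq)) / len(x_seq)
            assert 0.90 <= ident < 0.99

    def test_y_specific_kmers_absent_from_female_transcriptome(self, small_genome):
        female = set()
        for s in small_genome.female_transcriptome.values():
            female |= canonical_kmers(s, 25)
        for s in small_genome.y_specific.values():
            assert not (canonical_kmers(s, 25) & female)

    def test_truth_bed_consistent_with_haplotypes(self, small_genome):
        """Re-scan: the planted interval brackets every X/Y difference."""
        chrom, start, end = small_genome.msy_truth
        x = small_genome.x_haplotype[chrom]
        y = small_genome.y_haplotype[chrom]
        diffs = [i for i, (a, b) in enumerate(zip(x, y)) if a != b]
        assert diffs and min(diffs) >= start and max(diffs) < end


class TestSimulateReads:
    def test_unknown_labels_rejected(self, small_genome):
        with pytest.raises(ValueError):
            simulate_reads(small_genome, "other", "DNA", 10)
        with pytest.raises(ValueError):
            simulate_reads(small_genome, "male", "exome", 10)

    def test_deterministic(self, small_genome):
        r1, p1 = simulate_reads(small_genome, "male", "DNA", 5, seed=3)
        r2, p2 = simulate_reads(small_genome, "male", "DNA", 5, seed=3)
        assert r1 == r2 and p1.equals(p2)

    def test_coverage_conservation(self, small_genome):
        depth, read_len = 10.0, 100
        reads, _ = simulate_reads(small_genome, "female", "DNA", depth, read_len, seed=4)
        haploid = sum(small_genome.spec.chrom_lengths.values())
        total_bases = sum(len(r[1]) for r in reads)
        assert total_bases == pytest.approx(depth * haploid, rel=0.001)

    def test_female_reads_carry_no_y_alleles(self, small_genome):
        """No female read shares a k-mer with Y-specific sequence."""
        reads, _ = simulate_reads(small_genome, "female", "DNA", 4, seed=5)
        y_kmers = set()
        for s in small_genome.y_specific.values():
            y_kmers |= canonical_kmers(s, 25)
        for _t, seq, _q in reads:
            assert not (canonical_kmers(seq, 25) & y_kmers)

    def test_male_msy_depth_half_of_female(self, small_genome):
        from msy.coverage import build_profiles

        _, pm = simulate_reads(small_genome, "male", "DNA", 20, seed=6)
        _, pf = simulate_reads(small_genome, "female", "DNA", 20, seed=7)
        profiles = build_profiles(pm, pf, small_genome.spec.chrom_lengths, 20_000)
        chrom, start, end = small_genome.msy_truth
        for p in profiles:
            if p.chrom != chrom:
                continue
            bins = slice(start // 20_000, end // 20_000)
            assert np.nanmean(p.ratio[bins]) == pytest.approx(0.5, abs=0.05)

    def test_mean_depth_within_three_sds(self, small_genome):
        """Binomial/Poisson oracle on a diploid autosome at 20x."""
        _, placed = simulate_reads(small_genome, "male", "DNA", 20, seed=8)
        from msy.coverage import bin_depth

        depth = bin_depth(
            placed[placed["chrom"] == "chr1"],
            small_genome.spec.chrom_lengths["chr1"],
            bin_size=small_genome.spec.chrom_lengths["chr1"],
        )
        n_reads = 20 * small_genome.spec.chrom_lengths["chr1"] / 100
        sd = 20 / np.sqrt(n_reads)
        assert abs(depth[0] - 20) <= 3 * sd

    def test_error_rate_knob(self, small_genome):
        from msy.subtraction import revcomp

        noisy, _ = simulate_reads(small_genome, "female", "DNA", 2, seed=9, error_rate=0.05)
        diffs = total = 0
        for title, seq, _q in noisy:
            # title: female_DNA_<hap>_<chrom>_<start>_<serial>
            parts = title.split("_")
            chrom, start = parts[3], int(parts[4])
            origin = small_genome.x_haplotype[chrom][start : start + len(seq)]
            mm = min(
                sum(a != b for a, b in zip(seq, origin)),
                sum(a != b for a, b in zip(revcomp(seq), origin)),
            )
            diffs += mm
            total += len(seq)
        assert 0.03 < diffs / total < 0.07


class TestGametologSimulator:
    def test_zero_age_identical(self):
        spec = ClockSimSpec(true_age=0.0, seed=1)
        seqs = simulate_gametolog_pair(spec, 100, np.random.default_rng(1))
        assert (seqs["X"] == seqs["Y"]).all()

    def test_short_gene_rejected(self):
        with pytest.raises(ValueError):
            simulate_gametolog_pair(ClockSimSpec(true_age=10.0), 20)

    def test_expected_ds_recovered_within_three_ses(self):
        """NG86 on the simulated pair vs the 2*age*rate expectation."""
        spec = ClockSimSpec(true_age=100.0, rate=0.002, seed=2)
        rng = np.random.default_rng(2)
        n_codons = 4000
        seqs = simulate_gametolog_pair(spec, n_codons, rng)
        est = ng86_ds(codon_string(seqs["X"]), codon_string(seqs["Y"]))
        expected = 2 * 100.0 * 0.002  # 0.4
        p_exp = 0.75 * (1 - np.exp(-4 * expected / 3))
        se_p = np.sqrt(p_exp * (1 - p_exp) / est.S)
        se_ds = se_p / (1 - 4 * p_exp / 3)
        assert abs(est.ds - expected) <= 3 * se_ds

    def test_saturation_warning(self):
        spec = ClockSimSpec(
            true_age=100.0, rate=0.004, outgroup_ages=(("Out", 500.0),), seed=3
        )
        with pytest.warns(UserWarning, match="saturat"):
            simulate_gametolog_pair(spec, 60, np.random.default_rng(3))

    def test_age_must_precede_outgroups(self):
        with pytest.raises(ValueError):
            ClockSimSpec(true_age=200.0, outgroup_ages=(("Out", 100.0),))


class TestClimateSimulator:
    def test_cohort_sizes(self):
        grid, species, truth = simulate_climate(ClimateSimSpec(seed=1))
        assert len(species) == 101 + 99 + 1
        assert (species["system"] == "TSD").sum() == 101
        assert (species["system"] == "GSD").sum() == 99

    def test_deterministic(self):
        g1, s1, t1 = simulate_climate(ClimateSimSpec(seed=2))
        g2, s2, t2 = simulate_climate(ClimateSimSpec(seed=2))
        assert g1.equals(g2) and s1.equals(s2) and t1.equals(t2)

    def test_truth_consistent_with_grid(self):
        from msy.climate import species_breeding_temperature
        from msy.simulate.climate import records_from_frame

        grid, species, truth = simulate_climate(ClimateSimSpec(seed=3))
        for rec in records_from_frame(species)[:10]:
            expected = truth.loc[truth["species"] == rec.species, "true_temperature"].iloc[0]
            assert species_breeding_temperature(grid, rec) == pytest.approx(expected, abs=1e-9)


class TestPlacedReads:
    def test_matches_fastq_placement_semantics(self, small_genome, small_reads):
        """Fast path and full simulator agree on expected depth structure."""
        spec = small_genome.spec
        fast = simulate_placed_reads(
            spec.chrom_lengths, "male", 20, 100,
            msy_chrom=spec.msy_chrom, msy_interval=spec.msy_interval, seed=40,
        )
        _, _, _, placed_m, _ = small_reads
        for df in (fast, placed_m):
            chrom_reads = df[df["chrom"] == spec.msy_chrom]
            start, end = spec.msy_interval
            inside = chrom_reads[(chrom_reads["start"] >= start) & (chrom_reads["end"] <= end)]
            outside = chrom_reads[(chrom_reads["end"] <= start) | (chrom_reads["start"] >= end)]
            density_in = len(inside) / (end - start)
            density_out = len(outside) / (spec.chrom_lengths[spec.msy_chrom] - (end - start))
            assert density_in / density_out == pytest.approx(0.5, abs=0.06)
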