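"""End-to-end orchestration: simulate -> subtract -> scan -> pair -> date -> ...

The pipeline runs the stages in dependency order on a validated YAML
config, writes every stage's artifacts under the output directory, and
aggregates a machine-readable ``report.json``.  All randomness funnels
through per-stage seeds derived from the single top-level seed, so a
rerun with the same config produces a byte-identical report.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import io as msy_io
from .climate import class_distributions, outlier_score, species_breeding_temperature
from .clock import align_codons, bootstrap_age, concat_alignments
from .coverage import MsyCall, build_profiles, detect_half_coverage
from .markers import map_markers, msy_enrichment
from .pairing import check_copy_number, find_x_gametolog, synteny_check
from .simulate import (
    ClimateSimSpec,
    ClockSimSpec,
    GenomeSpec,
    dated_topology,
    simulate_climate,
    simulate_genome,
    simulate_reads,
)
from .simulate.climate import records_from_frame
from .subtraction import (
    assemble_candidates,
    build_kmer_index,
    classify_by_genomic_coverage,
    subtract_reads,
)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class GenomeConfig(BaseModel):
    chrom_lengths: dict[str, int] = Field(
        default_factory=lambda: {"chr1": 500_000, "chr5": 1_000_000}
    )
    msy_chrom: str = "chr5"
    msy_interval: tuple[int, int] = (400_000, 700_000)
    n_gametolog_genes: int = 14
    n_y_specific_genes: int = 6
    n_autosomal_genes: int = 16
    gene_length_codons: int = 300
    gc_content: float = 0.42
    true_age_myr: float = 116.0
    syn_rate_per_myr: float = 0.001
    outgroup_ages: list[tuple[str, float]] = Field(
        default_factory=lambda: [["OutA", 184.9], ["OutB", 311.9]]
    )


class ReadsConfig(BaseModel):
    dna_depth: float = 20.0
    rna_depth: float = 30.0
    read_length: int = 100
    error_rate: float = 0.0


class SubtractionConfig(BaseModel):
    k: int = 25
    min_contig_len: int = 200
    identity: float = 0.99
    male_depth_min: float = 4.0
    male_depth_max: float = 14.0
    female_depth_max: float = 0.0


class ScanConfig(BaseModel):
    bin_size: int = 100_000
    band: tuple[float, float] = (0.35, 0.65)
    min_bins: int = 3
    max_gap: int = 1


class PairConfig(BaseModel):
    identity_low: float = 0.90
    identity_high: float = 0.99
    pair_contigs: bool = True


class DateConfig(BaseModel):
    n_bootstrap: int = 100


class ClimateConfig(BaseModel):
    n_tsd: int = 101
    n_gsd: int = 99
    tsd_mean: float = 27.0
    tsd_sd: float = 4.0
    gsd_mean: float = 19.0
    gsd_sd: float = 5.0
    focal_offset_sd: float = -3.0


class MarkersConfig(BaseModel):
    max_mismatch_rate: float = 0.05
    unit: str = "bin"


class StagesConfig(BaseModel):
    simulate: bool = True
    subtract: bool = True
    assemble: bool = True
    classify: bool = True
    scan: bool = True
    pair: bool = True
    date: bool = True
    climate: bool = True
    markers: bool = True


class InputsConfig(BaseModel):
    """File inputs for runs that skip the simulate stage."""

    female_transcriptome: str | None = None
    male_rna_fastq: str | None = None
    male_dna_fastq: str | None = None
    female_dna_fastq: str | None = None
    male_placed_tsv: str | None = None
    female_placed_tsv: str | None = None
    y_cds_fasta: str | None = None
    annotation_tsv: str | None = None
    chrom_lengths: dict[str, int] | None = None


class PipelineConfig(BaseModel):
    seed: int = 0
    stages: StagesConfig = Field(default_factory=StagesConfig)
    genome: GenomeConfig = Field(default_factory=GenomeConfig)
    reads: ReadsConfig = Field(default_factory=ReadsConfig)
    subtraction: SubtractionConfig = Field(default_factory=SubtractionConfig)
    scan: ScanConfig = Field(default_factory=ScanConfig)
    pair: PairConfig = Field(default_factory=PairConfig)
    date: DateConfig = Field(default_factory=DateConfig)
    climate: ClimateConfig = Field(default_factory=ClimateConfig)
    markers: MarkersConfig = Field(default_factory=MarkersConfig)
    inputs: InputsConfig = Field(default_factory=InputsConfig)


def load_config(path: str | os.PathLike) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


_STAGE_NAMES = ["simulate", "reads", "date", "climate"]


def _require(value: Any, what: str, stage: str) -> Any:
    if value is None:
        raise PipelineStageError(stage, ValueError(f"missing input: {what}"))
    return value


def run_pipeline(config: PipelineConfig, outdir: str | os.PathLike) -> dict:
    """Execute the enabled stages and write ``report.json`` under ``outdir``."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    seeds = _stage_seeds(config.seed, _STAGE_NAMES)
    report: dict[str, Any] = {"seed": config.seed, "stage_seeds": seeds, "stages": {}}
    st = config.stages

    genome = None
    female_tx = None
    male_rna = male_dna = female_dna = None
    placed_m = placed_f = None
    chrom_lengths = config.inputs.chrom_lengths
    y_cds = None
    annotation = None
    clim_grid = clim_species = clim_truth = None
    clock_spec = ClockSimSpec(
        true_age=config.genome.true_age_myr,
        rate=config.genome.syn_rate_per_myr,
        outgroup_ages=tuple((n, a) for n, a in config.genome.outgroup_ages),
        gc_content=config.genome.gc_content,
    )

    def _run(stage: str, fn):
        try:
            return fn()
        except PipelineStageError:
            raise
        except Exception as exc:  # halt with a stage-tagged error, keep partial outputs
            raise PipelineStageError(stage, exc) from exc

    if st.simulate:
        def _simulate():
            nonlocal genome, female_tx, male_rna, male_dna, female_dna
            nonlocal placed_m, placed_f, chrom_lengths, y_cds, annotation
            nonlocal clim_grid, clim_species, clim_truth
            g = config.genome
            spec = GenomeSpec(
                chrom_lengths=dict(g.chrom_lengths),
                msy_chrom=g.msy_chrom,
                msy_interval=tuple(g.msy_interval),
                n_gametolog_genes=g.n_gametolog_genes,
                n_y_specific_genes=g.n_y_specific_genes,
                n_autosomal_genes=g.n_autosomal_genes,
                gene_length_codons=g.gene_length_codons,
                gc_content=g.gc_content,
                clock=clock_spec,
                seed=seeds["simulate"],
            )
            genome = simulate_genome(spec)
            simdir = os.path.join(outdir, "sim")
            genome.write(simdir)
            r = config.reads
            male_rna, _ = simulate_reads(
                genome, "male", "RNA", r.rna_depth, r.read_length,
                seed=seeds["reads"], error_rate=r.error_rate,
            )
            male_dna, placed_m = simulate_reads(
                genome, "male", "DNA", r.dna_depth, r.read_length,
                seed=seeds["reads"] + 1, error_rate=r.error_rate,
            )
            female_dna, placed_f = simulate_reads(
                genome, "female", "DNA", r.dna_depth, r.read_length,
                seed=seeds["reads"] + 2, error_rate=r.error_rate,
            )
            msy_io.write_fastq(male_rna, os.path.join(simdir, "male_rna.fastq"))
            msy_io.write_fastq(male_dna, os.path.join(simdir, "male_dna.fastq"))
            msy_io.write_fastq(female_dna, os.path.join(simdir, "female_dna.fastq"))
            msy_io.write_placed_reads(placed_m, os.path.join(simdir, "male_placed.tsv"))
            msy_io.write_placed_reads(placed_f, os.path.join(simdir, "female_placed.tsv"))
            c = config.climate
            clim_spec = ClimateSimSpec(
                n_tsd=c.n_tsd, n_gsd=c.n_gsd,
                tsd_mean=c.tsd_mean, tsd_sd=c.tsd_sd,
                gsd_mean=c.gsd_mean, gsd_sd=c.gsd_sd,
                focal_offset_sd=c.focal_offset_sd,
                seed=seeds["climate"],
            )
            clim_grid, clim_species, clim_truth = simulate_climate(clim_spec)
            clim_grid.to_csv(os.path.join(simdir, "climate_grid.csv"), index=False)
            clim_species.to_csv(os.path.join(simdir, "climate_species.csv"), index=False)
            clim_truth.to_csv(os.path.join(simdir, "climate_truth.csv"), index=False)
            female_tx = genome.female_transcriptome
            chrom_lengths = dict(spec.chrom_lengths)
            y_cds = genome.y_cds
            annotation = genome.annotation()
            report["stages"]["simulate"] = {
                "msy_truth": list(genome.msy_truth),
                "n_genes": int(len(genome.genes)),
                "n_male_rna_reads": len(male_rna),
                "n_male_dna_reads": len(male_dna),
                "n_female_dna_reads": len(female_dna),
                "n_climate_species": int(len(clim_species)),
            }
        _run("simulate", _simulate)
    else:
        inp = config.inputs
        if inp.female_transcriptome:
            female_tx = msy_io.read_fasta(inp.female_transcriptome)
        if inp.male_rna_fastq:
            male_rna = list(msy_io.read_fastq(inp.male_rna_fastq))
        if inp.male_dna_fastq:
            male_dna = list(msy_io.read_fastq(inp.male_dna_fastq))
        if inp.female_dna_fastq:
            female_dna = list(msy_io.read_fastq(inp.female_dna_fastq))
        if inp.male_placed_tsv:
            placed_m = msy_io.read_placed_reads(inp.male_placed_tsv)
        if inp.female_placed_tsv:
            placed_f = msy_io.read_placed_reads(inp.female_placed_tsv)
        if inp.y_cds_fasta:
            y_cds = msy_io.read_fasta(inp.y_cds_fasta)
        if inp.annotation_tsv:
            annotation = pd.read_csv(inp.annotation_tsv, sep="\t")

    retained_reads = None
    if st.subtract:
        def _subtract():
            nonlocal retained_reads
            sub = config.subtraction
            idx = build_kmer_index(_require(female_tx, "female transcriptome", "subtract"), sub.k)
            reads = _require(male_rna, "male RNA reads", "subtract")
            retained, stats = subtract_reads(reads, idx, female_tx)
            retained_reads = retained
            msy_io.write_fastq(retained, os.path.join(outdir, "retained_reads.fastq"))
            report["stages"]["subtract"] = {
                "k": sub.k,
                "n_input_reads": stats.n_input,
                "n_retained_reads": stats.n_retained,
                "n_kmer_hits": stats.n_kmer_hit,
                "n_exact_matches": stats.n_exact_match,
                "n_too_short": stats.n_too_short,
            }
        _run("subtract", _subtract)

    contigs = None
    if st.assemble:
        def _assemble():
            nonlocal contigs
            sub = config.subtraction
            reads = _require(retained_reads, "retained reads (run subtract)", "assemble")
            contigs = assemble_candidates(reads, sub.k, sub.min_contig_len)
            msy_io.write_fasta(contigs, os.path.join(outdir, "candidate_contigs.fa"))
            report["stages"]["assemble"] = {"n_contigs": len(contigs)}
        _run("assemble", _assemble)

    retained_contigs: dict[str, str] = {}
    if st.classify:
        def _classify():
            sub = config.subtraction
            cands = classify_by_genomic_coverage(
                _require(contigs, "contigs (run assemble)", "classify"),
                _require(male_dna, "male DNA reads", "classify"),
                _require(female_dna, "female DNA reads", "classify"),
                identity=sub.identity,
                male_depth_window=(sub.male_depth_min, sub.male_depth_max),
                female_depth_max=sub.female_depth_max,
                k=sub.k,
            )
            rows = [
                {
                    "id": c.id, "length": len(c.sequence),
                    "male_depth": round(c.male_depth, 3),
                    "female_depth": round(c.female_depth, 3),
                    "verdict": c.verdict,
                }
                for c in cands
            ]
            pd.DataFrame(rows).to_csv(
                os.path.join(outdir, "candidate_verdicts.tsv"), sep="\t", index=False
            )
            for c in cands:
                if c.verdict == "retained":
                    retained_contigs[c.id] = c.sequence
            report["stages"]["classify"] = {
                "n_candidates": len(cands),
                "n_retained": len(retained_contigs),
                "verdict_counts": {
                    v: sum(1 for c in cands if c.verdict == v)
                    for v in sorted({c.verdict for c in cands})
                },
            }
        _run("classify", _classify)

    msy_call: MsyCall | None = None
    if st.scan:
        def _scan():
            nonlocal msy_call
            sc = config.scan
            profiles = build_profiles(
                _require(placed_m, "male placed reads", "scan"),
                _require(placed_f, "female placed reads", "scan"),
                _require(chrom_lengths, "chromosome lengths", "scan"),
                sc.bin_size,
            )
            calls = []
            for p in profiles:
                calls.extend(detect_half_coverage(p, sc.band, sc.min_bins, sc.max_gap))
            pd.concat([p.to_frame() for p in profiles]).to_csv(
                os.path.join(outdir, "coverage_bins.tsv"), sep="\t", index=False
            )
            msy_io.write_bed(
                [(c.chrom, c.start, c.end, f"msy_call_{i}") for i, c in enumerate(calls)],
                os.path.join(outdir, "msy_calls.bed"),
            )
            if calls:
                msy_call = max(calls, key=lambda c: c.n_bins)
            entry = {
                "n_calls": len(calls),
                "calls": [
                    {
                        "chrom": c.chrom, "start": c.start, "end": c.end,
                        "mean_ratio": round(c.mean_ratio, 4), "n_bins": c.n_bins,
                    }
                    for c in calls
                ],
            }
            if genome is not None and msy_call is not None:
                t_chrom, t_start, t_end = genome.msy_truth
                err = max(abs(msy_call.start - t_start), abs(msy_call.end - t_end))
                entry["boundary_error_bins"] = (
                    err / sc.bin_size if msy_call.chrom == t_chrom else None
                )
            report["stages"]["scan"] = entry
        _run("scan", _scan)

    pairs = []
    if st.pair:
        def _pair():
            pc = config.pair
            tx = _require(female_tx, "female transcriptome", "pair")
            candidates: dict[str, str] = {}
            if y_cds:
                candidates.update(y_cds)
            if pc.pair_contigs:
                candidates.update(retained_contigs)
            window = (pc.identity_low, pc.identity_high)
            for cid in sorted(candidates):
                p = find_x_gametolog(cid, candidates[cid], tx, window)
                if p is not None:
                    pairs.append(p)
            if pairs and male_dna is not None and female_dna is not None:
                for p in pairs:
                    check_copy_number(p, male_dna, female_dna, k=config.subtraction.k)
            synteny = (
                synteny_check(pairs, annotation, msy_call)
                if annotation is not None
                else {"n_pairs": len(pairs)}
            )
            if msy_call is not None and "fraction_inside_msy" in synteny:
                msy_call.n_gametologs = round(
                    synteny["fraction_inside_msy"] * synteny["n_located"]
                )
            pd.DataFrame(
                [
                    {
                        "gene_id": p.gene_id, "x_id": p.x_id,
                        "identity": round(p.identity, 4),
                        "copy_number": p.copy_number_verdict,
                        "x_chrom": p.x_location[0] if p.x_location else None,
                    }
                    for p in pairs
                ]
            ).to_csv(os.path.join(outdir, "gametolog_pairs.tsv"), sep="\t", index=False)
            report["stages"]["pair"] = {
                "n_candidates": len(candidates),
                "n_pairs": len(pairs),
                "n_copy_number_consistent": sum(
                    1 for p in pairs if p.copy_number_verdict == "consistent"
                ),
                "synteny": synteny,
            }
        _run("pair", _pair)

    if st.date:
        def _date():
            g = _require(genome, "simulated genome (file-based dating uses the library API)", "date")
            alns = [align_codons(g.orthologs[gene]) for gene in sorted(g.orthologs)]
            concat = concat_alignments(alns)
            topology = dated_topology(clock_spec)
            est = bootstrap_age(
                concat,
                topology,
                clock_spec.calibrations("X"),
                n_bootstrap=config.date.n_bootstrap,
                seed=seeds["date"],
            )
            with open(os.path.join(outdir, "age_estimate.json"), "w") as fh:
                json.dump(
                    {
                        "age_myr": est.age, "ci_low": est.ci_low, "ci_high": est.ci_high,
                        "rate": est.rate, "n_bootstrap": est.n_bootstrap,
                    },
                    fh, indent=2, sort_keys=True,
                )
            report["stages"]["date"] = {
                "age_myr": round(est.age, 3),
                "ci_low_myr": round(est.ci_low, 3),
                "ci_high_myr": round(est.ci_high, 3),
                "rate_per_myr": round(est.rate, 6),
                "n_bootstrap": est.n_bootstrap,
                "n_codons": len(next(iter(concat.values()))) // 3,
                "calibration_ages": [a for _, a in clock_spec.outgroup_ages],
            }
        _run("date", _date)

    if st.climate:
        def _climate():
            grid = clim_grid
            species = clim_species
            if grid is None:
                raise ValueError("climate stage requires the simulate stage (or library API)")
            records = records_from_frame(species)
            temps = pd.DataFrame(
                {
                    "species": [r.species for r in records],
                    "system": [r.system for r in records],
                    "temperature": [species_breeding_temperature(grid, r) for r in records],
                }
            )
            temps.to_csv(os.path.join(outdir, "breeding_temperatures.csv"), index=False)
            classes = class_distributions(temps[temps["system"].isin(["TSD", "GSD"])])
            focal = temps[temps["system"] == "unknown"]
            scores = []
            for _, row in focal.iterrows():
                for cls in ("TSD", "GSD"):
                    s = outlier_score(
                        row["species"], row["temperature"], cls,
                        classes.loc[cls, "mean"], classes.loc[cls, "sd"],
                    )
                    scores.append(
                        {
                            "species": s.species, "class": cls,
                            "z": round(s.z, 3), "outlier": s.is_outlier,
                        }
                    )
            report["stages"]["climate"] = {
                "class_stats": {
                    cls: {
                        "n": int(classes.loc[cls, "n"]),
                        "mean": round(float(classes.loc[cls, "mean"]), 3),
                        "sd": round(float(classes.loc[cls, "sd"]), 3),
                    }
                    for cls in classes.index
                },
                "focal_scores": scores,
            }
        _run("climate", _climate)

    if st.markers:
        def _markers():
            g = _require(genome, "simulated genome (file-based markers use the library API)", "markers")
            hits = map_markers(
                g.markers, g.x_haplotype, config.markers.max_mismatch_rate
            )
            pd.DataFrame(
                [
                    {
                        "marker_id": h.marker_id, "length": h.length, "status": h.status,
                        "locations": ";".join(f"{c}:{s}-{e}" for c, s, e in h.locations),
                    }
                    for h in hits
                ]
            ).to_csv(os.path.join(outdir, "marker_hits.tsv"), sep="\t", index=False)
            entry: dict[str, Any] = {
                "n_markers": len(hits),
                "status_counts": {
                    s: sum(1 for h in hits if h.status == s)
                    for s in sorted({h.status for h in hits})
                },
            }
            if msy_call is not None:
                enr = msy_enrichment(
                    hits, msy_call, chrom_lengths,
                    config.scan.bin_size, config.markers.unit,
                )
                entry["enrichment"] = {
                    "table": enr.table,
                    "p_value": enr.p_value,
                    "unit": enr.unit,
                    "n_unique": enr.n_unique,
                }
            report["stages"]["markers"] = entry
        _run("markers", _markers)

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
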