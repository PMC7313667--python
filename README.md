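# msy — discovery and dating of a male-specific Y region

`msy` re-implements, as a tested and reusable Python pipeline, the
comparative-genomics workflow used to discover cryptic XY sex chromosomes
in a species previously classified as having temperature-dependent sex
determination (TSD). The target audience is researchers working on sex
chromosome evolution in non-model vertebrates who want each analytical
step available as a library function with a synthetic ground-truth
test-bed, rather than a chain of ad hoc shell scripts around external
tools.

## The analysis

Given sexed sequencing data (male and female RNA-seq and DNA-seq) the
pipeline asks: does this genome hide a male-specific region of a Y
chromosome (MSY), how old is it, and is the species' thermal ecology
consistent with genotypic sex determination?

1. **Subtraction** (`msy.subtraction`). Male RNA reads are filtered
   against the female transcriptome: any read with an exact full-length
   match, or sharing even one canonical k-mer (k = 25), is removed.
   Survivors are assembled into unitigs, and each contig is vetted by
   sexed genomic depth: retained iff mean male depth lies in the
   hemizygous window [4×, 14×] (at 20× diploid sequencing) and female
   depth is exactly zero.
2. **Coverage scan** (`msy.coverage`). Male and female genomic depth is
   binned in 100 kb windows; after per-sex median normalization, the
   ratio *r* = (male/median)/(female/median) drops to ≈ 0.5 over a
   hemizygous region. Maximal runs of bins with *r* ∈ [0.35, 0.65]
   (≥ 3 bins, one interior gap tolerated) are reported as MSY calls.
3. **Gametolog pairing** (`msy.pairing`). Each Y transcript's best
   full-length alignment in the female transcriptome is its candidate X
   gametolog, accepted in the identity window [90%, 99%) — 100% matches
   are alleles, not gametologs. Copy number is cross-checked
   (female:male ≈ 2:1 on X, male-only on Y) and the X locations tested
   for clustering on one syntenic block inside the MSY call.
4. **Molecular clock** (`msy.clock`). Synonymous divergence dS between
   X and Y copies is estimated with the Nei–Gojobori (1986) counting
   method with Jukes–Cantor correction:
   dS = −(3/4) ln(1 − 4·ps/3), ps = Sd/S. Branch dS lengths are fitted
   on a fixed topology by non-negative least squares, a per-lineage rate
   is calibrated on dated outgroup splits (e.g. 184.9 Ma), and the age
   of the X/Y split is dS(X,Y)/2 ÷ rate, with a 100-round codon-column
   bootstrap CI.
5. **Climate outliers** (`msy.climate`). Per species, the breeding-season
   temperature is the median of monthly gridded temperatures over its
   range cells and breeding months; a focal species is scored in SD
   units against the TSD and GSD class distributions, |z| ≥ 3 flagging a
   thermal outlier.
6. **Marker enrichment** (`msy.markers`). Short (17–70 bp) Y markers
   from a related species are mapped near-exactly; unique hits are
   tested for enrichment inside the MSY with a two-sided Fisher exact
   test against a length-proportional background.

Every input can be generated by `msy.simulate` with planted truth: a
diploid genome whose Y haplotype carries a diverged MSY of known
coordinates and age, sexed reads at known depth, gametologs evolved
under a strict synonymous clock, and a climate grid with separated
TSD/GSD distributions.

## Worked example

```python
from msy.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1), "out")
scan = report["stages"]["scan"]["calls"][0]
print(scan["chrom"], scan["start"], scan["end"], scan["mean_ratio"])
print(report["stages"]["pair"]["n_pairs"])
date = report["stages"]["date"]
print(f"{date['age_myr']:.1f} Myr  CI [{date['ci_low_myr']:.1f}, {date['ci_high_myr']:.1f}]")
```

prints (seed 1):

```
chr5 400000 700000 0.509
14
122.1 Myr  CI [112.5, 134.6]
```

That is: the half-coverage scan recovers the planted 300 kb MSY on chr5
exactly (mean male:female ratio 0.509 ≈ one Y copy against two X
copies); all 14 planted gametolog pairs are found at 93–94% identity on
one block inside the call; and the clock dates the planted 116 Myr X/Y
split at 122 Myr with a bootstrap CI covering the truth. The same
config re-run with the same seed reproduces the report byte for byte.

The same stages are exposed on the command line (`msy run`,
`msy subtract`, `msy assemble`, `msy classify`, `msy scan`, `msy pair`,
`msy climate`, `msy markers`); see `msy --help`.

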