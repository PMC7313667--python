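# Methods

This note records the models, parameter choices and known limitations of
the `msy` pipeline, in the order the stages run. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`;
nothing is quoted from elsewhere.

## Subtraction

A male-restricted transcriptome is obtained by removing every male RNA
read that could derive from the female transcriptome, under the
strictest reading of k-mer subtraction: a single shared canonical k-mer
(k = 25, the conventional assembler default) suffices for removal, in
addition to exact full-length matching with zero mismatches on either
strand. For reads of length ≥ k the k-mer rule subsumes exact matching;
both are implemented so the contract holds for any input.

Assembly of the surviving reads is a unitig traversal of the canonical
de Bruijn graph: maximal non-branching paths, emitted on a canonical
strand in sorted order (hence invariant to read order), with contigs
under 200 bp dropped. This is deliberately minimal — adequate for
high-identity, error-free reads, and not a general-purpose assembler.
Sequencing error is outside its design envelope; the read simulator's
error knob defaults to 0 accordingly.

The genomic vetting step computes, per contig, the mean depth of male
and female genomic reads matching at ≥ 99% identity over ≥ 90% of the
read length (ungapped, both strands, seeded by shared k-mers probed on a
stride small enough that any qualifying error-free placement yields at
least two seed windows). A contig is retained iff male depth ∈ [4, 14]
(inclusive — the window printed without open/closed qualification is
taken closed) and female depth is exactly zero. "Zero" is interpreted
literally; an `female_depth_max` epsilon exists for noisy real data but
defaults to 0. Female coverage takes precedence in the verdict when
several rejection reasons apply.

A structural consequence worth stating: at ~93–96% X/Y nucleotide
identity, every conserved 25-mer both removes the reads containing it
and severs the de Bruijn graph, so gametolog transcripts cannot be
recovered intact through this filter — only fragments from
diverged-dense stretches survive. Y-specific (Y-acquired) content with
no X counterpart is recovered completely. The synthetic genome
therefore plants both classes: gametolog pairs to exercise pairing and
dating, and Y-specific genes on which subtraction recall is measured.
In the pipeline, the pairing and dating stages consume the annotated Y
CDS set (in real use, the product of an external homology-annotation
step, which is out of scope here); retained contigs are also offered to
the pairing stage and correctly fail to pair, being Y-specific.

## Coverage scan

Depth is binned at 100 kb (0-based half-open bins tiling each
chromosome; the last bin may be short and its mean is per-base).
Normalization divides each sex by its genome-wide median bin depth,
making calls invariant to global library-size differences; the ratio is
undefined (NaN, treated as off-band) where female depth is zero. The
half-coverage band [0.35, 0.65] around the hemizygous expectation of
0.5 tolerates sampling noise at 10–20× depth; runs need ≥ 3 in-band
bins and may bridge one interior off-band bin. Run-based segmentation
is this package's own choice of boundary rule; alternatives (HMMs,
changepoint methods) would be drop-in replacements behind the same
call interface.

Input is a placed-read table (chrom, start, end). Read placement is the
job of an aligner and is out of scope; the simulator emits the table a
strict aligner would produce (male Y-haplotype reads overlapping the
MSY are unplaceable on the X-coordinate reference because the simulated
Y backbone there is ~15% diverged, emulating MSY degeneration).

## Gametolog pairing

The X counterpart of a Y transcript is its best full-length global
alignment (match +1, mismatch −1, gap open −4, extend −1, both strands)
across the female transcriptome, accepted in the half-open identity
window [90%, 99%). The window generalizes the observed gametolog
identity range while excluding identical alleles; ties break by
alignment length then lexicographic id, making pairing deterministic.
Copy-number consistency requires the female:male depth ratio on the X
copy to fall in [2^0.5, 2^1.5] (symmetric about 2 on the log scale) and
the Y copy to be male-only; zero male depth yields "indeterminate"
rather than failure.

## Molecular clock

dS is estimated by Nei–Gojobori (1986) counting: per-codon synonymous
site fractions from the nine single-nucleotide neighbours (changes to
stop codons count as nonsynonymous), differences for multi-hit codons
averaged over all substitution orderings with stop-passing orderings
excluded (all orderings used if every one is blocked), Jukes–Cantor
correction −(3/4)ln(1 − 4ps/3), saturation error at ps ≥ 3/4. The
estimator sits behind a small interface; a likelihood-based variant
could be added without touching the dating code. Codon alignment is
performed on codon units (gaps in multiples of three, linear gap score,
deterministic leftmost tie-breaking); gap and stop columns are excluded
from dS.

Branch dS lengths on the fixed rooted topology are fitted by
non-negative least squares on the pairwise dS matrix (negative branch
estimates are thereby clamped at zero and logged). The clock rate is
the mean over calibrations of patristic-dS(X, outgroup) / (2 × node
age) — the per-lineage path under the clock assumption; the default
calibrations are dated splits at 184.9 and 311.9 Myr. The age of the
X/Y split is dS(X,Y)/2 divided by the rate, clamped to [0, youngest
calibration], annotated with the bracketing calibrated ages. The CI is
a codon-column bootstrap (default 100 rounds, resampling unit = one
codon column of the concatenated alignment, seed recorded).

## Synthetic clock data

Root coding sequences are drawn from a 40-codon alphabet excluding
codons whose first two bases are TA, TG, TT, CT, AG or CG. This removes
every codon one third-position change away from a stop (so stop
rejection never perturbs the process) and every codon with
first-position synonymous degeneracy (so all synonymous sites are third
positions). Third positions then evolve under exact Jukes–Cantor at the
per-synonymous-site rate, which makes NG86 + JC an unbiased estimator
of rate × time at any divergence — gametolog divergence, outgroup
depths and the calibration are all simulated and estimated in the same
currency, so dating errors do not accumulate with depth. The default
rate, 0.001 substitutions per synonymous site per Myr per lineage, is
the canonical vertebrate neutral rate (~10⁻⁹/site/year); at the default
true age of 116 Myr it implies ~93% X/Y nucleotide identity, inside the
pairing window.

What the simulation does not contain: indels, rate variation among
sites or lineages, codon usage selection, GC-biased gene conversion,
polymorphism. Passing the recovery tests therefore shows the estimator
and calibration logic are correct under a strict clock, not that real
gametolog data meet those assumptions.

## Climate

The per-species statistic is the median (even cardinality: mean of the
central pair) of the flat multiset {cell × breeding-month temperature};
the class summary uses the mean and n−1 SD, with a 1 °C histogram for
plotting. Where the underlying wording of "average" versus "median" is
ambiguous, the per-species statistic is the median and the class
aggregation the mean, and both are exposed as options. A 30-year
climatology is assumed collapsed to a single monthly surface before
extraction. Outlier flagging uses |z| ≥ 3 with a 1-ulp numerical
tolerance so a species planted exactly on the threshold is not
unflagged by floating-point round-off.

The simulator gives each species its own disjoint cell set; TSD and GSD
cohort temperatures follow two normal distributions (defaults 27 ± 4 °C
and 19 ± 5 °C, n = 101 and 99). The focal species is planted against
the *realized* cohort moments — the empirical mean and SD of the
simulated TSD species' extracted temperatures — and its cell-month
values are written without scatter, so its true z-offset is exact by
construction. Planting against the generative parameters instead would
leave ~1/√n sampling noise in the z-score, which would test cohort
sampling rather than the scoring code. Real ranges overlap and share
climate cells; synthetic ones do not.

## Marker enrichment

Markers are searched with a sliding near-exact scan (mismatch budget
⌊0.05 × length⌋, both strands) — for 17–70 bp queries this plays the
role of a stringent short-sequence BLAST without e-value machinery.
The 2×2 enrichment table is [unique hits in/out of the MSY call] ×
[genomic extent in/out], with extent counted in coverage bins by
default (base pairs available via `unit="bp"`). The length-proportional
background is an explicit modelling choice: whether the appropriate
background unit is bp, bins, or genes is a judgement call, and the unit
changes the p-value. The Fisher p is the two-sided sum of
hypergeometric probabilities ≤ that of the observed table at fixed
margins (with the customary 1 + 10⁻⁷ relative slack on the comparison).

## Pipeline and problem sizes

All stage randomness derives from one seed via `SeedSequence` spawning;
the report contains no timestamps or absolute paths, so identical
configs reproduce it byte for byte. The default synthetic genome is
2 chromosomes totalling 1.5 Mb with a 300 kb MSY (3 scan bins), 14
gametolog + 6 Y-specific + 16 autosomal genes of 300 codons, 20× DNA
and 30× RNA at 100 bp — sizes chosen so a full run, including the
100-round bootstrap and the 201-species climate cohort, completes in
about a minute on one core while leaving every statistical signal
(hemizygous ratio, depth window, identity window, 3-SD outlier)
comfortably resolved. Scan-specific tests use a larger 4 Mb genome with
a 1 Mb MSY at the native 100 kb bin size. Dating recovery uses the full
14 × 300-codon concatenation per replicate; recovery is assessed on the
median point estimate over replicate simulations, since a single
replicate at the youngest age carries ~6% sampling error from the
finite number of synonymous sites.

## Known limitations

* The assembler and read matcher assume high-identity, error-free
  reads; real libraries need external assembly/alignment upstream.
* Reference-guided contig ordering (building chromosome coordinates
  from a related genome) is not reimplemented; coverage input is
  already placed.
* The Fisher background construction and the placement model for
  Y-derived reads are explicit simplifications, documented above.
* No indel, splice, repeat, or polymorphism modelling anywhere.
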