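# Methods

## Generative model

The simulator emulates a multiparent evolve-and-resequence design: a base
population founded by `n_founders = 18` sequenced strains, recombined to
quasi-linkage-equilibrium, then evolved in replicate for `n_cycles = 12`
weekly cycles of `gens_per_cycle = 18` mitotic generations each (216
selective generations) punctuated by one round of forced outcrossing per
cycle, at effective size `ne = 750,000`.

**Genome.** The default desk-scale genome is 4 chromosomes × 300 kb rather
than 16 real chromosomes; real chromosome lengths are accepted by
`GenomeGrid` directly. Haplotype frequencies live on a 1 kb locus grid at
positions whose centered 60 kb estimation window fits inside the
chromosome; coverage is summarised in 2 kb bins. All coordinates are
1-based closed, except the BED-like coverage files on disk (0-based
half-open, converted at the boundary).

**Founder panel.** SNPs are placed uniformly at `snp_density = 5` per kb.
A fraction `private_fraction = 0.3` carry their minor allele in exactly one
founder; the rest in 2–17 founders. One tract per chromosome copies one
founder's genotypes onto another so that roughly `twin_fraction = 10%` of
windows contain a locally indistinguishable pair, exercising
synthetic-founder merging. Base haplotype frequencies are per-locus
Dirichlet draws with concentration 20 per founder: near-uniform (mean 1/18
≈ 5.6%) with realistic jitter, which puts the typical private-SNP minor
allele frequency in the few-percent range observed in deeply sequenced
outbred pools.

**Selection and draft.** At a selected locus the favored haplotype follows
the deterministic haploid-selection recursion per cycle of G generations,
`p′ = p(1+s)^G / (p(1+s)^G + 1 − p)`, with the other haplotypes rescaled
proportionally; over c cycles this composes to the closed form with
exponent cG, which the tests verify to 1e−9. A linked neutral locus at map
distance d kb feels an effective coefficient `s·exp(−d·r_kb·c)` in cycle c,
where `r_kb = 0.0075` per kb per cycle (≈90 crossovers per meiosis over a
12 Mb genome). The decay compounds with elapsed cycles because the
association between a hitchhiking locus and the selected allele is eroded
anew by every round of recombination; a time-constant kernel would hold the
whole chromosome under near-constant drag for 12 weeks and blur the LOD
peak by tens of kb. Unlinked chromosomes are untouched. Multinomial drift
at `ne` is applied per locus after each cycle; `ne = inf` disables it, and
a neutral infinite-Ne run is exactly frequency-preserving.

**Measurement error.** Haplotype-estimation noise is zero-mean Gaussian on
the raw frequency scale (where the error magnitudes are defined), clipped
to [0, 1] and renormalized per locus: `eps_base = 0.004` for the deeply
(>2000x) sequenced base, `eps_evolved = 0.01` for evolved populations.

**Cheaters.** A haploid cheater fixes one random recombinant mosaic
genome-wide (junction rate 0.02 per kb), except a configurable mating-type
window held heterozygous at 0.5/0.5. A diploid cheater fixes a single
heterozygous clone built from two mosaics; the second genome copies the
first per segment with probability `relatedness = 0.35`, reflecting the
shared intercross ancestry of any two genomes drawn from the base
population, so both heterozygosity modes (0 and 0.5) hold well over 10% of
loci.

**Coverage and pools.** Bin coverage is Poisson; a duplication of g extra
copies on a diploid baseline scales the evolved expectation by (2+g)/2,
proportionally for partially overlapping bins. Pooled SNP counts are
Binomial(depth, truth) with truth the genotype-weighted local haplotype
frequency — binomial sampling is the dominant error for pools of ~1e8
cells.

What the generator does **not** emulate: sequence-level reads, epistasis,
clonal interference within a haplotype class, explicit meiosis/tetrad
structure, spatially autocorrelated estimation error, and the
mosaic-induced long blocks of real founder genomes beyond the planted twin
tracts. Passing tests therefore demonstrate the statistical machinery is
calibrated and recovers planted truth under the stated model, not that the
error model of any particular sequencing pipeline is captured.

## Windowed haplotype estimator

The full sliding-window haplotype caller of the source experiment is out of
scope; the package ships a deliberately simple stand-in with the same
contract. Founders with identical genotype vectors over a window's SNPs
are merged into a synthetic founder (label = concatenated member names,
frequency = sum of members). Observed pooled SNP frequencies are regressed
on the merged genotype matrix by non-negative least squares with the
sum-to-one constraint imposed through a heavily weighted (100×) augmented
row, followed by renormalization — exact on consistent systems, and a
probability vector by construction. If the merged matrix is still
rank-deficient (linear dependence without equality) a warning is issued
and the non-identifiable split is left to the NNLS minimizer. On simulated
18-founder pools at 111x the mean absolute per-haplotype error is ~0.005,
and error decreases monotonically in coverage (tested at 20x/111x/500x).

## Scan statistic

Degrees of freedom K are per locus (haplotypes at ≥0.5% base frequency;
synthetic founders make K vary along the genome). The replicate variance
term uses the unbiased (n−1) estimator and is averaged over the K tested
haplotypes of that locus, then shared across them. The measurement-error
variances enter on the transformed scale exactly as written above — they
are not re-scaled through the arcsine derivative — which double-counts
error at interior frequencies and makes the test conservative; the null
calibration test (2,000+ loci) verifies type-I error ≤ 0.075 at α = 0.05
and one-sided KS stochastic dominance over uniform.

Numerics: the reported p-value is floored at 1e−300, but the LOD column is
computed from the log survival function with an asymptotic
incomplete-gamma fallback for extreme statistics, so loci with p below the
floor remain strictly ordered (a flat floor would turn a selected
chromosome into a LOD plateau and break peak localization). Zero total
variance (identical replicates with zero assumed error) yields Δ = 0 where
δ̄ = 0.

**Peak caller.** Candidate peaks are strict local maxima (plateaus take the
leftmost locus); candidates are accepted greedily in decreasing LOD order
(ties to the left) and rejected within 2 × `min_separation` grid steps of
an accepted peak, so called peaks are pairwise ≥100 kb apart at the
defaults. Flanking minima are the nearest local minima (or chromosome
ends).

## Classification thresholds

The three population classes are separated by configurable thresholds
(defaults: haploid iff mean H < 0.1 and ≥90% of non-mating-type loci have a
haplotype above 0.9; diploid iff the 0-mode (H < 0.1) and 0.5-mode
(H ∈ [0.4, 0.6]) jointly hold ≥80% of loci with each mode ≥10%; otherwise
outbred sexual). These are engineering choices that operationalize
qualitative signatures; the skewness of the H distribution is reported but
not used as a hard criterion. The cladogram retention filter uses
1 − Spearman correlation of concatenated genome-wide frequency vectors and
a majority vote over q = 3 nearest neighbours; treatments keep ≥6 retained
sexual replicates (the no-drug control is exempt).

## Duplications and SNVs

The CNV HMM is two-state Bernoulli over the thresholded (≥1.25) fold-
coverage indicator: duplicated state emits 1 with probability 0.9, normal
with 0.05, symmetric switching 1e−4, decoded by the most-probable path
(a continuous-emission variant was considered and rejected for simplicity;
the binarized track is what the detection rule defines). Calls spanning
≥95% of a chromosome are labelled whole-chromosome. Note that relative-
coverage normalization shrinks the observed fold change of large
duplications (the duplication inflates the evolved genome mean), so a
2-extra-copy call on a third of a chromosome reports fold ≈ 1.7, not 2.0.

De novo SNV filtering annotates every candidate with the first failing
filter (founder variant → base population → depth → alt fraction →
cross-treatment recurrence) and is idempotent and order-invariant; the
"present in base" filter is a position blacklist of base variants at any
nonzero observed frequency. Multi-hit genes require SNVs from ≥2 distinct
replicates of the same treatment overlapping one annotated gene.

## Rates and fitness

`r0 = ln(10)/24` per hour encodes a culture that exactly survives a daily
10-fold dilution. The evolved rate uses the source convention
`r12 = e·m` (m = OLS slope of log10 counts on hours), giving fold change
`24·e·m/ln 10 ≅ 28.3·m`; the dimensionally conventional `ln(10)·m`
alternative is available via `convention="ln10"` and is clearly labelled
as the non-default. Recombination-rate comparisons are pure arithmetic on
crossovers per meiosis, meioses per division, genome size and gene count,
with the fitness-adjusted variant replacing 1/mitoses by
1/(10·fitness_gain + 10).

## Problem sizes and reproducibility

Default test and acceptance problem sizes are desk scale, chosen so the
full suite runs in well under a minute of simulation per scenario: 4 × 300
kb genomes (960 grid loci), 8 replicates, 50-seed recovery experiments,
2,000-locus null calibrations, 200-window estimator benchmarks, 50 + 50
planted/null CNV profiles. All randomness flows from explicit integer
seeds through per-operation child streams (`SeedSequence` spawn keys), so
every table, simulation and pipeline run is bit-reproducible; the pipeline
writes a config-hash + seed + version provenance header on every output.

The heterozygosity–repeatability association (less heterozygous cohorts
evolve less repeatably) is reproduced in sign on a cohort of six simulated
treatments differing in the number of selected loci at Ne = 2,000: the
association is driven by drift-amplified divergence among replicates, so a
cohort at the experiment's Ne ≈ 750,000 — where evolution is essentially
deterministic — would show only measurement noise. This is a statement
about the synthetic cohort used to exercise the metric, not an estimate of
the real experiment's stochasticity.

## Known limitations

- The windowed estimator is a contract-compatible stand-in, not a
  reimplementation of the source caller; its accuracy characteristics are
  its own.
- Draft is a deterministic kernel, not genealogical hitchhiking; linked
  diversity patterns (sweep shoulders, haplotype blocks) are stylized.
- The exact 11,604-locus grid of the source experiment is not
  reconstructed; the window-fits-inside-chromosome rule stands in.
- Real-data headline figures (e.g. the fraction of the genome above LOD 5
  in the actual experiment) depend on the real genome and coverage and are
  not targets of the synthetic runs.
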