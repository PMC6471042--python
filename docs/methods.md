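# Methods

## Pipeline model

The analysis consumes per-fraction nascent-DNA read positions (or pre-binned
counts) from a Repli-seq experiment and proceeds in fixed stages. All
coordinates are 0-based half-open; strand is ignored throughout; every
binned quantity carries a validity mask and downstream statistics use only
valid bins.

**Binning and spike filtering.** Reads are counted into 1 kb windows by
alignment start. Windows whose count Z-score (against the genome-wide mean
and sd of currently valid windows) exceeds 2.5 are masked; the test is
one-sided because the artifact being removed is PCR/alignment signal pile-up,
while deficient bins are the province of mappability masking. Counts are
then summed into 50 kb analysis bins; a 50 kb bin is kept when at least half
of its surviving 1 kb children are valid (`min_valid_fraction = 0.5`).

**E/L profiles.** Each fraction is scaled to reads per million over its
valid bins (so the log-ratio is not library-depth biased; this can be turned
off), and the profile is `log2(early/late)` — S1/S3 in the four-fraction
asynchronous design, 4h/10h in the three-timepoint synchronized design.
Bins with fewer than `min_count = 10` raw reads in either fraction are
marked missing rather than ratio'd: at 10 reads the log2-ratio sd is already
≈ 0.65, and admitting lower-count bins gives the genome a heteroskedastic
noise floor that the downstream global Z-statistic cannot absorb (it assumes
comparable per-bin variance and becomes anti-conservative in the
high-variance subpopulation). `min_count = 0` restores plain zero-count
invalidation, and a `pseudocount` mode (+0.5 to both counts) is available.

**Normalization and smoothing.** The two profiles being compared are
quantile-normalized jointly on their shared-valid bins (rank k value →
mean of both profiles' rank k values; ties receive the mean of their tied
targets), then loess-smoothed per chromosome: a tricube-weighted local
linear regression over valid bins within a fixed ±150 kb genomic window
(span 300 kb). Local linear fits reproduce constant and linear profiles
exactly, which the tests assert to 1e-9. The span is genomic, not a data
fraction, so smoothing bandwidth does not vary with chromosome length.
Estimates supported by fewer than `min_support` in-window valid bins are
marked missing in the pipeline (`min_support = 5` of the 7 window bins):
an estimate averaging 4 of 7 points carries ≥ 30% more sd, and such
gap-edge bins otherwise dominate false discoveries. Calling `loess_smooth`
directly defaults to `min_support = 2` with pass-through for degenerate
chromosomes.

**Differential timing.** Over bins valid in both smoothed profiles and with
mappability score > 0.5, `d = control − treated` is standardised with its
sample mean and sd (ddof = 1), two-sided normal p-values are
Benjamini–Hochberg adjusted, and bins with adjusted p < 0.05 are called
significant. Dispersion of the calls is summarised by the median
start-to-start distance between consecutive significant bins per chromosome.
Two experiments' significant sets are intersected by bin identity with
same-sign / opposite-sign counts from the sign of `d` in each.

**Weighted RT.** `wrt = Σ w_i f_i / Σ f_i` over all fractions'
reads-per-million, with default weights (1, 2/3, 1/3, 0) for S1–S4 and
(1, 1/2, 0) for the three timepoints — evenly spaced, earliest high. The
statistic is invariant to any fraction's library size by construction.
Feature sets are scored by the unweighted mean of overlapping valid bins
(BEDOPS `bedmap --mean` semantics; an overlap-length-weighted mode exists).
Differentially expressed genes are selected with linear fold change > 2
(repression < 1/2), adjusted p < 0.05, RPKM ≥ 0.5; a flag reinterprets the
fold-change column as log2.

**Boundaries.** Domain interval lists become boundary point sets
(deduplicated starts and ends). Classification tests absolute point-to-point
distance on the same chromosome, tolerance 500 kb inclusive, with precedence
compartment-proximal → invariant → Scc1-dependent, so the three classes
partition the input. Metaplots collect profile values at ±5 Mb of each
boundary (windows truncated at chromosome ends, missing bins skipped) and by
default flip each window so its higher-RT side lies at negative offsets —
without orientation, opposing domain transitions cancel. The summary
statistic `mean_step(max_offset)` compares the mean left and right of the
boundary; a ±250 kb window isolates the local step, since wider flanks
average over unrelated neighbouring domains.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
bit-identical output per (spec, seed).

**Landscape.** Domain lengths are gamma (mean 1 Mb, shape 4, minimum
200 kb); domain RT values are normal (mean 0, sd 1.5 log2 units); adjacent
domains are joined by linear 100 kb ramps. Defaults use a 2 × 50 Mb genome.

**Counts.** A locus's RT maps to an S-phase time `t = 1/(1+exp(rt/s))`
with scale `s = 2`: the scale was chosen so that the ±3 log2-unit spread of
domain RT occupies the informative part of the gate layout below, rather
than saturating it (any strictly monotone map would do in principle; a
steeper one wastes dynamic range at the extremes). Fraction *i* captures the
locus with a Gaussian gate kernel `exp(−(t−c_i)²/2σ²)`, σ = 0.15, centers
evenly spaced on [0.3, 0.7], mixed with a uniform cross-contamination floor
(`gate_contamination = 0.05`): FACS sort gates are imperfect, and a model in
which the earliest fraction receives literally zero reads from late loci is
unphysical and makes the E/L ratio undefined over much of the genome.
Counts are Poisson with mean `depth · n_fractions · share / 50` per 1 kb bin
(so `depth`, default 100, is the mean reads per 50 kb bin per fraction);
a negative-binomial mode adds overdispersion. Spike artifacts multiply the
rate of random 1 kb bins by 50 (rate 5e-4); unmappable regions (5% of the
genome, exponential lengths of mean 100 kb, shared between conditions) zero
the counts and define the 50 kb mappability track as the mappable-children
fraction.

**Condition pairs.** The treated condition shares the control landscape
except for `n_shifted_domains` domains whose RT is flipped toward the
opposite timing half by `shift_size` (default 2) log2 units. Shifted domains
are drawn from the mid-timing band (|RT| in [0.75, 1.25]) so that both
endpoints stay inside the S-phase window the gates resolve — the simulated
perturbation is an early↔late domain switch, the kind of change the assay
can actually measure. Among candidate subsets, the generator keeps the one
whose total length is closest to `n × mean domain length` (dose control):
without it the injected genome fraction varies ±30% between seeds, which —
see the limitation below — flips the benchmark between regimes and measures
seed luck rather than the caller. Ground truth records fully shifted 50 kb
bins (mean |ΔRT| ≥ 0.9 × shift), partially shifted ramp bins, and the
per-domain shift table.

**Boundary and gene files.** Compartment boundaries are a 30% subset of
RT-domain switches. Control TAD boundaries mix an invariant half placed at
remaining switches (boundaries that survive cohesin loss track compartment
/ timing structure) with a cohesin-dependent half placed uniformly; treated
boundaries are the invariant subset jittered by ≤ 100 kb. True classes are
recorded by an exhaustive all-pairs distance scan over the emitted
positions — deliberately a different code path from the package classifier.
The gene table plants known induced (fold change > 2) and repressed
(< 1/2) genes among decoys that each violate one cutoff.

**What the generator does not emulate.** Read-level sequence artifacts, GC
and replication-independent copy-number bias, correlated (wave-like) noise
along chromosomes, biological replicate variability, realistic mappability
structure (alignability tracks are smooth, not binary), and Hi-C contact
matrices themselves. Passing tests therefore show the statistical machinery
is correct and calibrated under the stated count model, not that real
libraries meet that model.

## Known limitations

**The global Z-score saturates when much of the genome shifts.** Because
`sd(d)` includes the shifted bins, the attainable |Z| for a shifted bin is
capped near `1/√f` when a fraction `f` of included bins carries the shift —
about 3.0 for `f ≈ 0.1` including ramp bins — while Benjamini–Hochberg at
α = 0.05 needs |Z| ≈ 2.84 at that discovery rank. The margin is a fraction
of a σ, so recovery of a 10-domain / ~10%-of-genome perturbation plateaus
around 85–92% of shifted bins regardless of depth, and can collapse
entirely at low depth; bins within ~100 kb of a shifted-domain edge have
their smoothed difference diluted below the cutoff by the 300 kb span and
are systematically missed. Smaller perturbed fractions (f ≤ ~0.06) are
recovered essentially completely. The power benchmark in the tests and
acceptance script therefore runs at 800 reads per 50 kb bin per fraction
(deep but attainable coverage) pooled over three simulations, and its
sensitivity should be read against this ceiling. A robust standardisation
(median/MAD) would remove the saturation but would change the published
statistic, so it is not the default.

**Coverage floors trade coverage for calibration.** At 30 reads per bin per
fraction, the `min_count = 10` floor excludes roughly two thirds of bins
(count-starved early/late extremes); calibration numbers at that depth
describe the included set.

**Problem sizes.** The test-suite and acceptance runs use 2 × 50 Mb genomes
(2,000 analysis bins), 20 seeds for null calibration, 3 pooled seeds for
power and metaplot comparisons, and 200 replicates of 10,000 draws for the
Benjamini–Hochberg check — sizes chosen so the full loop runs in seconds
per simulation while keeping Monte-Carlo error well below the margins being
asserted.
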