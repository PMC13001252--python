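# Methods

This note documents the models, algorithms and numerical choices behind
`tnarray`, and what the synthetic-data conditions do and do not show about
real pooled-library data.

## Pooling geometry

A library occupies a `grid_rows x grid_cols` array of plates with
`plate_rows x plate_cols` wells each. Four pool axes (well column, well
row, plate column, plate row) give every well a unique 4-pool signature;
the pool count is the axis sum `plate_cols + plate_rows + grid_cols +
grid_rows` and the capacity is the product of the four dimensions. For the
classic 19x19 grid of 96-well plates that is 58 pools and 34,656 wells.
Descriptions of this scheme sometimes quote a smaller total pool count for
the same geometry without stating which pools were merged; `tnarray` always
uses the axis sum, and the constructor accepts arbitrary dimensions (plus
an optional occupied-plate subset for partially filled grids) so any
variant geometry can be expressed explicitly. Well rows are lettered and
1-based, all other coordinates numeric and 1-based, following 96-well
convention.

## Saturation model

Under uniform per-bp insertion, a gene of length `L_g` in a genome of `G`
bp is missed by all of `n` picks with probability `(1 - L_g/G)^n`, so the
expected fraction of ORFs hit is `C(n) = mean_g [1 - (1 - L_g/G)^n]`. This
closed form is the oracle for the Monte Carlo estimator, which draws actual
insertion positions per replicate (vectorized `searchsorted` against sorted
gene intervals) and reports mean ± sd over replicates. Genes are treated as
non-overlapping intervals. A TA-site model (uniform over TA dinucleotides,
position recorded at the T) is provided because mariner-family transposons
insert at TA sites; the per-bp model is the default since GC-rich genomes
make the two nearly indistinguishable at library scale and the per-bp model
needs no sequence. `mutants_for_target` inverts the monotone analytic curve
by doubling then bisection; an optional Monte Carlo confirmation warns if
the simulated mean falls more than three standard errors short.

## Deconvolution

Per site and axis, counts are summarized as (top coordinate, top count,
second-highest count); the SNR is top/second, defined as +inf when the
runner-up is zero with a non-zero top and 0 when the axis is empty. An axis
resolves when `top >= primary_threshold` (default 50 reads) **and**
`snr >= snr_threshold` (default 9); an exact tie means SNR 1 and stays
unresolved. Defaults follow the thresholds used in practice for this kind
of data; both are exposed in `DeconvolutionConfig`.

Unresolved axes keep a candidate set: coordinates with count
`>= max(candidate_floor, top / snr_threshold)` (floor default 10). The
`top/snr_threshold` term keeps exactly the coordinates that *could* have
been the true signal given the observed peak; the absolute floor discards
contamination-level counts. This candidate rule is a design choice of this
implementation — interactive curation tools leave it to operator judgment —
and is fully parameterized.

First pass: sites resolved on all four axes are placed (`auto`) at the
coordinate intersection. Sites with ≥ 2 axes each carrying ≥ 2 coordinates
above the primary threshold are `multilocated` (the signature of a
duplicate clone picked into several wells) and are excluded from placement
rather than guessed. Two `auto` sites claiming one well are both demoted to
`ambiguous` instead of raising, since real pools contain artifacts.

Triangulation: unresolved sites are visited in descending total-read order
(ties broken by site id, making the procedure deterministic); a site whose
candidate wells — the Cartesian product of its per-axis candidate sets
minus wells already occupied by `auto`/`triangulated` sites — reduce to
exactly one is placed and immediately blocks that well. Sweeps repeat to a
fixpoint (cap `max_rounds = 100`, warning on truncation). Afterwards, sites
with several surviving candidate wells are `ambiguous`, with none
`unresolved`. The assigned-well set is injective at every stage, and
triangulation never revisits an `auto` placement.

Counts are thresholded as absolute reads, not depth-normalized: the
absolute primary threshold is part of the method's definition. The SNR is a
within-axis ratio and is depth-invariant.

`brute_force_oracle` re-derives the same classification with candidate
wells computed by exhaustive enumeration over every well of the design each
sweep, sharing only the per-axis threshold arithmetic with the pipeline. It
refuses plate grids larger than 4x4. Pipeline-vs-oracle equality over 100
seeded noisy instances is part of the test suite.

## Synthetic data

`generate_reference` lays non-overlapping genes with lognormal lengths
(mean ≈ 900 bp, floored at 120 bp) separated by multinomially split
intergenic gaps (default 10% of the genome), on a random GC-rich sequence
(GC 0.67). Essentiality labels (non-essential, high-fitness, essential) are
apportioned by largest remainder — exact counts, no rounding drift — with
default proportions (0.832, 0.042, 0.126) matching the strata of a
3,767-ORF alpha-proteobacterial annotation, then shuffled over genes.

`simulate_picking` fills wells in plate order. Each pick is a fresh uniform
insertion position except with probability `duplicate_rate` (default 0.36,
the duplication level implied by ~22,000 unique sites among ~34,700 picks)
an existing clone is re-picked into the next free well. Essential-gene
policies: `allow`, `exclude` (rejection sampling), or `ends-only`
(insertions in essential genes restricted to the terminal 10% of the gene —
the pattern expected when only near-terminal disruption is viable).

`simulate_pool_counts` builds the member multiplicity matrix (union of the
four pools of each well holding a site) and draws:

- per-pool depth factors ~ lognormal(sd 0.25, unit mean) — uneven pooling
  and sequencing depth;
- member counts ~ NegBin(mean = depth x factor x multiplicity, size =
  `dispersion`, default 5) — overdispersed pool counts; `dispersion=None`
  makes member counts deterministic;
- dropout: each member cell zeroed with probability δ (default 0.01);
- contamination: each non-member cell receives Poisson(λ = 3) reads with
  probability ε (default 0.005).

Defaults are depth 500, dispersion 5, ε 0.005, λ 3, δ 0.01. All five
sources draw from independent child streams of one seed, and ε enters only
as a threshold on a pre-drawn uniform matrix: for a fixed seed, raising ε
contaminates a strict superset of cells and leaves every other draw
untouched. That common-random-number design makes degradation ladders
exactly monotone, which the tests exploit.

`NoiseModel.noise_free()` is the reference condition (deterministic member
counts, even pools, ε = δ = 0) under which deconvolution must recover 100%
of singly-placed sites as `auto`. Deterministic member counts matter here:
with NegBin counts at mean 500, a ~2.6e-4 per-axis tail falls below the
50-read threshold, which on thousands of sites would break exact
completeness for reasons unrelated to the algorithm.

What the synthetic model does **not** emulate: sequencing error and
barcode hopping, PCR chimeras and jackpotting, positional effects within
plates, biological fitness differences among mutants, and genuinely
TA-constrained insertion in the picking step. Passing tests therefore
demonstrate algorithmic correctness under a plausible noise envelope, not
performance guarantees on any particular real dataset.

## Library assembly

Gene fraction is `(pos - start) / L` on the + strand and `(end - pos) / L`
on the − strand with `L = end - start + 1` (1-based inclusive coordinates):
0 at the translational start, < 1 always, and invariant under strand
relabeling with coordinate reflection. Annotation conventions differ here;
this one is stated once and tested. Insertions in overlapping genes count
for every containing gene.

`build_collection` keeps per gene up to three entries with distinct
insertion positions, ascending by gene fraction (ties by position, then
site id); rank 1 — the most upstream insertion, most likely to truncate the
product — is the consolidated representative. Intergenic placements are
retained as controls. Coverage reports stratify by essentiality class with
percentages rounded half-up to one decimal (the convention that makes
published stratified tables self-consistent); insertion-position
histograms use 20 left-closed bins of width 0.05 on [0, 1).

The redundancy-accuracy model treats each mutant's annotation as
independently correct with probability p (default 40/53 ≈ 0.755, the rate
from re-sequencing 53 randomly chosen mutants); a gene with k insertions is
then correctly represented with probability `a_k = 1 - (1-p)^k`, and the
collection-level expectation is the redundancy-share-weighted mean of
`a_k`. An option rounds each `a_k` half-up to two decimals before weighting
to match expectations quoted from percentage-precision intermediates.

## Screen statistics

Biofilm signal is OD540/OD660 per well; wells with OD660 ≤ 0 are masked.
Hit calling averages the normalized signal across replicates (m) and
compares it to the plate mean μ — computed per replicate over unmasked
wells, excluding designated controls by default (a flag includes them), then
averaged: `increased` if m ≥ fold·μ, `decreased` if m ≤ μ/fold (default
fold 1.5). Calling on replicate-averaged values (rather than per-replicate
votes) is the documented choice. The t-test is the classic two-sided
pooled-variance form via `scipy.stats.ttest_ind`, with Welch's correction
behind a flag; no multiple-testing correction is applied by default, with
Benjamini–Hochberg left to the caller's statistics stack.

## Test scale

The suite and the acceptance script run everything at desk scale, chosen as
the package's own study conditions: the full-recovery and contamination
ladders use a completely picked 5x5 grid of 96-well plates (2,400 wells,
150 genes); oracle-equivalence uses 100 seeded noisy instances on a 2x2
grid of 4x6 plates (60 picks each); Monte Carlo checks use 50 genes and
1,000 replicates. The 19x19 geometry is exercised for its arithmetic
(capacity, pool naming) rather than simulated end to end, which changes
nothing algorithmically — every code path is identical across design sizes.
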