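# Methods

## Overview

`haploscan` scans phased, gap-free biallelic haplotype data from a single
chromosome for footprints of recent positive selection. It combines three
components: (i) linear-time enumeration of *maximal perfect haplotype
blocks* with the positional Burrows–Wheeler transform (pBWT), (ii) a
closed-form maximum-composite-likelihood (MCL) estimator of the selection
coefficient *s* for every block under a deterministic selective-sweep
model, and (iii) two model-based filters that remove blocks explainable by
genetic drift or by chance recent common ancestry. Everything downstream
of the input is deterministic; the only randomness in the package lives in
the simulation module.

## Maximal perfect haplotype blocks

A block (K, i, j) is a set of at least two haplotype rows that are
identical over the column interval [i, j] and extensible neither left,
right, nor by another row. Blocks are identity-by-state segments treated
as identical by descent; because a block is the *intersection* of its
haplotypes' shared segments, its length understates the span of any
individual haplotype and the age inferred from it is biased old, which in
turn biases ŝ conservatively downward.

The enumerator maintains Durbin's pBWT arrays a_j (colexicographic prefix
order) and d_j (divergence: first column where neighbouring sorted
prefixes agree through j). Blocks ending at column j correspond to
intervals of sorted rows whose interior divergence maximum equals the
block start i, bounded on both sides by strictly larger divergence; they
are found with a monotone stack in O(k) per column, and right-maximality
is tested in O(1) per candidate via prefix sums of a next-column change
indicator. Total work is O(nk + z) for z blocks. The hot loop is
compiled with numba and runs twice — once to count blocks, once to fill
exactly-sized output arrays — because growing output buffers inside the
kernel costs an order of magnitude more than a second pass. Row sets are
materialized lazily by replaying the pBWT; the columnar representation
(i, j, a-interval) is what the pipeline computes on.

Correctness rests on an exhaustive oracle (`naive_blocks`): for every
column interval, rows are grouped into substring equivalence classes and
the three maximality conditions are checked directly. The two
enumerations agree exactly on 1,000+ random matrices.

## Sweep model and estimator

Each block is summarized by its sample frequency y = |K|/k and the
recombination fraction r of its genetic length (Haldane's map function,
r = (1 − e^(−2d/100))/2 for d in cM). Under a hard sweep with additive
fitness (heterozygote 1 + s/2) a haplotype at frequency y rose
logistically from y₀ = 1/(2Nₑ) in

    t = (1/s) ln( y(1−y₀) / (y₀(1−y)) )  generations,

and a flanking interval of recombination fraction r survives the sweep
unbroken with probability C(s, r, y) = e^(−rt)(1 − y₀(1 − e^(st)))^(r/s),
which simplifies exactly to (y₀/y)^(r/s). Treating the 2|K| block edges
as independent (star genealogy) gives the log composite likelihood

    ln L(s | r, y) = 2|K| ( (r/s) ln(y₀/y) + ln(1 − (y₀/y)^(Δr/s)) ),

with Δr the recombination fraction between contiguous SNPs (default: the
Haldane transform of the mean inter-SNP map distance of the analyzed
sites). Setting the derivative to zero yields the closed form

    ŝ = Δr / ln( r/(Δr+r) ) · ln( y₀/y ),

verified against golden-section maximization on hundreds of random
parameter draws. Degenerate blocks (r = 0 or y ≤ y₀) get a flagged ŝ = 0
and never pass the filters; fixed blocks (y = 1) are dated at
y = 1 − 1/(2k), one sample chromosome short of fixation, which keeps ages
finite at the sample's frequency resolution. All likelihood math runs in
log space; underflow returns −∞, never NaN.

Substituting ŝ back into the age formula gives two age estimates:
t̂₁ with y₀ = 1/(2Nₑ) (one copy) and t̂₂ with y₀ = 1/Nₑ (two copies,
a lower proxy for the block's TMRCA since t₁ > t₂ ≥ t_MRCA). Both are
attached to every reported block.

## Filters

Both filters bound the *age* of a reportable block from above — a block
must be too young for a neutral process to have produced its frequency
and extent.

**Drift filter.** The Wright–Fisher allele-age CDF approximation
Pr(t₁ ≤ t) = (1−p)^(−1+n/(1+nt/2)) (t in units of 2Nₑ generations, p the
sample frequency, n the number of sample chromosomes) is inverted to
t₁(q) = 2ln(1−p)/(ln q + ln(1−p)) − 2/n. The quantile q is adaptive: the
age t′ a sweep at the minimum reportable coefficient s_min would need to
reach p is mapped through the CDF and clamped to [0.01%, 1%]. A block
passes iff t̂₁ < 2Nₑ·t₁(q). Blocks older than that are attainable by
drift alone. s_min defaults to 0.005, below the smallest coefficient in
the validation designs (0.0075) and the lowest genome-track highlight
tier (1.5%); t′ (generations) is divided by 2Nₑ before entering the CDF,
which works in units of 2Nₑ generations.

**Coalescent filter.** For |K| lineages jointly conserving a segment of
recombination fraction r, the neutral TMRCA is a hypoexponential sum of
stage times with rates λᵢ = i(i−1+2Nₑr)/(2Nₑ), i = 2..|K| (rates as
published, i.e. pairwise coalescence at 1/Nₑ per generation; the
recombination term adds i·r per stage). A block passes iff t̂₂ falls
below the *first percentile* of that distribution — i.e. its age estimate
is recent enough to reject neutral common ancestry at the 1% level. This
is the direction the filter's purpose requires: a small family of close
relatives shares long segments with a large t̂₂ (tiny ŝ) and is removed,
while a genuine sweep produces an anomalously young t̂₂ and survives.
Published prose descriptions of this filter can be read in the opposite
direction (remove the young blocks); implemented that way, the scan
reports nothing at all — neither false positives on neutral data nor
true positives on strong sweeps — which no working selection scan could
exhibit, so the substantive direction is used.

**Exact TMRCA distribution and the gamma surrogate.** The hypoexponential
CDF is evaluated two ways: a phase-type matrix exponential of the
bidiagonal stage-chain generator (small |K|; the test oracle) and Talbot
numerical Laplace inversion of ∏(1+βᵢθ)^(−1)/θ evaluated in log space
(any |K|; the two agree to ~1e-10 where both apply, and well below the
1e-4 documented contract). The lookup table stores first percentiles of
a single-gamma surrogate that conserves the exact mean (shape·scale =
μ = Σβᵢ) and whose scale is anchored so the gamma CDF reproduces the
exact CDF at the working percentile; the fitted scale falls inside
μ/(k−1) ≤ β̂ ≤ max βᵢ across the test grid, with k = 2 collapsing to the
exact exponential. A published root equation for the scale is
dimensionally inhomogeneous as printed and, in the unit conventions where
it has a root at all, misses the first percentile by up to ~57%; plain
moment matching (the obvious fallback, kept as a guard for
near-degenerate corner cells) misses by up to ~66% at small r. The
anchored fit was chosen because the filter consumes exactly one
functional of the distribution — its lower tail — and the exact
distribution is the ground truth.

**Lookup table.** First percentiles are precomputed per Nₑ on a geometric
k-grid (ratio ≈ 1.4, capped at the sample size) × an r-grid of
{0} ∪ 64 log-spaced points in [1e-8, 0.5], serialized as self-describing
TSV (`#Ne=`, `#k_grid=`, `#r_grid=` headers; 17 significant digits, so
round-trips are bit-exact). Queries interpolate bilinearly in
(log k, log r), exactly at nodes, linearly in r below the smallest
positive node, clamped at the grid edges; interpolation error is under 5%
at random off-grid points. q01 grows with k (more coalescence stages)
and shrinks with r (faster stage rates); both monotonicities are asserted
on every built table.

## Pipeline

Stages run in fixed order: read VCF → attach genetic map (linear
interpolation of cM at sites missing from the map, clamped at the ends) →
drop SNPs inside centromere/telomere masks → enumerate blocks → annotate
geometry → estimate ŝ and ages → drift filter → coalescent filter →
remove blocks intersecting assembly gaps → remove blocks hidden behind a
containing block with an equal or higher ŝ (ties keep the longer block,
then the earlier start; resolved with a max-Fenwick tree over end
coordinates, checked against a quadratic oracle) → write the blocks TSV,
BED5 and per-position-maximum bedGraph tracks, and a JSON summary with
per-stage counts. Physical coordinates are 1-based inclusive internally
(VCF convention); all BED output is 0-based half-open. Alleles are used
exactly as coded (REF = 0, ALT = 1) — blocks are polarization-independent
— and any unphased or missing genotype is a hard error naming the record.
The Nₑ of a supplied lookup table must match the scan's Nₑ.

The MAF filter (`--maf-min`) defaults to off; 1% is the recommended
setting for real whole-genome sequencing data, where rare genotyping
errors and very recent mutations fragment IBD blocks. Note the
interaction documented below for simulated data.

## Simulation module

`simtools` generates every input the tests and the acceptance script
need; nothing is downloaded or stored.

* **Planted matrices** — i.i.d. Bernoulli(1/2) backgrounds with forced
  identical regions; ground truth is defined by the exhaustive oracle, so
  truth includes chance background blocks.
* **Neutral samples** — msprime coalescent simulations with binary
  mutations on discrete sites (collisions discarded; at these rates the
  retained sites behave as under infinite sites), constant recombination
  (hence a linear cM map). Demographies: constant (Nₑ = 10,000
  diploids); a bottleneck (10,000 diploids reduced to 5% for 10
  generations, 1,120 generations before sampling); a two-deme split
  (2 × 10,000 diploids, symmetric migration 3.11e-5, split 1,120
  generations ago, deme 0 sampled); and a three-population
  Out-of-Africa model with exponential growth (ancestral 7,310;
  African 14,474; bottleneck 1,861; European growth 0.38%/generation from
  1,032 at the 920-generation split; published migration rates).
  Defaults: 1 Mb region, recombination 1e-8 and mutation 2.5e-8 per bp
  per generation, 1,000 sampled diploids — the validation conditions with
  the region scaled down from 10 Mb.
* **Sweep samples** — msprime's structured-coalescent sweep model: the
  selected-allele frequency trajectory is generated internally and the
  genealogy is simulated conditional on it (the standard hybrid
  alternative to forward simulation of every individual). Its *s* is
  defined with heterozygote fitness 1 + s/2, identical to the additive
  convention above, so coefficients map one-to-one. The sweep ends at
  the target frequency, so the sample is conditioned on the
  selected-allele frequency at sampling; the realized carrier frequency
  is read off the focal tree as the clade nearest the target count.
  Replicates with s = 0 or target frequency 0 are neutral and labelled
  lost. Multi-deme sweeps are not supported by the coalescent machinery;
  sweeps on an Out-of-Africa-like history use a single-population
  piecewise rendering of the European lineage (geometric-mean size over
  the growth epoch, then the bottleneck/African/ancestral sizes).
* **SNP downsampling** — uniform, or matched to a target minor-allele
  frequency spectrum on equal MAF bins (best effort with logged deficit),
  preserving column order. This emulates reducing sequencing-density
  panels to genotype-array density.

What the simulations do *not* emulate: genotyping and phasing errors,
gene conversion, variable recombination and mutation rates along the
chromosome, and background selection. Passing the statistical acceptance
checks therefore demonstrates correct behaviour under the model's own
assumptions, not robustness to those real-data complications.

## Validation design and measured behaviour

The acceptance suite reruns the scaled validation designs end to end:
false-positive rate = fraction of neutral replicates reporting at least
one block (50 constant-model replicates; 20 each for bottleneck and
migration, compared through binomial intervals against the published
rates); accuracy = median of the best reported ŝ in the central third of
the region divided by the true s, over sweep replicates that report at
least one central block, at selected-allele frequency 0.5 for
s ∈ {0.01, 0.02, 0.05} (20 replicates per coefficient, 2 Mb region so
the strongest sweep's ~0.5 cM footprint is not truncated — at 1 Mb
truncation inverts the accuracy ordering). Accuracy is conditioned on
detection because the published accuracy summaries are computed over
blocks that pass the filters, while non-detection appears separately as
the minimum-frequency trend; at the weakest coefficient the detection
rate at this scale is ~50%, so the unconditional median would be a
bimodal, seed-dominated statistic. The published qualitative trends are
asserted as orderings: detection power increases with s, and accuracy
drops near fixation (checked at target frequency 0.95).

One interaction deserves emphasis: applying the 1% MAF filter to the
*simulated* samples (2,000 chromosomes) removes exactly the variants that
distinguish rare clades of ~20–50 haplotypes, manufacturing
region-spanning "perfect" blocks out of young neutral families and
inflating the false-positive rate by two orders of magnitude. The
validation designs therefore run without the MAF filter; the same
mechanism is why real-data scans should choose the MAF threshold with the
sample size in mind (the published false-positive mode — large but rare
haplotypes with unrealistically high ŝ — is this artifact's milder form).

## Numerical and degenerate-input conventions

* Haldane transforms use expm1/log1p forms; r ∈ [0, 0.5) always.
* Likelihoods in log space; −∞ (not NaN) on underflow; s ≤ 0 rejected.
* Gamma-fit bisection tolerance 1e-12 relative; Talbot with 64 nodes;
  the Talbot path raises on internal overflow and the caller falls back
  to moment matching (only reachable at near-degenerate k·r corners
  where thresholds are a few generations).
* Single-column blocks (i = j) are enumerated (r = 0 ⇒ ŝ = 0, so they
  are never reported); a `min_sites` flag can drop them early.
* Blocks are emitted grouped by end column, ordered by start then
  a-interval — a stable, documented convention.
* Mixed ploidy is allowed in VCF input; every phased allele is one row.
* Duplicate bp positions, unsorted maps with non-monotone cM, and BED
  intervals with start ≥ end are hard errors with line context.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| Nₑ | 10,000 diploids | sets y₀, both filters, and ŝ scale; choose the low end of the plausible range (or a geometric mean over time) — smaller Nₑ is conservative |
| s_min | 0.005 | smallest coefficient worth reporting; parametrizes the drift quantile |
| Δr | mean inter-SNP map distance (Haldane) | recomputed after any site filtering; overridable |
| maf_min | 0 (off) | 0.01 recommended for real sequencing data; see the artifact note above |
| min_sites | 1 | minimum SNPs per block |
| lookup grid | k ratio 1.4; 64 log r points + r=0 | meets the 5% interpolation bound |

## Known limitations

Additive selection only (dominant/recessive trajectories are not
sigmoidal); constant-Nₑ equilibrium assumed by both the estimator and the
filters — nonequilibrium demography inflates false positives (measured
here and published: bottleneck and migration rates are an order of
magnitude above the constant-model rate); perfect matching makes blocks
sensitive to genotyping error and recent mutation, biasing ŝ down;
composite (star-genealogy) likelihood understates uncertainty, so no
confidence intervals are attached; single chromosome per run.
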