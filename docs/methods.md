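# Methods

## Signal model and coordinate conventions

All signals live on a fixed grid of 10-bp bins (configurable); bin *k* of a
chromosome covers `[10k, 10k+10)` in 0-based half-open coordinates, the BED /
bedGraph convention. A crosslink event is located at the 5′-most genomic base
of the first-in-pair read (leftmost aligned base on the forward strand,
rightmost on the reverse strand); only mapped, primary, non-duplicate-flagged
Read-1 records count, and duplicate *removal* is assumed upstream of this
package. Uncovered bedGraph positions are **zero**, not missing; missingness
(NaN) is produced only by masking — blacklist intervals, off-chromosome
composite columns, beyond-TES/TSS exclusions, zero-denominator ratios — and
propagates through arithmetic and is excluded from all means and SEMs.

## The torsion signal

For each condition (in vivo "with torsion"; formaldehyde-fixed,
restriction-digested "zero torsion") each replicate track is
blacklist-masked, divided by its genome-wide mean over non-missing bins
(making the pipeline invariant to sequencing depth), and the replicates are
averaged; the torsion signal is the per-bin difference (with − without).
Positive values indicate net (−)/underwound torsion, negative values net
(+)/overwound torsion. Normalize-then-average is the default order; the
reverse is available (`normalize_before_average=False`) and differs only
when replicate depths vary across chromosomes.

Purified-DNA sequence normalization (`sequence_normalize`) divides (default)
or subtracts a mean-normalized purified-DNA track and is used **only** for
accessibility-style views (nucleosome footprints, NFR peaks); it never
enters the torsion computation, which cancels sequence and accessibility by
subtraction instead. The division pseudocount defaults to 0 with
zero-denominator bins set missing (counted in the log), since no principled
pseudocount presents itself; it is configurable.

Open choice, resolved: whether the normalization mean should exclude
blacklisted bins is not determined by the problem; the default includes all
non-missing bins (blacklisted bins are already NaN when masking precedes
normalization, which is the pipeline order), and `normalize_mean` accepts an
explicit exclusion mask.

## Composite matrices

`anchored_matrix` stacks fixed windows around TSS/TES anchors, reversing
minus-strand rows so transcription runs left→right; `beyond_TES` /
`beyond_TSS` exclusions blank, per row, the columns past the gene's own
other end, so neighbouring genes do not bleed into the composite.
`scaled_region_matrix` resamples variable-length regions (gene bodies,
intergenic gaps, loop interiors) onto a fixed number of body columns by
**coverage-weighted averaging** of the piecewise-constant source signal —
never interpolation at sample points and never summing — because averaging
is the unique choice that preserves signal amplitude exactly (a constant
region maps to the same constant, and each row's body mean equals its source
mean to machine precision). Flanks are appended unscaled. Column statistics
are mean, sample-SD-based SEM (`ddof=1`), and n over non-missing entries;
single-entry columns get SEM 0 by convention.

Default anchored flank: 1000 bp; default body columns: 100. Both
configurable per call and in the pipeline config.

## Peak/valley statistics

For grouped genes (percentile groups of expression or ORF size; default
quintiles 0–20–40–60–80–100, configurable), the composite torsion profile is
built at the TSS (peak) and TES (valley), the extremum located within
±500 bp of the anchor, and each gene's torsion averaged over the bins whose
centers lie within ±20 bp of the extremum's bin-start offset (4 bins at
10-bp binning); the reported statistic is the across-gene mean ± SEM.

The extremum is located **globally** (on the pooled composite of all groups)
by default. Locating it per group is statistically hazardous: for a group
whose composite is noise-dominated (e.g. the bottom expression quintile),
taking the argmax of ~100 noisy columns and then averaging the same data at
that position selects the maximum of noise and biases the group mean upward
— in simulation this inverted the expected monotone expression trend at the
low end. `extremum_scope="per_group"` remains available for strong-signal
groups.

Percentile ranks use the min-rank convention (rank = count of strictly
smaller keys), so ties share a group and an all-equal key places every item
in the first group; grouping is monotone in the key and partitions the input.

## Gene pairs, promoter classes, loops

Gene pairs are adjacent genes in per-chromosome coordinate order
(chromosome-terminal genes join one pair; overlapping ORFs are skipped with
a logged count), classified by strand configuration: divergent (←→),
convergent (→←), codirectional. The intergenic gap is "purified" when no
annotation from a superset list other than the two members (matched by name
or exact ORF coordinates) overlaps it; only the shared gap is tested, not
the pairs' outer flanks. Promoter classes (UNB = no sequence-specific factor
bound; TFO = insulator ssTFs such as Reb1/Abf1; STM = ssTFs plus further
factors/UAS; RP recognized as a label) are consumed from a two-column table;
calling them from ChIP data is out of scope. Class-restricted pair sets
require both members to belong to the requested classes.

Loop boundaries are intrachromosomal (L, R) pairs with a contact score.
Nested-loop refinement removes every loop that strictly contains a shorter
loop (loops sharing one boundary count as nested when the other boundary is
strictly inside), so each region is represented once and the retained set is
containment-free. Boundary snapping moves each boundary independently to the
nearest cohesin ChIP peak strictly within 500 bp (leftmost wins exact ties;
loops that would invert are dropped with a log; `require_both` makes
snapping all-or-nothing). The bundled peak caller is deliberately simple —
local maxima above a height threshold (default: 90th percentile), kept
greedily in descending height with a 250-bp exclusion radius, positions at
bin centers — because external peak positions are the expected input; it
exists so the pipeline is self-contained.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, on a
genome small enough that a full run takes under a second (defaults: 4
chromosomes × 300 kb, ~700 genes).

**Annotation.** ORF lengths are log-normal (log-mean 7.0, log-SD 0.55 →
mean ≈ 1.3 kb, clipped to [150 bp, 15 kb]), intergenic gaps gamma (mean
400 bp, shape 2, floor 60 bp), strands i.i.d. (p = 0.5), expression
log-normal (log-SD 1.0, arbitrary units), promoter classes UNB/TFO/STM at
0.45/0.35/0.20 — all chosen to caricature a compact yeast-like genome.

**Accessibility.** `a(x) = a₀ + NFR + nucleosome modulation`, clipped to
[0.05, 1]: a₀ = 0.5; a Gaussian NFR bump (amplitude 0.4, σ = 60 bp) centred
80 bp upstream of each TSS; and `A·exp(−d/λ_phase)·cos(2πd/p)` through each
gene body with A = 0.25, repeat p = 160 bp, phasing decay λ_phase = 800 bp —
positioned nucleosomes whose phasing decays away from the promoter.

**Torsion.** Each gene adds `+T_tss·E·exp(−d/λ_t)` upstream of its TSS and
`−(T_tes + c_len·size)·E·exp(−d/λ_t)` downstream of its TES, with
λ_t = 750 bp (torsion confined to within 1–2 kb), expression scaling E, and
a gene-length term at terminators. Divergent pairs whose promoter classes
are insulator-bound (probability 0 for UNB, 1 for TFO/STM; a mixed pair uses
the stronger member, since one bound insulator suffices to block rotation)
receive an insulator at the gap midpoint that truncates each promoter's
inward tail there (hard truncation by default; an `insulator_leakage`
fraction lets torsion pass).

**Emission.** Per bin, `rate_with = D·s·a·max(0, 1+κt)`,
`rate_without = D·s·a`, `rate_purified = D·s`, with κ = 0.5 (approximately
linear torsion→crosslinking response, clipped at zero rate; clipped bins are
logged), s a smooth multiplicative log-normal sequence-preference field
(log-SD 0.25, 200-bp correlation length), and counts Poisson, independent
across bins, replicates (2 with-torsion, 3 zero-torsion) and conditions.
D is a physical crosslink density (0.2 ICLs/kb, the assay's working range)
times a sequencing oversampling factor (default 30 000, i.e. 60 expected
counts per bin per replicate — a deeply sequenced library); the density and
the oversampling are separate knobs so depth titrations keep the physical
picture fixed.

**Companions.** mRNA tracks carry each gene's true expression (±5 % relative
noise) on its strand over the ORF, so the expression estimator recovers the
truth; loops connect consecutive convergent-gap midpoints (snapped to bin
centers), scored by the (+)-torsion magnitude at their boundaries; the
cohesin track is a 0.1 background plus Gaussian bumps (σ = 100 bp) at loop
boundaries with height proportional to score. All randomness derives from
one seed through named substreams (annotation, fields, sampling, fixtures),
so each stage is reproducible in isolation.

**Calibration.** Two generator constants were set, once, by measuring the
noise-free/simulated pipeline rather than by a priori choice, as the model
itself does not fix them: (i) T_tss = 0.2 (with κ = 0.5, A = 0.25,
NFR = 0.4) places the with-torsion/torsion composite peak-to-valley ratio at
≈ 5, the regime where accessibility dominates the raw signal roughly
five-fold over torsion; (ii) T_tes = 0.05 with c_len = 1 × 10⁻⁴ per bp makes
the terminator length dependence resolvable above Poisson noise at default
depth while keeping it subordinate to the promoter signal. These live in
`SimulationParams` defaults, not in code.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: mappability and library-preparation
artifacts, replication- or repair-generated torsion, topoisomerase kinetics
(torsion tails are stationary exponentials, not steady states of generation
and relaxation), correlated noise between conditions, UTRs (TSS/TES are ORF
bounds), overlapping or nested transcripts, and any absolute calibration of
torsion in physical units.

## Numerical and degenerate-input choices

Division by zero with a zero pseudocount yields missing bins plus a logged
count, not an exception. Composite columns with no data are missing; SEM of
a single observation is 0 by convention. Row sorting is stable (equal keys
keep input order; descending negates keys). Peak-caller ties prefer the
leftmost candidate; boundary-snapping ties prefer the left peak. Torsion
tails are cut off at 8 decay lengths (< 0.04 % of the amplitude). The
truth-recovery metric smooths the recovered track over 5 bins and correlates
over bins where the injected field exceeds 0.1 (the generator's noise
floor); both knobs are explicit parameters. Size-structured tests fix
expression to a constant (`expression_log_sd=0`) to isolate the gene-length
effect from independently sampled expression — a controlled experiment, not
a calibration.

## Problem sizes

The default simulation (≈ 1.2 Mb, ~700 genes, ~120 000 bins, 6 count
tracks) runs in well under a second, and the complete test suite — including
the end-to-end recovery at three depths and the permutation null — in under
half a minute. These sizes were chosen so that iterating on the analysis is
interactive while every statistical check retains comfortable power.
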