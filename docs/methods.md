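# Methods

This note documents the models, parameter choices and numerical conventions
behind `sccnv`, and what the simulation-based tests do and do not establish
about real data.

## Equal-read bins

Low-coverage CNV analysis needs bins whose expected read count is uniform
under flat coverage. We define a position as *uniquely mappable* when its
read-length k-mer (forward strand, no N) occurs exactly once among all
forward and reverse-complement k-mers of the genome, and build bins holding
equal numbers of mappable positions. This exact-uniqueness criterion stands
in for alignment-based mappability (e.g. `bowtie -v 2 -m 1`, which tolerates
mismatches); for the synthetic genomes the package targets they coincide
almost everywhere, but for a real reference the two tracks differ and an
alignment-derived mappability track would be preferable. Bins are allocated
across chromosomes by largest-remainder rounding of mappable-position
counts (ties to earlier chromosomes), and within a chromosome each bin takes
an equal share (±1, earlier bins take the remainder). A bin starts at its
first mappable position; unmappable gaps are absorbed into the preceding
bin. Coordinates are 0-based half-open (BED) everywhere.

Per-bin GC is `(#G + #C) / (#A + #C + #G + #T)` over the bin interval; all-N
bins get undefined GC and are masked.

## Normalization

`CNR_i = RPB_i / median(RPB)` over unmasked bins (zero-count and all-N bins
are masked rather than pseudocounted; log2 of zero is undefined, and
retaining the bin index keeps segment coordinates correct). GC correction
divides CNR by a robust lowess fit of CNR on GC (span 0.3, 2 robustness
iterations, fitted values floored at 0.05), then rescales the median of
nCNR to 1. The method is a standard choice for read-depth GC correction; if
the fit is degenerate (fitted ≤ 0 in over 10% of bins) the model falls back
to 20-quantile GC-group medians, and with fewer than 50 unmasked bins or
fewer than 10 distinct GC values normalization is the identity. Order of
operations is count → median ratio → GC fit.

## MAPD

`MAPD = median |log2 nCNR_{i+1} − log2 nCNR_i|` over genomically adjacent
unmasked bin pairs on the same chromosome; pairs spanning a chromosome
boundary or a masked bin are dropped (a chromosome boundary is not an
amplification adjacency). Even pair counts use the midpoint median. For
independent per-bin noise the statistic has a closed form
`0.6745 · sqrt(var_diff)`; for pure Poisson counts at λ per bin this is
`0.6745 · sqrt(2/λ)/ln 2` ≈ 0.049 at λ = 800, which is the floor that
unamplified DNA approaches. The QC gate defaults to MAPD ≤ 0.45. Unlike a
standard deviation across bins, MAPD is insensitive to a real CNV, which
moves a block of bins but only two adjacent differences.

## Chromosome-arm copy number

Per-arm read fractions are normalized to a *normalizer reference set*: the
median per-arm (and per-chromosome) fraction across euploid reference cells
amplified with the same chemistry. Chromosome-level reference fractions are
their own medians rather than sums of arm medians. For a sample, the raw
ratio per arm is rescaled by the autosomal median ratio (robust to a
single-arm event), multiplied by 2 for autosomes, and by the reference copy
number for sex chromosomes (so sex-chromosome CN is effectively relative to
the autosomes within the sample). Rounding is to the nearest integer, half
away from zero. Pooled samples skip rounding: a mosaic CN-4 arm carried by
cell fraction f reports ≈ 2 + 2f. Bins are attached to arms by midpoint;
a bin whose midpoint falls inside the centromere gap joins the nearer arm.

## Circular binary segmentation

Implemented from scratch. For the interval under test (one chromosome's
unmasked log2 nCNR values, treated as a circle) every arc whose length and
complement are both ≥ `min_width` (default 5) is scored with the absolute
pooled-variance two-sample t statistic of arc vs complement; enumerating
non-wrapped arcs suffices because a wrapped arc is the complement of a
non-wrapped one and the statistic is symmetric. The maximal |t| is referred
to a permutation null (`nperm = 1000`, `alpha = 0.02`): the p-value is the
fraction of permutations whose maximal |t| reaches the observed value. If
significant, the argmax arc's interior endpoints become breakpoints (two
for an interior arc, one for an edge arc) and the procedure recurses.
Afterward, sd-undo pruning repeatedly removes the breakpoint whose flanking
segment means differ least while that difference is below
`undo_sd × sd_noise` (default 1.0), with `sd_noise = 1.4826 ·
median|lag-1 diff| / √2` — a lag-difference MAD that is robust to the
segments themselves.

Numerical conventions: argmax ties (complementary arcs agree in exact
arithmetic) are resolved within a 1e-9 relative tolerance toward the
smallest (i, j); the permutation stream is seeded deterministically per
(sample, chromosome, recursion path), so identical inputs and seed give
identical segments; within-group sums of squares are floored at 1e-12.
The permutation loop stops early once the exceedance count is larger than
`alpha·nperm` — the count only grows, so the accept/reject decision is
exactly that of the full run; only the reported p-value is then based on
the permutations actually drawn. Segmentation runs per chromosome (not per
arm); centromere handling happens at calling. Segments tile each
chromosome: masked bins are assigned to the span of the enclosing segment.

## CNV calling

Within a compartment (all chromosomes for female/unknown samples; for males
the sex chromosomes are treated separately from autosomes), with M the
unweighted median of segment means and `Seg.dist_j = |Seg.mean_j − M|`, a
segment is called iff:

1. `Seg.dist_j ≥ 2 × MAD`, MAD = median of Seg.dist over segments
   (unweighted per segment, not per bin);
2. `Φ(Seg.dist_j / s) ≥ 0.9`, s the n−1 sample SD of segment means —
   identical to a one-tail Z-test p < 0.1 (if s = 0, any nonzero distance
   passes in the limit);
3. span ≥ 4 bins; 4. span ≥ 1 Mb (bp extent of the segment);
5. no bp overlap with an annotated centromere.

Integer CN is `round(baseline · 2^(Seg.mean_j − M))`, baseline 2 for
autosomes and female X, 1 for male sex chromosomes; centering on M assumes
the genome median sits at baseline ploidy, which holds because the nCNR
median is 1 by construction. Calls that round back to baseline are retained
but flagged *equivocal* — noninteger segment means are a known signature of
false positives in this setting.

Clonal events are connected components of same-direction calls from
different samples overlapping in ≥ 2 bins (a gain and a loss at one locus
are not one clonal event). For chained overlaps, the reported interval is
the bounding span of the pairwise shared regions. The companion permutation
test (`sharing_null`) re-places each sample's calls uniformly (preserving
counts, lengths, directions; chromosomes weighted by available start bins)
and reports `(1 + exceedances)/(1 + n_perm)`.

## Simulator

The simulator is the package's study bench: it emulates single-end 50 bp
low-coverage WGS (default T = 5 × 10⁶ reads/sample) on either small
sequence-level genomes (GC-track sequences with N-run centromeres and
optional duplicated blocks, for exercising bin construction) or an
hg19-proportioned bin map — 22 autosomes plus X with real chromosome-length
proportions, ~506 kb bins at the default 6,000 bins, and an isochore-like
smooth GC track.

Counts are `Poisson(T · w_i · g(GC_i) · (CN_i/2) · b_i)`: w the mappability
weight, g a mild quadratic GC response peaking near GC 0.45 (configurable;
its only role is to give the GC correction something real to remove), CN
from ground-truth events (bins partially covered by an event interpolate
proportionally), and b an AR(1) lognormal amplification bias restarted per
chromosome and renormalized to mean 1. The bias field is summarized by a
small-scale log SD σ₀ and a genomic correlation length ℓ; per-bin
parameters follow as σ = σ₀·sqrt(min(1, ℓ/w)) and ρ = exp(−w/ℓ) for bin
width w. With ℓ below the finest bin scale in use, coarser bins average out
more bias, so MAPD rises as bins shrink while unamplified (σ₀ = 0) samples
stay at the Poisson floor — the qualitative signature of WGA noise.
Presets: GenomePlex-like (σ₀ = 0.82, ℓ = 15 kb) and MDA-like (σ₀ = 1.335,
ℓ = 30 kb), chosen by inverting the closed-form MAPD approximation
`0.6745·sqrt(2(1−ρ)σ² + 2/λ)/ln 2` at the characteristic single-cell MAPD
of each chemistry (0.20 and 0.45 respectively) at ~830 reads per ~506 kb
bin. `calibrate_noise` additionally bisects σ against Monte-Carlo MAPD
measured through the full normalization pipeline (tolerance 0.01) when an
exact target level is required.

Populations: each cell carries each truth event independently with its cell
fraction; pooled samples average member expectations under a single shared
sequencing budget before Poisson sampling (pools are sequenced to the same
depth as single cells). `power_experiment` plants one event, simulates
replicate cells, runs QC → segmentation → calling, and scores a replicate
as detected when a same-direction call overlaps the truth interval in ≥ 2
bins; QC failures are excluded from the denominator, as they would be from
a real analysis.

What the simulator does **not** model: read-level artifacts (chimeras,
adapter content), allelic signal (SNVs/BAF), locus-specific amplification
failure (e.g. the systematic chromosome-19 under-representation seen in
some MDA libraries), GC bias that varies along the genome, or inter-cell
variability in amplification quality beyond the Poisson/bias model. Passing
simulation benchmarks therefore demonstrates correctness and calibration of
the algorithms under the stated noise model, not performance on any
particular real library.

## Problem sizes and defaults

Benchmarks run at the study scale the method targets: 6,000 bins, 100
replicate cells for detection power, `nperm = 1000`. Property and
regression tests use reduced sizes (1,500–2,000-bin maps, `nperm` 200–500,
60-chromosome nulls) chosen to exercise the same code paths at desk scale.
The type-I control test disables sd-undo to measure the raw per-interval
split rate against alpha.

## Known limitations

- Exact-uniqueness mappability is optimistic for real genomes (no
  mismatch-tolerant multi-mapping); feed an external mappability-aware bin
  map via the binmap TSV if one is available.
- The per-segment (unweighted) MAD/SD statistics follow the calling rules
  as published; with very few segments per compartment (< ~3) the MAD
  degenerates to 0 and criterion (1) is vacuous — criterion (2) then
  carries the specificity.
- No classification of genome-wide CN-imbalanced cells is attempted; the
  package reports per-arm CNs and leaves that judgement to the analyst.
- Clonal-sharing significance uses an explicit permutation null; no closed
  multi-sample test is claimed.
- k-mer mappability is computed with an exhaustive dictionary and is meant
  for genomes up to a few tens of Mb, not full mammalian references.
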