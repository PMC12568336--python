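# Methods

`loopscape` re-implements, as a tested library, the computational path from
Micro-C ligation-pair records to annotated enhancer–promoter loops: pair QC
and classification, contact matrices, A/B compartments, TAD boundaries,
distance-stratified interaction significance, focal loop calling, anchor
annotation, structural-deletion overlap, and promoter-anchored interaction
extraction. This note documents the models, the defaults and why they were
chosen, the synthetic-data generator that the test suite runs against, and
the known limitations.

## Pair processing

A pair record is one ligation junction: two genomic sides with strands.
Processing order is parse → chimeric filter → deduplicate → classify, with
record counts logged at every stage.

**Normalization.** Sides are stored in upper-triangle genome order
((chrom1, pos1) ≤ (chrom2, pos2)). Sides on the 4DN sentinel chromosome `!`
are unmapped; records on blacklisted chromosomes (e.g. chrM, chrY in a
mouse assembly — mitochondrial and sex-specific signal) are dropped and
counted.

**Chimeric filter.** A mapped pair is *chimeric* — the signature of a true
ligation junction rather than a self-ligated or undigested fragment — iff
the sides are on different chromosomes, the orientation is atypical, or the
separation strictly exceeds 2,000 bp (2,000 exactly is *not* chimeric).
"Atypical" is any configuration other than inward-facing convergent (`+` on
the leftmost side, `-` on the rightmost): self-ligation and undigested
products yield inward pairs, so inward-only is treated as typical;
same-strand is one example of atypical, not the whole definition. Only
chimeric pairs continue down the pipeline. Whether the original
2,000 bp filter ran before or after deduplication is not documented
anywhere we could check; this package filters first and logs both counts so
the orders can be compared.

**Deduplication.** Exact PCR duplicates share the full 6-tuple
(chrom1, pos1, strand1, chrom2, pos2, strand2); no positional slack is
allowed, matching duplicate semantics at mononucleosome precision. Input
must be coordinate-sorted; within each identical group exactly one record
stays unflagged.

**Classification.** Each mapped, non-duplicate record falls in exactly one
category: trans, cis < 1 kb, cis 1–10 kb, or cis ≥ 10 kb (lower bounds
inclusive). *Valid* pairs are trans plus cis ≥ 1 kb. The accounting table
reports mapping/duplication rows as percentages of total read pairs and
interaction-class rows as percentages of no-dup pairs, rounded to two
decimals, and every percentage is recomputed from the validated counts —
count identities (dup + nodup = mapped, cis + trans = nodup, …) are checked
first and a violation names the broken identity.

**Library complexity.** The saturation curve uses the one-parameter
Lander–Waterman form: distinct = L(1 − exp(−N/L)), with the library size L
obtained by monotone root-finding through the observed (total, distinct)
point. This is a deliberate, documented stand-in for rational-function
extrapolation approaches: it is closed-form and desk-testable, and its
extrapolations are not expected to match any particular external tool's
numbers. distinct = total has no finite solution and is reported as "no
saturation detectable".

## Matrices

Bins are 0-based half-open `[i·res, (i+1)·res)`; 1-based pair positions are
converted at binning (`bin = (pos−1)//res`). Cis matrices are sparse upper
triangular; total matrix mass always equals the number of binned valid
pairs (a conservation invariant the tests enforce through every
aggregation).

**Balancing** is plain ICE (iterative proportional fitting) to uniform
marginals, tolerance 1e-5 on the maximum relative marginal deviation,
200 iterations maximum. Bins are masked when their coverage is zero or
falls below the 2nd percentile of nonzero coverages **and** below half the
median — the second condition stops the percentile cut from biting into a
uniformly covered chromosome, where the "2nd percentile" is ordinary
signal, while preserving the intent of removing low-mappability outliers in
real data. Weights are scaled so balanced marginals are ≈ 1.

**P(s) decay** uses log-spaced distance bins (8/decade); the per-bin value
is the mean contact probability per bin pair, normalized so that
Σ prob × (bin-pair count) = 1 over all cis distances. Slopes are fitted by
log–log regression over 30 kb–3 Mb, a range far from both the resolution
floor and chromosome-end edge effects at the simulated chromosome sizes.

**Replicate correlation** is Pearson r of log(1+x) raw counts over bin
pairs where either replicate is nonzero, capped at 5 Mb separation so the
diagonal does not dominate; the transform and range are configurable since
upstream tools do not document theirs. Disjoint supports return NaN.

**Genome-wide views** aggregate every chromosome onto exactly 100 bins
(size-independent comparison); mass is conserved and chromosomes shorter
than the coarse grid trigger a warning.

## Compartments

E1 is computed per chromosome: the balanced map is distance-normalized
(each diagonal divided by its mean over usable bins), converted to a
Pearson correlation matrix, and the eigenvector of the largest-magnitude
eigenvalue taken. Working on the correlation matrix rather than raw O/E is
standard practice and is much less sensitive to residual coverage
structure. The eigenvector sign is arbitrary, so it is oriented against an
explicit per-bin activity track (ATAC peak density by default, gene density
as fallback); |r| < 0.1 against the track flags the orientation as
ambiguous rather than guessing. A is E1 > 0 after orientation. Fewer than
20 usable bins, or a variance-free O/E map (e.g. a uniform matrix), raise a
degenerate-matrix error instead of returning labels.

Saddle plots rank bins by E1 into quantiles (50 by default) and average
O/E per rank pair; compartmentalization strength is
(AA + BB)/(AB + BA) over the extreme 25% corner blocks, overall and per
genomic-distance band. On planted checkerboards the strength exceeds 1 and
shrinks toward 1 as the planted contrast approaches 1; permuting E1 gives
strength ≈ 1 (the permutation null the tests use).

## TAD boundaries

The insulation score of bin i is log2 of the mean balanced contact in the
w×w off-diagonal diamond crossing i (w = window/resolution; 100 kb default
window at 10 kb — the upstream window is undocumented, so this is exposed
as a parameter), normalized by the chromosome-wide mean of diamond means.
Diamonds may tolerate up to half their pixels on masked bins; beyond that
the score is undefined. The implementation uses summed-area tables and is
tested for exact (1e-10) agreement with a naive double-loop oracle.

A boundary is a local insulation minimum whose *delta* — the mean of the
nearest flanking local maxima minus the minimum — reaches 0.05; nearest-
flanking-maxima semantics mirror the delta definition used by the
established TAD callers this threshold comes from. Minima within 2 bins
merge onto the deeper one. "Strong" boundaries (used for signal pileups,
e.g. CTCF enrichment) are the top quartile by delta; the source analyses
say "strong" without a cutoff, so the quartile is this package's choice.

## Interaction significance

The expected model is the first-pass logic of count-based significance
callers: all possible bin pairs of a chromosome, sorted by distance, are
split into 100 strata whose bin-pair occupancies agree to within one (ties
at one distance straddle strata; their counts are allocated
proportionally). Each stratum's contact probability is its count share
divided by (N × bin pairs in stratum), N being the chromosome's total cis
count, followed by isotonic (monotone non-increasing) regression across
strata — deterministic and oracle-checkable, unlike spline fits. Raw
counts, not balanced values, feed the test, as the count-based binomial
model requires.

Every nonzero bin pair gets an upper-tail binomial p-value (≥ observed
successes in N trials at the stratum probability), O/E = observed/(N·p),
and Benjamini–Hochberg FDR within its chromosome (matching the
per-chromosome construction of the fragment files the approach mirrors).
Zero-probability strata with positive observations are flagged as
infinite-enrichment records rather than silently dropped. Locus queries
extend bin midpoints by half a bin and return all hits (flagged ambiguous
when multiple) or an explicit not-found result — needed because published
per-replicate tables leave absent records indistinguishable from zeros.

Trans contacts are ranked by raw count with deterministic lexicographic
tie-breaking; the chromosome-pair intensity matrix is the mean count over
all bin pairs of each chromosome pair.

## Loop calling

The dot caller scores each cis pixel against four local-neighborhood
expected values — donut (Chebyshev radius 5, inner exclusion 2),
lower-left, horizontal, vertical — computed on the distance-normalized map
so the steep P(s) decay cannot masquerade as enrichment, then rescaled to
counts by the diagonal mean. A candidate must be a 3×3 local maximum
exceeding all four expectations; its p-value is the upper-tail Poisson
probability of the raw count against the most conservative neighborhood,
with the global distance expected as a floor on the Poisson rate (a sparse
far-field neighborhood otherwise yields a spuriously tiny rate and floods
the calls with singleton pixels). BH FDR is taken over all candidates;
reported dots must additionally carry at least 4 raw counts — in
ultra-sparse maps every nonzero pixel is a "local maximum" with an
identical tiny discrete p-value, and a count floor at reporting time (not
in the FDR denominator) is the standard practical defence. Calls within
2 bins merge onto the strongest, and only separations between 2 bins and
10 Mb are tested. This is a deliberate substitution of a
scale-space detector by a four-neighborhood enrichment caller with the
same output contract (dot calls at 5–10 kb with FDR); genome-wide call
counts from the original detector are therefore not comparable numbers.

Loop distances fall in six categories (<200 kb, 200–400, 400–600, 600–800,
800 kb–1 Mb, >1 Mb), lower-inclusive/upper-exclusive except the last,
which is strictly >1 Mb. Anchors are the full calling-resolution bins.
Anchor annotation intersects anchors with ATAC peaks (accessible = ≥ 1 bp
overlap on half-open intervals — no minimum-overlap fraction is imposed
since none is documented) and with each mark BED; accessible anchors are
partitioned into H3K4me1-only / H3K4me3-only / both / neither, with
percentages at one decimal. Deletion overlap reports, per loop, the
deduplicated deletions hitting either anchor, plus the reverse map.

## Promoters

A promoter is the union (envelope) of accessible-chromatin peaks
overlapping the TSS base or, when no peak overlaps, the strand-aware window
[TSS−2000, TSS+500) on `+` (mirrored on `-`), clipped to the chromosome.
Strand-awareness is required for "upstream/downstream" to mean anything;
records missing strand are treated as `+` with a warning. Interaction
sides are re-inflated from midpoints to full bins before the ≥ 1 bp
half-open overlap test; retained records carry all overlapping gene symbols
per side. Gene-list filtering is exact, case-sensitive membership, and
commutes with the subsetting step.

## Synthetic data

The generator emulates the statistical structure the stages consume, never
sequence-level reads:

- cis distances from an inverse-CDF draw on a power law discretized at
  1 kb, exponent α (default 1, the canonical P(s) regime); positions
  uniform given the distance;
- a compartment checkerboard (block size 2 Mb default) and TAD blocks
  imposed by acceptance–rejection reweighting (same-label and within-TAD
  contacts up-weighted by their strength factors);
- planted loops added as extra pairs at the loop pixel, calibrated against
  the *empirical* distance-matched local background (same off-diagonal,
  ±20 bins) so the pixel ends up ≈ multiplier × background regardless of
  the surrounding structure; the extras displace randomly chosen
  background pairs so the total pair count is exact;
- one categorical role draw per record — duplicate (verbatim re-emission of
  a mapped original; default rate 0.53), unmapped (4DN `!` sentinel;
  default 0.12), or original — so each empirical rate is a plain binomial
  proportion of its denominator; the trans share among mapped uniques
  defaults to 0.30 and cross-chromosome partners are drawn
  length-proportionally. The default rates are the accounting of the
  cochlear library this package was designed around;
- a sub-1 kb same-strand fraction (default 5%) mimicking self-ligation
  artifacts, exercising the chimeric filter and the <1 kb stratum;
- matched BED fixtures: ATAC/H3K4me1/H3K4me3 peaks on a configurable
  fraction of loop anchors (background peaks explicitly avoid anchors so
  fraction 0 means zero overlap), CTCF peaks on planted TAD boundaries,
  stranded TSS records with gene symbols on anchors, and deletions placed
  over requested loops.

Everything is deterministic for a seed, down to byte-identical written
fixtures. What the generator does **not** model: mappability and GC bias,
restriction/MNase cut preferences, distance-dependent noise correlations,
copy-number variation, or cell-type mixtures. Passing recovery tests
therefore demonstrate algorithmic correctness under clean planted
structure, not performance on real libraries.

## Problem sizes and numerical choices

Recovery fixtures use 20–50 Mb single-chromosome genomes at 10 kb with
4×10⁵–10⁶ pairs — the package's chosen desk-scale study conditions: the
planted effects (3× checkerboard, 4× TAD contrast, 10× loops) sit at the
contrast levels the acceptance properties specify, and the measured
results (compartment accuracy ≥ 95%, boundary recall ≥ 90% within ±1 bin,
loop precision/recall ≥ 0.8, P(s) slope within ±0.1 of −α for
α ∈ {0.8, 1.0, 1.2}) are computed fresh by `scripts/acceptance.py`.
Degenerate inputs are first-class: uniform matrices give degenerate
compartment spectra and ≈ 0 insulation, empty boundary lists refuse to
pile, all-zero accounting warns instead of dividing by zero, and
zero-length intervals can overlap nothing under the half-open rule.

## Limitations

- The loop caller and the complexity model are documented stand-ins with
  the same contracts as the published tools they replace; their absolute
  outputs on real data will differ from those tools.
- FDR is controlled per chromosome; no genome-wide refinement pass exists.
- No nested/hierarchical TAD calling, no stripe detector, no
  sub-compartment clustering, no trans loop calling, no APA.
- The pipeline consumes pairs, not FASTQ; alignment and peak calling are
  upstream of this package.
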