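# Methods

## The measurement model

Repli-Seq sorts BrdU-pulse-labelled cells into six cell-cycle fractions
(G1b, S1, S2, S3, S4, G2M) and sequences the newly replicated DNA from
each. A locus that replicates early yields most of its signal in the G1b/S1
gates; a late locus in S4/G2M. `replitime` works on a fixed grid of 1 kb
loci (configurable bin width; chrY and chrM excluded by default; narrow
terminal bins are retained and flagged).

Per replicate the scoring chain is:

1. **High-density exclusion.** Reads are counted in a fixed 0-based 150 bp
   tiling; tiles holding strictly more than 20 reads are discarded from all
   subsequent sums. This guards against collapsed repeats and duplication
   artefacts. The comparison is strict: a tile with exactly 20 reads is
   kept.
2. **Window density.** Read starts (no fragment extension) are summed in a
   50 kb sliding window centred on each locus midpoint, truncated — not
   dropped — at chromosome ends. The same operation is available for
   per-locus count tracks (`sliding_window_sum`), where the window covers
   the loci whose midpoints fall within half a window of the centre locus.
3. **CPM and low-coverage filter.** Each fraction's windowed density is
   scaled to counts per million of that fraction's sequenced reads (the
   library size, not the windowed-track total — windowing counts each read
   once per overlapping window, which would inflate the denominator by
   roughly the window/bin ratio). Loci where any fraction falls strictly
   below 5 CPM are masked out; a cross-fraction-total variant is available
   (`per_fraction=False`).
4. **PNDV.** The six CPM values at a retained locus are converted to
   percentages of their sum (percent-normalised density values). This
   per-locus normalisation is what absorbs coverage, mappability and
   copy-number differences between cell types. PNDV rows sum to 100 exactly
   at every retained locus, an invariant the test suite enforces through
   the whole chain.
5. **WA.** The weighted-average replication-timing score is

   WA = 0.917·G1b + 0.750·S1 + 0.583·S2 + 0.417·S3 + 0.250·S4 + 0·G2M,

   computed on the percent basis (range 0–91.7; higher = earlier). A
   proportions basis (range 0–0.917) is available for unit-scale work. WA
   is monotone under moving PNDV mass toward an earlier fraction — a
   property test, not an assumption.
6. **Replicates.** Duplicate WA tracks are averaged on the intersection of
   their masks; the squared Pearson correlation over jointly measured loci
   is reported as the replicate-quality figure.

## Differential timing domains

Early/late cutoffs come from the top and bottom deciles of WA. Two
conventions are implemented: pooled quantiles of both samples (default —
it yields a single printed cutoff pair) and a per-sample-intersection mode
(the stricter of the two per-sample quantiles). Fixed cutoffs may always
be supplied directly (75/20 is the usual prostate-pair convention, 73/17
the breast-line one).

The change threshold is empirical: WA differences between replicates of
one sample are pure technical noise, so the largest replicate |ΔWA| bounds
what chance can produce. The suggested cutoff is the smallest multiple of
5 strictly above that maximum (a replicate max of 23 suggests 25; exactly
25 suggests 30); the user may override it. Loci with ΔWA = WA(case) −
WA(control) strictly beyond ±cutoff are labelled earlier/later; labelled
loci of the *same* direction within 50 kb (gap measured end-to-start,
inclusive) merge into domains. Domains are direction-pure: merging
opposite signs would manufacture self-contradictory calls, so earlier and
later loci never join even when adjacent. Merging is performed on the
replicate-averaged track.

## Epigenome integration

All occupancy logic is binary at locus resolution: a locus carries a mark
when it shares ≥ 1 bp with a called peak or broad domain (half-open
coordinates). Consequences of that choice: enrichment counts are locus
counts, not base pairs, and the universe for association tests defaults to
all measured loci.

* **Percentile occupancy** ranks measured loci by WA and splits them into
  equal-count bins (±1 locus); per bin the occupied fraction is reported.
  Equal-count bins were chosen over fixed WA-value bins because the
  quantity of interest is position in the timing distribution.
* **Gain/loss** and **hypo/hyper-methylation** follow locus-wise rules:
  gain = occupied in case only; hypomethylation = a drop of more than 0.2
  from a control value of at least 0.2; hypermethylation = a rise of more
  than 0.2 from a control value below 0.8.
* **Locus-set association** builds, per element class, the 2×2 table of
  query × element membership over the universe, applies the two-sided
  Fisher exact test and BH FDR across elements. Odds ratios with a zero
  cell get the Haldane–Anscombe +0.5 point estimate (flagged); the exact
  p-value is never corrected.
* **Promoters** are TSS ± 1000 bp, strand-symmetric (strand only locates
  the TSS), clipped and flagged at chromosome edges. Early/late labels are
  assigned only beyond the WA limits; CpG-island promoters are those whose
  2 kb window overlaps a CpG island.
* **Profile matrices** split each region into 50 equal-width bins; a bin's
  value is the overlap-length-weighted mean of measured locus values,
  which equals the per-bp mean of the piecewise-constant track.
* **LAD boundaries**: each control-LAD 5′ (start) and 3′ (end) edge is
  paired with the nearest case edge of the same polarity by absolute
  distance; negative distances mean the case boundary lies upstream. WA
  heatmap rows are ordered by decreasing distance; the window is ±1 Mb by
  default (configurable — the appropriate scale depends on LAD sizes).
  Zone tests pool loci strictly between paired boundaries: extension zones
  (case LAD grew) expect the case to replicate later, contraction zones
  earlier; both use one-tailed Mann–Whitney.

## Randomised-region nulls

The null for region-set tests is positional and length-matched: pick a
chromosome uniformly (a length-weighted mode exists), a uniform start, a
length resampled from the observed lengths, and reject draws that run off
the chromosome. The implementation draws from the exact conditional
distribution of that process — chromosome-length pairs weighted by their
acceptance probability, then a uniform fitting start — which is the same
law without the retry loop, and remains well defined when a length fits a
chromosome at a single position. Observed regions are compared with the
null on per-region mean WA (Mann–Whitney; regions overlapping no measured
locus are dropped with a warning) and on overlap with changed-timing
domains (exact binomial, with the null overlap proportion as the
hypothesised success probability; ≥ 1 bp counts as overlap).

## Statistics kernel

All tests are two-sided unless stated otherwise. The Fisher test uses the
probability-mass rule (sum of hypergeometric probabilities no larger than
the observed table's), the convention shared by R and scipy. Mann–Whitney
switches at a combined n of 16 (configurable) from exact enumeration over
all group assignments of the pooled values — valid under ties — to the
tie- and continuity-corrected normal approximation; fully tied data
returns p = 1 with a flag. The binomial and hypergeometric tests are exact
tail sums; BH is the standard step-up with monotonicity enforcement;
the equal-proportions test is the Yates-corrected chi-square.

The moderated t for many parallel two-group comparisons shrinks each
row's variance toward a prior: s²_post = (d₀s₀² + d·s²)/(d₀ + d), with
(d₀, s₀²) estimated across rows by method of moments on log sample
variances (the trigamma equation inverted by Newton iteration) and p-values
from a t distribution on d₀ + d degrees of freedom. Exact equivalence with
any particular published implementation is claimed only in the limits:
d₀ = 0 reproduces the ordinary t, d₀ → ∞ the pooled-prior z. Degenerate
inputs (a single-sample group, all-zero variances) fall back with a
warning rather than failing.

## Conserved cancer domains

Sample WA tracks are joined on jointly measured loci, quantile-normalised
(classic rank-based form, ties averaged — idempotent), and standardised
per sample (mean 0, sd 1; "scaled" is read as per-sample scaling, with a
per-locus option). "logFC" is the cancer-minus-noncancer difference of
group means on that scale. Loci passing FDR < 0.05 and |logFC| ≥ 1 merge
within 50 kb per sign: positive → earlier-in-cancer domains (ECD),
negative → later (LCD). Domains are annotated afterwards with variance
classes (top/bottom 20 % of loci by cross-sample variance) and, when an
embryonic-stem-cell sample is present, with ESC association: an ECD is
ESC-associated when mean(cancer) − ESC over its loci is below 0.5 scaled
units, an LCD when above −0.5.

Clustering uses Ward linkage on Euclidean distances between samples
(scipy's `ward`, i.e. the ward.D2 criterion on raw observations), cut at
k; PCA is computed on centred data with the variance-explained spectrum
reported. Cluster stability resamples loci with replacement B times,
reclusters, and matches each original cluster to the most similar
bootstrap cluster by Jaccard independently (no one-to-one assignment),
reporting per-cluster means.

A caveat the simulations exposed: quantile normalisation is rank-based, so
when the changed fraction of the genome is large and asymmetric between
directions, ranks of *unchanged* loci shift in the affected samples and
acquire spurious group differences near the modes of a multimodal timing
distribution. At a changed fraction of ~5 % (the realistic scale) the
artifact stays well below the |logFC| ≥ 1 filter; at ≳10 % it does not.
The packaged analyses and tests therefore keep planted changes near 5 % of
the simulated genome.

## Rearrangements

Pairs of breakends are cis if intra-chromosomal, trans otherwise — no
distance term. Enrichment testing assigns each breakend the WA of its
containing locus (breakends in masked loci are dropped and counted in a QC
figure) and builds, per stratum (all, cis, trans, any subtypes present) and
timing class (early/late), the 2×2 table of breakend-bearing versus other
measured loci against in-class versus not, with Fisher tests and BH FDR
across all strata × classes jointly. The tested unit is the locus, not the
breakend, mirroring the locus-based association testing used elsewhere in
the package; the exact contingency construction behind published figures
of this kind is not printed anywhere, so this is a documented
interpretation. Timing distributions per class use a fixed-bandwidth
(2 WA units) Gaussian density renormalised on [0, 91.7]. Fusion-partner
concordance reports, per pair and sample, whether both breakends share a
timing state (early/intermediate/late — intermediate is an explicit third
state), plus membership in changed-timing domains.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with known
ground truth. What it emulates, and what it does not:

* **Timing landscape**: piecewise-constant alternating early/late segments
  (exponential lengths, mean 1 Mb) at levels 0.8/0.2 "earliness" with
  ±0.05 per-segment jitter, on two 50 Mb chromosomes of 1 kb loci by
  default. Planted differential domains (mean 300 kb, minimum 150 kb)
  override the base level so the full shift is expressible: later-domains
  depart from the early level and shift down by 0.65 earliness units
  (≈ 40 WA units), earlier-domains the reverse.
* **Fraction counts**: locus earliness e maps to expected fraction weights
  by a Gaussian kernel (bandwidth 0.12) over six centres equally spaced
  from e = 1 (G1b) to e = 0 (G2M), mixed with a 15 % uniform background —
  the nonspecific signal BrdU immunoprecipitation leaves in every gate,
  without which the per-fraction 5-CPM filter would reject every locus.
  Counts are Poisson (a negative-binomial option exists for robustness
  work) with expected total 6 × 30 reads per locus; replicate noise is
  Gaussian jitter (sd 0.03) on e before kernel evaluation. Under these
  defaults replicate WA tracks agree at r² > 0.99 and the largest
  replicate |ΔWA| stays well below the 25-unit change cutoff, so the
  empirical-null machinery behaves as it does on real data.
* **Epigenome**: per-locus mark occupancy is Bernoulli with a logistic
  dependence on earliness (defaults: repressive marks late-enriched in the
  normal sample, redistributed in cancer), runs of positive loci emitted
  as intervals; methylation is Beta-distributed around a
  timing-interpolated mean (cancer hypomethylated at late loci); LADs are
  the late segments with optional boundary jitter/shift. Marks are
  independent across loci given timing — no spatial autocorrelation beyond
  the landscape itself, and no mark-mark dependence.
* **Rearrangements**: configurable biases place cis pairs in the
  latest-replicating quantile pool (default: bottom 20 % of loci by true
  timing) and trans pairs in the earliest, else uniformly; absolute
  earliness thresholds can override the quantile pools.
* **Multi-sample mode**: a shared landscape plus per-sample timing noise,
  with cancer samples sharing planted conserved shifts (0.55 earliness
  units over 4 earlier + 6 later domains), each sample pushed through the
  full two-replicate fraction-count pipeline.

Because the generator knows nothing of alignment, mappability structure,
copy-number change, or chromosome-scale timing gradients, passing tests
demonstrate that the *computational* chain recovers what it is defined to
recover under the stated noise model — not that any biological claim about
real genomes is reproduced.

Seeding: a single master seed spawns per-stage child generators through a
CRC-keyed `SeedSequence`, so every output is reproducible bit for bit and
stages are independently perturbable.

## Problem sizes and numerical choices

The packaged analyses run at desk scale: 100k loci (2 × 50 Mb) for the
single-pair pipeline, 50k loci for the multi-sample and breakpoint
analyses, 500 breakpoint pairs, 1000-region nulls, 100 bootstrap
resamples. These sizes were chosen so the full suite and the
reproduction script complete comfortably on a single CPU while keeping
every statistical regime (decile cutoffs, FDR across thousands of tests,
extreme-tail Fisher p-values) exercised at realistic magnitudes.

Tie-breaks and edge cases are fixed deliberately: combinatorial state
tables rank ties lexicographically; variance classes resolve quantile ties
by rank so class sizes are exact; boundary comparisons (20-read tile, 5
CPM, |ΔWA| cutoff) are strict in the directions stated above; LAD boundary
ties between upstream and downstream candidates resolve upstream.

## Known limitations

* The 2×2 construction behind breakpoint enrichment and the LAD heatmap
  window size are documented interpretations; both are configurable.
* The moderated-t prior is a method-of-moments empirical-Bayes fit, not a
  re-implementation of any specific published estimator.
* bigWig output is not supported; all formats are plain text.
* Copy-number aberrations are neither simulated nor corrected beyond what
  PNDV's per-locus normalisation absorbs.
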