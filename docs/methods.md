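# Methods

This note documents the models, statistics and numerical choices behind
`chromage`, and what the synthetic-data generator does and does not emulate.

## Coordinate model and overlap engine

All coordinates are 0-based half-open (BED convention) internally; gene
tables declared 1-based are converted on read. The TSS of a minus-strand gene
is `end - 1`, so a promoter window of halfwidth *h* is `[tss-h, tss+h)`
regardless of strand, clipped at chromosome bounds. Two intervals overlap iff
`max(start) < min(end)`. The overlap engine is a per-chromosome sorted sweep
(`searchsorted` on partner starts, then an end filter); it is deterministic
and returns pairs sorted by position index. Restriction-fragment maps must
tile each chromosome exactly (`end[i] == start[i+1]`), which the
`FragmentMap` constructor enforces.

## Negative-binomial differential test

Counts are normalized by median-of-ratios size factors: for libraries *j*,
`sf_j = median_i(count_ij / geomean_i)` over features whose geometric mean is
positive; factors are not rescaled afterwards. Features are pre-filtered by
the minimum-count rule (≥ `min_reads` in ≥ `min_reps` replicates of at least
one condition; defaults 25 and 2).

Each feature is then fitted with a log-linear negative-binomial model
`log mu = X beta + log sf`, where the design holds an intercept, the
condition indicator (aged vs young) and optionally additive batch indicators
(a batch confounded with condition raises an error). Fitting is iteratively
reweighted least squares, vectorized across features (batched `solve` on the
per-feature normal equations). The dispersion is a method-of-moments
estimate pooled within condition on normalized counts,
`alpha = sum_c (v_c - m_c * mean(1/sf)) (n_c-1) / sum_c m_c^2 (n_c-1)`,
floored at 1e-8 — the `mean(1/sf)` term accounts for the Poisson part of the
variance of normalized counts. No shrinkage across features and no
independent filtering are applied; these are deliberate simplifications of
the standard empirical-Bayes workflow and are the main reason per-gene
results can differ from it at very small replicate numbers.

The Wald statistic on the condition coefficient is referred to a
**t distribution with residual degrees of freedom** (`n_libraries -
n_parameters`) rather than a normal: with a plug-in moment dispersion at 3–4
replicates per group, the normal reference is visibly anti-conservative
(empirical type-I error near 0.10 at nominal 0.05 in simulation), while the
t reference restores calibration. Benjamini–Hochberg correction runs across
unfiltered features only; filtered or all-zero features carry NaN p-values.

The significance conventions are: adjusted p &lt; 0.05 for the aging
contrast, with an additional |log2FC| &gt; 1 filter available for the
developmental contrast; lower-stringency unadjusted thresholds used for the
chromatin-vs-expression comparisons default to p &lt; 0.005 (ATAC, H3K4me3)
and p &lt; 0.1 (H3K27me3, H3K27ac) and are plain config values.

## Consensus peaks and category analyses

Consensus is per-base voting: each replicate's peaks are self-merged so a
replicate votes at most once per base; bases with ≥ `min_support` votes
(default 3) form candidates, and candidates separated by fewer than
`merge_gap` bp (default 100) merge. Whether the original analysis voted on
base coverage or matched peak identities across replicates is ambiguous;
base-level voting is the unambiguous reading and is what the per-base oracle
in the tests checks.

Peak-to-gene assignment uses the gene body ± 1 kb. A peak overlapping any
significantly changed gene's window takes that direction; "unchanged-only"
means no changed-gene window is touched. A peak touching both an up- and a
down-gene window is labelled "ambiguous" and excluded from category
statistics with a warning (the source rules do not cover this case). Genes
flagged as suspected mature-cell contaminants are removed from the "up"
category when a flag list is supplied.

Per-category fold changes are `log2(median_aged / median_young)` of
normalized counts per peak, with a 0.5 pseudocount replacing zero medians
(zero handling is unspecified upstream; 0.5 is symmetric on the log scale).
Size factors should be passed in from the genome-wide differential analysis;
recomputing them from a subset in which everything changes would absorb the
signal. One-way ANOVA compares categories; BH across assays is applied by
the caller.

The pairwise fold-change correlation analysis de-duplicates overlap pairs by
choosing one random partner per multiply-overlapping peak under a stated
seed, computes Pearson r of the paired log2 fold changes, and repeats after
keeping only pairs where either peak's unadjusted-p rank is in the top 10%.

## Bernoulli hidden Markov segmentation

Emissions are independent Bernoulli per mark given the state; a bin's
likelihood is the product over marks. Mark vectors are packed into one of
2^M symbols so per-frame likelihoods are a table lookup, and the scaled
forward–backward recursions are numba-compiled; training is Baum–Welch EM
with random restarts (uniform(0.1, 0.9) emissions, sticky random transition
rows), stopping when the relative log-likelihood gain drops below `tol`
(default 1e-6) or at `max_iter` (default 500). The log-likelihood trace is
monotone up to 1e-8 relative slack, which the tests assert. One model is
trained on young and aged tracks jointly — every (chromosome, condition)
pair is an independent sequence, so transitions never cross those
boundaries — and decoding is per condition.

Decoding is posterior argmax by default (matching the common segmentation
convention); Viterbi is available behind `decode="viterbi"`. Model selection
over a state range reports log-likelihood and BIC but leaves the choice of
`n_states` to the user, since the original choice of 16 states was a
judgment call. The 16→6 collapse mapping is a required input; a default
mapping keyed on the fitted emissions (H3K4me3+H3K27me3 → bivalent, H3K4me3
→ active promoter, H3K27me3 → polycomb, H3K27ac/ATAC → active regulatory,
CTCF → insulator, quiet → background) is provided for synthetic runs and is
not a substitute for a curated table on real data.

Dominant-state assignment over a region takes the state with the largest bp
coverage, except that background wins only when no other state covers any
base; ties break by a fixed priority (polycomb &gt; bivalent &gt; active
promoter &gt; active regulatory &gt; insulator). Promoter occupancy change is
`aged - young` coverage per state over the 5-kb window; promoters in the top
fraction (default 0.5%) for increase or decrease of any non-background state
are selected, mean-centered per state, and clustered with complete linkage
on the correlation-profile distance (Euclidean distance between rows of the
feature-feature Pearson correlation matrix), cut at exactly k clusters
(default 9). On the default synthetic genome of 500 genes the analysis uses
`top_frac=0.04` so the selected set is comparable in size to the planted
60 flip promoters; 0.5% of 500 genes would select only ~10.

## Hi-C compartments

ICE balancing masks bins whose coverage falls below the 2% quantile of
nonzero row sums, then iterates `bias *= rowsum/mean` with the update applied
as a symmetric outer product (so symmetry is preserved exactly in floating
point) until all valid row sums are within 1e-5 relative of their mean, or
200 iterations (non-convergence warns and flags the result).

The compartment score is computed per chromosome: observed/expected by
dividing each diagonal by its mean over valid bins (distances beyond the
last valid diagonal reuse the last mean), Pearson correlation matrix of the
O/E columns, and its leading eigenvector by dense symmetric
eigendecomposition (matrices at 250-kb bins are small). Since the
eigenvector sign is arbitrary, scores are oriented so that the bin group
with the higher mean H3K4me3 enrichment is positive (A = active); the flip
is recorded. The score is invariant to global scaling of the contact matrix.

Switch calls combine two conditions per bin: one-way ANOVA of young vs aged
replicate scores at unadjusted p &lt; 0.05 (deliberately uncorrected), and a
standardized mean change above 3. The "standardized mean change" had to be
defined here: the default divisor is the **standard error of the mean
change with the within-group variance pooled genome-wide** (a z-score of
the change under a homoscedastic noise model, `standardize="se_shared"`);
a per-bin pooled SD is available (`"sd_bin"`). The choice matters at 2–3
replicates: a per-bin SD on 4 degrees of freedom is so noisy that the
combined rule both misses large planted effects and flags several null bins
per 200, whereas the shared-variance z-score detects 4-sigma effects with
~0.9+ sensitivity at well under one false positive per 200 bins. Flagged
bins whose young/aged means straddle zero are A→B or B→A; otherwise the
sign of the change gives the shift direction. A zero divisor with a nonzero
change yields an infinite standardized change and is logged.

## Capture interactions

An interaction is significant at a score ≥ 5 (the conventional capture Hi-C
confidence threshold; the score model itself is out of scope and simulated).
Gained/lost requires significance at exactly one age and a score difference
of at least 2 in the direction of the significant age; a record significant
at one age with a smaller difference stays "stable-significant" rather than
being dropped. Both ends baited → promoter:promoter, one end →
promoter:PIR, neither → error (capture-design violation).

PIR feature enrichment compares the observed count of PIR fragments
overlapping ≥ 1 peak with a permutation null: for each PIR, `n_draws`
(default 100) random non-baited fragments on the bait's chromosome whose
distance to that bait falls in the same log10-distance quantile bin
(deciles by default; nearest-bin fallback when empty). "Similar interaction
distances" is not defined more precisely upstream, so the bin count is
configurable. PIR fragments themselves are excluded from the null pools by
default (`exclude_pirs=True`): on a small synthetic genome the interacting
fragments are a noticeable fraction of the distance-matched candidates, and
leaving them in contaminates the background with the signal being measured
(a planted 3× enrichment reads as ~2.4 otherwise). The expected count is
the mean over draws and the interval the 2.5/97.5 draw percentiles.

Fragment chromatin states follow fixed priority rules on the set of
collapsed states overlapping the fragment: active promoter (present, no
polycomb/bivalent); polycomb (present, no active promoter/bivalent);
bivalent (present, or active promoter + polycomb together); active
regulatory (present, none of the above); insulator (present and nothing
else except background); background (nothing else, including the empty
set). The rules are total over all 64 subsets, which a hand-coded truth
table verifies exhaustively. A fragment is "active" when assigned to an
active state or carrying an H3K4me3/H3K27ac peak, unless it is
polycomb/bivalent-assigned or overlaps an H3K27me3 peak.

Gene-category statistics use two-sided Fisher tests (sidedness unspecified
upstream) with BH across category pairs, score log-ratios with a 0.5
pseudocount (scores may be 0), library-size-normalized median read-count
changes over category PIRs, and per-gene changes in the number of contacted
active fragments. Virtual 4C tallies ditag counts whose other end windows
into consecutive k-fragment blocks (default 5); a trailing shorter window is
kept and flagged.

## Synthetic data generator

One seeded `SimConfig` drives every layer; all generators are pure functions
of (config, seed). Defaults emulate the target study design: two conditions
× 4 chromatin / 3 expression / 2 Hi-C replicates; 2 chromosomes × 25 Mb;
200-bp chromatin bins and 250-kb Hi-C bins; exponential fragment lengths of
mean 4 kb (HindIII-like, floored at 200 bp) tiling each chromosome exactly;
500 genes whose TSS-covering fragments are baited with probability 0.9.

Counts are negative-binomial with log-uniform means in [20, 2000],
dispersion 0.05, library size factors log-uniform in [0.5, 2], and planted
log2 fold changes of ±2 on 10% of genes. Chromatin tracks come from a sticky
six-state Markov chain (self-transition 0.97) with per-state Bernoulli
emissions over five marks; planted promoter flips force the 5-kb window to a
from-state in young and a to-state in aged (three patterns × 20 promoters by
default), and otherwise the two conditions share one state path. Contacts
decay as d^-1 (a standard minimal Hi-C null), modulated ×(1±0.4) for
same/cross-compartment pairs on alternating 10-bin blocks, Poisson-sampled
and exactly symmetric; 5 bins per chromosome switch sign in aged, and genes
in switched bins are planted as differentially expressed in the matching
direction so expression-trend checks have signal. Interaction scores are
two-component (uniform [0, 4.8] noise vs 5 + exponential signal) with
gained/lost pairs swapping components between ages under an enforced ≥ 2
score difference.

What the generator does **not** emulate: read-level artifacts (mappability,
blacklist regions, GC bias, duplicates), irregular gene density and real
TSS structure, distance-dependent CHiCAGO score behaviour, trans contacts,
replicate-specific batch structure in chromatin assays, and the long-tailed
peak-size distributions of real data. Passing tests therefore demonstrate
the correctness and calibration of the algorithms under their own model
assumptions, not robustness to every artifact of real sequencing data.

## Problem sizes in the test suite

The suite and the acceptance script run HMM recovery at 50,000 bins
(best of 5 restarts), decoding oracles at 1,000 bins, ICE at 300×300,
compartment recovery and switch detection at 200 bins (20 simulated genomes
for the switch statistics), the NB calibration at 2,000 features × 4
replicates per group, enrichment calibration over 50 seeded repetitions of
100-draw nulls, and the full pipeline end-to-end on the default 2×25-Mb
genome — sizes chosen so each property is measured with useful precision on
a single CPU in seconds to a couple of minutes.
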