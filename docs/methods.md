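# Methods

This note documents the models and procedures implemented in `dielseason`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions that a maintainer would
otherwise have to reverse-engineer.

## Experimental design and data model

The root object couples a genes x libraries count matrix with a design
table (photoperiod, zeitgeber time, replicate) and per-gene spike-in flags.
The default design is three photoperiods — SD 8L:16D, EQ 12L:12D, LD 16L:8D
— sampled at ZT 0, 4, 8, 12, 16, 20 with three replicates (54 libraries).
All downstream statistics operate on replicate-mean expression per
(photoperiod, ZT) cell; this matches a serially sampled area-under-curve
design in which each library is an independent biological pool, not a
repeated measure.

## Normalization

Trimmed mean of M-values with the canonical published defaults: reference
library chosen by the 75th-percentile rule, 30 % symmetric trim on
M-values, 5 % on A-values, inverse asymptotic binomial variance weights,
factors rescaled to geometric mean 1. Spike-in rows are excluded before
factor computation and from library sizes. Expression is reported as CPM on
TMM-effective sizes; per-gene length normalization is unnecessary because
every downstream ratio (rDEI, correlation, fold change) is within-gene.
Note that TMM is only approximately invariant to scaling one library's
depth: the precision weights depend on counts, so factors move by well
under a percent — the tests assert near-invariance rather than identity.

## Photoperiodic gene screen

Each of the 18 (photoperiod pair, ZT) comparisons filters genes to those
with >= 10 reads in >= 3 of its six libraries, equalizes library sizes by
scaling counts to the geometric mean TMM-effective size (rounded to
integers — simpler than quantile-to-quantile pseudo-counts and adequate
for triplicates of similar depth), estimates a single dispersion phi per
comparison by maximizing the conditional-on-totals NB log-likelihood over
log phi in [−10, 5], and applies an exact conditional test: given the grand
total, the group-A sum follows a ratio of negative-binomial coefficient
products (binomial split in the Poisson limit phi = 0). Two-sided p-values
sum the probabilities of all splits no more likely than the observed one
(minimum-likelihood rule), which is well defined for asymmetric
conditionals and symmetric in the group labels. The union over comparisons
at unadjusted p < 0.2 defines the inclusive photoperiodic set; BH-FDR
< 0.05 within each comparison defines the stringent set. Moderated or
tagwise dispersion shrinkage is deliberately not implemented: the common
conditional-ML dispersion is the simplest member of that family and keeps
the test exactly enumerable, which the oracle tests exploit.

## Daily expression integral

DEI = trapezoid area under one day of replicate-mean expression with the
ZT0 value duplicated at ZT24. On the equally spaced 4-h grid this equals
4 x (sum of the six values); the implementation handles uneven grids and is
tested against a generic trapezoid oracle. rDEI is the DEI ratio between
photoperiods; the pseudocount defaults to 0 and undefined ratios (zero
denominator) are flagged NaN and excluded from rankings, since filtered
genes essentially never have zero DEI. Ternary shares raise the three DEIs
to the 4th power (exponent exposed as a parameter) and normalize; shares
are invariant to common scaling, and the implementation rescales by the
maximum before exponentiation so large expression values cannot overflow.

## Pattern clustering

Genes are represented by their 18-value concatenated SD||EQ||LD
replicate-mean profiles; similarity is Pearson correlation (affine
invariant per gene, so z-scoring is display-only). Affinity propagation
(damping 0.9, max 1000 iterations, 100-iteration convergence window,
shared preference = the 0.5 quantile of off-diagonal similarities) yields
fine clusters with exemplars; non-convergence falls back to a flagged
single cluster rather than raising.

Exemplar agglomeration merges, at each step, the pair of clusters whose
*best joint exemplar* — the member with the highest mean similarity to the
merged membership — has the highest such mean, recording that mean as the
merge height; merges are applied while the height stays at or above the
cut (0.82 by default) and the surviving clusters are the major clusters,
labelled C1..Cn by descending size. Heights from this greedy rule are not
guaranteed monotone, so the cut is implemented as "stop at the first
merge below the threshold".

Within each major cluster an average-linkage tree on 1 − r is cut with a
hybrid dynamic procedure. A branch qualifies as a subgroup when (a) it has
at least `min_cluster_size` (20) leaves, (b) its *core scatter* — the mean
of its lowest merge heights, where the core comprises the
`min_cluster_size − 1 + sqrt(size)` lowest merges — does not exceed
`maxCoreScatter`, and (c) the *gap* between its attachment height and its
own top (the 90th percentile of its internal merge heights) is at least
`minGap`. Deep-split level 2 maps to (0.82, 0.09) and level 3 to
(0.91, 0.045); level 3 relaxes both criteria, so the deeper partition
refines the shallower one on the same tree. Two implementation choices
matter and were made deliberately after the per-tree-normalized variant
proved unstable: heights enter the criteria in **raw correlation
dissimilarity units**, making a branch's verdict independent of what else
shares its major cluster, and the branch top is a **90th-percentile**
statistic because the literal maximum is dragged to the attachment height
by single chained outliers. A split is taken only when both children
qualify; a qualifying child with a sub-minimum sibling absorbs the split
and the sibling's genes are re-attached afterwards to the subgroup whose
medoid they correlate with best (this re-attachment is the one step that
can break strict nesting between depth levels). Subgroup exemplars are
similarity medoids with lexicographic tie-breaking; subgroup letters
follow dendrogram leaf order.

## Phase

Both estimators fix the period at 24 h — a single-day design cannot
resolve period. The cosinor fit a + b cos(wt) + c sin(wt) gives phase =
atan2(c, b)/w mapped to [0, 24) and a rhythmicity p from the exact F-test
of (b, c) = 0 (df 2, n − 3). The template-rank estimator computes
Kendall's tau against cosine templates at integer lags 0..23,
deduplicated by rank signature; phase is the best lag (ties resolved by
circular mean) and p is the best lag's one-sided tail Bonferroni-scaled
by the number of distinct templates. The combined phase is the unweighted
circular mean — the upstream combination's weighting is not specified
anywhere authoritative, and the unweighted mean is the symmetric default;
exactly antipodal estimates are flagged and the cosinor phase reported.

## Enrichment

Preranked GSEA uses the classical weighted Kolmogorov–Smirnov running sum
(weight p = 1; hits increment by |r|^p normalized, misses by 1/(N − m))
with a seeded gene-label permutation null (default 1000), two-sided p from
the matching-sign tail with the +1 correction, and NES = ES / mean |null
ES| of the same sign. The ranking metric is log2 rDEI — monotone in the
raw ratio, so hit ordering is unchanged, but symmetric about zero so the
two directions are weighted comparably. ORA is the exact hypergeometric
upper tail; set-size filters default to 20–500 (GSEA) and 10–500 (ORA).
BH adjustment is applied within each analysis.

## Promoter motifs

Promoters are the −1500..+500 window around the TSS (first annotated
transcript), strand-oriented, truncated and flagged at chromosome edges.
PFMs are regularized with pseudo-probability 0.001 per cell before log2
odds against the background (uniform by default), and every window on both
strands is scored; windows containing N are skipped, and a promoter
contains a motif when >= 1 window reaches the threshold (8 bits by
default, exposed as a flag). Enrichment per subgroup is hypergeometric
against the promoter universe of all detected genes — GC-matched
background sampling is not reproduced, a documented simplification.
Reporting thresholds (FDR 0.01 or 0.001) are configuration, not code.

## Pathway catalog

Catalog rows carry gene, effect, molecular function, branch and step
label. Groups are scored by a one-sample two-sided Wilcoxon signed-rank
test of log2 rDEI_SD:LD against zero: exact zeros are excluded before
ranking, absolute values ranked with midranks, and the null distribution
of W computed exactly by convolution over doubled ranks for n <= 25
(tie-aware), otherwise by normal approximation with tie and continuity
corrections. Per-step shading is the mean log2 rDEI across a step's
homologs, flagged unshaded when homolog signs disagree.

## The synthetic generator

Mean traces are sums of interpretable components — smooth light gate
(logistic edges, 0.5 h width, avoiding sampled-dusk discontinuities), its
dark complement, a post-dusk pulse (0.5 h rise, exponential decay, default
0.5 /h, anchored to lights-off), a wrapped-Gaussian dawn pulse, a cosine
with phase = intercept + slope x daylength, and a multiplicative trough —
scaled by per-photoperiod gains. Counts are NB(mean, phi) with phi = 0.05
by default (typical bulk RNA-seq overdispersion); library depth factors
are drawn once per library from ±25 %. Nineteen shipped archetypes named
after the major co-expression subgroups reproduce the qualitative pattern
vocabulary (light-induced, LD-trough, phase-delaying, EQ-specific,
post-dusk vs dawn-phased dark-induced, ...); their parameter values are
fixtures, not fits to any real data set.

Three design points deserve emphasis. First, populations include a large
**constant background** (default 2000 genes vs ~1000 regulated, matching
the roughly one-third regulated fraction of a real detectable
transcriptome): without it, CPM normalization absorbs the shared waveform
and TMM trimming becomes asymmetric, producing rDEI offsets that no real
analysis would see. Second, per-gene jitter (log-normal baseline, ±15 %
component amplitudes, ±12 % photoperiod gains) makes genes of one
archetype strongly but imperfectly correlated and spreads their rDEI
around the archetype's designed preference — the regime where clustering
and group-level testing are actually informative. Third, the post-dusk
(11Oa-like) and dawn-phased (11Ob-like) archetypes are deliberately
parameterized as a near-continuum (noiseless r ~ 0.94, above the 0.82
major-cluster cut): at study scale they land in one major cluster, remain
one subgroup at deep-split 2, and separate at deep-split 3 — the
calibration target for the depth-dependent behaviour of the tree cut.
This behaviour is a property of the full study-scale context (the
affinity-propagation preference and the stray genes that pad the
dendrogram branches both depend on the whole population); the pair in
isolation splits more readily.

What the generator does **not** emulate: read-level sequencing artifacts
(GC/length bias, multimapping), gene–gene correlation beyond shared
archetypes, realistic promoter sequence composition (background is
uniform i.i.d.), ontology-structured gene sets, and any fit of archetype
parameters to real expression values. Passing recovery tests therefore
demonstrates the pipeline's correctness and calibration, not performance
guarantees on real libraries.

## Numerical choices and degenerate inputs

Exact-test p-values compare log-probabilities with a 1e−10 slack so ties
in the conditional pmf are included deterministically. Dispersion
estimates at the lower search bound are snapped to the Poisson limit.
Constant expression series yield flagged-undefined phases with p = 1;
constant profiles are dropped before correlation with a warning. All-zero
DEI triples and zero-denominator rDEIs are NaN-flagged and excluded from
rankings. Every stochastic step (count draws, permutations, promoter
backgrounds) takes an explicit seed, and the pipeline manifest records
parameter values and output hashes so identical configurations produce
identical runs.

## Problem sizes

The shipped verification suite runs the study-scale preset at about 1000
regulated genes plus 2000 background (one to two minutes end to end),
2000 null genes for screen calibration, 1000 null series for rhythmicity
calibration, and 150–200 promoters for motif planting and null draws —
sizes at which every exact oracle (full enumeration of conditional
distributions, 2^n sign patterns, combinatorial tails) is computable and
the stochastic recovery metrics are stable across seeds.

## Known limitations

The screen's union rule at p < 0.2 is intentionally inclusive and admits
most null genes somewhere among 18 comparisons; it is a recall-oriented
pre-filter ahead of clustering, not an error-controlled discovery set (the
FDR mode is). The agglomeration cut assumes effectively monotone merge
heights. The hybrid tree cut implements the core-scatter/gap branch logic
but not the optional PAM-like reassignment stage, keeping depth-level
nesting strict on clean data. Motif enrichment ignores promoter GC
composition. The phase combination is unweighted rather than
confidence-weighted.
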