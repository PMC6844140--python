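# Methods

## The scoring statistic

Within one sample, genes are ranked ascending by expression
(`1` = lowest, `N` = highest; ties take the minimum rank by default,
the policy we recommend for RNA-seq because it is stable under the
heavy zero-ties of count data). For a gene set of size `n` with ranks
`r_1..r_n` the directed score is the mean rank linearly rescaled by its
theoretical extremes: the minimum mean rank of any `n`-subset of
`1..N` is `(n+1)/2` (the bottom `n` ranks) and the maximum is
`(2N−n+1)/2` (the top `n`), so

```
u = (r̄ − (n+1)/2) / (N − n) ∈ [0, 1]
```

These bounds are derived analytically rather than by enumeration; the
test suite verifies them against exhaustive enumeration of all
`n`-subsets for `N ≤ 12`, `n ≤ 4`. Down-regulated sets are scored on
reflected ranks `N+1−r_i`, equivalent to negating the centred score.
Centring subtracts 0.5; a paired signature's total is the sum of its
centred components (range `[−1, 1]`). In uncentred mode a paired total
is the *mean* of the two components, keeping the `[0, 1]` range —
centring is a linear transformation either way, so the choice is
cosmetic.

For sets of unknown direction the statistic is the mean absolute
deviation of ranks from the median rank `(N+1)/2`, normalised against
the smallest and largest achievable means of `n` values drawn from the
multiset `{|k−(N+1)/2| : k=1..N}` (computed by sorting that multiset —
O(N log N), exact). These scores live in `[0, 1]` and cannot be
centred; the scorer refuses the request rather than silently ignoring
it.

**Dispersion.** Each score is accompanied by the dispersion of the
signature-gene ranks in that sample: the median absolute deviation
scaled by 1.4826 (the normal-consistency constant; configurable to 1,
since conventions differ) or optionally the inter-quartile range. MAD
is invariant under rank reversal, so it is irrelevant whether down-set
dispersion is computed on raw or reflected ranks; for IQR the package
uses raw ranks. A paired signature's total dispersion is the mean of
its component dispersions.

**Missing genes.** Signature genes absent from the data produce a
warning naming the count and the sorted missing IDs; scoring proceeds
with `n` equal to the number of *present* genes, and the normalisation
bounds use that `n`, which keeps scores exactly in range.

**Ties.** Tied expression values reduce the number of distinct ranks,
but the normalisation bounds keep the no-tie formulas. This is a
documented approximation: heavily tied data (unfiltered counts) can
leave the extremes unattainable. The CPM filter exists largely to
avoid rank duplication, and with `min` ties the all-tied column
degrades gracefully (every gene at rank 1).

## Preprocessing

Filtering keeps genes with CPM > 1 in strictly more than 50% of
samples (both inequalities strict, matching the convention
`prop_expressed > 0.5` of standard differential-expression practice);
library sizes are recomputed after subsetting. TMM factors follow the
published trimmed-mean-of-M-values definition — reference sample by
closest 75th percentile of count/library-size, per-sample M/A values
over co-expressed genes, double trimming at 30% (M) and 5% (A),
inverse-delta-method-variance weights, factors rescaled to geometric
mean 1. The implementation is validated against edgeR's
`calcNormFactors` on a frozen fixture (agreement to 8 decimals) —
hand-written because no Python package provides it. logFPKM uses
exon-union gene lengths (pyranges interval merge; per-base union
oracle in tests) and a library-size-adjusted prior count of 0.5 to
keep zeros finite; as the scorer is rank-based, the prior is cosmetic.
Ensembl version suffixes are stripped with a trailing-`.digits` regex;
cross-vocabulary ID harmonisation keeps only one-to-one mappings in
both directions, reporting discards by biotype.

## Prediction and stratification

Mutation-status models are binomial GLMs (logit link) fitted by IRLS
via statsmodels, with the signature score and optionally its dispersion
as predictors. Evaluation is deliberately in-sample — the models
characterise how well scores *explain* the labels, not out-of-sample
generalisation (a cohort-scale question the desk-scale fixtures cannot
answer). The classifier is the natural one: predict mutant when the
linear predictor is positive (probability > 0.5). Precision is NaN
when nothing is predicted positive; F1 is defined as
`2TP/(2TP+FP+FN)` so it is 0, not NaN, in that case. Quasi-separation
(common at strong planted effects) is flagged, not raised: the induced
classifier is still well-defined even when coefficients diverge.

Unsupervised stratification offers a 1-D Gaussian mixture
(scikit-learn EM, tolerance 1e-8, up to 1000 iterations, 10 seeded
restarts, free variances by default with an equal-variance option;
per-sample uncertainty = 1 − max posterior; components relabelled by
increasing mean for stable output), k-means (best of 100 seeded
restarts) and complete-linkage hierarchical clustering cut at k = 2.
k-means and hierarchical clustering operate on raw
(score, dispersion) columns by default even though dispersion is
orders of magnitude larger and dominates the distances — this mirrors
common practice of clustering the score frame as-is; a `standardize`
flag rescales the axes when score-driven structure is wanted.
Partition agreement is the Hubert–Arabie adjusted Rand index
(scikit-learn), cross-checked in the tests against a brute-force
pair-counting oracle.

## Landscapes

Two score tables on identical, identically ordered samples are binned
on a hexagonal lattice (matplotlib's hexbin geometry on a headless
canvas; 25 bins per axis by default — a resolution chosen to resolve
structure in cohorts of a few hundred samples without emptying most
bins). Association between signatures is Spearman's rank correlation.
Projection returns overlay coordinates, a categorical annotation per
point, and text labels only for samples whose mixture classification
uncertainty exceeds 0.3 — the uncertain calls are the ones worth
inspecting individually. All landscape functions return data;
rendering to PNG/SVG is a thin optional layer.

## Synthetic cohorts

The generator draws gene baseline abundances log-normal with a
near-zero tail covering half the genes (as in real RNA-seq, where most
annotated genes fall below the low-count filter — this is what gives
the pre-filter logCPM histogram its zero spike), library sizes uniform
on [18.6M, 49.7M] reads, and counts negative binomial with dispersion
0.2 (overdispersed like biological replicates; the exact family is
irrelevant to a rank-based scorer). A mutant fraction of 0.3 of the
200 samples has the 30 up-signature genes shifted up by `delta` log2
units and the 30 down-genes shifted down; `delta = 2` is the
strong-signal condition used for recovery checks and `delta = 0` the
null. Sample barcodes are TCGA-style so the barcode-prefix patient
join is exercised. The toy GTF writer lays genes along one chromosome
and deliberately overlaps the first two exons of multi-exon genes, so
recovering the annotation lengths requires genuine interval union.

What passing on these fixtures shows: the statistics, their ranges and
invariances, and end-to-end plumbing are correct. What it does not
show: behaviour under batch effects, correlated gene modules,
co-occurring mutations, or realistic signature/biology mismatch — the
generator plants exactly the structure the score assumes.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale — cohorts of 60–200
samples and 300–2,000 genes, enumeration oracles at `N ≤ 12` — sizes
chosen so the full suite completes in well under a minute per module
while still exercising every code path. Every stochastic step takes an
explicit seed (the workflow config carries one; `tie_method='random'`
requires one), and reruns are bit-identical.

## Known limitations

Tie handling approximates normalisation bounds (above). The TMM
implementation covers the standard positive-library case, not edgeR's
degenerate-sample fallbacks. Statistical significance of scores
(permutation nulls) is out of scope, as are interactive plots and any
network retrieval — signatures and annotations are read from local
files only.
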