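# Methods

This note documents the models, parameter choices and numerical decisions
behind `exopba`, and what the synthetic cohorts do and do not establish
about behavior on real data.

## The generative model of the simulator

A cohort design specifies sample groups, K exosome subpopulations, a K × P
signature matrix of nonnegative per-protein detection weights, per-group
mixing proportions π_g, and a sequencing error model.  For each exosome:

- subpopulation label ~ Categorical(π_g);
- molecule count m ~ 1 + Poisson(μ − 1) with μ = 2.4 by default — a
  *detected* exosome necessarily carries at least one molecule, hence the
  shifted distribution;
- the m detected proteins are drawn **without replacement** with
  probabilities proportional to the subpopulation's signature row (Gumbel
  top-m sampling), capped at the signature's support size.

Proteins are drawn without replacement so that the number of deduplicated
molecules on an exosome equals the number of distinct proteins detected on
it.  This is deliberate: the assay's headline per-exosome statistic is
"proteins detected per exosome" (~2.4), and its molecule and exosome totals
(2.42 × 10⁵ molecules over 1.06 × 10⁵ exosomes) give essentially the same
ratio — in the real data, molecules per exosome and distinct proteins per
exosome are interchangeable at this sparsity.  An i.i.d. (with-replacement)
draw from signatures this sparse would instead make distinct proteins
(~1.7) fall visibly below the molecule mean and contradict that
calibration.

Signature rows put 95% of their mass on a dominant marker block and spread
the remaining 5% uniformly over the whole panel (a nonspecific detection
floor).  The packaged cohort fixture plants twelve subpopulations over a
115-marker panel:

- a tumor-associated cluster with a dominant ITGA6/ITGB3 core
  (within-block weights 0.42/0.38) and secondary ADAM10/CD151/CD9
  (0.08/0.06/0.06), mixing 13.61% → 23.03% → 52.06% across
  HC → primary → metastatic;
- a monocyte/macrophage-associated ITGAM/ITGAL/ITGB2 cluster
  (0.40/0.35/0.25), mixing 13.47% → 1.13% → 1.13%;
- ten residual clusters with disjoint 3-marker blocks sharing the leftover
  mass equally.

The block structure matters: with only ~2.4 molecules per exosome, a
subpopulation is recoverable only if its members usually share at least one
core marker.  Concentrating each block on a 2–3 marker core makes the
planted clusters as cohesive as the sparsity allows; a flat 5-marker block
fragments into single-marker sub-patterns that no clustering method can
reunite at this detection depth.

Cohort sizes mirror the study (HC n = 13, primary n = 10, metastatic
n = 11) at 3,000 exosomes per sample — the scale at which the study itself
clusters after downsampling.  Heavier runs (10⁴ exosomes/sample) are used
only where a calibration demands them.

### Read rendering and the error model

Each molecule is rendered as 1 + Poisson(d) sequenced copies (duplication
rate d = 0.5 by default, i.e. 1.5 reads per molecule).  The default read
layout is `[protein tag 8 nt][UMI 10 nt][anchor 12 nt][exosome tag 15 nt]`
padded to 75 nt, fully configurable since assay dialects differ.  Exosome
tags are drawn uniformly from the 4¹⁵ tag space with within-sample
uniqueness enforced by rejection (a duplicated tag would silently fuse two
vesicles; at 10⁵ exosomes the birthday bound makes raw uniform draws
collide a handful of times per cohort, so uniqueness is imposed at
generation).

Qualities follow a two-state model: good reads are uniformly Q37; a fixed
fraction (default 5%, exactly `round(0.05·n)` reads) receive 30% of bases
at Q2 and thereby deterministically fail the downstream quality rule.  The
per-base substitution rate defaults to 2 × 10⁻⁴ — the error probability
implied by Q37 — keeping the error model internally consistent: reads that
pass the filter carry Q37-level noise.

UMI collisions, chimeric reads, index hopping, antibody cross-reactivity
and capture-efficiency effects are not modeled.

## Read processing

The funnel is: quality filter → field extraction → protein-tag matching →
UMI deduplication → matrix assembly, with monotone counters asserted at
every stage.

- **Quality rule**: survive iff the fraction of bases at Q ≥ 20 strictly
  exceeds 0.75 ("more than 75%"); both threshold and fraction are
  configurable.
- **Field extraction**: reads shorter than the layout span are rejected, as
  are reads with N inside the UMI or exosome tag (molecule and vesicle
  identity must be exact).  N in the protein tag is tolerated and counts as
  a mismatch.
- **Tag matching**: exact match wins; otherwise a *unique* panel entry
  within Hamming distance 1 wins; ties and misses are counted rejections.
  The default panel's tags are generated with pairwise distance ≥ 3, so
  single-error correction is never ambiguous for error-free panels.
- **UMI deduplication**: within each (exosome tag, antibody) group, the
  directional network rule — `u` absorbs `v` when Hamming(u,v) ≤ 1 and
  count(u) ≥ 2·count(v) − 1, traversed transitively in (count desc,
  lexicographic) order.  Deterministic, idempotent on its own output, and
  verified against an independent graph-traversal oracle in the tests.  An
  `exact` mode (distinct UMIs) is available.
- **Exosome tags are grouped exactly** by default; a frequency-based
  Hamming-1 collapse exists but is off, because tags are arbitrary
  extension products with no whitelist and merging risks fusing true
  vesicles.  The cost of exact grouping is a small population of spurious
  singleton exosomes from tag-position sequencing errors (~1% of exosomes
  at default error rates), which is visible in the calibration below.

With all error processes disabled, the processed matrix is bit-identical
(as sorted triplets) to the simulated truth; this exactness is a standing
test.  At default error rates the pipeline reports ~2.32–2.33 mean proteins
per exosome against the planted 2.4: the deficit is molecules lost to the
5% bad-quality reads (a molecule disappears only when *all* its copies are
bad), plus the dilution from spurious singleton exosomes.  Both mechanisms
are intrinsic to the assay, and the reported value stays within the
±0.1 calibration band.

## Expression statistics

Sample-level expression is the column sum of the single-exosome matrix.
TMM normalization follows the canonical definition: reference sample =
the one whose upper-quartile/library-size statistic is closest to the mean;
M and A values over proteins positive in both sample and reference; double
trim (30% on M, 5% on A, by average ranks); inverse-asymptotic-variance
weights; 2^(weighted mean); factors rescaled to geometric mean 1.  The
implementation is checked to 10⁻¹⁰ against an independently coded
brute-force oracle on random tables, and to 10⁻⁸ against
`edgeR::calcNormFactors` via Rscript on a fixed table.  Normalized values
are counts-per-million on TMM-effective library sizes.

Differential testing routes per protein: Shapiro–Wilk on each group at
α = 0.05; if both pass, an F-ratio test at 0.05 chooses Student's *t*
(equal variances) or Welch's *t*; if normality fails in either group, a
two-sided Wilcoxon rank-sum test (switchable to always-parametric).  Two
numerical choices matter:

- **Tests run on log2(value + 0.5).**  Expression noise is multiplicative,
  so the Gaussian model that the routing assumes is meaningful on the log
  scale; on the raw scale the Welch route cannot push p-values deep enough
  to survive a 200-protein BH family even for a 4-fold shift at n = 10
  per group.  Fold changes are always reported from raw group means with a
  0.5 pseudocount.
- **The Wilcoxon fallback uses the exact Mann–Whitney null** when there are
  no ties and group sizes are ≤ 25: the normal approximation is badly
  conservative in the extreme tail, exactly where multiple-testing
  survival is decided.

Proteins constant in both groups get a missing p and are excluded from the
BH family.  BH adjustment is the standard step-up (delegated to
statsmodels), with missing values passed through.

Cluster-level differential abundance uses a two-sample *t* test on
per-sample proportions with BH adjustment, mirroring the expression module.

## Subpopulation discovery

Pooled, downsampled (3,000/sample) exosome profiles are binarized to
presence/absence — at 2.4 proteins per exosome counts are near-binary, and
presence frequencies are the natural cluster signature — and then each row
is L2-normalized.  The normalization is load-bearing: on raw sparse binary
vectors, Euclidean distance has an origin pathology in which diffuse
low-norm prototypes (mixtures of unrelated single-marker patterns) are
closer to *every* singleton exosome than that exosome's own cluster
centroid is, and such prototypes chain unrelated clusters together during
linkage.  Row normalization makes Euclidean distance equivalent to cosine
distance and removes the pathology.  A log1p transform is offered as an
alternative for count-valued analyses.

The SOM is a batch self-organizing map: 10 × 10 grid, Gaussian grid
neighborhood with width shrinking linearly from σ = 3.0 to 0.05 over 20
epochs, codebook initialized on the plane of the first two principal
components (±2 SD; the classic deterministic linear initialization, with
random-data-row init available).  The long low-σ tail of the schedule
sharpens node prototypes toward local data means; with the default
settings, planted-cluster recovery on the packaged fixture is stable
across seeds, which random-row initialization with a short schedule does
not achieve.  Nodes that no exosome maps to after training are dropped
before metaclustering — they carry no data and would otherwise form
phantom clusters in empty regions of the feature space.

Metaclustering is consensus clustering of the codebook: 100 replicates,
each subsampling 80% of nodes and cutting an average-linkage Euclidean
dendrogram at k; consensus(i,j) = co-cluster count / co-sample count; the
final partition cuts an average-linkage tree on 1 − consensus at K.
K = 12 by default.  Exosomes inherit the metacluster of their nearest
codebook node; cluster labels are renumbered by decreasing abundance;
signatures are per-cluster marker detection frequencies.

### Choosing K automatically, and why the default is fixed

`auto_k` scores each candidate k by one of three criteria: mean silhouette
of the consensus partition in codebook space, weighted by node occupancy
(default); the proportion of ambiguous clustering (PAC); or the relative
change in consensus-CDF area (delta-area).  Two caveats are documented
rather than hidden.  First, the area under the consensus CDF equals
1 − mean(consensus), so the *argmax* of the relative delta-area is
structurally attained at small k and cannot localize a plateau; the
criterion is retained for completeness but is not the default.  Second, and
more fundamentally, on the packaged fixture no internal-validity criterion
identifies the planted K = 12 reliably: the data contain twelve planted
clusters *plus* a small genuine noise population (background-only and
spurious-tag singleton exosomes), and merging two residual-mass clusters or
splitting off the noise changes every criterion negligibly, so selections
wander over 11–14 (and occasionally further) across seeds.  Consensus over
a fixed node set is also near-binary at every k, which degenerates
PAC-style stability measures.  This mirrors the practical reality that in
cytometry-style workflows the metacluster count is usually fixed by the
analyst; the package defaults to K = 12 with `auto_k` as a diagnostic, and
the selection curves are exported for inspection.

Recovery at the default K is the relevant guarantee, and it is strong: on
the packaged fixture the recovered proportions of the tumor- and
immune-signature clusters are within ~1–2 percentage points of the planted
mixing in every group, across seeds.

The 2-D embedding is scikit-learn t-SNE under a fixed seed, treated as a
visualization-only black box; nothing downstream consumes the coordinates.

## ROC diagnostics

Marker scores are TMM-normalized expression values (or subpopulation
proportions); the curve sweeps unique scores descending with ties grouped,
so the trapezoidal area equals the Mann–Whitney statistic with ties counted
½ — asserted exactly against an exhaustive pair-count oracle.  Orientation
is fixed by the declared positive class: a marker that *decreases* in the
positive class shows AUC < 0.5 rather than being silently flipped (a `flip`
flag reverses it explicitly).

The 95% interval is DeLong's: placement values V₁₀, V₀₁, variance
S₁₀/m + S₀₁/n, normal approximation, clipped to [0, 1]; perfect separation
degenerates to a point interval with a warning.  The implementation agrees
with `pROC::ci.auc(method = "delong")` to six decimals on shared data.  A
known property, measured here over 5,000 simulated cohorts: at true AUC
0.85 with n = 25 per class, the clipped normal interval's true coverage is
≈ 0.919, not 0.95 — small-sample undercoverage of the standard
construction itself, not an implementation artifact.  The package reports
the standard interval because its truncated-at-1 form is what the assay
literature prints.

## What the synthetic cohorts do not show

The simulator plants clean block signatures, independent exosomes,
homogeneous samples within groups, and a benign error model.  Passing
recovery tests therefore demonstrates the pipeline's correctness and its
behavior at realistic sparsity, sample sizes and error rates — not
robustness to antibody cross-reactivity, capture bias, batch effects,
within-group biological heterogeneity, or subpopulations defined by
graded (rather than block) marker frequencies.  Cohort-level findings of
the original study (patient AUCs, specific marker lists) are inputs to the
fixture design, not outputs this package can re-derive.

## Problem sizes used in the standing checks

Exactness checks run at 2,000 exosomes; the proteins-per-exosome
calibration at 6 samples × 10⁴ exosomes; subpopulation recovery at the
full fixture (34 samples × 3,000 exosomes, five seeds); oracle equivalence
at 100 random tables (TMM) and 1,000 random instances (AUC); error control
at 200 proteins × 100 replicates; interval coverage at 500 cohorts.  These
sizes make every stochastic check's Monte Carlo error small relative to its
tolerance while keeping the whole suite fast enough to run routinely.
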