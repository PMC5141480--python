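# Methods

## Scope and data model

`subtypekit` operates downstream of quantification: its inputs are gene ×
sample expression matrices (raw counts or log2 values), curated luminal/basal
marker-gene signatures, sample group labels, called peak intervals (BED,
0-based half-open throughout), genomic FASTA, and JASPAR-style position
frequency matrices. Read alignment, transcript quantification, peak calling
and de novo motif discovery are out of scope; alteration annotations are
consumed as given labels.

## Count normalization

`size_factor_normalize` implements median-of-ratios scaling: the reference
for gene *g* is its geometric mean across libraries; genes with a zero count
in any library are excluded from the reference (but retained in the output);
the factor for library *j* is the median over reference genes of
`n_gj / ref_g`, and normalized values are `n_gj / f_j`. Note that raw
factors are only defined up to the reference scale: multiplying one
library's counts by *c* multiplies its factor by `c^((m−1)/m)` and every
other factor by `c^(−1/m)`, so factor *ratios* — the quantity that matters —
scale by exactly *c*.

## Subtype discovery

Discovery restricts the (log2) matrix to the signature genes present
(absent genes are logged, not fatal), median-centers each gene across
samples, and optionally drops genes below a variance percentile.
Agglomerative clustering runs on sample profiles with configurable linkage
(average/complete/ward; default average) and metric (1 − Pearson or
Euclidean; default correlation, the common choice for expression subtype
work). Samples are ordered lexicographically before tree construction so
equal-height merges resolve identically across runs. Clusters are labeled
from their mean marker-panel scores on the centered matrix: non-type when
both panels fall below `nontype_threshold` (default 0, i.e. below the
cohort-median profile), otherwise the larger panel wins.

A caveat the synthetic experiments make explicit: samples defined by the
*absence* of signal (non-type) have no coherent correlation structure —
their centered profiles are noise, and 1 − Pearson distance cannot group
them (three-group recovery plateaus near ARI 0.7). Euclidean distance on
the centered signature matrix separates all three groups exactly, so the
recovery experiments (tests and acceptance script) use
`metric="euclidean"`; both metrics remain available and the default is
unchanged for two-class discovery, where correlation distance behaves well
(luminal and basal profiles are strongly anticorrelated).

## Nearest-centroid classification (ClaNC-style)

`build_centroids` computes per-class per-gene means and a pooled
within-class standard deviation `s_g = sqrt(Σ_k Σ_{i∈k}(x_gi − c_gk)²/(n−K))`,
stabilized by `s_0` = median of `s_g` over genes (floor 1e−6 when every
gene is exact). Gene selection scores each gene and class with

    d_gk = (x̄_gk − x̄_g) / (m_k (s_g + s_0)),    m_k = √(1/n_k − 1/n),

the standard error of a class mean against the overall mean. Each gene is
assigned to the class maximizing |d|; because |d| is exactly antisymmetric
for two balanced classes, near-ties (relative 1e−9) go to the class where
the gene is up-regulated — this keeps the selection deterministic and maps
planted marker panels to their own class. The top ⌈n_total/K⌉ genes per
class are kept (balanced allocation, ClaNC's default; the final list is
trimmed to n_total by dropping the smallest |d|; remaining ties break on
gene id).

Classification uses the diagonal-covariance discriminant
`D_k = Σ_g (x_g − c_gk)²/(s_g + s_0)²` over the selected genes; the label is
the argmin, with "ambiguous" reserved for distances within 1e−9 (a
floating-point guard, not a biological call). Up to 20% of model genes may
be missing from a query (dropped pairwise, logged); class priors are
omitted (balanced designs assumed).

**Reference frame.** Queries are centered on the *training* per-gene
medians (`signature_medians` + `preprocess(..., reference_medians=...)`),
never on their own: a perturbed sample must not be able to move its own
reference point, and with even, balanced cohorts at low noise a single
perturbed sample can tip its cohort's median discontinuously.

The shift score is `D_basal − D_luminal`; its difference treated-minus-control
measures movement along the basal→luminal axis (positive = toward luminal).
Replicate consensus is unanimity: a class is called only if every replicate
carries that label (an ambiguous replicate makes the set discordant).

## Cross-dataset centroid concordance

`correlate_centroids` computes Spearman rank correlation (average ranks on
ties) over the gene intersection of two centroid models; p-values come from
the t approximation `t = ρ√((n−2)/(1−ρ²))` with n−2 df, or from exact
permutation enumeration for n ≤ 9. Concordance is evaluated on the
**uncentered log2 scale**: per-gene centering reduces a centroid built from
a two-level generative model to a two-block vector whose Spearman
correlation across independent realizations is capped near 0.75 by
block-rank structure alone, whereas on the expression scale the per-gene
baseline carries genuine cross-dataset rank information (measured
same-class ρ ≈ 0.81–0.94 under batch shifts of sd 0.5, always above
cross-class ρ).

## Differential expression and the TF screen

The per-gene test is a pooled-variance two-sample t on log2 expression
(group1 − group2, groups ordered lexicographically). With shrinkage on
(default), the sample variances are squeezed toward a common prior by the
moment match on log variances: with `e_g = log s²_g − ψ(d_g/2) + log(d_g/2)`,
the prior df solves `ψ′(d₀/2) = var(e) − ψ′(d_g/2)` (trigamma inverse by
Newton; d₀ = ∞ when the observed spread is no larger than chi-square noise),
`s₀² = exp(ē + ψ(d₀/2) − log(d₀/2))`, and
`s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g)` with d₀+d_g df. This is the standard
moderated-t construction, written to be verifiable against a brute-force
oracle. Zero-variance genes with unequal means are testable only with
shrinkage (s̃ > 0); with shrinkage off they are flagged NA and excluded from
adjustment. Multiple testing uses the Benjamini–Hochberg step-up
(Bonferroni available); fold-change lists use `|log2fc| ≥ log2(threshold)`
with inclusive boundaries and deliberately no significance filter — the
two-replicate reprogramming design has too little residual df for p-values
to mean much. The cross-cohort TF screen calls a factor replicated when its
q-value clears the threshold in both cohorts and (optionally, default on)
the fold-change signs agree; q-values are taken from the supplied
differential-expression tables, so the caller controls the testing family.

## Peak concordance and motif association

Consensus peaks: intervals from both replicates are pooled and swept into
maximal runs of mutually overlapping intervals; a run is emitted (as its
union span) when it contains at least one replicate-1/replicate-2 pair
overlapping by ≥ `min_overlap_bp` (default 1). The rule is symmetric and is
property-tested against an all-pairs overlap-graph oracle.

Scanning windows are `[center−h, center+h)` around peak centers
(`center = ⌊(start+end)/2⌋`, default h = 100 bp, clipped at chromosome
ends). PWM scoring adds a 0.5 pseudocount to every PFM cell, normalizes
per column, and scores log2 odds against the background (uniform 0.25
unless overridden); both strands by default; an ambiguous base contributes
the log2 background-weighted average odds of its compatible bases (exactly
0 for N). A window hits when its best score reaches
`threshold_value × max achievable score` (default 0.8) or an absolute
log-odds cutoff. Enrichment counts sequences with ≥ 1 hit (binary per
sequence, matching "% of sites associated with a motif" reporting), tests
each motif's 2×2 table with a one-sided Fisher exact test (foreground
greater), and adjusts across motifs with BH (significant at q < 0.05 by
default). Background windows are user-supplied intervals or seeded
dinucleotide-preserving shuffles of the foreground (Euler-path shuffle).
Fisher's exact test is used rather than a binomial approximation because it
is exactly verifiable by hypergeometric enumeration.

## Synthetic data generator

The expression generator draws a per-gene baseline from N(6, 1²) log2 units
(typical bulk RNA dynamic range; the spread is inert to any median-centered
inference), then plants two disjoint marker panels: luminal samples sit
`effect_size` (default 2 log2 units) above baseline on the luminal panel,
basal samples on the basal panel, non-type samples at baseline on both, and
non-marker genes are identical across classes — an exact null set for FDR
calibration. I.i.d. N(0, noise_sd²) noise (default 0.5) is added; `apply_batch`
adds one N(0, batch_sd²) offset per gene across all samples; `resample_noise`
redraws the noise to emulate sibling datasets or replicate measurements;
`apply_perturbation` sets a sample's expected marker values to the convex
combination `(1−f)·own + f·target` template, reusing the original noise draw
so f = 0 reproduces the input bit-exactly. Default cohort sizes are 20
luminal + 20 basal (+10 non-type where discovery is exercised), the scale of
the cell-line panels this kind of analysis targets.

The peak simulator packs shared, replicate-unique and background intervals
(200 bp, ≥ 15 bp margins) into non-overlapping slots of a random genome,
jitters the replicate-2 copy of each shared peak by ≤ 10 bp, and plants the
motif consensus (random strand) at window centers by **quota sampling** —
exactly `round(rate × n)` instances — so enrichment ground truth is
deterministic rather than binomially noisy.

What the generator does not emulate: count overdispersion (values are
log-scale Gaussian), correlated gene modules, gradated marker effect sizes,
partial-overlap signatures, or sequence composition bias in peaks. Passing
recovery tests therefore demonstrates correctness of the machinery under
the stated generative assumptions, not performance on real cohorts.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use: 10 seeds × 50-sample
cohorts for clustering/labeling recovery; 10 seeds × (40 train + 40
held-out) for classifier accuracy; 50 pure-noise replicates of 2000 genes ×
20 samples for FDR calibration (plus 5 planted-marker cohorts for power);
10 seeds for centroid concordance; and 50 simulated ChIP experiments (200
shared + 2×20 unique peaks, 400 background windows, 20 decoy PWMs) for
motif recovery — sizes chosen so the whole suite completes in well under a
minute per stage on one CPU while keeping Monte-Carlo standard errors small
relative to the asserted margins. Every random draw flows from an explicit
seed (numpy `default_rng`); identical seeds reproduce every artifact, table
and CLI output byte-exactly.

## Known limitations

- Non-type is a discovery label only; the classifier predicts luminal vs
  basal and never emits non-type.
- The variance-prior fit assumes a common residual df across genes (no
  missing values within a matrix).
- The exact Spearman permutation p is enumerated (n ≤ 9 only).
- `fcluster(..., maxclust)` can return fewer than k groups on pathological
  ties; the discovery CLI reports the realized clusters.
- The motif scanner reports the single best window per sequence; occurrence
  counts per sequence are not modeled (binary association only).
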