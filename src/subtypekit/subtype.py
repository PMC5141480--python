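"""Normalization, signature-restricted preprocessing, and subtype discovery.

Count normalization is the median-of-ratios scheme: each library is scaled by
the median, over genes expressed in every sample, of its counts divided by the
per-gene geometric-mean reference. Discovery clustering is agglomerative on
sample profiles restricted to the signature genes; clusters are then named
luminal / basal / non-type from their mean marker-panel scores, with non-type
reserved for clusters low on both panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .dataio import (
    DataError,
    ExpressionMatrix,
    GeneSignature,
    NONTYPE_LABEL,
    logger,
)

LINKAGES = ("average", "complete", "ward")
METRICS = ("correlation", "euclidean")


@dataclass
class SizeFactors:
    factors: dict[str, float]

    def __post_init__(self) -> None:
        for sid, f in self.factors.items():
            if not f > 0:
                raise DataError(f"non-positive size factor for sample {sid!r}")


@dataclass
class ClusterResult:
    assignments: dict[str, int]     # sample -> cluster index (1..k)
    merge_tree: np.ndarray          # scipy linkage matrix over ordered samples
    sample_order: list[str]         # lexicographic order used for the tree
    linkage: str
    metric: str
    k: int


@dataclass
class SubtypeLabeling:
    cluster_labels: dict[int, str]                    # cluster -> label
    cluster_scores: dict[int, tuple[float, float]]    # (luminal, basal) means

    def sample_labels(self, clusters: ClusterResult) -> dict[str, str]:
        return {s: self.cluster_labels[c] for s, c in clusters.assignments.items()}


def size_factor_normalize(counts: ExpressionMatrix) -> tuple[SizeFactors, ExpressionMatrix]:
    """Median-of-ratios library size factors; returns factors and scaled counts.

    The reference for gene g is its geometric mean across samples; genes with
    a zero in any sample are excluded from the median (but kept in the output).
    """
    if counts.scale_tag != "counts":
        raise DataError("size_factor_normalize expects a counts matrix")
    X = counts.values
    all_pos = np.all(X > 0, axis=1)
    if not np.any(all_pos):
        raise DataError("cannot form reference: no gene has nonzero counts in all samples")
    logref = np.mean(np.log(X[all_pos, :]), axis=1)   # log geometric mean
    ratios = np.log(X[all_pos, :]) - logref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    sf = SizeFactors(dict(zip(counts.sample_ids, factors.astype(float))))
    normalized = ExpressionMatrix(list(counts.gene_ids), list(counts.sample_ids),
                                  X / factors[None, :], "counts")
    logger.info("size factors over %d/%d reference genes: min=%.4g max=%.4g",
                int(all_pos.sum()), counts.n_genes, factors.min(), factors.max())
    return sf, normalized


def signature_medians(matrix: ExpressionMatrix, signature: GeneSignature,
                      log_offset: float = 1.0) -> dict[str, float]:
    """Per-gene medians (after log transform) of the signature genes present.

    Use these as ``reference_medians`` in :func:`preprocess` to center a query
    dataset in the same frame as the training data.
    """
    X = matrix.values
    if matrix.scale_tag == "counts":
        X = np.log2(X + log_offset)
    idx = {g: i for i, g in enumerate(matrix.gene_ids)}
    return {g: float(np.median(X[idx[g], :]))
            for g in signature.genes() if g in idx}


def preprocess(matrix: ExpressionMatrix, signature: GeneSignature,
               log_offset: float = 1.0,
               min_variance_percentile: float = 0.0,
               reference_medians: dict[str, float] | None = None) -> ExpressionMatrix:
    """Log-transform (if counts), restrict to signature genes, median-center.

    Signature genes absent from the matrix are logged and dropped, not fatal.
    Genes with variance below the given percentile of per-gene variances are
    removed (percentile 0 keeps everything). With ``reference_medians`` the
    genes are centered on those values (a training cohort's frame) instead of
    the matrix's own medians — required when classifying external samples, so
    that the query cannot move its own reference point.
    """
    X = matrix.values
    if matrix.scale_tag == "counts":
        X = np.log2(X + log_offset)
    present = [g for g in signature.genes() if g in set(matrix.gene_ids)]
    missing = [g for g in signature.genes() if g not in set(matrix.gene_ids)]
    if missing:
        logger.warning("signature genes absent from matrix (%d): %s",
                       len(missing), ", ".join(missing))
    if reference_medians is not None:
        dropped = [g for g in present if g not in reference_medians]
        if dropped:
            logger.warning("genes without a reference median dropped: %s",
                           ", ".join(dropped))
        present = [g for g in present if g in reference_medians]
    if len(present) < 2:
        raise DataError("fewer than 2 signature genes present in the matrix")
    idx = {g: i for i, g in enumerate(matrix.gene_ids)}
    rows = [idx[g] for g in present]
    sub = X[rows, :]
    if reference_medians is None:
        centers = np.median(sub, axis=1, keepdims=True)
    else:
        centers = np.array([[reference_medians[g]] for g in present])
    centered = sub - centers
    if min_variance_percentile > 0:
        variances = centered.var(axis=1, ddof=1)
        cutoff = np.percentile(variances, min_variance_percentile)
        keep = variances >= cutoff
        present = [g for g, k in zip(present, keep) if k]
        centered = centered[keep, :]
        if len(present) < 2:
            raise DataError("variance filter left fewer than 2 genes")
    return ExpressionMatrix(present, list(matrix.sample_ids), centered, "log2")


def agglomerative_cluster(matrix: ExpressionMatrix, k: int,
                          linkage: str = "average",
                          metric: str = "correlation") -> ClusterResult:
    """Hierarchical clustering of sample profiles; cut to exactly k clusters.

    Samples are ordered lexicographically before building the tree so that
    equal-height merges resolve identically across runs and column orders.
    """
    if linkage not in LINKAGES:
        raise DataError(f"unknown linkage {linkage!r}")
    if metric not in METRICS:
        raise DataError(f"unknown metric {metric!r}")
    n = matrix.n_samples
    if n < 2:
        raise DataError("need at least 2 samples to cluster")
    if k > n:
        raise DataError(f"k={k} exceeds number of samples ({n})")
    order = sorted(matrix.sample_ids)
    col = {s: j for j, s in enumerate(matrix.sample_ids)}
    profiles = matrix.values[:, [col[s] for s in order]].T   # samples x genes
    if metric == "correlation":
        sds = profiles.std(axis=1)
        for s, sd in zip(order, sds):
            if sd == 0:
                raise DataError(
                    f"sample {s!r} has a zero-variance profile; "
                    "correlation distance is undefined"
                )
    D = pdist(profiles, metric=metric)
    Z = scipy_linkage(D, method=linkage)
    flat = fcluster(Z, t=k, criterion="maxclust")
    assignments = {s: int(c) for s, c in zip(order, flat)}
    logger.info("clustered %d samples x %d genes: k=%d, linkage=%s, metric=%s",
                n, matrix.n_genes, k, linkage, metric)
    return ClusterResult(assignments, Z, order, linkage, metric, k)


def label_clusters(matrix: ExpressionMatrix, clusters: ClusterResult,
                   signature: GeneSignature,
                   nontype_threshold: float = 0.0) -> SubtypeLabeling:
    """Name clusters from mean marker-panel scores on the centered matrix.

    A cluster is non-type when both panel scores fall below the threshold
    (default 0 = the cohort-median profile); otherwise it takes the label of
    the larger score.
    """
    signature.require_both_classes()
    gene_idx = {g: i for i, g in enumerate(matrix.gene_ids)}
    lum_rows = [gene_idx[g] for g in signature.genes("luminal") if g in gene_idx]
    bas_rows = [gene_idx[g] for g in signature.genes("basal") if g in gene_idx]
    if not lum_rows or not bas_rows:
        raise DataError("signature class has no genes present in the matrix")
    col = {s: j for j, s in enumerate(matrix.sample_ids)}
    labels: dict[int, str] = {}
    scores: dict[int, tuple[float, float]] = {}
    for c in sorted(set(clusters.assignments.values())):
        cols = [col[s] for s, ci in clusters.assignments.items() if ci == c]
        lum = float(matrix.values[np.ix_(lum_rows, cols)].mean())
        bas = float(matrix.values[np.ix_(bas_rows, cols)].mean())
        if not (np.isfinite(lum) and np.isfinite(bas)):
            raise DataError(f"non-finite panel score for cluster {c}")
        if lum < nontype_threshold and bas < nontype_threshold:
            labels[c] = NONTYPE_LABEL
        else:
            labels[c] = "luminal" if lum >= bas else "basal"
        scores[c] = (lum, bas)
    return SubtypeLabeling(labels, scores)
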