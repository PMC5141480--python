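"""Subtype centroids, cross-cohort concordance, and nearest-centroid calls.

The classifier follows the classification-to-nearest-centroids (ClaNC)
recipe: per gene and class, a standardized class-vs-overall-mean statistic

    d_gk = (mean_gk - mean_g) / (m_k * (pooled_sd_g + s0)),   m_k = sqrt(1/n_k - 1/n)

ranks genes; each gene is assigned to the class where |d| is largest, the
classifier keeps a balanced number of top genes per class, and a query is
assigned to the class minimizing the variance-standardized squared distance

    D_k = sum_g (x_g - centroid_gk)^2 / (pooled_sd_g + s0)^2 .

The shift score D_basal - D_luminal measures movement along the
basal-to-luminal axis; its change versus a control quantifies
transdifferentiation of a perturbed sample.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import DataError, ExpressionMatrix, logger

AMBIGUOUS_TIE = 1e-9     # discriminant-unit tie band; a float guard only
MIN_COVERAGE = 0.8       # required fraction of model genes present in a query


@dataclass
class CentroidModel:
    classes: list[str]
    selected_genes: list[str]
    centroid: np.ndarray            # classes x genes
    pooled_sd: np.ndarray           # per gene
    s0: float
    training_counts: dict[str, int]
    gene_stats: pd.DataFrame | None = None   # selection statistics, if any

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.pooled_sd = np.asarray(self.pooled_sd, dtype=float)
        if len(self.selected_genes) < 1:
            raise DataError("centroid model needs at least one gene")
        if self.centroid.shape != (len(self.classes), len(self.selected_genes)):
            raise DataError("centroid matrix shape mismatch")
        if not np.all(np.isfinite(self.centroid)):
            raise DataError("non-finite centroid value")
        if np.any(self.pooled_sd + self.s0 <= 0):
            raise DataError("pooled_sd + s0 must be positive for every gene")

    def fingerprint(self) -> tuple[str, ...]:
        return tuple(self.selected_genes)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": self.classes,
            "selected_genes": self.selected_genes,
            "centroid": self.centroid.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "training_counts": self.training_counts,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CentroidModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(payload["classes"], payload["selected_genes"],
                   np.array(payload["centroid"]), np.array(payload["pooled_sd"]),
                   float(payload["s0"]), dict(payload["training_counts"]))


@dataclass
class SubtypeCall:
    sample_id: str
    distances: dict[str, float]
    label: str                      # class label or "ambiguous"
    shift: float                    # d_basal - d_luminal
    model_fingerprint: tuple[str, ...] = ()


def build_centroids(matrix: ExpressionMatrix, labels: Mapping[str, str],
                    genes: Sequence[str] | None = None) -> CentroidModel:
    """Per-class gene means plus a pooled within-class spread (no selection).

    pooled_sd_g = sqrt( sum_k sum_{i in k} (x_gi - centroid_gk)^2 / (n - K) );
    s0 is the median pooled sd across genes (1e-6 when every gene is exact).
    """
    if genes is None:
        genes = list(matrix.gene_ids)
    sub = matrix.subset_genes(genes)
    classes = sorted(set(labels.values()))
    col = {s: j for j, s in enumerate(sub.sample_ids)}
    unknown = [s for s in labels if s not in col]
    if unknown:
        raise DataError(f"labeled samples absent from matrix: {unknown[:10]}")
    members = {k: [col[s] for s, lab in labels.items() if lab == k] for k in classes}
    for k, cols in members.items():
        if not cols:
            raise DataError(f"class {k!r} has no samples")
    n = sum(len(c) for c in members.values())
    K = len(classes)
    if n <= K:
        raise DataError(f"pooled sd undefined: n={n} samples <= K={K} classes")
    centroid = np.vstack([sub.values[:, members[k]].mean(axis=1) for k in classes])
    ss = np.zeros(sub.n_genes)
    for ki, k in enumerate(classes):
        resid = sub.values[:, members[k]] - centroid[ki][:, None]
        ss += (resid ** 2).sum(axis=1)
    pooled_sd = np.sqrt(ss / (n - K))
    s0 = float(np.median(pooled_sd))
    if s0 == 0.0:
        s0 = 1e-6
    return CentroidModel(classes, list(sub.gene_ids), centroid, pooled_sd, s0,
                         {k: len(members[k]) for k in classes})


def correlate_centroids(model_a: CentroidModel, model_b: CentroidModel,
                        class_pair: tuple[str, str] = ("luminal", "luminal"),
                        method: str = "auto") -> tuple[float, float, int]:
    """Spearman correlation of two centroid vectors over their shared genes.

    ``method``: "t" uses the t approximation with n-2 df; "exact" enumerates
    all rank permutations (only for n <= 9); "auto" picks exact for n <= 9.
    Returns (rho, two-sided p, number of shared genes).
    """
    ca, cb = class_pair
    if ca not in model_a.classes or cb not in model_b.classes:
        raise DataError(f"class pair {class_pair} not present in both models")
    shared = [g for g in model_a.selected_genes if g in set(model_b.selected_genes)]
    if len(shared) < 3:
        raise DataError(f"only {len(shared)} shared genes; need >= 3")
    ia = {g: i for i, g in enumerate(model_a.selected_genes)}
    ib = {g: i for i, g in enumerate(model_b.selected_genes)}
    va = model_a.centroid[model_a.classes.index(ca), [ia[g] for g in shared]]
    vb = model_b.centroid[model_b.classes.index(cb), [ib[g] for g in shared]]
    ra = stats.rankdata(va)
    rb = stats.rankdata(vb)
    if np.all(ra == ra[0]) or np.all(rb == rb[0]):
        raise DataError("zero rank variance in a centroid vector")
    n = len(shared)
    rho = float(np.corrcoef(ra, rb)[0, 1])
    if method == "auto":
        method = "exact" if n <= 9 else "t"
    if method == "exact":
        if n > 9:
            raise DataError("exact permutation p only offered for n <= 9")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(np.corrcoef(ra, rb[list(perm)])[0, 1])
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = count / total
    elif method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    else:
        raise DataError(f"unknown method {method!r}")
    return rho, p, n


def select_genes_clanc(matrix: ExpressionMatrix, labels: Mapping[str, str],
                       n_total: int,
                       candidate_genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Balanced per-class gene selection by the standardized class statistic.

    Each candidate gene is assigned to the class maximizing |d_gk|; the top
    ceil(n_total / K) genes per class are kept, then trimmed back to n_total
    by dropping the smallest |d|. Ties break on gene id, so the selection is
    deterministic. Returns a DataFrame (gene, class, d, abs_d) in final order.
    """
    if candidate_genes is None:
        candidate_genes = list(matrix.gene_ids)
    candidate_genes = [g for g in candidate_genes if g in set(matrix.gene_ids)]
    classes = sorted(set(labels.values()))
    K = len(classes)
    if n_total < K:
        raise DataError(f"n_total={n_total} is below the number of classes ({K})")
    col = {s: j for j, s in enumerate(matrix.sample_ids)}
    members = {k: [col[s] for s, lab in labels.items() if lab == k] for k in classes}
    for k, cols in members.items():
        if len(cols) < 2:
            raise DataError(f"class {k!r} has fewer than 2 samples")
    if len(candidate_genes) < n_total:
        logger.warning("only %d candidate genes for n_total=%d; using all",
                       len(candidate_genes), n_total)
    model = build_centroids(matrix, labels, candidate_genes)
    n = sum(len(c) for c in members.values())
    used_cols = sorted(j for cols in members.values() for j in cols)
    sub = matrix.subset_genes(candidate_genes)
    overall = sub.values[:, used_cols].mean(axis=1)
    denom_base = model.pooled_sd + model.s0
    records = []
    for gi, g in enumerate(candidate_genes):
        ds = {}
        for ki, k in enumerate(classes):
            m_k = math.sqrt(1.0 / len(members[k]) - 1.0 / n)
            ds[k] = (model.centroid[ki, gi] - overall[gi]) / (m_k * denom_base[gi])
        # |d| is exactly antisymmetric for two balanced classes, so near-ties
        # go to the class where the gene is UP (largest signed d)
        amax = max(abs(d) for d in ds.values())
        tol = 1e-9 * max(1.0, amax)
        tied = [k for k, d in ds.items() if abs(d) >= amax - tol]
        best_k = max(tied, key=lambda k: (ds[k], k))
        records.append({"gene": g, "class": best_k, "d": ds[best_k],
                        "abs_d": abs(ds[best_k])})
    df = pd.DataFrame(records)
    per_class = math.ceil(n_total / K)
    picked = []
    for k in classes:
        dk = df[df["class"] == k].sort_values(["abs_d", "gene"],
                                              ascending=[False, True])
        picked.append(dk.head(per_class))
    sel = pd.concat(picked).sort_values(["abs_d", "gene"], ascending=[False, True])
    sel = sel.head(n_total).reset_index(drop=True)
    return sel


def build_clanc_model(matrix: ExpressionMatrix, labels: Mapping[str, str],
                      n_total: int,
                      candidate_genes: Sequence[str] | None = None) -> CentroidModel:
    """Select genes then build the centroid model restricted to them."""
    sel = select_genes_clanc(matrix, labels, n_total, candidate_genes)
    model = build_centroids(matrix, labels, list(sel["gene"]))
    model.gene_stats = sel
    return model


def classify_clanc(model: CentroidModel, profile: Mapping[str, float] | pd.Series,
                   sample_id: str | None = None) -> SubtypeCall:
    """Assign a sample to the nearest centroid by standardized squared distance."""
    if isinstance(profile, pd.Series):
        sample_id = sample_id or str(profile.name)
        profile = profile.to_dict()
    sample_id = sample_id or "sample"
    present = [i for i, g in enumerate(model.selected_genes) if g in profile]
    missing = [g for g in model.selected_genes if g not in profile]
    coverage = len(present) / len(model.selected_genes)
    if coverage < MIN_COVERAGE:
        raise DataError(
            f"sample {sample_id!r} covers only {coverage:.0%} of model genes; "
            f"missing: {', '.join(missing)}"
        )
    if missing:
        logger.warning("sample %s: %d model genes missing, dropped pairwise: %s",
                       sample_id, len(missing), ", ".join(missing))
    x = np.array([profile[model.selected_genes[i]] for i in present], dtype=float)
    denom = (model.pooled_sd[present] + model.s0) ** 2
    distances = {}
    for ki, k in enumerate(model.classes):
        diff = x - model.centroid[ki, present]
        distances[k] = float(np.sum(diff ** 2 / denom))
    ordered = sorted(distances.items(), key=lambda kv: (kv[1], kv[0]))
    if len(ordered) > 1 and ordered[1][1] - ordered[0][1] < AMBIGUOUS_TIE:
        label = "ambiguous"
    else:
        label = ordered[0][0]
    shift = distances.get("basal", math.nan) - distances.get("luminal", math.nan)
    return SubtypeCall(sample_id, distances, label, shift, model.fingerprint())


def classify_matrix(model: CentroidModel, matrix: ExpressionMatrix) -> list[SubtypeCall]:
    return [classify_clanc(model, matrix.sample_profile(s)) for s in matrix.sample_ids]


def shift_score(model: CentroidModel, treated: SubtypeCall, control: SubtypeCall) -> float:
    """Change in the basal-minus-luminal discriminant; positive = toward luminal."""
    fp = model.fingerprint()
    if treated.model_fingerprint != fp or control.model_fingerprint != fp:
        raise DataError("shift_score: calls were made against a different model")
    return treated.shift - control.shift


def consensus_call(replicate_calls: Sequence[SubtypeCall]) -> str:
    """Replicate-consensus label: unanimous class or 'discordant'."""
    if not replicate_calls:
        raise DataError("consensus_call needs at least one replicate")
    if len(replicate_calls) < 2:
        raise DataError("consensus_call needs >= 2 replicate calls")
    labels = {c.label for c in replicate_calls}
    if len(labels) == 1 and "ambiguous" not in labels:
        return labels.pop()
    return "discordant"
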