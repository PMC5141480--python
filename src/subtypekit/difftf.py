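"""Two-group differential expression, BH FDR, fold-change lists, TF screen.

The per-gene test is a pooled-variance two-sample t on log2 expression.
With shrinkage on (the default), the per-gene variance is squeezed toward a
common prior by the empirical-Bayes moment match on log sample variances:
the prior degrees of freedom d0 solve

    trigamma(d0/2) = var(e_g) - trigamma(d_g/2),
    e_g = log(s_g^2) - digamma(d_g/2) + log(d_g/2),

and the moderated variance is s~^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g) with
d0 + d_g degrees of freedom — the standard moderated-t construction.
Multiple testing uses the Benjamini–Hochberg step-up by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .dataio import DataError, ExpressionMatrix, GroupDesign, logger


@dataclass
class DEResult:
    """Per-gene differential-expression table.

    ``table`` columns: gene, mean1, mean2, sd1, sd2, log2fc (group1 - group2),
    t, p, q, df. Genes excluded from testing (zero variance with shrinkage
    off) carry NaN t/p/q.
    """

    table: pd.DataFrame
    group1: str
    group2: str
    shrink: bool
    prior_df: float = math.nan
    prior_var: float = math.nan

    def gene_row(self, gene: str) -> pd.Series:
        return self.table.set_index("gene").loc[gene]


def _trigamma_inverse(x: float, tol: float = 1e-8) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, limma-style)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) to the spread of log sample variances.

    Returns (prior df, prior variance); prior df is inf when the observed
    spread of log variances is no larger than expected from chi-square noise
    alone (all genes then share s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        return math.inf, float(pos.mean()) if pos.size else 0.0
    z = np.log(pos)
    e = z - float(special.digamma(df_resid / 2.0)) + math.log(df_resid / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df_resid / 2.0))
    if evar <= 0:
        d0 = math.inf
        s0_2 = float(np.exp(e.mean()))
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(e.mean() + special.digamma(d0 / 2.0)
                            - math.log(d0 / 2.0)))
    return d0, s0_2


def differential_expression(matrix: ExpressionMatrix, design: GroupDesign,
                            shrink: bool = True) -> DEResult:
    """Per-gene two-group t-test on a log2 matrix, with optional shrinkage.

    log2fc is group1 minus group2, where group1 is the lexicographically
    first design label; name groups accordingly to fix the sign convention.
    """
    if matrix.scale_tag != "log2":
        raise DataError("differential_expression expects a log2-scale matrix")
    design.validate_against(matrix)
    groups = design.labels()
    if len(groups) != 2:
        raise DataError(f"need exactly two groups, got {groups}")
    g1, g2 = groups
    col = {s: j for j, s in enumerate(matrix.sample_ids)}
    idx1 = [col[s] for s in design.samples(g1)]
    idx2 = [col[s] for s in design.samples(g2)]
    n1, n2 = len(idx1), len(idx2)
    min_n = 1 if shrink else 2
    if n1 < min_n or n2 < min_n:
        raise DataError(
            f"each group needs >= {min_n} samples (shrink={shrink}); "
            f"got {g1}:{n1}, {g2}:{n2}"
        )
    if n1 + n2 < 3:
        raise DataError("too few samples for any residual degrees of freedom")
    X1 = matrix.values[:, idx1]
    X2 = matrix.values[:, idx2]
    m1 = X1.mean(axis=1)
    m2 = X2.mean(axis=1)
    sd1 = X1.std(axis=1, ddof=1) if n1 > 1 else np.zeros(matrix.n_genes)
    sd2 = X2.std(axis=1, ddof=1) if n2 > 1 else np.zeros(matrix.n_genes)
    df_resid = n1 + n2 - 2
    s2 = (((X1 - m1[:, None]) ** 2).sum(axis=1)
          + ((X2 - m2[:, None]) ** 2).sum(axis=1)) / df_resid
    log2fc = m1 - m2
    se_factor = math.sqrt(1.0 / n1 + 1.0 / n2)

    prior_df = prior_var = math.nan
    if shrink:
        prior_df, prior_var = fit_variance_prior(s2, df_resid)
        if math.isinf(prior_df):
            s2_mod = np.full_like(s2, prior_var)
            df_total = np.inf
        else:
            s2_mod = (prior_df * prior_var + df_resid * s2) / (prior_df + df_resid)
            df_total = prior_df + df_resid
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / (np.sqrt(s2_mod) * se_factor)
        t = np.where((s2_mod == 0), 0.0, t)   # fully degenerate matrix
        dfv = np.inf if math.isinf(df_total) else df_total
        p = 2.0 * (stats.norm.sf(np.abs(t)) if math.isinf(dfv)
                   else stats.t.sf(np.abs(t), df=dfv))
        p = np.where(np.isinf(t), 0.0, p)
        df_col = np.full(matrix.n_genes, dfv)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / (np.sqrt(s2) * se_factor)
        zero_var = s2 == 0
        t = np.where(zero_var & (log2fc == 0), 0.0, t)
        # zero spread but distinct means: not testable without shrinkage
        t = np.where(zero_var & (log2fc != 0), np.nan, t)
        if np.any(zero_var & (log2fc != 0)):
            logger.warning("%d zero-variance genes with unequal means flagged NA "
                           "(shrink off)", int((zero_var & (log2fc != 0)).sum()))
        p = 2.0 * stats.t.sf(np.abs(t), df=df_resid)
        p = np.where(zero_var & (log2fc == 0), 1.0, p)
        df_col = np.full(matrix.n_genes, float(df_resid))

    q = np.full(matrix.n_genes, np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        q[tested] = adjust_bh(p[tested])
    table = pd.DataFrame({
        "gene": matrix.gene_ids, "mean1": m1, "mean2": m2,
        "sd1": sd1, "sd2": sd2, "log2fc": log2fc,
        "t": t, "p": p, "q": q, "df": df_col,
    })
    logger.info("differential expression %s vs %s: %d genes, %d+%d samples, "
                "shrink=%s (d0=%.3g)", g1, g2, matrix.n_genes, n1, n2, shrink, prior_df)
    return DEResult(table, g1, g2, shrink, prior_df, prior_var)


def adjust_bh(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def adjust_bonferroni(pvalues: np.ndarray | list[float]) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def fold_change_lists(de: DEResult, fc_threshold: float) -> tuple[list[str], list[str]]:
    """Genes up/down past a (linear) fold-change threshold, no p/q filter.

    Boundaries are inclusive: |log2fc| == log2(threshold) qualifies.
    """
    if fc_threshold <= 1:
        raise DataError("fc_threshold must be > 1")
    cut = math.log2(fc_threshold)
    tab = de.table
    up = list(tab.loc[tab["log2fc"] >= cut, "gene"])
    down = list(tab.loc[tab["log2fc"] <= -cut, "gene"])
    return up, down


@dataclass
class TFScreenResult:
    table: pd.DataFrame   # gene, log2fc_a, q_a, dir_a, log2fc_b, q_b, dir_b, replicated

    def replicated_genes(self) -> list[str]:
        return list(self.table.loc[self.table["replicated"], "gene"])


def cross_cohort_tf_screen(de_a: DEResult, de_b: DEResult, tf_list: list[str],
                           q_threshold: float = 0.1,
                           require_same_direction: bool = True) -> TFScreenResult:
    """Which transcription factors replicate across two cohorts.

    A TF replicates when q < threshold in both cohorts and, if required, the
    fold-change signs agree. Directions are reported as luminal-up/basal-up
    using each DEResult's group1/group2 naming (group1 positive).
    """
    if not tf_list:
        raise DataError("tf_list is empty")
    ta = de_a.table.set_index("gene")
    tb = de_b.table.set_index("gene")
    shared = [g for g in tf_list if g in ta.index and g in tb.index]
    if not shared:
        raise DataError("no TF from the list is present in both cohorts")
    rows = []
    for g in shared:
        fa, qa = float(ta.loc[g, "log2fc"]), float(ta.loc[g, "q"])
        fb, qb = float(tb.loc[g, "log2fc"]), float(tb.loc[g, "q"])
        sig = (qa < q_threshold) and (qb < q_threshold)
        same = np.sign(fa) == np.sign(fb) and fa != 0
        replicated = sig and (same or not require_same_direction)
        rows.append({
            "gene": g,
            "log2fc_a": fa, "q_a": qa,
            "dir_a": f"{de_a.group1}-up" if fa >= 0 else f"{de_a.group2}-up",
            "log2fc_b": fb, "q_b": qb,
            "dir_b": f"{de_b.group1}-up" if fb >= 0 else f"{de_b.group2}-up",
            "replicated": replicated,
        })
    return TFScreenResult(pd.DataFrame(rows))
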