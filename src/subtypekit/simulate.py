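"""Synthetic cohorts and ChIP-seq peak/motif fixtures.

The expression generator plants two marker panels (luminal, basal) on a
shared per-gene baseline: luminal samples sit ``effect_size`` log2 units
above baseline on the luminal panel, basal samples on the basal panel, and
"non-type" samples stay at baseline on both. Per-gene i.i.d. Gaussian noise
is added on top, and an optional per-gene batch offset models dataset shifts.
Non-marker genes are non-differential by construction, which gives an exact
null set for FDR calibration. Motif planting in the peak simulator uses quota
sampling (an exact planted fraction, not Bernoulli draws) so enrichment tests
have deterministic ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import (
    DataError,
    ExpressionMatrix,
    GeneSignature,
    Interval,
    PeakSet,
    PWM,
    logger,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

BASELINE_MEAN = 6.0   # log2 units; typical bulk RNA dynamic range midpoint
BASELINE_SD = 1.0


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CohortConfig:
    """Generative parameters for a two-panel luminal/basal expression cohort."""

    n_genes: int = 500
    n_marker_per_class: int = 25
    n_luminal: int = 20
    n_basal: int = 20
    n_nontype: int = 10
    effect_size: float = 2.0   # log2 units separating marker means
    noise_sd: float = 0.5      # per-gene Gaussian sd, log2 units
    batch_shift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_marker_per_class,
               self.n_luminal, self.n_basal, self.n_nontype) < 0:
            raise DataError("cohort counts must be non-negative")
        if self.n_luminal + self.n_basal + self.n_nontype == 0:
            raise DataError("zero samples in every class")
        if self.noise_sd < 0 or self.effect_size < 0 or self.batch_shift_sd < 0:
            raise DataError("noise_sd, effect_size and batch_shift_sd must be >= 0")
        if 2 * self.n_marker_per_class > self.n_genes:
            raise DataError("marker panels do not fit in n_genes")


@dataclass
class SyntheticCohort:
    matrix: ExpressionMatrix            # log2 scale
    true_labels: dict[str, str]         # sample -> luminal | basal | non-type
    marker_truth: GeneSignature
    templates: dict[str, np.ndarray]    # class -> per-gene mean vector
    config: CohortConfig
    noise: np.ndarray = field(repr=False, default=None)  # genes x samples draw

    def copy(self) -> "SyntheticCohort":
        return SyntheticCohort(
            ExpressionMatrix(list(self.matrix.gene_ids), list(self.matrix.sample_ids),
                             self.matrix.values.copy(), self.matrix.scale_tag),
            dict(self.true_labels),
            GeneSignature(list(self.marker_truth.entries)),
            {k: v.copy() for k, v in self.templates.items()},
            replace(self.config),
            None if self.noise is None else self.noise.copy(),
        )


def simulate_expression_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a cohort from the two-panel generative model (seed-deterministic)."""
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    nm = config.n_marker_per_class
    gene_ids = [f"g{i + 1:04d}" for i in range(G)]
    lum_markers = gene_ids[:nm]
    bas_markers = gene_ids[nm:2 * nm]
    marker_truth = GeneSignature([(g, "luminal") for g in lum_markers]
                                 + [(g, "basal") for g in bas_markers])

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=G)
    templates = {
        "luminal": baseline.copy(),
        "basal": baseline.copy(),
        "non-type": baseline.copy(),
    }
    templates["luminal"][:nm] += config.effect_size
    templates["basal"][nm:2 * nm] += config.effect_size

    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    mean_cols: list[np.ndarray] = []
    for cls, prefix, n in (("luminal", "lum", config.n_luminal),
                           ("basal", "bas", config.n_basal),
                           ("non-type", "non", config.n_nontype)):
        for i in range(n):
            sid = f"{prefix}{i + 1:03d}"
            sample_ids.append(sid)
            labels[sid] = cls
            mean_cols.append(templates[cls])
    means = np.column_stack(mean_cols)
    noise = rng.normal(0.0, config.noise_sd, size=means.shape) if config.noise_sd > 0 \
        else np.zeros_like(means)
    matrix = ExpressionMatrix(gene_ids, sample_ids, means + noise, "log2")
    cohort = SyntheticCohort(matrix, labels, marker_truth, templates, config, noise)
    if config.batch_shift_sd > 0:
        cohort = apply_batch(cohort, config.batch_shift_sd, seed=config.seed + 1)
    logger.info("simulated cohort: %d genes, %d samples, effect=%g, noise_sd=%g, seed=%d",
                G, len(sample_ids), config.effect_size, config.noise_sd, config.seed)
    return cohort


def resample_noise(cohort: SyntheticCohort, seed: int) -> SyntheticCohort:
    """Redraw the per-cell noise with a new seed, keeping the templates.

    Together with :func:`apply_batch`, this builds independent datasets that
    share the same class templates — the setting for cross-dataset centroid
    concordance.
    """
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    means = out.matrix.values - out.noise
    out.noise = (rng.normal(0.0, out.config.noise_sd, size=means.shape)
                 if out.config.noise_sd > 0 else np.zeros_like(means))
    out.matrix.values = means + out.noise
    return out


def apply_batch(cohort: SyntheticCohort, batch_shift_sd: float, seed: int) -> SyntheticCohort:
    """Add one N(0, sd^2) offset per gene to every sample (a dataset shift)."""
    if batch_shift_sd < 0:
        raise DataError("batch_shift_sd must be >= 0")
    out = cohort.copy()
    if batch_shift_sd == 0:
        return out
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, batch_shift_sd, size=out.matrix.n_genes)
    out.matrix.values += offsets[:, None]
    for tmpl in out.templates.values():
        tmpl += offsets
    return out


def apply_perturbation(cohort: SyntheticCohort, samples: list[str],
                       shift_fraction: float, target_class: str) -> SyntheticCohort:
    """Move selected samples' expected marker values toward a target template.

    The perturbed expectation is the convex combination
    ``(1 - f) * own_template + f * target_template`` on marker genes; the
    sample's original noise draw is reused, so ``shift_fraction=0`` reproduces
    the input exactly and ``noise_sd=0`` yields the mixture exactly.
    """
    if not 0.0 <= shift_fraction <= 1.0:
        raise DataError("shift_fraction must be in [0, 1]")
    if target_class not in cohort.templates:
        raise DataError(f"no template for target class {target_class!r}")
    out = cohort.copy()
    marker_genes = set(out.marker_truth.genes())
    marker_rows = np.array([i for i, g in enumerate(out.matrix.gene_ids)
                            if g in marker_genes])
    target = out.templates[target_class]
    for sid in samples:
        if sid not in out.matrix.sample_ids:
            raise DataError(f"unknown sample id {sid!r}")
        j = out.matrix.sample_ids.index(sid)
        own = out.templates[out.true_labels[sid]]
        mixed = (1.0 - shift_fraction) * own + shift_fraction * target
        out.matrix.values[marker_rows, j] = (
            mixed[marker_rows] + out.noise[marker_rows, j]
        )
    return out


# ---------------------------------------------------------------------------
# Peak / motif fixture simulation
# ---------------------------------------------------------------------------

@dataclass
class PeakSimResult:
    rep1: PeakSet
    rep2: PeakSet
    background: PeakSet
    genome: dict[str, str]
    truth: pd.DataFrame   # name, category, start, end, planted, strand
    motif: PWM


def simulate_peak_experiment(n_shared: int, n_unique_each: int, genome_length: int,
                             motif: PWM, fg_rate: float, bg_rate: float, seed: int,
                             n_background: int | None = None, peak_width: int = 200,
                             jitter: int = 10, chrom: str = "chr1") -> PeakSimResult:
    """Build two replicate peak sets plus background windows on one chromosome.

    ``n_shared`` peaks appear in both replicates (replicate 2 jittered by at
    most ``jitter`` bp); each replicate also gets ``n_unique_each`` private
    peaks. The motif consensus is planted (forward or reverse strand) at the
    center of exactly ``round(fg_rate * n_shared)`` shared peaks and
    ``round(bg_rate * n_background)`` background windows — quota sampling, so
    the planted fractions are exact.
    """
    if not (0.0 <= fg_rate <= 1.0 and 0.0 <= bg_rate <= 1.0):
        raise DataError("fg_rate and bg_rate must be in [0, 1]")
    if n_background is None:
        n_background = 2 * n_shared
    total = n_shared + 2 * n_unique_each + n_background
    if total == 0:
        raise DataError("no peaks requested")
    slot = genome_length // total
    margin = jitter + 5
    if slot < peak_width + 2 * margin:
        raise DataError(
            f"cannot pack {total} peaks of width {peak_width} (+{margin} bp margins) "
            f"into {genome_length} bp"
        )
    rng = np.random.default_rng(seed)
    genome = np.array(list("ACGT"))[rng.integers(0, 4, size=genome_length)]

    order = rng.permutation(total)
    cat_of_slot = np.empty(total, dtype=object)
    cat_of_slot[order[:n_shared]] = "shared"
    cat_of_slot[order[n_shared:n_shared + n_unique_each]] = "unique1"
    cat_of_slot[order[n_shared + n_unique_each:n_shared + 2 * n_unique_each]] = "unique2"
    cat_of_slot[order[n_shared + 2 * n_unique_each:]] = "background"

    consensus = motif.consensus()
    shared_idx = [i for i in range(total) if cat_of_slot[i] == "shared"]
    bg_idx = [i for i in range(total) if cat_of_slot[i] == "background"]
    n_fg_plant = int(round(fg_rate * n_shared))
    n_bg_plant = int(round(bg_rate * n_background))
    fg_planted = set(rng.choice(shared_idx, size=n_fg_plant, replace=False)) \
        if n_fg_plant else set()
    bg_planted = set(rng.choice(bg_idx, size=n_bg_plant, replace=False)) \
        if n_bg_plant else set()

    rep1, rep2, background, rows = [], [], [], []
    counters = {"shared": 0, "unique1": 0, "unique2": 0, "background": 0}
    for i in range(total):
        cat = cat_of_slot[i]
        counters[cat] += 1
        name = f"{cat}_{counters[cat]:05d}"
        lo = i * slot + margin
        hi = (i + 1) * slot - margin - peak_width
        start = int(rng.integers(lo, max(lo + 1, hi)))
        end = start + peak_width
        planted = i in fg_planted or i in bg_planted
        strand = "."
        if planted:
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            inst = consensus if strand == "+" else reverse_complement(consensus)
            center = (start + end) // 2
            pos = center - len(inst) // 2
            genome[pos:pos + len(inst)] = list(inst)
        iv = Interval(chrom, start, end, name)
        if cat == "shared":
            rep1.append(iv)
            shift = int(rng.integers(-jitter, jitter + 1))
            rep2.append(Interval(chrom, start + shift, end + shift, name))
        elif cat == "unique1":
            rep1.append(iv)
        elif cat == "unique2":
            rep2.append(iv)
        else:
            background.append(iv)
        rows.append({"name": name, "category": cat, "start": start, "end": end,
                     "planted": planted, "strand": strand})

    truth = pd.DataFrame(rows)
    logger.info("simulated peaks: %d shared, %d unique/rep, %d background; "
                "planted %d fg / %d bg instances of %s (seed=%d)",
                n_shared, n_unique_each, n_background, n_fg_plant, n_bg_plant,
                motif.motif_id, seed)
    return PeakSimResult(PeakSet(rep1), PeakSet(rep2), PeakSet(background),
                         {chrom: "".join(genome)}, truth, motif)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide counts (Euler-path walk).

    Altschul–Erikson style: build the multigraph of dinucleotide transitions,
    pick a random last-exit edge ordering that keeps the walk connected to the
    terminal vertex, and randomize the remaining edge order.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    vertices = list(edges)
    last = seq[-1]
    # choose last-exit edges forming a tree toward `last` (sampled until valid)
    for _ in range(1000):
        last_exit = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices
                     if v != last}
        # check connectivity: following last-exit edges from v must reach `last`
        ok = True
        for v in last_exit:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_exit.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - sampling essentially always succeeds
        return seq
    shuffled_edges: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v != last:
            rest.remove(last_exit[v])
        perm = rng.permutation(len(rest))
        ordered = [rest[i] for i in perm]
        if v != last:
            ordered.append(last_exit[v])
        shuffled_edges[v] = ordered
    out = [seq[0]]
    ptr = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)
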