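"""Replicate peak concordance, window extraction, PWM scanning, enrichment.

Consensus ("shared") peaks: intervals from both replicates are pooled and
grouped into maximal runs of mutually overlapping intervals; a run yields one
consensus region (the union span) when it contains at least one replicate-1
and one replicate-2 interval that themselves overlap by the minimum number of
base pairs (default 1). Motif association then counts, per motif, the number
of foreground vs background windows carrying at least one log-odds hit and
tests the 2x2 table with a one-sided Fisher exact test, BH-corrected across
motifs — per-sequence binary counting, matching the "% of sites associated
with a motif" reporting convention.

Scoring: the log-odds of a window at offset o is
``sum_j log2(p[base_{o+j}, j] / background[base_{o+j}])`` with a pseudocount
added to the PFM; an ambiguous base contributes the log2 of the
background-weighted average odds over its compatible bases (exactly 0 for N).
Scanning is vectorized: sequences are integer-encoded once and all offsets of
all sequences of a common length are scored per motif in a handful of numpy
gathers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import DataError, Interval, PeakSet, PWM, _IUPAC_NT, logger
from .simulate import dinucleotide_shuffle


@dataclass
class ScanParams:
    window_halfwidth: int = 100
    score_threshold_rule: str = "fraction_of_max"   # | "logodds_absolute"
    threshold_value: float = 0.8
    scan_both_strands: bool = True
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.window_halfwidth < 1:
            raise DataError("window_halfwidth must be >= 1")
        if self.score_threshold_rule not in ("fraction_of_max", "logodds_absolute"):
            raise DataError(f"unknown threshold rule {self.score_threshold_rule!r}")
        if self.score_threshold_rule == "fraction_of_max" and not (
                0.0 < self.threshold_value <= 1.0):
            raise DataError("fraction_of_max threshold must be in (0, 1]")

    def threshold_for(self, pwm: PWM) -> float:
        if self.score_threshold_rule == "fraction_of_max":
            return self.threshold_value * pwm.max_score(self.pseudocount)
        return self.threshold_value


@dataclass
class ScanHit:
    hit: bool
    best_score: float
    best_pos: int       # offset of the best window on the forward strand, -1 if none
    strand: str         # "+", "-", or "."


# ---------------------------------------------------------------------------
# Replicate concordance
# ---------------------------------------------------------------------------

def intersect_replicates(rep1: PeakSet, rep2: PeakSet,
                         min_overlap_bp: int = 1) -> PeakSet:
    """Consensus regions supported by both replicates (see module docstring)."""
    for c in sorted(rep1.chroms() ^ rep2.chroms()):
        logger.warning("chromosome %s present in only one replicate", c)
    tagged = [(iv, 1) for iv in rep1] + [(iv, 2) for iv in rep2]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1]))
    consensus: list[Interval] = []
    run: list[tuple[Interval, int]] = []
    run_end = -1
    run_chrom: str | None = None

    def flush() -> None:
        if not run or {tag for _, tag in run} != {1, 2}:
            return
        paired = any(a.overlap(b) >= min_overlap_bp
                     for a, ta in run if ta == 1
                     for b, tb in run if tb == 2)
        if paired:
            consensus.append(Interval(
                run_chrom,
                min(iv.start for iv, _ in run),
                max(iv.end for iv, _ in run),
                f"consensus_{len(consensus) + 1:06d}"))

    for iv, tag in tagged:
        if run and iv.chrom == run_chrom and iv.start < run_end:
            run.append((iv, tag))
            run_end = max(run_end, iv.end)
        else:
            flush()
            run = [(iv, tag)]
            run_chrom = iv.chrom
            run_end = iv.end
    flush()
    logger.info("consensus peaks: %d shared regions from %d + %d intervals",
                len(consensus), len(rep1), len(rep2))
    return PeakSet(consensus)


def extract_windows(peaks: PeakSet, genome: dict[str, str],
                    halfwidth: int) -> list[str]:
    """Fixed windows around peak centers: [center - h, center + h), clipped."""
    missing = sorted(peaks.chroms() - set(genome))
    if missing:
        raise DataError(f"chromosomes missing from the genome FASTA: {missing}")
    out = []
    clipped = 0
    for iv in peaks:
        center = (iv.start + iv.end) // 2
        lo, hi = center - halfwidth, center + halfwidth
        chrom_len = len(genome[iv.chrom])
        if lo < 0 or hi > chrom_len:
            clipped += 1
        out.append(genome[iv.chrom][max(0, lo):min(chrom_len, hi)].upper())
    if clipped:
        logger.info("%d windows clipped at chromosome ends", clipped)
    return out


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

_CODE_LUT = np.full(256, -2, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE_LUT[ord(_b)] = _i
_CODE_LUT[ord("U")] = 3
for _amb in "RYSWKMBDHVN":
    _CODE_LUT[ord(_amb)] = -1

_IUPAC_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "R": "Y", "Y": "R",
             "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
             "D": "H", "H": "D", "N": "N"}


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; other IUPAC codes -> -1; anything else is fatal."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code = _CODE_LUT[arr]
    if np.any(code == -2):
        bad = seq[int(np.argmax(code == -2))]
        raise DataError(f"invalid nucleotide {bad!r} in sequence")
    return code


def _revcomp_iupac(seq: str) -> str:
    try:
        return "".join(_IUPAC_RC[c] for c in reversed(seq))
    except KeyError as exc:
        raise DataError(f"invalid nucleotide {exc.args[0]!r} in sequence") from None


def _weight_track(seq: str, code: np.ndarray, lom: np.ndarray,
                  background: np.ndarray) -> np.ndarray:
    """len(seq) x L matrix of per-position per-column score contributions."""
    L = lom.shape[1]
    W = np.empty((len(seq), L))
    known = code >= 0
    W[known, :] = lom[code[known], :]
    if not np.all(known):
        odds = 2.0 ** lom
        for i in np.where(~known)[0]:
            bases = np.array(["ACGT".index(b) for b in _IUPAC_NT[seq[i]]])
            w = background[bases]
            W[i, :] = np.log2((w[:, None] * odds[bases, :]).sum(axis=0) / w.sum())
    return W


def _best_offset(W: np.ndarray) -> tuple[float, int]:
    n, L = W.shape
    M = n - L + 1
    if M <= 0:
        return -math.inf, -1
    scores = np.zeros(M)
    for j in range(L):
        scores += W[j:j + M, j]
    best = int(np.argmax(scores))
    return float(scores[best]), best


def _batch_best_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Best window score per row for pure-ACGT code rows of equal length."""
    n, m = codes.shape
    L = lom.shape[1]
    M = m - L + 1
    if M <= 0:
        return np.full(n, -math.inf)
    scores = np.zeros((n, M))
    for j in range(L):
        scores += lom[codes[:, j:j + M], j]
    return scores.max(axis=1)


def scan_pwm(sequence: str, pwm: PWM, params: ScanParams | None = None) -> ScanHit:
    """Best log-odds window of a PWM in one sequence; hit if above threshold.

    A sequence shorter than the motif is a no-hit, not an error. With
    both-strand scanning the reported offset is mirrored onto the forward
    strand.
    """
    params = params or ScanParams()
    sequence = sequence.upper()
    lom = pwm.log_odds(params.pseudocount)
    L = pwm.length
    if len(sequence) < L:
        return ScanHit(False, -math.inf, -1, ".")
    code = _encode(sequence)
    best_score, best_pos, strand = -math.inf, -1, "."
    s, pos = _best_offset(_weight_track(sequence, code, lom, pwm.background))
    if s > best_score:
        best_score, best_pos, strand = s, pos, "+"
    if params.scan_both_strands:
        rc = _revcomp_iupac(sequence)
        s, pos = _best_offset(_weight_track(rc, _encode(rc), lom, pwm.background))
        if s > best_score:
            best_score, best_pos, strand = s, len(sequence) - pos - L, "-"
    return ScanHit(best_score >= params.threshold_for(pwm), best_score,
                   best_pos, strand)


def _hit_vector(seqs: list[str], pwm: PWM, params: ScanParams) -> np.ndarray:
    """Binary has-a-hit flag per sequence, batching same-length ACGT sequences."""
    lom = pwm.log_odds(params.pseudocount)
    threshold = params.threshold_for(pwm)
    best = np.full(len(seqs), -math.inf)
    groups: dict[int, list[int]] = {}
    scalar: list[int] = []
    codes = []
    for i, s in enumerate(seqs):
        c = _encode(s.upper())
        codes.append(c)
        if np.any(c < 0):
            scalar.append(i)
        else:
            groups.setdefault(len(s), []).append(i)
    for length, idx in groups.items():
        if length < pwm.length:
            continue
        block = np.stack([codes[i] for i in idx])
        sc = _batch_best_scores(block, lom)
        if params.scan_both_strands:
            rc_block = (3 - block)[:, ::-1]
            sc = np.maximum(sc, _batch_best_scores(rc_block, lom))
        best[idx] = sc
    for i in scalar:
        best[i] = scan_pwm(seqs[i], pwm, params).best_score
    return best >= threshold


def motif_enrichment(foreground: list[str], background: list[str],
                     pwms: list[PWM], params: ScanParams | None = None,
                     q_cutoff: float = 0.05) -> pd.DataFrame:
    """Per-motif foreground-vs-background association table.

    Columns: motif_id, fg_hits, fg_total, bg_hits, bg_total, fg_pct, bg_pct,
    p (one-sided Fisher exact, alternative = foreground greater), q (BH
    across motifs), significant (q < q_cutoff). A motif longer than every
    sequence gets an NA row.
    """
    if not foreground or not background:
        raise DataError("foreground and background sequence lists must be non-empty")
    params = params or ScanParams()
    rows = []
    for pwm in pwms:
        if all(len(s) < pwm.length for s in foreground) and \
                all(len(s) < pwm.length for s in background):
            rows.append({"motif_id": pwm.motif_id, "fg_hits": 0, "fg_total": 0,
                         "bg_hits": 0, "bg_total": 0, "fg_pct": math.nan,
                         "bg_pct": math.nan, "p": math.nan})
            logger.warning("motif %s is longer than every sequence; row flagged NA",
                           pwm.motif_id)
            continue
        fg_hits = int(_hit_vector(foreground, pwm, params).sum())
        bg_hits = int(_hit_vector(background, pwm, params).sum())
        fg_total, bg_total = len(foreground), len(background)
        _, p = stats.fisher_exact(
            [[fg_hits, fg_total - fg_hits], [bg_hits, bg_total - bg_hits]],
            alternative="greater")
        rows.append({"motif_id": pwm.motif_id,
                     "fg_hits": fg_hits, "fg_total": fg_total,
                     "bg_hits": bg_hits, "bg_total": bg_total,
                     "fg_pct": 100.0 * fg_hits / fg_total,
                     "bg_pct": 100.0 * bg_hits / bg_total,
                     "p": float(p)})
    df = pd.DataFrame(rows)
    from .difftf import adjust_bh
    tested = df["p"].notna()
    df["q"] = np.nan
    if tested.any():
        df.loc[tested, "q"] = adjust_bh(df.loc[tested, "p"].to_numpy())
    df["significant"] = df["q"] < q_cutoff
    return df


def shuffle_background(foreground: list[str], seed: int) -> list[str]:
    """Dinucleotide-preserving shuffles of the foreground windows (seeded)."""
    rng = np.random.default_rng(seed)
    return [dinucleotide_shuffle(s, rng) for s in foreground]
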