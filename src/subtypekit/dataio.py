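"""Readers, writers and core containers for the formats the pipeline touches.

All genomic intervals are BED-style 0-based half-open throughout the package;
any 1-based coordinate shown to a user is labeled as such. Expression tables
are TSV (tab-separated; decimal point) to sidestep gene symbols containing
commas. Floats are written with ``repr`` (shortest round-trip form), so a
write/read cycle reproduces values bit-exactly.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO, motifs as bio_motifs

logger = logging.getLogger("subtypekit")

SUBTYPE_CLASSES = ("luminal", "basal")
NONTYPE_LABEL = "non-type"

_IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class DataError(ValueError):
    """Fatal problem with an input file or container invariant."""


def configure_logging(run_log: str | Path | None = None, level: int = logging.INFO) -> None:
    """Log to stderr and, optionally, mirror everything to a run-log file."""
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    stream = logging.StreamHandler(sys.stderr)
    stream.setFormatter(fmt)
    logger.addHandler(stream)
    if run_log is not None:
        fh = logging.FileHandler(run_log)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


def load_config(path: str | Path) -> dict:
    """Load a YAML config file into a plain dict (empty file -> empty dict)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_run_metadata(path: str | Path, **fields) -> None:
    """Record parameters/seed of a pipeline stage as JSON."""
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression values, either raw counts or log2 scale."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_tag: str = "log2"  # "counts" | "log2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale_tag not in ("counts", "log2"):
            raise DataError(f"unknown scale_tag {self.scale_tag!r}")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.scale_tag == "counts" and np.any(self.values < 0):
            raise DataError("negative value in a counts matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale_tag: str = "log2") -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), scale_tag)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise DataError(f"genes absent from matrix: {missing[:10]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids),
                                self.values[rows, :], self.scale_tag)

    def sample_profile(self, sample_id: str) -> pd.Series:
        j = self.sample_ids.index(sample_id)
        return pd.Series(self.values[:, j], index=self.gene_ids, name=sample_id)


@dataclass
class GeneSignature:
    """Marker genes with a luminal/basal class label each."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene, label in self.entries:
            if label not in SUBTYPE_CLASSES:
                raise DataError(f"unknown signature class {label!r} for gene {gene}")
            if gene in seen:
                raise DataError(f"duplicate gene in signature: {gene}")
            seen.add(gene)

    def genes(self, label: str | None = None) -> list[str]:
        return [g for g, lab in self.entries if label is None or lab == label]

    def require_both_classes(self) -> None:
        for label in SUBTYPE_CLASSES:
            if not self.genes(label):
                raise DataError(f"signature has no {label} genes")


@dataclass
class GroupDesign:
    """Sample -> group label mapping (two groups for differential expression)."""

    groups: dict[str, str]

    def labels(self) -> list[str]:
        return sorted(set(self.groups.values()))

    def samples(self, label: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == label]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in self.groups if s not in matrix.sample_ids]
        if missing:
            raise DataError(f"design samples absent from matrix: {missing[:10]}")


@dataclass(frozen=True, order=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise DataError(f"negative coordinate in interval {self}")
        if self.start >= self.end:
            raise DataError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def overlap(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class PeakSet:
    """A set of 0-based half-open genomic intervals."""

    intervals: list[Interval]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def sorted(self) -> "PeakSet":
        return PeakSet(sorted(self.intervals))

    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}


@dataclass
class PWM:
    """Position frequency matrix over A,C,G,T with a background distribution."""

    motif_id: str
    counts: np.ndarray  # 4 x L, rows in A,C,G,T order
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise DataError(f"PWM {self.motif_id}: counts must be 4 x L with L >= 1")
        if np.any(self.counts < 0):
            raise DataError(f"PWM {self.motif_id}: negative count")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise DataError(f"PWM {self.motif_id}: background does not sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def log_odds(self, pseudocount: float = 0.5) -> np.ndarray:
        """4 x L log2-odds matrix after adding a pseudocount to every cell."""
        c = self.counts + pseudocount
        p = c / c.sum(axis=0, keepdims=True)
        return np.log2(p / self.background[:, None])

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.counts, axis=0))

    def max_score(self, pseudocount: float = 0.5) -> float:
        return float(self.log_odds(pseudocount).max(axis=0).sum())


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise DataError(f"duplicate {kind} identifier: {x}")
        seen.add(x)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, scale_tag: str = "log2") -> ExpressionMatrix:
    """Read a genes-x-samples TSV (header row = sample ids, first column = gene id)."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise DataError(f"{path}: no genes (header-only file)")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(gene_ids, "gene")
    _check_unique(sample_ids, "sample")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise DataError(
                    f"{path}: non-numeric value {raw[i, j]!r} at gene "
                    f"{gene_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
    if scale_tag == "counts" and np.any(values < 0):
        i, j = map(int, np.argwhere(values < 0)[0])
        raise DataError(
            f"{path}: negative count at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    em = ExpressionMatrix(gene_ids, sample_ids, values, scale_tag)
    logger.info("read expression matrix %s: %d genes x %d samples (%s)",
                path, em.n_genes, em.n_samples, scale_tag)
    return em


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, g in enumerate(matrix.gene_ids):
            row = "\t".join(repr(float(v)) for v in matrix.values[i, :])
            fh.write(f"{g}\t{row}\n")


def read_gene_signature(path: str | Path) -> GeneSignature:
    """Read a two-column TSV of (gene_id, class_label); labels lower-cased."""
    entries: list[tuple[str, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"{path}:{ln}: expected two tab-separated columns")
            entries.append((parts[0], parts[1].strip().lower()))
    return GeneSignature(entries)


def write_gene_signature(sig: GeneSignature, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, label in sig.entries:
            fh.write(f"{gene}\t{label}\n")


def read_group_design(path: str | Path) -> GroupDesign:
    """Read a two-column TSV of (sample_id, group_label)."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"{path}:{ln}: expected two tab-separated columns")
            if parts[0] in groups:
                raise DataError(f"{path}:{ln}: duplicate sample {parts[0]!r}")
            groups[parts[0]] = parts[1]
    return GroupDesign(groups)


def read_intervals_bed(path: str | Path) -> PeakSet:
    """Read BED3+ (0-based half-open); columns past name/score are ignored."""
    intervals: list[Interval] = []
    extra_cols_seen = False
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{ln}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise DataError(f"{path}:{ln}: non-integer coordinate") from None
            if start >= end:
                raise DataError(f"{path}:{ln}: empty/inverted interval ({start} >= {end})")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] != ".":
                try:
                    score = float(parts[4])
                except ValueError:
                    raise DataError(f"{path}:{ln}: non-numeric score {parts[4]!r}") from None
            if len(parts) > 5:
                extra_cols_seen = True
            intervals.append(Interval(parts[0], start, end, name, score))
    if extra_cols_seen:
        logger.info("%s: columns beyond name/score ignored", path)
    logger.info("read %d intervals from %s", len(intervals), path)
    return PeakSet(intervals)


def write_intervals_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(repr(float(iv.score)))
            fh.write("\t".join(cols) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {record id: uppercase sequence}."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise DataError(f"{path}: duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise DataError(f"{path}: empty sequence for record {rec.id!r}")
        bad = set(seq) - set(_IUPAC_NT)
        if bad:
            raise DataError(f"{path}: record {rec.id!r} has non-IUPAC letters {sorted(bad)}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_motifs_jaspar(path: str | Path,
                       background: Sequence[float] | None = None) -> list[PWM]:
    """Read JASPAR-style PFM blocks (">id" then four A/C/G/T count rows).

    The background defaults to uniform 0.25 per base unless overridden.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:  # unequal row lengths etc. surface here
            raise DataError(f"{path}: cannot parse JASPAR PFM blocks: {exc}") from None
    pwms: list[PWM] = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        motif_id = m.matrix_id or m.name or f"motif{len(pwms) + 1}"
        if np.any(counts < 0):
            raise DataError(f"{path}: motif {motif_id}: negative count")
        pwms.append(PWM(motif_id, counts, bg))
    if not pwms:
        raise DataError(f"{path}: no motifs found")
    logger.info("read %d PWMs from %s", len(pwms), path)
    return pwms


def write_motifs_jaspar(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for bi, base in enumerate("ACGT"):
                row = " ".join(repr(float(v)) for v in pwm.counts[bi])
                fh.write(f"{base} [ {row} ]\n")
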