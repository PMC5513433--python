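"""Input/output for every external representation the model touches.

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open, locus-local (BED-like).
Genomic inputs (BED accessibility intervals) are translated onto the locus
at read time.  Axis positions are percent embryo length measured from the
anterior pole.

Formats
-------
* sequence: FASTA (first record used);
* TF concentration / target mRNA profiles: TSV with a ``position`` column
  followed by one numeric column per TF or target;
* accessibility: BED3+ in genomic coordinates;
* PWMs: a labelled-matrix text format (see :func:`read_pwm_set`), accepting
  either raw count matrices or pre-computed log-odds (natural log).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

logger = logging.getLogger("thermolocus")

VALID_BASES = set("ACGTN")
BASE_ORDER = "ACGT"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusSequence:
    """A named DNA sequence over {A,C,G,T,N}, uppercase.

    ``genome_offset`` is the 1-based genomic start of the locus, kept for
    provenance only; nothing downstream depends on it.
    """

    name: str
    bases: str
    genome_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise FormatError("empty sequence")
        bad = set(self.bases) - VALID_BASES
        if bad:
            raise FormatError(f"non-nucleotide characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.bases)

    def subsequence(self, start: int, end: int, name: str | None = None) -> "LocusSequence":
        if not (0 <= start < end <= self.length):
            raise ValueError(f"fragment [{start},{end}) outside locus of length {self.length}")
        return LocusSequence(name or f"{self.name}:{start}-{end}", self.bases[start:end])


@dataclass(frozen=True)
class PWMRecord:
    """Log-odds position weight matrix for one TF.

    ``matrix`` has shape (L, 4) ordered A,C,G,T, natural-log odds against
    ``background``.  ``s_max`` is the best attainable score (sum of
    per-position column maxima).
    """

    tf_name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise FormatError(f"PWM {self.tf_name}: matrix must be L x 4")
        if not np.all(np.isfinite(m)):
            raise FormatError(f"PWM {self.tf_name}: non-finite entries")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise FormatError(f"PWM {self.tf_name}: background must be 4 probabilities summing to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def s_max(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @classmethod
    def from_counts(cls, tf_name: str, counts: np.ndarray,
                    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                    pseudocount: float = 1.0) -> "PWMRecord":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise FormatError(f"PWM {tf_name}: count matrix must be L x 4")
        if np.any(counts < 0):
            raise FormatError(f"PWM {tf_name}: negative counts")
        bg = np.asarray(background, dtype=float)
        probs = (counts + pseudocount)
        probs = probs / probs.sum(axis=1, keepdims=True)
        return cls(tf_name, np.log(probs / bg), bg)


@dataclass(frozen=True)
class ProfileTable:
    """Per-axis-position concentration (or target mRNA) profiles.

    Positions are percent embryo length, strictly increasing and evenly
    spaced; each column holds non-negative fluorescence-scale values.
    """

    positions: np.ndarray
    columns: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 1 or pos.size == 0:
            raise FormatError("positions must be a non-empty 1-D array")
        if pos.size > 1:
            d = np.diff(pos)
            if np.any(d <= 0):
                raise FormatError("positions must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
                raise FormatError("positions must be evenly spaced")
        cols = {}
        for name, vals in self.columns.items():
            v = np.asarray(vals, dtype=float)
            if v.shape != pos.shape:
                raise FormatError(f"column {name!r} length {v.size} != {pos.size} positions")
            if np.any(~np.isfinite(v)):
                raise FormatError(f"column {name!r} has missing/non-finite values")
            if np.any(v < 0):
                raise FormatError(f"column {name!r} has negative values")
            cols[name] = v
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "columns", cols)

    @property
    def n_positions(self) -> int:
        return self.positions.size

    def __getitem__(self, name: str) -> np.ndarray:
        return self.columns[name]

    def __contains__(self, name: str) -> bool:
        return name in self.columns

    def names(self) -> list[str]:
        return list(self.columns)

    def replace(self, name: str, values: np.ndarray) -> "ProfileTable":
        if name not in self.columns:
            raise KeyError(f"unknown column {name!r}")
        cols = dict(self.columns)
        cols[name] = np.asarray(values, dtype=float)
        return ProfileTable(self.positions, cols)


@dataclass(frozen=True)
class AccessibilityMask:
    """Sorted, disjoint half-open locus-local intervals flagged accessible."""

    intervals: tuple[tuple[int, int], ...]
    locus_length: int

    def __post_init__(self) -> None:
        merged = merge_intervals(self.intervals)
        for s, e in merged:
            if not (0 <= s < e <= self.locus_length):
                raise FormatError(f"interval ({s},{e}) outside [0,{self.locus_length}]")
        object.__setattr__(self, "intervals", merged)

    def contains(self, start: int, end: int) -> bool:
        """True iff [start, end) lies entirely within one accessible interval."""
        for s, e in self.intervals:
            if s <= start and end <= e:
                return True
        return False

    def overlaps(self, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.intervals)


def merge_intervals(intervals) -> tuple[tuple[int, int], ...]:
    """Union of half-open intervals via an interval tree; sorted, disjoint."""
    tree = IntervalTree()
    for s, e in intervals:
        if e > s:
            tree[s:e] = None
    tree.merge_overlaps(strict=False)  # also joins bookended intervals
    return tuple(sorted((iv.begin, iv.end) for iv in tree))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path) -> LocusSequence:
    """Read the first record of a FASTA file as an uppercase locus sequence."""
    records = SeqIO.parse(str(path), "fasta")
    try:
        rec = next(records)
    except StopIteration:
        raise FormatError(f"{path}: no FASTA records") from None
    return LocusSequence(rec.id or Path(str(path)).stem, str(rec.seq).upper())


def write_fasta(seq: LocusSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq.name}\n")
        for i in range(0, seq.length, width):
            fh.write(seq.bases[i:i + width] + "\n")


def read_pwm_set(path, pseudocount: float = 1.0) -> list[PWMRecord]:
    """Read one or more PWMs from a labelled-matrix text file.

    Format: blocks introduced by ``>NAME [counts|logodds]`` followed by four
    whitespace-separated lines ``A: ...``, ``C: ...``, ``G: ...``, ``T: ...``
    (JASPAR-style row-per-base).  ``counts`` blocks are converted to
    natural-log odds against a uniform background with ``pseudocount``.
    """
    pwms: list[PWMRecord] = []
    name = None
    dialect = "counts"
    rows: dict[str, list[float]] = {}

    def flush():
        if name is None:
            return
        missing = [b for b in BASE_ORDER if b not in rows]
        if missing:
            raise FormatError(f"PWM {name}: missing rows for {missing}")
        lengths = {len(rows[b]) for b in BASE_ORDER}
        if len(lengths) != 1:
            raise FormatError(f"PWM {name}: ragged rows")
        mat = np.array([rows[b] for b in BASE_ORDER], dtype=float).T
        if dialect == "counts":
            pwms.append(PWMRecord.from_counts(name, mat, pseudocount=pseudocount))
        elif dialect == "logodds":
            pwms.append(PWMRecord(name, mat))
        else:
            raise FormatError(f"PWM {name}: unknown dialect {dialect!r}")

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                if not parts:
                    raise FormatError(f"{path}:{lineno}: header without a name")
                name = parts[0]
                dialect = parts[1].lower() if len(parts) > 1 else "counts"
                rows = {}
            else:
                base, _, rest = line.partition(":")
                base = base.strip().upper()
                if base not in BASE_ORDER or not rest:
                    raise FormatError(f"{path}:{lineno}: expected '<base>: values'")
                try:
                    rows[base] = [float(v) for v in rest.split()]
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
    flush()
    if not pwms:
        raise FormatError(f"{path}: no PWM blocks found")
    return pwms


def write_pwm_set(pwms: Sequence[PWMRecord], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf_name} logodds\n")
            for j, base in enumerate(BASE_ORDER):
                vals = " ".join(f"{v:.10g}" for v in pwm.matrix[:, j])
                fh.write(f"{base}: {vals}\n")


def read_profiles(path, resort: bool = False) -> ProfileTable:
    """Read a profile TSV: a ``position`` column then one column per name.

    Rows out of order are rejected unless ``resort`` is set, in which case
    they are sorted by position first.
    """
    df = pd.read_csv(path, sep="\t")
    if "position" not in df.columns:
        raise FormatError(f"{path}: missing 'position' column")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values")
    if resort:
        df = df.sort_values("position", kind="stable").reset_index(drop=True)
    pos = df["position"].to_numpy(dtype=float)
    cols = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "position"}
    return ProfileTable(pos, cols)


def write_profiles(table: ProfileTable, path) -> None:
    df = pd.DataFrame({"position": table.positions, **table.columns})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_accessibility(paths: Sequence, locus_start: int, locus_length: int) -> AccessibilityMask:
    """Union the intervals of several BED files and map onto the locus.

    ``locus_start`` is the 0-based genomic start of the locus; BED intervals
    are intersected with [locus_start, locus_start + locus_length), translated
    to locus-local coordinates and merged.  Intervals wholly outside the locus
    are dropped (logged).  An empty path list yields an empty mask, meaning
    every site is masked out when masking is enabled.
    """
    locus_end = locus_start + locus_length
    local: list[tuple[int, int]] = []
    for path in paths:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 3:
                    raise FormatError(f"{path}:{lineno}: malformed BED line")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
                if end <= start:
                    raise FormatError(f"{path}:{lineno}: end <= start")
                s = max(start, locus_start)
                e = min(end, locus_end)
                if e <= s:
                    logger.info("%s:%d: interval (%d,%d) outside locus, dropped",
                                path, lineno, start, end)
                    continue
                local.append((s - locus_start, e - locus_start))
    return AccessibilityMask(tuple(local), locus_length)


def write_bed(intervals, path, chrom: str = "locus") -> None:
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")
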