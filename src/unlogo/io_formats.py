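"""Motif file formats and the PWM comparison metric.

Writers cover the three reconstruction output formats — CSV (rows A,C,G,T,
columns = positions), a TRANSFAC-like tab-delimited "PO A C G T" dialect
used for logo re-rendering tools, and the MEME suite's minimal motif
interchange format (letter-probability matrix, uniform background).
Readers for MEME and JASPAR PFM files are thin wrappers over Biopython's
``Bio.motifs`` parsers; all readers renormalize columns so that count
matrices and 6-decimal rounded probabilities come back as valid PWMs.

The evaluation metric is Pearson correlation over the 4 x L matrix entries
flattened in fixed row-major (A,C,G,T) order; a per-column averaged variant
is available via ``per_column=True``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import motifs as bio_motifs

from .errors import ParseError, UndefinedCorrelationError, ValidationError
from .pwm_core import ALPHABET, PWM


@dataclass(frozen=True)
class MotifRecord:
    """A named PWM with its source dialect."""

    id: str
    pwm: PWM
    source_dialect: str  # csv | enologos | meme | jaspar_pfm


def _normalize_counts(matrix: np.ndarray, what: str) -> PWM:
    sums = matrix.sum(axis=0)
    if np.any(sums <= 0):
        raise ValidationError(f"{what}: zero-sum column cannot be normalized")
    return PWM(probs=matrix / sums)


# ---------------------------------------------------------------------------
# CSV

def write_csv(pwm: PWM, path: str | Path) -> None:
    """Header of 1-based position indices, then one row per nucleotide."""
    lines = ["," + ",".join(str(j + 1) for j in range(pwm.length))]
    for i, base in enumerate(ALPHABET):
        lines.append(base + "," + ",".join(f"{v:.6f}" for v in pwm.probs[i]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_csv(path: str | Path) -> MotifRecord:
    lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]
    if len(lines) != 5:
        raise ParseError(f"expected header plus 4 nucleotide rows, got {len(lines)} lines")
    rows = []
    for base, line in zip(ALPHABET, lines[1:]):
        cells = line.split(",")
        if cells[0].strip().upper() != base:
            raise ParseError(f"expected row label {base}, got {cells[0]!r}")
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise ParseError(f"non-numeric cell in row {base}") from exc
    matrix = np.array(rows, dtype=float)
    return MotifRecord(id=Path(path).stem, pwm=_normalize_counts(matrix, "csv"),
                       source_dialect="csv")


# ---------------------------------------------------------------------------
# enologos-style dialect (TRANSFAC-like probability table)

def write_enologos(pwm: PWM, path: str | Path) -> None:
    """Tab-delimited: ``PO A C G T`` header, one row per position."""
    lines = ["PO\tA\tC\tG\tT"]
    for j in range(pwm.length):
        vals = "\t".join(f"{pwm.probs[i, j]:.6f}" for i in range(4))
        lines.append(f"{j + 1}\t{vals}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_enologos(path: str | Path) -> MotifRecord:
    lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines or lines[0].split() != ["PO", "A", "C", "G", "T"]:
        raise ParseError("missing 'PO A C G T' header")
    cols = []
    for k, line in enumerate(lines[1:], start=1):
        cells = line.split()
        if len(cells) != 5:
            raise ParseError(f"row {k}: expected index plus 4 values")
        try:
            cols.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise ParseError(f"row {k}: non-numeric value") from exc
    matrix = np.array(cols, dtype=float).T
    return MotifRecord(id=Path(path).stem, pwm=_normalize_counts(matrix, "enologos"),
                       source_dialect="enologos")


# ---------------------------------------------------------------------------
# MEME minimal motif format

def write_meme(pwm: PWM, motif_id: str, path: str | Path) -> None:
    """MEME minimal format with a uniform background and probability matrix."""
    out = io.StringIO()
    out.write("MEME version 4\n\n")
    out.write("ALPHABET= ACGT\n\n")
    out.write("strands: + -\n\n")
    out.write("Background letter frequencies\n")
    out.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
    out.write(f"MOTIF {motif_id}\n")
    # large nsites so parsers that reconstruct counts as round(p * nsites)
    # keep the full 6-decimal precision
    out.write(
        f"letter-probability matrix: alength= 4 w= {pwm.length} "
        f"nsites= 1000000 E= 0\n"
    )
    for j in range(pwm.length):
        out.write(" " + " ".join(f"{pwm.probs[i, j]:.6f}" for i in range(4)) + "\n")
    Path(path).write_text(out.getvalue(), encoding="utf-8")


def read_meme(path: str | Path) -> MotifRecord:
    try:
        with open(path, encoding="utf-8") as fh:
            parsed = bio_motifs.parse(fh, "minimal")
            motif = parsed[0]
    except (ValueError, KeyError, IndexError) as exc:
        raise ParseError(f"cannot parse MEME minimal file {path}: {exc}") from exc
    matrix = np.array([list(motif.pwm[b]) for b in ALPHABET], dtype=float)
    return MotifRecord(
        id=motif.name or Path(path).stem,
        pwm=_normalize_counts(matrix, "meme"),
        source_dialect="meme",
    )


# ---------------------------------------------------------------------------
# JASPAR PFM

def read_jaspar_pfm(path: str | Path) -> MotifRecord:
    """Read a JASPAR PFM (``>`` header plus four bracketed count rows)."""
    try:
        with open(path, encoding="utf-8") as fh:
            parsed = bio_motifs.parse(fh, "jaspar")
            motif = parsed[0]
        counts = np.array([list(motif.counts[b]) for b in ALPHABET], dtype=float)
    except ValidationError:
        raise
    except Exception as exc:  # Biopython raises assorted types on bad input
        raise ParseError(f"cannot parse JASPAR PFM {path}: {exc}") from exc
    if counts.shape[0] != 4 or counts.shape[1] < 1:
        raise ParseError("JASPAR PFM must have 4 count rows")
    if np.any(counts < 0):
        raise ParseError("JASPAR PFM counts must be nonnegative")
    name = getattr(motif, "matrix_id", None) or motif.name or Path(path).stem
    return MotifRecord(
        id=str(name),
        pwm=_normalize_counts(counts, "jaspar_pfm"),
        source_dialect="jaspar_pfm",
    )


# ---------------------------------------------------------------------------
# comparison metric

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        if np.allclose(x, y, atol=1e-9):
            return 1.0
        raise UndefinedCorrelationError(
            "correlation undefined: zero variance and matrices differ"
        )
    return float(np.corrcoef(x, y)[0, 1])


def pwm_correlation(a: PWM, b: PWM, per_column: bool = False) -> float:
    """Pearson correlation between two PWMs of identical shape.

    Default: over all 4*L entries flattened row-major (A,C,G,T rows).  With
    ``per_column=True``: the mean of per-column correlations (columns where
    the correlation is undefined but the columns agree contribute 1.0).
    """
    if a.probs.shape != b.probs.shape:
        raise ValidationError(
            f"PWM shapes differ: {a.probs.shape} vs {b.probs.shape}"
        )
    if not per_column:
        return _pearson(a.probs.ravel(), b.probs.ravel())
    vals = [_pearson(a.probs[:, j], b.probs[:, j]) for j in range(a.length)]
    return float(np.mean(vals))
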