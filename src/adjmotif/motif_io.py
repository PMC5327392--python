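"""TRANSFAC motif matrix parsing and frequency-matrix utilities.

A transcription factor's binding preference is modelled as a position
frequency matrix: for an ``l``-base motif, a 4 x ``l`` table of nucleotide
frequencies whose columns each sum to 1.  TRANSFAC flat files carry these
either as raw alignment counts or as already-normalized frequencies; both
dialects are accepted here and autodetected per matrix block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ALPHABET",
    "FrequencyMatrix",
    "TransfacParseError",
    "parse_transfac",
    "parse_transfac_file",
    "write_transfac",
    "write_matrix_tsv",
    "apply_pseudocount",
    "reverse_complement",
]

log = logging.getLogger(__name__)

ALPHABET = "ACGT"
_COMPLEMENT_ORDER = (3, 2, 1, 0)  # A<->T, C<->G row swap

#: column sums above this are taken as alignment counts, not frequencies
_COUNT_DETECT_THRESHOLD = 1.5

DEFAULT_PSEUDOCOUNT = 0.001


class TransfacParseError(ValueError):
    """Malformed TRANSFAC matrix block; message names the block and line."""


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position nucleotide frequencies of one motif.

    Attributes
    ----------
    motif_id:
        Identifier from the TRANSFAC ``ID`` (or ``AC``) line.
    probs:
        Array of shape ``(4, l)``; rows are A, C, G, T in that order and
        every column sums to 1.
    pseudocount_applied:
        True once :func:`apply_pseudocount` has regularized the entries,
        guaranteeing strictly positive frequencies.
    """

    motif_id: str
    probs: np.ndarray = field(repr=False)
    pseudocount_applied: bool = False

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4 or probs.shape[1] < 1:
            raise ValueError(
                f"motif {self.motif_id!r}: expected a 4 x l matrix, got shape {probs.shape}"
            )
        if np.any(probs < 0):
            raise ValueError(f"motif {self.motif_id!r}: negative frequency entries")
        sums = probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(
                f"motif {self.motif_id!r}: columns must sum to 1 (got {sums})"
            )
        object.__setattr__(self, "probs", probs)

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        """Per-column argmax sequence (ties -> alphabetically first base)."""
        return "".join(ALPHABET[q] for q in np.argmax(self.probs, axis=0))


def _normalize_columns(raw: np.ndarray, motif_id: str, lineno: int) -> np.ndarray:
    sums = raw.sum(axis=0)
    if np.any(sums <= 0):
        raise TransfacParseError(
            f"matrix {motif_id!r} (line {lineno}): column with non-positive sum"
        )
    if np.any(sums > _COUNT_DETECT_THRESHOLD):
        log.debug("matrix %s: column sums up to %.3g, treating as counts",
                  motif_id, sums.max())
    # dividing by the column sum converts counts to frequencies and absorbs
    # rounding drift in frequency blocks alike
    return raw / sums


def parse_transfac(text: str) -> list[FrequencyMatrix]:
    """Parse TRANSFAC flat-file content into frequency matrices.

    Accepts both count and frequency matrix blocks (autodetected via column
    sums).  A trailing one-letter consensus column and rows for ambiguous
    nucleotides are tolerated; the latter are dropped with a warning.

    Raises
    ------
    TransfacParseError
        On a malformed block (missing ``P0`` header, non-numeric cell, or a
        row without exactly four nucleotide values); the message names the
        offending block and line number.
    """
    matrices: list[FrequencyMatrix] = []
    block_id: str | None = None
    block_ac: str | None = None
    in_table = False
    rows: list[list[float]] = []
    first_row_line = 0

    def finish(lineno: int) -> None:
        nonlocal block_id, block_ac, in_table, rows
        if block_id is None and block_ac is None and not in_table and not rows:
            return  # stray separator / leading //
        motif_id = block_id or block_ac or f"<block ending line {lineno}>"
        if not in_table:
            raise TransfacParseError(
                f"matrix {motif_id!r} (line {lineno}): block has no P0 header"
            )
        if not rows:
            raise TransfacParseError(
                f"matrix {motif_id!r} (line {lineno}): P0 header with no matrix rows"
            )
        raw = np.array(rows, dtype=float).T  # (4, l)
        probs = _normalize_columns(raw, motif_id, first_row_line)
        matrices.append(FrequencyMatrix(motif_id=motif_id, probs=probs))
        block_id = block_ac = None
        in_table = False
        rows = []

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("//"):
            finish(lineno)
            continue
        tag = stripped.split(maxsplit=1)
        key = tag[0]
        if key == "ID":
            block_id = tag[1].strip() if len(tag) > 1 else ""
            continue
        if key == "AC":
            block_ac = tag[1].strip() if len(tag) > 1 else ""
            continue
        if key in ("P0", "PO"):
            header = stripped.split()[1:]
            if [h.upper() for h in header[:4]] != list(ALPHABET):
                raise TransfacParseError(
                    f"matrix {block_id or block_ac!r} (line {lineno}): "
                    f"P0 header must list A C G T, got {header}"
                )
            if len(header) > 4:
                log.warning(
                    "matrix %s: ignoring extra P0 columns %s",
                    block_id or block_ac, header[4:],
                )
            in_table = True
            continue
        if in_table and key[:1].isdigit():
            fields = stripped.split()
            cells = fields[1:]
            # drop a trailing consensus letter if present
            if cells and not _is_number(cells[-1]):
                cells = cells[:-1]
            if len(cells) != 4:
                raise TransfacParseError(
                    f"matrix {block_id or block_ac!r} (line {lineno}): "
                    f"expected 4 nucleotide values, got {len(cells)}"
                )
            try:
                values = [float(c) for c in cells]
            except ValueError:
                raise TransfacParseError(
                    f"matrix {block_id or block_ac!r} (line {lineno}): "
                    f"non-numeric cell in row {fields[0]!r}"
                ) from None
            if not rows:
                first_row_line = lineno
            rows.append(values)
            continue
        # XX, BF, DE, CC and any other annotation lines are ignored

    if text.strip():  # accept an unterminated final block
        finish(lineno)
    return matrices


def parse_transfac_file(path) -> list[FrequencyMatrix]:
    with open(path, "rt", encoding="utf-8") as fh:
        return parse_transfac(fh.read())


def write_transfac(matrices: list[FrequencyMatrix]) -> str:
    """Serialize matrices back to TRANSFAC frequency blocks (round-trip safe)."""
    out = []
    for m in matrices:
        out.append(f"ID  {m.motif_id}")
        out.append("P0      A      C      G      T")
        for p in range(m.length):
            cells = "      ".join(f"{m.probs[q, p]:.9f}" for q in range(4))
            out.append(f"{p + 1:02d}      {cells}")
        out.append("//")
    return "\n".join(out) + "\n"


def write_matrix_tsv(matrices: list[FrequencyMatrix], path) -> None:
    """Write an inspection TSV: motif_id, position, A, C, G, T."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("motif_id\tposition\tA\tC\tG\tT\n")
        for m in matrices:
            for p in range(m.length):
                vals = "\t".join(f"{m.probs[q, p]:.9f}" for q in range(4))
                fh.write(f"{m.motif_id}\t{p + 1}\t{vals}\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def apply_pseudocount(
    m: FrequencyMatrix, epsilon: float = DEFAULT_PSEUDOCOUNT
) -> FrequencyMatrix:
    """Regularize frequencies to (theta + eps) / (1 + 4*eps).

    Keeps columns summing to 1 and makes every entry strictly positive so the
    log-odds score is finite.  The per-column argmax base is unchanged.
    """
    if epsilon <= 0:
        raise ValueError(f"pseudocount must be positive, got {epsilon}")
    probs = (m.probs + epsilon) / (1.0 + 4.0 * epsilon)
    return replace(m, probs=probs, pseudocount_applied=True)


def reverse_complement(m: FrequencyMatrix) -> FrequencyMatrix:
    """Frequency matrix of the motif read on the opposite strand.

    Columns are reversed and the A/T and C/G rows swapped; applying it twice
    returns the original matrix.
    """
    probs = m.probs[list(_COMPLEMENT_ORDER), ::-1]
    return replace(m, probs=probs)
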