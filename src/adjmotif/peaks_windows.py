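"""ChIP-seq peak points and ±m bp sequence windows.

Peak inputs are BED-like TSV: either two columns (chrom, 1-based peak
coordinate) or a standard 3-column BED interval, in which case the midpoint
is taken as the peak point.  Around each peak ``p`` the half-open interval
[p-m, p+m) of 1-based coordinates is extracted — exactly ``2m`` bases
covering positions p-m .. p+m-1, with the peak base itself at offset ``m``
of the window sequence.  An optional symmetric flank lets callers score
motif placements whose centers lie anywhere in the ±m span even when the
motif body pokes past it; the core window contract is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "PeakRecord",
    "SequenceWindow",
    "PeakParseError",
    "read_peaks",
    "extract_windows",
]

log = logging.getLogger(__name__)


class PeakParseError(ValueError):
    pass


@dataclass(frozen=True)
class PeakRecord:
    """One ChIP-seq peak point (1-based genomic coordinate)."""

    chrom: str
    position: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("peak chrom must be non-empty")
        if self.position < 1:
            raise ValueError(f"peak position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class SequenceWindow:
    """The 2m bases around one peak, with coordinate provenance.

    ``start``/``end`` are the half-open interval ``[p - m, p + m)`` in the
    peaks' own 1-based coordinates; ``sequence`` holds exactly those ``2m``
    bases (upper-case) and the peak base sits at offset ``m``.
    ``flank`` extra bases on each side, when requested, live in
    ``left_flank``/``right_flank`` so scanning can use them without changing
    the window's extent.
    """

    peak: PeakRecord
    sequence: str
    start: int
    end: int
    m: int
    left_flank: str = ""
    right_flank: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start != 2 * self.m or len(self.sequence) != 2 * self.m:
            raise ValueError(
                f"window at {self.peak.chrom}:{self.peak.position}: "
                f"interval/sequence length must equal 2m = {2 * self.m}"
            )

    @property
    def scan_sequence(self) -> str:
        """Core sequence with flanks attached (what the scanner sees)."""
        return self.left_flank + self.sequence + self.right_flank

    @property
    def flank(self) -> int:
        return len(self.left_flank)


def read_peaks(path) -> list[PeakRecord]:
    """Read peak points from a BED-like TSV.

    Lines starting with '#' (and BED track/browser lines) are skipped.  A
    line with >= 3 integer-parsable columns is treated as a BED interval and
    its midpoint (rounded down) becomes the peak point, converted to the
    1-based convention; a 2-column line is (chrom, 1-based position).
    """
    peaks: list[PeakRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t")
            if len(fields) < 2:
                raise PeakParseError(
                    f"{path}:{lineno}: expected >= 2 tab-separated fields"
                )
            chrom = fields[0]
            try:
                if len(fields) >= 3 and _is_int(fields[2]):
                    start, end = int(fields[1]), int(fields[2])
                    position = (start + end) // 2  # interval midpoint, floor
                else:
                    position = int(fields[1])
            except ValueError:
                raise PeakParseError(
                    f"{path}:{lineno}: non-integer peak position {fields[1]!r}"
                ) from None
            peaks.append(PeakRecord(chrom=chrom, position=position))
    return peaks


def _is_int(token: str) -> bool:
    try:
        int(token)
    except ValueError:
        return False
    return True


def extract_windows(
    genome: Mapping[str, object],
    peaks: Sequence[PeakRecord],
    m: int = 1000,
    flank: int = 0,
    strict: bool = False,
) -> list[SequenceWindow]:
    """Extract the ±m bp window around each peak from an indexed genome.

    ``genome`` is anything mapping chrom name to a sliceable sequence — a
    ``pyfaidx.Fasta`` or a plain ``dict`` of strings.  Peaks whose window
    (including ``flank``) would run off the contig are skipped and counted;
    unknown chroms are skipped with a warning unless ``strict``.
    """
    if m < 1:
        raise ValueError(f"half-window m must be >= 1, got {m}")
    windows: list[SequenceWindow] = []
    n_edge = 0
    for peak in peaks:
        if peak.chrom not in genome:
            msg = f"peak chrom {peak.chrom!r} absent from genome"
            if strict:
                raise KeyError(msg)
            log.warning("%s; skipping peak at %d", msg, peak.position)
            continue
        contig = genome[peak.chrom]
        start0 = peak.position - m - 1  # 0-based slice start of the core
        if start0 - flank < 0 or start0 + 2 * m + flank > len(contig):
            n_edge += 1
            continue
        seq = str(contig[start0 - flank : start0 + 2 * m + flank]).upper()
        windows.append(
            SequenceWindow(
                peak=peak,
                sequence=seq[flank : flank + 2 * m],
                start=peak.position - m,
                end=peak.position + m,
                m=m,
                left_flank=seq[:flank],
                right_flank=seq[flank + 2 * m :],
            )
        )
    if n_edge:
        log.info("skipped %d peak(s) within %d bp of a contig edge", n_edge, m + flank)
    return windows
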