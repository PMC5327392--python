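"""Synthetic desk-scale ChIP-seq datasets with a planted co-motif.

The generator emulates the premise the method rests on: a co-associated
factor's binding sites sit close to the ChIPed factor's peaks, with the
unsigned distance following a decaying ("peak-like") law.  It produces a
random background contig, evenly spaced peak points, instances of one
planted motif written near a random subset of peaks at
Exponential(λ)-distributed distances, and decoy motifs that are never
planted and therefore have no positional preference.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .motif_io import ALPHABET, FrequencyMatrix

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "random_frequency_matrix",
    "generate_background",
    "make_peak_positions",
    "plant_instances",
    "generate_dataset",
    "write_dataset",
]

log = logging.getLogger(__name__)

#: Dirichlet concentration for random motif columns; 0.5 gives realistically
#: informative columns (typical max frequency ~0.6-0.8)
_MOTIF_DIRICHLET_ALPHA = 0.5


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults are the package's reference recovery setting: 500 peaks, ±1 kb
    windows, one planted 10-mer written near 80% of peaks at exponentially
    distributed distances (mean 50 bp), against 20 unplanted decoy motifs on
    a 41% GC background.
    """

    seed: int = 0
    n_peaks: int = 500
    m: int = 1000
    gc: float = 0.41
    plant_prob: float = 0.8
    distance_scale: float = 50.0  # mean unsigned planted distance, bp
    motif_length: int = 10
    n_decoys: int = 20
    contig_length: int | None = None  # None -> derived from spacing
    chrom: str = "chrS"
    peak_spacing: int | None = None  # None -> 2m + 200
    edge_margin: int | None = None  # None -> m + 100

    def __post_init__(self) -> None:
        if not 0 <= self.plant_prob <= 1:
            raise ValueError(f"plant_prob must be in [0, 1], got {self.plant_prob}")
        if not 0 < self.gc < 1:
            raise ValueError(f"gc must be in (0, 1), got {self.gc}")
        if self.distance_scale >= self.m:
            raise ValueError("distance scale must be smaller than the half-window m")
        if self.n_peaks < 1 or self.motif_length < 1:
            raise ValueError("n_peaks and motif_length must be positive")

    @property
    def spacing(self) -> int:
        return self.peak_spacing if self.peak_spacing is not None else 2 * self.m + 200

    @property
    def margin(self) -> int:
        return self.edge_margin if self.edge_margin is not None else self.m + 100

    @property
    def resolved_contig_length(self) -> int:
        derived = 2 * self.margin + (self.n_peaks - 1) * self.spacing + 1
        if self.contig_length is None:
            return derived
        if self.contig_length < derived:
            raise ValueError(
                f"contig_length {self.contig_length} too short for "
                f"{self.n_peaks} peaks spaced {self.spacing} bp (need {derived})"
            )
        return self.contig_length


@dataclass(frozen=True)
class SyntheticDataset:
    """In-memory synthetic dataset plus its ground truth."""

    spec: SyntheticSpec
    contig: str
    peak_positions: tuple[int, ...]  # 1-based
    planted_motif: FrequencyMatrix
    decoy_motifs: tuple[FrequencyMatrix, ...]
    truth: tuple[dict, ...]  # one record per planted instance

    @property
    def motifs(self) -> list[FrequencyMatrix]:
        return [self.planted_motif, *self.decoy_motifs]

    @property
    def labels(self) -> dict[str, bool]:
        out = {self.planted_motif.motif_id: True}
        out.update({d.motif_id: False for d in self.decoy_motifs})
        return out


def random_frequency_matrix(
    rng: np.random.Generator,
    length: int,
    motif_id: str,
    alpha: float = _MOTIF_DIRICHLET_ALPHA,
) -> FrequencyMatrix:
    """Random motif: each column drawn from a symmetric Dirichlet(alpha)."""
    probs = rng.dirichlet([alpha] * 4, size=length).T  # (4, l)
    return FrequencyMatrix(motif_id=motif_id, probs=probs)


def generate_background(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. background base codes with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    p_at = (1.0 - spec.gc) / 2.0
    p_gc = spec.gc / 2.0
    return rng.choice(4, size=spec.resolved_contig_length, p=[p_at, p_gc, p_gc, p_at]).astype(np.uint8)


def make_peak_positions(spec: SyntheticSpec) -> tuple[int, ...]:
    """Evenly spaced 1-based peak positions, >= 2m apart, away from edges."""
    first = spec.margin + 1
    return tuple(first + i * spec.spacing for i in range(spec.n_peaks))


def _sample_instance(rng: np.random.Generator, motif: FrequencyMatrix) -> np.ndarray:
    """Draw one site column-wise from the motif's frequencies (codes)."""
    cum = np.cumsum(motif.probs, axis=0)
    u = rng.random(motif.length)
    return (u[None, :] < cum).argmax(axis=0).astype(np.uint8)


_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def plant_instances(
    contig_codes: np.ndarray,
    peak_positions: tuple[int, ...],
    spec: SyntheticSpec,
    motif: FrequencyMatrix,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[dict]]:
    """Write motif instances near peaks; returns (modified codes, truth table).

    For each peak, with probability ``plant_prob`` one instance sampled from
    the motif's PWM is written so its center sits at unsigned distance
    d ~ Exponential(distance_scale) from the peak (rounded, capped at
    m − l), on a uniformly chosen side and strand.  Overlaps with previously
    planted instances trigger a distance resample (<= 100 tries).
    """
    codes = contig_codes.copy()
    l = motif.length
    occupied: list[tuple[int, int]] = []
    truth: list[dict] = []
    for peak_1b in peak_positions:
        if rng.random() >= spec.plant_prob:
            continue
        peak0 = peak_1b - 1
        placed = False
        for _try in range(100):
            d = int(round(rng.exponential(spec.distance_scale)))
            d = min(d, spec.m - l)
            side = 1 if rng.random() < 0.5 else -1
            start = peak0 + side * d - (l - 1) // 2
            if start < 0 or start + l > codes.size:
                continue
            if any(start < e and s < start + l for s, e in occupied):
                continue
            placed = True
            break
        if not placed:
            log.warning("could not place instance near peak %d; skipped", peak_1b)
            continue
        site = _sample_instance(rng, motif)
        strand = "+" if rng.random() < 0.5 else "-"
        written = site if strand == "+" else _COMP[site][::-1]
        codes[start : start + l] = written
        occupied.append((start, start + l))
        truth.append(
            {
                "peak": peak_1b,
                "start": start,  # 0-based genomic start of the instance
                "distance": d,
                "side": side,
                "strand": strand,
                "site": "".join(ALPHABET[c] for c in site),
            }
        )
    return codes, truth


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the full in-memory dataset: contig, peaks, motifs, truth."""
    rng = np.random.default_rng(spec.seed)
    planted = random_frequency_matrix(rng, spec.motif_length, "PLANTED_01")
    decoys = tuple(
        random_frequency_matrix(rng, spec.motif_length, f"DECOY_{k + 1:02d}")
        for k in range(spec.n_decoys)
    )
    codes = generate_background(spec, rng)
    peaks = make_peak_positions(spec)
    codes, truth = plant_instances(codes, peaks, spec, planted, rng)
    bases = np.array(list(ALPHABET), dtype="U1")
    return SyntheticDataset(
        spec=spec,
        contig="".join(bases[codes]),
        peak_positions=peaks,
        planted_motif=planted,
        decoy_motifs=decoys,
        truth=tuple(truth),
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write genome.fa, peaks.bed, labels.tsv, truth.tsv (reproducible bytes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "peaks": outdir / "peaks.bed",
        "labels": outdir / "labels.tsv",
        "truth": outdir / "truth.tsv",
        "motifs": outdir / "motifs.transfac",
    }
    with open(paths["genome"], "wt") as fh:
        fh.write(f">{ds.spec.chrom}\n")
        seq = ds.contig
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    with open(paths["peaks"], "wt") as fh:
        for p in ds.peak_positions:
            fh.write(f"{ds.spec.chrom}\t{p}\n")
    with open(paths["labels"], "wt") as fh:
        fh.write("motif_id\tfamily\tlabel\n")
        fh.write(f"{ds.planted_motif.motif_id}\tPLANTED\tpos\n")
        for d in ds.decoy_motifs:
            fh.write(f"{d.motif_id}\t{d.motif_id}\tneg\n")
    with open(paths["truth"], "wt") as fh:
        fh.write("peak\tstart\tdistance\tside\tstrand\tsite\n")
        for t in ds.truth:
            fh.write(
                f"{t['peak']}\t{t['start']}\t{t['distance']}\t{t['side']}\t"
                f"{t['strand']}\t{t['site']}\n"
            )
    from .motif_io import write_transfac

    with open(paths["motifs"], "wt") as fh:
        fh.write(write_transfac(ds.motifs))
    return paths
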