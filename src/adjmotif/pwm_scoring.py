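"""Log-odds PWM scoring and min-max normalized binding scores.

The PWM score of an ``l``-base sequence ``s`` under a frequency matrix Θ is
the log likelihood ratio against a uniform 0-order background,

    score(s) = Σ_i log( Θ[s[i], i] / 0.25 ),

natural log throughout.  Because the per-column maximum (minimum) base gives
the analytic maximum (minimum) of this sum, every score can be linearly
rescaled to the sequence-specific binding score

    V = (score − score_min) / (score_max − score_min)  ∈  [0, 1],

which is the quantity binned and differenced downstream.  A window is scanned
at every full motif placement; placements overlapping an ambiguous base (N)
are conservatively given V = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .motif_io import ALPHABET, FrequencyMatrix, reverse_complement

__all__ = [
    "BindingScore",
    "encode_sequence",
    "log_odds_matrix",
    "pwm_score",
    "pwm_score_max",
    "pwm_score_min",
    "normalized_score",
    "scan_window",
]

log = logging.getLogger(__name__)

_BACKGROUND = 0.25
_DEGENERATE_RANGE = 1e-12

# byte-level encoder: A,C,G,T (either case) -> 0..3, anything else -> 4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class BindingScore:
    """One motif placement: normalized score, raw log-odds, offset, strand."""

    value: float  # V in [0, 1]
    raw: float  # natural-log odds
    position: int  # start offset of the placement within the window
    strand: str  # '+' or '-'


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def log_odds_matrix(m: FrequencyMatrix) -> np.ndarray:
    """Per-position log(Θ/0.25) table, shape ``(l, 4)``.

    Zero frequencies map to -inf; apply a pseudocount first to avoid them.
    """
    with np.errstate(divide="ignore"):
        return np.log(m.probs.T / _BACKGROUND)


def pwm_score(s: str, m: FrequencyMatrix) -> float:
    """Log likelihood ratio of ``s`` under Θ versus the uniform background."""
    if len(s) != m.length:
        raise ValueError(
            f"sequence length {len(s)} != motif length {m.length} ({m.motif_id})"
        )
    codes = encode_sequence(s)
    if np.any(codes > 3):
        bad = s[int(np.argmax(codes > 3))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence {s!r}")
    lom = log_odds_matrix(m)
    return float(lom[np.arange(m.length), codes].sum())


def pwm_score_max(m: FrequencyMatrix) -> float:
    """Score of the per-column argmax (consensus) sequence."""
    with np.errstate(divide="ignore"):
        return float(np.log(m.probs.max(axis=0) / _BACKGROUND).sum())


def pwm_score_min(m: FrequencyMatrix) -> float:
    """Score of the per-column argmin (anti-consensus) sequence."""
    with np.errstate(divide="ignore"):
        return float(np.log(m.probs.min(axis=0) / _BACKGROUND).sum())


def _normalize_raw(raw, lo: float, hi: float):
    if hi - lo < _DEGENERATE_RANGE:
        return np.full_like(np.asarray(raw, dtype=float), 0.5)
    return (np.asarray(raw, dtype=float) - lo) / (hi - lo)


def normalized_score(s: str, m: FrequencyMatrix) -> BindingScore:
    """Min-max normalized binding score V of ``s`` under Θ (forward strand)."""
    raw = pwm_score(s, m)
    v = _normalize_raw(raw, pwm_score_min(m), pwm_score_max(m))
    return BindingScore(value=float(v), raw=raw, position=0, strand="+")


def _scan_codes(codes: np.ndarray, lom: np.ndarray):
    """Raw log-odds at every full placement of a motif over coded sequences.

    Parameters
    ----------
    codes: uint8 array, shape ``(n, L)`` (code 4 = ambiguous base)
    lom: log-odds table, shape ``(l, 4)``

    Returns
    -------
    raw: float array ``(n, L - l + 1)``; contributions of ambiguous bases are 0
    nmask: bool array ``(n, L - l + 1)``; True where a placement overlaps an N
    """
    n, width = codes.shape
    l = lom.shape[0]
    p = width - l + 1
    if p < 1:
        raise ValueError(f"window length {width} shorter than motif length {l}")
    lut = np.zeros((l, 5))
    lut[:, :4] = lom
    raw = np.zeros((n, p))
    nmask = np.zeros((n, p), dtype=bool)
    for i in range(l):
        seg = codes[:, i : i + p]
        raw += lut[i, seg]
        nmask |= seg == 4
    return raw, nmask


def scan_window(
    w: str, m: FrequencyMatrix, strand_mode: str = "both"
) -> list[BindingScore]:
    """Score every full motif placement in a window.

    A length-``L`` window yields ``L - l + 1`` scores.  With
    ``strand_mode='both'`` each start is scored with the matrix and its
    reverse complement and the larger V is kept (ties go to '+'); min and max
    scores, hence V, are identical for the two orientations.  Placements
    overlapping an ambiguous base get V = 0.
    """
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"strand_mode must be 'forward' or 'both', got {strand_mode!r}")
    if len(w) < m.length:
        log.warning(
            "window of length %d shorter than motif %s (length %d); no placements",
            len(w), m.motif_id, m.length,
        )
        return []
    codes = encode_sequence(w)[np.newaxis, :]
    lo, hi = pwm_score_min(m), pwm_score_max(m)

    raw_f, nmask = _scan_codes(codes, log_odds_matrix(m))
    v_f = _normalize_raw(raw_f, lo, hi)
    if strand_mode == "both":
        raw_r, _ = _scan_codes(codes, log_odds_matrix(reverse_complement(m)))
        v_r = _normalize_raw(raw_r, lo, hi)
        minus = v_r > v_f
        raw = np.where(minus, raw_r, raw_f)
        v = np.where(minus, v_r, v_f)
    else:
        minus = np.zeros_like(nmask)
        raw, v = raw_f, v_f
    v = np.where(nmask, 0.0, v)

    return [
        BindingScore(
            value=float(v[0, p]),
            raw=float(raw[0, p]),
            position=p,
            strand="-" if minus[0, p] else "+",
        )
        for p in range(v.shape[1])
    ]
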