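"""Independent brute-force reference implementations used only by tests.

Everything here is written in plain Python (math module, loops, no shared
helpers with the package) so it can serve as an independent cross-check of
the vectorized implementations.
"""

from __future__ import annotations

import itertools
import math

BASES = "ACGT"


# -- PWM scoring -----------------------------------------------------------


def pwm_score_terms(seq: str, probs) -> float:
    """Term-by-term log likelihood ratio; probs is a 4 x l nested list."""
    total = 0.0
    for i, base in enumerate(seq):
        total += math.log(probs[BASES.index(base)][i] / 0.25)
    return total


def exhaustive_extreme(probs, want_max: bool) -> float:
    """Max/min PWM score by enumerating all 4^l sequences."""
    l = len(probs[0])
    best = None
    for seq in itertools.product(BASES, repeat=l):
        s = pwm_score_terms("".join(seq), probs)
        if best is None or (s > best if want_max else s < best):
            best = s
    return best


# -- adjacency scoring -----------------------------------------------------


def gamma_pdf(x: float, shape: float, scale: float) -> float:
    return (
        x ** (shape - 1.0)
        * math.exp(-x / scale)
        / (math.gamma(shape) * scale**shape)
    )


def sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def adjacency_straight_line(ms, m, b, gamma_shape, gamma_scale, w1, w2, t_grid):
    """Straight-line recomputation of the full adjacency score.

    ``ms`` is the descending-order matrix as a list of rows (r x b).
    Returns a dict with f1, f2, s1, s2, t_star and the final score.
    """
    r = len(ms)
    assert all(len(row) == b for row in ms)
    f1 = [[ms[i][j] - ms[i][j + 1] for j in range(b - 1)] for i in range(r)]
    weights = [gamma_pdf(j + 0.5, gamma_shape, gamma_scale) for j in range(b - 1)]

    depths = sorted({min(r, max(1, math.ceil(frac * r))) for frac in t_grid})
    s1_by_t = {}
    for t in depths:
        total = 0.0
        for j in range(b - 1):
            col = 0.0
            for i in range(t):
                col += f1[i][j]
            total += weights[j] * col
        s1_by_t[t] = total
    t_star = min(s1_by_t, key=lambda t: (-s1_by_t[t], t))
    s1 = s1_by_t[t_star]

    f2 = []
    dmax = [max(abs(f1[i][j]) for i in range(r)) for j in range(b - 1)]
    for i in range(r):
        f2.append(
            [f1[i][j] / dmax[j] if dmax[j] > 0 else 0.0 for j in range(b - 1)]
        )
    s2 = 0.0
    for j in range(b - 1):
        z = sum(f2[i][j] for i in range(r)) / r
        s2 += sigmoid(z) - 0.5
    return {
        "f1": f1,
        "f2": f2,
        "s1": s1,
        "s2": s2,
        "t_star": t_star,
        "score": w1 * s1 + w2 * s2,
    }


# -- ROC / AUC -------------------------------------------------------------


def pairwise_auc(scores_pos, scores_neg) -> float:
    """Concordant-pair AUC with ties counted 1/2."""
    wins = 0.0
    for p in scores_pos:
        for n in scores_neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(scores_pos) * len(scores_neg))
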