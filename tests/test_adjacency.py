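import math

import numpy as np
import pytest

from adjmotif import (
    BinnedScoreMatrix,
    FrequencyMatrix,
    PeakRecord,
    ScoringConfig,
    SequenceWindow,
    adjacency_score,
    build_descending_matrix,
    first_order_difference,
    gamma_weights,
    normalized_score,
    score_S1,
    score_S2,
    second_order_difference,
)
from adjmotif.adjacency import _placement_bins

from _oracles import adjacency_straight_line, gamma_pdf


def make_bsm(matrix, n=1, m=1000):
    matrix = np.asarray(matrix, dtype=float)
    r, b = matrix.shape
    return BinnedScoreMatrix(
        matrix=matrix, r=r, b=b, n=n, bin_edges=np.arange(b + 1) * (m / b)
    )


def random_descending_matrix(rng, r, b):
    """Columns independently sorted descending — a positionally null motif."""
    m = rng.random((r, b))
    return np.sort(m, axis=0)[::-1]


class TestBuildDescendingMatrix:
    def _window(self, seq, m, flank=0):
        core = seq[flank : len(seq) - flank] if flank else seq
        return SequenceWindow(
            peak=PeakRecord("c", m + 1),
            sequence=core,
            start=0,
            end=len(core),
            m=m,
            left_flank=seq[:flank],
            right_flank=seq[len(seq) - flank :] if flank else "",
        )

    def test_matches_naive_binning_and_sorting(self, rng, random_matrix_factory):
        """Brute-force oracle: score each placement, bin by center distance."""
        motif = random_matrix_factory(2)
        m, b = 4, 2
        cfg = ScoringConfig(m=m, b=b, strand_mode="forward", pseudocount=1e-9)
        windows = [
            self._window("".join(rng.choice(list("ACGT"), size=2 * m)), m)
            for _ in range(2)
        ]
        bsm = build_descending_matrix(windows, motif, cfg)
        # oracle: enumerate placements, V via normalized_score, fold distances
        per_bin = {0: [], 1: []}
        for w in windows:
            for p in range(2 * m - motif.length + 1):
                center = p + (motif.length - 1) / 2
                s = center - m
                if s >= 0:
                    j = int(s // (m / b))
                else:
                    j = int((-s - 0.5) // (m / b))
                if j >= b:
                    continue
                v = normalized_score(w.sequence[p : p + motif.length], motif).value
                per_bin[j].append(v)
        r = max(len(vs) for vs in per_bin.values())
        expected = np.zeros((r, b))
        for j, vs in per_bin.items():
            expected[: len(vs), j] = sorted(vs, reverse=True)
        np.testing.assert_allclose(bsm.matrix, expected, atol=1e-12)

    def test_columns_sorted_descending(self, rng, random_matrix_factory):
        motif = random_matrix_factory(4)
        cfg = ScoringConfig(m=50, b=5)
        windows = [
            self._window("".join(rng.choice(list("ACGT"), size=108)), 50, flank=4)
            for _ in range(3)
        ]
        bsm = build_descending_matrix(windows, motif, cfg)
        assert np.all(np.diff(bsm.matrix, axis=0) <= 1e-12)
        assert bsm.matrix.min() >= 0.0 and bsm.matrix.max() <= 1.0

    def test_flanked_windows_fill_all_bins_evenly(self, rng, random_matrix_factory):
        """With a flank >= motif overhang every bin gets 2m/b placements."""
        motif = random_matrix_factory(6)
        m, b, n = 60, 6, 4
        cfg = ScoringConfig(m=m, b=b)
        windows = [
            self._window("".join(rng.choice(list("ACGT"), size=2 * m + 12)), m, flank=6)
            for _ in range(n)
        ]
        bsm = build_descending_matrix(windows, motif, cfg)
        assert bsm.r == 2 * m * n // b
        # no padding zeros beyond genuine scores: bottom row can still be > 0
        bins = _placement_bins(2 * m + 12, motif.length, m, b, flank=6)
        counts = np.bincount(bins[bins >= 0], minlength=b)
        assert np.all(counts == 2 * m // b)

    def test_unflanked_outer_bin_is_padded(self, rng, random_matrix_factory):
        motif = random_matrix_factory(6)
        m, b = 60, 6
        cfg = ScoringConfig(m=m, b=b)
        windows = [self._window("".join(rng.choice(list("ACGT"), size=2 * m)), m)]
        bsm = build_descending_matrix(windows, motif, cfg)
        bins = _placement_bins(2 * m, motif.length, m, b, flank=0)
        counts = np.bincount(bins[bins >= 0], minlength=b)
        assert counts[-1] < counts[0] == bsm.r
        # shorter outer column zero-padded at the bottom
        assert bsm.matrix[counts[-1] :, b - 1] == pytest.approx(0.0)


class TestFirstOrderDifference:
    def test_constant_matrix_gives_zeros(self):
        f1 = first_order_difference(make_bsm(np.full((3, 4), 0.7)))
        np.testing.assert_allclose(f1, 0.0)

    def test_toy_subtraction(self):
        f1 = first_order_difference(make_bsm([[3, 2, 1], [1, 1, 0]]))
        np.testing.assert_allclose(f1, [[1, 1], [0, 1]])

    def test_first_row_is_difference_of_column_maxima(self, rng):
        ms = random_descending_matrix(rng, 6, 5)
        f1 = first_order_difference(make_bsm(ms))
        np.testing.assert_allclose(
            f1[0], ms.max(axis=0)[:-1] - ms.max(axis=0)[1:], atol=1e-12
        )


class TestGammaWeights:
    def test_exponential_case_strictly_decreasing(self):
        w = gamma_weights(b=40, c=1.0, scale=10.0)
        assert np.all(np.diff(w) < 0)

    def test_closed_form_value(self):
        w = gamma_weights(b=40, c=1.0, scale=10.0)
        assert w[0] == pytest.approx(0.1 * math.exp(-0.05), abs=1e-12)
        assert w[0] == pytest.approx(0.09512, abs=5e-6)

    def test_positive_for_random_parameters(self, rng):
        for _ in range(20):
            c, scale = rng.uniform(0.2, 5.0), rng.uniform(0.5, 30.0)
            w = gamma_weights(b=12, c=c, scale=scale)
            assert np.all(w > 0)
            assert w == pytest.approx(
                [gamma_pdf(j + 0.5, c, scale) for j in range(11)], abs=1e-12
            )

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            gamma_weights(b=10, c=0.0, scale=1.0)
        with pytest.raises(ValueError):
            gamma_weights(b=10, c=1.0, scale=-2.0)


class TestScoreS1:
    def test_zero_f1_scores_zero(self):
        f1 = np.zeros((5, 3))
        assert score_S1(f1, np.ones(3), t=2) == 0.0

    def test_full_depth_unit_weights_is_grand_sum(self, rng):
        f1 = rng.normal(size=(6, 4))
        assert score_S1(f1, np.ones(4), t=6) == pytest.approx(f1.sum())

    def test_toy_arithmetic(self):
        f1 = np.array([[1.0, 1.0], [0.0, 1.0]])
        assert score_S1(f1, np.array([0.5, 0.25]), t=2) == pytest.approx(1.0)

    def test_depth_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_S1(np.zeros((3, 2)), np.ones(2), t=4)


class TestSecondOrderDifference:
    def test_column_rescaled_by_max_abs(self):
        f1 = np.array([[2.0], [1.0], [-1.0]])
        np.testing.assert_allclose(
            second_order_difference(f1), [[1.0], [0.5], [-0.5]]
        )

    def test_zero_column_guard(self):
        np.testing.assert_allclose(second_order_difference(np.zeros((4, 3))), 0.0)

    def test_bounded_by_one(self, rng):
        f2 = second_order_difference(rng.normal(size=(50, 8)))
        assert np.all(np.abs(f2) <= 1.0 + 1e-12)


class TestScoreS2:
    def test_null_input_scores_zero(self):
        assert score_S2(np.zeros((10, 4))) == 0.0

    def test_sigmoid_saturation_limits(self):
        # region means at the sigmoid's extremes contribute ±1/2
        assert score_S2(np.full((1, 1), 1e9)) == pytest.approx(0.5)
        assert score_S2(np.full((1, 1), -1e9)) == pytest.approx(-0.5)

    def test_odd_symmetry_of_regions(self):
        f2 = np.array([[1.0, -1.0]])
        assert score_S2(f2) == pytest.approx(0.0, abs=1e-12)


class TestAdjacencyScore:
    def test_degenerate_weights_reduce_to_components(self, rng):
        ms = random_descending_matrix(rng, 8, 4)
        bsm = make_bsm(ms, m=40)
        grid = (0.25, 1.0)
        only_s1 = adjacency_score(bsm, ScoringConfig(m=40, b=4, w1=1.0, w2=0.0, t_grid=grid))
        only_s2 = adjacency_score(bsm, ScoringConfig(m=40, b=4, w1=0.0, w2=1.0, t_grid=grid))
        assert only_s1.score == pytest.approx(only_s1.s1)
        assert only_s1.s1 == pytest.approx(max(only_s1.s1_by_t.values()))
        assert only_s2.score == pytest.approx(only_s2.s2)
        assert only_s2.t_star in only_s2.s1_by_t

    def test_matches_straight_line_oracle(self, rng):
        for _ in range(25):
            r = int(rng.integers(2, 9))
            b = int(rng.integers(2, 6))
            ms = random_descending_matrix(rng, r, b)
            cfg = ScoringConfig(
                m=100,
                b=b,
                gamma_shape=float(rng.uniform(0.5, 3.0)),
                gamma_scale=float(rng.uniform(1.0, 10.0)),
                w1=float(rng.uniform(0, 2)),
                w2=float(rng.uniform(0.1, 2)),
                t_grid=(0.2, 0.5, 1.0),
            )
            res = adjacency_score(make_bsm(ms, m=100), cfg)
            ref = adjacency_straight_line(
                ms.tolist(), 100, b, cfg.gamma_shape, cfg.resolved_gamma_scale,
                cfg.w1, cfg.w2, cfg.t_grid,
            )
            np.testing.assert_allclose(res.f1, ref["f1"], atol=1e-9)
            np.testing.assert_allclose(res.f2, ref["f2"], atol=1e-9)
            assert res.s1 == pytest.approx(ref["s1"], abs=1e-9)
            assert res.s2 == pytest.approx(ref["s2"], abs=1e-9)
            assert res.t_star == ref["t_star"]
            assert res.score == pytest.approx(ref["score"], abs=1e-9)

    def test_scale_property(self, rng):
        """Scaling M_s by λ scales f1 and S1 by λ and leaves f2, S2 unchanged."""
        ms = random_descending_matrix(rng, 10, 5)
        cfg = ScoringConfig(m=50, b=5, t_grid=(0.3, 1.0))
        lam = 0.37
        base = adjacency_score(make_bsm(ms, m=50), cfg)
        scaled = adjacency_score(make_bsm(lam * ms, m=50), cfg)
        np.testing.assert_allclose(scaled.f1, lam * base.f1, atol=1e-12)
        assert scaled.s1 == pytest.approx(lam * base.s1)
        np.testing.assert_allclose(scaled.f2, base.f2, atol=1e-12)
        assert scaled.s2 == pytest.approx(base.s2)

    def test_enrichment_monotonicity(self, rng):
        """Shifting near-bin scores up by δ strictly increases S1 and S."""
        ms = random_descending_matrix(rng, 12, 6) * 0.5
        cfg = ScoringConfig(m=60, b=6)
        scores = []
        for delta in (0.0, 0.1, 0.2, 0.3):
            shifted = ms.copy()
            shifted[:, 0] += delta  # nearest bin enriched
            res = adjacency_score(make_bsm(shifted, m=60), cfg)
            scores.append((res.s1, res.score))
        s1s = [s[0] for s in scores]
        finals = [s[1] for s in scores]
        assert all(a < b for a, b in zip(s1s, s1s[1:]))
        assert all(a < b for a, b in zip(finals, finals[1:]))

    def test_null_matrices_have_mean_score_near_zero(self, rng):
        """Positionally uniform motifs: E[S] ≈ 0 (within 3 standard errors)."""
        scores = []
        cfg = ScoringConfig(m=80, b=8)
        for _ in range(200):
            ms = random_descending_matrix(rng, 30, 8)
            scores.append(adjacency_score(make_bsm(ms, m=80), cfg).score)
        scores = np.asarray(scores)
        se = scores.std(ddof=1) / math.sqrt(len(scores))
        assert abs(scores.mean()) <= 3 * se
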