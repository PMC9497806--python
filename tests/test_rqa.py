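"""Recurrence matrices, line histograms and the six RQA measures, checked
against brute-force oracles."""

from collections import Counter

import numpy as np
import pytest

from pirodyn import (
    DegenerateInputError,
    RecurrenceMatrix,
    delay_embed,
    line_histograms,
    recurrence_matrix,
    rqa_measures,
)


# --- independent oracles ---------------------------------------------------

def brute_matrix(points, radius_fraction):
    """O(N^2) double-loop construction of the recurrence matrix."""
    n = len(points)
    dmax = 0.0
    for i in range(n):
        for j in range(n):
            dmax = max(dmax, np.linalg.norm(points[i] - points[j]))
    r = radius_fraction * dmax
    out = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for j in range(n):
            if np.linalg.norm(points[i] - points[j]) <= r:
                out[i, j] = 1
    return out, r


def brute_diag_hist(R):
    """Run-length scan over every super-diagonal of the upper triangle."""
    n = R.shape[0]
    hist = Counter()
    for k in range(1, n):
        run = 0
        for i in range(n - k):
            if R[i, i + k]:
                run += 1
            elif run:
                hist[run] += 1
                run = 0
        if run:
            hist[run] += 1
    return dict(hist)


def brute_vert_hist(R):
    """Run-length scan down every column, rows above the main diagonal."""
    n = R.shape[0]
    hist = Counter()
    for j in range(n):
        run = 0
        for i in range(j):
            if R[i, j]:
                run += 1
            elif run:
                hist[run] += 1
                run = 0
        if run:
            hist[run] += 1
    return dict(hist)


def _matrix_from_indicator(R):
    return RecurrenceMatrix(indicator=R.astype(np.uint8), radius=1.0, N=R.shape[0])


# --- tests -----------------------------------------------------------------

class TestRecurrenceMatrix:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_construction(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((50, 3))
        rm = recurrence_matrix(pts, radius_fraction=0.2)
        oracle, r = brute_matrix(pts, 0.2)
        assert rm.radius == pytest.approx(r)
        np.testing.assert_array_equal(rm.indicator, oracle)

    def test_identical_points_recur(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [3.0, 0.0]])
        rm = recurrence_matrix(pts, radius_fraction=0.01)
        assert rm.indicator[0, 2] == rm.indicator[2, 0] == 1

    def test_collinear_threshold_example(self):
        pts = np.array([[0.0], [1.0], [100.0]])
        rm = recurrence_matrix(pts, radius_fraction=0.02)
        assert rm.radius == pytest.approx(2.0)
        assert rm.indicator[0, 1] == 1  # distance 1 <= 2
        assert rm.indicator[0, 2] == 0 and rm.indicator[1, 2] == 0

    def test_boundary_distance_is_recurrent(self):
        # Theta(0) = 1: a pair at exactly the radius counts
        pts = np.array([[0.0], [1.0], [50.0]])
        rm = recurrence_matrix(pts, radius_fraction=0.02)  # r = 1.0 exactly
        assert rm.radius == pytest.approx(1.0)
        assert rm.indicator[0, 1] == 1

    def test_rec_monotone_in_radius(self, rng):
        pts = rng.standard_normal((80, 2))
        recs = []
        for frac in (0.01, 0.05, 0.1, 0.3, 0.6, 1.0):
            rm = recurrence_matrix(pts, frac)
            recs.append(rqa_measures(rm).rec)
        assert all(a <= b + 1e-12 for a, b in zip(recs, recs[1:]))
        assert recs[-1] == pytest.approx(100.0)  # r = diameter: all recurrent

    def test_zero_diameter_rejected(self):
        with pytest.raises(DegenerateInputError):
            recurrence_matrix(np.zeros((5, 2)))


class TestLineHistograms:
    def test_isolated_points_give_only_length_one_lines(self):
        # ones on even (i, j) only: no two adjacent cells along any diagonal
        # or vertical, so every line has length 1
        n = 12
        i, j = np.indices((n, n))
        R = ((i % 2 == 0) & (j % 2 == 0)).astype(np.uint8)
        hist = line_histograms(_matrix_from_indicator(R))
        assert set(hist.diagonal) == {1}
        assert set(hist.vertical) == {1}

    def test_single_full_superdiagonal(self):
        n, k = 20, 4
        R = np.zeros((n, n), dtype=np.uint8)
        idx = np.arange(n - k)
        R[idx, idx + k] = 1
        hist = line_histograms(_matrix_from_indicator(R))
        assert hist.diagonal == {n - k: 1}

    @pytest.mark.parametrize("seed", range(10))
    def test_random_matrices_match_run_length_oracle(self, seed):
        rng = np.random.default_rng(seed)
        R = (rng.uniform(size=(30, 30)) < 0.3).astype(np.uint8)
        R = np.maximum(R, R.T)
        np.fill_diagonal(R, 1)
        hist = line_histograms(_matrix_from_indicator(R))
        assert hist.diagonal == brute_diag_hist(R)
        assert hist.vertical == brute_vert_hist(R)


class TestRQAMeasures:
    def test_all_recurrent_gives_full_recurrence(self):
        pts = np.array([[0.0], [0.1], [0.05], [0.02]])
        rm = recurrence_matrix(pts, radius_fraction=1.0)
        m = rqa_measures(rm)
        assert m.rec == pytest.approx(100.0)
        # full upper triangle: diagonal runs of lengths 3, 2, 1 -> 5 of the
        # 6 recurrent cells lie on lines of length >= 2
        assert m.det == pytest.approx(100.0 * 5 / 6)
        assert m.lmax == 3

    def test_no_off_diagonal_recurrence_gives_zeros(self):
        pts = np.arange(10.0)[:, None] * 10
        rm = recurrence_matrix(pts, radius_fraction=0.01)
        m = rqa_measures(rm)
        assert m.rec == 0.0 and m.det == 0.0 and m.lmax == 0
        assert m.ent == 0.0 and m.lam == 0.0 and m.tt == 0.0

    def test_hand_built_histogram_formulas(self):
        """One diagonal line of length 3 and one of length 2: DET = 100%,
        LMAX = 3, ENT = ln 2 (two equiprobable line lengths)."""
        R = np.eye(8, dtype=np.uint8)
        # length-3 run on offset 3: cells (0,3),(1,4),(2,5)
        for i in range(3):
            R[i, i + 3] = 1
        # length-2 run on offset 5: cells (1,6),(2,7)
        R[1, 6] = R[2, 7] = 1
        R = np.maximum(R, R.T)
        rm = _matrix_from_indicator(R)
        hist = line_histograms(rm)
        assert hist.diagonal == {3: 1, 2: 1}
        m = rqa_measures(rm, hist)
        assert m.det == pytest.approx(100.0)
        assert m.lmax == 3
        assert m.ent == pytest.approx(np.log(2.0))

    def test_noiseless_periodic_embedding_highly_deterministic(self):
        """Periodic dynamics: nearly all recurrent points align on diagonal
        lines, and the longest line grows with the series."""
        t = np.arange(3000.0)
        x = np.sin(2 * np.pi * t / 53.7)
        lmaxes = []
        for n in (1000, 2000, 3000):
            emb = delay_embed(x[:n], D=2, tau=13)
            rm = recurrence_matrix(emb, 0.01)
            m = rqa_measures(rm)
            assert m.det >= 99.0
            lmaxes.append(m.lmax)
        assert lmaxes[0] < lmaxes[1] < lmaxes[2]

    @pytest.mark.parametrize("seed", range(40))
    def test_measures_match_oracle_on_random_clouds(self, seed):
        """End-to-end equivalence with the brute-force oracles on random
        point clouds (the formulas applied to hand-scanned histograms)."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(10, 61))
        dim = int(rng.integers(1, 4))
        pts = rng.standard_normal((n, dim))
        frac = float(rng.uniform(0.05, 0.6))
        rm = recurrence_matrix(pts, frac)
        oracle_R, _ = brute_matrix(pts, frac)
        np.testing.assert_array_equal(rm.indicator, oracle_R)
        hist = line_histograms(rm)
        d_hist = brute_diag_hist(oracle_R)
        v_hist = brute_vert_hist(oracle_R)
        assert hist.diagonal == d_hist
        assert hist.vertical == v_hist

        m = rqa_measures(rm, hist)
        upper_cells = int(np.triu(oracle_R, 1).sum())
        assert m.rec == pytest.approx(100.0 * upper_cells / (n * (n - 1) / 2))
        total = sum(l * c for l, c in d_hist.items())
        assert total == upper_cells  # conservation: every recurrent cell on a run
        long_pts = sum(l * c for l, c in d_hist.items() if l >= 2)
        assert m.det == pytest.approx(100.0 * long_pts / total if total else 0.0)
        assert m.lmax == (max(d_hist) if d_hist else 0)
        n_lines = sum(c for l, c in d_hist.items() if l >= 2)
        if n_lines:
            ent = -sum(
                (c / n_lines) * np.log(c / n_lines) for l, c in d_hist.items() if l >= 2
            )
            assert m.ent == pytest.approx(max(ent, 0.0))
        v_total = sum(v * c for v, c in v_hist.items())
        v_long = sum(v * c for v, c in v_hist.items() if v >= 2)
        assert m.lam == pytest.approx(100.0 * v_long / v_total if v_total else 0.0)
        v_lines = sum(c for v, c in v_hist.items() if v >= 2)
        assert m.tt == pytest.approx(v_long / v_lines if v_lines else 0.0)

    def test_full_normalization_halves_rec(self, rng):
        pts = rng.standard_normal((40, 2))
        rm = recurrence_matrix(pts, 0.3)
        upper = rqa_measures(rm, rec_normalization="upper_triangle").rec
        full = rqa_measures(rm, rec_normalization="full").rec
        n = 40
        assert full == pytest.approx(upper * (n * (n - 1) / 2) / n**2)
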