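"""Pairwise LD, sample-size correction, Ne inversion and NeS slopes."""

import numpy as np
import pandas as pd
import pytest

from equidiv.genotypes import MISSING
from equidiv.ne import (
    adjust_r2,
    distance_to_c,
    estimate_ne,
    nes_slopes,
    pairwise_r2,
)

from conftest import matrix_from_rows, uniform_map


class TestPairwiseR2:
    def test_duplicated_snp_gives_r2_one(self):
        mmap = uniform_map(1, 2, spacing_bp=600_000, freq=None)
        col = [0, 1, 2, 1, 0, 2, 1, 1, 2, 0, 1, 2]
        g = matrix_from_rows([[c, c] for c in col], mmap)
        pairs = pairwise_r2(g, min_dist_bp=100_000, max_dist_bp=10_000_000)
        assert len(pairs) == 1
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_perfect_negative_correlation_gives_one(self):
        mmap = uniform_map(1, 2, spacing_bp=600_000, freq=None)
        col = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0])
        g = matrix_from_rows(np.column_stack([col, 2 - col]), mmap)
        pairs = pairwise_r2(g, min_dist_bp=100_000, max_dist_bp=10_000_000)
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        mmap = uniform_map(1, 2, spacing_bp=600_000, freq=None)
        x = rng.integers(0, 3, size=50)
        y = rng.integers(0, 3, size=50)
        g = matrix_from_rows(np.column_stack([x, y]), mmap)
        pairs = pairwise_r2(g, min_dist_bp=100_000, max_dist_bp=10_000_000)
        want = (np.cov(x, y, bias=True)[0, 1] ** 2
                / (np.var(x) * np.var(y)))
        assert pairs["r2"].iloc[0] == pytest.approx(want, abs=1e-12)

    def test_pairwise_complete_with_missing(self, rng):
        mmap = uniform_map(1, 2, spacing_bp=600_000, freq=None)
        x = rng.integers(0, 3, size=60).astype(np.int8)
        y = rng.integers(0, 3, size=60).astype(np.int8)
        x[:7] = MISSING
        y[5:12] = MISSING
        g = matrix_from_rows(np.column_stack([x, y]), mmap)
        pairs = pairwise_r2(g, min_dist_bp=100_000, max_dist_bp=10_000_000)
        ok = (x != MISSING) & (y != MISSING)
        want = (np.cov(x[ok], y[ok], bias=True)[0, 1] ** 2
                / (np.var(x[ok]) * np.var(y[ok])))
        assert pairs["n_obs"].iloc[0] == ok.sum()
        assert pairs["r2"].iloc[0] == pytest.approx(want, abs=1e-12)

    def test_zero_variance_and_sparse_pairs_skipped(self):
        mmap = uniform_map(1, 2, spacing_bp=600_000, freq=None)
        g = matrix_from_rows([[2, 1], [2, 0], [2, 2], [2, 1]] * 4, mmap)
        pairs = pairwise_r2(g, min_dist_bp=100_000, max_dist_bp=10_000_000)
        assert len(pairs) == 0

    def test_distance_window_respected(self, rng):
        mmap = uniform_map(1, 50, spacing_bp=200_000, freq=None)
        g = matrix_from_rows(rng.integers(0, 3, size=(30, 50)), mmap)
        pairs = pairwise_r2(g, min_dist_bp=500_000, max_dist_bp=2_000_000)
        assert pairs["distance_bp"].between(500_000, 2_000_000).all()

    def test_invariant_to_recoding_and_sample_order(self, rng):
        mmap = uniform_map(1, 10, spacing_bp=200_000, freq=None)
        g = matrix_from_rows(rng.integers(0, 3, size=(40, 10)), mmap)
        a = pairwise_r2(g, 100_000, 2_000_000)
        b = pairwise_r2(g.recode(), 100_000, 2_000_000)
        assert np.allclose(a["r2"], b["r2"])
        perm = rng.permutation(40)
        c = pairwise_r2(g.subset(sample_idx=perm), 100_000, 2_000_000)
        assert np.allclose(a["r2"], c["r2"])


class TestAdjustR2:
    def test_unphased_subtracts_one_over_n(self):
        # SNeP convention: unphased genotype r2 is inflated by ~1/n
        assert adjust_r2(0.25, 50) == pytest.approx(0.23)

    def test_phased_subtracts_one_over_2n(self):
        assert adjust_r2(0.25, 50, phased=True) == pytest.approx(0.24)
        diff = adjust_r2(0.5, 20) - adjust_r2(0.5, 20, phased=True)
        assert diff == pytest.approx(1 / 40 - 1 / 20)

    def test_floor_case_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            out = adjust_r2(1 / 100, 50)
        assert out > 0 and "floored" in caplog.text


class TestDistanceToC:
    def test_linear_anchors(self):
        assert distance_to_c(1_240_000) == pytest.approx(0.01)
        assert distance_to_c(26_000_000) == pytest.approx(0.209677, abs=1e-6)

    def test_haldane_matches_linear_to_first_order(self):
        m = distance_to_c(100_000)
        h = distance_to_c(100_000, mapping="haldane")
        assert h == pytest.approx(m, rel=1e-2)
        assert h < m

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            distance_to_c(0)


def _pairs_at(distances_bp, r2, n_each=50):
    rows = []
    for d, r in zip(distances_bp, r2):
        for _ in range(n_each):
            rows.append({"chrom": 1, "snp_i": 0, "snp_j": 1,
                         "distance_bp": d, "r2": r, "n_obs": 60})
    return pd.DataFrame(rows)


class TestEstimateNe:
    def test_closed_form_roundtrip_exact(self):
        n_samples, alpha, n_true = 80, 2.2, 100.0
        d = 1_550_000  # c = 0.0125 under 1.24 Mbp/cM
        c = distance_to_c(d)
        assert c == pytest.approx(0.0125)
        r2 = 1.0 / (alpha + 4 * n_true * c) + 1.0 / n_samples
        est = estimate_ne(_pairs_at([d], [r2]), n_samples=n_samples,
                          n_bins=1, alpha=alpha, min_dist_bp=d - 1,
                          max_dist_bp=d + 1)
        assert est["ne"].iloc[0] == pytest.approx(n_true, rel=1e-12)

    def test_limit_r2adj_at_inverse_alpha_drops_bin(self):
        d = 1_550_000
        r2 = 1 / 2.2 + 1 / 60
        with pytest.raises(ValueError, match="no valid"):
            estimate_ne(_pairs_at([d], [r2]), n_samples=60, n_bins=1,
                        alpha=2.2, min_dist_bp=d - 1, max_dist_bp=d + 1)

    def test_t_decreasing_with_distance(self):
        dists = [1_000_000, 5_000_000, 10_000_000, 20_000_000]
        r2 = [0.3, 0.2, 0.1, 0.05]
        est = estimate_ne(_pairs_at(dists, r2), n_samples=60, n_bins=4,
                          min_dist_bp=500_000, max_dist_bp=26_000_000)
        t = est.sort_values("mean_distance_bp")["t"].to_numpy()
        assert all(a > b for a, b in zip(t, t[1:]))

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            estimate_ne(pd.DataFrame(columns=["distance_bp", "r2"]),
                        n_samples=60)


def _trajectory(t, ne):
    return pd.DataFrame({"t": t, "ne": ne})


class TestNesSlopes:
    def test_affine_trajectory_is_flat_zero(self):
        t = np.linspace(2, 20, 12)
        out = nes_slopes(_trajectory(t, 10 * t + 3))
        assert np.allclose(out["nes"], 0.0, atol=1e-9)

    def test_slope_doubling_gives_nes_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ne = np.array([0.0, 2.0, 3.0, 4.0, 5.0])  # first slope doubled
        out = nes_slopes(_trajectory(t, ne))
        assert out["nes"].iloc[0] == pytest.approx(1.0)

    def test_matches_direct_recomputation(self, rng):
        for _ in range(10):
            t = np.sort(rng.uniform(1, 30, size=9))
            ne = np.cumsum(rng.uniform(0.5, 5, size=9))
            out = nes_slopes(_trajectory(t, ne))
            slopes = np.diff(ne) / np.diff(t)
            for row in out.itertuples(index=False):
                k = int(np.argmin(np.abs(t[:-1] - row.t)))
                ref = np.median(slopes[k + 1:k + 3])
                assert row.nes == pytest.approx(slopes[k] / ref - 1)

    def test_two_deepest_segments_omitted(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = nes_slopes(_trajectory(t, t ** 2))
        assert len(out) == 2  # 4 slopes, last two lack a reference

    def test_requires_four_estimates(self):
        with pytest.raises(ValueError):
            nes_slopes(_trajectory([1, 2, 3], [1, 2, 3]))
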