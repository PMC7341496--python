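"""Runs-of-homozygosity scanner vs planted truth and a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from equidiv.genotypes import MISSING
from equidiv.roh import (
    LENGTH_CLASSES,
    RohParams,
    classify_length,
    detect_roh,
    detect_roh_all,
    summarize_roh,
)

from conftest import matrix_from_rows, uniform_map


# --- independent brute-force oracle -----------------------------------------

def oracle_windows(dosages, positions, p: RohParams):
    """Enumerate every SNP index window, check the five rules directly,
    keep maximal passing windows, then resolve overlaps longest-first with
    ties toward the smaller start."""
    d = np.asarray(dosages)
    pos = np.asarray(positions)
    m = d.size
    passing = []
    for i in range(m):
        for j in range(i, m):
            w = d[i:j + 1]
            if w[0] in (MISSING, 1) or w[-1] in (MISSING, 1):
                continue
            if (w == 1).sum() > p.max_het_in_run:
                continue
            if (w == MISSING).sum() > p.max_miss_in_run:
                continue
            if j > i and np.diff(pos[i:j + 1]).max() > p.max_gap_bp:
                continue
            n_snp = int(((w != 1) & (w != MISSING)).sum())
            length = int(pos[j] - pos[i] + 1)
            if n_snp < p.min_snp or length < p.min_length_bp:
                continue
            if n_snp / length < p.min_density_snp_per_bp:
                continue
            passing.append((i, j))
    maximal = [
        w for w in passing
        if not any(v != w and v[0] <= w[0] and w[1] <= v[1] for v in passing)
    ]
    kept = []
    for i, j in sorted(maximal,
                       key=lambda w: (-(pos[w[1]] - pos[w[0]]), pos[w[0]])):
        if all(j < a or i > b for a, b in kept):
            kept.append((i, j))
    return sorted(kept)


def scanner_windows(dosages, markers, p):
    segs = detect_roh(np.asarray(dosages, dtype=np.int8), markers, p)
    pos = markers.pos_bp
    return sorted(
        (int(np.searchsorted(pos, s.start_bp)), int(np.searchsorted(pos, s.end_bp)))
        for s in segs
    )


# --- planted examples --------------------------------------------------------

def _track(markers, hom_idx=(), het_idx=(), miss_idx=(), fill=1):
    d = np.full(len(markers), fill, dtype=np.int8)
    d[list(hom_idx)] = 2
    d[list(het_idx)] = 1
    d[list(miss_idx)] = MISSING
    return d


class TestDetectRoh:
    def test_planted_clean_run_detected(self):
        mmap = uniform_map(1, 40, spacing_bp=36_800, freq=None)  # 20 SNPs ~700kb
        d = _track(mmap, hom_idx=range(10, 30))
        segs = detect_roh(d, mmap, RohParams())
        assert len(segs) == 1
        s = segs[0]
        assert s.n_snp == 20
        assert s.start_bp == mmap.pos_bp[10] and s.end_bp == mmap.pos_bp[29]

    def test_two_internal_hets_split_the_run(self):
        mmap = uniform_map(1, 40, spacing_bp=36_800, freq=None)
        d = _track(mmap, hom_idx=range(5, 35))
        d[[15, 25]] = 1
        segs = detect_roh(d, mmap, RohParams())
        pos = mmap.pos_bp
        for s in segs:
            inside = (pos >= s.start_bp) & (pos <= s.end_bp)
            assert (d[inside] == 1).sum() <= 1

    def test_too_few_snps_rejected(self):
        mmap = uniform_map(1, 30, spacing_bp=43_000, freq=None)  # 14 SNPs ~600kb
        d = _track(mmap, hom_idx=range(8, 22))
        assert detect_roh(d, mmap, RohParams()) == []

    def test_too_short_rejected(self):
        mmap = uniform_map(1, 40, spacing_bp=26_500, freq=None)  # 16 SNPs ~400kb
        d = _track(mmap, hom_idx=range(10, 26))
        assert detect_roh(d, mmap, RohParams()) == []

    def test_gap_always_terminates_run(self):
        # 40 homozygous SNPs but a 1.5 Mbp hole in the middle
        pos = list(range(40_000, 40_000 * 21, 40_000))
        pos += [pos[-1] + 1_500_000 + k * 40_000 for k in range(20)]
        snp_id = [f"s{k}" for k in range(40)]
        from equidiv.genotypes import MarkerMap
        mmap = MarkerMap.from_arrays(snp_id, [1] * 40, pos)
        d = np.full(40, 2, dtype=np.int8)
        segs = detect_roh(d, mmap, RohParams())
        assert len(segs) == 2
        assert all(s.end_bp - s.start_bp < 1_000_000 for s in segs)

    def test_recode_invariance(self, rng):
        mmap = uniform_map(1, 120, freq=None)
        d = rng.choice([0, 1, 2, 2, 2], size=120).astype(np.int8)
        a = detect_roh(d, mmap, RohParams(min_snp=8, min_length_bp=200_000))
        sw = np.where(d != MISSING, 2 - d, MISSING).astype(np.int8)
        b = detect_roh(sw, mmap, RohParams(min_snp=8, min_length_bp=200_000))
        assert [(s.start_bp, s.end_bp) for s in a] == \
               [(s.start_bp, s.end_bp) for s in b]

    def test_relaxing_thresholds_never_loses_segments(self, rng):
        mmap = uniform_map(1, 150, freq=None)
        for _ in range(10):
            d = rng.choice([0, 1, 2, 2, 2, 2], size=150).astype(np.int8)
            strict = RohParams(min_snp=12, min_length_bp=400_000)
            loose = RohParams(min_snp=8, min_length_bp=250_000)
            assert len(detect_roh(d, mmap, loose)) >= \
                len(detect_roh(d, mmap, strict))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_tracks_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(60, 201))
        gaps = rng.exponential(40_000, size=m).astype(np.int64) + 1
        if seed % 2:  # occasionally include run-breaking gaps
            gaps[rng.integers(0, m, size=2)] += 1_200_000
        pos = np.cumsum(gaps)
        from equidiv.genotypes import MarkerMap
        mmap = MarkerMap.from_arrays([f"s{k}" for k in range(m)], [1] * m, pos)
        d = rng.choice([0, 1, 2, MISSING], p=[0.35, 0.12, 0.5, 0.03],
                       size=m).astype(np.int8)
        p = RohParams(min_snp=10, min_length_bp=300_000)
        assert scanner_windows(d, mmap, p) == oracle_windows(d, pos, p)

    def test_density_limited_case_matches_bruteforce(self):
        # sparse map where the density rule, not length, is binding
        rng = np.random.default_rng(42)
        m = 80
        pos = np.cumsum(rng.integers(60_000, 220_000, size=m))
        from equidiv.genotypes import MarkerMap
        mmap = MarkerMap.from_arrays([f"s{k}" for k in range(m)], [1] * m, pos)
        for seed in range(5):
            r2 = np.random.default_rng(seed)
            d = r2.choice([0, 1, 2, 2, 2, 2, 2], size=m).astype(np.int8)
            p = RohParams(min_snp=6, min_length_bp=300_000, max_gap_bp=2_000_000,
                          min_density_snp_per_bp=1 / 120_000)
            assert scanner_windows(d, mmap, p) == oracle_windows(d, pos, p)


class TestClassification:
    @pytest.mark.parametrize("length,expected", [
        (999_999, "0.5-1"),
        (1_000_000, "1-2"),
        (2_000_000, "2-4"),
        (7_999_999, "4-8"),
        (8_000_000, ">8"),
        (13_400_000, ">8"),
    ])
    def test_boundaries_promote_upward(self, length, expected):
        assert classify_length(length) == expected

    def test_below_floor_rejected(self):
        with pytest.raises(ValueError):
            classify_length(499_999)


class TestSummarize:
    def test_single_segment(self):
        seg = pd.DataFrame(
            [{"sample_id": "a", "chrom": 1, "start_bp": 1, "end_bp": 700_000,
              "n_snp": 20, "length_bp": 700_000, "length_class": "0.5-1"}])
        s = summarize_roh(seg, 1)["per_class"]
        row = s[s["length_class"] == "0.5-1"].iloc[0]
        assert row["percentage"] == 100.0 and row["s_roh"] == 1.0

    def test_matches_groupby_oracle(self, rng):
        n = 300
        seg = pd.DataFrame({
            "sample_id": rng.choice([f"i{k}" for k in range(12)], size=n),
            "chrom": rng.integers(1, 6, size=n),
            "length_bp": rng.integers(500_000, 12_000_000, size=n),
        })
        seg["start_bp"] = 1
        seg["end_bp"] = seg["length_bp"]
        seg["n_snp"] = 20
        seg["length_class"] = seg["length_bp"].map(classify_length)
        s = summarize_roh(seg, 12)["per_class"]
        for cls in LENGTH_CLASSES:
            sub = seg[seg["length_class"] == cls]
            row = s[s["length_class"] == cls].iloc[0]
            assert row["n_roh"] == len(sub)
            if len(sub):
                assert row["s_roh"] == pytest.approx(
                    len(sub) / sub["sample_id"].nunique())
                assert row["l_roh_mbp"] == pytest.approx(
                    sub["length_bp"].mean() / 1e6)

    def test_summary_revalidates_against_detection(self, rng):
        mmap = uniform_map(2, 150, freq=None)
        dos = rng.choice([0, 1, 2, 2, 2, 2], size=(6, 300)).astype(np.int8)
        g = matrix_from_rows(dos, mmap)
        segs = detect_roh_all(g, RohParams(min_snp=8, min_length_bp=250_000))
        for row in segs.itertuples(index=False):
            assert row.length_bp == row.end_bp - row.start_bp + 1
            if row.length_bp >= 500_000:
                assert row.length_class == classify_length(row.length_bp)
            else:
                assert row.length_class == "<0.5"
            sl = g.markers.chrom_slice(row.chrom)
            pos = g.markers.pos_bp[sl]
            i = np.searchsorted(pos, row.start_bp)
            j = np.searchsorted(pos, row.end_bp)
            track = dos[[int(row.sample_id[3:])], sl][0]
            assert row.n_snp == int(np.isin(track[i:j + 1], [0, 2]).sum())
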