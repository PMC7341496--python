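"""LD-based historical effective population size and its slope statistic.

The expected squared allele-dosage correlation between two loci at
recombination distance c Morgans in a population of effective size N is
approximately

    E[r2] = 1 / (alpha + 4 N c) + sample-size inflation,

with alpha the mutation-rate modifier (2.2 for the Sved & Feldman
correction, 2 for Ohta & Kimura, 1 for drift only).  Inverting the
relationship per distance bin gives an Ne estimate referring to
t = 1/(2 c) generations ago, so short distances probe the deep past and
long distances the recent past.

The slope statistic (NeS) normalizes the slope of each segment of the
Ne(t) curve by the median of the two slopes immediately deeper in time;
an affine trajectory is a flat line at 0, and excursions mark abrupt
changes in the rate of Ne change (e.g. bottlenecks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .inbreeding import DEFAULT_MBP_PER_CM

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["chrom", "snp_i", "snp_j", "distance_bp", "r2", "n_obs"]


def pairwise_r2(g: GenotypeMatrix, min_dist_bp: int = 500_000,
                max_dist_bp: int = 26_000_000, min_obs: int = 10) -> pd.DataFrame:
    """Squared dosage correlation for all within-chromosome SNP pairs with
    physical distance in [min_dist_bp, max_dist_bp].

    r2 is the squared Pearson correlation over pairwise-complete samples;
    pairs with zero variance at either SNP, or fewer than ``min_obs``
    complete observations, are skipped (with a logged count).
    """
    frames = []
    n_skipped = 0
    for chrom in g.markers.chromosomes():
        sl = g.markers.chrom_slice(chrom)
        pos = g.markers.pos_bp[sl]
        d = g.dosages[:, sl].astype(np.float64)
        mask = d != MISSING
        d[~mask] = 0.0
        m = pos.size
        if m < 2:
            continue
        mk = mask.astype(np.float64)
        n_ij = mk.T @ mk
        s_xy = d.T @ d
        s_x = d.T @ mk          # s_x[j,k] = sum over pairwise-complete of x_j
        s_xx = (d * d).T @ mk
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = n_ij * s_xy - s_x * s_x.T
            var_x = n_ij * s_xx - s_x ** 2
            r2 = cov ** 2 / (var_x * var_x.T)

        ii, jj = np.triu_indices(m, k=1)
        dist = pos[jj] - pos[ii]
        in_range = (dist >= min_dist_bp) & (dist <= max_dist_bp)
        ii, jj, dist = ii[in_range], jj[in_range], dist[in_range]
        ok = (
            (n_ij[ii, jj] >= max(min_obs, 2))
            & (var_x[ii, jj] > 0)
            & (var_x[jj, ii] > 0)
        )
        n_skipped += int((~ok).sum())
        ii, jj, dist = ii[ok], jj[ok], dist[ok]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": np.full(ii.size, chrom, dtype=np.int64),
                    "snp_i": ii.astype(np.int64),
                    "snp_j": jj.astype(np.int64),
                    "distance_bp": dist.astype(np.int64),
                    "r2": r2[ii, jj],
                    "n_obs": n_ij[ii, jj].astype(np.int64),
                }
            )
        )
    if n_skipped:
        logger.info("pairwise_r2: skipped %d pair(s) (few observations or "
                    "zero variance)", n_skipped)
    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def adjust_r2(mean_r2: float, n_samples: int, phased: bool = False,
              eps: float = 1e-9) -> float:
    """Sample-size correction of a mean r2.

    Unphased genotype data inflate r2 by ~1/n (n individuals); phased
    haplotype data by ~1/(2n).  The corrected value is floored at a small
    positive epsilon (with a warning) if the correction exceeds it.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    correction = 1.0 / (2.0 * n_samples) if phased else 1.0 / n_samples
    adj = mean_r2 - correction
    if adj <= 0:
        logger.warning("adjusted r2 non-positive (%g); floored at %g", adj, eps)
        return eps
    return adj


def distance_to_c(distance_bp: float, mbp_per_cm: float = DEFAULT_MBP_PER_CM,
                  mapping: str = "linear") -> float:
    """Physical distance to recombination distance in Morgans.

    ``linear``: c = bp / (mbp_per_cm * 1e6 * 100).  ``haldane`` and
    ``kosambi`` apply the standard map-function transform to the linear
    map distance.
    """
    if distance_bp <= 0:
        raise ValueError("distance must be positive")
    m = distance_bp / (mbp_per_cm * 1e6 * 100.0)
    if mapping == "linear":
        return m
    if mapping == "haldane":
        return 0.5 * (1.0 - np.exp(-2.0 * m))
    if mapping == "kosambi":
        return 0.5 * np.tanh(2.0 * m)
    raise ValueError(f"unknown mapping {mapping!r}")


NE_COLUMNS = ["bin", "n_pairs", "mean_distance_bp", "c", "t",
              "mean_r2", "mean_r2_adj", "ne"]


def estimate_ne(pairs: pd.DataFrame, n_samples: int, n_bins: int = 30,
                alpha: float = 2.2, phased: bool = False,
                min_dist_bp: int = 500_000, max_dist_bp: int = 26_000_000,
                mbp_per_cm: float = DEFAULT_MBP_PER_CM,
                mapping: str = "linear") -> pd.DataFrame:
    """Ne trajectory from binned pairwise LD.

    Pairs are partitioned into ``n_bins`` equal-width physical-distance
    bins on [min_dist_bp, max_dist_bp]; each bin contributes one estimate
    Ne = (1/(4 f(c))) * (1/mean_r2_adj - alpha) at t = 1/(2 f(c))
    generations ago, with c taken from the bin's mean distance.  Empty
    bins, and bins whose adjusted r2 is >= 1/alpha (non-positive Ne), are
    dropped with a log message.
    """
    if alpha not in (1.0, 2.0, 2.2):
        raise ValueError("alpha must be one of 1, 2, 2.2")
    if len(pairs) == 0:
        raise ValueError("no LD pairs to bin")
    edges = np.linspace(min_dist_bp, max_dist_bp, n_bins + 1)
    idx = np.clip(np.digitize(pairs["distance_bp"], edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sub = pairs.loc[idx == b]
        if len(sub) == 0:
            logger.info("bin %d empty; dropped", b)
            continue
        mean_r2 = float(sub["r2"].mean())
        r2_adj = adjust_r2(mean_r2, n_samples, phased=phased)
        c = distance_to_c(float(sub["distance_bp"].mean()), mbp_per_cm, mapping)
        if r2_adj >= 1.0 / alpha:
            logger.info("bin %d: adjusted r2 %.4f >= 1/alpha; no estimate",
                        b, r2_adj)
            continue
        rows.append(
            {
                "bin": b,
                "n_pairs": len(sub),
                "mean_distance_bp": float(sub["distance_bp"].mean()),
                "c": c,
                "t": 1.0 / (2.0 * c),
                "mean_r2": mean_r2,
                "mean_r2_adj": r2_adj,
                "ne": (1.0 / (4.0 * c)) * (1.0 / r2_adj - alpha),
            }
        )
    if not rows:
        raise ValueError("no valid distance bins")
    return pd.DataFrame(rows, columns=NE_COLUMNS)


NES_COLUMNS = ["t", "slope", "reference", "ratio", "nes"]


def nes_slopes(estimates: pd.DataFrame) -> pd.DataFrame:
    """Normalized-slope (NeS) points from an Ne trajectory.

    With estimates sorted by t ascending, slope_k spans (t_k, t_{k+1});
    its reference is the median of the two slopes immediately deeper in
    time (slope_{k+1}, slope_{k+2}) and nes_k = slope_k/reference_k - 1.
    The two deepest segments lack a reference and are omitted, as are
    points whose reference slope is exactly zero (flagged in the log).
    """
    if len(estimates) < 4:
        raise ValueError("need at least four Ne estimates")
    est = estimates.sort_values("t").reset_index(drop=True)
    t = est["t"].to_numpy(dtype=float)
    ne = est["ne"].to_numpy(dtype=float)
    slopes = np.diff(ne) / np.diff(t)
    rows = []
    for k in range(slopes.size - 2):
        ref = float(np.median(slopes[k + 1:k + 3]))
        if ref == 0.0:
            logger.warning("NeS point at t=%.3f undefined (zero reference "
                           "slope); omitted", t[k])
            continue
        ratio = float(slopes[k] / ref)
        rows.append({"t": float(t[k]), "slope": float(slopes[k]),
                     "reference": ref, "ratio": ratio, "nes": ratio - 1.0})
    return pd.DataFrame(rows, columns=NES_COLUMNS)


def filter_birth_cohort(g: GenotypeMatrix, year_min: int,
                        year_max: int) -> GenotypeMatrix:
    """Subset to samples whose birth year lies in [year_min, year_max].

    Samples without birth-year metadata are kept (the filter is a no-op
    when no metadata is present).
    """
    by = pd.to_numeric(g.samples.get("birth_year"), errors="coerce")
    keep = by.isna() | ((by >= year_min) & (by <= year_max))
    return g.subset(sample_idx=np.flatnonzero(keep.to_numpy()))
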