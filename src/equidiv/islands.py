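"""ROH islands: population-shared homozygous regions.

For every SNP the incidence track counts how many individuals have a run
of homozygosity spanning its position (each individual at most once per
SNP).  Islands are maximal stretches of consecutive SNPs whose sharing
fraction exceeds a threshold — 70% of individuals by default, with a
stricter 85% reporting tier conventionally used for functional follow-up.
Sharing is strict (fraction > threshold); a single below-threshold SNP
separates two islands.  Island coordinates are SNP positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genotypes import AnnotationSet, MarkerMap

ISLAND_COLUMNS = ["chrom", "start_bp", "end_bp", "length_kb", "n_snp",
                  "support_max", "support_min"]


def snp_incidence(segments: pd.DataFrame, markers: MarkerMap,
                  n_individuals: int) -> pd.DataFrame:
    """Per-SNP count and fraction of individuals covered by an ROH.

    A SNP is covered by an individual iff one of that individual's
    segments spans its position (1-based inclusive); overlapping segments
    from one individual count once.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    known = set(markers.chromosomes())
    if len(segments):
        bad = set(segments["chrom"].unique()) - known
        if bad:
            raise ValueError(f"segment chromosome(s) {sorted(bad)} absent from map")

    counts = np.zeros(len(markers), dtype=np.int64)
    pos = markers.pos_bp
    chrom_arr = markers.chrom
    if len(segments):
        for (sid, chrom), grp in segments.groupby(["sample_id", "chrom"]):
            sl = markers.chrom_slice(int(chrom))
            cpos = pos[sl]
            covered = np.zeros(cpos.size, dtype=bool)
            for start, end in grp[["start_bp", "end_bp"]].itertuples(index=False):
                lo = int(np.searchsorted(cpos, start, side="left"))
                hi = int(np.searchsorted(cpos, end, side="right"))
                covered[lo:hi] = True
            counts[sl] += covered
    return pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos_bp": pos,
            "n_covered": counts,
            "fraction": counts / n_individuals,
        }
    )


def call_islands(track: pd.DataFrame, threshold: float = 0.70,
                 strict: bool = True) -> pd.DataFrame:
    """Maximal runs of consecutive SNPs with sharing above the threshold.

    ``strict=True`` implements "more than X% of individuals" (fraction >
    threshold); set False for an inclusive (>=) mode.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    rows = []
    if len(track) == 0:
        return pd.DataFrame(columns=ISLAND_COLUMNS)
    for chrom, grp in track.groupby("chrom", sort=True):
        frac = grp["fraction"].to_numpy()
        cpos = grp["pos_bp"].to_numpy()
        above = frac > threshold if strict else frac >= threshold
        if not above.any():
            continue
        padded = np.concatenate(([False], above, [False])).astype(np.int8)
        starts = np.flatnonzero(np.diff(padded) == 1)
        ends = np.flatnonzero(np.diff(padded) == -1) - 1
        for a, b in zip(starts, ends):
            rows.append(
                {
                    "chrom": int(chrom),
                    "start_bp": int(cpos[a]),
                    "end_bp": int(cpos[b]),
                    "length_kb": (cpos[b] - cpos[a] + 1) / 1000.0,
                    "n_snp": int(b - a + 1),
                    "support_max": float(frac[a:b + 1].max()),
                    "support_min": float(frac[a:b + 1].min()),
                }
            )
    return pd.DataFrame(rows, columns=ISLAND_COLUMNS)


def overlap_annotations(islands: pd.DataFrame, ann: AnnotationSet) -> pd.DataFrame:
    """Attach overlapping feature lists to each island.

    Closed-interval intersection: features sharing at least one base pair
    with the island are reported, ordered by start position; islands with
    no overlap get an empty list.
    """
    trees: dict[int, IntervalTree] = {}
    for row in ann.table.itertuples(index=False):
        # IntervalTree is half-open; +1 on the end keeps closed-interval
        # semantics for 1-based inclusive coordinates.
        trees.setdefault(int(row.chrom), IntervalTree()).addi(
            int(row.start_bp), int(row.end_bp) + 1, str(row.feature_id)
        )
    out = islands.copy()
    features = []
    for row in islands.itertuples(index=False):
        tree = trees.get(int(row.chrom))
        if tree is None:
            features.append([])
            continue
        hits = tree.overlap(int(row.start_bp), int(row.end_bp) + 1)
        features.append([iv.data for iv in sorted(hits, key=lambda iv: iv.begin)])
    out["features"] = features
    return out
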