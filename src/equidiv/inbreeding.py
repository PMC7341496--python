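"""ROH-based genomic inbreeding.

F_ROH for an individual is the summed length of its runs of homozygosity
divided by the autosomal length covered by SNPs (L_AUTO):

    F_ROH = sum(L_ROH) / L_AUTO

Because the runs partition exactly into the five length classes, the
class-wise components (same genome-wide denominator) sum to the total.
Per-chromosome components are normalized by each chromosome's own covered
length, so they live on a comparable [0, 1] scale.

Run length also dates the inbreeding event: a segment of L Morgans points
to a common ancestor ~1/(2L) generations back; physical length converts
to map length through a genome-wide 1 cM = 1.24 Mbp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MarkerMap
from .roh import LENGTH_CLASSES

#: Genome-wide physical-to-map conversion used for horses.
DEFAULT_MBP_PER_CM: float = 1.24


@dataclass(frozen=True)
class FrohRecord:
    sample_id: str
    f_total: float
    f_by_class: dict[str, float]
    f_by_chromosome: dict[int, float]
    l_auto_bp: int


def compute_l_auto(markers: MarkerMap) -> int:
    """Autosomal length covered by SNPs: sum of per-chromosome spans.

    Chromosomes with fewer than two SNPs are excluded (with a warning from
    the map layer) since they cover no span.
    """
    return int(sum(markers.covered_lengths().values()))


def froh(segments: pd.DataFrame, l_auto_bp: int,
         chrom_lengths: dict[int, int] | None = None,
         sample_id: str | None = None) -> FrohRecord:
    """F_ROH record for one individual's segment table."""
    if l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    if len(segments) and segments["sample_id"].nunique() > 1:
        raise ValueError("froh expects segments from a single individual")
    sid = sample_id or (str(segments["sample_id"].iloc[0]) if len(segments) else "?")

    total_len = int(segments["length_bp"].sum()) if len(segments) else 0
    f_by_class = {}
    for cls in LENGTH_CLASSES:
        ln = segments.loc[segments["length_class"] == cls, "length_bp"].sum() \
            if len(segments) else 0
        f_by_class[cls] = float(ln) / l_auto_bp

    f_by_chrom: dict[int, float] = {}
    if chrom_lengths:
        for chrom, clen in chrom_lengths.items():
            ln = segments.loc[segments["chrom"] == chrom, "length_bp"].sum() \
                if len(segments) else 0
            if ln > clen:
                raise ValueError(
                    f"ROH length {ln} exceeds covered length {clen} on "
                    f"chromosome {chrom}"
                )
            f_by_chrom[chrom] = float(ln) / clen

    return FrohRecord(
        sample_id=sid,
        f_total=float(total_len) / l_auto_bp,
        f_by_class=f_by_class,
        f_by_chromosome=f_by_chrom,
        l_auto_bp=l_auto_bp,
    )


def froh_all(segments: pd.DataFrame, sample_ids, markers: MarkerMap,
             l_auto_bp: int | None = None) -> pd.DataFrame:
    """Per-individual F_ROH table (total, per class, per chromosome).

    ``l_auto_bp`` defaults to the SNP-covered autosome length of the map;
    pass an explicit value (e.g. 2,276,000,000 bp) to pin the denominator.
    """
    chrom_lengths = markers.covered_lengths()
    if l_auto_bp is None:
        l_auto_bp = int(sum(chrom_lengths.values()))
    rows = []
    for sid in sample_ids:
        sid = str(sid)
        sub = segments[segments["sample_id"] == sid] if len(segments) else segments
        rec = froh(sub, l_auto_bp, chrom_lengths, sample_id=sid)
        row = {"sample_id": sid, "f_total": rec.f_total, "l_auto_bp": rec.l_auto_bp}
        for cls in LENGTH_CLASSES:
            row[f"f_{cls}"] = rec.f_by_class[cls]
        for chrom in sorted(chrom_lengths):
            row[f"f_chr{chrom}"] = rec.f_by_chromosome[chrom]
        rows.append(row)
    return pd.DataFrame(rows)


def generations_ago(roh_length_mbp: float,
                    mbp_per_cm: float = DEFAULT_MBP_PER_CM) -> float:
    """Generations back to the inbreeding event implied by a run's length.

    A run of L Morgans dates to g = 1/(2L) generations ago; L in Morgans
    is length_mbp / (mbp_per_cm * 100).
    """
    if roh_length_mbp <= 0:
        raise ValueError("ROH length must be positive")
    l_morgan = roh_length_mbp / (mbp_per_cm * 100.0)
    return 1.0 / (2.0 * l_morgan)


@dataclass(frozen=True)
class ChromosomeMoments:
    chromosome: int
    mean: float
    sd: float
    skewness: float   # third standardized population moment
    kurtosis: float   # fourth standardized population moment (normal = 3)
    defined: bool = True


def chromosome_moments(values, chromosome: int = 0) -> ChromosomeMoments:
    """Population-moment skewness and (non-excess) kurtosis of per-sample
    inbreeding values on one chromosome.

    Uses plain moment ratios m3/m2^1.5 and m4/m2^2 (no bias correction), so
    a normal distribution has kurtosis 3 — matching the convention where
    kurtosis above three flags outlier individuals.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 values for skewness")
    sd = float(np.std(x))  # population SD
    if sd == 0.0:
        return ChromosomeMoments(chromosome, float(x.mean()), 0.0,
                                 float("nan"), float("nan"), defined=False)
    skew = float(stats.skew(x, bias=True))
    if x.size < 4:
        kurt = float("nan")
    else:
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    return ChromosomeMoments(chromosome, float(x.mean()), sd, skew, kurt)


def chromosome_moment_table(froh_table: pd.DataFrame) -> pd.DataFrame:
    """Moments of per-chromosome F_ROH across individuals (one row/chrom)."""
    rows = []
    for col in froh_table.columns:
        if not col.startswith("f_chr"):
            continue
        chrom = int(col[len("f_chr"):])
        m = chromosome_moments(froh_table[col].to_numpy(), chromosome=chrom)
        rows.append(
            {"chrom": chrom, "mean": m.mean, "sd": m.sd,
             "skewness": m.skewness, "kurtosis": m.kurtosis}
        )
    return pd.DataFrame(rows).sort_values("chrom").reset_index(drop=True)


def froh_class_summary(froh_table: pd.DataFrame) -> pd.DataFrame:
    """Mean/min/max/SD of F_ROH per length class plus a Total row."""
    rows = []
    for cls in LENGTH_CLASSES:
        col = froh_table[f"f_{cls}"]
        rows.append({"length_class": cls, "mean": col.mean(), "min": col.min(),
                     "max": col.max(), "sd": col.std(ddof=1)})
    col = froh_table["f_total"]
    rows.append({"length_class": "Total", "mean": col.mean(), "min": col.min(),
                 "max": col.max(), "sd": col.std(ddof=1)})
    return pd.DataFrame(rows)
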