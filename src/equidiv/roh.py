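"""Runs-of-homozygosity detection by the consecutive-runs method.

A run is a stretch of consecutive SNPs, anchored on homozygous non-missing
calls at both ends, that satisfies five constraints:

 (i)   at least ``min_snp`` homozygous SNPs in the run (15),
 (ii)  a minimum physical length (500 kb),
 (iii) no gap between consecutive SNPs larger than ``max_gap_bp`` (1000 kb),
 (iv)  a minimum SNP density (1 SNP per 100 kb), applied as the post-hoc
       filter n_snp / length >= density, and
 (v)   at most one heterozygous and one missing call inside the run.

Heterozygous/missing calls inside a run do not count toward (i) but do lie
inside the reported interval.  The scanner returns the maximal windows
satisfying all five rules; where maximal windows overlap (a single run
could absorb its one allowed heterozygote in either direction) the longest
window wins, with ties broken toward the smaller start coordinate, so the
segments reported per individual per chromosome are non-overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, MarkerMap

#: Length-class labels, 0.5-1 / 1-2 / 2-4 / 4-8 / >8 Mbp.
LENGTH_CLASSES: tuple[str, ...] = ("0.5-1", "1-2", "2-4", "4-8", ">8")
_CLASS_EDGES_BP = (500_000, 1_000_000, 2_000_000, 4_000_000, 8_000_000)

SEGMENT_COLUMNS = ["sample_id", "chrom", "start_bp", "end_bp", "n_snp",
                   "length_bp", "length_class"]


@dataclass(frozen=True)
class RohParams:
    min_snp: int = 15
    min_length_bp: int = 500_000
    max_gap_bp: int = 1_000_000
    min_density_snp_per_bp: float = 1.0 / 100_000
    max_het_in_run: int = 1
    max_miss_in_run: int = 1

    def __post_init__(self) -> None:
        if min(self.min_snp, self.min_length_bp, self.max_gap_bp) <= 0:
            raise ValueError("ROH parameters must be positive")
        if self.min_density_snp_per_bp <= 0:
            raise ValueError("density limit must be positive")


@dataclass(frozen=True)
class RohSegment:
    sample_id: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snp: int  # homozygous SNPs in the run

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_class(self) -> str:
        # runs below the class floor only exist under non-default parameters
        if self.length_bp < _CLASS_EDGES_BP[0]:
            return "<0.5"
        return classify_length(self.length_bp)


def classify_length(length_bp: int) -> str:
    """Length class of a run; classes are half-open, boundaries promote up."""
    if length_bp < _CLASS_EDGES_BP[0]:
        raise ValueError(f"length {length_bp} bp below the 0.5 Mbp class floor")
    idx = int(np.searchsorted(_CLASS_EDGES_BP[1:], length_bp, side="right"))
    return LENGTH_CLASSES[idx]


def _window_passes(pos: np.ndarray, is_hom: np.ndarray, is_het: np.ndarray,
                   is_miss: np.ndarray, i: int, j: int, p: RohParams) -> bool:
    """Check rules (i)-(v) for the SNP index window [i, j] directly."""
    if not (is_hom[i] and is_hom[j]):
        return False
    sl = slice(i, j + 1)
    if is_het[sl].sum() > p.max_het_in_run:
        return False
    if is_miss[sl].sum() > p.max_miss_in_run:
        return False
    if i < j and np.max(np.diff(pos[sl])) > p.max_gap_bp:
        return False
    n_snp = int(is_hom[sl].sum())
    length = int(pos[j] - pos[i] + 1)
    return (
        n_snp >= p.min_snp
        and length >= p.min_length_bp
        and n_snp / length >= p.min_density_snp_per_bp
    )


def _resolve_overlaps(windows: list[tuple[int, int]],
                      pos: np.ndarray) -> list[tuple[int, int]]:
    """Greedy selection: longest window first, ties toward smaller start."""
    order = sorted(windows, key=lambda w: (-(pos[w[1]] - pos[w[0]]), pos[w[0]]))
    kept: list[tuple[int, int]] = []
    for i, j in order:
        if all(j < a or i > b for a, b in kept):
            kept.append((i, j))
    return sorted(kept)


def _drop_contained(windows: set[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for w in windows:
        if not any(v != w and v[0] <= w[0] and w[1] <= v[1] for v in windows):
            out.append(w)
    return sorted(out)


def _scan_block(pos: np.ndarray, is_hom: np.ndarray, is_het: np.ndarray,
                is_miss: np.ndarray, lo: int, hi: int,
                p: RohParams) -> set[tuple[int, int]]:
    """All maximal passing windows inside the gap-free block [lo, hi]."""
    bad = [k for k in range(lo, hi + 1) if not is_hom[k]]
    hom_idx = np.flatnonzero(is_hom[lo:hi + 1]) + lo
    if hom_idx.size == 0:
        return set()
    hom_prefix = np.zeros(hi - lo + 2, dtype=np.int64)
    hom_prefix[1:] = np.cumsum(is_hom[lo:hi + 1])

    def n_hom(a: int, b: int) -> int:
        return int(hom_prefix[b - lo + 1] - hom_prefix[a - lo])

    def allowed(subset: list[int]) -> bool:
        return (
            sum(is_het[k] for k in subset) <= p.max_het_in_run
            and sum(is_miss[k] for k in subset) <= p.max_miss_in_run
        )

    # Candidate interior bad-call subsets: contiguous runs of bad calls of
    # size 0, 1 or 2 (one het plus one missing at most).
    subsets: list[tuple[int | None, int | None]] = []  # (prev_bad, next_bad)
    bounds = [lo - 1] + bad + [hi + 1]
    for k in range(len(bounds) - 1):
        subsets.append((bounds[k], bounds[k + 1]))  # empty interior
    for k, b in enumerate(bad):
        if allowed([b]):
            prev_b = bad[k - 1] if k > 0 else lo - 1
            next_b = bad[k + 1] if k + 1 < len(bad) else hi + 1
            subsets.append((prev_b, next_b))
    for k in range(len(bad) - 1):
        pair = [bad[k], bad[k + 1]]
        if allowed(pair):
            prev_b = bad[k - 1] if k > 0 else lo - 1
            next_b = bad[k + 2] if k + 2 < len(bad) else hi + 1
            subsets.append((prev_b, next_b))

    found: set[tuple[int, int]] = set()
    for prev_b, next_b in subsets:
        inside = hom_idx[(hom_idx > prev_b) & (hom_idx < next_b)]
        if inside.size == 0:
            continue
        i, j = int(inside[0]), int(inside[-1])
        n_snp = n_hom(i, j)
        length = int(pos[j] - pos[i] + 1)
        if n_snp < p.min_snp or length < p.min_length_bp:
            continue
        if n_snp / length >= p.min_density_snp_per_bp:
            found.add((i, j))
            continue
        # The full extent fails only the density rule; a denser sub-window
        # may still pass.  Enumerate homozygous endpoint pairs exactly.
        ext = inside
        for ai in range(ext.size):
            a = int(ext[ai])
            for bi in range(ext.size - 1, ai - 1, -1):
                b = int(ext[bi])
                ln = int(pos[b] - pos[a] + 1)
                if ln < p.min_length_bp:
                    break
                ns = n_hom(a, b)
                if ns < p.min_snp:
                    break
                if ns / ln >= p.min_density_snp_per_bp and _window_passes(
                    pos, is_hom, is_het, is_miss, a, b, p
                ):
                    found.add((a, b))
    return set(_drop_contained(found))


def detect_roh(dosages: np.ndarray, markers: MarkerMap, params: RohParams,
               sample_id: str = "sample") -> list[RohSegment]:
    """Detect ROH for one individual across all chromosomes of the map."""
    dosages = np.asarray(dosages)
    if dosages.shape != (len(markers),):
        raise ValueError("dosage track length does not match the marker map")
    segments: list[RohSegment] = []
    for chrom in markers.chromosomes():
        sl = markers.chrom_slice(chrom)
        pos = markers.pos_bp[sl]
        d = dosages[sl]
        is_miss = d == MISSING
        is_het = d == 1
        is_hom = ~is_miss & ~is_het

        # gap rule (iii): a gap > max_gap_bp can never be inside a run
        breaks = np.flatnonzero(np.diff(pos) > params.max_gap_bp)
        block_bounds = np.concatenate(([0], breaks + 1, [pos.size]))
        windows: set[tuple[int, int]] = set()
        for b in range(block_bounds.size - 1):
            lo, hi = int(block_bounds[b]), int(block_bounds[b + 1]) - 1
            if hi - lo + 1 >= params.min_snp:
                windows |= _scan_block(pos, is_hom, is_het, is_miss, lo, hi, params)
        for i, j in _resolve_overlaps(_drop_contained(windows), pos):
            segments.append(
                RohSegment(
                    sample_id=sample_id,
                    chrom=int(chrom),
                    start_bp=int(pos[i]),
                    end_bp=int(pos[j]),
                    n_snp=int(np.sum(is_hom[i:j + 1])),
                )
            )
    return segments


def detect_roh_all(g: GenotypeMatrix, params: RohParams = RohParams()) -> pd.DataFrame:
    """ROH for every individual, as a segment table (one row per run)."""
    rows = []
    for i in range(g.n_samples):
        sid = str(g.sample_ids[i])
        for s in detect_roh(g.dosages[i], g.markers, params, sample_id=sid):
            rows.append((s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_snp,
                         s.length_bp, s.length_class))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def summarize_roh(segments: pd.DataFrame, n_individuals: int) -> dict[str, pd.DataFrame]:
    """Descriptive statistics by length class and by chromosome.

    Per class: number of animals carrying at least one run in the class,
    total run count (N_ROH), percentage of all runs, mean runs per carrier
    animal (S_ROH) and mean run length in Mbp (L_ROH).
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    total = len(segments)
    class_rows = []
    for cls in LENGTH_CLASSES:
        sub = segments[segments["length_class"] == cls] if total else segments
        n_roh = len(sub)
        n_animals = sub["sample_id"].nunique() if n_roh else 0
        class_rows.append(
            {
                "length_class": cls,
                "n_animals": n_animals,
                "n_roh": n_roh,
                "percentage": 100.0 * n_roh / total if total else 0.0,
                "s_roh": n_roh / n_animals if n_animals else 0.0,
                "l_roh_mbp": sub["length_bp"].mean() / 1e6 if n_roh else 0.0,
            }
        )
    per_class = pd.DataFrame(class_rows)

    if total:
        per_chrom = (
            segments.groupby("chrom")
            .agg(n_roh=("length_bp", "size"), mean_length_mbp=("length_bp", "mean"))
            .reset_index()
        )
        per_chrom["mean_length_mbp"] /= 1e6
    else:
        per_chrom = pd.DataFrame(columns=["chrom", "n_roh", "mean_length_mbp"])
    return {"per_class": per_class, "per_chromosome": per_chrom}
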