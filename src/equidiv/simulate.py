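"""Synthetic genotype generators with known ground truth.

Three generators cover the three verification needs of the pipeline:

* :func:`make_panel` + :func:`plant_roh` — a medium-density SNP panel
  (defaults emulate a 65k equine array: 31 autosomes, ~40 kb mean
  spacing) with homozygous segments planted at known coordinates, for
  validating the ROH scanner against planted truth.
* :func:`gene_drop` — allele transmission down an explicit pedigree with
  recombination, tracking founder-haplotype labels so identity-by-descent
  (autozygosity) truth intervals are exact; validates F_ROH against
  pedigree expectations (e.g. full-sib offspring: 0.25).
* :func:`simulate_wf` — a forward-in-time diploid Wright-Fisher
  population with a piecewise-constant size history, for validating the
  LD-based Ne estimator.

Recombination uses a constant 1.24 Mbp/cM genome-wide map; crossovers are
modelled as independent interval switches with Haldane probabilities
r_i = (1 - exp(-2 d_i))/2 per inter-SNP interval of d_i Morgans.  All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, MarkerMap
from .inbreeding import DEFAULT_MBP_PER_CM

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PanelSpec:
    """Marker-panel layout: chromosomes, density, allele-frequency spectrum."""

    n_chromosomes: int = 31
    snps_per_chromosome: int = 2100
    mean_spacing_bp: float = 40_000.0
    maf_lo: float = 0.05
    maf_hi: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_spacing_bp <= 0:
            raise ValueError("spacing must be positive")
        if not (0.0 < self.maf_lo <= self.maf_hi <= 0.5):
            raise ValueError("MAF bounds must satisfy 0 < lo <= hi <= 0.5")


@dataclass(frozen=True)
class PlantedRohSpec:
    """Truth intervals per individual plus background genotype behaviour.

    ``truth`` maps sample index -> list of (chromosome, start_bp, end_bp),
    non-overlapping per individual.  Outside truth intervals genotypes are
    Hardy-Weinberg draws at each SNP's frequency; ``background_het``
    overrides the heterozygote probability (the remaining mass is split
    between the homozygotes in proportion p^2 : q^2).  When
    ``mark_boundaries`` is set, the two SNPs flanking each truth interval
    on each side are forced heterozygous so that planted boundaries are
    identifiable to within one inter-SNP spacing by any scanner that
    tolerates at most one heterozygote per run.
    """

    n_individuals: int
    truth: dict[int, list[tuple[int, int, int]]] = field(default_factory=dict)
    background_het: float | None = None
    missing_rate: float = 0.0
    mark_boundaries: bool = True

    def __post_init__(self) -> None:
        for ind, intervals in self.truth.items():
            by_chrom: dict[int, list[tuple[int, int]]] = {}
            for chrom, s, e in intervals:
                by_chrom.setdefault(chrom, []).append((s, e))
            for chrom, ivs in by_chrom.items():
                ivs = sorted(ivs)
                for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                    if s2 <= e1:
                        raise ValueError(
                            f"overlapping truth intervals for individual {ind} "
                            f"on chromosome {chrom}"
                        )


@dataclass(frozen=True)
class DemographySpec:
    """Piecewise-constant diploid population size history.

    ``epochs`` runs forward in time: [(n_e, n_generations), ...]; the
    final epoch's population parents the emitted sample.
    """

    epochs: tuple[tuple[int, int], ...]
    sample_size: int
    mbp_per_cm: float = DEFAULT_MBP_PER_CM

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("need at least one epoch")
        for n_e, g in self.epochs:
            if n_e < 2:
                raise ValueError("every epoch Ne must be >= 2")
            if g < 0:
                raise ValueError("epoch lengths must be non-negative")
        if self.sample_size > 2 * self.epochs[-1][0]:
            raise ValueError("sample_size exceeds 2 x final-epoch Ne")


@dataclass(frozen=True)
class Pedigree:
    """Pedigree records (id, sire, dam, generation); founders have None
    parents and parents precede offspring."""

    records: tuple[tuple[str, str | None, str | None, int], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pid, sire, dam, _gen in self.records:
            if (sire is None) != (dam is None):
                raise ValueError(f"{pid}: both parents must be known or unknown")
            for parent in (sire, dam):
                if parent is not None and parent not in seen:
                    raise ValueError(
                        f"{pid}: parent {parent} not defined earlier (pedigree "
                        "must be acyclic with parents preceding offspring)"
                    )
            if pid in seen:
                raise ValueError(f"duplicate id {pid}")
            seen.add(pid)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @classmethod
    def full_sib_trio(cls) -> "Pedigree":
        """Two founders, two full sibs, one full-sib-mating offspring
        (expected inbreeding 0.25)."""
        return cls(
            (
                ("F1", None, None, 0),
                ("F2", None, None, 0),
                ("S1", "F1", "F2", 1),
                ("S2", "F1", "F2", 1),
                ("X", "S1", "S2", 2),
            )
        )


def make_panel(spec: PanelSpec) -> MarkerMap:
    """Random marker map: exponential inter-SNP gaps, uniform MAF spectrum.

    The returned map carries a ``freq`` column (reference-allele
    frequency) used by the genotype generators.
    """
    rng = np.random.default_rng(spec.seed)
    snp_id, chrom, pos, freq = [], [], [], []
    for c in range(1, spec.n_chromosomes + 1):
        gaps = rng.exponential(spec.mean_spacing_bp, size=spec.snps_per_chromosome)
        positions = np.cumsum(np.maximum(1, np.round(gaps).astype(np.int64)))
        pos.extend(positions.tolist())
        chrom.extend([c] * spec.snps_per_chromosome)
        snp_id.extend(f"snp{c}_{k}" for k in range(spec.snps_per_chromosome))
        freq.extend(rng.uniform(spec.maf_lo, spec.maf_hi,
                                size=spec.snps_per_chromosome).tolist())
    return MarkerMap.from_arrays(snp_id, chrom, pos, freq=freq)


def _panel_freqs(markers: MarkerMap) -> np.ndarray:
    if "freq" not in markers.table.columns:
        raise ValueError("marker map lacks a 'freq' column (use make_panel)")
    return markers.table["freq"].to_numpy(dtype=float)


def _sample_frame(n: int, prefix: str = "ind") -> pd.DataFrame:
    return pd.DataFrame(
        {"sample_id": [f"{prefix}{i}" for i in range(n)],
         "sex": pd.NA, "birth_year": pd.NA}
    )


def plant_roh(markers: MarkerMap, spec: PlantedRohSpec,
              seed: int = 0) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Genotypes with homozygous segments planted at known coordinates.

    Returns the matrix and the truth table (sample_id, chrom, start_bp,
    end_bp, n_snp).  Truth intervals containing fewer than 15 SNPs are
    emitted with a warning (undetectable by scanners requiring 15 SNPs).
    """
    rng = np.random.default_rng(seed)
    p = _panel_freqs(markers)
    n, m = spec.n_individuals, len(markers)

    if spec.background_het is None:
        het_prob = 2.0 * p * (1.0 - p)
    else:
        het_prob = np.full(m, float(spec.background_het))
    hom_ref_share = p ** 2 / (p ** 2 + (1.0 - p) ** 2)

    u = rng.random((n, m))
    dos = np.where(
        u < het_prob,
        1,
        np.where(rng.random((n, m)) < hom_ref_share, 2, 0),
    ).astype(np.int8)

    pos, chrom_arr = markers.pos_bp, markers.chrom
    truth_rows = []
    for ind in sorted(spec.truth):
        for chrom, start, end in spec.truth[ind]:
            sl = markers.chrom_slice(chrom)
            in_iv = np.flatnonzero(
                (pos[sl] >= start) & (pos[sl] <= end)) + sl.start
            if in_iv.size < 15:
                logger.warning(
                    "truth interval %d:%d-%d for individual %d holds only "
                    "%d SNP(s)", chrom, start, end, ind, in_iv.size)
            allele = 2 if rng.random() < 0.5 else 0
            dos[ind, in_iv] = allele
            if spec.mark_boundaries and in_iv.size:
                lo = max(sl.start, in_iv[0] - 2)
                hi = min(sl.stop, in_iv[-1] + 3)
                dos[ind, lo:in_iv[0]] = 1
                dos[ind, in_iv[-1] + 1:hi] = 1
            truth_rows.append(
                {"sample_id": f"ind{ind}", "chrom": chrom, "start_bp": start,
                 "end_bp": end, "n_snp": int(in_iv.size)}
            )

    if spec.missing_rate > 0:
        dos[rng.random((n, m)) < spec.missing_rate] = MISSING

    g = GenotypeMatrix(_sample_frame(n), markers, dos)
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snp"]
    )
    return g, truth


# ---------------------------------------------------------------------------
# recombination machinery shared by gene_drop and simulate_wf


def _interval_morgans(pos: np.ndarray, mbp_per_cm: float) -> np.ndarray:
    return np.diff(pos) / (mbp_per_cm * 1e6 * 100.0)


def _switch_probs(pos: np.ndarray, mbp_per_cm: float) -> np.ndarray:
    """Haldane per-interval crossover probabilities."""
    return 0.5 * (1.0 - np.exp(-2.0 * _interval_morgans(pos, mbp_per_cm)))


def _make_gametes(haps: np.ndarray, parents: np.ndarray, r: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per parent index.

    ``haps``: (2P, m) parental haplotypes; ``parents``: (K,) diploid
    parent indices; ``r``: (m-1,) interval switch probabilities.
    """
    k, m = parents.size, haps.shape[1]
    start = rng.integers(0, 2, size=k)
    switches = rng.random((k, m - 1)) < r
    chooser = (start[:, None] + np.concatenate(
        [np.zeros((k, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1
    )) % 2
    h0 = haps[2 * parents]
    h1 = haps[2 * parents + 1]
    return np.where(chooser == 0, h0, h1)


def gene_drop(ped: Pedigree, markers: MarkerMap,
              seed: int = 0) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop founder haplotype labels down a pedigree with recombination.

    Founders receive two globally unique labels each; every meiosis
    recombines its parent's two label tracks.  The returned truth table
    lists the autozygous intervals (sample_id, chrom, start_bp, end_bp)
    where an individual's two labels coincide — the exact IBD ground truth
    for F_ROH validation.  Genotypes are realized by assigning each
    founder haplotype an allele per SNP from the panel frequency.
    """
    rng = np.random.default_rng(seed)
    p = _panel_freqs(markers)
    ids = ped.ids
    n = len(ids)
    founders = [pid for pid, s, d, _ in ped.records if s is None]
    n_founder_haps = 2 * len(founders)

    # founder haplotype alleles: (n_founder_haps, m)
    founder_alleles = (rng.random((n_founder_haps, m_ := len(markers))) < p).astype(
        np.int8
    )

    # per chromosome, label tracks at SNP resolution: (2n, m_chrom) int
    label_tracks: dict[int, np.ndarray] = {}
    index_of = {pid: k for k, pid in enumerate(ids)}
    for chrom in markers.chromosomes():
        sl = markers.chrom_slice(chrom)
        pos = markers.pos_bp[sl]
        r = _switch_probs(pos, DEFAULT_MBP_PER_CM)
        tracks = np.zeros((2 * n, pos.size), dtype=np.int64)
        fcount = 0
        for pid, sire, dam, _gen in ped.records:
            k = index_of[pid]
            if sire is None:
                tracks[2 * k] = 2 * fcount
                tracks[2 * k + 1] = 2 * fcount + 1
                fcount += 1
            else:
                for gi, parent in enumerate((sire, dam)):
                    pk = index_of[parent]
                    tracks[2 * k + gi] = _make_gametes(
                        tracks[2 * pk:2 * pk + 2] ,
                        np.zeros(1, dtype=np.int64), r, rng
                    )[0]
        label_tracks[chrom] = tracks

    # genotypes: dosage = allele(label of gamete 1) + allele(label of gamete 2)
    dos = np.empty((n, len(markers)), dtype=np.int8)
    truth_rows = []
    for chrom in markers.chromosomes():
        sl = markers.chrom_slice(chrom)
        pos = markers.pos_bp[sl]
        tracks = label_tracks[chrom]
        cols = np.arange(sl.start, sl.stop)
        for k in range(n):
            lab0, lab1 = tracks[2 * k], tracks[2 * k + 1]
            a0 = founder_alleles[lab0, cols]
            a1 = founder_alleles[lab1, cols]
            dos[k, sl] = a0 + a1
            auto = lab0 == lab1
            if auto.any():
                padded = np.concatenate(([False], auto, [False])).astype(np.int8)
                starts = np.flatnonzero(np.diff(padded) == 1)
                ends = np.flatnonzero(np.diff(padded) == -1) - 1
                for a, b in zip(starts, ends):
                    truth_rows.append(
                        {"sample_id": ids[k], "chrom": int(chrom),
                         "start_bp": int(pos[a]), "end_bp": int(pos[b])}
                    )

    samples = pd.DataFrame(
        {"sample_id": ids, "sex": pd.NA, "birth_year": pd.NA}
    )
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "chrom", "start_bp", "end_bp"]
    )
    return GenotypeMatrix(samples, markers, dos), truth


def autozygous_fraction(truth: pd.DataFrame, markers: MarkerMap,
                        sample_id: str) -> float:
    """Fraction of the SNP-covered genome autozygous for one individual."""
    total = sum(markers.covered_lengths().values())
    sub = truth[truth["sample_id"] == sample_id]
    covered = (sub["end_bp"] - sub["start_bp"] + 1).sum() if len(sub) else 0
    return float(covered) / total


def simulate_wf(dem: DemographySpec, markers: MarkerMap,
                seed: int = 0) -> GenotypeMatrix:
    """Forward diploid Wright-Fisher simulation over a marker panel.

    Random mating (monoecious, selfing allowed), no mutation or selection;
    initial haplotypes are independent Bernoulli draws at the panel
    frequencies.  After the last epoch, ``sample_size`` offspring of the
    final population are emitted.  SNPs that drift to fixation are
    retained (downstream QC removes them).
    """
    rng = np.random.default_rng(seed)
    p = _panel_freqs(markers)
    chroms = markers.chromosomes()
    slices = {c: markers.chrom_slice(c) for c in chroms}
    rs = {c: _switch_probs(markers.pos_bp[slices[c]], dem.mbp_per_cm)
          for c in chroms}

    n0 = dem.epochs[0][0]
    haps = {c: (rng.random((2 * n0, slices[c].stop - slices[c].start))
                < p[slices[c]]).astype(np.int8) for c in chroms}

    def next_generation(n_off: int) -> dict[int, np.ndarray]:
        n_par = next(iter(haps.values())).shape[0] // 2
        sires = rng.integers(0, n_par, size=n_off)
        dams = rng.integers(0, n_par, size=n_off)
        out: dict[int, np.ndarray] = {}
        for c in chroms:
            g1 = _make_gametes(haps[c], sires, rs[c], rng)
            g2 = _make_gametes(haps[c], dams, rs[c], rng)
            out[c] = np.empty((2 * n_off, g1.shape[1]), dtype=np.int8)
            out[c][0::2] = g1
            out[c][1::2] = g2
        return out

    for n_e, n_gen in dem.epochs:
        for _ in range(n_gen):
            haps = next_generation(n_e)

    sample = next_generation(dem.sample_size)
    dos = np.empty((dem.sample_size, len(markers)), dtype=np.int8)
    for c in chroms:
        dos[:, slices[c]] = sample[c][0::2] + sample[c][1::2]
    return GenotypeMatrix(_sample_frame(dem.sample_size), markers, dos)
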