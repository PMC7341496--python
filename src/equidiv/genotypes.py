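"""Core genotype data model.

Genotypes are stored as allele-dosage matrices (individuals x SNPs) with
entries in {0, 1, 2} counting copies of a declared reference allele, and a
distinct sentinel (:data:`MISSING` = -1) for no-calls — 0 is a valid
homozygote and is never reused for missing data.

Coordinates are 1-based inclusive throughout the package; conversion from
half-open 0-based BED happens only at the I/O boundary (:mod:`equidiv.plink`).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

#: Default autosome labels (horse karyotype: 31 autosomes).
DEFAULT_AUTOSOMES: tuple[int, ...] = tuple(range(1, 32))


class GenotypeError(ValueError):
    """Raised for inconsistent genotype containers or malformed inputs."""


@dataclass(frozen=True)
class MarkerMap:
    """SNP map: identifiers, chromosome labels, physical positions, alleles.

    Wraps a DataFrame with columns ``snp_id``, ``chrom``, ``pos_bp``,
    ``a1``, ``a2`` (and optionally ``freq`` for synthetic panels), sorted
    canonically by (chromosome, position).
    """

    table: pd.DataFrame
    autosomes: tuple[int, ...] = DEFAULT_AUTOSOMES

    REQUIRED = ("snp_id", "chrom", "pos_bp", "a1", "a2")

    def __post_init__(self) -> None:
        missing_cols = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing_cols:
            raise GenotypeError(f"marker table lacks columns {missing_cols}")
        t = self.table
        if t["snp_id"].duplicated().any():
            dup = t.loc[t["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise GenotypeError(f"duplicated snp_id {dup!r}")
        if (t["pos_bp"] < 1).any():
            raise GenotypeError("positions must be >= 1")
        bad_chrom = set(t["chrom"].unique()) - set(self.autosomes)
        if bad_chrom:
            raise GenotypeError(f"non-autosomal chromosome labels {sorted(bad_chrom)}")
        order = np.lexsort((t["pos_bp"].to_numpy(), t["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(t))):
            raise GenotypeError("markers must be sorted by (chromosome, position)")
        for chrom, grp in t.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise GenotypeError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @classmethod
    def from_arrays(cls, snp_id, chrom, pos_bp, a1=None, a2=None, freq=None,
                    autosomes: tuple[int, ...] = DEFAULT_AUTOSOMES) -> "MarkerMap":
        n = len(snp_id)
        df = pd.DataFrame(
            {
                "snp_id": list(snp_id),
                "chrom": np.asarray(chrom, dtype=np.int64),
                "pos_bp": np.asarray(pos_bp, dtype=np.int64),
                "a1": list(a1) if a1 is not None else ["A"] * n,
                "a2": list(a2) if a2 is not None else ["B"] * n,
            }
        )
        if freq is not None:
            df["freq"] = np.asarray(freq, dtype=float)
        df = df.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)
        return cls(df, autosomes=autosomes)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.table["pos_bp"].to_numpy()

    @property
    def snp_id(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    def chromosomes(self) -> list[int]:
        """Chromosome labels present, in canonical order."""
        return list(pd.unique(self.table["chrom"]))

    def chrom_slice(self, chrom: int) -> slice:
        """Column slice covering one chromosome (markers are sorted)."""
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            raise GenotypeError(f"chromosome {chrom} absent from map")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def covered_lengths(self) -> dict[int, int]:
        """Per-chromosome SNP-covered span (max - min + 1 bp); needs >= 2 SNPs."""
        out: dict[int, int] = {}
        for chrom, grp in self.table.groupby("chrom", sort=True):
            if len(grp) < 2:
                logger.warning(
                    "chromosome %s has <2 SNPs; excluded from covered length", chrom
                )
                continue
            pos = grp["pos_bp"].to_numpy()
            out[int(chrom)] = int(pos.max() - pos.min() + 1)
        return out

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[idx].reset_index(drop=True),
                         autosomes=self.autosomes)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-dosage matrix plus sample metadata and map.

    ``dosages[i, j]`` counts copies of marker ``j``'s reference allele
    (``a1``) carried by sample ``i``; :data:`MISSING` marks no-calls.
    """

    samples: pd.DataFrame  # columns: sample_id, sex (opt), birth_year (opt)
    markers: MarkerMap
    dosages: np.ndarray  # int8, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        if "sample_id" not in self.samples.columns:
            raise GenotypeError("samples table lacks 'sample_id'")
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise GenotypeError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        valid = np.isin(self.dosages, (MISSING, 0, 1, 2))
        if not valid.all():
            raise GenotypeError("dosages must be in {0,1,2} or MISSING (-1)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.markers)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["sample_id"].to_numpy()

    def recode(self) -> "GenotypeMatrix":
        """Swap the reference allele at every marker (d -> 2 - d).

        Homozygosity, allele-frequency folding and |r| are invariant under
        this recoding; it exists to assert exactly that.
        """
        d = self.dosages.copy()
        nm = d != MISSING
        d[nm] = 2 - d[nm]
        t = self.markers.table.copy()
        t[["a1", "a2"]] = t[["a2", "a1"]].to_numpy()
        return GenotypeMatrix(self.samples.copy(),
                              MarkerMap(t, autosomes=self.markers.autosomes), d)

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            self.samples.iloc[si].reset_index(drop=True),
            self.markers.subset(mi),
            self.dosages[np.ix_(si, mi)],
        )


@dataclass(frozen=True)
class AnnotationSet:
    """Genomic feature intervals (genes, QTL, other), 1-based inclusive."""

    table: pd.DataFrame  # chrom, start_bp, end_bp, feature_id, feature_class

    REQUIRED = ("chrom", "start_bp", "end_bp", "feature_id", "feature_class")

    def __post_init__(self) -> None:
        missing_cols = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing_cols:
            raise GenotypeError(f"annotation table lacks columns {missing_cols}")
        if (self.table["end_bp"] < self.table["start_bp"]).any():
            raise GenotypeError("annotation with end < start")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def empty(cls) -> "AnnotationSet":
        return cls(pd.DataFrame({c: [] for c in cls.REQUIRED}))
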