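"""PLINK-format genotype I/O and annotation-interval readers.

Supports the two classic PLINK dialects: text PED/MAP and binary
BED/BIM/FAM (v1.00 magic ``0x6c 0x1b``, SNP-major mode ``0x01``, two bits
per genotype, each SNP padded to a byte boundary).  Non-autosomal markers
(X, Y, MT, unplaced) are dropped at read time with a logged count, and
markers are always returned in canonical (chromosome, position) order;
sample order is never changed.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import (
    DEFAULT_AUTOSOMES,
    MISSING,
    AnnotationSet,
    GenotypeMatrix,
    MarkerMap,
)

logger = logging.getLogger(__name__)

BED_MAGIC = bytes((0x6C, 0x1B))
SNP_MAJOR = 0x01

# 2-bit BED codes -> dosage of allele a1 (00 hom a1, 01 missing, 10 het, 11 hom a2)
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkParseError(ValueError):
    """Malformed PED/MAP/BIM/FAM content."""


class PlinkFormatError(ValueError):
    """Binary BED structure violation (magic bytes, mode, payload size)."""


def _parse_chrom(label: str) -> int | None:
    """Numeric autosome label, or None for anything else (X/Y/MT/0/...)."""
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    try:
        return int(s)
    except ValueError:
        return None


def _read_map_table(map_path, autosomes, n_meta_cols=4):
    rows = []
    dropped = 0
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < n_meta_cols:
                raise PlinkParseError(
                    f"{map_path}: line {lineno}: expected >= {n_meta_cols} columns, "
                    f"got {len(parts)}"
                )
            chrom = _parse_chrom(parts[0])
            keep = chrom is not None and chrom in autosomes
            if not keep:
                dropped += 1
            a1, a2 = (parts[4], parts[5]) if len(parts) >= 6 else ("0", "0")
            rows.append((parts[1], chrom if keep else -1, int(parts[3]), a1, a2, keep))
    if dropped:
        logger.info("%s: dropped %d non-autosomal marker(s)", map_path, dropped)
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp", "a1", "a2", "keep"])
    dup = df.loc[df["keep"], "snp_id"]
    if dup.duplicated().any():
        raise PlinkParseError(
            f"{map_path}: duplicated snp_id {dup[dup.duplicated()].iloc[0]!r}"
        )
    return df, dropped


def read_plink_text(ped_path, map_path,
                    autosomes: tuple[int, ...] = DEFAULT_AUTOSOMES) -> GenotypeMatrix:
    """Read a PED/MAP pair.

    Dosages are encoded against the first allele observed per SNP while
    scanning samples in file order; ``0 0`` pairs become missing.
    """
    map_df, _ = _read_map_table(map_path, autosomes)
    n_snps_file = len(map_df)

    sample_rows = []
    allele_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps_file:
                raise PlinkParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_snps_file} "
                    f"columns for {n_snps_file} SNPs, got {len(parts)}"
                )
            sample_rows.append(parts[:6])
            allele_rows.append(parts[6:])
    if not sample_rows:
        raise PlinkParseError(f"{ped_path}: no samples")

    alleles = np.array(allele_rows, dtype="U2").reshape(len(sample_rows), n_snps_file, 2)
    keep = map_df["keep"].to_numpy()
    alleles = alleles[:, keep, :]
    map_df = map_df.loc[keep].drop(columns="keep").reset_index(drop=True)

    n, m = alleles.shape[:2]
    dos = np.full((n, m), MISSING, dtype=np.int8)
    a1_list, a2_list = [], []
    for j in range(m):
        col = alleles[:, j, :]
        nonzero = col[col != "0"]
        ref = nonzero[0] if nonzero.size else "0"
        alt_candidates = nonzero[nonzero != ref]
        alt = alt_candidates[0] if alt_candidates.size else "0"
        called = (col != "0").all(axis=1)
        dos[called, j] = (col[called] == ref).sum(axis=1)
        a1_list.append(ref)
        a2_list.append(alt)
    map_df["a1"] = a1_list
    map_df["a2"] = a2_list

    order = np.lexsort((map_df["pos_bp"].to_numpy(), map_df["chrom"].to_numpy()))
    markers = MarkerMap(map_df.iloc[order].reset_index(drop=True), autosomes=autosomes)
    samples = _samples_from_fam_rows(sample_rows)
    return GenotypeMatrix(samples, markers, dos[:, order])


def _samples_from_fam_rows(rows):
    df = pd.DataFrame(rows, columns=["fid", "sample_id", "pat", "mat", "sex", "pheno"])
    sex = pd.to_numeric(df["sex"], errors="coerce")
    df["sex"] = sex.where(sex.isin([1, 2]))
    if df["sample_id"].duplicated().any():
        raise PlinkParseError("duplicated sample_id in pedigree columns")
    return df[["sample_id", "sex"]].assign(birth_year=pd.NA)


def write_plink_text(g: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    prefix = Path(prefix)
    ped_path, map_path = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    t = g.markers.table
    with open(map_path, "w") as fh:
        for row in t.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos_bp}\n")
    a1 = t["a1"].to_numpy()
    a2 = np.where(t["a2"].to_numpy() == "0", a1, t["a2"].to_numpy())
    with open(ped_path, "w") as fh:
        for i, srow in enumerate(g.samples.itertuples(index=False)):
            sex = int(srow.sex) if pd.notna(srow.sex) else 0
            fields = [str(srow.sample_id), str(srow.sample_id), "0", "0", str(sex), "-9"]
            d = g.dosages[i]
            for j in range(g.n_snps):
                if d[j] == MISSING:
                    fields += ["0", "0"]
                elif d[j] == 2:
                    fields += [a1[j], a1[j]]
                elif d[j] == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def write_plink_binary(g: GenotypeMatrix, prefix) -> tuple[Path, Path, Path]:
    """Write BED/BIM/FAM (SNP-major v1.00 layout, 2 bits per genotype)."""
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")

    t = g.markers.table
    with open(bim_path, "w") as fh:
        for row in t.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos_bp}\t{row.a1}\t{row.a2}\n")
    with open(fam_path, "w") as fh:
        for srow in g.samples.itertuples(index=False):
            sex = int(srow.sex) if pd.notna(srow.sex) else 0
            fh.write(f"{srow.sample_id} {srow.sample_id} 0 0 {sex} -9\n")

    n = g.n_samples
    codes = np.empty((g.n_snps, n), dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_BED_CODE.items():
        codes[(g.dosages.T == dosage)] = code
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((g.n_snps, pad), dtype=np.uint8)], axis=1
        )
    quads = codes.reshape(g.n_snps, -1, 4)
    payload = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(BED_MAGIC + bytes([SNP_MAJOR]))
        fh.write(payload.tobytes())
    return bed_path, bim_path, fam_path


def read_plink_binary(bed_path, bim_path, fam_path,
                      autosomes: tuple[int, ...] = DEFAULT_AUTOSOMES) -> GenotypeMatrix:
    fam_rows = []
    with open(fam_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise PlinkParseError(f"{fam_path}: line {lineno}: expected 6 columns")
            fam_rows.append(parts)
    if not fam_rows:
        raise PlinkParseError(f"{fam_path}: no samples")
    samples = _samples_from_fam_rows(fam_rows)
    n = len(samples)

    map_df, _ = _read_map_table(bim_path, autosomes, n_meta_cols=6)
    m_file = len(map_df)

    raw = Path(bed_path).read_bytes()
    if raw[:2] != BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if len(raw) < 3 or raw[2] != SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: not SNP-major (mode byte != 0x01)")
    bytes_per_snp = math.ceil(n / 4)
    expected = 3 + bytes_per_snp * m_file
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: payload is {len(raw) - 3} bytes, expected "
            f"{expected - 3} for {n} samples x {m_file} SNPs"
        )
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m_file, bytes_per_snp)
    codes = np.empty((m_file, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (payload >> (2 * k)) & 0b11
    dos = _BED_CODE_TO_DOSAGE[codes[:, :n]].T  # (n, m_file)

    keep = map_df["keep"].to_numpy()
    map_df = map_df.loc[keep].drop(columns="keep").reset_index(drop=True)
    dos = dos[:, keep]
    order = np.lexsort((map_df["pos_bp"].to_numpy(), map_df["chrom"].to_numpy()))
    markers = MarkerMap(map_df.iloc[order].reset_index(drop=True), autosomes=autosomes)
    return GenotypeMatrix(samples, markers, dos[:, order])


def read_annotations(path, fmt: str) -> AnnotationSet:
    """Read feature intervals from BED4+ or GFF3.

    BED's half-open 0-based coordinates are converted to 1-based inclusive
    (start+1, end); GFF3 coordinates are kept as-is.  Records that end
    before they start after conversion are rejected with a warning.
    """
    fmt = fmt.upper()
    if fmt not in {"BED", "GFF3"}:
        raise ValueError(f"unrecognized annotation format {fmt!r}")
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return AnnotationSet.empty()
    records = []
    if fmt == "BED":
        for row in df.itertuples(index=False):
            chrom = _parse_chrom(row[0])
            start, end = int(row[1]) + 1, int(row[2])
            name = row[3] if len(row) > 3 and pd.notna(row[3]) else f"{row[0]}:{row[1]}"
            klass = row[4] if len(row) > 4 and pd.notna(row[4]) else "other"
            if klass not in {"gene", "QTL", "other"}:
                klass = "other"
            if end < start or chrom is None:
                logger.warning("rejected BED record %s:%s-%s", row[0], row[1], row[2])
                continue
            records.append((chrom, start, end, name, klass))
    else:  # GFF3
        for row in df.itertuples(index=False):
            if len(row) < 9:
                logger.warning("rejected short GFF3 record %r", tuple(row))
                continue
            chrom = _parse_chrom(row[0])
            ftype = str(row[2])
            start, end = int(row[3]), int(row[4])
            attrs = dict(
                kv.split("=", 1) for kv in str(row[8]).split(";") if "=" in kv
            )
            name = attrs.get("ID", attrs.get("Name", f"{row[0]}:{row[3]}"))
            if ftype == "gene":
                klass = "gene"
            elif "qtl" in ftype.lower():
                klass = "QTL"
            else:
                klass = "other"
            if end < start or chrom is None:
                logger.warning("rejected GFF3 record %s:%s-%s", row[0], start, end)
                continue
            records.append((chrom, start, end, name, klass))
    if not records:
        return AnnotationSet.empty()
    out = pd.DataFrame(
        records, columns=["chrom", "start_bp", "end_bp", "feature_id", "feature_class"]
    )
    return AnnotationSet(out)
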