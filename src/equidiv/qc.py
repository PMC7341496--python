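"""SNP-array quality control.

Filters, in a fixed documented order: SNP call rate, Hardy-Weinberg exact
test, minor allele frequency, then sample call rate.  Defaults match
common practice for medium-density livestock panels: call rates >= 0.90,
HWE p >= 1e-6, MAF >= 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix


class EmptyAfterQcError(ValueError):
    """All SNPs or all samples were removed by quality control."""


@dataclass(frozen=True)
class QcThresholds:
    snp_call_rate_min: float = 0.90
    sample_call_rate_min: float = 0.90
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "sample_call_rate_min", "hwe_p_min",
                     "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class QcReport:
    """Removal counts per criterion, in application order."""

    steps: list[tuple[str, str, int]] = field(default_factory=list)  # (axis, name, n)
    n_snps_in: int = 0
    n_samples_in: int = 0
    n_snps_out: int = 0
    n_samples_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.steps, columns=["axis", "criterion", "n_removed"])
        return df

    def removed(self, criterion: str) -> int:
        return sum(n for _, name, n in self.steps if name == criterion)


def snp_call_rate(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per SNP."""
    if g.n_samples < 1:
        raise ValueError("need at least one sample")
    return (g.dosages != MISSING).mean(axis=0)


def sample_call_rate(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per sample."""
    if g.n_snps < 1:
        raise ValueError("need at least one SNP")
    return (g.dosages != MISSING).mean(axis=1)


def minor_allele_frequency(g: GenotypeMatrix) -> np.ndarray:
    """Folded allele frequency min(p, 1-p) per SNP.

    SNPs with no non-missing calls get MAF 0 (undefined; they are flagged
    by the call-rate filter anyway).
    """
    d = g.dosages
    called = d != MISSING
    n_called = called.sum(axis=0)
    totals = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, totals / (2.0 * np.maximum(n_called, 1)), 0.0)
    return np.minimum(p, 1.0 - p)


def hwe_exact_pvalue(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton et al. 2005).

    Conditions on the observed minor-allele count: the p-value sums the
    probabilities of every heterozygote count with the same sample size,
    same minor-allele count and matching parity whose conditional
    probability does not exceed that of the observed count.  No mid-p
    correction is applied.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("need at least one genotype")
    n_minor = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)

    # Conditional distribution of the het count given (n, n_minor):
    # P(h) ∝ 2^h * n! / (hom_minor! hom_major! h!); computed in log space.
    het_counts = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - het_counts) // 2
    hom_major = n - het_counts - hom_minor
    logp = (
        het_counts * np.log(2.0)
        - gammaln(hom_minor + 1)
        - gammaln(hom_major + 1)
        - gammaln(het_counts + 1)
    )
    probs = np.exp(logp - logp.max())
    total = probs.sum()
    obs_idx = int(np.searchsorted(het_counts, n_het))
    if obs_idx >= het_counts.size or het_counts[obs_idx] != n_het:
        raise ValueError(
            f"heterozygote count {n_het} unattainable for minor-allele "
            f"count {n_minor} in {n} genotypes"
        )
    p_obs = probs[obs_idx]
    pval = probs[probs <= p_obs * (1 + 1e-12)].sum() / total
    return float(min(1.0, pval))


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p-value per SNP (1.0 for SNPs with no calls)."""
    d = g.dosages
    out = np.ones(g.n_snps)
    n_hom1 = (d == 2).sum(axis=0)
    n_het = (d == 1).sum(axis=0)
    n_hom2 = (d == 0).sum(axis=0)
    for j in range(g.n_snps):
        n = n_hom1[j] + n_het[j] + n_hom2[j]
        if n >= 1:
            out[j] = hwe_exact_pvalue(int(n_hom1[j]), int(n_het[j]), int(n_hom2[j]))
    return out


def apply_qc(g: GenotypeMatrix,
             t: QcThresholds = QcThresholds()) -> tuple[GenotypeMatrix, QcReport]:
    """Apply all filters in order and report removals per step.

    Order: SNP call rate -> HWE -> MAF -> sample call rate.  MAF and HWE
    are computed on post-call-rate, pre-sample-filter data.
    """
    report = QcReport(n_snps_in=g.n_snps, n_samples_in=g.n_samples)

    keep = snp_call_rate(g) >= t.snp_call_rate_min
    report.steps.append(("snp", "snp_call_rate", int((~keep).sum())))
    g = g.subset(snp_idx=np.flatnonzero(keep))

    if g.n_snps:
        keep = hwe_pvalues(g) >= t.hwe_p_min
        report.steps.append(("snp", "hwe", int((~keep).sum())))
        g = g.subset(snp_idx=np.flatnonzero(keep))
    else:
        report.steps.append(("snp", "hwe", 0))

    if g.n_snps:
        keep = minor_allele_frequency(g) >= t.maf_min
        report.steps.append(("snp", "maf", int((~keep).sum())))
        g = g.subset(snp_idx=np.flatnonzero(keep))
    else:
        report.steps.append(("snp", "maf", 0))

    if g.n_snps == 0:
        raise EmptyAfterQcError("no SNPs survive quality control")

    keep = sample_call_rate(g) >= t.sample_call_rate_min
    report.steps.append(("sample", "sample_call_rate", int((~keep).sum())))
    g = g.subset(sample_idx=np.flatnonzero(keep))
    if g.n_samples == 0:
        raise EmptyAfterQcError("no samples survive quality control")

    report.n_snps_out = g.n_snps
    report.n_samples_out = g.n_samples
    return g, report
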