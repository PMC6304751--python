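"""Marker and animal quality control applied before the deficiency scan.

Animals failing the call-rate threshold are removed first; SNP statistics
(call rate, MAF, Hardy-Weinberg chi-square) are then computed on the
surviving animals, from called genotypes only.  The HWE filter is the
3-genotype-class Pearson chi-square against expectations at the observed
allele frequency, removed when the statistic reaches the threshold
(strict "less than" retention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING_ALLELE, PhasedGenotypes, SnpMap

AUTOSOMES = {str(i) for i in range(1, 40)}  # numeric labels; covers pig 1..18


@dataclass
class QcThresholds:
    animal_call_rate_min: float = 0.95
    snp_call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_chisq_max: float = 600.0
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        for r in (self.animal_call_rate_min, self.snp_call_rate_min, self.maf_min):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rate thresholds must lie in [0, 1]")
        if self.hwe_chisq_max <= 0:
            raise ValueError("HWE chi-square threshold must be positive")


def hwe_chisq(n_aa: int, n_ab: int, n_bb: int) -> float:
    """3-class Pearson chi-square against Hardy-Weinberg expectations.

    Expectations use the allele frequency observed in the same counts, so a
    sample in exact HWE proportions returns 0.
    """
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("hwe_chisq requires at least one genotyped animal")
    p = (2 * n_aa + n_ab) / (2 * n)
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)], dtype=float)
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
    return float(terms.sum())


def genotype_counts(geno: PhasedGenotypes) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP genotype counts (nAA, nAB, nBB) over called animals, shape (snps, 3)."""
    g = geno.genotypes()
    called = g != MISSING_ALLELE
    return np.stack([(g == k).sum(axis=0) for k in (0, 1, 2)], axis=1), called


def snp_stats(geno: PhasedGenotypes) -> pd.DataFrame:
    """Per-SNP MAF, call rate, genotype counts and HWE chi-square."""
    counts, _ = genotype_counts(geno)
    n_called = counts.sum(axis=1)
    n_animals = geno.n_animals
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = (counts[:, 1] + 2 * counts[:, 2]) / (2 * np.maximum(n_called, 1))
    maf = np.minimum(p_alt, 1 - p_alt)
    maf[n_called == 0] = np.nan
    hwe = np.array([hwe_chisq(*c) if c.sum() > 0 else np.nan for c in counts])
    return pd.DataFrame({
        "nAA": counts[:, 0], "nAB": counts[:, 1], "nBB": counts[:, 2],
        "call_rate": n_called / n_animals, "alt_freq": p_alt, "maf": maf,
        "hwe_chisq": hwe,
    })


def animal_qc(geno: PhasedGenotypes, thresholds: QcThresholds) -> np.ndarray:
    """Indices of animals whose genotype call rate meets the threshold."""
    g = geno.genotypes()
    rate = (g != MISSING_ALLELE).mean(axis=1)
    return np.flatnonzero(rate >= thresholds.animal_call_rate_min)


def snp_qc(geno: PhasedGenotypes, snpmap: SnpMap,
           thresholds: QcThresholds | None = None,
           exclude_ids: set[str] | None = None,
           ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Apply animal-then-SNP QC.

    Returns (kept SNP indices, kept animal indices, per-SNP report).  The
    report carries every SNP with its statistics, kept flag and removal
    reason.  ``exclude_ids`` is an optional pre-supplied exclusion list
    (e.g. markers with poor imputation accuracy).
    """
    thresholds = thresholds or QcThresholds()
    keep_animals = animal_qc(geno, thresholds)
    sub = PhasedGenotypes([geno.animals[i] for i in keep_animals],
                          geno.alleles[keep_animals], geno.phased)
    stats = snp_stats(sub)
    stats.insert(0, "snp_id", snpmap.ids)
    stats.insert(1, "chrom", snpmap.chrom)

    reason = pd.Series("", index=stats.index, dtype=object)
    if exclude_ids:
        reason[stats["snp_id"].isin(exclude_ids)] = "excluded"
    if thresholds.autosomes_only:
        m = (reason == "") & ~stats["chrom"].isin(AUTOSOMES)
        reason[m] = "non-autosomal"
    m = (reason == "") & (stats["call_rate"] < thresholds.snp_call_rate_min)
    reason[m] = "call rate"
    m = (reason == "") & ~(stats["maf"] >= thresholds.maf_min)  # NaN MAF removed too
    reason[m] = "MAF"
    m = (reason == "") & ~(stats["hwe_chisq"] < thresholds.hwe_chisq_max)
    reason[m] = "HWE"
    stats["kept"] = reason == ""
    stats["reason"] = reason
    kept = np.flatnonzero(stats["kept"].to_numpy())
    return kept, keep_animals, stats


def write_qc_report(path, stats: pd.DataFrame) -> None:
    stats.to_csv(path, sep="\t", index=False, float_format="%.6g")
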