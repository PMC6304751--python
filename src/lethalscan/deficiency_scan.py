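"""Homozygote-deficiency tests and candidacy calls for SNPs and haplotypes.

A recessive lethal acting in utero leaves a signature in the genotypes of
live animals: carriers segregate but homozygotes are absent.  The scan
compares the observed number of homozygotes at each locus with the
random-mating expectation and flags loci where the expectation is
comfortably above zero yet no homozygote was seen.

Expected homozygotes:
  * SNP: N * maf^2.
  * Haplotype allele, two conventions: "hwe" uses N * f^2 with f the allele
    frequency (diplotype Hardy-Weinberg); "vanraden" uses N / 4 * c^2 with c
    the carrier frequency.  Under HWE with a rare allele the two agree
    (c ~ 2f).  The default is "hwe".

The deficiency statistic is the one-class chi-square (O - E)^2 / E on 1
degree of freedom; raw P-values are Bonferroni-corrected over the family of
loci tested (SNPs and haplotype alleles form separate families).  A locus is
a lethal candidate when no homozygote was observed, the expectation exceeds
the minimum (5 for SNPs, 6 for haplotype alleles) and the corrected P is
below 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .block_builder import HaplotypeAllele
from .io_formats import MISSING_ALLELE, PhasedGenotypes
from .qc_filters import snp_stats


@dataclass
class CandidacyRule:
    min_expected_snp: float = 5.0
    min_expected_hap: float = 6.0
    corrected_p_max: float = 0.01
    required_observed: int = 0

    def __post_init__(self) -> None:
        if self.min_expected_snp <= 0 or self.min_expected_hap <= 0:
            raise ValueError("minimum expected counts must be positive")


@dataclass
class DeficiencyResult:
    locus: str
    n_animals: int
    frequency: float
    expected: float
    observed: int
    chisq: float
    p_raw: float
    p_corrected: float
    candidate: bool
    kind: str = "snp"        # "snp" or "haplotype"
    mode: str = ""           # expected-homozygote convention for haplotypes
    chrom: str = ""
    start_mb: float = np.nan
    end_mb: float = np.nan
    n_snps: int = 0
    allele: str = ""
    carriers: int = 0


def expected_hom_snp(n_animals: int, maf: float) -> float:
    """Expected minor-allele homozygotes under random mating: N * maf^2."""
    if n_animals <= 0:
        raise ValueError("need at least one animal")
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF must lie in [0, 0.5], got {maf}")
    return n_animals * maf * maf


def expected_hom_hap(n_animals: int, allele_freq: float | None = None,
                     carrier_freq: float | None = None, mode: str = "hwe") -> float:
    """Expected haplotype homozygotes: N*f^2 ("hwe") or N/4*c^2 ("vanraden")."""
    if mode == "hwe":
        if allele_freq is None or not 0.0 <= allele_freq <= 1.0:
            raise ValueError("hwe mode requires allele frequency in [0, 1]")
        return n_animals * allele_freq ** 2
    if mode == "vanraden":
        if carrier_freq is None or not 0.0 <= carrier_freq <= 1.0:
            raise ValueError("vanraden mode requires carrier frequency in [0, 1]")
        return n_animals / 4.0 * carrier_freq ** 2
    raise ValueError(f"unknown expected-homozygote mode {mode!r}")


def deficiency_test(observed: int, expected: float) -> tuple[float, float]:
    """One-class chi-square (O-E)^2/E with its df=1 upper-tail P-value."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    chisq = (observed - expected) ** 2 / expected
    return chisq, float(stats.chi2.sf(chisq, df=1))


def bonferroni_adjust(p_raw: float, m_tests: int) -> float:
    """min(1, p * m)."""
    if m_tests < 1:
        raise ValueError("number of tests must be >= 1")
    return min(1.0, p_raw * m_tests)


def _results_frame(results: list[DeficiencyResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def scan_snps(geno: PhasedGenotypes, rule: CandidacyRule | None = None,
              stats_df: pd.DataFrame | None = None,
              snp_ids: np.ndarray | None = None,
              stat: str = "deficiency") -> list[DeficiencyResult]:
    """Deficiency test per SNP for the minor allele.

    Bonferroni correction is over the SNPs tested here (the QC-passing set
    when QC has been applied upstream).  Monomorphic SNPs are reported with
    E=0 and no test.  ``stat`` selects the statistic: "deficiency" is the
    one-class (O-E)^2/E form; "hwe3" the 3-genotype-class Pearson
    chi-square against HWE, still referred to 1 df.
    """
    rule = rule or CandidacyRule()
    if stat not in ("deficiency", "hwe3"):
        raise ValueError(f"unknown statistic {stat!r}")
    if stats_df is None:
        stats_df = snp_stats(geno)
    g = geno.genotypes()
    minor_is_alt = stats_df["alt_freq"].to_numpy() <= 0.5
    hom_minor = np.where(minor_is_alt, (g == 2).sum(axis=0), (g == 0).sum(axis=0))
    n_called = (g != MISSING_ALLELE).sum(axis=0)
    maf = stats_df["maf"].to_numpy()
    testable = (maf > 0) & (n_called > 0)
    m = int(testable.sum())
    ids = snp_ids if snp_ids is not None else (
        stats_df["snp_id"].to_numpy() if "snp_id" in stats_df else np.arange(len(maf)).astype(str))
    results = []
    for j in range(len(maf)):
        if not testable[j]:
            continue
        expected = expected_hom_snp(int(n_called[j]), float(maf[j]))
        observed = int(hom_minor[j])
        if expected <= 0:
            chisq, p_raw = 0.0, 1.0
        elif stat == "hwe3":
            from .qc_filters import hwe_chisq
            chisq = hwe_chisq(int(stats_df["nAA"].iloc[j]), int(stats_df["nAB"].iloc[j]),
                              int(stats_df["nBB"].iloc[j]))
            p_raw = float(stats.chi2.sf(chisq, df=1))
        else:
            chisq, p_raw = deficiency_test(observed, expected)
        p_corr = bonferroni_adjust(p_raw, m)
        cand = (observed == rule.required_observed and expected > rule.min_expected_snp
                and p_corr < rule.corrected_p_max)
        results.append(DeficiencyResult(str(ids[j]), int(n_called[j]), float(maf[j]),
                                        expected, observed, chisq, p_raw, p_corr, cand,
                                        kind="snp", mode=stat))
    return results


def scan_haplotypes(alleles: list[HaplotypeAllele], rule: CandidacyRule | None = None,
                    mode: str = "hwe") -> list[DeficiencyResult]:
    """Deficiency test per haplotype allele, Bonferroni over all alleles tested."""
    rule = rule or CandidacyRule()
    m = len(alleles)
    results = []
    for h in alleles:
        if mode == "hwe":
            expected = expected_hom_hap(h.n_used, allele_freq=h.frequency, mode="hwe")
        else:
            expected = expected_hom_hap(h.n_used, carrier_freq=h.carrier_frequency,
                                        mode="vanraden")
        if expected > 0:
            chisq, p_raw = deficiency_test(h.homozygotes, expected)
        else:
            chisq, p_raw = 0.0, 1.0
        p_corr = bonferroni_adjust(p_raw, max(m, 1))
        cand = (h.homozygotes == rule.required_observed and expected > rule.min_expected_hap
                and p_corr < rule.corrected_p_max)
        results.append(DeficiencyResult(
            f"{h.block.label}|{h.allele}", h.n_used, h.frequency, expected,
            h.homozygotes, chisq, p_raw, p_corr, cand, kind="haplotype", mode=mode,
            chrom=h.block.chrom, start_mb=h.block.start / 1e6, end_mb=h.block.end / 1e6,
            n_snps=h.block.n_snps, allele=h.allele, carriers=h.carriers))
    return results


def results_table(results: list[DeficiencyResult]) -> pd.DataFrame:
    """Result table mirroring the scan report layout (SSC, locus Mb, E(HOM), P)."""
    df = _results_frame(results)
    if df.empty:
        return df
    cols = ["kind", "locus", "chrom", "start_mb", "end_mb", "n_snps", "allele",
            "n_animals", "frequency", "carriers", "expected", "observed",
            "chisq", "p_raw", "p_corrected", "candidate", "mode"]
    return df[cols]
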