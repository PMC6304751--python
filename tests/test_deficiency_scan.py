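"""Expected-homozygote formulas, the deficiency chi-square and candidacy
logic, with a brute-force recount oracle."""

import numpy as np
import pytest
from scipy.stats import chi2

from lethalscan.block_builder import Block, HaplotypeAllele
from lethalscan.deficiency_scan import (bonferroni_adjust, deficiency_test,
                                        expected_hom_hap, expected_hom_snp,
                                        scan_haplotypes, scan_snps)
from lethalscan.io_formats import PhasedGenotypes


@pytest.mark.parametrize("n, maf, expected", [
    (100, 0.5, 25.0),
    (1000, 0.0, 0.0),
    (1359, 0.17, 39.2751),
])
def test_expected_hom_snp(n, maf, expected):
    assert expected_hom_snp(n, maf) == pytest.approx(expected, abs=1e-4)


def test_expected_hom_snp_rejects_major_allele():
    with pytest.raises(ValueError):
        expected_hom_snp(100, 0.6)


def test_expected_hom_hap_conventions():
    assert expected_hom_hap(1359, carrier_freq=0.376, mode="vanraden") == \
        pytest.approx(1359 / 4 * 0.376 ** 2)
    assert expected_hom_hap(1359, allele_freq=0.112, mode="hwe") == \
        pytest.approx(1359 * 0.112 ** 2)
    assert expected_hom_hap(500, carrier_freq=0.0, mode="vanraden") == 0.0


def test_deficiency_test_values():
    assert deficiency_test(5, 5.0) == pytest.approx((0.0, 1.0))
    chisq, p = deficiency_test(0, 10.0)
    assert chisq == pytest.approx(10.0)
    assert p == pytest.approx(chi2.sf(10.0, 1))
    assert p == pytest.approx(1.565e-3, rel=1e-3)
    chisq, p = deficiency_test(0, 45.3)
    assert chisq == pytest.approx(45.3)
    assert p == pytest.approx(1.69e-11, rel=1e-2)


def test_deficiency_test_requires_positive_expectation():
    with pytest.raises(ValueError):
        deficiency_test(0, 0.0)


@pytest.mark.parametrize("p, m, out", [(0.5, 1, 0.5), (1e-6, 1000, 1e-3), (0.9, 10, 1.0)])
def test_bonferroni(p, m, out):
    assert bonferroni_adjust(p, m) == pytest.approx(out)


def _panel(dosages):
    g = np.asarray(dosages)
    a = np.zeros((*g.shape, 2), dtype=np.int8)
    a[..., 0] = g >= 1
    a[..., 1] = g == 2
    return PhasedGenotypes([f"a{i}" for i in range(g.shape[0])], a)


def test_scan_snps_no_candidates_when_homozygotes_present(rng):
    g = rng.binomial(2, 0.3, size=(300, 8))
    g[0] = 2  # force a minor homozygote everywhere
    res = scan_snps(_panel(g))
    assert not any(r.candidate for r in res)


def test_scan_snps_flags_planted_deficit(rng):
    # one SNP with MAF 0.2 and no minor homozygotes among many neutral SNPs
    n = 500
    g = rng.binomial(2, 0.3, size=(n, 100))
    het = np.zeros(n, dtype=int)
    het[:200] = 1                    # allele freq 0.2, zero homozygotes
    g[:, 0] = het
    res = scan_snps(_panel(g))
    r0 = next(r for r in res if r.locus == "0")
    assert r0.expected == pytest.approx(n * 0.2 ** 2)
    assert r0.chisq == pytest.approx(20.0)
    assert r0.candidate
    others = [r for r in res if r.locus != "0"]
    assert not any(r.candidate for r in others)


def test_scan_snps_matches_bruteforce_recount(rng):
    """Candidacy on random 20-SNP panels equals an independent recount."""
    for _ in range(5):
        g = rng.binomial(2, rng.uniform(0.05, 0.5, size=20), size=(400, 20))
        panel = _panel(g)
        res = {r.locus: r for r in scan_snps(panel)}
        m = len(res)
        for j in range(20):
            col = g[:, j]
            p1 = col.mean() / 2
            maf = min(p1, 1 - p1)
            if maf == 0:
                assert str(j) not in res
                continue
            minor_hom = int(((col == 2) if p1 <= 0.5 else (col == 0)).sum())
            e = 400 * maf ** 2
            praw = chi2.sf((minor_hom - e) ** 2 / e, 1)
            r = res[str(j)]
            assert r.observed == minor_hom
            assert r.expected == pytest.approx(e)
            assert r.candidate == (minor_hom == 0 and e > 5
                                   and min(1, praw * m) < 0.01)


def _allele(n_used, copies, carriers, homozygotes, allele="1111"):
    block = Block("1", 0, 400_000, np.arange(len(allele)))
    return HaplotypeAllele(block, allele, copies, n_used, carriers, homozygotes)


def test_haplotype_with_observed_homozygote_never_candidate():
    h = _allele(1000, 500, 400, 1)
    res = scan_haplotypes([h])[0]
    assert res.expected > 6 and not res.candidate


def test_haplotype_expectation_threshold_is_strict():
    # E = 5.9 < 6: not a candidate no matter how small P is
    f = np.sqrt(5.9 / 1000)
    h = _allele(1000, int(round(2000 * f)), int(round(2000 * f)), 0)
    res = scan_haplotypes([h])[0]
    assert res.expected == pytest.approx(5.9, abs=0.1)
    assert not res.candidate


def test_planted_frequency_gives_expected_33_75():
    h = _allele(1500, 450, 450, 0)  # freq 0.15
    res = scan_haplotypes([h])[0]
    assert res.frequency == pytest.approx(0.15)
    assert res.expected == pytest.approx(1500 * 0.15 ** 2)
    assert res.candidate        # corrected P tiny even for m = 2e5? here m=1


def test_corrected_p_monotone_in_expectation():
    es = np.linspace(7, 60, 25)
    ps = []
    for e in es:
        chisq, praw = deficiency_test(0, float(e))
        ps.append(bonferroni_adjust(praw, 1000))
    assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


def test_snp_scan_hwe3_statistic_switch(rng):
    """The 3-class HWE variant reproduces hwe_chisq per SNP and is at least
    as extreme as the one-class statistic when minor homozygotes are absent."""
    from lethalscan.qc_filters import hwe_chisq
    g = rng.binomial(2, 0.3, size=(400, 6))
    g[g[:, 0] == 2, 0] = 1   # no minor homozygotes at SNP 0
    res1 = {r.locus: r for r in scan_snps(_panel(g), stat="deficiency")}
    res3 = {r.locus: r for r in scan_snps(_panel(g), stat="hwe3")}
    for j in range(6):
        col = g[:, j]
        counts = [(col == k).sum() for k in (0, 1, 2)]
        assert res3[str(j)].chisq == pytest.approx(hwe_chisq(*counts))
    assert res3["0"].chisq >= res1["0"].chisq
    with pytest.raises(ValueError):
        scan_snps(_panel(g), stat="other")


def test_vanraden_mode_uses_carrier_frequency():
    h = _allele(1359, 300, 511, 0)   # carrier freq 0.376
    res = scan_haplotypes([h], mode="vanraden")[0]
    assert res.expected == pytest.approx(1359 / 4 * (511 / 1359) ** 2)
    assert res.mode == "vanraden"
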