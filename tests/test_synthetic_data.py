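"""Generator contracts: determinism, planted-allele frequencies, the lethal
mechanism's analytic expectations, and file round trips."""

import numpy as np
import pytest

from lethalscan.block_builder import ScanConfig, build_blocks, enumerate_alleles
from lethalscan.deficiency_scan import scan_haplotypes
from lethalscan.io_formats import (PhasedGenotypes, read_litters, read_pedigree,
                                   read_phased_vcf, validate_litters)
from lethalscan.qc_filters import snp_qc
from lethalscan.synthetic_data import (PlantedBlock, SimulationConfig,
                                       simulate_founders, simulate_litters,
                                       simulate_mating_type_litters,
                                       write_dataset)


def _small_config(seed=11, **kw):
    defaults = dict(seed=seed, n_boars=800, n_sows=600, n_service_sires=120,
                    n_litters=800,
                    planted=[PlantedBlock("1", 3_000_000, frequency=0.22)])
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_same_seed_bit_identical():
    c = _small_config()
    s1 = simulate_founders(_small_config())
    s2 = simulate_founders(_small_config())
    np.testing.assert_array_equal(s1[1].alleles, s2[1].alleles)
    l1, _ = simulate_litters(s1[1], s1[3], c)
    l2, _ = simulate_litters(s2[1], s2[3], c)
    assert l1.equals(l2)


def test_different_seed_differs():
    s1 = simulate_founders(_small_config(seed=1))
    s2 = simulate_founders(_small_config(seed=2))
    assert not np.array_equal(s1[1].alleles, s2[1].alleles)


def test_realized_frequency_near_target():
    cfg = SimulationConfig(seed=5, n_boars=1500,
                           planted=[PlantedBlock("1", 2_000_000, frequency=0.15)])
    *_, truths = simulate_founders(cfg)
    assert truths[0].realized_frequency == pytest.approx(0.15, abs=0.02)


def test_no_live_animal_homozygous_for_planted_allele():
    snpmap, geno, _, truths = simulate_founders(_small_config())
    t = truths[0]
    sub = geno.alleles[:, t.block.snp_indices, :]
    hom = np.all(sub == 1, axis=(1, 2))
    assert not hom.any()
    assert len(t.carrier_ids) > 0


def test_target_frequency_above_half_rejected():
    with pytest.raises(ValueError):
        PlantedBlock("1", 2_000_000, frequency=0.6)


def test_background_frequencies_conserved():
    cfg = SimulationConfig(seed=9, n_boars=1500, planted=[])
    snpmap, geno, *_ = simulate_founders(cfg)
    freqs_cfg = np.random.default_rng(
        np.random.SeedSequence(9).spawn(4)[3]).uniform(0.05, 0.5, geno.n_snps)
    realized = geno.alleles.mean(axis=(0, 2))
    sd = np.sqrt(freqs_cfg * (1 - freqs_cfg) / (2 * 1500))
    assert np.all(np.abs(realized - freqs_cfg) < 3.5 * sd)


def test_mating_type_expectations():
    """E[TNB]: 00 -> mu; 11 -> 3mu/4; with pi_mm = 1, E[MM | 11] = mu/4."""
    df, mt, _ = simulate_mating_type_litters(3, (2000, 0, 2000), mu=12.0, pi_mm=1.0,
                                             sb_rate=0.0, neonatal_loss_rate=0.0)
    t00 = df.loc[mt == "00", "TNB"].mean()
    t11 = df.loc[mt == "11", "TNB"].mean()
    assert t00 == pytest.approx(12.0, abs=0.25)
    assert t11 == pytest.approx(9.0, abs=0.25)
    assert (t00 - t11) == pytest.approx(3.0, abs=0.3)
    assert df.loc[mt == "11", "MM"].mean() == pytest.approx(3.0, abs=0.25)
    assert (df.loc[mt == "00", "MM"] == 0).all()


def test_litter_invariants_and_mm_attribution(planted_scan_litters):
    litters, truths = planted_scan_litters
    valid, rejected = validate_litters(litters)
    assert len(rejected) == 0
    assert (litters["BA"] <= litters["TNB"]).all()
    assert (litters["L24"] <= litters["BA"]).all()
    removed = np.sum([t.removed_per_litter for t in truths], axis=0)
    assert removed.sum() > 0
    # losses only occur in litters of carrier sires
    carrier_sires = set().union(*(t.carrier_ids for t in truths))
    assert set(litters.loc[removed > 0, "sire"]) <= carrier_sires


def test_round_trip_write_read_scan(tmp_path):
    """simulate -> write -> read -> scan recovers the planted block."""
    cfg = _small_config()
    snpmap, geno, ped, truths = simulate_founders(cfg)
    litters, truths = simulate_litters(geno, truths, cfg)
    paths = write_dataset(tmp_path / "ds", snpmap, geno, ped, litters, truths)
    snpmap2, geno2 = read_phased_vcf(paths["vcf"])
    np.testing.assert_array_equal(geno2.alleles, geno.alleles)
    ped2 = read_pedigree(paths["pedigree"])
    assert set(ped2.animals) == set(ped.animals)
    valid, rejected = read_litters(paths["litters"])
    assert len(valid) == len(litters) and len(rejected) == 0

    kept, kept_an, stats = snp_qc(geno2, snpmap2)
    blocks = build_blocks(snpmap2, snp_subset=kept)
    col_of = {int(j): c for c, j in enumerate(kept)}
    sub = PhasedGenotypes(geno2.animals, geno2.alleles[:, kept])
    alleles = []
    for b in blocks:
        b.snp_indices = np.array([col_of[int(j)] for j in b.snp_indices])
        alleles.extend(enumerate_alleles(sub, b))
    res = scan_haplotypes(alleles)
    t = truths[0]
    hits = [r for r in res if r.candidate and r.chrom == t.block.chrom
            and r.start_mb <= t.block.start / 1e6 + 1e-9 <= r.end_mb]
    assert t.realized_frequency ** 2 * 800 > 6
    assert hits, "planted lethal not recovered after file round trip"
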