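"""Carrier status, the animal-model fits on exactly-solvable toys, and
calibration under the null."""

import numpy as np
import pandas as pd
import pytest

from lethalscan.association import (carrier_status, fit_linear_animal_model,
                                    fit_mating_type_model,
                                    fit_poisson_animal_model)
from lethalscan.block_builder import Block, HaplotypeAllele
from lethalscan.io_formats import PhasedGenotypes, build_pedigree
from lethalscan.mixedlm import fit_lmm
from lethalscan.synthetic_data import simulate_trait_dataset


def _geno(hap_pairs):
    n, k = len(hap_pairs), len(hap_pairs[0][0])
    a = np.zeros((n, k, 2), dtype=np.int8)
    for i, (h1, h2) in enumerate(hap_pairs):
        a[i, :, 0] = [int(c) for c in h1]
        a[i, :, 1] = [int(c) for c in h2]
    return PhasedGenotypes([f"a{i}" for i in range(n)], a)


def _hap(allele="01"):
    block = Block("1", 0, 400_000, np.arange(len(allele)))
    return HaplotypeAllele(block, allele, 1, 1, 1, 0)


def test_carrier_status_definitions():
    geno = _geno([("01", "11"), ("11", "11"), ("01", "01")])
    status = carrier_status(geno, _hap("01"))
    np.testing.assert_array_equal(status, [1, 0, 1])  # homozygote is a carrier


def test_carrier_status_missing_flagged():
    geno = _geno([("01", "11")])
    geno.alleles[0, 1, 0] = -1
    assert carrier_status(geno, _hap("01"))[0] == -1


def _records(y_by_group, sires_per_group=None, trait="L24"):
    """One litter per unique sire/sow; carrier defined by group membership."""
    rows, carrier = [], {}
    k = 0
    for level, ys in y_by_group.items():
        for y in ys:
            sire = f"s{k}"
            carrier[sire] = level
            rows.append({"sire": sire, "sow": f"w{k}", "parity": "1",
                         "year_season": "y1", "TNB": y, "BA": y, "L24": y,
                         "SB": 0, "MM": 0})
            k += 1
    df = pd.DataFrame(rows)
    for t in ("TNB", "BA", "L24"):
        df[t] = df[t].astype(float)
    ped = build_pedigree([(s, None, None) for s in carrier])
    return df, carrier, ped


def _balanced_values(mean, n, spread=0.5):
    """n values averaging exactly `mean`."""
    vals = [mean + spread if i % 2 == 0 else mean - spread for i in range(n - n % 2)]
    if n % 2:
        vals.append(mean)
    return vals


def test_linear_model_contrast_on_exact_group_means():
    """Non-carrier minus carrier contrast equals the difference of printed
    adjusted means (0.24 piglets alive at 24 h)."""
    df, carrier, ped = _records({0: _balanced_values(9.04, 20),
                                 1: _balanced_values(8.80, 20)})
    est = fit_linear_animal_model(df, "L24", carrier, ped)
    assert est.difference == pytest.approx(0.24, abs=1e-6)
    assert est.means[0][0] == pytest.approx(9.04, abs=1e-6)
    assert est.means[1][0] == pytest.approx(8.80, abs=1e-6)


def test_single_carrier_level_rejected():
    df, carrier, ped = _records({0: [10.0] * 6})
    with pytest.raises(ValueError, match="constant"):
        fit_linear_animal_model(df, "TNB", carrier, ped)


def test_poisson_all_zero_counts_rejected():
    df, carrier, ped = _records({0: [0] * 4, 1: [0] * 4})
    df["MM"] = 0
    with pytest.raises(ValueError, match="zero"):
        fit_poisson_animal_model(df, "MM", carrier, ped)


def test_poisson_constant_counts_zero_effect():
    """Equal counts with no structure: intercept log(c), no carrier effect."""
    df, carrier, ped = _records({0: [0] * 10, 1: [0] * 10})
    df["MM"] = 3
    est = fit_poisson_animal_model(df, "MM", carrier, ped)
    assert est.effect == pytest.approx(0.0, abs=1e-6)
    assert est.model.beta[0] == pytest.approx(np.log(3), abs=1e-6)


def test_mating_type_means_recover_printed_table_row():
    """Mating-type adjusted means reproduce the printed 11.59/10.51/9.63 TNB
    row and its 1.96-piglet 00-11 contrast."""
    df, groups, ped = _records({0: _balanced_values(11.59, 17),
                                1: _balanced_values(10.51, 20),
                                2: _balanced_values(9.63, 13)}, trait="TNB")
    mt = df["sire"].map({s: ("00", "01", "11")[g] for s, g in groups.items()})
    res = fit_mating_type_model(df, "TNB", mt, ped)
    assert res.means["00"][0] == pytest.approx(11.59, abs=1e-6)
    assert res.means["11"][0] == pytest.approx(9.63, abs=1e-6)
    assert res.means["00"][2] == 17 and res.means["11"][2] == 13
    diff, se, p = res.contrasts[("00", "11")]
    assert diff == pytest.approx(1.96, abs=1e-6)


def test_mating_type_absent_level_contrast_subset():
    df, groups, ped = _records({0: _balanced_values(11.0, 8),
                                1: _balanced_values(10.0, 8)})
    mt = df["sire"].map({s: ("00", "01")[g] for s, g in groups.items()})
    res = fit_mating_type_model(df, "L24", mt, ped)
    assert set(res.means) == {"00", "01"}
    assert set(res.contrasts) == {("00", "01")}


def test_lmm_reduces_to_ols_when_variances_pinned(rng):
    n, q = 120, 20
    X = np.column_stack([np.ones(n), rng.integers(0, 2, size=n)])
    from scipy import sparse
    Z = sparse.csr_matrix((np.ones(n), (np.arange(n), rng.integers(0, q, n))),
                          shape=(n, q))
    W = sparse.csr_matrix((np.ones(n), (np.arange(n), rng.integers(0, q, n))),
                          shape=(n, q))
    y = X @ [10.0, -0.5] + rng.normal(0, 1, n)
    fit = fit_lmm(y, X, Z, W, np.eye(q), fix_lambda=(1e-10, 1e-10))
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)


def test_null_linear_calibration():
    """Simulated null carrier effect covered by +/- 2 SE in >= 90% of seeds."""
    covered = 0
    for seed in range(20):
        df, carrier, ped = simulate_trait_dataset(
            1000 + seed, trait="TNB", n_sires=300, n_litters=900,
            carrier_effect=0.0)
        est = fit_linear_animal_model(df, "TNB", carrier, ped)
        covered += abs(est.effect) < 2 * est.se
    assert covered >= 18


def test_null_poisson_calibration():
    covered = 0
    for seed in range(20):
        df, carrier, ped = simulate_trait_dataset(
            2000 + seed, trait="MM", n_sires=300, n_litters=900,
            carrier_effect=0.0, poisson=True)
        est = fit_poisson_animal_model(df, "MM", carrier, ped)
        covered += abs(est.effect) < 2 * est.se
    assert covered >= 18


def test_variance_components_recovered(linear_recovery_fits):
    """Median REML estimates within 25% of (0.25, 0.25, 1.0) at 5000 litters."""
    fits = [e.model for e in linear_recovery_fits[:10]]
    va = np.median([f.sigma_a2 for f in fits])
    vs = np.median([f.sigma_s2 for f in fits])
    ve = np.median([f.sigma_e2 for f in fits])
    assert va == pytest.approx(0.25, rel=0.25)
    assert vs == pytest.approx(0.25, rel=0.25)
    assert ve == pytest.approx(1.0, rel=0.25)
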