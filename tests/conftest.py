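"""Shared fixtures: small synthetic datasets and (expensive) model refits.

The parameter-recovery fits are session-scoped so the estimator-verification
tests and the calibration checks share one set of fits instead of refitting.
"""

from __future__ import annotations

import numpy as np
import pytest

from lethalscan.association import fit_linear_animal_model, fit_poisson_animal_model
from lethalscan.synthetic_data import (PlantedBlock, SimulationConfig,
                                       simulate_founders, simulate_litters,
                                       simulate_trait_dataset)

N_RECOVERY_SEEDS = 20
LINEAR_EFFECT = -0.30
POISSON_EFFECT = 0.20


@pytest.fixture(scope="session")
def planted_scan_sim():
    """N=1500 boar panel with three planted lethals (freq 0.12, 0.15, 0.20)."""
    config = SimulationConfig(
        seed=20_001, n_boars=1500,
        planted=[PlantedBlock("1", 2_000_000, frequency=0.12, pi_mm=0.5),
                 PlantedBlock("1", 7_000_000, frequency=0.15, pi_mm=0.5),
                 PlantedBlock("2", 5_000_000, frequency=0.20, pi_mm=0.5)])
    snpmap, geno, ped, truths = simulate_founders(config)
    return config, snpmap, geno, ped, truths


@pytest.fixture(scope="session")
def planted_scan_litters(planted_scan_sim):
    config, snpmap, geno, ped, truths = planted_scan_sim
    litters, truths = simulate_litters(geno, truths, config)
    return litters, truths


@pytest.fixture(scope="session")
def linear_recovery_fits():
    """Carrier-effect estimates on data drawn exactly from the linear model."""
    fits = []
    for seed in range(N_RECOVERY_SEEDS):
        df, carrier, ped = simulate_trait_dataset(seed, trait="TNB",
                                                  carrier_effect=LINEAR_EFFECT)
        fits.append(fit_linear_animal_model(df, "TNB", carrier, ped))
    return fits


@pytest.fixture(scope="session")
def poisson_recovery_fits():
    """Carrier-effect estimates on MM counts drawn from the Poisson GLMM."""
    fits = []
    for seed in range(N_RECOVERY_SEEDS):
        df, carrier, ped = simulate_trait_dataset(seed, trait="MM",
                                                  carrier_effect=POISSON_EFFECT,
                                                  poisson=True)
        fits.append(fit_poisson_animal_model(df, "MM", carrier, ped))
    return fits


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
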