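"""Synthetic breeding populations with planted recessive-lethal haplotypes.

The generator emulates the study design the scan targets: a panel of
genotyped AI boars, sows of mostly unknown genotype, and litter records
(TNB, BA, L24, SB, MM) from their matings.  At each planted block a
designated haplotype allele segregates at a target frequency with complete
LD across its SNPs; homozygous conceptuses die in utero with penetrance 1
(by default) and each loss is recorded as a mummified fetus with
probability pi_mm.  Because lethal homozygotes never reach sampling, no
genotyped animal is homozygous for a planted allele (rejection at
sampling).  Background SNPs are in linkage equilibrium, so truth phase is
exact and phasing needs no external tool.

Every stochastic call derives from one master seed through
numpy's SeedSequence spawning (a documented counter scheme): child 0 drives
founder genotypes, child 1 sow genotypes, child 2 litters.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .block_builder import Block
from .io_formats import (LITTER_COLUMNS, PedigreeTable, PhasedGenotypes, SnpMap,
                         build_pedigree, write_litters, write_pedigree,
                         write_phased_vcf)

PARITY_LEVELS = ("1", "2", "3", "4", "5", ">6")


@dataclass
class PlantedBlock:
    """A recessive-lethal haplotype to plant: location, span and frequency.

    The planted allele is the all-"1" string over every SNP inside
    (start_bp, start_bp + span_bp], in complete LD.  The first member SNP is
    an anchor whose "1" allele occurs only on the lethal haplotype, so the
    single-SNP scan sees the same signal as the haplotype scan.
    """

    chrom: str
    start_bp: int             # window-grid aligned start (block covers start+1..start+span)
    span_bp: int = 400_000
    frequency: float = 0.15   # target haplotype allele frequency in [0.10, 0.26]
    pi_mm: float = 0.5        # probability a dead conceptus is recorded as MM
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.frequency <= 0.5:
            raise ValueError("planted allele frequency must lie in (0, 0.5]")


@dataclass
class ChromSpec:
    """One simulated chromosome.

    Markers are spaced so a 400 Kb window holds 5-6 of them: with the
    linkage-equilibrium background (no LD decay model, by design) a denser
    map would make every window-wide haplotype string essentially unique and
    the allele-frequency filter would remove them all.
    """

    name: str
    length_bp: int = 12_000_000
    snp_spacing_bp: int = 70_000


@dataclass
class SimulationConfig:
    """All parameters of the synthetic breeding population.

    Defaults emulate the study population: ~1359 genotyped boars of which
    192 serve as sires of 5340 recorded litters from 3460 sows, litters of
    mean 12 conceptuses, parity and year-season fixed effects, and additive
    sire / sow / residual variance components on the litter-size scale.
    """

    seed: int
    n_boars: int = 1359
    n_sows: int = 3460
    n_service_sires: int = 192
    n_litters: int = 5340
    chromosomes: list[ChromSpec] = field(default_factory=lambda: [
        ChromSpec("1"), ChromSpec("2")])
    freq_range: tuple[float, float] = (0.05, 0.5)
    planted: list[PlantedBlock] = field(default_factory=list)
    mu_conceptus: float = 12.0
    sb_rate: float = 0.05
    neonatal_loss_rate: float = 0.03
    mm_base: float = 0.2          # background mummified fetuses per litter
    n_year_seasons: int = 12
    parity_effects: tuple[float, ...] = (0.0, 0.4, 0.6, 0.6, 0.4, 0.1)
    ys_effect_sd: float = 0.3
    sigma_a2: float = 0.25
    sigma_s2: float = 0.25
    sigma_e2: float = 1.0
    carrier_effect: float = 0.0   # extra additive shift for carrier sires (power knob)

    def __post_init__(self) -> None:
        if self.mu_conceptus <= 0:
            raise ValueError("conceptus mean must be positive")
        for pb in self.planted:
            if not 0.0 <= pb.pi_mm <= 1.0:
                raise ValueError("pi_mm must lie in [0, 1]")

    def rngs(self) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return [np.random.default_rng(c) for c in children]


@dataclass
class PlantedTruth:
    block: Block
    allele: str
    target_frequency: float
    realized_frequency: float = np.nan
    carrier_ids: list[str] = field(default_factory=list)
    removed_per_litter: np.ndarray | None = None
    pi_mm: float = 0.5
    penetrance: float = 1.0


def _build_map(config: SimulationConfig) -> SnpMap:
    chrom, pos = [], []
    for cs in config.chromosomes:
        p = np.arange(cs.snp_spacing_bp, cs.length_bp + 1, cs.snp_spacing_bp)
        chrom.extend([cs.name] * len(p))
        pos.extend(p.tolist())
    n = len(pos)
    ids = np.array([f"{c}_{p}" for c, p in zip(chrom, pos)], dtype=object)
    return SnpMap(np.array(chrom, dtype=object), np.array(pos),
                  ids, np.array(["A"] * n, dtype=object), np.array(["B"] * n, dtype=object))


def _planted_indices(snpmap: SnpMap, pb: PlantedBlock) -> np.ndarray:
    ci = snpmap.chrom_indices(pb.chrom)
    pos = snpmap.pos[ci]
    inside = np.flatnonzero((pos > pb.start_bp) & (pos <= pb.start_bp + pb.span_bp))
    if len(inside) < 4:
        raise ValueError(f"planted block at {pb.chrom}:{pb.start_bp} spans fewer "
                         "than 4 SNPs and would be filtered")
    return ci[inside]


def _draw_panel(rng: np.random.Generator, n_animals: int, freqs: np.ndarray,
                planted: list[tuple[np.ndarray, float]]) -> np.ndarray:
    """Phased alleles (n, snps, 2): LE background + full-LD planted strings.

    Any animal homozygous for a planted string is redrawn at that block
    (a live animal cannot be a lethal homozygote).
    """
    alleles = (rng.random((n_animals, len(freqs), 2)) < freqs[None, :, None]).astype(np.int8)
    for idx, f in planted:
        # the target is the frequency among LIVE animals; sampling at f/(1-f)
        # compensates for the rejection of lethal homozygotes
        ind = rng.random((n_animals, 2)) < f / (1.0 - f)
        for k in (0, 1):
            sel = np.flatnonzero(ind[:, k])
            a = alleles[np.ix_(sel, idx)]
            a[:, :, k] = 1
            alleles[np.ix_(sel, idx)] = a
        # rejection: a lethal homozygote cannot be alive; redraw its whole
        # diplotype (truncated HW sampling leaves the live-animal frequency
        # at the target because the inflated draw compensates exactly)
        string = np.ones(len(idx), dtype=np.int8)
        fp = f / (1.0 - f)
        for _ in range(1000):
            sub = alleles[:, idx, :]
            hom = (np.all(sub[:, :, 0] == string, axis=1)
                   & np.all(sub[:, :, 1] == string, axis=1))
            if not hom.any():
                break
            sel = np.flatnonzero(hom)
            a = (rng.random((len(sel), len(idx), 2))
                 < freqs[idx][None, :, None]).astype(np.int8)
            lethal = rng.random((len(sel), 2)) < fp
            for k in (0, 1):
                a[lethal[:, k], :, k] = 1
            alleles[np.ix_(sel, idx)] = a
    return alleles


def simulate_founders(config: SimulationConfig,
                      ) -> tuple[SnpMap, PhasedGenotypes, PedigreeTable, list[PlantedTruth]]:
    """Genotyped boar panel with planted lethal haplotypes and its pedigree."""
    rng_f, _, _, rng_bg = config.rngs()
    snpmap = _build_map(config)
    freqs = rng_bg.uniform(*config.freq_range, size=len(snpmap))
    planted_idx = [(_planted_indices(snpmap, pb), pb.frequency) for pb in config.planted]
    for idx, _ in planted_idx:
        freqs[idx[0]] = 0.0     # anchor SNP: "1" allele exists only on the lethal haplotype
    alleles = _draw_panel(rng_f, config.n_boars, freqs, planted_idx)
    animals = [f"B{i:05d}" for i in range(config.n_boars)]
    geno = PhasedGenotypes(animals, alleles, phased=True)
    ped = build_pedigree([(a, None, None) for a in animals])

    truths = []
    for pb, (idx, _) in zip(config.planted, planted_idx):
        block = Block(pb.chrom, pb.start_bp, pb.start_bp + pb.span_bp, idx)
        string = "1" * len(idx)
        sub = alleles[:, idx, :]
        match = np.all(sub == 1, axis=1)          # (n, 2) per-haplotype match
        copies = int(match.sum())
        carriers = np.flatnonzero(match.any(axis=1))
        truths.append(PlantedTruth(block, string, pb.frequency,
                                   copies / (2 * config.n_boars),
                                   [animals[i] for i in carriers],
                                   pi_mm=pb.pi_mm, penetrance=pb.penetrance))
    return snpmap, geno, ped, truths


def _sow_carrier_draw(rng, n_sows: int, f: float) -> np.ndarray:
    """Carrier (heterozygote) indicator for live, ungenotyped sows.

    Live sows cannot be lethal homozygotes, so P(carrier) = 2f(1-f)/(1-f^2).
    """
    p = 2 * f * (1 - f) / (1 - f * f)
    return rng.random(n_sows) < p


def simulate_litters(geno: PhasedGenotypes, truths: list[PlantedTruth],
                     config: SimulationConfig,
                     ) -> tuple[pd.DataFrame, list[PlantedTruth]]:
    """Litter phenotypes from sire x sow matings with in-utero lethal losses.

    Per litter the conceptus count is Poisson(mu); each conceptus inherits
    one haplotype per parent at every planted block (no recombination inside
    a block); homozygous-lethal conceptuses are removed before birth and
    recorded as MM with probability pi_mm.  TNB/BA/L24 then receive parity,
    year-season, sire additive, sow and residual shifts, rounded to
    non-negative counts preserving BA <= TNB and L24 <= BA.
    """
    _, rng_sow, rng_lit, _ = config.rngs()
    n_lit = config.n_litters
    sire_pool = rng_lit.choice(geno.n_animals, size=min(config.n_service_sires,
                                                        geno.n_animals), replace=False)
    sire_of = rng_lit.choice(sire_pool, size=n_lit)
    sow_of = rng_lit.integers(0, config.n_sows, size=n_lit)

    # sire het status per planted block (genotyped; homozygotes cannot occur)
    sire_het = np.zeros((geno.n_animals, len(truths)), dtype=bool)
    for b, t in enumerate(truths):
        sub = geno.alleles[:, t.block.snp_indices, :]
        match = np.all(sub == 1, axis=1)
        sire_het[:, b] = match.any(axis=1)
    sow_het = np.zeros((config.n_sows, len(truths)), dtype=bool)
    for b, t in enumerate(truths):
        sow_het[:, b] = _sow_carrier_draw(rng_sow, config.n_sows, t.target_frequency)

    m = rng_lit.poisson(config.mu_conceptus, size=n_lit)
    removed = np.zeros((n_lit, len(truths)), dtype=np.int64)
    mm_recorded = np.zeros(n_lit, dtype=np.int64)
    remaining = m.copy()
    for b, t in enumerate(truths):
        risk = sire_het[sire_of, b] & sow_het[sow_of, b]
        p_die = 0.25 * t.penetrance
        deaths = np.where(risk, rng_lit.binomial(remaining, p_die), 0)
        removed[:, b] = deaths
        mm_recorded += rng_lit.binomial(deaths, t.pi_mm)
        remaining = remaining - deaths

    tnb = remaining
    sb = rng_lit.binomial(tnb, config.sb_rate)
    ba = tnb - sb
    l24 = ba - rng_lit.binomial(ba, config.neonatal_loss_rate)
    mm = mm_recorded + rng_lit.poisson(config.mm_base, size=n_lit)

    # fixed and random shifts on the litter-size traits
    parity_idx = np.minimum(rng_lit.poisson(1.2, size=n_lit), len(PARITY_LEVELS) - 1)
    ys_idx = rng_lit.integers(0, config.n_year_seasons, size=n_lit)
    ys_eff = rng_lit.normal(0, config.ys_effect_sd, size=config.n_year_seasons)
    a_eff = rng_lit.normal(0, np.sqrt(config.sigma_a2), size=geno.n_animals)
    if config.carrier_effect:
        a_eff = a_eff + config.carrier_effect * sire_het.any(axis=1)
    v_eff = rng_lit.normal(0, np.sqrt(config.sigma_s2), size=config.n_sows)
    e = rng_lit.normal(0, np.sqrt(config.sigma_e2), size=n_lit)
    shift = (np.asarray(config.parity_effects)[parity_idx] + ys_eff[ys_idx]
             + a_eff[sire_of] + v_eff[sow_of] + e)

    tnb2 = np.maximum(np.round(tnb + shift), 0).astype(np.int64)
    delta = tnb2 - tnb
    ba2 = np.clip(ba + delta, 0, tnb2)
    l242 = np.clip(l24 + delta, 0, ba2)

    df = pd.DataFrame({
        "sire": [geno.animals[i] for i in sire_of],
        "sow": [f"S{i:05d}" for i in sow_of],
        "parity": [PARITY_LEVELS[k] for k in parity_idx],
        "year_season": [f"ys{k:02d}" for k in ys_idx],
        "TNB": tnb2, "BA": ba2, "L24": l242, "SB": sb, "MM": mm,
    })
    for b, t in enumerate(truths):
        t.removed_per_litter = removed[:, b]
    return df, truths


def write_dataset(directory: str | os.PathLike, snpmap: SnpMap, geno: PhasedGenotypes,
                  ped: PedigreeTable, litters: pd.DataFrame,
                  truths: list[PlantedTruth]) -> dict[str, str]:
    """Write VCF + pedigree CSV + litter CSV + truth JSON sidecar."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "vcf": os.path.join(directory, "genotypes.vcf"),
        "pedigree": os.path.join(directory, "pedigree.csv"),
        "litters": os.path.join(directory, "litters.csv"),
        "truth": os.path.join(directory, "truth.json"),
    }
    write_phased_vcf(paths["vcf"], snpmap, geno)
    write_pedigree(paths["pedigree"], ped)
    write_litters(paths["litters"], litters)
    payload = [{
        "chrom": t.block.chrom, "start_bp": t.block.start, "end_bp": t.block.end,
        "allele": t.allele, "target_frequency": t.target_frequency,
        "realized_frequency": t.realized_frequency, "carrier_ids": t.carrier_ids,
        "pi_mm": t.pi_mm, "penetrance": t.penetrance,
        "removed_per_litter": (t.removed_per_litter.tolist()
                               if t.removed_per_litter is not None else None),
    } for t in truths]
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1)
    return paths


def simulate_mating_type_litters(seed: int, n_per_type: tuple[int, int, int],
                                 mu: float = 12.0, pi_mm: float = 0.5,
                                 sb_rate: float = 0.05,
                                 neonatal_loss_rate: float = 0.03,
                                 sigma_e2: float = 0.0,
                                 ) -> tuple[pd.DataFrame, pd.Series, PedigreeTable]:
    """Litters with known parental mating types (dataset-2 emulation).

    Only carrier x carrier (type "11") matings can produce lethal
    homozygotes: each conceptus dies with probability 1/4, so the analytic
    expectation is TNB(00) - TNB(11) = mu / 4.  Each litter gets a unique
    sire and sow.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    types = ["00"] * n_per_type[0] + ["01"] * n_per_type[1] + ["11"] * n_per_type[2]
    n = len(types)
    m = rng.poisson(mu, size=n)
    at_risk = np.array([t == "11" for t in types])
    deaths = np.where(at_risk, rng.binomial(m, 0.25), 0)
    tnb = m - deaths
    mm = rng.binomial(deaths, pi_mm)
    sb = rng.binomial(tnb, sb_rate)
    ba = tnb - sb
    l24 = ba - rng.binomial(ba, neonatal_loss_rate)
    if sigma_e2 > 0:
        shift = np.round(rng.normal(0, np.sqrt(sigma_e2), size=n)).astype(int)
        tnb = np.maximum(tnb + shift, 0)
        ba = np.clip(ba + shift, 0, tnb)
        l24 = np.clip(l24 + shift, 0, ba)
    sires = [f"B{i:04d}" for i in range(n)]
    df = pd.DataFrame({
        "sire": sires, "sow": [f"S{i:04d}" for i in range(n)],
        "parity": "1", "year_season": "ys00",
        "TNB": tnb, "BA": ba, "L24": l24, "SB": sb, "MM": mm,
    })
    ped = build_pedigree([(s, None, None) for s in sires])
    return df, pd.Series(types, index=df.index), ped


# ---------------------------------------------------------------------------
# model-based trait simulation for estimator verification


def simulate_trait_dataset(seed: int, trait: str = "TNB", n_sires: int = 1500,
                           litters_per_sire: int | None = None, n_litters: int = 5000,
                           carrier_effect: float = -0.30, base_mean: float = 10.5,
                           sigma_a2: float = 0.25, sigma_s2: float = 0.25,
                           sigma_e2: float = 1.0, poisson: bool = False,
                           base_rate: float = 0.40, n_year_seasons: int = 10,
                           ) -> tuple[pd.DataFrame, dict[str, int], PedigreeTable]:
    """Records drawn exactly from the association model, for parameter recovery.

    Gaussian: y = b0 + parity + year-season + i*carrier + a + v + e.
    Poisson:  y ~ Poisson(exp(log(base_rate) + i*carrier + a + v)), no parity
    (matching the MM model).  Carrier status is a sire-level Bernoulli(1/2).
    Returns the litter table, the sire carrier map and a founder pedigree.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if litters_per_sire is None:
        litters_per_sire = max(1, n_litters // n_sires)
    n = n_sires * litters_per_sire
    sires = [f"B{i:05d}" for i in range(n_sires)]
    carrier = dict(zip(sires, rng.integers(0, 2, size=n_sires).tolist()))
    sire_of = np.repeat(np.arange(n_sires), litters_per_sire)
    n_sows = max(1, n // 2)
    sow_of = rng.permutation(np.repeat(np.arange(n_sows), 2)[:n])
    a = rng.normal(0, np.sqrt(sigma_a2), size=n_sires)
    v = rng.normal(0, np.sqrt(sigma_s2), size=n_sows)
    status = np.array([carrier[sires[i]] for i in sire_of], dtype=float)
    ys_idx = rng.integers(0, n_year_seasons, size=n)
    ys_eff = rng.normal(0, 0.3, size=n_year_seasons)
    parity_idx = np.minimum(rng.poisson(1.2, size=n), len(PARITY_LEVELS) - 1)
    parity_eff = np.array([0.0, 0.4, 0.6, 0.6, 0.4, 0.1])

    if poisson:
        eta = np.log(base_rate) + carrier_effect * status + a[sire_of] + v[sow_of]
        y = rng.poisson(np.exp(eta))
    else:
        e = rng.normal(0, np.sqrt(sigma_e2), size=n)
        y = (base_mean + parity_eff[parity_idx] + ys_eff[ys_idx]
             + carrier_effect * status + a[sire_of] + v[sow_of] + e)
    df = pd.DataFrame({
        "sire": [sires[i] for i in sire_of],
        "sow": [f"S{i:05d}" for i in sow_of],
        "parity": [PARITY_LEVELS[k] for k in parity_idx],
        "year_season": [f"ys{k:02d}" for k in ys_idx],
    })
    for t in LITTER_COLUMNS[4:]:
        df[t] = 0
    df[trait] = y
    ped = build_pedigree([(s, None, None) for s in sires])
    return df, carrier, ped
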