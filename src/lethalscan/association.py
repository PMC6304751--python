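"""Carrier and mating-type effects on litter traits with animal models.

Dataset-1 style fits regress litter phenotypes on the sire's carrier status
for a candidate haplotype allele (0 = non-carrier, 1 = carrier) with fixed
parity (classes 1..5, ">6"; omitted for MM) and farrowing year-season
effects, a random additive genetic effect of the sire with covariance
A sigma_a^2, a random sow effect and a residual.  TNB, BA and L24 are fit as
Gaussian responses (REML); SB and MM as Poisson responses (PQL), with the
carrier effect on the log-count scale.  Reported differences follow the
non-carrier minus carrier sign convention.

Dataset-2 style fits use the mating type for a candidate allele (00 = both
parents non-carrier, 01 = one carrier, 11 = both carriers) as the only fixed
effect besides the mean, retaining the random terms, and report adjusted
means per type with pairwise contrasts (significance label at P < 0.10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse

from .block_builder import Block, HaplotypeAllele
from .io_formats import MISSING_ALLELE, PedigreeTable, PhasedGenotypes
from .mixedlm import MixedModelFit, fit_lmm, fit_poisson_glmm
from .pedigree_kinship import a_matrix

LINEAR_TRAITS = ("TNB", "BA", "L24")
POISSON_TRAITS = ("SB", "MM")
SIGNIFICANCE_P = 0.10   # reporting label threshold


@dataclass
class EffectEstimate:
    trait: str
    effect: float               # carrier coefficient i (carrier minus non-carrier)
    se: float
    p_value: float
    difference: float           # non-carrier minus carrier, the reported sign
    means: dict = field(default_factory=dict)   # level -> (adjusted mean, SE)
    scale: str = "trait units"  # or "log-count"
    model: MixedModelFit | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_P


@dataclass
class MatingTypeResult:
    trait: str
    means: dict                  # type -> (adjusted mean, SE, n litters)
    contrasts: dict              # (typeA, typeB) -> (mean difference, SE, P)
    model: MixedModelFit | None = None


def carrier_status(geno: PhasedGenotypes, allele: HaplotypeAllele | tuple[Block, str],
                   ) -> np.ndarray:
    """Per-animal carrier status for a haplotype allele: 1, 0, or -1 undetermined.

    An animal is a carrier (1) when at least one of its two phased
    haplotypes over the block equals the allele string (homozygotes are
    carriers); -1 flags animals with missing alleles in the block.
    """
    if isinstance(allele, HaplotypeAllele):
        block, target = allele.block, allele.allele
    else:
        block, target = allele
    codes = np.array([int(c) for c in target], dtype=np.int8)
    sub = geno.alleles[:, block.snp_indices, :]
    if sub.shape[1] != len(codes):
        raise ValueError("allele string length does not match block SNP count")
    missing = np.any(sub == MISSING_ALLELE, axis=(1, 2))
    match = np.any(np.all(sub == codes[None, :, None], axis=1), axis=1)
    out = np.where(match, 1, 0).astype(np.int8)
    out[missing] = -1
    return out


# ---------------------------------------------------------------------------
# design construction


def _dummies(series: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    levels = sorted(series.astype(str).unique())
    cols, names = [], []
    for lv in levels[1:]:          # first level is the reference
        cols.append((series.astype(str) == lv).to_numpy(float))
        names.append(f"{prefix}[{lv}]")
    if not cols:
        return np.empty((len(series), 0)), []
    return np.column_stack(cols), names


def _drop_aliased(X: np.ndarray, names: list[str], protected: set[str],
                  ) -> tuple[np.ndarray, list[str]]:
    """Greedily drop columns that are linearly dependent on earlier ones.

    Protected columns (intercept, the effect of interest) are ordered first
    so an aliased nuisance level is dropped instead, with a warning.
    """
    order = sorted(range(X.shape[1]), key=lambda j: (names[j] not in protected, j))
    keep: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j in order:
        cand = np.column_stack([basis, X[:, j]])
        if np.linalg.matrix_rank(cand) > basis.shape[1]:
            keep.append(j)
            basis = cand
        elif names[j] in protected:
            raise ValueError(f"effect column {names[j]!r} is confounded with other terms")
        else:
            warnings.warn(f"dropping aliased fixed-effect level {names[j]}")
    keep.sort()
    return X[:, keep], [names[j] for j in keep]


def _build_design(records: pd.DataFrame, trait: str, effect_col: np.ndarray,
                  effect_names: list[str], ped: PedigreeTable,
                  include_parity: bool | None = None):
    """Assemble (y, X, Z, W, Ainv, names) for one trait."""
    y = records[trait].to_numpy(float)
    n = len(records)
    if include_parity is None:
        include_parity = trait != "MM"   # parity is not fitted for MM
    parts = [np.ones((n, 1))]
    names = ["intercept"]
    if effect_col.ndim == 1:
        effect_col = effect_col[:, None]
    parts.append(effect_col.astype(float))
    names += effect_names
    if include_parity and records["parity"].nunique() > 1:
        d, dn = _dummies(records["parity"], "parity")
        parts.append(d)
        names += dn
    if "year_season" in records and records["year_season"].nunique() > 1:
        d, dn = _dummies(records["year_season"], "ys")
        parts.append(d)
        names += dn
    X = np.column_stack(parts)
    X, names = _drop_aliased(X, names, protected={"intercept", *effect_names})

    A, animals = a_matrix(ped)
    aidx = {a: i for i, a in enumerate(animals)}
    missing_sires = sorted(set(records["sire"]) - set(aidx))
    if missing_sires:
        raise ValueError(f"sires absent from pedigree: {missing_sires[:5]}")
    Ainv = np.linalg.inv(A)
    rows = np.arange(n)
    Z = sparse.csr_matrix((np.ones(n), (rows, [aidx[s] for s in records["sire"]])),
                          shape=(n, len(animals)))
    sows = sorted(records["sow"].unique())
    sidx = {s: i for i, s in enumerate(sows)}
    W = sparse.csr_matrix((np.ones(n), (rows, [sidx[s] for s in records["sow"]])),
                          shape=(n, len(sows)))
    return y, X, Z, W, Ainv, names


def _adjusted_means(fit: MixedModelFit, X: np.ndarray, names: list[str],
                    effect_name: str, levels=(0.0, 1.0)) -> dict:
    """Population-averaged (least-squares) means at each level of the effect."""
    j = names.index(effect_name)
    xbar = X.mean(axis=0)
    out = {}
    for lv in levels:
        x = xbar.copy()
        x[j] = lv
        mean = float(x @ fit.beta)
        se = float(np.sqrt(max(x @ fit.cov_beta @ x, 0.0))) if fit.cov_beta is not None else np.nan
        out[int(lv)] = (mean, se)
    return out


def _prepare_carrier(records: pd.DataFrame, carrier: dict[str, int] | pd.Series,
                     ) -> np.ndarray:
    carrier = dict(carrier)
    status = np.array([carrier.get(s, -1) for s in records["sire"]], dtype=float)
    if np.any(status < 0):
        raise ValueError("records reference sires with undetermined carrier status")
    if len(np.unique(status)) < 2:
        raise ValueError("carrier status is constant across sires; no contrast to estimate")
    return status


def fit_linear_animal_model(records: pd.DataFrame, trait: str,
                            carrier: dict[str, int] | pd.Series,
                            ped: PedigreeTable) -> EffectEstimate:
    """REML animal-model fit of a sire carrier effect on TNB, BA or L24."""
    if trait not in LINEAR_TRAITS:
        raise ValueError(f"linear model is for {LINEAR_TRAITS}, got {trait!r}")
    status = _prepare_carrier(records, carrier)
    y, X, Z, W, Ainv, names = _build_design(records, trait, status, ["carrier"], ped)
    fit = fit_lmm(y, X, Z, W, Ainv, fixed_names=names)
    est, se, p = fit.wald("carrier")
    means = _adjusted_means(fit, X, names, "carrier")
    return EffectEstimate(trait, est, se, p, difference=-est, means=means,
                          scale="trait units", model=fit)


def fit_poisson_animal_model(records: pd.DataFrame, trait: str,
                             carrier: dict[str, int] | pd.Series,
                             ped: PedigreeTable) -> EffectEstimate:
    """Poisson (PQL) animal-model fit of a sire carrier effect on SB or MM.

    The effect is on the log-count scale; ``difference`` carries the
    non-carrier minus carrier convention.  Parity is excluded for MM.
    """
    if trait not in POISSON_TRAITS:
        raise ValueError(f"Poisson model is for {POISSON_TRAITS}, got {trait!r}")
    status = _prepare_carrier(records, carrier)
    y, X, Z, W, Ainv, names = _build_design(records, trait, status, ["carrier"], ped)
    fit = fit_poisson_glmm(y, X, Z, W, Ainv, fixed_names=names)
    est, se, p = fit.wald("carrier")
    means = _adjusted_means(fit, X, names, "carrier")
    return EffectEstimate(trait, est, se, p, difference=-est, means=means,
                          scale="log-count", model=fit)


MATING_TYPES = ("00", "01", "11")


def fit_mating_type_model(records: pd.DataFrame, trait: str,
                          mating_type: pd.Series | np.ndarray,
                          ped: PedigreeTable,
                          include_random: bool = True) -> MatingTypeResult:
    """Mating-type model: y = mean + matingType + a + v + e.

    The population mean and the mating-type factor are the only fixed
    effects.  Types "10" are folded into "01" (one carrier parent).
    Adjusted means are reported per present type; contrasts only for present
    pairs.
    """
    mt = pd.Series(np.asarray(mating_type, dtype=object), index=records.index).astype(str)
    mt = mt.replace({"10": "01"})
    bad = set(mt.unique()) - set(MATING_TYPES)
    if bad:
        raise ValueError(f"unknown mating types {sorted(bad)}")
    present = [t for t in MATING_TYPES if (mt == t).any()]
    if len(present) < 2:
        raise ValueError("need at least two mating types present")
    n = len(records)
    cols = np.column_stack([(mt == t).to_numpy(float) for t in present[1:]])
    names = ["intercept"] + [f"mt[{t}]" for t in present[1:]]
    X = np.column_stack([np.ones(n), cols])

    A, animals = a_matrix(ped)
    aidx = {a: i for i, a in enumerate(animals)}
    rows = np.arange(n)
    Z = sparse.csr_matrix((np.ones(n), (rows, [aidx[s] for s in records["sire"]])),
                          shape=(n, len(animals)))
    sows = sorted(records["sow"].unique())
    sidx = {s: i for i, s in enumerate(sows)}
    W = sparse.csr_matrix((np.ones(n), (rows, [sidx[s] for s in records["sow"]])),
                          shape=(n, len(sows)))
    if not include_random:
        Z = sparse.csr_matrix((n, len(animals)))
        W = sparse.csr_matrix((n, len(sows)))
    y = records[trait].to_numpy(float)
    fit = fit_lmm(y, X, Z, W, np.linalg.inv(A), fixed_names=names)

    means = {}
    for t in present:
        if t == present[0]:
            vec = np.zeros(len(names))
            vec[0] = 1.0
        else:
            vec = np.zeros(len(names))
            vec[0] = 1.0
            vec[names.index(f"mt[{t}]")] = 1.0
        mean = float(vec @ fit.beta)
        se = float(np.sqrt(max(vec @ fit.cov_beta @ vec, 0.0)))
        means[t] = (mean, se, int((mt == t).sum()))
    contrasts = {}
    for ta, tb in combinations(present, 2):
        va = np.zeros(len(names))
        vb = np.zeros(len(names))
        if ta != present[0]:
            va[names.index(f"mt[{ta}]")] = 1.0
        if tb != present[0]:
            vb[names.index(f"mt[{tb}]")] = 1.0
        d = va - vb
        diff = float(d @ fit.beta)
        se = float(np.sqrt(max(d @ fit.cov_beta @ d, 0.0)))
        from scipy.stats import norm
        p = float(2 * norm.sf(abs(diff / se))) if se > 0 else float("nan")
        contrasts[(ta, tb)] = (diff, se, p)
    return MatingTypeResult(trait, means, contrasts, model=fit)


def effects_table(estimates: list[EffectEstimate], labels: list[str] | None = None,
                  ) -> pd.DataFrame:
    rows = []
    for k, e in enumerate(estimates):
        rows.append({
            "locus": labels[k] if labels else "",
            "trait": e.trait,
            "scale": e.scale,
            "mean_noncarrier": e.means.get(0, (np.nan, np.nan))[0],
            "mean_carrier": e.means.get(1, (np.nan, np.nan))[0],
            "difference_0_minus_1": e.difference,
            "se": e.se,
            "p_value": e.p_value,
            "significant_p_lt_0.10": e.significant,
        })
    return pd.DataFrame(rows)
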