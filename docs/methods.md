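# Methods

`lethalscan` detects recessive alleles that kill homozygous conceptuses
before birth, from the genotypes of live animals only: a lethal segregating
at frequency *f* leaves carriers in the population but no live homozygote,
so the observed count of homozygous animals falls far below its
random-mating expectation. The package implements the scan for phased SNP
panels of breeding populations (the motivating setting is purebred pig
sire lines), the mixed "animal models" that test whether a candidate
haplotype depresses litter traits, gene-flanking annotation, and a
synthetic-population generator that makes every stage testable without any
proprietary data.

## Deficiency scan

**Quality control.** Animals with genotype call rate < 95% are removed
first; SNP statistics are then computed on the surviving animals, from
called genotypes only (the animal-first order avoids circular call-rate
definitions). A SNP is kept iff call rate ≥ 95%, MAF ≥ 5%, it maps to an
autosome, and the 3-class Pearson Hardy–Weinberg chi-square is < 600 (a
deliberately permissive bound that removes only gross genotyping
artifacts; whether the original rule used 2 or 3 genotype classes is not
documented, so the 3-class Pearson form is used and recorded here).

**Expected homozygotes.**

* SNP: `E = N · maf²`, with `N` the called animals at that SNP.
* Haplotype allele, two selectable conventions: `hwe` (default)
  `E = N · f²` with `f` the allele frequency of the 2N phased haplotypes;
  `vanraden` `E = N/4 · c²` with `c` the carrier frequency. Under HWE with
  a rare allele `c ≈ 2f` and the two coincide; the `hwe` default was chosen
  because published expectation columns in this literature track `N·f²`.
  Both expectations are reported and the convention is recorded per result.

**Test.** The one-class deficiency chi-square `(O − E)²/E` on 1 df, with
the upper-tail P-value, Bonferroni-corrected over the family actually
tested (QC-passing SNPs and filtered haplotype alleles form separate
families — no cross-correction). A locus is a lethal **candidate** when
`O = 0`, `E` exceeds the minimum (strictly > 5 for SNPs, > 6 for haplotype
alleles) and corrected `P < 0.01`. Requiring `O = 0` makes the two-sided
statistic effectively one-sided in the deficiency direction.

**Blocks.** Sliding windows of 400 Kb advancing in 100 Kb steps on a bp
grid anchored at coordinate 0 (so block bounds land on round coordinates,
e.g. 82.0–82.4 Mb); a window with start `s` covers positions
`[s+1, s+window]`, right edge inclusive. Windows retaining ≤ 3 QC-passing
SNPs are dropped; haplotype alleles with frequency < 0.01 are removed
after counting. Animals with any missing allele inside a block are
excluded from that block's denominators rather than having haplotypes
fabricated. Adjacent significant windows are not merged at detection time;
merging is a reporting choice left to the analyst.

## Association models

For each candidate haplotype allele, litter records are regressed on the
sire's carrier status (0 = non-carrier, 1 = carrier; homozygous carriers
do not exist for a true lethal):

    y = Xb + Mi + Za + Wv + e

with fixed parity (1, 2, 3, 4, 5, >6; omitted for mummified fetuses) and
farrowing year-season classes in `X`, the carrier indicator in `M`, a
random additive genetic effect `a ~ N(0, A σa²)` of the service sire
(`A` the pedigree numerator relationship matrix), a random sow effect
`v ~ N(0, I σs²)` and residual `e ~ N(0, I σe²)`. TNB, BA and L24 are fit
as Gaussian responses; SB and MM as Poisson responses with a log link, the
carrier effect then living on the log-count scale. Reported differences
follow the non-carrier − carrier convention. Wald tests are used for
effects; `P < 0.10` is reproduced as a reporting label only. The sow
variance is written σs², distinct from the residual σe² (the source
literature overloads one symbol for both; treating them as one component
would be a specification error, so they are separated here and documented).

*Estimation.* No installed library fits a general pedigree covariance, so
the engine is purpose-built on Henderson's mixed-model equations with a
sparse factorization (`mixedlm.py`). The restricted likelihood is
evaluated from a single sparse LU of the MME coefficient matrix (the
`log|T|` terms cancel, leaving only `log|C|`), with the residual variance
profiled out, and maximized derivative-free (Nelder–Mead) over the two log
variance ratios; ratios are clamped to `[e⁻¹³, e⁷]` and components floored
at 1e-8. Convergence: simplex tolerance 1e-3 on the log-ratios, at most
200 evaluations. Poisson fits use penalized quasi-likelihood: the working
response `z = η + (y − μ)/μ` with weights `μ` is iterated through the same
weighted MME (residual precision fixed at the weights); variance
components are searched at the first and third outer iteration and then
frozen, since the working-scale surface is stable, and the loop stops when
the linear predictor moves < 1e-5. PQL slope estimates for a sire-level
indicator are effectively unbiased here because the frailty distribution
does not depend on carrier status; PQL's known downward bias in variance
components at low counts is accepted, as variance components are nuisance
parameters in these fits.

*Aliasing.* Fixed-effect levels perfectly confounded with other terms are
dropped greedily with a warning; the intercept and the effect of interest
are protected, and a confounded effect of interest is an error.

Dataset-2 style fits replace the carrier indicator by the **mating type**
(00 / 01 / 11 = neither / one / both parents carriers; 10 is folded into
01) as the only fixed term besides the mean, retaining both random terms
(with ~50 litters the random variances shrink to the floor and the
adjusted means reduce to group means, which is the intended behaviour of
the published small-sample model; a `include_random=False` variant is
available). Adjusted means per type and all pairwise contrasts are
reported. Population-averaged (least-squares) means are computed at the
average observed design row with the factor of interest set to each level.

## Relationship matrix

`A` is computed densely by the tabular recursion over the founders-first
pedigree order — `a(i,j) = ½[a(j,s_i) + a(j,d_i)]`,
`a(i,i) = 1 + ½ a(s_i, d_i)`, unknown parents contributing 0 — which is
exact and ample at study scale (10³–10⁴ animals). Animals appearing only
as parents are promoted to founders automatically. An independent
gene-dropping Monte-Carlo estimator (`gene_drop_kinship`) exists solely as
a test oracle and shares no code with the tabular method.

## Gene flanking annotation

A gene is reported for a block when it overlaps the block or its bp gap to
the nearer edge is < 400 Kb. The signed distance is 0 for any overlap
("Within"), `+round((geneStart − blockEnd)/1000)` Kb downstream,
`−round((blockStart − geneEnd)/1000)` Kb upstream; rounding is to the
nearest Kb (floor and round agree on all reference rows used in tests).
Block bounds are the window bounds in bp (Mb label × 10⁶). All internal
coordinates are 1-based inclusive; BED input is converted on read.

## Synthetic populations

The generator emulates the target study design: ~1359 genotyped AI boars
(default), 192 service sires, 3460 sows of unknown genotype, 5340 litters.
Defaults: conceptus count per litter Poisson with mean μ = 12; stillbirth
rate 5% of born; neonatal loss 3% of born alive; background mummified
fetuses Poisson(0.2) per litter; parity and year-season shifts plus sire
additive (σa² = 0.25), sow (σs² = 0.25) and residual (σe² = 1.0) effects
on the litter-size traits, rounded to non-negative counts preserving
BA ≤ TNB and L24 ≤ BA. These place the carrier-effect magnitudes and
per-litter dispersion in the range reported for purebred sire-line litter
records after fixed-effect adjustment.

Planted lethal haplotypes are all-"1" strings over every SNP of a window,
in complete LD, at a target frequency in the live population; sampling
draws haplotypes at `f/(1−f)` and rejects (redraws) homozygous diplotypes,
which reproduces exactly the truncated-HW distribution of survivors — so
the realized live-animal frequency equals the target and no genotyped
animal is ever homozygous for a planted allele. The first SNP of a planted
block is an anchor whose alternative allele occurs only on the lethal
haplotype, giving the single-SNP scan the same plantable signal. Each
homozygous conceptus dies in utero (penetrance 1 by default; a partial
penetrance knob exists for power studies) and is recorded as a mummified
fetus with probability π_mm.

Background SNPs are in linkage equilibrium — LD decay, selection and drift
are deliberately out of scope — which has one structural consequence:
common multi-SNP haplotype alleles only exist if windows hold few markers.
Default marker spacing is therefore 70 Kb (5–6 SNPs per 400 Kb window)
rather than chip density. Passing tests on these populations demonstrate
the counting, testing and model machinery, not robustness to real LD
structure, phasing error or imputation error, none of which are modeled.
Phase is exact by construction, consistent with keeping phasing tools out
of scope.

All randomness fans out from one master seed through numpy `SeedSequence`
spawning (children: founder genotypes, sow genotypes, litters, background
frequencies), so identical configurations are bit-reproducible.

## Verification design and problem sizes

The estimator-verification suite draws data exactly from the association
model: 1500 sires with carrier status Bernoulli(½), 5000 litters, sows
with two litters each; Gaussian traits with σa² = σs² = 0.25, σe² = 1.0
and a −0.30 piglet carrier effect; Poisson MM with baseline rate 0.40 per
litter, log-scale frailties of variance 0.05 and a +0.20 log-scale carrier
effect. These sizes were fixed by a prior power calculation: the carrier
contrast's nominal SE is ≈ 0.04 in both designs, so the ±0.10 recovery
band corresponds to ≈ 2.5 SE and the 19/20-seeds criterion has adequate
power, while the sire-level term (4σa²/n_sires) — which bounds the SE from
below regardless of litter count — stays small. Null calibration uses 300
sires × 3 litters. The scan suite uses N = 1500 boars with planted
frequencies 0.12/0.15/0.20 (π_mm = 0.5) and 20 null replicates at
N = 1000, several thousand haplotype alleles per replicate.

## Known limitations

* No LD model: block alleles in the simulator are either planted (full LD)
  or background (no LD); power against partially-linked lethals is not
  assessed.
* PQL is a first-order approximation; for very low counts (< ~0.1 per
  litter) its variance components are biased low.
* The X chromosome is excluded by the autosomes-only QC rule; no
  hemizygous logic exists.
* FDR or permutation multiplicity control is not provided; Bonferroni
  only, as in the detection rule implemented.
* Imputation accuracy cannot be recomputed from standard formats; poorly
  imputed markers can only be removed via a pre-supplied exclusion list.
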