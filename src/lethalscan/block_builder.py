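"""Sliding haplotype-block construction and allele enumeration.

Windows are 400 Kb wide and slide in 100 Kb steps on a bp grid anchored at
coordinate 0, so a window with start ``s`` covers positions [s+1, s+window]
(1-based inclusive).  Anchoring at 0 rather than at the first SNP keeps
block bounds on round coordinates (e.g. 82.0-82.4 Mb).  Blocks retaining
3 SNPs or fewer are discarded; haplotype alleles with frequency below 0.01
are removed after counting.  Animals with any missing allele inside a block
are excluded from that block's denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING_ALLELE, PhasedGenotypes, SnpMap


@dataclass
class ScanConfig:
    window_bp: int = 400_000
    step_bp: int = 100_000
    min_snps: int = 4          # blocks with 3 SNPs or less are excluded
    min_allele_freq: float = 0.01

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window size must be positive")
        if self.step_bp > self.window_bp:
            raise ValueError("step must not exceed window size")


@dataclass
class Block:
    """A genomic window and its member SNPs."""

    chrom: str
    start: int            # window covers [start + 1, start + window] in bp
    end: int              # = start + window
    snp_indices: np.ndarray  # indices into the genome-wide SnpMap

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start / 1e6:.1f}-{self.end / 1e6:.1f}Mb"


@dataclass
class HaplotypeAllele:
    """One distinct allele string of a block with its population counts."""

    block: Block
    allele: str           # e.g. "01101" over the block's member SNPs
    copies: int           # haplotype copies among used animals
    n_used: int           # animals with no missing allele in the block
    carriers: int         # animals with >= 1 copy
    homozygotes: int      # animals with 2 copies
    carrier_ids: list[str] = field(default_factory=list, repr=False)

    @property
    def frequency(self) -> float:
        return self.copies / (2 * self.n_used) if self.n_used else 0.0

    @property
    def carrier_frequency(self) -> float:
        return self.carriers / self.n_used if self.n_used else 0.0


def make_windows(positions: np.ndarray, config: ScanConfig) -> np.ndarray:
    """Window start coordinates 0, step, 2*step, ... while start < max position."""
    positions = np.asarray(positions)
    if len(positions) == 0:
        return np.array([], dtype=np.int64)
    max_pos = int(positions.max())
    return np.arange(0, max_pos, config.step_bp, dtype=np.int64)


def assign_snps(start: int, snpmap: SnpMap, chrom: str, config: ScanConfig) -> np.ndarray:
    """Indices of SNPs inside [start+1, start+window] on the chromosome (inclusive right edge)."""
    idx = snpmap.chrom_indices(chrom)
    pos = snpmap.pos[idx]
    inside = (pos >= start + 1) & (pos <= start + config.window_bp)
    return idx[inside]


def build_blocks(snpmap: SnpMap, config: ScanConfig | None = None,
                 snp_subset: np.ndarray | None = None) -> list[Block]:
    """All sliding windows over every chromosome, keeping blocks with > min SNPs.

    ``snp_subset`` restricts to QC-passing SNP indices (window membership is
    evaluated on the surviving SNPs).
    """
    config = config or ScanConfig()
    sub = SnpMap(snpmap.chrom[snp_subset], snpmap.pos[snp_subset], snpmap.ids[snp_subset],
                 snpmap.ref[snp_subset], snpmap.alt[snp_subset]) if snp_subset is not None else snpmap
    orig = np.asarray(snp_subset) if snp_subset is not None else np.arange(len(snpmap))
    blocks = []
    for chrom in sub.chromosomes:
        ci = sub.chrom_indices(chrom)
        for start in make_windows(sub.pos[ci], config):
            members = assign_snps(int(start), sub, chrom, config)
            if len(members) >= config.min_snps:
                blocks.append(Block(chrom, int(start), int(start) + config.window_bp,
                                    orig[members]))
    return blocks


def enumerate_alleles(geno: PhasedGenotypes, block: Block,
                      config: ScanConfig | None = None,
                      collect_carrier_ids: bool = False) -> list[HaplotypeAllele]:
    """Distinct haplotype alleles of a block with frequency/carrier/homozygote counts.

    Animals with a missing allele anywhere in the block are dropped from the
    denominators.  Alleles below the minimum frequency are removed after
    counting.  Output is ordered by descending frequency, ties broken
    lexicographically on the allele string.
    """
    config = config or ScanConfig()
    sub = geno.alleles[:, block.snp_indices, :]          # (n, k, 2)
    used = ~np.any(sub == MISSING_ALLELE, axis=(1, 2))
    idx_used = np.flatnonzero(used)
    n_used = len(idx_used)
    if n_used == 0:
        return []
    haps = np.concatenate([sub[idx_used, :, 0], sub[idx_used, :, 1]], axis=0)  # (2n, k)
    uniq, inv = np.unique(haps, axis=0, return_inverse=True)
    h1, h2 = inv[:n_used], inv[n_used:]
    out = []
    for a in range(len(uniq)):
        c1, c2 = h1 == a, h2 == a
        copies = int(c1.sum() + c2.sum())
        carrier_mask = c1 | c2
        hom_mask = c1 & c2
        allele = "".join(map(str, uniq[a]))
        ha = HaplotypeAllele(block, allele, copies, n_used,
                             int(carrier_mask.sum()), int(hom_mask.sum()))
        if collect_carrier_ids:
            ha.carrier_ids = [geno.animals[i] for i in idx_used[carrier_mask]]
        out.append(ha)
    out = [h for h in out if h.frequency >= config.min_allele_freq]
    out.sort(key=lambda h: (-h.frequency, h.allele))
    return out


def alleles_table(alleles: list[HaplotypeAllele]) -> pd.DataFrame:
    rows = [{
        "chrom": h.block.chrom,
        "start_mb": h.block.start / 1e6,
        "end_mb": h.block.end / 1e6,
        "n_snps": h.block.n_snps,
        "allele": h.allele,
        "frequency": h.frequency,
        "carriers": h.carriers,
        "homozygotes": h.homozygotes,
    } for h in alleles]
    return pd.DataFrame(rows, columns=["chrom", "start_mb", "end_mb", "n_snps",
                                       "allele", "frequency", "carriers", "homozygotes"])
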