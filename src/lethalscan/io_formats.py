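"""Readers and writers for every external representation the pipeline touches.

All genomic coordinates are held 1-based inclusive internally; BED input is
converted on read.  Chromosome labels are kept as strings ("1".."18"); a
leading "chr" is stripped on read so that SNP maps and gene tables written
with either convention compare equal.  No statistics live in this module.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING_ALLELE = -1
UNKNOWN_PARENT = "0"

LITTER_COLUMNS = ["sire", "sow", "parity", "year_season", "TNB", "BA", "L24", "SB", "MM"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _norm_chrom(label: str) -> str:
    label = str(label)
    return label[3:] if label.lower().startswith("chr") else label


@dataclass
class SnpMap:
    """Per-SNP map: chromosome, 1-based bp position, id and allele labels."""

    chrom: np.ndarray  # str per SNP
    pos: np.ndarray    # int64, 1-based
    ids: np.ndarray    # str, unique
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if np.any(self.pos < 1):
            raise FormatError("SNP positions must be >= 1 (1-based)")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("SNP ids must be unique")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise FormatError(f"positions not strictly increasing on chromosome {c}")

    def __len__(self) -> int:
        return len(self.pos)

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)


@dataclass
class PhasedGenotypes:
    """Allele matrix of shape (animals, SNPs, 2) with codes {0, 1, -1=missing}."""

    animals: list[str]
    alleles: np.ndarray
    phased: bool = True

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise FormatError("allele matrix must have shape (animals, snps, 2)")
        if self.alleles.shape[0] != len(self.animals):
            raise FormatError("animal ids inconsistent with allele matrix")
        if len(set(self.animals)) != len(self.animals):
            raise FormatError("animal ids must be unique")

    @property
    def n_animals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def genotypes(self) -> np.ndarray:
        """Unphased dosage matrix (animals, snps): 0/1/2, -1 where any allele missing."""
        g = self.alleles.sum(axis=2).astype(np.int8)
        g[np.any(self.alleles == MISSING_ALLELE, axis=2)] = MISSING_ALLELE
        return g


def read_phased_vcf(path: str | os.PathLike) -> tuple[SnpMap, PhasedGenotypes]:
    """Read a phased biallelic VCF into a SnpMap and allele matrix.

    GT fields must use the "|" separator; a "/" separated genotype raises
    FormatError naming the site.  Missing genotypes become the missing code.
    """
    vcf = VCF(str(path))
    animals = list(vcf.samples)
    chrom, pos, ids, ref, alt = [], [], [], [], []
    cols = []
    for v in vcf:
        if len(v.ALT) > 1:
            raise FormatError(f"multi-allelic site {v.CHROM}:{v.POS} not supported")
        site = np.full((len(animals), 2), MISSING_ALLELE, dtype=np.int8)
        for i, g in enumerate(v.genotypes):  # [a0, a1, phased]
            a0, a1, ph = g[0], g[1], g[2]
            if a0 >= 0 and a1 >= 0 and not ph:
                raise FormatError(f"unphased genotype at {v.CHROM}:{v.POS} sample {animals[i]}")
            if a0 >= 0:
                site[i, 0] = a0
            if a1 >= 0:
                site[i, 1] = a1
        chrom.append(_norm_chrom(v.CHROM))
        pos.append(v.POS)
        ids.append(v.ID if v.ID not in (None, ".") else f"{_norm_chrom(v.CHROM)}_{v.POS}")
        ref.append(v.REF)
        alt.append(v.ALT[0] if v.ALT else "B")
        cols.append(site)
    vcf.close()
    if not cols:
        raise FormatError(f"no variant records in {path}")
    alleles = np.stack(cols, axis=1)
    snpmap = SnpMap(np.array(chrom, dtype=object), np.array(pos), np.array(ids, dtype=object),
                    np.array(ref, dtype=object), np.array(alt, dtype=object))
    return snpmap, PhasedGenotypes(animals, alleles, phased=True)


def write_phased_vcf(path: str | os.PathLike, snpmap: SnpMap, geno: PhasedGenotypes) -> None:
    """Write phased genotypes as a minimal VCF v4.2 with "|" separated GTs."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in snpmap.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.animals) + "\n")
        for j in range(len(snpmap)):
            gts = []
            for i in range(geno.n_animals):
                a0, a1 = geno.alleles[i, j]
                s0 = "." if a0 == MISSING_ALLELE else str(int(a0))
                s1 = "." if a1 == MISSING_ALLELE else str(int(a1))
                gts.append(f"{s0}|{s1}")
            fh.write(f"{snpmap.chrom[j]}\t{snpmap.pos[j]}\t{snpmap.ids[j]}\t"
                     f"{snpmap.ref[j]}\t{snpmap.alt[j]}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# pedigree


@dataclass
class PedigreeTable:
    """Pedigree records ordered founders-first (parents precede offspring)."""

    df: pd.DataFrame = field(repr=False)  # columns animal, sire, dam

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    @property
    def animals(self) -> list[str]:
        return list(self.df["animal"])

    def parents(self, animal: str) -> tuple[str, str]:
        row = self.df.loc[self.df["animal"] == animal].iloc[0]
        return row["sire"], row["dam"]

    def __len__(self) -> int:
        return len(self.df)


def _topo_sort_pedigree(df: pd.DataFrame) -> pd.DataFrame:
    g = nx.DiGraph()
    g.add_nodes_from(df["animal"])
    for _, r in df.iterrows():
        for p in (r["sire"], r["dam"]):
            if p != UNKNOWN_PARENT:
                g.add_edge(p, r["animal"])
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cyc = nx.find_cycle(g)
        raise FormatError(f"pedigree contains a cycle through {cyc[0][0]!r}") from None
    known = dict(zip(df["animal"], zip(df["sire"], df["dam"])))
    rows = []
    for a in order:  # parents-only animals become founders
        sire, dam = known.get(a, (UNKNOWN_PARENT, UNKNOWN_PARENT))
        rows.append((a, sire, dam))
    return pd.DataFrame(rows, columns=["animal", "sire", "dam"])


def build_pedigree(records: list[tuple[str, str | None, str | None]]) -> PedigreeTable:
    """Normalize unknown parents and topologically sort; cycles raise."""
    rows = []
    for animal, sire, dam in records:
        def norm(p):
            return UNKNOWN_PARENT if p in (None, "", "0", "-", "NA", ".") else str(p)
        rows.append((str(animal), norm(sire), norm(dam)))
    df = pd.DataFrame(rows, columns=["animal", "sire", "dam"])
    if df["animal"].duplicated().any():
        dup = df.loc[df["animal"].duplicated(), "animal"].iloc[0]
        raise FormatError(f"duplicate pedigree entry for animal {dup!r}")
    return PedigreeTable(_topo_sort_pedigree(df))


def read_pedigree(path: str | os.PathLike) -> PedigreeTable:
    df = pd.read_csv(path, dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("animal", "sire", "dam"):
        if col not in df.columns:
            raise FormatError(f"pedigree file missing column {col!r}")
    return build_pedigree(list(df[["animal", "sire", "dam"]].itertuples(index=False, name=None)))


def write_pedigree(path: str | os.PathLike, ped: PedigreeTable) -> None:
    ped.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# litter records


def validate_litters(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw litter table into valid records and rejected rows.

    Enforces the count invariants: all counts >= 0, BA <= TNB, L24 <= BA.
    The rejected frame carries a ``reason`` column and the original row index.
    """
    missing = [c for c in LITTER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"litter file missing columns {missing}")
    counts = df[["TNB", "BA", "L24", "SB", "MM"]].astype(float)
    reasons = pd.Series("", index=df.index, dtype=object)
    bad = (counts < 0).any(axis=1)
    reasons[bad] = "negative count"
    m = ~bad & (counts["BA"] > counts["TNB"])
    reasons[m] = "BA > TNB"
    bad |= m
    m = ~bad & (counts["L24"] > counts["BA"])
    reasons[m] = "L24 > BA"
    bad |= m
    valid = df.loc[~bad].copy()
    for c in ["TNB", "BA", "L24", "SB", "MM"]:
        valid[c] = valid[c].astype(int)
    rejected = df.loc[bad].copy()
    rejected["reason"] = reasons[bad]
    return valid, rejected


def read_litters(path: str | os.PathLike, strict: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a litter CSV; returns (valid records, rejected rows with reasons)."""
    df = pd.read_csv(path, dtype={"sire": str, "sow": str, "parity": str, "year_season": str})
    valid, rejected = validate_litters(df)
    if strict and len(rejected):
        rows = list(rejected.index[:5])
        raise FormatError(f"invalid litter rows at indices {rows}: "
                          f"{list(rejected['reason'][:5])}")
    return valid, rejected


def write_litters(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df[LITTER_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# gene coordinates


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval, 1-based inclusive."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"gene {self.name}: start > end")
        if self.start < 1:
            raise FormatError(f"gene {self.name}: start < 1")


def _read_bed_genes(path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
                     dtype={0: str, 3: str})
    out = []
    for r in df.itertuples(index=False):
        if int(r.start) >= int(r.end):
            raise FormatError(f"BED interval with start >= end for {r.name}")
        # BED is 0-based half-open; internal coordinates are 1-based inclusive
        out.append(GeneRecord(str(r.name), _norm_chrom(r.chrom), int(r.start) + 1, int(r.end)))
    return out


def _read_gff3_genes(path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["seqid", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"],
                     dtype={"seqid": str, "attributes": str})
    out = []
    for r in df.itertuples(index=False):
        if r.type != "gene":
            continue
        name = None
        for kv in str(r.attributes).split(";"):
            k, _, v = kv.partition("=")
            if k.strip() in ("Name", "gene_name"):
                name = v.strip()
                break
            if k.strip() == "ID" and name is None:
                name = v.strip()
        if name is None:
            name = f"{r.seqid}:{r.start}-{r.end}"
        out.append(GeneRecord(name, _norm_chrom(r.seqid), int(r.start), int(r.end)))
    return out


def read_genes(path: str | os.PathLike, format: str = "bed") -> list[GeneRecord]:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based).

    Both are normalized to 1-based inclusive GeneRecords.
    """
    if format == "bed":
        return _read_bed_genes(path)
    if format == "gff3":
        return _read_gff3_genes(path)
    raise FormatError(f"unknown gene file format {format!r} (expected 'bed' or 'gff3')")
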