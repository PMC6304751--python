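"""Candidate-gene annotation around significant haplotype blocks.

A gene is reported when it lies inside the block or within the flank
distance (default 400 Kb) of either edge.  Distances use the signed-Kb
convention: 0 for any overlap ("Within"), positive gene-start minus
block-end for a gene beyond the block ("Down-stream"), negative block-start
minus gene-end for a gene before it ("Up-stream"), rounded to the nearest
whole Kb.  Block bounds are the window bounds in bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import GeneRecord

FLANK_BP_DEFAULT = 400_000


@dataclass(frozen=True)
class FlankAnnotation:
    chrom: str
    block_start: int          # 1-based inclusive bp
    block_end: int
    gene: GeneRecord
    distance_kb: int          # signed; 0 = overlap
    location: str             # Within / Up-stream / Down-stream


def flank_distance(block_start: int, block_end: int, gene: GeneRecord,
                   chrom: str | None = None) -> tuple[int, str]:
    """Signed distance in whole Kb from a block to a gene, with location label."""
    if chrom is not None and gene.chrom != chrom:
        raise ValueError(f"gene {gene.name} on chromosome {gene.chrom}, block on {chrom}")
    if gene.start <= block_end and gene.end >= block_start:
        return 0, "Within"
    if gene.start > block_end:
        return int(round((gene.start - block_end) / 1000)), "Down-stream"
    return -int(round((block_start - gene.end) / 1000)), "Up-stream"


def annotate_blocks(blocks: list[tuple[str, int, int]], genes: list[GeneRecord],
                    flank_bp: int = FLANK_BP_DEFAULT) -> list[FlankAnnotation]:
    """Annotate blocks (chrom, start bp, end bp) with genes within the flank.

    Overlapping genes count; the bound on the bp gap is strict ("less than"
    the flank).  Output is sorted per block by signed distance.
    """
    out = []
    for chrom, bstart, bend in blocks:
        hits = []
        for g in genes:
            if g.chrom != chrom:
                continue
            kb, label = flank_distance(bstart, bend, g)
            if label == "Within":
                gap = 0
            elif label == "Down-stream":
                gap = g.start - bend
            else:
                gap = bstart - g.end
            if gap < flank_bp:
                hits.append(FlankAnnotation(chrom, bstart, bend, g, kb, label))
        hits.sort(key=lambda h: h.distance_kb)
        out.extend(hits)
    return out


def annotation_table(annotations: list[FlankAnnotation]) -> pd.DataFrame:
    rows = [{
        "SSC": a.chrom,
        "block_start_bp": a.block_start,
        "block_end_bp": a.block_end,
        "gene": a.gene.name,
        "gene_start_bp": a.gene.start,
        "gene_end_bp": a.gene.end,
        "distance_kb": a.distance_kb,
        "location": a.location,
    } for a in annotations]
    return pd.DataFrame(rows, columns=["SSC", "block_start_bp", "block_end_bp", "gene",
                                       "gene_start_bp", "gene_end_bp", "distance_kb",
                                       "location"])
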