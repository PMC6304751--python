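#!/usr/bin/env python
"""Flanking-gene annotation of the published candidate blocks.

Annotates the candidate haplotype blocks (data/candidate_blocks.tsv) with
the Sscrofa 10.2 fertility-pathway genes (data/genes_sscrofa10_2.bed):
every gene inside a block or within 400 Kb of its edge, with the signed-Kb
distance convention.  Table under results/gene_annotations.tsv.
"""

from pathlib import Path

import pandas as pd

from lethalscan.gene_flank import annotate_blocks, annotation_table
from lethalscan.io_formats import read_genes

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    genes = read_genes(ROOT / "data" / "genes_sscrofa10_2.bed", "bed")
    blocks = pd.read_csv(ROOT / "data" / "candidate_blocks.tsv", sep="\t",
                         dtype={"chrom": str})
    triples = [(r["chrom"], int(round(r["start_mb"] * 1e6)) + 1,
                int(round(r["end_mb"] * 1e6))) for _, r in blocks.iterrows()]
    ann = annotate_blocks(triples, genes)
    table = annotation_table(ann)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "gene_annotations.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"\n{len(table)} gene annotations written to results/gene_annotations.tsv")


if __name__ == "__main__":
    main()
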