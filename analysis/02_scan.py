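#!/usr/bin/env python
"""QC, haplotype-block construction and the homozygote-deficiency scan.

Consumes the dataset written by 01_simulate.py and writes the QC report,
the full scan table and the candidate table under results/scan/.  Both
planted lethals should reappear as candidates (SNP-level via their anchor
markers and haplotype-level via the block alleles); no background locus
should.
"""

from pathlib import Path

from lethalscan.pipeline import RunConfig, report, run_scan

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "demo_data"
OUT = ROOT / "results" / "scan"


def main() -> None:
    config = RunConfig(vcf=str(DATA / "genotypes.vcf"), out_dir=str(OUT))
    tables = run_scan(config)
    print(report(tables))
    scan = tables["scan"]
    n_hap = (scan["kind"] == "haplotype").sum()
    print(f"\n{(scan['kind'] == 'snp').sum()} SNPs and {n_hap} haplotype alleles "
          f"tested; tables under {OUT}")


if __name__ == "__main__":
    main()
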