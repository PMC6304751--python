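"""End-to-end orchestration: QC -> blocks -> deficiency scan -> association
-> gene annotation, with per-stage record counts logged and a manifest
sufficient to reproduce every output.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .association import (LINEAR_TRAITS, POISSON_TRAITS, carrier_status,
                          effects_table, fit_linear_animal_model,
                          fit_poisson_animal_model)
from .block_builder import ScanConfig, build_blocks, enumerate_alleles
from .deficiency_scan import CandidacyRule, results_table, scan_haplotypes, scan_snps
from .gene_flank import FLANK_BP_DEFAULT, annotate_blocks, annotation_table
from .io_formats import read_genes, read_litters, read_pedigree, read_phased_vcf
from .qc_filters import PhasedGenotypes, QcThresholds, snp_qc, write_qc_report


@dataclass
class RunConfig:
    vcf: str
    out_dir: str
    pedigree: str | None = None
    litters: str | None = None
    genes: str | None = None
    genes_format: str = "bed"
    qc: QcThresholds = field(default_factory=QcThresholds)
    scan: ScanConfig = field(default_factory=ScanConfig)
    rule: CandidacyRule = field(default_factory=CandidacyRule)
    traits: tuple[str, ...] = ("TNB", "BA", "L24", "SB", "MM")
    expected_mode: str = "hwe"          # or "vanraden"
    mode: str = "both"                  # snp | hap | both
    flank_bp: int = FLANK_BP_DEFAULT
    seed: int = 0


class RunLog:
    def __init__(self) -> None:
        self.lines: list[str] = []

    def info(self, msg: str) -> None:
        self.lines.append(msg)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.lines) + "\n")


def _manifest(config: RunConfig) -> dict:
    def enc(x):
        return asdict(x) if hasattr(x, "__dataclass_fields__") else x
    payload = {k: enc(v) for k, v in asdict(config).items()}
    blob = json.dumps(payload, sort_keys=True, default=str)
    return {"config": payload, "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "lethalscan_version": __version__}


def run_scan(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the scan (and association/annotation when inputs allow).

    Returns the result tables; also writes them as TSV under ``out_dir``
    together with the QC report, run log and manifest.
    """
    log = RunLog()
    os.makedirs(config.out_dir, exist_ok=True)
    if not os.path.exists(config.vcf):
        raise FileNotFoundError(f"genotype input not found: {config.vcf}")
    snpmap, geno = read_phased_vcf(config.vcf)
    log.info(f"loaded {geno.n_animals} animals x {geno.n_snps} SNPs from {config.vcf}")

    kept_snps, kept_animals, qc_stats = snp_qc(geno, snpmap, config.qc)
    log.info(f"animal QC: {len(kept_animals)} of {geno.n_animals} animals kept")
    log.info(f"SNP QC: {len(kept_snps)} of {geno.n_snps} SNPs kept")
    write_qc_report(os.path.join(config.out_dir, "qc_report.tsv"), qc_stats)
    geno_qc = PhasedGenotypes([geno.animals[i] for i in kept_animals],
                              geno.alleles[np.ix_(kept_animals, kept_snps)], geno.phased)
    sub_stats = qc_stats.iloc[kept_snps].reset_index(drop=True)

    tables: dict[str, pd.DataFrame] = {"qc": qc_stats}
    results = []
    if config.mode in ("snp", "both"):
        snp_res = scan_snps(geno_qc, config.rule, stats_df=sub_stats)
        results += snp_res
        log.info(f"SNP scan: {len(snp_res)} tested, "
                 f"{sum(r.candidate for r in snp_res)} candidates")
    alleles = []
    if config.mode in ("hap", "both"):
        blocks = build_blocks(snpmap, config.scan, snp_subset=kept_snps)
        # block SNP indices refer to the full map; translate to QC-kept columns
        col_of = {int(j): c for c, j in enumerate(kept_snps)}
        for b in blocks:
            b.snp_indices = np.array([col_of[int(j)] for j in b.snp_indices])
        log.info(f"blocks: {len(blocks)} windows with > {config.scan.min_snps - 1} SNPs")
        for b in blocks:
            alleles.extend(enumerate_alleles(geno_qc, b, config.scan))
        log.info(f"haplotype alleles tested: {len(alleles)}")
        hap_res = scan_haplotypes(alleles, config.rule, mode=config.expected_mode)
        results += hap_res
        log.info(f"haplotype scan: {sum(r.candidate for r in hap_res)} candidates")
    res_df = results_table(results)
    tables["scan"] = res_df
    res_df.to_csv(os.path.join(config.out_dir, "scan_results.tsv"), sep="\t", index=False)
    cand_df = res_df[res_df["candidate"]] if len(res_df) else res_df
    cand_df.to_csv(os.path.join(config.out_dir, "candidates.tsv"), sep="\t", index=False)

    cand_alleles = [h for h, r in zip(alleles, (r for r in results if r.kind == "haplotype"))
                    if r.candidate]
    if config.litters and config.pedigree and cand_alleles:
        litters, rejected = read_litters(config.litters)
        if len(rejected):
            log.info(f"litters: rejected {len(rejected)} invalid rows")
        ped = read_pedigree(config.pedigree)
        ests, labels = [], []
        for h in cand_alleles:
            status = carrier_status(geno_qc, h)
            cmap = {a: int(s) for a, s in zip(geno_qc.animals, status) if s >= 0}
            recs = litters[litters["sire"].isin(cmap)].reset_index(drop=True)
            for trait in config.traits:
                try:
                    if trait in LINEAR_TRAITS:
                        ests.append(fit_linear_animal_model(recs, trait, cmap, ped))
                    elif trait in POISSON_TRAITS:
                        ests.append(fit_poisson_animal_model(recs, trait, cmap, ped))
                    labels.append(f"{h.block.label}|{h.allele}")
                except ValueError as exc:
                    log.info(f"association skipped for {h.block.label} {trait}: {exc}")
        assoc = effects_table(ests, labels)
        tables["association"] = assoc
        assoc.to_csv(os.path.join(config.out_dir, "association.tsv"), sep="\t", index=False)
        log.info(f"association: {len(ests)} trait fits")
    elif config.litters is None:
        log.info("no litter file supplied: scan-only mode, association skipped")

    if config.genes and cand_alleles:
        genes = read_genes(config.genes, config.genes_format)
        blocks3 = sorted({(h.block.chrom, h.block.start + 1, h.block.end)
                          for h in cand_alleles})
        ann = annotate_blocks(list(blocks3), genes, config.flank_bp)
        ann_df = annotation_table(ann)
        tables["genes"] = ann_df
        ann_df.to_csv(os.path.join(config.out_dir, "gene_annotations.tsv"),
                      sep="\t", index=False)
        log.info(f"gene annotation: {len(ann_df)} genes within {config.flank_bp / 1000:.0f} Kb")

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(_manifest(config), fh, indent=1, default=str)
    log.write(os.path.join(config.out_dir, "run.log"))
    return tables


def report(tables: dict[str, pd.DataFrame]) -> str:
    """Human-readable summary of a completed run."""
    out = []
    scan = tables.get("scan")
    if scan is None or scan.empty or not scan["candidate"].any():
        out.append("no candidates detected")
    else:
        cand = scan[scan["candidate"]]
        out.append(f"{len(cand)} candidate loci:")
        for _, r in cand.iterrows():
            if r["kind"] == "haplotype":
                out.append(f"  SSC{r['chrom']} {r['start_mb']:.1f}-{r['end_mb']:.1f} Mb  "
                           f"{r['n_snps']} SNPs  freq {r['frequency']:.3f}  "
                           f"E(HOM) {r['expected']:.1f}  P {r['p_corrected']:.2g}")
            else:
                out.append(f"  SNP {r['locus']}  MAF {r['frequency']:.3f}  "
                           f"E(HOM) {r['expected']:.1f}  P {r['p_corrected']:.2g}")
    if "association" in tables and len(tables["association"]):
        sig = tables["association"]["significant_p_lt_0.10"].sum()
        out.append(f"association fits: {len(tables['association'])} "
                   f"({sig} significant at P < 0.10)")
    if "genes" in tables and len(tables["genes"]):
        out.append(f"flanking genes reported: {len(tables['genes'])}")
    return "\n".join(out)
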