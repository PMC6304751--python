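#!/usr/bin/env python
"""Generate the demonstration breeding population.

A panel of 1500 genotyped boars on two 12-Mb chromosomes with two planted
recessive-lethal haplotypes (allele frequencies 0.15 and 0.20, half of the
in-utero losses recorded as mummified fetuses), 192 service sires and 5340
recorded litters.  Writes phased VCF, pedigree, litters and the truth
sidecar under results/demo_data/.
"""

import sys
from pathlib import Path

from lethalscan.synthetic_data import (PlantedBlock, SimulationConfig,
                                       simulate_founders, simulate_litters,
                                       write_dataset)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "demo_data"


def main() -> None:
    config = SimulationConfig(
        seed=SEED, n_boars=1500,
        planted=[PlantedBlock("1", 2_000_000, frequency=0.15, pi_mm=0.5),
                 PlantedBlock("2", 5_000_000, frequency=0.20, pi_mm=0.5)])
    snpmap, geno, ped, truths = simulate_founders(config)
    litters, truths = simulate_litters(geno, truths, config)
    paths = write_dataset(OUT, snpmap, geno, ped, litters, truths)
    print(f"simulated {geno.n_animals} boars x {geno.n_snps} SNPs, "
          f"{len(litters)} litters (seed {SEED})")
    for t in truths:
        print(f"  planted lethal {t.block.label}: realized frequency "
              f"{t.realized_frequency:.3f}, {len(t.carrier_ids)} carrier boars, "
              f"{int(t.removed_per_litter.sum())} conceptuses lost in utero")
    for k, v in paths.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
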