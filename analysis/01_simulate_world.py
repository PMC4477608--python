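"""Simulate the breed-pool world all later analyses consume.

Builds the default stated world — 12 dog breeds plus a wolf founded on
the D/L/S haplotypes, 200 SNPs over 3 Mb with a 5' ear block and a 3'
mass block, 5 high-coverage sequence-capture pools and 6 low-coverage
WGS pools — and writes the panel, pool pileups, genotypes and ground
truth under results/simulated/.
"""

import sys
from pathlib import Path

from breedscan import pileup_io, synthdata

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
# pileup text is bulky (one base character per read); park it in scratch/
PILEUPS = Path(__file__).resolve().parents[1] / "scratch" / "pileups"


def main(seed: int = 1) -> None:
    cfg = synthdata.SimConfig(seed=seed)
    panel = synthdata.simulate_breed_panel(cfg)
    truth = synthdata.simulate_haplotype_pools(cfg, panel)
    pools = synthdata.simulate_pool_pileups(truth, cfg)

    OUT.mkdir(parents=True, exist_ok=True)
    PILEUPS.mkdir(parents=True, exist_ok=True)
    panel.to_csv(OUT / "panel.tsv", sep="\t", index=False)
    truth.class_freqs.to_csv(OUT / "breed_class_freqs.tsv", sep="\t")
    with open(OUT / "genotypes.tsv", "w") as fh:
        pileup_io.write_genotype_table(truth.genotypes, fh)
    for p in pools:
        with open(PILEUPS / f"{p.pool}.pileup", "w") as fh:
            pileup_io.write_pileup(p, fh)

    ear = truth.positions[truth.causal_ear_idx]
    mass = truth.positions[truth.causal_mass_idx]
    print(f"world seed={seed}: {len(panel)} dog breeds, "
          f"{cfg.n_snps} SNPs, {len(pools)} pools")
    print(f"planted ear-block SNPs:  {list(ear)}")
    print(f"planted mass-block SNPs: {list(mass)}")
    print(f"tables -> {OUT}; pileups -> {PILEUPS}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
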