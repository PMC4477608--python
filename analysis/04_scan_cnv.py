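"""Scan read depth for pool-asymmetric coverage (CNV candidates).

Generates dense per-base coverage for the sequence-capture pools over a
50 kb focus interval, plants one deletion (fold 0) and one duplication
(fold 2.5) in single pools, and runs the 100 bp window scan to show both
are recovered with no background flags.
"""

from pathlib import Path

from breedscan import cnvscan, synthdata

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    cfg = synthdata.SimConfig(seed=seed)
    panel = synthdata.simulate_breed_panel(cfg)
    truth = synthdata.simulate_haplotype_pools(cfg, panel)
    focus = (1_000_001, 1_050_000)
    pools = synthdata.simulate_pool_pileups(truth, cfg, dense_region=focus)
    sc = [p for p in pools if p.kind == "SC"]
    sc = [type(p)(pool=p.pool, sites=p.sites[p.sites["pos"].between(*focus)]
                  .reset_index(drop=True), kind=p.kind,
                  size_class=p.size_class, ear_class=p.ear_class)
          for p in sc]

    deletion = (1_010_001, 1_010_400)
    duplication = (1_030_001, 1_030_300)
    sc = synthdata.plant_cnv(sc, deletion, 0.0, ["WEI"])
    sc = synthdata.plant_cnv(sc, duplication, 2.5, ["BT"])

    windows = cnvscan.normalized_window_depths(sc, 100, region=focus)
    flags = cnvscan.flag_cnv_windows(windows, synthdata.phenotype_scheme(cfg))

    OUT.mkdir(exist_ok=True)
    flags.to_csv(OUT / "cnv_regions.tsv", sep="\t", index=False)
    print(f"planted deletion {deletion} in WEI, duplication {duplication} "
          "in BT")
    print(f"{len(windows.starts)} windows scanned, "
          f"{len(flags)} regions flagged:")
    print(flags.to_string(index=False))


if __name__ == "__main__":
    main()
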