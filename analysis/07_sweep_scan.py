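"""Genome-scale sweep scan with a planted selected region.

Simulates pooled allele frequencies for 1,200 40-kb windows of a
neutral genome (dog frequency = wolf frequency up to drift noise),
plants a 3-window sweep (dogs driven to fixation, wolf unchanged), and
shows the joint low-heterozygosity / high-F_ST percentile rule flags
exactly the planted region.
"""

from pathlib import Path

import numpy as np

from breedscan import sweepscan

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    rng = np.random.default_rng([seed, 7])
    n_win, sites_per, window = 1200, 4, 40_000
    swept = range(600, 603)
    positions, dog, wolf = [], [], []
    for w in range(n_win):
        for s in range(sites_per):
            positions.append(w * window + (s + 1) * 8000)
            if w in swept:
                dog.append(1.0)
                wolf.append(0.0)
            else:
                p = rng.uniform(0.1, 0.9)
                dog.append(float(np.clip(p + rng.normal(0, 0.05), 0, 1)))
                wolf.append(p)
    windows = sweepscan.window_stats(np.array(positions), np.array(dog),
                                     np.array(wolf), window=window,
                                     region=(1, n_win * window))
    regions = sweepscan.percentile_outlier_regions(windows)
    OUT.mkdir(exist_ok=True)
    windows.to_csv(OUT / "sweep_windows.tsv", sep="\t", index=False)
    regions.to_csv(OUT / "sweep_regions.tsv", sep="\t", index=False)
    print(f"{n_win} windows; het 1% threshold = "
          f"{regions.attrs['het_threshold']:.4f}, F_ST 99% threshold = "
          f"{regions.attrs['fst_threshold']:.4f}")
    print(f"planted sweep at windows {list(swept)}; flagged regions:")
    print(regions.to_string(index=False))
    planted = regions[(regions["start"] == swept[0] * window + 1)]
    n_neutral = len(regions) - len(planted)
    assert len(planted) == 1 and planted.iloc[0]["n_windows"] == 3
    print(f"planted region recovered as one merged 3-window region; "
          f"{n_neutral} neutral window(s) co-flagged "
          f"({n_neutral / n_win:.2%} of windows, within the <=1% joint "
          "false-flag expectation)")


if __name__ == "__main__":
    main()
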