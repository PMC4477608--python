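"""Selective-sweep scan: windowed heterozygosity and dog–wolf F_ST.

A sweep leaves a footprint of reduced diversity in the selected
population and elevated differentiation from the ancestor.  The genome is
tiled into windows (default 40 kb); per window, heterozygosity is the
mean of 2p(1−p) over variable sites using the combined-dog allele
frequency, and F_ST is the per-site two-population (dog vs wolf)
(H_T − H_S)/H_T averaged over sites (ratio-of-averages offered as an
option).  Windows jointly below the genome-wide low percentile of
heterozygosity and above the high percentile of F_ST (both strict, linear
interpolation) are flagged and merged into candidate sweep regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def pairwise_fst(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Per-site two-population F_ST = (H_T − H_S)/H_T; NaN where H_T = 0."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    pbar = (p1 + p2) / 2
    ht = 2 * pbar * (1 - pbar)
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(ht > 0, (ht - hs) / ht, np.nan)


def window_stats(positions: np.ndarray, dog_freqs: np.ndarray,
                 wolf_freqs: np.ndarray, window: int = 40_000,
                 region: tuple[int, int] | None = None,
                 chrom: str = "chr", ratio_of_averages: bool = False
                 ) -> pd.DataFrame:
    """Windowed dog heterozygosity and dog–wolf F_ST at variable sites.

    ``positions`` (1-based) index site-level allele frequencies estimated
    from pooled read counts.  Windows with no variable site report
    heterozygosity 0 and F_ST NaN.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    positions = np.asarray(positions, dtype=np.int64)
    dog_freqs = np.asarray(dog_freqs, dtype=float)
    wolf_freqs = np.asarray(wolf_freqs, dtype=float)
    if region is None:
        region = (int(positions.min()), int(positions.max()))
    lo, hi = region
    starts = np.arange(lo, hi + 1, window, dtype=np.int64)
    ends = np.minimum(starts + window - 1, hi)
    idx = (positions - lo) // window
    ok = (idx >= 0) & (idx < len(starts))
    idx, dog, wolf = idx[ok], dog_freqs[ok], wolf_freqs[ok]

    het_site = 2 * dog * (1 - dog)
    fst_site = pairwise_fst(dog, wolf)
    n_sites = np.bincount(idx, minlength=len(starts))
    het_sum = np.bincount(idx, weights=het_site, minlength=len(starts))
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_sites > 0, het_sum / np.maximum(n_sites, 1), 0.0)
        if ratio_of_averages:
            pbar = (dog + wolf) / 2
            ht_sum = np.bincount(idx, weights=2 * pbar * (1 - pbar),
                                 minlength=len(starts))
            hs_sum = np.bincount(
                idx, weights=(2 * dog * (1 - dog) + 2 * wolf * (1 - wolf)) / 2,
                minlength=len(starts))
            fst = np.where(ht_sum > 0, (ht_sum - hs_sum) / ht_sum, np.nan)
        else:
            valid = ~np.isnan(fst_site)
            n_valid = np.bincount(idx[valid], minlength=len(starts))
            fst_sum = np.bincount(idx[valid], weights=fst_site[valid],
                                  minlength=len(starts))
            fst = np.where(n_valid > 0, fst_sum / np.maximum(n_valid, 1), np.nan)
    fst_clamped = np.clip(fst, 0.0, 1.0)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                         "n_sites": n_sites, "het": het, "fst_raw": fst,
                         "fst": fst_clamped})


def percentile_outlier_regions(windows: pd.DataFrame, low_pct: float = 1.0,
                               high_pct: float = 99.0) -> pd.DataFrame:
    """Flag windows jointly extreme in heterozygosity and F_ST, merge runs.

    Thresholds are genome-wide percentiles (linear interpolation) over all
    windows; a window is jointly flagged iff het < low threshold AND
    F_ST > high threshold, both strict — so identical windows never flag
    themselves.  Adjacent flagged windows merge into maximal regions.
    """
    n = len(windows)
    if n < int(100 / min(low_pct, 100 - high_pct)):
        raise ValueError(f"{n} windows are too few for the "
                         f"{low_pct}/{high_pct} percentiles")
    het = windows["het"].to_numpy(dtype=float)
    fst = windows["fst"].to_numpy(dtype=float)
    het_thr = np.percentile(het, low_pct)
    fst_thr = np.nanpercentile(fst, high_pct)
    joint = (het < het_thr) & (fst > fst_thr)
    flagged = windows.assign(low_het=het < het_thr, high_fst=fst > fst_thr,
                             joint=joint)
    regions = []
    i = 0
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    chrom = windows["chrom"].to_numpy()
    while i < n:
        if not joint[i]:
            i += 1
            continue
        j = i
        while j < n and joint[j] and chrom[j] == chrom[i]:
            j += 1
        regions.append((chrom[i], int(starts[i]), int(ends[j - 1]), j - i))
        i = j
    reg = pd.DataFrame(regions, columns=["chrom", "start", "end", "n_windows"])
    reg.attrs["het_threshold"] = float(het_thr)
    reg.attrs["fst_threshold"] = float(fst_thr)
    reg.attrs["windows"] = flagged
    return reg
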