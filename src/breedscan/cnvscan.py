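"""Read-depth CNV scan over non-overlapping 100 bp windows.

Copy-number differences between pools show up as pool-asymmetric coverage.
For each window we compute each pool's mean raw depth, its *relative*
depth (window depth / that pool's genome-wide mean window depth, which
removes library-size differences), and the *normalized* relative depth
(relative depth / cross-pool mean of relative depths in the window, whose
cross-pool mean is 1 by construction).

A window is flagged when some pool's relative depth exceeds twice the mean
relative depth of the remaining pools (duplication-like; with the
symmetric option, below half — deletion-like), or when a pool has zero raw
coverage while another does not.  Adjacent flagged windows are merged and
each region is annotated with whether the deviant pools partition by ear
or size class, replacing manual browser inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .candidates import PhenotypeScheme
from .pileup_io import PoolAlleleCounts


@dataclass
class DepthWindows:
    """Tiled windows with per-pool depth matrices (windows × pools)."""

    chrom: str
    starts: np.ndarray  # 1-based inclusive
    ends: np.ndarray
    pools: list[str]
    raw: np.ndarray        # mean raw depth per bp
    relative: np.ndarray   # raw / per-pool mean over windows
    normalized: np.ndarray  # relative / cross-pool mean per window

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.starts)):
            for j, pool in enumerate(self.pools):
                rows.append((self.chrom, self.starts[i], self.ends[i], pool,
                             self.raw[i, j], self.relative[i, j],
                             self.normalized[i, j]))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "pool",
                                           "raw_depth", "relative_depth",
                                           "normalized_depth"])


def normalized_window_depths(pools: list[PoolAlleleCounts], window: int = 100,
                             region: tuple[int, int] | None = None
                             ) -> DepthWindows:
    """Tile the region into ``window`` bp windows and normalize depths.

    ``region`` is 1-based inclusive; by default it spans the union of
    covered positions.  Pools with zero total coverage are excluded with a
    warning column left to the caller (they would make relative depth
    undefined).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(pools) < 2:
        raise ValueError("need at least 2 pools to normalize across pools")
    chrom = pools[0].sites["chrom"].iloc[0] if len(pools[0].sites) else "chr"
    if region is None:
        lo = min(int(p.sites["pos"].min()) for p in pools if len(p.sites))
        hi = max(int(p.sites["pos"].max()) for p in pools if len(p.sites))
    else:
        lo, hi = region
    starts = np.arange(lo, hi + 1, window, dtype=np.int64)
    ends = np.minimum(starts + window - 1, hi)
    n_win = len(starts)

    keep: list[PoolAlleleCounts] = []
    for p in pools:
        if p.depth.sum() == 0:
            continue  # zero-coverage pool: excluded from normalization
        keep.append(p)
    if len(keep) < 2:
        raise ValueError("fewer than 2 pools with coverage")

    raw = np.zeros((n_win, len(keep)))
    for j, p in enumerate(keep):
        pos = p.sites["pos"].to_numpy()
        depth = p.depth.astype(float)
        idx = (pos - lo) // window
        ok = (idx >= 0) & (idx < n_win)
        np.add.at(raw[:, j], idx[ok], depth[ok])
    widths = (ends - starts + 1).astype(float)
    raw /= widths[:, None]

    pool_mean = raw.mean(axis=0)
    relative = raw / pool_mean[None, :]
    cross = relative.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(cross[:, None] > 0, relative / cross[:, None],
                              np.nan)
    return DepthWindows(chrom=chrom, starts=starts, ends=ends,
                        pools=[p.pool for p in keep], raw=raw,
                        relative=relative, normalized=normalized)


def _deviant_pools(rel_row: np.ndarray, raw_row: np.ndarray,
                   fold: float, symmetric: bool) -> list[int]:
    """Pools whose depth deviates from the others' average in one window."""
    n = len(rel_row)
    out = []
    for j in range(n):
        others = np.delete(rel_row, j)
        base = others.mean()
        if raw_row[j] == 0 and np.any(raw_row > 0):
            out.append(j)
        elif base > 0 and rel_row[j] > fold * base:
            out.append(j)
        elif symmetric and base > 0 and rel_row[j] < base / fold:
            out.append(j)
    return out


def flag_cnv_windows(windows: DepthWindows,
                     scheme: PhenotypeScheme | None = None,
                     fold: float = 2.0, symmetric: bool = True
                     ) -> pd.DataFrame:
    """Flag asymmetric-coverage windows and merge them into regions.

    A pool is deviant in a window when its relative depth exceeds ``fold``
    times the mean relative depth of the other pools (or is below 1/fold
    with ``symmetric``), or when it completely lacks coverage while
    another pool has reads.  Adjacent flagged windows merge; each region
    reports the deviant pools and whether they coincide with an ear-type
    or size-class partition of the pools.
    """
    flags: list[list[int]] = []
    for i in range(len(windows.starts)):
        if np.all(windows.raw[i] == 0):
            flags.append([])
            continue
        flags.append(_deviant_pools(windows.relative[i], windows.raw[i],
                                    fold, symmetric))
    regions = []
    i = 0
    n = len(flags)
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        pools_involved: set[int] = set()
        while j < n and flags[j]:
            pools_involved.update(flags[j])
            j += 1
        names = sorted(windows.pools[k] for k in pools_involved)
        regions.append((windows.chrom, int(windows.starts[i]),
                        int(windows.ends[j - 1]), j - i, ";".join(names),
                        _phenotype_partition(names, windows.pools, scheme)))
        i = j
    return pd.DataFrame(regions, columns=["chrom", "start", "end",
                                          "n_windows", "deviant_pools",
                                          "phenotype_partition"])


def _phenotype_partition(deviant: list[str], pools: list[str],
                         scheme: PhenotypeScheme | None) -> str:
    """Does the deviant-pool set coincide with a phenotype class?"""
    if scheme is None:
        return "unknown"
    dev = set(deviant)
    for trait, idx in (("ear", 1), ("mass", 0)):
        classes: dict[str, set[str]] = {}
        for p in pools:
            if p in scheme.labels:
                classes.setdefault(scheme.labels[p][idx], set()).add(p)
        for cls, members in classes.items():
            if dev == members and len(classes) > 1:
                return f"{trait}:{cls}"
    return "none"
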