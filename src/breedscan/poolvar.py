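"""Pooled SNP calling: variable-site detection and per-pool fixation calls.

A site is a variable SNP when, summing reads over all pools, strictly more
than ``min_minor_fraction`` (default 10 %) of reads carry the minor allele.
Each pool is then classified at each variable site as fixed for the
reference allele, fixed for the non-reference allele, polymorphic, or
missing, under a configurable fixation cutoff.  High-coverage sequence
capture (SC) pools use a per-pool depth floor (default 100 reads) and a
majority-fraction cutoff from {0.70, 0.90, 0.99}; low-coverage WGS pools
are called fixed only when every read agrees, and missing only at zero
depth.

Counts arriving here are already base-quality filtered (see pileup_io);
this module is pure arithmetic on read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pileup_io import PoolAlleleCounts

FIXED_REF = "fixed_ref"
FIXED_NONREF = "fixed_nonref"
POLYMORPHIC = "polymorphic"
MISSING = "missing"


@dataclass
class FixationConfig:
    min_site_depth: int = 100
    min_minor_fraction: float = 0.10
    fixation_cutoffs: tuple[float, ...] = (0.70, 0.90, 0.99)
    wgs_fixed_requires_all_reads: bool = True

    def __post_init__(self):
        if not 0 <= self.min_minor_fraction < 0.5:
            raise ValueError("min_minor_fraction must be in [0, 0.5)")
        for c in self.fixation_cutoffs:
            if not 0.5 < c <= 1.0:
                raise ValueError(f"fixation cutoff {c} not in (0.5, 1.0]")


@dataclass
class SiteClassification:
    site: int  # position
    pool: str
    call: str
    cutoff: float
    fraction: float  # majority-allele fraction (NaN when missing)
    depth: int


def detect_variable_sites(pools: list[PoolAlleleCounts],
                          cfg: FixationConfig | None = None) -> pd.DataFrame:
    """Screen sites for variability across all pools combined.

    Returns a frame indexed like the pools' shared site list with columns
    total_ref, total_nonref, minor_fraction, variable (bool) and
    low_depth_pools (count of pools under the SC depth floor).  The minor
    fraction must be *strictly* greater than ``min_minor_fraction``.
    """
    if not pools:
        raise ValueError("need at least one pool")
    cfg = cfg or FixationConfig()
    base = pools[0].sites[["chrom", "pos"]].copy()
    total_ref = np.zeros(len(base), dtype=np.int64)
    total_nonref = np.zeros(len(base), dtype=np.int64)
    low_depth = np.zeros(len(base), dtype=np.int64)
    for p in pools:
        if len(p.sites) != len(base) or not np.array_equal(
                p.sites["pos"].to_numpy(), base["pos"].to_numpy()):
            raise ValueError(f"pool {p.pool!r} sites do not match the first pool")
        total_ref += p.sites["ref_count"].to_numpy(dtype=np.int64)
        total_nonref += p.sites["nonref_count"].to_numpy(dtype=np.int64)
        if p.kind == "SC":
            low_depth += (p.depth < cfg.min_site_depth).astype(np.int64)
    total = total_ref + total_nonref
    minor = np.minimum(total_ref, total_nonref)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, minor / total, 0.0)
    base["total_ref"] = total_ref
    base["total_nonref"] = total_nonref
    base["minor_fraction"] = frac
    base["variable"] = frac > cfg.min_minor_fraction
    base["low_depth_pools"] = low_depth
    return base


def classify_pool_site(ref_count: int, nonref_count: int, cutoff: float,
                       cfg: FixationConfig, pool_kind: str = "SC"
                       ) -> tuple[str, float]:
    """Classify one pool at one variable site; returns (call, fraction).

    SC pools: depth < min_site_depth → missing; else the majority allele's
    fraction ≥ cutoff → fixed for that allele, otherwise polymorphic.
    WGS pools: zero depth → missing; fixed only when all reads agree
    (fraction = 1.0) under the all-reads rule, otherwise polymorphic.
    """
    if cutoff not in cfg.fixation_cutoffs:
        raise ValueError(f"cutoff {cutoff} not configured "
                         f"(have {cfg.fixation_cutoffs})")
    depth = ref_count + nonref_count
    if pool_kind == "SC":
        if depth < cfg.min_site_depth:
            return MISSING, float("nan")
    elif pool_kind == "WGS":
        if depth == 0:
            return MISSING, float("nan")
    else:
        raise ValueError(f"unknown pool kind {pool_kind!r}")
    major_is_ref = ref_count >= nonref_count
    frac = max(ref_count, nonref_count) / depth
    if pool_kind == "WGS" and cfg.wgs_fixed_requires_all_reads:
        threshold = 1.0
    else:
        threshold = cutoff
    if frac >= threshold:
        return (FIXED_REF if major_is_ref else FIXED_NONREF), frac
    return POLYMORPHIC, frac


def classify_pools(pools: list[PoolAlleleCounts], variable: pd.DataFrame,
                   cfg: FixationConfig | None = None,
                   cutoffs: tuple[float, ...] | None = None) -> pd.DataFrame:
    """Classify every pool at every variable site at each cutoff.

    Returns a long frame: pos, pool, kind, cutoff, call, fraction, depth —
    one row per (variable site, pool, cutoff).
    """
    cfg = cfg or FixationConfig()
    cutoffs = cutoffs or cfg.fixation_cutoffs
    var_pos = variable.loc[variable["variable"], "pos"].to_numpy()
    rows = []
    for p in pools:
        sub = p.sites[p.sites["pos"].isin(var_pos)]
        for r in sub.itertuples(index=False):
            for cut in cutoffs:
                call, frac = classify_pool_site(
                    r.ref_count, r.nonref_count, cut, cfg, p.kind)
                rows.append((r.pos, p.pool, p.kind, cut, call, frac,
                             r.ref_count + r.nonref_count))
    return pd.DataFrame(
        rows, columns=["pos", "pool", "kind", "cutoff", "call", "fraction",
                       "depth"])


def apply_ess_rule(classifications: pd.DataFrame, low_cov_pool: str,
                   partner_pool: str) -> pd.DataFrame:
    """Guard a low-coverage pool's calls with its phenotype partner.

    Whenever the partner pool is missing at a site (same cutoff), the
    low-coverage pool's call becomes missing too, so the phenotype class is
    never represented by the unreliable pool alone.
    """
    pools = set(classifications["pool"])
    for name in (low_cov_pool, partner_pool):
        if name not in pools:
            raise ValueError(f"unknown pool {name!r}")
    out = classifications.copy()
    partner = out[out["pool"] == partner_pool].set_index(["pos", "cutoff"])["call"]
    mask = out["pool"] == low_cov_pool
    keys = list(zip(out.loc[mask, "pos"], out.loc[mask, "cutoff"]))
    partner_missing = np.array(
        [partner.get(k, MISSING) == MISSING for k in keys])
    idx = out.index[mask][partner_missing]
    out.loc[idx, "call"] = MISSING
    out.loc[idx, "fraction"] = np.nan
    return out
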