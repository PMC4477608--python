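"""Trait-candidate SNP selection from per-pool fixation patterns.

A candidate for a trait (ear type or body mass) is a variable site where
the two phenotype classes of sequence-capture pools are each internally
fixed for one allele, and the two classes carry opposite alleles.  WGS
pools then act as a consistency filter: a candidate is dropped when any
phenotypically informative WGS pool is fixed for the allele that
contradicts the association.  Dog–wolf fixed differences and a cluster
SNP-density statistic (Fisher's exact test) round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pileup_io import PoolAlleleCounts
from .poolvar import FIXED_NONREF, FIXED_REF, MISSING, POLYMORPHIC

EAR = "ear"
MASS = "mass"
DOGWOLF = "dogwolf"

RETAINED = "retained"
REJECTED_BY_WGS = "rejected_by_wgs"


@dataclass
class PhenotypeScheme:
    """Pool → (size class, ear class) labels plus the wolf pool name.

    size class ∈ {small, large}; ear class ∈ {drop, non-drop, mix}.  The
    wolf pool is labelled large / non-drop: it joins the ear filter on the
    non-drop side and the mass filter on the large side.
    """

    labels: dict[str, tuple[str, str]]  # pool -> (size, ear)
    wolf_pool: str = ""

    def __post_init__(self):
        if self.wolf_pool and self.wolf_pool not in self.labels:
            raise ValueError(f"wolf pool {self.wolf_pool!r} not labelled")
        if self.wolf_pool:
            size, ear = self.labels[self.wolf_pool]
            if (size, ear) != ("large", "non-drop"):
                raise ValueError("wolf pool must be labelled large / non-drop")

    @classmethod
    def from_pool_design(cls, design: pd.DataFrame,
                         wolf_pool: str = "Pool1") -> "PhenotypeScheme":
        labels = {r.code: (r.size_class, r.ear_class)
                  for r in design.itertuples(index=False)}
        return cls(labels=labels, wolf_pool=wolf_pool)

    def groups(self, trait: str) -> tuple[dict[str, list[str]], str, str]:
        """Partition pools into the two phenotype classes for a trait.

        Returns ({class: pools}, focal_class, other_class) where the focal
        class is the one whose shared allele is reported as the trait
        allele (drop for ear, small for mass).  Mixed-ear pools are
        uninformative for ear and omitted.
        """
        if trait == EAR:
            by = {"drop": [], "non-drop": []}
            for pool, (_, ear) in self.labels.items():
                if ear in by:
                    by[ear].append(pool)
            return by, "drop", "non-drop"
        if trait == MASS:
            by = {"small": [], "large": []}
            for pool, (size, _) in self.labels.items():
                if size in by:
                    by[size].append(pool)
            return by, "small", "large"
        raise ValueError(f"unknown trait {trait!r}")


@dataclass
class CandidateSNP:
    pos: int
    trait: str
    trait_allele: str  # ref | nonref: the allele travelling with the focal class
    cutoff: float
    evidence: dict[str, str] = field(default_factory=dict)  # pool -> call
    status: str = RETAINED


def _group_allele(calls: dict[str, str], pools: list[str],
                  low_cov_pool: str | None, strict_missing: bool
                  ) -> str | None:
    """Shared fixed allele of a pool group, or None if the group fails.

    Polymorphic always blocks.  A missing pool blocks unless it is the
    designated low-coverage pool and another pool in the group is fixed
    (strict_missing=True makes every missing pool block).
    """
    fixed: set[str] = set()
    missing_pools = []
    for p in pools:
        call = calls.get(p, MISSING)
        if call == POLYMORPHIC:
            return None
        if call == MISSING:
            missing_pools.append(p)
        elif call == FIXED_REF:
            fixed.add("ref")
        elif call == FIXED_NONREF:
            fixed.add("nonref")
    if len(fixed) != 1:
        return None
    for p in missing_pools:
        if strict_missing or p != low_cov_pool:
            return None
    return fixed.pop()


def sc_candidates(classifications: pd.DataFrame, scheme: PhenotypeScheme,
                  trait: str, cutoff: float,
                  low_cov_pool: str | None = None,
                  strict_missing: bool = False) -> list[CandidateSNP]:
    """Candidate sites where SC fixation segregates with a phenotype.

    ``classifications`` is the long frame from poolvar.classify_pools,
    restricted here to SC pools at ``cutoff``.  A site qualifies when each
    phenotype class is internally concordant-fixed and the classes carry
    opposite alleles.
    """
    groups, focal, other = scheme.groups(trait)
    sc = classifications[(classifications["kind"] == "SC")
                         & (classifications["cutoff"] == cutoff)]
    out: list[CandidateSNP] = []
    for pos, site_df in sc.groupby("pos", sort=True):
        calls = dict(zip(site_df["pool"], site_df["call"]))
        alleles = {}
        skip = False
        for cls in (focal, other):
            pools = [p for p in groups[cls] if p in calls]
            if not pools:
                skip = True  # phenotype class unrepresented: skip, no error
                break
            alleles[cls] = _group_allele(calls, pools, low_cov_pool,
                                         strict_missing)
        if skip or alleles[focal] is None or alleles[other] is None:
            continue
        if alleles[focal] != alleles[other]:
            out.append(CandidateSNP(pos=int(pos), trait=trait,
                                    trait_allele=alleles[focal],
                                    cutoff=cutoff, evidence=calls))
    return out


def wgs_consistency_filter(cands: list[CandidateSNP],
                           wgs_classifications: pd.DataFrame,
                           scheme: PhenotypeScheme) -> list[CandidateSNP]:
    """Reject candidates contradicted by a fixed call in any informative WGS pool.

    For an ear candidate, WGS pools labelled drop or non-drop (including
    the wolf as non-drop) are informative; mixed pools are not.  For a
    mass candidate every WGS pool is informative via its size label.  A
    pool rejects only when *fixed* for the phenotype-inconsistent allele;
    missing or polymorphic calls never reject.
    """
    wgs = wgs_classifications[wgs_classifications["kind"] == "WGS"]
    calls_by_pos: dict[int, dict[str, str]] = {}
    for pos, df in wgs.groupby("pos"):
        calls_by_pos[int(pos)] = dict(zip(df["pool"], df["call"]))
    out = []
    for cand in cands:
        groups, focal, other = scheme.groups(cand.trait)
        focal_allele = cand.trait_allele
        other_allele = "ref" if focal_allele == "nonref" else "nonref"
        expected: dict[str, str] = {}
        for cls, allele in ((focal, focal_allele), (other, other_allele)):
            for pool in groups[cls]:
                expected[pool] = allele
        calls = calls_by_pos.get(cand.pos, {})
        rejected = False
        for pool, call in calls.items():
            if pool not in expected:
                continue  # uninformative label (e.g. mixed ears)
            fixed_for = {FIXED_REF: "ref", FIXED_NONREF: "nonref"}.get(call)
            if fixed_for is not None and fixed_for != expected[pool]:
                rejected = True
                break
        status = REJECTED_BY_WGS if rejected else RETAINED
        out.append(CandidateSNP(pos=cand.pos, trait=cand.trait,
                                trait_allele=cand.trait_allele,
                                cutoff=cand.cutoff,
                                evidence={**cand.evidence, **calls},
                                status=status))
    return out


def candidates_to_frame(cands: list[CandidateSNP]) -> pd.DataFrame:
    rows = [(c.pos, c.trait, c.trait_allele, c.cutoff, c.status)
            for c in cands]
    return pd.DataFrame(rows, columns=["pos", "trait", "trait_allele",
                                       "cutoff", "status"])


def dog_wolf_fixations(dog_pools: list[PoolAlleleCounts],
                       wolf_pool: PoolAlleleCounts,
                       min_dog_depth: int = 3000, min_wolf_depth: int = 3,
                       max_discordant: float = 0.01) -> pd.DataFrame:
    """Sites fixed for alternative alleles in all dogs vs the wolf pool.

    Requires combined dog depth > min_dog_depth, wolf depth > min_wolf_depth,
    opposite majority alleles, and ≤ max_discordant reads supporting a
    different allele on each side.
    """
    if not dog_pools:
        raise ValueError("need at least one dog pool")
    base = dog_pools[0].sites[["chrom", "pos"]].copy()
    dog_ref = np.zeros(len(base), dtype=np.int64)
    dog_nonref = np.zeros(len(base), dtype=np.int64)
    for p in dog_pools:
        if not np.array_equal(p.sites["pos"].to_numpy(), base["pos"].to_numpy()):
            raise ValueError(f"pool {p.pool!r} sites do not match")
        dog_ref += p.sites["ref_count"].to_numpy()
        dog_nonref += p.sites["nonref_count"].to_numpy()
    if not np.array_equal(wolf_pool.sites["pos"].to_numpy(),
                          base["pos"].to_numpy()):
        raise ValueError("wolf pool sites do not match")
    wolf_ref = wolf_pool.sites["ref_count"].to_numpy()
    wolf_nonref = wolf_pool.sites["nonref_count"].to_numpy()

    dog_total = dog_ref + dog_nonref
    wolf_total = wolf_ref + wolf_nonref
    with np.errstate(invalid="ignore", divide="ignore"):
        dog_minor = np.minimum(dog_ref, dog_nonref) / np.maximum(dog_total, 1)
        wolf_minor = np.minimum(wolf_ref, wolf_nonref) / np.maximum(wolf_total, 1)
    dog_major_ref = dog_ref >= dog_nonref
    wolf_major_ref = wolf_ref >= wolf_nonref
    ok = ((dog_total > min_dog_depth) & (wolf_total > min_wolf_depth)
          & (dog_major_ref != wolf_major_ref)
          & (dog_minor <= max_discordant) & (wolf_minor <= max_discordant))
    out = base[ok].copy()
    out["dog_depth"] = dog_total[ok]
    out["wolf_depth"] = wolf_total[ok]
    out["dog_allele"] = np.where(dog_major_ref[ok], "ref", "nonref")
    return out.reset_index(drop=True)


def snp_density(positions, cluster_interval: tuple[int, int],
                background_interval: tuple[int, int]
                ) -> tuple[float, float, float]:
    """SNP density (kb per SNP) inside and outside a cluster, with Fisher p.

    Intervals are 1-based inclusive; the cluster must lie within the
    background.  The 2×2 table counts SNP bp vs non-SNP bp inside and
    outside the cluster; the two-sided p-value is the exact hypergeometric
    tail sum (scipy's Fisher test).
    """
    a, b = cluster_interval
    big_a, big_b = background_interval
    if not (big_a <= a <= b <= big_b):
        raise ValueError("cluster must be contained in the background interval")
    pos = np.asarray(list(positions), dtype=np.int64)
    in_cluster = int(np.sum((pos >= a) & (pos <= b)))
    in_background = int(np.sum((pos >= big_a) & (pos <= big_b)))
    outside = in_background - in_cluster
    span_in = b - a + 1
    span_out = (big_b - big_a + 1) - span_in
    density_in = (span_in / 1000) / in_cluster if in_cluster else float("inf")
    density_out = (span_out / 1000) / outside if outside else float("inf")
    table = [[in_cluster, span_in - in_cluster],
             [outside, span_out - outside]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return density_in, density_out, float(p)
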