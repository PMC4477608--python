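"""Trait candidates, WGS consistency filter, dog-wolf fixations, SNP density."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from breedscan.candidates import (EAR, MASS, REJECTED_BY_WGS, RETAINED,
                                  CandidateSNP, PhenotypeScheme,
                                  dog_wolf_fixations, sc_candidates,
                                  snp_density, wgs_consistency_filter)
from breedscan.pileup_io import PoolAlleleCounts
from breedscan.poolvar import FIXED_NONREF, FIXED_REF, MISSING, POLYMORPHIC

SC_SCHEME = PhenotypeScheme(labels={
    "BT": ("small", "non-drop"), "JR": ("small", "non-drop"),
    "GS": ("large", "non-drop"), "WEI": ("large", "drop"),
    "ESS": ("large", "drop"),
    "Pool1": ("large", "non-drop"),  # wolf
    "Pool3": ("large", "drop"), "Pool2": ("large", "mix"),
}, wolf_pool="Pool1")


def calls_frame(calls: dict, cutoff=0.99, pos=100, kind="SC"):
    kinds = {"Pool1": "WGS", "Pool2": "WGS", "Pool3": "WGS"}
    rows = [(pos, p, kinds.get(p, "SC"), cutoff, c, 1.0, 500)
            for p, c in calls.items()]
    return pd.DataFrame(rows, columns=["pos", "pool", "kind", "cutoff",
                                       "call", "fraction", "depth"])


class TestScCandidates:
    def test_ear_candidate_pattern(self):
        # drop pools fixed nonref, non-drop fixed ref: drop allele = nonref
        df = calls_frame({"BT": FIXED_REF, "JR": FIXED_REF, "GS": FIXED_REF,
                          "WEI": FIXED_NONREF, "ESS": FIXED_NONREF})
        cands = sc_candidates(df, SC_SCHEME, EAR, 0.99)
        assert len(cands) == 1
        assert cands[0].trait_allele == "nonref"

    def test_discordant_small_pools_block_mass(self):
        df = calls_frame({"BT": FIXED_REF, "JR": FIXED_NONREF,
                          "GS": FIXED_REF, "WEI": FIXED_REF,
                          "ESS": FIXED_REF})
        assert sc_candidates(df, SC_SCHEME, MASS, 0.99) == []

    def test_polymorphic_pool_blocks(self):
        df = calls_frame({"BT": FIXED_REF, "JR": FIXED_REF,
                          "GS": POLYMORPHIC, "WEI": FIXED_NONREF,
                          "ESS": FIXED_NONREF})
        assert sc_candidates(df, SC_SCHEME, EAR, 0.99) == []

    def test_missing_low_coverage_pool_tolerated(self):
        df = calls_frame({"BT": FIXED_REF, "JR": FIXED_REF, "GS": FIXED_REF,
                          "WEI": FIXED_NONREF, "ESS": MISSING})
        assert sc_candidates(df, SC_SCHEME, EAR, 0.99,
                             low_cov_pool="ESS") != []
        # but any other missing pool blocks
        df2 = calls_frame({"BT": FIXED_REF, "JR": MISSING, "GS": FIXED_REF,
                           "WEI": FIXED_NONREF, "ESS": FIXED_NONREF})
        assert sc_candidates(df2, SC_SCHEME, EAR, 0.99,
                             low_cov_pool="ESS") == []
        # strict mode blocks even the designated pool
        assert sc_candidates(df, SC_SCHEME, EAR, 0.99, low_cov_pool="ESS",
                             strict_missing=True) == []


class TestWgsFilter:
    def cand(self, trait=EAR, allele="nonref"):
        return [CandidateSNP(pos=100, trait=trait, trait_allele=allele,
                             cutoff=0.99)]

    def test_drop_pool_fixed_for_wrong_allele_rejects(self):
        wgs = calls_frame({"Pool3": FIXED_REF})  # drop pool, drop allele=nonref
        out = wgs_consistency_filter(self.cand(), wgs, SC_SCHEME)
        assert out[0].status == REJECTED_BY_WGS

    def test_all_missing_retains(self):
        wgs = calls_frame({"Pool3": MISSING, "Pool1": MISSING})
        out = wgs_consistency_filter(self.cand(), wgs, SC_SCHEME)
        assert out[0].status == RETAINED

    def test_mixed_ear_pool_uninformative(self):
        wgs = calls_frame({"Pool2": FIXED_REF})  # mixed ears: cannot reject ear
        out = wgs_consistency_filter(self.cand(), wgs, SC_SCHEME)
        assert out[0].status == RETAINED

    def test_consistency_enumeration(self):
        """Exhaustive check against an independent statement of the rule:
        reject iff some informative pool is fixed for the allele its
        phenotype class should not carry (mass: all WGS pools are large)."""
        small_allele = "nonref"
        for c1, c3 in itertools.product(
                [FIXED_REF, FIXED_NONREF, MISSING, POLYMORPHIC], repeat=2):
            wgs = calls_frame({"Pool1": c1, "Pool3": c3})
            out = wgs_consistency_filter(self.cand(MASS, small_allele), wgs,
                                         SC_SCHEME)
            expected_reject = FIXED_NONREF in (c1, c3)  # large pool w/ small allele
            assert (out[0].status == REJECTED_BY_WGS) is expected_reject


def counts(name, rows, kind="SC"):
    sites = pd.DataFrame(rows, columns=["pos", "ref_count", "nonref_count"])
    sites.insert(0, "chrom", "chr1")
    sites["ref"] = "A"
    sites["nonref_base"] = "G"
    sites["other_count"] = 0
    return PoolAlleleCounts(pool=name, sites=sites, kind=kind)


class TestDogWolf:
    @pytest.mark.parametrize("dog,wolf,n_hits", [
        ((0, 3500), (4, 0), 1),      # clean fixed difference
        ((0, 2900), (10, 0), 0),     # dog depth not > 3000
        ((70, 3430), (0, 4), 0),     # 2 % discordant reads on the dog side
        ((0, 3500), (0, 4), 0),      # same majority allele on both sides
        ((0, 3500), (3, 0), 0),      # wolf depth not > 3
    ])
    def test_thresholds(self, dog, wolf, n_hits):
        dogs = [counts("d", [(1, *dog)])]
        wolfp = counts("w", [(1, *wolf)], kind="WGS")
        assert len(dog_wolf_fixations(dogs, wolfp)) == n_hits

    def test_counts_summed_over_dog_pools(self):
        dogs = [counts("d1", [(1, 0, 1800)]), counts("d2", [(1, 0, 1800)])]
        wolfp = counts("w", [(1, 5, 0)], kind="WGS")
        assert len(dog_wolf_fixations(dogs, wolfp)) == 1


def fisher_two_sided_oracle(table):
    """Enumerate all 2x2 tables at fixed margins; two-sided p sums the
    probabilities of tables no more likely than the observed one."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


class TestSnpDensity:
    def test_worked_example(self):
        """12 clustered variants over 26.7 kb give 2.2 kb per SNP."""
        lo, hi = 10_916_652, 10_943_326
        inner = np.linspace(lo, hi, 12).astype(int)
        outside = np.linspace(9_500_000, 10_900_000, 33).astype(int)
        d_in, d_out, p = snp_density(np.r_[inner, outside], (lo, hi),
                                     (9_500_000, 12_500_000))
        assert round(d_in, 1) == 2.2
        # the clustering is overwhelmingly non-random; the exact p depends
        # on the (undefined) 2x2 table construction, so it is descriptive
        assert p < 1e-10

    def test_proportional_table_p_one(self):
        pos = [10, 20, 30, 110, 120, 130]
        d_in, d_out, p = snp_density(pos, (1, 100), (1, 200))
        assert d_in == pytest.approx(d_out)
        assert p == pytest.approx(1.0)

    def test_two_sided_matches_enumeration_oracle(self):
        assert fisher_two_sided_oracle([[2, 0], [0, 2]]) == pytest.approx(1 / 3)
        # 2 SNPs in a 2 bp cluster, 0 SNPs in the 2 bp remainder
        _, _, p = snp_density([1, 2], (1, 2), (1, 4))
        assert p == pytest.approx(1 / 3)

    def test_zero_snps_infinite_density(self):
        d_in, _, p = snp_density([150], (1, 100), (1, 200))
        assert math.isinf(d_in) and 0 <= p <= 1

    def test_cluster_outside_background_rejected(self):
        with pytest.raises(ValueError):
            snp_density([5], (1, 100), (50, 200))
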