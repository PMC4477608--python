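"""Ground-truth generator: determinism, planted structure, read sampling."""

import numpy as np
import pandas as pd
import pytest

from breedscan.synthdata import (SimConfig, plant_cnv, simulate_breed_panel,
                                 simulate_haplotype_pools,
                                 simulate_pool_pileups)


class TestConfig:
    def test_too_few_breeds(self):
        with pytest.raises(ValueError, match="breeds"):
            SimConfig(n_breeds=1)

    def test_blocks_must_be_ordered_disjoint(self):
        with pytest.raises(ValueError, match="blocks"):
            SimConfig(ear_block_span=(2_000_000, 2_100_000),
                      mass_block_span=(1_000_000, 1_100_000))

    def test_error_rate_range(self):
        with pytest.raises(ValueError, match="error"):
            SimConfig(error_rate=0.5)

    def test_unknown_pool_breed(self):
        from breedscan.synthdata import PoolSpec
        with pytest.raises(ValueError, match="unknown"):
            SimConfig(pool_specs=(PoolSpec("x", ("nope",), 100),
                                  PoolSpec("y", ("B01",), 100)))


class TestBreedPanel:
    def test_no_effect_no_noise_gives_baseline(self):
        cfg = SimConfig(mass_effect_kg=0.0, mass_noise_sd=0.0)
        panel = simulate_breed_panel(cfg)
        assert (panel["body_mass_kg"] == cfg.baseline_mass_kg).all()

    def test_dosage_times_effect(self):
        cfg = SimConfig(mass_effect_kg=-8.0, mass_noise_sd=0.0)
        panel = simulate_breed_panel(cfg)
        small = panel.loc[panel["size_class"] == "small", "body_mass_kg"]
        large = panel.loc[panel["size_class"] == "large", "body_mass_kg"]
        assert (large.iloc[0] - small.iloc[0]) == pytest.approx(16.0)

    def test_same_seed_identical(self):
        p1 = simulate_breed_panel(SimConfig(seed=5))
        p2 = simulate_breed_panel(SimConfig(seed=5))
        pd.testing.assert_frame_equal(p1, p2)


class TestHaplotypePools:
    def test_determinism_end_to_end(self):
        outs = []
        for _ in range(2):
            cfg = SimConfig(seed=9, n_snps=40)
            panel = simulate_breed_panel(cfg)
            truth = simulate_haplotype_pools(cfg, panel)
            pools = simulate_pool_pileups(truth, cfg)
            outs.append((truth, pools))
        t1, t2 = outs[0][0], outs[1][0]
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.genotypes.dosages, t2.genotypes.dosages)
        for a, b in zip(outs[0][1], outs[1][1]):
            pd.testing.assert_frame_equal(a.sites, b.sites)

    def test_degenerate_drift_fixes_drop_breeds_for_d(self, ideal_world):
        cfg, panel, truth, _ = ideal_world
        for breed, (size, ear) in cfg.breed_phenotypes.items():
            if ear != "drop":
                continue
            i = truth.breed_index(breed)
            assert truth.breed_freqs[i, truth.causal_ear_idx].min() == 1.0
        # every drop-breed individual is D/D at ear-block SNPs
        sample_breeds = np.array(truth.genotypes.breeds)
        for breed, (size, ear) in cfg.breed_phenotypes.items():
            if ear == "drop":
                haps = truth.haplotypes[sample_breeds == breed]
                assert np.all(haps[:, :, truth.causal_ear_idx] == 1)

    def test_class_frequencies_sum_to_one(self, drifted_world):
        _, _, truth, _ = drifted_world
        assert np.allclose(truth.class_freqs.sum(axis=1), 1.0, atol=1e-9)

    def test_pool_frequency_is_member_breed_average(self, drifted_world):
        cfg, _, truth, _ = drifted_world
        for spec in cfg.pool_specs:
            idx = [truth.breed_index(b) for b in spec.breeds]
            expected = truth.breed_freqs[idx].mean(axis=0)
            assert np.allclose(truth.pool_freqs[spec.name], expected)

    def test_no_recombinants_without_recombination(self, ideal_world):
        cfg, _, truth, _ = ideal_world
        assert cfg.recomb_rate == 0.0
        ear = truth.haplotypes[:, :, truth.causal_ear_idx].all(axis=2)
        mass = truth.haplotypes[:, :, truth.causal_mass_idx].all(axis=2)
        assert not np.any(ear & mass)  # no haplotype is both D-ear and S-mass

    def test_sampled_genotypes_match_breed_truth(self):
        """Allele frequencies over many sampled individuals approach the
        breed truth within 3 binomial standard errors."""
        from breedscan.synthdata import PoolSpec
        cfg = SimConfig(seed=31, n_breeds=2, samples_per_breed=5000,
                        n_snps=12,
                        pool_specs=(PoolSpec("a", ("B01",), 100.0),
                                    PoolSpec("b", ("B02",), 100.0)))
        panel = simulate_breed_panel(cfg)
        truth = simulate_haplotype_pools(cfg, panel)
        sample_breeds = np.array(truth.genotypes.breeds)
        breed = "B01"
        i = truth.breed_index(breed)
        dosages = truth.genotypes.dosages[sample_breeds == breed]
        n_chrom = 2 * dosages.shape[0]
        obs = dosages.sum(axis=0) / n_chrom
        p = truth.breed_freqs[i]
        se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / n_chrom)
        assert np.all(np.abs(obs - p) <= 3 * se + 1e-9)


class TestPileups:
    @pytest.mark.parametrize("f,expect", [(1.0, "all_nonref"),
                                          (0.0, "all_ref")])
    def test_error_free_extremes(self, f, expect, ideal_world):
        cfg, _, truth, pools = ideal_world
        for spec, pc in zip(cfg.pool_specs, pools):
            mask = truth.pool_freqs[spec.name] == f
            sub = pc.sites[mask]
            if expect == "all_nonref":
                assert (sub["ref_count"] == 0).all()
            else:
                assert (sub["nonref_count"] == 0).all()

    def test_conservation_and_counts_nonnegative(self, drifted_world):
        _, _, _, pools = drifted_world
        for pc in pools:
            assert (pc.sites["ref_count"] >= 0).all()
            assert (pc.sites["nonref_count"] >= 0).all()
            assert np.array_equal(
                pc.depth, (pc.sites["ref_count"]
                           + pc.sites["nonref_count"]).to_numpy())

    def test_binomial_concentration_at_high_depth(self):
        """Observed pool fraction near f = 0.5 within 3 binomial SE at
        5,000x; at f = 0.9 the bias is e(1-2f)."""
        from breedscan.synthdata import PoolSpec
        cfg = SimConfig(seed=17, n_breeds=2, samples_per_breed=2,
                        n_snps=400, error_rate=0.01,
                        pool_specs=(PoolSpec("hi", ("B01",), 5000.0),
                                    PoolSpec("lo", ("B02",), 5000.0)))
        panel = simulate_breed_panel(cfg)
        truth = simulate_haplotype_pools(cfg, panel)
        truth.pool_freqs["hi"] = np.full(cfg.n_snps, 0.5)
        truth.pool_freqs["lo"] = np.full(cfg.n_snps, 0.9)
        pools = simulate_pool_pileups(truth, cfg)
        for pc, f in zip(pools, (0.5, 0.9)):
            frac = pc.frequencies().mean()
            expected = f * (1 - cfg.error_rate) + (1 - f) * cfg.error_rate
            se = np.sqrt(0.25 / (5000 * cfg.n_snps))
            assert abs(frac - expected) <= 3 * se + 1e-3


class TestPlantCnv:
    def make_counts(self):
        cfg = SimConfig(seed=3, n_snps=50)
        panel = simulate_breed_panel(cfg)
        truth = simulate_haplotype_pools(cfg, panel)
        return cfg, simulate_pool_pileups(truth, cfg)

    def test_identity_fold(self):
        cfg, counts = self.make_counts()
        out = plant_cnv(counts, (1, cfg.region_length), 1.0, ["BT"])
        pd.testing.assert_frame_equal(out[0].sites, counts[0].sites)

    def test_deletion(self):
        cfg, counts = self.make_counts()
        lo, hi = 1, cfg.region_length
        out = plant_cnv(counts, (lo, hi), 0.0, ["BT"])
        bt = next(p for p in out if p.pool == "BT")
        assert bt.depth.sum() == 0
        other = next(p for p in out if p.pool == "JR")
        assert other.depth.sum() > 0  # untouched pool keeps its reads

    def test_fold_scales_mean_depth(self):
        cfg, counts = self.make_counts()
        out = plant_cnv(counts, (1, cfg.region_length), 2.5, ["BT"])
        bt_in = next(p for p in counts if p.pool == "BT")
        bt_out = next(p for p in out if p.pool == "BT")
        ratio = bt_out.depth.mean() / bt_in.depth.mean()
        assert ratio == pytest.approx(2.5, rel=0.01)

    def test_interval_validation(self):
        cfg, counts = self.make_counts()
        with pytest.raises(ValueError, match="interval"):
            plant_cnv(counts, (1, cfg.region_length + 5), 2.0, ["BT"],
                      region_length=cfg.region_length)
        with pytest.raises(ValueError, match="fold"):
            plant_cnv(counts, (1, 10), -1.0, ["BT"])
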