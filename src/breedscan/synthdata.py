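"""Synthetic breed-pool worlds with known ground truth.

The generator emulates the study design every downstream stage assumes:
a handful of breeds founded from three region haplotypes — D carrying the
derived alleles of a 5′ "ear" block, S carrying the derived alleles of a
3′ "mass" block, and L carrying neither — with drop-ear breeds near-fixed
for D, small breeds near-fixed for S, and large prick-ear breeds (and the
wolf) near-fixed for L.  Post-bottleneck drift is modeled by drawing each
breed's haplotype-class frequencies from a Dirichlet concentrated on the
phenotype-consistent class (concentration = ``drift_strength``); unlinked
background SNPs drift independently per breed via a beta distribution
around a shared ancestral frequency.  Recombinants joining D ear alleles
with S mass alleles arise at a configurable, default-rare rate.

Individuals receive two haplotypes per breed; pools receive Poisson read
depth per site and binomial non-reference read counts at the error-folded
frequency f·(1−e) + (1−f)·e.  Everything is reproducible from
``SimConfig.seed``: per-operation generators are derived from it, so the
same config yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pileup_io import GenotypeTable, PoolAlleleCounts

CLASSES = ("D", "L", "S")  # founder haplotype classes


@dataclass
class PoolSpec:
    name: str
    breeds: tuple[str, ...]
    mean_depth: float
    kind: str = "SC"  # SC | WGS
    size_class: str = "large"
    ear_class: str = "non-drop"


@dataclass
class SimConfig:
    """Stated world for the generator; defaults mirror the study design."""

    n_breeds: int = 12
    samples_per_breed: int = 12
    n_snps: int = 200
    region_length: int = 3_000_000
    ear_block_span: tuple[int, int] = (1_050_000, 1_110_000)   # 5' block
    mass_block_span: tuple[int, int] = (1_400_000, 1_500_000)  # 3' block
    n_causal_ear: int = 4
    n_causal_mass: int = 4
    error_rate: float = 0.002
    drift_strength: float = 30.0
    recomb_rate: float = 0.005   # recombinants observed at < 1 % in breeds
    mass_effect_kg: float = -8.0  # per small-haplotype copy
    baseline_mass_kg: float = 25.0
    mass_noise_sd: float = 0.08   # log-normal sigma on the baseline
    seed: int = 0
    # breed -> (size_class, ear_class); generated when None
    breed_phenotypes: dict[str, tuple[str, str]] | None = None
    wolf_breed: str = "Wolf"
    pool_specs: tuple[PoolSpec, ...] | None = None

    def __post_init__(self):
        if self.n_breeds < 2:
            raise ValueError("need at least 2 breeds")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error rate must be in [0, 0.5)")
        e0, e1 = self.ear_block_span
        m0, m1 = self.mass_block_span
        if not (1 <= e0 <= e1 < m0 <= m1 <= self.region_length):
            raise ValueError("blocks must be disjoint, ordered 5'->3', "
                             "inside the region")
        if self.breed_phenotypes is None:
            self.breed_phenotypes = self._default_breeds()
        if self.pool_specs is None:
            self.pool_specs = self._default_pools()
        for spec in self.pool_specs:
            if spec.mean_depth <= 0:
                raise ValueError(f"pool {spec.name!r} depth must be > 0")
            for b in spec.breeds:
                if b not in self.breed_phenotypes:
                    raise ValueError(f"pool {spec.name!r} references unknown "
                                     f"breed {b!r}")

    def _default_breeds(self) -> dict[str, tuple[str, str]]:
        """n_breeds dogs cycling over realistic phenotype combinations,
        plus the wolf (large, non-drop, ancestral haplotype)."""
        pattern = [("small", "non-drop"), ("small", "non-drop"),
                   ("large", "non-drop"), ("large", "drop"),
                   ("large", "drop"), ("large", "non-drop"),
                   ("large", "drop"), ("large", "drop"),
                   ("large", "non-drop"), ("large", "drop"),
                   ("large", "non-drop"), ("large", "drop")]
        out = {}
        for i in range(self.n_breeds):
            out[f"B{i + 1:02d}"] = pattern[i % len(pattern)]
        out[self.wolf_breed] = ("large", "non-drop")
        return out

    def _default_pools(self) -> tuple[PoolSpec, ...]:
        """5 single-breed high-coverage SC pools + 6 low-coverage WGS pools
        (one of them the wolf pool), mirroring the shipped pool design."""
        names = [b for b in self.breed_phenotypes if b != self.wolf_breed]

        def pick(size, ear, k):
            found = [b for b in names
                     if self.breed_phenotypes[b] == (size, ear)]
            return found[:k]

        small = pick("small", "non-drop", 2)
        large_nd = pick("large", "non-drop", 4)
        large_d = pick("large", "drop", 5)
        if len(small) < 2 or len(large_nd) < 2 or len(large_d) < 3:
            raise ValueError("default pool design needs >=2 small non-drop, "
                             ">=2 large non-drop and >=3 large drop breeds")
        sc = [
            PoolSpec("BT", (small[0],), 4748, "SC", "small", "non-drop"),
            PoolSpec("JR", (small[1],), 4910, "SC", "small", "non-drop"),
            PoolSpec("GS", (large_nd[0],), 5182, "SC", "large", "non-drop"),
            PoolSpec("WEI", (large_d[0],), 4305, "SC", "large", "drop"),
            PoolSpec("ESS", (large_d[1],), 1990, "SC", "large", "drop"),
        ]
        mix1 = tuple([large_nd[0], large_d[2]])
        mix2 = tuple([large_nd[1], large_d[0]])
        wgs = [
            PoolSpec("Pool1", (self.wolf_breed,), 7.5, "WGS", "large", "non-drop"),
            PoolSpec("Pool2", mix1, 6.9, "WGS", "large", "mix"),
            PoolSpec("Pool3", (large_d[1], large_d[2]), 6.1, "WGS", "large", "drop"),
            PoolSpec("Pool4", (large_d[0],), 8.0, "WGS", "large", "drop"),
            PoolSpec("Pool5", (large_nd[1],), 8.1, "WGS", "large", "non-drop"),
            PoolSpec("Pool6", mix2, 7.9, "WGS", "large", "mix"),
        ]
        return tuple(sc + wgs)

    def rng(self, op: int) -> np.random.Generator:
        """Per-operation generator so each stage is independently seeded."""
        return np.random.default_rng([self.seed, op])


@dataclass
class TruthSet:
    """Everything the generator knows that the pipeline must rediscover."""

    cfg: SimConfig
    positions: np.ndarray              # 1-based, sorted, unique
    causal_ear_idx: np.ndarray         # indices into positions
    causal_mass_idx: np.ndarray
    breeds: list[str]
    class_freqs: pd.DataFrame          # breeds × (D, L, S)
    breed_freqs: np.ndarray            # breeds × snps alt-allele frequency
    genotypes: GenotypeTable
    haplotypes: np.ndarray             # samples × 2 × snps uint8
    pool_freqs: dict[str, np.ndarray]  # pool -> true alt frequency f per site
    cnv_intervals: list[tuple[int, int, float, tuple[str, ...]]] = field(
        default_factory=list)

    def breed_index(self, breed: str) -> int:
        return self.breeds.index(breed)


def simulate_breed_panel(cfg: SimConfig) -> pd.DataFrame:
    """Breed panel with ear class, breed-average mass and sample counts.

    Mass = log-normal baseline × noise + mass_effect_kg × small-haplotype
    dosage (2 for small breeds, 0 for large); ear type 'drop' or 'prick'
    from the breed's ear class (the wolf is excluded — it is a sequencing
    pool, not a GWAS breed).
    """
    rng = cfg.rng(1)
    rows = []
    for breed, (size, ear) in cfg.breed_phenotypes.items():
        if breed == cfg.wolf_breed:
            continue
        noise = float(np.exp(rng.normal(0.0, cfg.mass_noise_sd))) \
            if cfg.mass_noise_sd > 0 else 1.0
        dosage = 2 if size == "small" else 0
        mass = cfg.baseline_mass_kg * noise + cfg.mass_effect_kg * dosage
        rows.append((breed, cfg.samples_per_breed,
                     "drop" if ear == "drop" else "prick",
                     max(mass, 1.0), size))
    return pd.DataFrame(rows, columns=["breed", "n", "ear_type",
                                       "body_mass_kg", "size_class"])


def _snp_positions(cfg: SimConfig, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place causal SNPs inside their blocks, the rest uniformly."""
    e0, e1 = cfg.ear_block_span
    m0, m1 = cfg.mass_block_span
    n_bg = cfg.n_snps - cfg.n_causal_ear - cfg.n_causal_mass
    if n_bg < 0:
        raise ValueError("n_snps smaller than the number of causal SNPs")
    ear = np.sort(rng.choice(np.arange(e0, e1 + 1), cfg.n_causal_ear,
                             replace=False))
    mass = np.sort(rng.choice(np.arange(m0, m1 + 1), cfg.n_causal_mass,
                              replace=False))
    taken = set(ear) | set(mass)
    bg = []
    while len(bg) < n_bg:
        cand = int(rng.integers(1, cfg.region_length + 1))
        if cand not in taken:
            taken.add(cand)
            bg.append(cand)
    pos = np.sort(np.concatenate([ear, mass, np.array(bg, dtype=np.int64)]))
    ear_idx = np.searchsorted(pos, ear)
    mass_idx = np.searchsorted(pos, mass)
    return pos, ear_idx, mass_idx


def _phenotype_class(size: str, ear: str) -> str:
    """The founder haplotype a breed's phenotype is consistent with."""
    if ear == "drop":
        return "D"
    return "S" if size == "small" else "L"


def simulate_haplotype_pools(cfg: SimConfig, panel: pd.DataFrame) -> TruthSet:
    """Found breeds on D/L/S haplotypes, drift them, and sample genotypes.

    Breed class frequencies ~ Dirichlet(drift_strength · one-hot(class)
    + 0.5): near-fixed for the phenotype-consistent class, degenerating to
    exactly fixed as drift_strength → ∞.  Background SNPs drift per breed
    as Beta(drift·π, drift·(1−π)) around ancestral π ~ U(0.05, 0.95);
    the wolf sits at the ancestral frequency (no breed bottleneck).
    Each individual samples two haplotypes; with probability
    ``recomb_rate`` a haplotype's mass-block class is resampled
    independently of its ear-block class (a recombinant).
    """
    rng = cfg.rng(2)
    pos, ear_idx, mass_idx = _snp_positions(cfg, rng)
    n_snps = cfg.n_snps
    breeds = list(cfg.breed_phenotypes)

    # founder allele carried at causal sites by each class
    class_allele = {c: np.zeros(n_snps, dtype=np.uint8) for c in CLASSES}
    class_allele["D"][ear_idx] = 1
    class_allele["S"][mass_idx] = 1

    # breed haplotype-class frequencies
    cf_rows = []
    for breed in breeds:
        size, ear = cfg.breed_phenotypes[breed]
        target = _phenotype_class(size, ear)
        onehot = np.array([1.0 if c == target else 0.0 for c in CLASSES])
        if breed == cfg.wolf_breed or np.isinf(cfg.drift_strength):
            freqs = onehot
        else:
            freqs = rng.dirichlet(cfg.drift_strength * onehot + 0.5)
        cf_rows.append(freqs)
    class_freqs = pd.DataFrame(cf_rows, index=breeds, columns=list(CLASSES))

    # background drift
    causal = np.zeros(n_snps, dtype=bool)
    causal[ear_idx] = True
    causal[mass_idx] = True
    ancestral = rng.uniform(0.05, 0.95, size=n_snps)
    breed_freqs = np.zeros((len(breeds), n_snps))
    for i, breed in enumerate(breeds):
        if breed == cfg.wolf_breed or np.isinf(cfg.drift_strength):
            bg = ancestral.copy()
        else:
            bg = rng.beta(cfg.drift_strength * ancestral,
                          cfg.drift_strength * (1 - ancestral))
        f = class_freqs.loc[breed].to_numpy()
        implied = (f[:, None] * np.stack([class_allele[c] for c in CLASSES])
                   ).sum(axis=0)
        breed_freqs[i] = np.where(causal, implied, bg)

    # individuals: two haplotypes each, wolf excluded from the sample set
    samples, sample_breeds, haps = [], [], []
    dog_breeds = [b for b in breeds if b != cfg.wolf_breed]
    for breed in dog_breeds:
        i = breeds.index(breed)
        f = class_freqs.loc[breed].to_numpy()
        for s in range(cfg.samples_per_breed):
            pair = []
            for _ in range(2):
                cls_ear = rng.choice(3, p=f)
                cls_mass = cls_ear
                if cfg.recomb_rate > 0 and rng.random() < cfg.recomb_rate:
                    cls_mass = rng.choice(3, p=f)
                hap = (rng.random(n_snps) < breed_freqs[i]).astype(np.uint8)
                hap[ear_idx] = class_allele[CLASSES[cls_ear]][ear_idx]
                hap[mass_idx] = class_allele[CLASSES[cls_mass]][mass_idx]
                pair.append(hap)
            haps.append(np.stack(pair))
            samples.append(f"{breed}_{s + 1:03d}")
            sample_breeds.append(breed)
    haplotypes = np.stack(haps)
    dosages = haplotypes.sum(axis=1).astype(np.int8)
    snp_map = pd.DataFrame({"snp": [f"snp{k + 1:04d}" for k in range(n_snps)],
                            "chrom": "chrS", "pos": pos,
                            "ref": "A", "alt": "G"})
    gt = GenotypeTable(samples=samples, breeds=sample_breeds,
                       snps=list(snp_map["snp"]), dosages=dosages,
                       snp_map=snp_map)

    pool_freqs = {}
    for spec in cfg.pool_specs:
        idx = [breeds.index(b) for b in spec.breeds]
        pool_freqs[spec.name] = breed_freqs[idx].mean(axis=0)
    return TruthSet(cfg=cfg, positions=pos, causal_ear_idx=ear_idx,
                    causal_mass_idx=mass_idx, breeds=breeds,
                    class_freqs=class_freqs, breed_freqs=breed_freqs,
                    genotypes=gt, haplotypes=haplotypes,
                    pool_freqs=pool_freqs)


def simulate_pool_pileups(truth: TruthSet, cfg: SimConfig | None = None,
                          dense_region: tuple[int, int] | None = None
                          ) -> list[PoolAlleleCounts]:
    """Draw read counts for every pool at every SNP site.

    Depth ~ Poisson(pool mean); non-reference reads ~ Binomial(depth,
    f·(1−e) + (1−f)·e).  With ``dense_region`` the counts additionally
    cover every base of that interval (f = 0 between SNPs), which is what
    the window-based CNV scan consumes.
    """
    cfg = cfg or truth.cfg
    rng = cfg.rng(3)
    e = cfg.error_rate
    out = []
    for spec in cfg.pool_specs:
        f = truth.pool_freqs[spec.name]
        pos = truth.positions
        if dense_region is not None:
            lo, hi = dense_region
            if not (1 <= lo <= hi <= cfg.region_length):
                raise ValueError("dense region outside the simulated region")
            dense_pos = np.arange(lo, hi + 1, dtype=np.int64)
            dense_f = np.zeros(len(dense_pos))
            inside = (pos >= lo) & (pos <= hi)
            dense_f[pos[inside] - lo] = f[inside]
            keep = ~np.isin(pos, dense_pos)
            pos = np.concatenate([pos[keep], dense_pos])
            f = np.concatenate([f[keep], dense_f])
            order = np.argsort(pos, kind="stable")
            pos, f = pos[order], f[order]
        depth = rng.poisson(spec.mean_depth, size=len(pos))
        p_read = f * (1 - e) + (1 - f) * e
        nonref = rng.binomial(depth, p_read)
        sites = pd.DataFrame({"chrom": "chrS", "pos": pos, "ref": "A",
                              "ref_count": depth - nonref,
                              "nonref_count": nonref,
                              "nonref_base": "G",
                              "other_count": 0})
        out.append(PoolAlleleCounts(pool=spec.name, sites=sites,
                                    kind=spec.kind,
                                    size_class=spec.size_class,
                                    ear_class=spec.ear_class))
    return out


def plant_cnv(counts: list[PoolAlleleCounts], interval: tuple[int, int],
              fold: float, pools: tuple[str, ...] | list[str],
              region_length: int | None = None) -> list[PoolAlleleCounts]:
    """Scale read depth inside an interval for selected pools.

    fold = 0 deletes coverage; fold = 1 is the identity; counts are scaled
    and rounded deterministically so the mean depth scales by ``fold``.
    """
    if fold < 0:
        raise ValueError("fold must be >= 0")
    lo, hi = interval
    if region_length is not None and not (1 <= lo <= hi <= region_length):
        raise ValueError("CNV interval outside the region")
    wanted = set(pools)
    out = []
    for pc in counts:
        if pc.pool not in wanted:
            out.append(pc)
            continue
        sites = pc.sites.copy()
        mask = (sites["pos"] >= lo) & (sites["pos"] <= hi)
        for col in ("ref_count", "nonref_count", "other_count"):
            scaled = np.rint(sites.loc[mask, col].to_numpy() * fold)
            sites.loc[mask, col] = scaled.astype(np.int64)
        out.append(PoolAlleleCounts(pool=pc.pool, sites=sites, kind=pc.kind,
                                    size_class=pc.size_class,
                                    ear_class=pc.ear_class))
    return out


def phenotype_scheme(cfg: SimConfig):
    """PhenotypeScheme for the config's pools (wolf pool auto-detected)."""
    from .candidates import PhenotypeScheme
    labels = {s.name: (s.size_class, s.ear_class) for s in cfg.pool_specs}
    wolf = ""
    for s in cfg.pool_specs:
        if s.breeds == (cfg.wolf_breed,):
            wolf = s.name
            break
    return PhenotypeScheme(labels=labels, wolf_pool=wolf)
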