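"""Across-breed quantitative GWAS with breed-permutation significance.

Every sample of a breed carries the breed's phenotype value (ear code
prick = 1, intermediate = 2, drop = 3; or breed-average mass in kg), so the
exchangeable unit under the null is the *breed*, not the sample.  The
association statistic per SNP is the 1-df score test chi² = n·r² with r
the Pearson correlation between allele dosage and trait.  Significance
comes from permuting breed-level trait values among breeds and
broadcasting to samples: EMP1 compares each SNP with its own permuted
statistics, EMP2 with the genome-wide maximum per permutation (both with
+1 smoothing, so the floor at P permutations is 1/(P+1)).

Also here: the Kruskal–Wallis test for trait confounding at breed-level
units, and the among-breed F_ST scan (unweighted Nei G_ST) with MAF and
consecutive-run reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pileup_io import GenotypeTable

EAR_CODES = {"prick": 1, "intermediate": 2, "drop": 3}


@dataclass
class TraitVector:
    """Per-sample trait values constant within breed."""

    values: np.ndarray
    breeds: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.breeds):
            raise ValueError("values and breed labels differ in length")
        for b in set(self.breeds):
            vals = self.values[np.array(self.breeds) == b]
            if not np.allclose(vals, vals[0]):
                raise ValueError(f"breed {b!r} has non-identical trait values")

    @classmethod
    def from_panel(cls, panel: pd.DataFrame, trait: str) -> "TraitVector":
        """Expand a breed panel into per-sample values (trait: ear|mass)."""
        values, breeds = [], []
        for r in panel.itertuples(index=False):
            v = EAR_CODES[r.ear_type] if trait == "ear" else float(r.body_mass_kg)
            values.extend([v] * int(r.n))
            breeds.extend([r.breed] * int(r.n))
        return cls(values=np.array(values, dtype=float), breeds=breeds)


def _chi2_vector(dosages: np.ndarray, trait: np.ndarray) -> np.ndarray:
    """n·r² per SNP column, NaN where the SNP is monomorphic/unusable.

    Missing dosages (<0) are excluded per SNP; n counts the non-missing
    samples at that SNP.
    """
    m = dosages.shape[1]
    out = np.full(m, np.nan)
    for j in range(m):
        col = dosages[:, j].astype(float)
        ok = col >= 0
        x = col[ok]
        y = trait[ok]
        if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        out[j] = x.size * r * r
    return out


def _chi2_fast(dos: np.ndarray, trait: np.ndarray) -> np.ndarray:
    """Vectorized n·r² for a complete (no-missing) dosage matrix."""
    n = dos.shape[0]
    xc = dos - dos.mean(axis=0)
    yc = trait - trait.mean()
    sxx = (xc ** 2).sum(axis=0)
    syy = (yc ** 2).sum()
    sxy = xc.T @ yc
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where((sxx > 0) & (syy > 0), sxy ** 2 / (sxx * syy), np.nan)
    return n * r2


def assoc_chi2(dosages: np.ndarray, trait: TraitVector
               ) -> tuple[np.ndarray, np.ndarray]:
    """Score-test chi² = n·r² and its 1-df asymptotic p per SNP.

    Monomorphic SNPs (or a constant trait) give NaN, not zero.
    """
    dosages = np.atleast_2d(np.asarray(dosages))
    if dosages.shape[0] == 1 and len(trait.values) != 1:
        dosages = dosages.T
    chi2 = _chi2_vector(dosages, trait.values)
    p = stats.chi2.sf(chi2, df=1)
    return chi2, p


def breed_permutation_test(gt: GenotypeTable, trait: TraitVector,
                           n_perm: int = 1000, seed: int = 0
                           ) -> pd.DataFrame:
    """Breed-label permutation GWAS: EMP1 (pointwise) and EMP2 (genome-wide).

    Each permutation shuffles the breed-level trait values among breeds,
    broadcasts to samples, and recomputes every SNP statistic.  Counting
    uses ≥ (ties count against significance) and +1 smoothing:
    EMP1 = (1 + #{perm stat ≥ observed}) / (P + 1), EMP2 likewise against
    the per-permutation maximum over SNPs.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    breeds = sorted(set(trait.breeds))
    if len(breeds) < 2:
        raise ValueError("breed permutation needs at least 2 breeds")
    breed_value = {}
    arr_breeds = np.array(trait.breeds)
    for b in breeds:
        breed_value[b] = float(trait.values[arr_breeds == b][0])
    breed_idx = np.array([breeds.index(b) for b in trait.breeds])
    level_values = np.array([breed_value[b] for b in breeds])

    dos = gt.dosages.astype(float)
    has_missing = np.any(dos < 0)
    obs = (_chi2_vector(gt.dosages, trait.values) if has_missing
           else _chi2_fast(dos, trait.values))

    rng = np.random.default_rng(seed)
    ge_point = np.zeros(len(gt.snps))
    ge_max = np.zeros(len(gt.snps))
    for _ in range(n_perm):
        perm_levels = level_values[rng.permutation(len(breeds))]
        perm_trait = perm_levels[breed_idx]
        stat = (_chi2_vector(gt.dosages, perm_trait) if has_missing
                else _chi2_fast(dos, perm_trait))
        with np.errstate(invalid="ignore"):
            ge_point += np.where(np.isnan(obs), 0, stat >= obs)
            mx = np.nanmax(stat) if np.any(~np.isnan(stat)) else -np.inf
            ge_max += np.where(np.isnan(obs), 0, mx >= obs)
    emp1 = (1 + ge_point) / (n_perm + 1)
    emp2 = (1 + ge_max) / (n_perm + 1)
    emp1[np.isnan(obs)] = np.nan
    emp2[np.isnan(obs)] = np.nan
    return pd.DataFrame({"snp": gt.snps, "chi2": obs,
                         "p_raw": stats.chi2.sf(obs, df=1),
                         "emp1": emp1, "emp2": emp2})


def kruskal_wallis(panel: pd.DataFrame, breed_level: bool = True
                   ) -> dict:
    """Kruskal–Wallis test of body mass across ear classes.

    Breed-level units by default (each breed one observation of its
    average mass); sample-level weighting behind the flag.  Returns the
    tie-corrected H, p, and group means/sizes.
    """
    groups, means, sizes = [], {}, {}
    for ear, df in panel.groupby("ear_type"):
        masses = df["body_mass_kg"].to_numpy(dtype=float)
        if not breed_level:
            masses = np.repeat(masses, df["n"].to_numpy(dtype=int))
        groups.append(masses)
        means[ear] = float(np.mean(masses))
        sizes[ear] = len(masses)
    if len(groups) < 2:
        raise ValueError("need at least 2 ear classes")
    if np.ptp(np.concatenate(groups)) == 0:
        # all masses identical: H = 0 by the tie-correction convention
        return {"H": 0.0, "p": 1.0, "group_means": means, "group_sizes": sizes}
    h, p = stats.kruskal(*groups)
    return {"H": float(h), "p": float(p), "group_means": means,
            "group_sizes": sizes}


def breed_frequencies(gt: GenotypeTable) -> tuple[list[str], np.ndarray]:
    """Per-breed alt-allele frequency matrix (breeds × SNPs), NaN-aware."""
    breeds = sorted(set(gt.breeds))
    arr = np.array(gt.breeds)
    freqs = np.full((len(breeds), len(gt.snps)), np.nan)
    for i, b in enumerate(breeds):
        sub = gt.dosages[arr == b].astype(float)
        sub[sub < 0] = np.nan
        with np.errstate(invalid="ignore"):
            freqs[i] = np.nanmean(sub, axis=0) / 2.0
    return breeds, freqs


def amongbreed_fst(freqs: np.ndarray) -> np.ndarray:
    """Unweighted Nei-style G_ST per SNP from breed frequencies.

    F_ST = (H_T − H_S)/H_T with H_T = 2·p̄(1−p̄) over the unweighted mean
    breed frequency and H_S the mean within-breed expected heterozygosity.
    NaN where H_T = 0.
    """
    with np.errstate(invalid="ignore"):
        pbar = np.nanmean(freqs, axis=0)
        ht = 2 * pbar * (1 - pbar)
        hs = np.nanmean(2 * freqs * (1 - freqs), axis=0)
        return np.where(ht > 0, (ht - hs) / ht, np.nan)


def amongbreed_fst_scan(gt: GenotypeTable, fst_min: float = 0.55,
                        maf_min: float = 0.15) -> pd.DataFrame:
    """SNPs with high among-breed differentiation and common minor allele.

    Reports per-SNP F_ST and MAF, a qualifying flag (F_ST > fst_min and
    MAF > maf_min, both strict), and the maximal consecutive runs of
    qualifying SNPs in map order (run id and length annotated per SNP).
    """
    _, freqs = breed_frequencies(gt)
    fst = amongbreed_fst(freqs)
    af = gt.allele_frequencies()
    maf = np.minimum(af, 1 - af)
    qualifies = np.where(np.isnan(fst) | np.isnan(maf), False,
                         (fst > fst_min) & (maf > maf_min))
    run_id = np.full(len(gt.snps), -1)
    run_len = np.zeros(len(gt.snps), dtype=int)
    rid = 0
    i = 0
    while i < len(qualifies):
        if qualifies[i]:
            j = i
            while j < len(qualifies) and qualifies[j]:
                j += 1
            run_id[i:j] = rid
            run_len[i:j] = j - i
            rid += 1
            i = j
        else:
            i += 1
    return pd.DataFrame({"snp": gt.snps, "fst": fst, "maf": maf,
                         "qualifies": qualifies, "run_id": run_id,
                         "run_length": run_len})
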