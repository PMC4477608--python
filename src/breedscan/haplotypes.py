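"""EM haplotype-frequency estimation and linkage disequilibrium.

Phasing follows the classic Excoffier–Slatkin EM under random mating:
each sample's unphased genotype over L biallelic SNPs is compatible with
a set of ordered haplotype pairs; the E-step weights pair (h1, h2) by
2^[h1≠h2]·f(h1)·f(h2) renormalized per sample, and the M-step sets each
haplotype frequency to its expected count over 2n chromosomes.  The
log-likelihood is non-decreasing by construction and is tracked every
iteration.  After convergence each sample is assigned its most probable
pair (ties broken lexicographically on the haplotype codes); samples with
best-pair posterior below a confidence floor stay unassigned, as do
all-missing samples.

Missing genotypes are marginalized: a sample's compatible pairs enumerate
both alleles at untyped sites.  Enumeration is exponential in the number
of heterozygous + missing sites, so L is capped at 20.

LD between two SNPs is computed from the fitted haplotype frequencies:
D = pAB − pA·pB, |D'| = |D| / D_max, r² = D² / (pA·pa·pB·pb).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class HaplotypeSet:
    """EM output: haplotype frequencies plus per-sample assignments."""

    n_snps: int
    haplotypes: np.ndarray      # int codes (bit i = alt allele at SNP i)
    frequencies: np.ndarray
    assignments: list[tuple[int, int] | None]  # per sample, None = unassigned
    posteriors: np.ndarray      # best-pair posterior per sample
    loglik_trace: np.ndarray

    def hap_string(self, code: int) -> str:
        return "".join(str((code >> i) & 1) for i in range(self.n_snps))

    def frequency_table(self) -> pd.DataFrame:
        order = np.argsort(-self.frequencies)
        return pd.DataFrame({
            "haplotype": [self.hap_string(int(h)) for h in self.haplotypes[order]],
            "frequency": self.frequencies[order]})

    def snp_allele_freq(self, i: int) -> float:
        """Alt-allele frequency at SNP i implied by haplotype frequencies."""
        bits = (self.haplotypes >> i) & 1
        return float(self.frequencies[bits == 1].sum())


def _compatible_pairs(genotype: np.ndarray) -> list[tuple[int, int]]:
    """All ordered-canonical (h1 ≤ h2) haplotype pairs matching a genotype.

    Homozygous sites pin both haplotypes; heterozygous sites split the two
    alleles between them; missing sites enumerate all four combinations.
    """
    l = len(genotype)
    base1 = 0
    base2 = 0
    free: list[tuple[int, str]] = []  # (site, kind): het splits, miss frees both
    for i in range(l):
        g = genotype[i]
        if g == 2:
            base1 |= 1 << i
            base2 |= 1 << i
        elif g == 1:
            free.append((i, "het"))
        elif g < 0:
            free.append((i, "miss"))
    pairs: set[tuple[int, int]] = set()
    n_choices = 1
    for _, kind in free:
        n_choices *= 2 if kind == "het" else 4
    for combo in range(n_choices):
        h1, h2 = base1, base2
        c = combo
        for i, kind in free:
            if kind == "het":
                if c & 1:
                    h1 |= 1 << i
                else:
                    h2 |= 1 << i
                c >>= 1
            else:
                if c & 1:
                    h1 |= 1 << i
                if c & 2:
                    h2 |= 1 << i
                c >>= 2
        pairs.add((h1, h2) if h1 <= h2 else (h2, h1))
    return sorted(pairs)


def em_phase(genotypes: np.ndarray, tol: float = 1e-8, max_iter: int = 200,
             seed: int = 0, confidence_floor: float = 0.0) -> HaplotypeSet:
    """Fit haplotype frequencies by EM and assign most-probable pairs.

    ``genotypes`` is (n_samples × L) with dosages 0/1/2 and −1 for
    missing.  Initialization is uniform over the haplotypes appearing in
    any sample's compatible set (the EM fixed point does not depend on the
    seed for this initialization; ``seed`` is accepted for interface
    stability).  Convergence: log-likelihood gain < tol.
    """
    genotypes = np.asarray(genotypes)
    n, l = genotypes.shape
    if l > 20:
        raise ValueError("enumeration capped at 20 SNPs")
    if n < 1:
        raise ValueError("need at least one sample")

    sample_pairs: list[list[tuple[int, int]]] = []
    informative: list[int] = []
    for s in range(n):
        g = genotypes[s]
        if np.all(g < 0):
            sample_pairs.append([])
            continue
        sample_pairs.append(_compatible_pairs(g))
        informative.append(s)
    if not informative:
        raise ValueError("all samples are entirely missing")

    hap_codes = sorted({h for s in informative for pr in sample_pairs[s]
                        for h in pr})
    hap_index = {h: k for k, h in enumerate(hap_codes)}
    n_hap = len(hap_codes)

    # flatten pairs for vectorized E-steps
    flat_h1, flat_h2, offsets = [], [], [0]
    for s in informative:
        for h1, h2 in sample_pairs[s]:
            flat_h1.append(hap_index[h1])
            flat_h2.append(hap_index[h2])
        offsets.append(len(flat_h1))
    flat_h1 = np.array(flat_h1)
    flat_h2 = np.array(flat_h2)
    offsets = np.array(offsets)
    het_mult = np.where(flat_h1 != flat_h2, 2.0, 1.0)
    seg = np.repeat(np.arange(len(informative)), np.diff(offsets))

    freqs = np.full(n_hap, 1.0 / n_hap)
    trace = []
    for _ in range(max_iter):
        w = het_mult * freqs[flat_h1] * freqs[flat_h2]
        per_sample = np.bincount(seg, weights=w, minlength=len(informative))
        loglik = float(np.log(per_sample).sum())
        trace.append(loglik)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
        post = w / per_sample[seg]
        counts = np.bincount(flat_h1, weights=post, minlength=n_hap)
        counts += np.bincount(flat_h2, weights=post, minlength=n_hap)
        freqs = counts / (2 * len(informative))

    # most-probable pair per sample under the final frequencies
    w = het_mult * freqs[flat_h1] * freqs[flat_h2]
    per_sample = np.bincount(seg, weights=w, minlength=len(informative))
    assignments: list[tuple[int, int] | None] = [None] * n
    posteriors = np.zeros(n)
    for k, s in enumerate(informative):
        lo, hi = offsets[k], offsets[k + 1]
        ws = w[lo:hi]
        best = int(np.argmax(ws))  # argmax takes the first = lexicographic tie-break
        post = ws[best] / per_sample[k] if per_sample[k] > 0 else 0.0
        posteriors[s] = post
        if post >= confidence_floor and per_sample[k] > 0:
            assignments[s] = sample_pairs[s][best]
    return HaplotypeSet(n_snps=l, haplotypes=np.array(hap_codes),
                        frequencies=freqs, assignments=assignments,
                        posteriors=posteriors,
                        loglik_trace=np.array(trace))


def enumerate_breed_haplotypes(hapset: HaplotypeSet, breeds: list[str],
                               min_freq: float = 0.015
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-breed haplotype counts from best-guess pairs, majors named.

    Haplotypes with overall frequency (among assigned chromosomes)
    > ``min_freq`` are reported individually; the rest pool into "Other".
    Returns (long counts frame, breed × major-haplotype table).
    """
    counts: dict[tuple[str, int], int] = {}
    total: dict[int, int] = {}
    n_assigned = 0
    for breed, pair in zip(breeds, hapset.assignments):
        if pair is None:
            continue
        n_assigned += 1
        for h in pair:
            counts[(breed, h)] = counts.get((breed, h), 0) + 1
            total[h] = total.get(h, 0) + 1
    denom = 2 * n_assigned
    majors = sorted((h for h, c in total.items() if c / denom > min_freq),
                    key=lambda h: -total[h])
    rows = [(b, hapset.hap_string(h), c) for (b, h), c in sorted(counts.items())]
    long = pd.DataFrame(rows, columns=["breed", "haplotype", "count"])
    table_rows = []
    for b in sorted(set(breeds)):
        row = {"breed": b}
        other = 0
        for h, c in ((h, counts.get((b, h), 0)) for h in total):
            if h in majors:
                row[hapset.hap_string(h)] = c
            else:
                other += c
        for h in majors:
            row.setdefault(hapset.hap_string(h), 0)
        row["Other"] = other
        table_rows.append(row)
    return long, pd.DataFrame(table_rows)


def ld_from_pair_freqs(p_ab: float, p_aB: float, p_Ab: float, p_AB: float
                       ) -> dict:
    """D, |D'| and r² from the four two-locus haplotype frequencies.

    Uppercase = alt allele at each locus; frequencies must sum to 1.
    """
    pA = p_AB + p_Ab
    pB = p_AB + p_aB
    pa, pb = 1 - pA, 1 - pB
    if min(pA, pa, pB, pb) <= 0:
        return {"D": np.nan, "Dprime": np.nan, "r2": np.nan,
                "pA": pA, "pB": pB}
    d = p_AB - pA * pB
    dmax = min(pA * pb, pa * pB) if d > 0 else min(pA * pB, pa * pb)
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    r2 = d * d / (pA * pa * pB * pb)
    return {"D": d, "Dprime": dprime, "r2": r2, "pA": pA, "pB": pB}


def ld_pair(hapset: HaplotypeSet, i: int, j: int) -> dict:
    """LD between SNPs i and j from fitted haplotype frequencies."""
    bits_i = (hapset.haplotypes >> i) & 1
    bits_j = (hapset.haplotypes >> j) & 1
    f = hapset.frequencies
    p_AB = float(f[(bits_i == 1) & (bits_j == 1)].sum())
    p_Ab = float(f[(bits_i == 1) & (bits_j == 0)].sum())
    p_aB = float(f[(bits_i == 0) & (bits_j == 1)].sum())
    p_ab = float(f[(bits_i == 0) & (bits_j == 0)].sum())
    return ld_from_pair_freqs(p_ab, p_aB, p_Ab, p_AB)


def ld_matrix(hapset: HaplotypeSet) -> pd.DataFrame:
    """Long-format pairwise LD over all SNP pairs (NaN for monomorphic)."""
    rows = []
    for i in range(hapset.n_snps):
        for j in range(i + 1, hapset.n_snps):
            ld = ld_pair(hapset, i, j)
            rows.append((i, j, ld["D"], ld["Dprime"], ld["r2"]))
    return pd.DataFrame(rows, columns=["snp_i", "snp_j", "D", "Dprime", "r2"])
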