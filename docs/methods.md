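# Methods

`breedscan` implements an analysis chain for mapping linked morphological
variants in dog breeds from two complementary data types: pooled
resequencing of a candidate region (allele frequencies read off as read
fractions) and an across-breed GWAS panel (per-sample dosages with
breed-level phenotypes). This note records the models, the thresholds and
their defaults, what the synthetic-data generator does and does not
emulate, and the design choices made where the procedure was genuinely
open.

## Pooled SNP calling (`poolvar`)

Counts reaching the caller are base-quality filtered (phred ≥ 20, in
`pileup_io`); the caller itself is pure arithmetic on reference /
non-reference read counts.

* **Variability screen.** A site is a variable SNP iff, summing reads over
  all pools, the minor allele carries *strictly more than* 10 % of reads
  (`min_minor_fraction = 0.10`). Strict reading of the ">10 %" rule; a
  site at exactly 10 % is not variable.
* **Fixation classification.** Sequence-capture (SC) pools: depth < 100
  reads ⇒ `missing`; otherwise the majority allele's fraction ≥ cutoff ⇒
  `fixed_ref`/`fixed_nonref`, else `polymorphic`. Cutoff tiers 0.70 /
  0.90 / 0.99 (very loose / loose / strict). WGS pools (~4–8× coverage):
  `missing` only at zero depth; fixed only when *every* read agrees.
  Comparisons: fixation uses ≥ cutoff, so a pool at exactly the cutoff is
  fixed. Fixation at a strict cutoff implies fixation at every looser one
  (monotonicity; property-tested).
* **Low-coverage-pool guard.** One SC pool (the ESS analogue) had
  noticeably lower, more variable coverage; its call at a site is revoked
  to `missing` whenever its phenotype partner (WEI analogue) is missing
  there, so a phenotype class is never represented by the unreliable pool
  alone.

## Candidate selection (`candidates`)

A site is a trait candidate at a cutoff when the two phenotype classes of
SC pools (drop vs non-drop for ear; small vs large for mass) are each
internally fixed for one allele and the classes carry opposite alleles.
Polymorphic pools always block. Missing-pool policy: any missing pool
blocks *except* the designated low-coverage pool, tolerated when another
pool of its class is fixed — the only reading under which the
low-coverage guard has an effect; a `strict_missing` switch restores the
all-pools-must-call behaviour.

The WGS consistency filter rejects a candidate iff some phenotypically
informative WGS pool is *fixed* (all-reads rule) for the allele that
contradicts the association. Mixed-ear pools are uninformative for ear;
every WGS pool is large, hence informative for mass; the wolf pool
participates as large and prick-eared. Missing or polymorphic WGS calls
never reject.

Dog–wolf fixed differences require combined dog depth > 3000×, wolf depth
> 3×, opposite majority alleles, and ≤ 1 % discordant reads on each side.

**SNP density.** Density is interval span (kb, 1-based inclusive) divided
by SNP count. The clustering test is Fisher's exact test on the 2×2 table
[SNP bp, non-SNP bp] × [inside, outside cluster] (scipy's hypergeometric
enumeration). The table construction — bp as trials — is our choice; the
resulting p-value is descriptive, and only the density itself is treated
as a checked quantity.

## CNV depth scan (`cnvscan`)

Non-overlapping 100 bp windows. Per pool: window mean depth → *relative*
depth (window / pool-wide mean window depth, removing library size) →
*normalized* relative depth (relative / cross-pool mean per window; the
cross-pool mean is 1 by construction and asserted).

**Flag rule.** "Coverage more than two times the average" is read
leave-one-out: a pool is deviant in a window when its relative depth
exceeds 2× the mean relative depth of the *other* pools, or (symmetric
option, on by default) falls below half of it, or when it has zero raw
coverage while another pool has reads. The leave-one-out form makes the
detection ratio equal the planted fold change exactly — a fold-2.5 event
among five pools is detected (ratio 2.5) while its normalized depth is
only 2.5/1.3 ≈ 1.92, which a naive > 2.0 threshold on normalized depth
would miss. Adjacent flagged windows merge; each region is annotated with
whether the deviant pools coincide with an ear- or size-class partition
(replacing manual browser inspection). Mean (not median) pool coverage is
used for relativization.

## Across-breed GWAS (`breedgwas`)

Every sample of a breed carries the breed value: ear coded prick = 1,
intermediate = 2, drop = 3; mass is the breed-average in kg. The
association statistic is the 1-df score test χ² = n·r² (r = Pearson
correlation of dosage with trait). The exact statistic form matters
little because significance is permutation-based: breed-level trait
values are shuffled among breeds and broadcast to samples.
EMP1(snp) = (1 + #{perm: stat ≥ obs}) / (P + 1) pointwise;
EMP2 compares against each permutation's genome-wide maximum. Ties count
against significance (≥), the +1 smoothing puts the floor at 1/(P+1),
and the default P = 1000 supports a "< 0.001" genome-wide floor.

*Calibration subtlety.* With unequal breed sample sizes the sample-level
statistic is not exactly exchangeable across breed relabelings: the
pairing of trait values with breed sizes changes its distribution, so
per-SNP EMP1 is uniform only on average over pairings. The type-I-error
validation therefore uses equal samples per breed, which is also how the
synthetic generator builds its world. EMP2's genome-wide control (the
max-statistic null) is the quantity the design targets.

Kruskal–Wallis (tie-corrected, scipy) tests mass across ear classes at
breed-level units (one observation per breed; a sample-level flag
exists). Among-breed differentiation uses the unweighted Nei-style
G\_ST: F\_ST = (H\_T − H\_S)/H\_T with H\_T = 2p̄(1−p̄) over the
unweighted mean breed frequency; the scan reports SNPs with F\_ST > 0.55
and MAF > 0.15 (both strict) and their maximal consecutive runs.

## Haplotype phasing and LD (`haplotypes`)

Excoffier–Slatkin EM under random mating: a sample's unphased genotype
over L ≤ 20 biallelic SNPs defines its compatible haplotype pairs
(missing sites marginalized by enumerating both alleles); the E-step
weights pair (h₁,h₂) by 2^[h₁≠h₂]·f(h₁)·f(h₂), the M-step sets
frequencies to expected counts over 2n chromosomes. Initialization is
uniform over the haplotypes appearing in any compatible set (making the
fit deterministic); convergence when the log-likelihood gain drops below
`tol = 1e-8`; the trace is kept and its monotonicity asserted. Each
sample gets its most probable pair, ties broken lexicographically on the
haplotype codes; the assignment confidence floor defaults to 0 (assign
always) because the criterion that left some samples unassigned in
practice is not specified. Breed haplotype tables count best-guess pairs
(2 per assigned sample); haplotypes above 1.5 % overall frequency are
named, the rest pool into "Other".

LD from fitted haplotype frequencies: D = p\_AB − p\_A·p\_B;
|D′| = |D| / D\_max with D\_max = min(p\_A·p\_b, p\_a·p\_B) for D > 0 and
min(p\_A·p\_B, p\_a·p\_b) otherwise; r² = D²/(p\_A p\_a p\_B p\_b).
r² ≤ |D′| always (property-tested on fuzzed frequency vectors).

## Sweep scan (`sweepscan`)

40 kb windows by default. Heterozygosity per window is the mean of
2p(1−p) over *variable sites* using the combined-dog pool frequency
(per-bp mode behind a flag — the estimator of the source data is
inherited from prior work and unspecified). Dog–wolf F\_ST per site is
the two-population (H\_T − H\_S)/H\_T; the window value is the mean over
sites (average-of-ratios; ratio-of-averages available — the two differ on
real data). Windows without variable sites report het 0 and F\_ST NA;
negative site estimates are kept raw and also clamped. Outlier calling:
genome-wide percentiles (linear interpolation), joint flag iff het
*strictly below* the 1 % percentile AND F\_ST *strictly above* the 99 %
percentile; strictness means a constant genome flags nothing. Adjacent
flagged windows merge into maximal regions.

## Synthetic worlds (`synthdata`)

The generator states the world the sequencing design assumes: three founder
haplotypes over one region — D carrying the derived alleles of a 5′
"ear" block, S those of a 3′ "mass" block, L neither — with drop breeds
near-fixed for D, small breeds for S, large prick breeds and the wolf
for L.

* Breed haplotype-class frequencies ~ Dirichlet(drift·onehot + 0.5);
  `drift_strength = 30` gives post-bottleneck breeds ~0.95–0.99 fixed for
  their class, degenerating to exact fixation as drift → ∞ (the
  "noise-free" validation world). Background SNPs drift per breed as
  Beta(drift·π, drift·(1−π)) around ancestral π ~ U(0.05, 0.95); the
  wolf sits at π (no breed bottleneck).
* Individuals draw two haplotypes; with probability `recomb_rate = 0.005`
  a haplotype's mass-block class is resampled independently of its ear
  class, mirroring the observed rarity (< 1 %) of recombinants.
* Pools: depth ~ Poisson(pool mean; defaults match the shipped pool
  design, 1990–5182× SC,
  6–8× WGS), non-reference reads ~ Binomial(depth, f(1−e)+(1−f)e) with
  symmetric per-read error `e = 0.002`. Poisson depth and the symmetric
  flip are modelling choices — no generative model is stated for the real
  data — and both are exposed in the config. Estimated pool frequency is
  biased by e(1−2f), which the tests assert rather than correct.
* Breed mass = log-normal baseline (25 kg, σ_log = 0.08) +
  (−8 kg) × small-haplotype dosage, putting fixed-S breeds near 9 kg —
  the small-breed range of the real panel.
* CNVs are planted by deterministic count scaling (mean depth scales by
  the fold; fold 1 is the identity).

Everything derives from `SimConfig.seed` via per-operation generators:
the same config is byte-identical on rerun.

**What the generator does not emulate** — and hence what a green test
does not establish: sequence context (no reads, no mapping or
repeat-driven artifacts, the dominant cause of real CNV false flags);
linkage *within* the background SNPs (they drift independently);
overdispersed coverage (capture efficiency varies along real targets);
multi-allelic sites and indels; related breeds or within-breed structure.
Recovery results on synthetic pools bound algorithmic, not data-quality,
behaviour.

## Limitations

* The candidate filter is a hard combinatorial rule; one mislabelled pool
  phenotype produces systematic false negatives, which no test here can
  surface.
* EM phasing enumerates compatible pairs, exponential in heterozygous +
  missing sites per sample; L is capped at 20 and realistic use is ~15
  SNPs.
* EMP1 with unequal breed sizes is approximate (above); treat pointwise
  permutation p-values accordingly.
* The Fisher clustering p depends on an arbitrary bp-as-trials table and
  is reported for orientation only.
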