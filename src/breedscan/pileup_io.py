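"""Reading and writing the pipeline's text formats.

Pool sequencing data arrives as samtools 6-column pileup text (one line per
covered position: chrom, 1-based pos, reference base, depth, base-call
string, phred+33 quality string).  This module turns that into per-site
reference / non-reference read counts after base-quality filtering, and
handles the tabular side formats: a dosage-coded genotype table with a SNP
map, the breed panel table, and BED export.

Coordinates are 1-based inclusive internally; BED output converts to
0-based half-open.
"""

from __future__ import annotations

import importlib.resources
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np
import pandas as pd

_BASES = frozenset("ACGT")


class PileupParseError(ValueError):
    """Malformed pileup input; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"pileup line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class PileupSite:
    """One parsed pileup line before counting."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    base_calls: str
    base_quals: str


@dataclass
class PoolAlleleCounts:
    """Per-site read counts for one pool after quality filtering.

    ``sites`` columns: chrom, pos, ref, ref_count, nonref_count,
    nonref_base, other_count.  ``nonref_count`` tracks the dominant
    non-reference base only (biallelic assumption); additional alleles are
    accumulated in ``other_count`` and excluded from frequencies.
    """

    pool: str
    sites: pd.DataFrame
    kind: str = "SC"  # SC | WGS
    size_class: str = ""  # small | large
    ear_class: str = ""  # drop | non-drop | mix

    @property
    def depth(self) -> np.ndarray:
        return (self.sites["ref_count"] + self.sites["nonref_count"]).to_numpy()

    def frequencies(self) -> np.ndarray:
        """Non-reference allele frequency per site (NaN at zero depth)."""
        d = self.depth.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(d > 0, self.sites["nonref_count"] / d, np.nan)


def _strip_and_count(bases: str, quals: str, ref: str, min_qual: int,
                     lineno: int) -> tuple[int, dict[str, int]]:
    """Walk a pileup base string, dropping markers and low-quality bases.

    Returns (ref_count, {base: count}).  '*' (deletion placeholder) consumes
    a quality character but is counted as neither allele.
    """
    ref = ref.upper()
    ref_count = 0
    nonref: dict[str, int] = {}
    qi = 0
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # '^' + mapping-quality char, no base consumed
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(lineno, f"indel marker '{c}' without length")
            length = int(bases[i + 1:j])
            i = j + length  # inserted/deleted bases carry no quality chars
            continue
        # a real base column: consumes one quality char
        if qi >= len(quals):
            raise PileupParseError(
                lineno, "base string longer than quality string after stripping")
        q = ord(quals[qi]) - 33
        qi += 1
        i += 1
        if c == "*":
            continue  # deletion: neither ref nor nonref
        if q < min_qual:
            continue
        if c in ".,":
            ref_count += 1
        else:
            b = c.upper()
            if b in _BASES:
                if b == ref:
                    ref_count += 1
                else:
                    nonref[b] = nonref.get(b, 0) + 1
            # 'N'/'n' and anything else: ignored
    if qi != len(quals):
        raise PileupParseError(
            lineno, f"quality string length {len(quals)} does not match "
                    f"{qi} bases after stripping")
    return ref_count, nonref


def parse_pileup_line(line: str, lineno: int = 1, min_base_qual: int = 20
                      ) -> tuple[str, int, str, int, dict[str, int]]:
    """Parse one pileup line into (chrom, pos, ref, ref_count, nonref_counts)."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 6:
        raise PileupParseError(lineno, f"expected 6 columns, got {len(fields)}")
    chrom, pos_s, ref, depth_s, bases, quals = fields
    try:
        pos = int(pos_s)
    except ValueError:
        raise PileupParseError(lineno, f"non-integer position {pos_s!r}") from None
    if int(depth_s) == 0:
        return chrom, pos, ref, 0, {}
    ref_count, nonref = _strip_and_count(bases, quals, ref, min_base_qual, lineno)
    return chrom, pos, ref, ref_count, nonref


def read_pileup(stream: TextIO | str, min_base_qual: int = 20,
                pool: str = "", kind: str = "SC", size_class: str = "",
                ear_class: str = "") -> PoolAlleleCounts:
    """Read 6-column pileup text into per-site allele counts.

    Bases below ``min_base_qual`` are dropped before counting, so
    ref_count + nonref_count + other_count ≤ raw depth.  The dominant
    non-reference base at each site becomes ``nonref_count``; any remaining
    mismatching bases go to ``other_count``.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    rows = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        chrom, pos, ref, ref_count, nonref = parse_pileup_line(
            line, lineno, min_base_qual)
        if nonref:
            # deterministic tie-break: count desc, then base alphabetical
            top = sorted(nonref.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            nb, nc = top
            other = sum(nonref.values()) - nc
        else:
            nb, nc, other = "", 0, 0
        rows.append((chrom, pos, ref.upper(), ref_count, nc, nb, other))
    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "ref_count", "nonref_count",
                       "nonref_base", "other_count"])
    return PoolAlleleCounts(pool=pool, sites=sites, kind=kind,
                            size_class=size_class, ear_class=ear_class)


def write_pileup(counts: PoolAlleleCounts, stream: TextIO,
                 qual_char: str = "I") -> None:
    """Emit counts as 6-column pileup text (ref '.', nonref its base)."""
    for row in counts.sites.itertuples(index=False):
        depth = row.ref_count + row.nonref_count
        bases = "." * row.ref_count + (row.nonref_base or "A") * row.nonref_count
        quals = qual_char * depth
        stream.write(f"{row.chrom}\t{row.pos}\t{row.ref}\t{depth}\t{bases}\t{quals}\n")


# ---------------------------------------------------------------------------
# genotype table


@dataclass
class GenotypeTable:
    """Samples × SNPs dosage matrix with a SNP map and breed labels.

    ``dosages`` holds 0/1/2 counts of the alternative allele with -1 for
    missing; ``snp_map`` columns: snp, chrom, pos, ref, alt.
    """

    samples: list[str]
    breeds: list[str]
    snps: list[str]
    dosages: np.ndarray  # (n_samples, n_snps) int8, -1 = missing
    snp_map: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosages < 0

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per SNP over non-missing samples."""
        d = np.ma.masked_less(self.dosages, 0)
        return (d.mean(axis=0) / 2.0).filled(np.nan)

    def monomorphic_mask(self) -> np.ndarray:
        """SNPs with <2 distinct observed dosages (incl. all-missing)."""
        out = np.zeros(len(self.snps), dtype=bool)
        for j in range(self.dosages.shape[1]):
            col = self.dosages[:, j]
            obs = np.unique(col[col >= 0])
            out[j] = obs.size < 2
        return out


def read_genotype_table(stream: TextIO | str) -> GenotypeTable:
    """Read a TSV of sample, breed, then one dosage column per SNP.

    Dosages must be 0, 1, 2 or NA; anything else raises with the offending
    cell named.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "sample" or df.columns[1] != "breed":
        raise ValueError("genotype table must start with 'sample' and 'breed' columns")
    snps = list(df.columns[2:])
    dosages = np.empty((len(df), len(snps)), dtype=np.int8)
    for j, snp in enumerate(snps):
        for i, v in enumerate(df[snp]):
            if v in ("NA", ""):
                dosages[i, j] = -1
            elif v in ("0", "1", "2"):
                dosages[i, j] = int(v)
            else:
                raise ValueError(
                    f"invalid dosage {v!r} at sample {df['sample'][i]!r}, SNP {snp!r}")
    return GenotypeTable(samples=list(df["sample"]), breeds=list(df["breed"]),
                         snps=snps, dosages=dosages)


def write_genotype_table(gt: GenotypeTable, stream: TextIO) -> None:
    stream.write("sample\tbreed\t" + "\t".join(gt.snps) + "\n")
    for i, (s, b) in enumerate(zip(gt.samples, gt.breeds)):
        row = ["NA" if d < 0 else str(int(d)) for d in gt.dosages[i]]
        stream.write(f"{s}\t{b}\t" + "\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# breed panel and pool design


def read_breed_panel(stream: TextIO | str) -> pd.DataFrame:
    """Breed panel TSV: breed, n, ear_type, body_mass_kg."""
    df = pd.read_csv(stream, sep="\t")
    required = {"breed", "n", "ear_type", "body_mass_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"breed panel missing columns: {sorted(missing)}")
    return df


def load_breed_panel() -> pd.DataFrame:
    """The shipped 46-breed GWAS panel (breed, sample count, ear type, mass)."""
    ref = importlib.resources.files("breedscan.data") / "breed_panel.tsv"
    with ref.open() as fh:
        return read_breed_panel(fh)


def load_pool_design() -> pd.DataFrame:
    """The shipped resequencing pool design (5 SC + 6 WGS pools)."""
    ref = importlib.resources.files("breedscan.data") / "pool_design.tsv"
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# BED


def write_bed(regions: Iterable[tuple], stream: TextIO) -> None:
    """Write regions as BED (0-based half-open).

    Each region is (chrom, start, end[, name[, score]]) with start/end
    1-based inclusive; [a, b] becomes (a-1, b).
    """
    for region in regions:
        chrom, start, end = region[0], int(region[1]), int(region[2])
        if end < start:
            raise ValueError(f"region end {end} < start {start}")
        extra = "\t".join(str(x) for x in region[3:])
        line = f"{chrom}\t{start - 1}\t{end}"
        stream.write(line + ("\t" + extra if extra else "") + "\n")
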