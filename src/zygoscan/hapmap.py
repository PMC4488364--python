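"""Reading and recoding HapMap phase III genotype text files.

The format is whitespace-delimited: a header line

    rs# alleles chrom pos strand assembly# center protLSID assayLSID panelLSID QCcode <sample ids...>

followed by one row per SNP, e.g. ``rs123 A/G chr7 1500321 + ... AG GG NN``.
Genotypes are recoded to a single diallelic locus per SNP by the fixed
precedence rule A > C > G over the SNP's allele pair: the highest-precedence
allele present plays the reference role (homozygote code 2), the other
homozygote codes 0, heterozygotes code 1.  Missing calls (``NN``) code -1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

HEADER_COLUMNS = (
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
)
MISSING_TOKEN = "NN"
MISSING = -1
INVALID = -2
_PRECEDENCE = "ACG"  # first member of the pair present acts as the reference allele


class HapmapFormatError(ValueError):
    """Raised on a structurally invalid HapMap genotype file."""


@dataclass(frozen=True)
class SnpRecord:
    rsid: str
    chrom: str
    pos: int
    alleles: tuple[str, str]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1")
        a, b = self.alleles
        if a == b or not {a, b} <= set("ACGT"):
            raise ValueError(f"{self.rsid}: alleles must be two distinct bases, got {self.alleles}")


@dataclass
class GenotypeDataset:
    """Unphased genotype panel: samples x SNPs matrix of {0,1,2,-1} codes."""

    population: str
    samples: list[str]
    snps: list[SnpRecord]
    codes: np.ndarray  # int8, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.snps)):
            raise ValueError("codes matrix does not match samples x snps")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("codes must be in {0,1,2} or missing (-1)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    def restrict_snps(self, keep: Sequence[int]) -> "GenotypeDataset":
        keep = list(keep)
        return GenotypeDataset(
            population=self.population,
            samples=list(self.samples),
            snps=[self.snps[i] for i in keep],
            codes=self.codes[:, keep],
        )

    def drop_samples(self, exclude: Iterable[str]) -> "GenotypeDataset":
        """Optional sample-exclusion hook (e.g. known relatives); no default policy."""
        excl = set(exclude)
        keep = [i for i, s in enumerate(self.samples) if s not in excl]
        return GenotypeDataset(
            population=self.population,
            samples=[self.samples[i] for i in keep],
            snps=list(self.snps),
            codes=self.codes[keep, :],
        )


def reference_allele(alleles: tuple[str, str]) -> str:
    """The allele playing the recoded 'A' role, by the precedence A > C > G."""
    pair = set(alleles)
    for letter in _PRECEDENCE:
        if letter in pair:
            return letter
    raise ValueError(f"invalid allele pair {alleles}")  # pragma: no cover


def recode_biallelic(genotype: str, alleles: tuple[str, str]) -> int:
    """Recode a two-letter genotype string against a SNP's allele pair.

    Returns 2 for the reference-allele homozygote, 1 for heterozygotes,
    0 for the other homozygote, MISSING (-1) for ``NN`` and INVALID (-2)
    when a letter is outside the allele pair.  Letter order is irrelevant
    ("GA" == "AG").
    """
    if genotype == MISSING_TOKEN:
        return MISSING
    if len(genotype) != 2:
        return INVALID
    pair = set(alleles)
    if not set(genotype) <= pair:
        return INVALID
    ref = reference_allele(alleles)
    return sum(1 for letter in genotype if letter == ref)


def read_hapmap(path: str | Path, population: str | None = None,
                exclude_samples: Iterable[str] = ()) -> GenotypeDataset:
    """Parse a HapMap phase III genotype file into a coded dataset.

    Tolerates space and tab delimiters.  Rows whose genotype letters fall
    outside the declared allele pair, or that are otherwise malformed, are
    skipped and logged with their line number.  Strand is parsed but
    ignored by the recoding (the rule operates on the printed letters).
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) < len(HEADER_COLUMNS) or header[0] != "rs#":
            raise HapmapFormatError(f"{path}: missing HapMap header line")
        samples = header[len(HEADER_COLUMNS):]
        logger.info("%s: strand column parsed but ignored in recoding", path.name)
        snps: list[SnpRecord] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != len(HEADER_COLUMNS) + len(samples):
                logger.warning("%s line %d: expected %d fields, got %d; row skipped",
                               path.name, lineno, len(HEADER_COLUMNS) + len(samples), len(fields))
                continue
            rsid, allele_str, chrom, pos, strand = fields[:5]
            try:
                a, _, b = allele_str
                snp = SnpRecord(rsid=rsid, chrom=chrom, pos=int(pos),
                                alleles=(a, b), strand=strand)
            except (ValueError, TypeError) as exc:
                logger.warning("%s line %d: malformed SNP record (%s); row skipped",
                               path.name, lineno, exc)
                continue
            codes = [recode_biallelic(g, snp.alleles) for g in fields[len(HEADER_COLUMNS):]]
            if INVALID in codes:
                bad = fields[len(HEADER_COLUMNS) + codes.index(INVALID)]
                logger.warning("%s line %d: genotype %r outside alleles %s; row skipped",
                               path.name, lineno, bad, allele_str)
                continue
            snps.append(snp)
            rows.append(codes)
    codes = (np.array(rows, dtype=np.int8).T if rows
             else np.empty((len(samples), 0), dtype=np.int8))
    ds = GenotypeDataset(population=population or path.stem, samples=samples,
                         snps=snps, codes=codes)
    if exclude_samples:
        ds = ds.drop_samples(exclude_samples)
    return ds


def write_hapmap(dataset: GenotypeDataset, path: str | Path,
                 population: str | None = None) -> Path:
    """Write a coded dataset back to the HapMap genotype dialect.

    The reference (code 2) homozygote is written with the allele the
    precedence rule selects, so ``read_hapmap(write_hapmap(x))`` reproduces
    the code matrix exactly.
    """
    path = Path(path)
    pop = population or dataset.population
    with path.open("w") as fh:
        fh.write(" ".join(HEADER_COLUMNS + tuple(dataset.samples)) + "\n")
        for j, snp in enumerate(dataset.snps):
            ref = reference_allele(snp.alleles)
            alt = snp.alleles[0] if snp.alleles[1] == ref else snp.alleles[1]
            geno_by_code = {2: ref + ref, 1: ref + alt, 0: alt + alt, MISSING: MISSING_TOKEN}
            fields = [snp.rsid, f"{snp.alleles[0]}/{snp.alleles[1]}", snp.chrom,
                      str(snp.pos), snp.strand, "synthetic", pop,
                      "urn:na", "urn:na", "urn:na", "QC+"]
            fields += [geno_by_code[int(c)] for c in dataset.codes[:, j]]
            fh.write(" ".join(fields) + "\n")
    return path


def allele_frequency(codes: np.ndarray) -> float:
    """Reference-allele frequency from one SNP's codes; NaN if all missing."""
    valid = codes[codes >= 0]
    if valid.size == 0:
        return float("nan")
    return float(valid.sum() / (2 * valid.size))


def filter_maf(dataset: GenotypeDataset, threshold: float = 0.05) -> GenotypeDataset:
    """Keep SNPs with minor allele frequency >= threshold (inclusive).

    MAF is min(p, 1-p) with p estimated from non-missing codes as
    (2 n_AA + n_Aa) / (2 n_nonmissing).  SNPs with no non-missing calls
    are dropped with a warning.
    """
    if not (0 < threshold <= 0.5):
        raise ValueError("threshold must be in (0, 0.5]")
    keep = []
    for j in range(dataset.n_snps):
        p = allele_frequency(dataset.codes[:, j])
        if np.isnan(p):
            logger.warning("%s: no non-missing calls; SNP dropped", dataset.snps[j].rsid)
            continue
        if min(p, 1 - p) >= threshold:
            keep.append(j)
    return dataset.restrict_snps(keep)


def intersect_common_snps(
    datasets: Sequence[GenotypeDataset],
) -> tuple[list[str], list[GenotypeDataset]]:
    """Restrict datasets to the rs IDs shared by all of them.

    Returns the common rsids (in the first dataset's order) and each
    dataset restricted to the intersection in its own original order.
    Commutative in dataset order; an empty intersection is not an error.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to intersect")
    common = set(datasets[0].rsids)
    for ds in datasets[1:]:
        common &= set(ds.rsids)
    restricted = [
        ds.restrict_snps([i for i, r in enumerate(ds.rsids) if r in common])
        for ds in datasets
    ]
    ordered = [r for r in datasets[0].rsids if r in common]
    return ordered, restricted
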