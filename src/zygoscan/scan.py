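"""Genome-wide staged scan over syntenic SNP pairs.

For every pair of SNPs on the same chromosome within the window (default
10 Mb, boundary inclusive) the scan applies the staged protocol: (1) test
the four tracked zygotic LDs; (2) only if at least one is significant,
test the composite digenic LD with the zeroing substitutions; (3) under
the same gate, test the difference d between the composite and the maximum
zygotic LD and classify the pair (additive / epistatic / weak).  One TSV
record is emitted per pair, streamed so memory does not grow with the
number of pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO

import numpy as np
import pandas as pd

from . import ld
from ._bulk import TRACKED
from .hapmap import GenotypeDataset, SnpRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    window_bp: int = 10_000_000
    alpha: float = 1e-9
    maf_threshold: float = 0.05
    d_variance_method: str = "delta"     # "delta" | "bootstrap"
    variance_reading: str = "literal"
    n_boot: int = 2000
    seed: int = 0
    population: str = ""

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PairScanRecord:
    rsid1: str
    rsid2: str
    chrom: str
    pos1: int
    pos2: int
    n: int
    zygotic: Optional[ld.ZygoticLDSet] = None
    hwd_a: Optional[ld.HwdResult] = None
    hwd_b: Optional[ld.HwdResult] = None
    composite: Optional[ld.CompositeLDResult] = None
    difference: Optional[ld.DifferenceResult] = None
    usable: bool = True

    @property
    def distance_bp(self) -> int:
        return abs(self.pos2 - self.pos1)

    @property
    def classification(self) -> str:
        if not self.usable:
            return "unusable"
        if self.difference is None:
            return "not_tested"
        return self.difference.classification


_ZYG_COLS = [f"{s}_{g}" for g in TRACKED for s in ("D", "chi2", "r2", "p", "sig")]
COLUMNS = (
    ["rsid1", "rsid2", "chrom", "pos1", "pos2", "dist", "n"]
    + _ZYG_COLS
    + ["D_hw_A", "chi2_hw_A", "p_hw_A", "sig_hw_A",
       "D_hw_B", "chi2_hw_B", "p_hw_B", "sig_hw_B",
       "delta", "V_delta", "chi2_delta", "r2_delta", "p_delta", "sig_delta",
       "d", "max_component", "sign_case", "V_d", "chi2_d", "r2_d", "p_d",
       "class"]
)


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, bool) or isinstance(x, np.bool_):
        return "1" if x else "0"
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return "NA"
        return format(x, ".10g")
    return str(x)


def record_to_row(rec: PairScanRecord) -> list[str]:
    row = [rec.rsid1, rec.rsid2, rec.chrom, str(rec.pos1), str(rec.pos2),
           str(rec.distance_bp), str(rec.n)]
    z = rec.zygotic
    for g in TRACKED:
        if z is None:
            row += ["NA"] * 5
        else:
            row += [_fmt(z.tracked[g]), _fmt(z.chi2[g]), _fmt(z.r2[g]),
                    _fmt(z.p[g]), _fmt(z.significant[g])]
    for h in (rec.hwd_a, rec.hwd_b):
        if h is None:
            row += ["NA"] * 4
        else:
            row += [_fmt(h.D_hw), _fmt(h.chi2), _fmt(h.p), _fmt(h.significant)]
    c = rec.composite
    if c is None or not c.performed:
        row += ["NA"] * 6
    else:
        row += [_fmt(c.delta), _fmt(c.variance), _fmt(c.chi2), _fmt(c.r2_delta),
                _fmt(c.p), _fmt(c.significant)]
    d = rec.difference
    if d is None:
        row += ["NA"] * 7
    else:
        row += [_fmt(d.d), d.max_component, d.sign_case, _fmt(d.variance),
                _fmt(d.chi2), _fmt(d.r2_d), _fmt(d.p)]
    row.append(rec.classification)
    return row


def enumerate_pairs(snps: list[SnpRecord], window_bp: int) -> Iterator[tuple[int, int]]:
    """Yield index pairs of same-chromosome SNPs within the window.

    Pairs are emitted once each in deterministic (left position, right
    position) order; the window boundary is inclusive.  Input is sorted by
    (chrom, pos) internally if needed.
    """
    order = sorted(range(len(snps)), key=lambda i: (snps[i].chrom, snps[i].pos))
    if order != list(range(len(snps))):
        logger.info("SNPs not sorted by (chrom, pos); sorted internally")
    for a in range(len(order)):
        i = order[a]
        for b in range(a + 1, len(order)):
            j = order[b]
            if snps[j].chrom != snps[i].chrom:
                break
            if snps[j].pos - snps[i].pos > window_bp:
                break
            yield i, j


def scan_pair(
    codes1: np.ndarray, codes2: np.ndarray,
    snp1: SnpRecord, snp2: SnpRecord,
    config: ScanConfig, seed: Optional[int] = None,
) -> PairScanRecord:
    """Run the three-stage protocol on one SNP pair."""
    rec = PairScanRecord(rsid1=snp1.rsid, rsid2=snp2.rsid, chrom=snp1.chrom,
                         pos1=snp1.pos, pos2=snp2.pos, n=0)
    try:
        table = ld.count_two_locus(codes1, codes2)
    except ld.DegenerateTableError:
        rec.usable = False
        return rec
    rec.n = table.n
    # monomorphic after pairwise-complete exclusion -> unusable
    if (table.n_ij > 0).sum() < 2 or (table.n_kl > 0).sum() < 2:
        rec.usable = False
        return rec
    zyg = ld.zygotic_ld(table, config.alpha)
    rec.zygotic = zyg
    rec.hwd_a = ld.hwd_test(table, "A", config.alpha)
    rec.hwd_b = ld.hwd_test(table, "B", config.alpha)
    if not zyg.any_significant:
        return rec
    rec.composite = ld.composite_ld_test(
        table, zyg, rec.hwd_a, rec.hwd_b,
        alpha=config.alpha, variance_reading=config.variance_reading,
    )
    rec.difference = ld.difference_d_test(
        table, delta=rec.composite.delta, alpha=config.alpha,
        method=config.d_variance_method, n_boot=config.n_boot, seed=seed,
    )
    return rec


@dataclass
class ScanRunLog:
    n_snps: int = 0
    n_pairs: int = 0
    n_gated: int = 0          # pairs that reached stages 2-3
    n_unusable: int = 0
    classifications: dict = field(default_factory=dict)


def iter_scan(dataset: GenotypeDataset, config: ScanConfig) -> Iterator[PairScanRecord]:
    """Generate one PairScanRecord per enumerated pair."""
    for k, (i, j) in enumerate(enumerate_pairs(dataset.snps, config.window_bp)):
        pair_seed = int(np.random.SeedSequence((config.seed, k)).generate_state(1)[0] % (2**31))
        yield scan_pair(dataset.codes[:, i], dataset.codes[:, j],
                        dataset.snps[i], dataset.snps[j], config, seed=pair_seed)


def run_scan(dataset: GenotypeDataset, config: ScanConfig,
             out: str | Path | TextIO) -> ScanRunLog:
    """Scan every in-window pair and stream records to a TSV.

    Deterministic for a fixed config seed (bootstrap stages are seeded per
    pair); memory use is independent of the number of pairs.
    """
    log = ScanRunLog(n_snps=dataset.n_snps)
    close = False
    if isinstance(out, (str, Path)):
        fh = open(out, "w")
        close = True
    else:
        fh = out
    try:
        fh.write("\t".join(COLUMNS) + "\n")
        for rec in iter_scan(dataset, config):
            log.n_pairs += 1
            if not rec.usable:
                log.n_unusable += 1
            elif rec.composite is not None:
                log.n_gated += 1
            cls = rec.classification
            log.classifications[cls] = log.classifications.get(cls, 0) + 1
            fh.write("\t".join(record_to_row(rec)) + "\n")
    finally:
        if close:
            fh.close()
    logger.info("scan: %d SNPs, %d pairs, %d gated, %d unusable",
                log.n_snps, log.n_pairs, log.n_gated, log.n_unusable)
    return log


def read_scan(path: str | Path) -> pd.DataFrame:
    """Load a scan TSV with typed columns."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], low_memory=False)
    for col in df.columns:
        if col.startswith("sig_"):
            df[col] = df[col].fillna(0).astype(bool)
    return df
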