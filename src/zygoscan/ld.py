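"""Estimators and tests of zygotic, composite and difference LD on one SNP pair.

For two diallelic loci A and B scored on unphased diploids, the sufficient
statistic is the 3x3 table of two-locus genotype counts.  From it this
module estimates

* the nine zygotic LDs ``D_ijkl = P_ijkl - p_ij p_kl`` (covariances between
  one-locus genotype indicators), of which four are free — the tracked
  genotypes AABB, AABb, AaBB, AaBb — and five follow from the row/column
  constraints ``sum_i D_ijkl = sum_l D_ijkl = 0``;
* the Hardy-Weinberg disequilibrium ``D_A = p_AA - p_A^2`` per locus;
* the composite digenic LD ``Delta = 2 p_AABB + p_AABb + p_AaBB +
  p_AaBb/2 - 2 p_A p_B`` (Weir's phase-free digenic association, equal to
  the gametic LD under random mating), with its delta-method variance and
  chi-square test under the staged zeroing protocol;
* the difference statistic ``d = |Delta| - max(|D_AABB|, |D_AABb|,
  |D_AaBB|, |D_AaBb|)``, whose significantly negative values flag
  epistatic selection and significantly positive values additive effects.

All chi-square statistics carry one degree of freedom and satisfy
``chi2 = n * r2`` with the normalized statistic ``r2`` in [0, 1] for the
zygotic tests.  Individuals missing at either locus are excluded pair-wise,
so ``n`` varies across pairs of the same panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from . import _bulk
from ._bulk import TRACKED

_TRACKED_IDX = {"AABB": (0, 0), "AABb": (0, 1), "AaBB": (1, 0), "AaBb": (1, 1)}

#: genotype code for missing calls in {0,1,2,-1} coded matrices
MISSING = -1


class DegenerateTableError(ValueError):
    """Raised when a pair has no pairwise-complete individuals."""


@dataclass(frozen=True)
class TwoLocusTable:
    """3x3 genotype count table for a SNP pair; rows AA/Aa/aa, cols BB/Bb/bb."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("counts must be a nonnegative 3x3 table")
        object.__setattr__(self, "counts", c)
        if self.n == 0:
            raise DegenerateTableError("empty two-locus table")
        if self.n < 30:
            warnings.warn(
                f"n={self.n} < 30: delta-method variances may be unstable",
                UserWarning,
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def p(self) -> np.ndarray:
        """Nine class proportions."""
        return self.counts / self.n

    @property
    def n_ij(self) -> np.ndarray:
        """Locus-A genotype counts (AA, Aa, aa)."""
        return self.counts.sum(axis=1)

    @property
    def n_kl(self) -> np.ndarray:
        """Locus-B genotype counts (BB, Bb, bb)."""
        return self.counts.sum(axis=0)

    @property
    def p_A(self) -> float:
        return float(_bulk.allele_freqs(self.p)[0])

    @property
    def p_B(self) -> float:
        return float(_bulk.allele_freqs(self.p)[1])


def count_two_locus(codes1: np.ndarray, codes2: np.ndarray) -> TwoLocusTable:
    """Tally the 3x3 table from {0,1,2,missing} code vectors, pairwise-complete.

    Codes count copies of the recoded reference allele (2=AA, 1=Aa, 0=aa);
    an individual contributes only when non-missing at both loci.
    """
    c1 = np.asarray(codes1)
    c2 = np.asarray(codes2)
    if c1.shape != c2.shape:
        raise ValueError("code vectors must have equal length")
    keep = (c1 >= 0) & (c2 >= 0)
    # code 2 = AA maps to row/column 0
    rows = 2 - c1[keep]
    cols = 2 - c2[keep]
    counts = np.bincount(rows * 3 + cols, minlength=9).reshape(3, 3)
    return TwoLocusTable(counts)


@dataclass(frozen=True)
class ZygoticLDSet:
    """Nine zygotic LDs with tests for the four tracked genotypes."""

    D: np.ndarray                      # (3,3) all nine D_ijkl
    chi2: dict[str, float]             # tracked genotype -> chi-square (NaN if undefined)
    p: dict[str, float]
    r2: dict[str, float]
    significant: dict[str, bool]
    defined: dict[str, bool]
    alpha: float

    @property
    def tracked(self) -> dict[str, float]:
        return {g: float(self.D[_TRACKED_IDX[g]]) for g in TRACKED}

    @property
    def any_significant(self) -> bool:
        return any(self.significant.values())


def zygotic_ld(table: TwoLocusTable, alpha: float = 1e-9) -> ZygoticLDSet:
    """Estimate all nine zygotic LDs and chi-square test the four tracked ones.

    chi2 = n D^2 / (p_Aj(1-p_Aj) p_Bl(1-p_Bl)), 1 df; r2 = chi2/n.  A test
    whose marginal genotype frequency is 0 or 1 is flagged undefined rather
    than propagating NaN into the significance logic.
    """
    p = table.p
    d = _bulk.zygotic_d(p)
    chi2_all = _bulk.zygotic_chi2(p, table.n)
    chi2, pvals, r2, sig, defined = {}, {}, {}, {}, {}
    for g, (j, l) in _TRACKED_IDX.items():
        c = float(chi2_all[j, l])
        ok = np.isfinite(c)
        defined[g] = bool(ok)
        chi2[g] = c if ok else float("nan")
        pvals[g] = float(_chi2_dist.sf(c, 1)) if ok else float("nan")
        r2[g] = c / table.n if ok else float("nan")
        sig[g] = bool(ok and pvals[g] < alpha)
    return ZygoticLDSet(D=d, chi2=chi2, p=pvals, r2=r2, significant=sig,
                        defined=defined, alpha=alpha)


@dataclass(frozen=True)
class HwdResult:
    """Hardy-Weinberg disequilibrium test at one locus."""

    locus: str
    D_hw: float
    chi2: float
    p: float
    significant: bool
    defined: bool


def hwd_test(table: TwoLocusTable, locus: str, alpha: float = 1e-9) -> HwdResult:
    """Test D_A = p_AA - p_A^2 (or D_B) with chi2 = n D^2 / (p q)^2, 1 df."""
    if locus not in ("A", "B"):
        raise ValueError("locus must be 'A' or 'B'")
    p = table.p
    d_a, d_b = _bulk.hwd(p)
    c_a, c_b = _bulk.hwd_chi2(p, table.n)
    d, c = (float(d_a), float(c_a)) if locus == "A" else (float(d_b), float(c_b))
    defined = bool(np.isfinite(c))
    pval = float(_chi2_dist.sf(c, 1)) if defined else float("nan")
    return HwdResult(locus=locus, D_hw=d, chi2=c if defined else float("nan"),
                     p=pval, significant=bool(defined and pval < alpha),
                     defined=defined)


def composite_ld(table: TwoLocusTable) -> float:
    """Composite digenic LD by the counting definition.

    Delta = 2 p_AABB + p_AABb + p_AaBB + p_AaBb/2 - 2 p_A p_B, identically
    equal to 2 D_AABB + D_AABb + D_AaBB + D_AaBb/2.
    """
    return float(_bulk.composite_delta(table.p))


@dataclass(frozen=True)
class CompositeLDResult:
    """Composite-LD chi-square test under the staged zeroing protocol."""

    delta: float
    variance: float
    chi2: float
    p: float
    r2_delta: float
    significant: bool
    performed: bool
    r2_clipped: bool = False
    diagnostic: str = ""


def composite_ld_test(
    table: TwoLocusTable,
    zygotic: ZygoticLDSet,
    hwd_a: HwdResult,
    hwd_b: HwdResult,
    alpha: float = 1e-9,
    variance_reading: str = "literal",
) -> CompositeLDResult:
    """Test H0: Delta = 0 with the delta-method variance and zeroing protocol.

    Inside the variance, Delta is set to zero and each zygotic-LD or HWD
    term is dropped (zeroed) unless it is individually significant at
    ``alpha``.  chi2 = Delta^2 / Var(Delta-hat), 1 df; r2 = chi2/n (flagged
    if the substitutions push it above 1).  The caller is responsible for
    the gating rule (test only when >=1 zygotic LD is significant).
    """
    delta = composite_ld(table)
    dz = {g: (zygotic.tracked[g] if zygotic.significant[g] else 0.0) for g in TRACKED}
    d_a = hwd_a.D_hw if hwd_a.significant else 0.0
    d_b = hwd_b.D_hw if hwd_b.significant else 0.0
    k = float(
        _bulk.delta_variance_bracket(
            table.p_A, table.p_B, d_a, d_b,
            dz["AABB"], dz["AABb"], dz["AaBB"], dz["AaBb"],
            0.0, reading=variance_reading,
        )
    )
    var = k / table.n
    if not np.isfinite(var) or var <= 0:
        return CompositeLDResult(
            delta=delta, variance=var, chi2=float("nan"), p=float("nan"),
            r2_delta=float("nan"), significant=False, performed=False,
            diagnostic=f"nonpositive variance after substitutions (V={var!r})",
        )
    chi2 = delta**2 / var
    pval = float(_chi2_dist.sf(chi2, 1))
    r2 = chi2 / table.n
    return CompositeLDResult(
        delta=delta, variance=var, chi2=chi2, p=pval, r2_delta=r2,
        significant=pval < alpha, performed=True, r2_clipped=r2 > 1.0,
    )


@dataclass(frozen=True)
class DifferenceResult:
    """d statistic test and additive/epistatic classification."""

    d: float
    max_component: str
    max_value: float
    sign_case: str                      # "same" (6a) or "opposite" (6b)
    variance: float
    chi2: float
    p: float
    r2_d: float
    classification: str                 # additive | epistatic | weak | undefined
    method: str                         # delta | bootstrap
    tie: bool = False
    diagnostic: str = ""


def difference_d(table: TwoLocusTable, delta: Optional[float] = None) -> tuple[float, str, str]:
    """d-hat = |Delta| - max|tracked D|, the argmax genotype, and the sign case.

    The sign case is "same" when Delta and the maximal zygotic LD share a
    sign (both >= 0 or both <= 0) and "opposite" otherwise; argmax ties
    break by the fixed order AABB, AABb, AaBB, AaBb.
    """
    if delta is None:
        delta = composite_ld(table)
    dval, idx, dmax, _ = _bulk.d_statistic(table.p)
    name = TRACKED[int(idx)]
    sign_case = "same" if delta * float(dmax) >= 0 else "opposite"
    return float(dval), name, sign_case


def difference_d_test(
    table: TwoLocusTable,
    delta: Optional[float] = None,
    alpha: float = 1e-9,
    method: str = "delta",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> DifferenceResult:
    """Test H0: d = 0 and classify the pair.

    Var(d-hat) comes from the plug-in multinomial delta method by default
    (gradient of d in the nine class proportions at the observed table); a
    tie in the argmax makes d non-differentiable and triggers the
    nonparametric bootstrap fallback, as does ``method='bootstrap'``.
    chi2 = d^2 / Var, 1 df; r2_d = chi2/n.  Classification: additive when
    d > 0 and p < alpha, epistatic when d < 0 and p < alpha, else weak.
    The caller enforces the gating rule.
    """
    if delta is None:
        delta = composite_ld(table)
    dval, name, sign_case = difference_d(table, delta)
    dmax = float(zygotic_ld(table, alpha).tracked[name])
    var_delta, tie = _bulk.d_variance_delta(table.p, table.n)
    tie = bool(tie)
    used = method
    diagnostic = ""
    if method == "delta" and tie:
        used = "bootstrap"
        diagnostic = "argmax tie: delta method non-differentiable, bootstrap fallback"
    elif method == "delta" and not (np.isfinite(var_delta) and var_delta > 0):
        # zero/invalid gradient variance (e.g. statistic at a stationary
        # point of the class proportions): resampling still measures spread
        used = "bootstrap"
        diagnostic = "degenerate delta-method variance, bootstrap fallback"
    if used == "bootstrap":
        var = bootstrap_variance(table, "d", B=n_boot, seed=seed if seed is not None else 0)
    elif used == "delta":
        var = float(var_delta)
    else:
        raise ValueError(f"unknown variance method {method!r}")
    if not np.isfinite(var) or var <= 0:
        return DifferenceResult(
            d=dval, max_component=name, max_value=dmax, sign_case=sign_case,
            variance=var, chi2=float("nan"), p=float("nan"), r2_d=float("nan"),
            classification="undefined", method=used, tie=tie,
            diagnostic=diagnostic or f"nonpositive variance (V={var!r})",
        )
    chi2 = dval**2 / var
    pval = float(_chi2_dist.sf(chi2, 1))
    if pval < alpha and dval > 0:
        cls = "additive"
    elif pval < alpha and dval < 0:
        cls = "epistatic"
    else:
        cls = "weak"
    return DifferenceResult(
        d=dval, max_component=name, max_value=dmax, sign_case=sign_case,
        variance=var, chi2=chi2, p=pval, r2_d=chi2 / table.n,
        classification=cls, method=used, tie=tie, diagnostic=diagnostic,
    )


_BOOT_STATS = {"delta", "d"} | set(TRACKED)


def bootstrap_variance(table: TwoLocusTable, statistic: str, B: int = 2000,
                       seed: int = 0) -> float:
    """Nonparametric bootstrap variance of a pair statistic.

    Resamples n individuals with replacement from the empirical nine-class
    distribution B times and returns the variance of the statistic across
    resamples.  ``statistic`` is one of 'delta', 'd', or a tracked genotype
    name for its zygotic LD.  A single-class (degenerate) table has
    variance 0 for every statistic.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if statistic not in _BOOT_STATS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if (table.counts > 0).sum() == 1:
        return 0.0
    rng = np.random.default_rng(seed)
    boots = _bulk.bootstrap_tables(table.counts, B, rng)
    p, _ = _bulk.proportions(boots)
    if statistic == "delta":
        vals = _bulk.composite_delta(p)
    elif statistic == "d":
        vals = _bulk.d_statistic(p)[0]
    else:
        j, l = _TRACKED_IDX[statistic]
        vals = _bulk.zygotic_d(p)[:, j, l]
    return float(np.var(vals, ddof=1))
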