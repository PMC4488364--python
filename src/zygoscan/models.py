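"""Two-locus genotype models and synthetic chromosome simulation.

A :class:`TwoLocusModel` holds the nine true unphased genotype
probabilities ``P_ijkl`` for a SNP pair, from which every population
quantity downstream estimates — zygotic LDs, HWD, the composite digenic LD
— is defined exactly.  Models are built either from four free zygotic LDs
plus one-locus genotype frequencies (the remaining five LDs follow from the
row/column constraints) or from haplotype frequencies under random union of
gametes, in which case the composite LD equals the gametic LD.

Scenario constructors emulate the qualitative regimes a genome scan must
distinguish: independent loci (null), gametic coupling (additive signal),
double-homozygote excess (drift/inbreeding-like), admixture-induced
association, and double-heterozygote excess with near-zero composite LD
(the epistatic-selection signature).

:func:`simulate_chromosome` draws a whole panel of unphased genotypes:
background SNPs are mutually independent at Hardy-Weinberg proportions and
only declared scenario pairs carry LD, which makes null rejection-rate
suites exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .hapmap import GenotypeDataset, SnpRecord
from .ld import TwoLocusTable
from . import _bulk

_SIMPLEX_TOL = 1e-12
CLASS_ORDER = ("AABB", "AABb", "AAbb", "AaBB", "AaBb", "Aabb", "aaBB", "aaBb", "aabb")
SCENARIOS = ("null", "coupling", "drift_homozygote", "admixture",
             "epistatic_heterozygote", "custom")


class InfeasibleModelError(ValueError):
    """Raised when requested disequilibria imply a probability outside [0,1]."""


@dataclass(frozen=True)
class TwoLocusModel:
    """Nine true genotype probabilities for a SNP pair (rows AA/Aa/aa, cols BB/Bb/bb)."""

    probs: np.ndarray
    scenario: str = "custom"
    true_gametic_ld: Optional[float] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float).reshape(3, 3)
        if (p < -_SIMPLEX_TOL).any() or abs(p.sum() - 1.0) > _SIMPLEX_TOL:
            raise InfeasibleModelError("probabilities must be nonnegative and sum to 1")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        object.__setattr__(self, "probs", np.clip(p, 0.0, 1.0))

    @property
    def zygotic_lds(self) -> np.ndarray:
        """All nine true D_ijkl."""
        return _bulk.zygotic_d(self.probs)

    @property
    def delta(self) -> float:
        """True composite digenic LD."""
        return float(_bulk.composite_delta(self.probs))

    @property
    def allele_freqs(self) -> tuple[float, float]:
        pa, pb = _bulk.allele_freqs(self.probs)
        return float(pa), float(pb)


def model_from_zygotic_lds(
    p_AA: float, p_Aa: float, p_BB: float, p_Bb: float,
    D_AABB: float, D_AABb: float, D_AaBB: float, D_AaBb: float,
    scenario: str = "custom",
) -> TwoLocusModel:
    """Build a model from one-locus genotype frequencies and four zygotic LDs.

    The five untracked LDs follow from sum-to-zero constraints across rows
    and columns; P_ijkl = p_ij p_kl + D_ijkl must all land in [0,1].
    """
    p_aa, p_bb = 1 - p_AA - p_Aa, 1 - p_BB - p_Bb
    for name, v in (("p_AA", p_AA), ("p_Aa", p_Aa), ("p_aa", p_aa),
                    ("p_BB", p_BB), ("p_Bb", p_Bb), ("p_bb", p_bb)):
        if not -_SIMPLEX_TOL <= v <= 1 + _SIMPLEX_TOL:
            raise InfeasibleModelError(f"marginal {name}={v} outside [0,1]")
    d = np.empty((3, 3))
    d[0, 0], d[0, 1], d[1, 0], d[1, 1] = D_AABB, D_AABb, D_AaBB, D_AaBb
    d[0, 2] = -(d[0, 0] + d[0, 1])
    d[1, 2] = -(d[1, 0] + d[1, 1])
    d[2, :] = -(d[0, :] + d[1, :])
    probs = np.outer([p_AA, p_Aa, p_aa], [p_BB, p_Bb, p_bb]) + d
    if (probs < -_SIMPLEX_TOL).any() or (probs > 1 + _SIMPLEX_TOL).any():
        raise InfeasibleModelError(
            f"implied genotype probabilities outside [0,1]: {probs.round(6).tolist()}"
        )
    return TwoLocusModel(probs=np.clip(probs, 0, 1), scenario=scenario)


def model_from_haplotypes(p_A: float, p_B: float, D_AB: float,
                          scenario: str = "coupling") -> TwoLocusModel:
    """Build a model by random union of gametes from haplotype frequencies.

    Haplotype frequencies are p_AB = p_A p_B + D_AB etc.; the resulting
    marginals sit at Hardy-Weinberg proportions and the model's composite
    LD equals D_AB exactly.
    """
    hap = {
        "AB": p_A * p_B + D_AB,
        "Ab": p_A * (1 - p_B) - D_AB,
        "aB": (1 - p_A) * p_B - D_AB,
        "ab": (1 - p_A) * (1 - p_B) + D_AB,
    }
    for name, f in hap.items():
        if not -_SIMPLEX_TOL <= f <= 1 + _SIMPLEX_TOL:
            raise InfeasibleModelError(
                f"D_AB={D_AB} outside the Lewontin bounds: haplotype {name} frequency {f}"
            )
    probs = np.zeros((3, 3))
    names = list(hap)
    for h1 in names:
        for h2 in names:
            i = (h1[0] == "a") + (h2[0] == "a")   # copies of 'a' -> row 0=AA,1=Aa,2=aa
            k = (h1[1] == "b") + (h2[1] == "b")
            probs[i, k] += hap[h1] * hap[h2]
    return TwoLocusModel(probs=probs, scenario=scenario, true_gametic_ld=float(D_AB))


def null_model(p_A: float = 0.3, p_B: float = 0.3) -> TwoLocusModel:
    """Independent loci at Hardy-Weinberg proportions."""
    m = model_from_haplotypes(p_A, p_B, 0.0)
    return TwoLocusModel(probs=m.probs, scenario="null", true_gametic_ld=0.0)


def drift_homozygote_model(p_A: float = 0.5, p_B: float = 0.5,
                           excess: float = 0.1) -> TwoLocusModel:
    """Double-homozygote excess, the drift/bottleneck-like regime.

    Mass ``excess`` moves onto the coupling double homozygotes AABB/aabb,
    away from independence, yielding positive D_AABB and positive Delta.
    """
    base = null_model(p_A, p_B).probs.copy()
    take = base * excess
    probs = base - take
    shifted = take.sum()
    probs[0, 0] += shifted / 2
    probs[2, 2] += shifted / 2
    return TwoLocusModel(probs=probs, scenario="drift_homozygote")


def admixture_model(p_A1: float = 0.2, p_B1: float = 0.2,
                    p_A2: float = 0.8, p_B2: float = 0.8,
                    weight: float = 0.5) -> TwoLocusModel:
    """Mixture of two internally-equilibrium subpopulations (Wahlund-type LD)."""
    m1 = null_model(p_A1, p_B1).probs
    m2 = null_model(p_A2, p_B2).probs
    return TwoLocusModel(probs=weight * m1 + (1 - weight) * m2, scenario="admixture")


def epistatic_heterozygote_model(p_homo: float = 0.2, d_het: float = 0.24) -> TwoLocusModel:
    """Double-heterozygote excess with composite LD held at zero.

    The signature of epistatic selection favouring the double heterozygote:
    D_AaBb = ``d_het`` > 0 while Delta = 2 D_AABB + D_AABb + D_AaBB +
    D_AaBb/2 = 0, arranged by D_AABB = d_het/4, D_AABb = D_AaBB = -d_het/2.
    Defaults give the nine-class table with P_AaBb = 0.6 and corner
    homozygotes at 0.1 each.
    """
    p_het = 1 - 2 * p_homo
    m = model_from_zygotic_lds(
        p_AA=p_homo, p_Aa=p_het, p_BB=p_homo, p_Bb=p_het,
        D_AABB=d_het / 4, D_AABb=-d_het / 2, D_AaBB=-d_het / 2, D_AaBb=d_het,
    )
    return TwoLocusModel(probs=m.probs, scenario="epistatic_heterozygote")


def scenario_model(name: str, rng: Optional[np.random.Generator] = None) -> TwoLocusModel:
    """A representative model for a named scenario (fixed defaults)."""
    if name == "null":
        return null_model()
    if name == "coupling":
        return model_from_haplotypes(0.5, 0.5, 0.2)
    if name == "drift_homozygote":
        return drift_homozygote_model()
    if name == "admixture":
        return admixture_model()
    if name == "epistatic_heterozygote":
        return epistatic_heterozygote_model()
    raise ValueError(f"unknown scenario {name!r}")


def d_method_validation_models() -> list[TwoLocusModel]:
    """LD-carrying models on which the d-test delta-method variance is valid.

    The plug-in delta method linearizes d = |Delta| - max|D| at the observed
    table, so it requires local smoothness: |Delta| bounded away from 0 and
    the top two |D| components separated by at least ~3 sampling SEs at the
    working sample size (n ~ 1000).  These models — coupling, admixture and
    drift-like regimes with argmax gaps >= 0.03 — satisfy that condition;
    they are also the regimes in which the staged protocol's zygotic gate
    actually admits pairs.  Near a fold (Delta ~ 0, as in the epistatic
    signature model) or an argmax tie, the bootstrap is the appropriate
    variance estimator instead.
    """
    return [
        model_from_haplotypes(0.3, 0.3, 0.15),
        model_from_haplotypes(0.25, 0.4, 0.12),
        admixture_model(),
        admixture_model(p_A1=0.1, p_B1=0.3, p_A2=0.9, p_B2=0.7),
        admixture_model(p_A1=0.3, p_B1=0.2, p_A2=0.7, p_B2=0.9, weight=0.4),
        drift_homozygote_model(excess=0.3),
        drift_homozygote_model(p_A=0.4, p_B=0.4, excess=0.35),
        drift_homozygote_model(p_A=0.45, p_B=0.55, excess=0.4),
    ]


def sample_pair(model: TwoLocusModel, n: int,
                seed: int | np.random.Generator = 0) -> TwoLocusTable:
    """Draw n individuals from the nine-class multinomial of a model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(n, model.probs.reshape(9)).reshape(3, 3)
    return TwoLocusTable(counts)


@dataclass(frozen=True)
class SyntheticChromosomeSpec:
    """Recipe for one simulated chromosome of unphased genotypes."""

    n_snps: int
    chrom_length: int = 50_000_000
    n_individuals: int = 100
    allele_freq_range: tuple[float, float] = (0.1, 0.5)
    pair_scenarios: Sequence[tuple[tuple[int, int], TwoLocusModel]] = field(default_factory=tuple)
    seed: int = 0
    missing_rate: float = 0.0
    chrom: str = "chr1"
    population: str = "SIM"

    def __post_init__(self) -> None:
        if self.n_snps > self.chrom_length:
            raise ValueError("more SNPs than distinct positions on the chromosome")
        lo, hi = self.allele_freq_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("allele_freq_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        used = set()
        for (i, j), _model in self.pair_scenarios:
            if not (0 <= i < self.n_snps and 0 <= j < self.n_snps) or i == j:
                raise ValueError(f"invalid scenario pair indices ({i}, {j})")
            if i in used or j in used:
                raise ValueError("scenario pairs must not share SNP indices")
            used.update((i, j))


_ALLELE_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))


def simulate_chromosome(spec: SyntheticChromosomeSpec) -> GenotypeDataset:
    """Simulate one chromosome of unphased genotype codes.

    Background SNPs are independent with Hardy-Weinberg genotype
    proportions at a MAF drawn uniformly from ``allele_freq_range``;
    declared scenario pairs are overwritten with joint draws from their
    models.  Positions are strictly increasing in [1, chrom_length] and the
    draw is fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    positions = np.sort(rng.choice(spec.chrom_length, size=spec.n_snps, replace=False)) + 1
    mafs = rng.uniform(*spec.allele_freq_range, size=spec.n_snps)
    # background: independent HWE draws, codes = copies of the reference allele
    codes = rng.binomial(2, mafs[None, :], size=(spec.n_individuals, spec.n_snps)).astype(np.int8)
    for (i, j), model in spec.pair_scenarios:
        classes = rng.choice(9, size=spec.n_individuals, p=model.probs.reshape(9))
        codes[:, i] = 2 - classes // 3   # row 0 = AA -> code 2
        codes[:, j] = 2 - classes % 3
    if spec.missing_rate > 0:
        mask = rng.random(codes.shape) < spec.missing_rate
        codes[mask] = -1
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=spec.n_snps)
    snps = [
        SnpRecord(rsid=f"rs{k + 1:06d}", chrom=spec.chrom, pos=int(positions[k]),
                  alleles=_ALLELE_PAIRS[pair_idx[k]])
        for k in range(spec.n_snps)
    ]
    samples = [f"{spec.population}{s + 1:04d}" for s in range(spec.n_individuals)]
    return GenotypeDataset(population=spec.population, samples=samples,
                           snps=snps, codes=codes)
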