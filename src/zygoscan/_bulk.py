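"""Vectorized kernels over batches of 3x3 two-locus genotype tables.

Every function accepts an array of shape ``(..., 3, 3)`` holding either
counts or class proportions for the nine unphased two-locus genotype
classes.  Rows index the locus-A genotype (0=AA, 1=Aa, 2=aa), columns the
locus-B genotype (0=BB, 1=Bb, 2=bb).  These kernels back both the scalar
per-pair API in :mod:`zygoscan.ld` and the Monte-Carlo / bootstrap suites,
so they avoid Python-level loops entirely.
"""

from __future__ import annotations

import numpy as np

# d(p_A)/d(P_g) and d(p_B)/d(P_g), flattened row-major over the 9 classes
_GRAD_PA = np.array([1, 1, 1, 0.5, 0.5, 0.5, 0, 0, 0])
_GRAD_PB = np.array([1, 0.5, 0, 1, 0.5, 0, 1, 0.5, 0])
# counting-formula weights: Delta = 2P_AABB + P_AABb + P_AaBB + P_AaBb/2 - 2 p_A p_B
_DELTA_W = np.array([2, 1, 0, 1, 0.5, 0, 0, 0, 0])

#: fixed genotype order used for the four tracked zygotic LDs and argmax ties
TRACKED = ("AABB", "AABb", "AaBB", "AaBb")
_TRACKED_IDX = ((0, 0), (0, 1), (1, 0), (1, 1))


def proportions(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (class proportions, n) for count tables."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=(-1, -2))
    return counts / n[..., None, None], n


def genotype_marginals(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-locus genotype frequencies: rows (locus A) and columns (locus B)."""
    return p.sum(axis=-1), p.sum(axis=-2)


def allele_freqs(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Allele frequencies p_A, p_B by gene counting from genotype classes."""
    row, col = genotype_marginals(p)
    return row[..., 0] + row[..., 1] / 2, col[..., 0] + col[..., 1] / 2


def zygotic_d(p: np.ndarray) -> np.ndarray:
    """All nine zygotic LDs D_ijkl = P_ijkl - p_ij * p_kl, shape (..., 3, 3)."""
    row, col = genotype_marginals(p)
    return p - row[..., :, None] * col[..., None, :]


def hwd(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hardy-Weinberg disequilibria D_A = p_AA - p_A^2 and D_B at both loci."""
    row, col = genotype_marginals(p)
    p_a, p_b = allele_freqs(p)
    return row[..., 0] - p_a**2, col[..., 0] - p_b**2


def composite_delta(p: np.ndarray) -> np.ndarray:
    """Composite digenic LD by the counting definition."""
    p_a, p_b = allele_freqs(p)
    flat = p.reshape(p.shape[:-2] + (9,))
    return flat @ _DELTA_W - 2 * p_a * p_b


def zygotic_chi2(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Chi-square (1 df) for each of the nine zygotic LDs.

    chi2_ijkl = n * D^2 / (p_ij (1 - p_ij) p_kl (1 - p_kl)); entries whose
    marginal genotype frequency is 0 or 1 are NaN (test undefined).
    """
    row, col = genotype_marginals(p)
    d = zygotic_d(p)
    denom = (row * (1 - row))[..., :, None] * (col * (1 - col))[..., None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.asarray(n)[..., None, None] * d**2 / denom
    return np.where(denom > 0, chi2, np.nan)


def hwd_chi2(p: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """HWD chi-square (1 df) per locus: n * D_hw^2 / (p q)^2; NaN if monomorphic."""
    d_a, d_b = hwd(p)
    p_a, p_b = allele_freqs(p)
    out = []
    for d, q in ((d_a, p_a), (d_b, p_b)):
        denom = (q * (1 - q)) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.asarray(n) * d**2 / denom
        out.append(np.where(denom > 0, chi2, np.nan))
    return out[0], out[1]


def delta_variance_bracket(
    p_a: np.ndarray,
    p_b: np.ndarray,
    d_a: np.ndarray,
    d_b: np.ndarray,
    d_aabb: np.ndarray,
    d_aabb_het: np.ndarray,
    d_het_aabb: np.ndarray,
    d_aabb_double_het: np.ndarray,
    delta: np.ndarray,
    reading: str = "literal",
) -> np.ndarray:
    """n * Var(Delta-hat) as a function of its component disequilibria.

    Arguments follow the tracked genotype order: ``d_aabb`` = D_AABB,
    ``d_aabb_het`` = D_AABb, ``d_het_aabb`` = D_AaBB,
    ``d_aabb_double_het`` = D_AaBb.  ``reading`` selects how the printed
    term "2 D_AABB - D_AaBb / 4" is parenthesized: the default ``literal``
    reading ``2*D_AABB - D_AaBb/4`` reproduces the exact first-order
    delta-method variance; ``quarter`` applies the /4 to both terms.
    """
    if reading == "literal":
        extra = 2 * d_aabb - d_aabb_double_het / 4
    elif reading == "quarter":
        extra = (2 * d_aabb - d_aabb_double_het) / 4
    else:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown variance reading: {reading!r}")
    return (
        delta * (1 - delta - 2 * (p_a + p_b - 4 * p_a * p_b))
        + (p_a * (1 - p_a) + d_a) * (p_b * (1 - p_b) + d_b)
        + extra
        - 4 * p_a * (d_aabb + d_het_aabb / 2)
        - 4 * p_b * (d_aabb + d_aabb_het / 2)
    )


def composite_variance_truth(p: np.ndarray, n: np.ndarray, reading: str = "literal") -> np.ndarray:
    """Var(Delta-hat) evaluated at a table/model with no zeroing substitutions."""
    p_a, p_b = allele_freqs(p)
    d_a, d_b = hwd(p)
    d = zygotic_d(p)
    k = delta_variance_bracket(
        p_a, p_b, d_a, d_b,
        d[..., 0, 0], d[..., 0, 1], d[..., 1, 0], d[..., 1, 1],
        composite_delta(p), reading=reading,
    )
    return k / np.asarray(n)


def composite_chi2_protocol(
    counts: np.ndarray, alpha: float, reading: str = "literal"
) -> tuple[np.ndarray, np.ndarray]:
    """Composite-LD chi-square with the staged zeroing protocol, vectorized.

    Delta is set to zero inside the variance; zygotic LD and HWD terms are
    zeroed unless individually significant at ``alpha``.  Returns
    (chi2, variance); entries with a nonpositive variance are NaN.
    """
    from scipy.stats import chi2 as chi2_dist

    p, n = proportions(counts)
    crit = chi2_dist.isf(alpha, 1)
    zc = zygotic_chi2(p, n)
    d = zygotic_d(p)
    dz = np.where(np.nan_to_num(zc) > crit, d, 0.0)
    d_a, d_b = hwd(p)
    hc_a, hc_b = hwd_chi2(p, n)
    d_a = np.where(np.nan_to_num(hc_a) > crit, d_a, 0.0)
    d_b = np.where(np.nan_to_num(hc_b) > crit, d_b, 0.0)
    p_a, p_b = allele_freqs(p)
    delta = composite_delta(p)
    k = delta_variance_bracket(
        p_a, p_b, d_a, d_b,
        dz[..., 0, 0], dz[..., 0, 1], dz[..., 1, 0], dz[..., 1, 1],
        np.zeros_like(delta), reading=reading,
    )
    var = k / n
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = delta**2 / var
    return np.where(var > 0, chi2, np.nan), var


def _delta_gradient(p_flat: np.ndarray) -> np.ndarray:
    """Gradient of the counting-formula Delta in the nine class proportions."""
    p_a = p_flat @ _GRAD_PA
    p_b = p_flat @ _GRAD_PB
    return (
        _DELTA_W
        - 2 * (p_b[..., None] * _GRAD_PA + p_a[..., None] * _GRAD_PB)
    )


def _zygotic_gradient(p: np.ndarray, j: int, l: int) -> np.ndarray:
    """Gradient of D_jl (tracked genotype row j, col l) in the nine proportions."""
    row, col = genotype_marginals(p)
    shape = p.shape[:-2] + (3, 3)
    g = np.zeros(shape)
    g[..., j, l] += 1.0
    g[..., j, :] -= col[..., l, None]
    g[..., :, l] -= row[..., j, None]
    return g.reshape(p.shape[:-2] + (9,))


def d_statistic(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """d-hat = |Delta| - max|D| over the four tracked zygotic LDs.

    Returns (d, argmax index into TRACKED, max component value, Delta).
    Ties in the argmax resolve to the first genotype in TRACKED order.
    """
    delta = composite_delta(p)
    d = zygotic_d(p)
    four = np.stack([d[..., j, l] for j, l in _TRACKED_IDX], axis=-1)
    idx = np.argmax(np.abs(four), axis=-1)
    dmax = np.take_along_axis(four, idx[..., None], axis=-1)[..., 0]
    return np.abs(delta) - np.abs(dmax), idx, dmax, delta


def multinomial_quadratic_variance(p_flat: np.ndarray, c: np.ndarray, n: np.ndarray) -> np.ndarray:
    """First-order variance (1/n)(sum p c^2 - (sum p c)^2) of a statistic
    with gradient ``c`` under multinomial sampling of the nine classes."""
    s1 = np.sum(p_flat * c, axis=-1)
    s2 = np.sum(p_flat * c**2, axis=-1)
    return (s2 - s1**2) / np.asarray(n)


def d_variance_delta(p: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plug-in delta-method Var(d-hat) via the exact multinomial covariance.

    The gradient of d = sign(Delta)*Delta - sign(D_m)*D_m is evaluated at the
    observed proportions, treating the argmax component m as locally fixed.
    Returns (variance, tie flag); a tie in max|D| (within 1e-12) marks the
    statistic non-differentiable and the caller should fall back to the
    bootstrap.
    """
    p = np.asarray(p, dtype=float)
    p_flat = p.reshape(p.shape[:-2] + (9,))
    dval, idx, dmax, delta = d_statistic(p)
    dz = zygotic_d(p)
    four = np.stack([np.abs(dz[..., j, l]) for j, l in _TRACKED_IDX], axis=-1)
    sorted_abs = np.sort(four, axis=-1)
    tie = (sorted_abs[..., -1] - sorted_abs[..., -2]) < 1e-12 if four.shape[-1] > 1 else np.zeros_like(dval, bool)

    grads = np.stack([_zygotic_gradient(p, j, l) for j, l in _TRACKED_IDX], axis=-2)
    gm = np.take_along_axis(grads, idx[..., None, None], axis=-2)[..., 0, :]
    c = np.sign(delta)[..., None] * _delta_gradient(p_flat) - np.sign(dmax)[..., None] * gm
    return multinomial_quadratic_variance(p_flat, c, n), tie


def bootstrap_tables(
    counts: np.ndarray, b: int, rng: np.random.Generator
) -> np.ndarray:
    """B nonparametric resamples of a single table: multinomial(n, p-hat)."""
    counts = np.asarray(counts)
    n = int(counts.sum())
    p = (counts / n).reshape(9)
    return rng.multinomial(n, p, size=b).reshape(b, 3, 3)
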