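"""Aggregation of scan tables into population-level summaries.

Per population the scan yields seven categories of significant signals —
the four tracked zygotic LDs, the composite LD, and the two tails of the
difference statistic (d>0 additive, d<0 epistatic).  This module computes
their counts, mean +/- SD of the normalized r-square, physical-distance
statistics, and the Pearson correlation between significant r-square and
physical distance; builds the 20-dimensional feature vector (five
categories x four statistics, d tails excluded) used to compare
populations; intersects epistatic pair sets across populations; and
clusters populations by Canberra distance with feature-bootstrap support
values on an average-linkage dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

#: summary categories and the scan-table columns backing them
CATEGORIES = ("AABB", "AABb", "AaBB", "AaBb", "delta", "d_pos", "d_neg")
#: categories entering the 20-dimensional population feature vector
FEATURE_CATEGORIES = ("AABB", "AABb", "AaBB", "AaBb", "delta")
#: per-category statistics in the feature vector, in order
FEATURE_STATS = ("count", "mean_r2", "mean_dist_mb", "dist_correlation")


@dataclass(frozen=True)
class CategoryStats:
    count: int
    mean_r2: float = float("nan")
    sd_r2: float = float("nan")
    mean_dist_mb: float = float("nan")
    cv_dist: float = float("nan")
    dist_correlation: float = float("nan")
    dist_correlation_p: float = float("nan")
    correlation_defined: bool = False


@dataclass(frozen=True)
class PopulationSummary:
    population: str
    categories: dict[str, CategoryStats]

    def __getitem__(self, cat: str) -> CategoryStats:
        return self.categories[cat]


def _category_records(df: pd.DataFrame, category: str) -> tuple[pd.Series, pd.Series]:
    """(r2 values, distances in Mb) of the significant records of a category."""
    if category in ("AABB", "AABb", "AaBB", "AaBb"):
        mask = df[f"sig_{category}"].astype(bool)
        r2 = df.loc[mask, f"r2_{category}"]
    elif category == "delta":
        mask = df["sig_delta"].astype(bool) if "sig_delta" in df else pd.Series(False, index=df.index)
        r2 = df.loc[mask, "r2_delta"]
    elif category == "d_pos":
        mask = df["class"] == "additive"
        r2 = df.loc[mask, "r2_d"]
    elif category == "d_neg":
        mask = df["class"] == "epistatic"
        r2 = df.loc[mask, "r2_d"]
    else:
        raise ValueError(f"unknown category {category!r}")
    return r2.astype(float), df.loc[mask, "dist"].astype(float) / 1e6


def correlate_r2_distance(r2: Sequence[float], dist: Sequence[float]) -> tuple[float, float, bool]:
    """Pearson correlation of significant r-square with physical distance.

    Returns (r, two-sided p, defined).  Undefined (flagged) with fewer than
    3 records or zero variance in either variable.
    """
    r2 = np.asarray(r2, dtype=float)
    dist = np.asarray(dist, dtype=float)
    if r2.size < 3 or np.std(r2) == 0 or np.std(dist) == 0:
        return float("nan"), float("nan"), False
    r, p = pearsonr(r2, dist)
    return float(r), float(p), True


def summarize_scan(df: pd.DataFrame, population: str = "") -> PopulationSummary:
    """Per-category counts, r-square and distance statistics of a scan table.

    Only significant records contribute; distances are reported in Mb and
    their dispersion as the coefficient of variation SD/mean.  Categories
    with no significant records carry count 0 and absent statistics.
    """
    if df.empty:
        raise ValueError("empty scan table")
    cats: dict[str, CategoryStats] = {}
    for cat in CATEGORIES:
        r2, dist = _category_records(df, cat)
        count = int(len(r2))
        if count == 0:
            cats[cat] = CategoryStats(count=0)
            continue
        mean_dist = float(dist.mean())
        cv = float(dist.std(ddof=1) / mean_dist) if count > 1 and mean_dist > 0 else float("nan")
        r, p, ok = correlate_r2_distance(r2, dist)
        cats[cat] = CategoryStats(
            count=count,
            mean_r2=float(r2.mean()),
            sd_r2=float(r2.std(ddof=1)) if count > 1 else 0.0,
            mean_dist_mb=mean_dist,
            cv_dist=cv,
            dist_correlation=r,
            dist_correlation_p=p,
            correlation_defined=ok,
        )
    return PopulationSummary(population=population, categories=cats)


def feature_vector(summary: PopulationSummary) -> np.ndarray:
    """20-dimensional population feature vector, category-major.

    For each of AABB, AABb, AaBB, AaBb, delta (d tails excluded):
    [significant count, mean r2, mean distance (Mb), distance correlation].
    Raises if any cell is absent — the vector must be complete.
    """
    out = []
    for cat in FEATURE_CATEGORIES:
        st = summary[cat]
        for stat in FEATURE_STATS:
            v = float(getattr(st, stat))
            if np.isnan(v):
                raise ValueError(
                    f"population {summary.population!r}: missing {stat} for category {cat}"
                )
            out.append(v)
    return np.asarray(out)


def intersect_epistatic_pairs(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """SNP pairs classified epistatic (significant d<0) in every population.

    Pairs are keyed by the sorted rsid pair, so the result is commutative
    in table order and idempotent on repeats; for each common pair the mean
    and SD of d and r2_d across populations are reported.
    """
    if len(tables) < 2:
        raise ValueError("need at least two scan tables")
    keyed: list[dict[tuple, tuple[float, float]]] = []
    for df in tables:
        epi = df[df["class"] == "epistatic"]
        table = {}
        for rs1, rs2, dval, r2val in zip(epi["rsid1"], epi["rsid2"],
                                         epi["d"], epi["r2_d"]):
            table.setdefault(tuple(sorted((rs1, rs2))), (float(dval), float(r2val)))
        keyed.append(table)
    common = set(keyed[0])
    for k in keyed[1:]:
        common &= set(k)
    rows = []
    for pair in sorted(common):
        d = np.array([k[pair][0] for k in keyed])
        r2 = np.array([k[pair][1] for k in keyed])
        rows.append({
            "rsid1": pair[0], "rsid2": pair[1], "n_populations": len(keyed),
            "mean_d": d.mean(), "sd_d": d.std(ddof=1),
            "mean_r2_d": r2.mean(), "sd_r2_d": r2.std(ddof=1),
        })
    cols = ["rsid1", "rsid2", "n_populations", "mean_d", "sd_d", "mean_r2_d", "sd_r2_d"]
    return pd.DataFrame(rows, columns=cols)


def canberra_distance_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise Canberra distances: sum_k |x_k - y_k| / (|x_k| + |y_k|),
    with terms where both coordinates are zero contributing 0."""
    return squareform(pdist(np.asarray(vectors, float), metric="canberra"))


@dataclass
class ClusterResult:
    labels: list[str]
    distance_matrix: np.ndarray
    linkage: np.ndarray
    bootstrap_proportions: dict[frozenset, float]   # clade -> BP out of 100
    newick: str

    def bp_for(self, members: Sequence[str]) -> float:
        return self.bootstrap_proportions.get(frozenset(members), 0.0)


def _clades(linkage: np.ndarray, labels: Sequence[str]) -> list[frozenset]:
    tree = hierarchy.to_tree(linkage)
    clades = []

    def walk(node) -> frozenset:
        if node.is_leaf():
            return frozenset([labels[node.id]])
        members = walk(node.left) | walk(node.right)
        clades.append(members)
        return members

    walk(tree)
    return clades


def _newick(linkage: np.ndarray, labels: Sequence[str],
            bp: dict[frozenset, float]) -> str:
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> tuple[str, frozenset]:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}", frozenset([labels[node.id]])
        left, lm = walk(node.left, node.dist)
        right, rm = walk(node.right, node.dist)
        members = lm | rm
        label = f"{bp.get(members, 0.0):.0f}"
        return f"({left},{right}){label}:{length:.6g}", members

    body, _ = walk(tree, tree.dist)
    return body + ";"


def canberra_cluster(
    vectors: np.ndarray,
    labels: Sequence[str],
    linkage_method: str = "average",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Hierarchical clustering of population feature vectors.

    Canberra distance, agglomerative linkage (average by default, matching
    the common tooling default for this analysis), and plain bootstrap
    proportions: features are resampled with replacement ``n_bootstrap``
    times and each observed clade's BP is the percentage of bootstrap trees
    containing it.  Features enter raw — Canberra is scale-aware by
    construction.
    """
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two equal-length vectors")
    if x.shape[0] != len(labels):
        raise ValueError("labels must match the number of vectors")
    dmat = canberra_distance_matrix(x)
    z = hierarchy.linkage(squareform(dmat), method=linkage_method)
    observed = _clades(z, labels)
    counts = {c: 0 for c in observed}
    rng = np.random.default_rng(seed)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, x.shape[1], size=x.shape[1])
        zb = hierarchy.linkage(pdist(x[:, idx], metric="canberra"),
                               method=linkage_method)
        for c in _clades(zb, labels):
            if c in counts:
                counts[c] += 1
    bp = {c: 100.0 * k / n_bootstrap for c, k in counts.items()}
    return ClusterResult(labels=list(labels), distance_matrix=dmat, linkage=z,
                         bootstrap_proportions=bp,
                         newick=_newick(z, labels, bp))
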