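"""Beta diversity: distances, principal coordinates and permutation tests.

Distances (Bray-Curtis, unweighted and weighted UniFrac) are computed on
the rarefied ASV table; UniFrac additionally needs the rooted phylogeny
over ASVs.  Ordination is classical PCoA (Gower double-centering of the
squared distances followed by an eigendecomposition).  Group structure is
tested by ANOSIM (rank-based), one-way PERMANOVA (Adonis-style partition
of squared distances) and PERMDISP (homogeneity of distances to group
centroids); all three use the ``(exceedances + 1) / (permutations + 1)``
p-value estimator and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy import stats
from skbio.diversity import beta_diversity as _skbio_beta

from .tabletools import FeatureTable, PhyloTree, RelativeAbundanceTable

__all__ = [
    "bray_curtis",
    "unweighted_unifrac",
    "weighted_unifrac",
    "pcoa",
    "anosim",
    "permanova",
    "permdisp",
    "OrdinationResult",
    "PermTestResult",
]

DistanceMatrix = skbio.DistanceMatrix


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame       # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray         # positive eigenvalues, descending
    proportion_explained: np.ndarray


@dataclass
class PermTestResult:
    method: str
    statistic: float                 # R (ANOSIM) or pseudo-F (PERMANOVA, PERMDISP)
    effect: float | None             # R^2 for PERMANOVA
    p: float
    permutations: int
    seed: int


def _counts_matrix(table):
    if isinstance(table, RelativeAbundanceTable):
        return table.fractions.to_numpy(dtype=float), table.sample_ids
    return table.counts.to_numpy(dtype=float), table.sample_ids


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity ``sum|u-v| / sum(u+v)`` between all sample pairs."""
    data, ids = _counts_matrix(table)
    if data.shape[0] < 2:
        raise ValueError("need at least two samples")
    zero_rows = np.flatnonzero(data.sum(axis=1) == 0)
    if len(zero_rows) >= 2:
        raise ValueError(
            f"Bray-Curtis undefined between all-zero samples "
            f"{[ids[i] for i in zero_rows]}"
        )
    return _skbio_beta("braycurtis", data, ids=ids)


def _check_tree(table, tree: PhyloTree):
    leaves = {leaf.name for leaf in tree.tips()}
    for taxon in table.taxon_ids:
        if taxon not in leaves:
            raise ValueError(f"taxon {taxon!r} missing from the tree")


def unweighted_unifrac(table: FeatureTable, tree: PhyloTree) -> DistanceMatrix:
    """Fraction of branch length unique to either sample's taxon set."""
    _check_tree(table, tree)
    data, ids = _counts_matrix(table)
    return _skbio_beta(
        "unweighted_unifrac", data, ids=ids, taxa=table.taxon_ids, tree=tree
    )


def weighted_unifrac(
    table: FeatureTable, tree: PhyloTree, normalized: bool = False
) -> DistanceMatrix:
    """Abundance-weighted UniFrac; un-normalized classic form by default."""
    _check_tree(table, tree)
    data, ids = _counts_matrix(table)
    return _skbio_beta(
        "weighted_unifrac", data, ids=ids, taxa=table.taxon_ids, tree=tree,
        normalized=normalized,
    )


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix, correction: str | None = None) -> OrdinationResult:
    """Classical scaling of a distance matrix.

    Coordinates are reported for positive eigenvalues only and the
    proportion explained is relative to the sum of positive eigenvalues.
    ``correction="lingoes"`` adds the constant that makes all eigenvalues
    non-negative before decomposing.
    """
    d = dm.data.astype(float)
    if correction == "lingoes":
        eigvals = np.linalg.eigvalsh(_gower_center(d))
        c = max(0.0, -eigvals.min())
        if c > 0:
            off = ~np.eye(len(d), dtype=bool)
            d = d.copy()
            d[off] = np.sqrt(d[off] ** 2 + 2 * c)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    g = _gower_center(d)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals[0])) if len(eigvals) else 0.0
    pos = eigvals > tol
    lam = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(lam)
    frame = pd.DataFrame(
        coords, index=list(dm.ids),
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return OrdinationResult(frame, lam, lam / lam.sum() if lam.sum() > 0 else lam)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _align_grouping(dm: DistanceMatrix, grouping) -> np.ndarray:
    if isinstance(grouping, pd.Series):
        missing = [i for i in dm.ids if i not in grouping.index]
        if missing:
            raise ValueError(f"samples missing from grouping: {missing}")
        return grouping.loc[list(dm.ids)].to_numpy()
    labels = np.asarray(grouping)
    if len(labels) != len(dm.ids):
        raise ValueError("grouping length does not match distance matrix")
    return labels


def _check_groups(labels, min_size=2):
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    small = uniq[counts < min_size]
    if len(small):
        raise ValueError(f"group {small[0]!r} has fewer than {min_size} samples")
    return uniq


def anosim(
    dm: DistanceMatrix, grouping, permutations: int = 999, seed: int = 0
) -> PermTestResult:
    """ANOSIM R with mid-ranked distances and label-permutation p-value.

    ``R = (mean between-group rank - mean within-group rank) / (M/2)`` with
    ``M = n(n-1)/2`` pairwise distances.
    """
    labels = _align_grouping(dm, grouping)
    _check_groups(labels)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dm.data[iu])
    m = len(ranks)
    denom = m / 2.0

    def r_stat(lab):
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    observed = r_stat(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        if r_stat(rng.permutation(labels)) >= observed:
            exceed += 1
    return PermTestResult(
        "anosim", float(observed), None,
        (exceed + 1) / (permutations + 1), permutations, seed,
    )


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, groups) -> tuple[float, float]:
    n = len(labels)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in groups:
        mask = labels == g
        nk = mask.sum()
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(nk, k=1)].sum() / nk
    return ss_total, ss_within


def permanova(
    dm: DistanceMatrix, grouping, permutations: int = 999, seed: int = 0
) -> PermTestResult:
    """One-way PERMANOVA (Adonis) pseudo-F, R^2 and label-permutation p."""
    labels = _align_grouping(dm, grouping)
    groups = _check_groups(labels, min_size=1)
    n, a = len(labels), len(groups)
    if n <= a:
        raise ValueError("need more samples than groups")
    d2 = dm.data.astype(float) ** 2

    def f_stat(lab):
        ss_total, ss_within = _permanova_ss(d2, lab, groups)
        ss_between = ss_total - ss_within
        if ss_within == 0.0:  # perfectly separated groups
            return np.inf, ss_between / ss_total
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
        return f, ss_between / ss_total

    observed_f, r2 = f_stat(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        if f_stat(rng.permutation(labels))[0] >= observed_f:
            exceed += 1
    return PermTestResult(
        "permanova", float(observed_f), float(r2),
        (exceed + 1) / (permutations + 1), permutations, seed,
    )


def _centroid_distances(axes: np.ndarray, signs: np.ndarray, labels, groups):
    """Distance of each sample to its group centroid in the PCoA embedding.

    Axes from negative eigenvalues contribute negatively to the squared
    distance (the embedding is semi-metric); totals are clamped at zero.
    """
    d2 = np.zeros(len(labels))
    for g in groups:
        mask = labels == g
        centered = axes[mask] - axes[mask].mean(axis=0)
        d2[mask] = (centered**2 * signs).sum(axis=1)
    return np.sqrt(np.clip(d2, 0.0, None))


def permdisp(
    dm: DistanceMatrix, grouping, permutations: int = 999, seed: int = 0
) -> PermTestResult:
    """Homogeneity of multivariate dispersion around group centroids.

    Embeds the samples by PCoA (keeping negative-eigenvalue axes with
    negative sign), computes each sample's distance to its group centroid
    and tests equality of mean distances with a one-way ANOVA F whose null
    distribution comes from permuting group labels.
    """
    labels = _align_grouping(dm, grouping)
    groups = _check_groups(labels)
    g = _gower_center(dm.data.astype(float))
    eigvals, eigvecs = np.linalg.eigh(g)
    keep = np.abs(eigvals) > 1e-10 * max(1.0, np.abs(eigvals).max())
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    axes = eigvecs * np.sqrt(np.abs(eigvals))
    signs = np.sign(eigvals)

    def f_stat(lab):
        dist = _centroid_distances(axes, signs, lab, groups)
        per_group = [dist[lab == g_] for g_ in groups]
        with np.errstate(invalid="ignore"):
            f, _ = stats.f_oneway(*per_group)
        return 0.0 if np.isnan(f) else float(f)

    observed = f_stat(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        if f_stat(rng.permutation(labels)) >= observed:
            exceed += 1
    return PermTestResult(
        "permdisp", observed, None,
        (exceed + 1) / (permutations + 1), permutations, seed,
    )
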