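"""Community dissimilarity, ordination, and permutation tests.

Bray-Curtis and binary Jaccard come from scipy's pdist; unweighted UniFrac
from scikit-bio.  PCoA, PERMANOVA (McArdle-Anderson partition, which also
yields the R^2 the study reports), pairwise PERMANOVA with Holm
adjustment, and the multivariate-dispersion test (betadisper analogue) are
implemented here with seeded, vectorizable permutation schemes.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from statsmodels.stats.multitest import multipletests

from .core_io import CommunityTable


def _check_no_empty(table: CommunityTable) -> None:
    empty = np.asarray(table.sample_ids)[table.counts.sum(axis=1) == 0]
    if len(empty):
        raise ValueError(f"all-zero sample(s): {', '.join(empty)}")


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """d(x, y) = sum|x_j - y_j| / sum(x_j + y_j)."""
    _check_no_empty(table)
    return DistanceMatrix(squareform(pdist(table.counts.astype(float), "braycurtis")),
                          ids=table.sample_ids)


def jaccard_binary(table: CommunityTable) -> DistanceMatrix:
    """Presence-absence Jaccard: 1 - |A & B| / |A | B|."""
    _check_no_empty(table)
    return DistanceMatrix(squareform(pdist(table.counts > 0, "jaccard")),
                          ids=table.sample_ids)


def unweighted_unifrac(table: CommunityTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: branch length unique to either presence set over
    branch length spanned by their union."""
    _check_no_empty(table)
    return beta_diversity("unweighted_unifrac", table.counts, ids=table.sample_ids,
                          taxa=table.otu_ids, tree=tree)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    ids: list
    coordinates: pd.DataFrame        # positive-eigenvalue axes, sqrt(lambda)-scaled
    eigenvalues: np.ndarray          # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues only


def _gower_center(d_squared: np.ndarray) -> np.ndarray:
    a = -0.5 * d_squared
    row = a.mean(axis=1, keepdims=True)
    return a - row - row.T + a.mean()


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Eigenvector sign convention: largest-magnitude loading positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def _eig_sorted(dm: DistanceMatrix):
    g = _gower_center(dm.data.astype(float) ** 2)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    return vals[order], _fix_signs(vecs[:, order])


def pcoa(dm: DistanceMatrix, eps: float = 1e-9) -> OrdinationResult:
    """Classical scaling (Gower double-centering + eigendecomposition).

    Coordinates are returned for positive eigenvalues only; negative
    eigenvalues are reported, not corrected.  Axis proportions use the sum
    of positive eigenvalues as denominator, the axis-percentage convention
    of PCoA ordination figures.
    """
    vals, vecs = _eig_sorted(dm)
    pos = vals > eps * max(vals.max(), 1.0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    frame = pd.DataFrame(coords, index=list(dm.ids),
                         columns=[f"PCo{i + 1}" for i in range(pos.sum())])
    return OrdinationResult(ids=list(dm.ids), coordinates=frame, eigenvalues=vals,
                            proportion_explained=vals[pos] / vals[pos].sum())


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    statistic: float   # pseudo-F
    r2: float
    pvalue: float
    n_permutations: int
    term: str = ""


def _align_grouping(dm: DistanceMatrix, grouping) -> np.ndarray:
    if isinstance(grouping, pd.Series):
        grouping = grouping.loc[list(dm.ids)].to_numpy()
    grouping = np.asarray(grouping)
    if len(grouping) != len(dm.ids):
        raise ValueError("grouping length does not match distance matrix")
    return grouping


def _ss_within(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    ssw = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ssw


def permanova(dm: DistanceMatrix, grouping, n_perm: int = 999,
              seed: int | None = None, term: str = "") -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F from the among/within partition of
    squared distances, R^2 = SS_among / SS_total, add-one permutation p
    with free label permutation."""
    grouping = _align_grouping(dm, grouping)
    codes, labels = pd.factorize(grouping)
    k = len(labels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if min(np.bincount(codes)) < 2:
        raise ValueError("every group needs >= 2 samples")
    n = len(codes)
    d2 = dm.data.astype(float) ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def f_of(c):
        ssw = _ss_within(d2, c, k)
        ssa = ss_total - ssw
        if ssw <= 0:
            return (np.inf if ssa > 0 else 0.0), ssa
        return (ssa / (k - 1)) / (ssw / (n - k)), ssa

    f_obs, ss_among = f_of(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_p, _ = f_of(rng.permutation(codes))
        if f_p >= f_obs:
            hits += 1
    return PermanovaResult(statistic=float(f_obs), r2=float(ss_among / ss_total),
                           pvalue=(1 + hits) / (1 + n_perm), n_permutations=n_perm,
                           term=term)


def pairwise_permanova(dm: DistanceMatrix, grouping, n_perm: int = 999,
                       seed: int | None = None) -> pd.DataFrame:
    """One PERMANOVA per group pair on the pair-subsetted matrix, with Holm
    step-down adjustment over all pairs."""
    grouping = pd.Series(_align_grouping(dm, grouping), index=list(dm.ids))
    labels = pd.unique(grouping)
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in combinations(labels, 2):
        ids = grouping.index[grouping.isin([a, b])]
        sub = dm.filter(ids)
        res = permanova(sub, grouping.loc[list(sub.ids)], n_perm=n_perm,
                        seed=int(rng.integers(2 ** 31)), term=f"{a} vs {b}")
        rows.append({"group_a": a, "group_b": b, "pseudo_f": res.statistic,
                     "r2": res.r2, "p_raw": res.pvalue})
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out


# ---------------------------------------------------------------------------
# PERMDISP (betadisper analogue)
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    distances: pd.Series      # per-sample distance to its group centroid
    group_means: pd.Series
    statistic: float          # ANOVA F on the distances
    pvalue: float
    n_permutations: int


def permdisp(dm: DistanceMatrix, grouping, n_perm: int = 999,
             seed: int | None = None) -> DispersionResult:
    """Multivariate homogeneity of group dispersions.

    Samples are embedded by PCoA keeping negative-eigenvalue axes as
    imaginary coordinates; squared distances to group centroids subtract
    the negative-axis contributions (clamped at zero), following the
    betadisper convention with group centroids and no bias adjustment.
    The homogeneity test is a permutation F-test on those distances.
    """
    grouping = _align_grouping(dm, grouping)
    codes, labels = pd.factorize(grouping)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    vals, vecs = _eig_sorted(dm)
    tol = 1e-9 * max(abs(vals).max(), 1.0)
    pos, neg = vals > tol, vals < -tol
    x_pos = vecs[:, pos] * np.sqrt(vals[pos])
    x_neg = vecs[:, neg] * np.sqrt(-vals[neg])

    n = len(codes)
    d2 = np.zeros(n)
    for g in range(len(labels)):
        idx = codes == g
        d2[idx] = (((x_pos[idx] - x_pos[idx].mean(axis=0)) ** 2).sum(axis=1)
                   - ((x_neg[idx] - x_neg[idx].mean(axis=0)) ** 2).sum(axis=1))
    dist = np.sqrt(np.clip(d2, 0.0, None))

    def anova_f(c):
        gm = dist.mean()
        ss_between = sum((dist[c == g].mean() - gm) ** 2 * (c == g).sum()
                         for g in range(len(labels)))
        ss_within = sum(((dist[c == g] - dist[c == g].mean()) ** 2).sum()
                        for g in range(len(labels)))
        if ss_within == 0:
            return np.inf if ss_between > 0 else 0.0
        return (ss_between / (len(labels) - 1)) / (ss_within / (n - len(labels)))

    f_obs = anova_f(codes)
    rng = np.random.default_rng(seed)
    hits = sum(anova_f(rng.permutation(codes)) >= f_obs for _ in range(n_perm))
    series = pd.Series(dist, index=list(dm.ids), name="dist_to_centroid")
    means = pd.Series({labels[g]: dist[codes == g].mean() for g in range(len(labels))})
    return DispersionResult(distances=series, group_means=means,
                            statistic=float(f_obs), pvalue=(1 + hits) / (1 + n_perm),
                            n_permutations=n_perm)
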