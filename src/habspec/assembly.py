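"""Null-model quantification of ecological assembly processes.

Implements the phylogenetic-turnover route (betaMNTD and its tip-shuffle
z-score betaNTI) and the taxonomic route (Bray-Curtis Raup-Crick, RC_Bray),
then the two-step threshold classification: |betaNTI| > 2 assigns
selection (variable if positive, homogeneous if negative); otherwise
RC_Bray > 0.95 assigns dispersal limitation, RC_Bray < -0.95 homogenizing
dispersal, and the remainder ecological drift.  Thresholds are strict
inequalities; boundary values fall to the stochastic / drift side.

betaMNTD for a pair (k, m) is the abundance-weighted mean patristic
distance from each taxon in one community to its nearest taxon in the
other:

    betaMNTD = 1/2 [ sum_{i in k} f_ik min_{j in m} D_ij
                   + sum_{j in m} f_jm min_{i in k} D_ij ]

The null shuffles tip labels across the whole phylogeny; by default one
shuffle per replicate is shared across all pairs (statistically equivalent
per pair marginally, and much cheaper); per-pair independent shuffles are
available behind a flag.

The RC_Bray null preserves each sample's observed richness and total
abundance, draws species without replacement with probability proportional
to their metacommunity occurrence frequency, allocates the remaining
individuals proportionally to metacommunity relative abundance among the
drawn species, and scores the observed Bray-Curtis against the null
distribution with half-weight ties:

    RC = 2 [ (#{BC_null < BC_obs} + 1/2 #{BC_null = BC_obs}) / n_null ] - 1
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .core_io import CommunityTable

logger = logging.getLogger("habspec")

PROCESS_LABELS = (
    "variable_selection",
    "homogeneous_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "drift",
)


def patristic_matrix(tree: TreeNode, otu_ids) -> np.ndarray:
    """Tip-to-tip patristic distances in ``otu_ids`` order."""
    dm = tree.tip_tip_distances(list(otu_ids))
    order = [list(dm.ids).index(o) for o in otu_ids]
    return dm.data[np.ix_(order, order)]


def _weights(table: CommunityTable, weighted: bool) -> np.ndarray:
    counts = table.counts.astype(float)
    if counts.sum(axis=1).min() == 0:
        raise ValueError("empty sample in table")
    if weighted:
        return counts / counts.sum(axis=1, keepdims=True)
    pres = (counts > 0).astype(float)
    return pres / pres.sum(axis=1, keepdims=True)


def _bmntd_matrix(f: np.ndarray, d: np.ndarray, idx_lists, perm=None) -> np.ndarray:
    """Pairwise betaMNTD for all samples.

    ``g[m, i]`` is the distance from taxon i to its nearest taxon of sample
    m; with a tip permutation ``perm``, taxon i occupies tree position
    perm[i], so columns and rows of D are looked up through perm.
    """
    n, s = f.shape
    g = np.empty((n, s))
    for m, idx in enumerate(idx_lists):
        cols = idx if perm is None else perm[idx]
        gm = d[:, cols].min(axis=1)
        g[m] = gm if perm is None else gm[perm]
    m_half = f @ g.T  # [k, m] = sum_i f_ki g_m[i]
    out = 0.5 * (m_half + m_half.T)
    np.fill_diagonal(out, 0.0)
    return out


def beta_mntd(table: CommunityTable, tree: TreeNode | None = None,
              weighted: bool = True, dist: np.ndarray | None = None) -> DistanceMatrix:
    """Observed betaMNTD matrix (abundance-weighted by default)."""
    if dist is None:
        dist = patristic_matrix(tree, table.otu_ids)
    f = _weights(table, weighted)
    idx_lists = [np.flatnonzero(row) for row in table.counts]
    return DistanceMatrix(_bmntd_matrix(f, dist, idx_lists), ids=table.sample_ids)


@dataclass
class BetaNtiResult:
    ids: list
    observed: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    nti: np.ndarray        # NaN where null sd == 0 (degenerate pair)
    n_null: int

    def to_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(self.nti, index=self.ids, columns=self.ids)


def beta_nti(table: CommunityTable, tree: TreeNode, n_null: int = 999,
             weighted: bool = True, seed: int | None = None,
             shared_shuffles: bool = True) -> BetaNtiResult:
    """betaNTI = (observed betaMNTD - null mean) / null sd under the
    taxa-shuffle null (tip labels permuted across the whole phylogeny)."""
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    d = patristic_matrix(tree, table.otu_ids)
    f = _weights(table, weighted)
    idx_lists = [np.flatnonzero(row) for row in table.counts]
    obs = _bmntd_matrix(f, d, idx_lists)
    n, s = f.shape
    rng = np.random.default_rng(seed)
    acc = np.zeros((n, n))
    acc2 = np.zeros((n, n))
    if shared_shuffles:
        for _ in range(n_null):
            perm = rng.permutation(s)
            b = _bmntd_matrix(f, d, idx_lists, perm=perm)
            acc += b
            acc2 += b * b
    else:
        # independent shuffles per pair: one permutation per (pair, replicate)
        for _ in range(n_null):
            b = np.zeros((n, n))
            for k in range(n):
                for m in range(k + 1, n):
                    perm = rng.permutation(s)
                    fk = f[[k, m]]
                    sub = _bmntd_matrix(fk, d, [idx_lists[k], idx_lists[m]], perm=perm)
                    b[k, m] = b[m, k] = sub[0, 1]
            acc += b
            acc2 += b * b
    mean = acc / n_null
    var = np.maximum(acc2 / n_null - mean ** 2, 0.0)
    sd = np.sqrt(var * n_null / max(n_null - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        nti = (obs - mean) / sd
    nti[sd == 0] = np.nan
    np.fill_diagonal(nti, np.nan)
    degenerate = int(np.isnan(nti[np.triu_indices(n, 1)]).sum())
    if degenerate:
        logger.warning("beta_nti: %d pair(s) with zero null sd flagged undefined", degenerate)
    return BetaNtiResult(ids=table.sample_ids, observed=obs, null_mean=mean,
                         null_sd=sd, nti=nti, n_null=n_null)


@dataclass
class RaupCrickResult:
    ids: list
    rc: np.ndarray
    n_null: int

    def to_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(self.rc, index=self.ids, columns=self.ids)


def _null_community(rng, sel_weight_log, ab_rel, richness, total, s):
    """One null community: top-``richness`` species by Gumbel-perturbed
    occurrence weight (weighted sampling without replacement), one
    individual each, remainder multinomial by metacommunity abundance."""
    keys = sel_weight_log + rng.gumbel(size=s)
    sel = np.argpartition(keys, s - richness)[s - richness:]
    counts = np.zeros(s)
    p = ab_rel[sel]
    counts[sel] = 1 + rng.multinomial(total - richness, p / p.sum())
    return counts


def raup_crick_bray(table: CommunityTable, n_null: int = 999,
                    seed: int | None = None, pairs=None,
                    occurrence=None, abundance=None) -> RaupCrickResult:
    """Bray-Curtis Raup-Crick null model.

    The metacommunity defaults to the input table itself: occurrence
    frequency = number of samples containing each OTU; relative abundance =
    total counts.  An explicit regional pool can be supplied instead via
    ``occurrence`` and ``abundance`` (arrays over the table's OTUs).
    ``pairs`` (list of (id_a, id_b)) restricts computation to the given
    pairs; the full matrix is computed otherwise.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if n_null < 99:
        logger.warning("raup_crick_bray: n_null=%d is low; RC resolution is coarse", n_null)
    counts = table.counts.astype(float)
    n, s = counts.shape
    if n < 2:
        raise ValueError("need >= 2 samples")
    pres = counts > 0
    occ = pres.sum(axis=0).astype(float) if occurrence is None \
        else np.asarray(occurrence, dtype=float)
    ab = counts.sum(axis=0) if abundance is None else np.asarray(abundance, dtype=float)
    ab_rel = ab / ab.sum()
    with np.errstate(divide="ignore"):
        w_log = np.where(occ > 0, np.log(occ), -np.inf)
    richness = pres.sum(axis=1)
    totals = counts.sum(axis=1).astype(int)
    rng = np.random.default_rng(seed)

    if pairs is None:
        iu = np.triu_indices(n, 1)
        obs = pdist(counts, "braycurtis")
        less = np.zeros(len(obs))
        equal = np.zeros(len(obs))
        for _ in range(n_null):
            null = np.empty((n, s))
            for i in range(n):
                null[i] = _null_community(rng, w_log, ab_rel, richness[i], totals[i], s)
            bc = pdist(null, "braycurtis")
            less += bc < obs - 1e-12
            equal += np.abs(bc - obs) <= 1e-12
        rc_cond = 2.0 * ((less + 0.5 * equal) / n_null) - 1.0
        rc = squareform(rc_cond)
        np.fill_diagonal(rc, 0.0)
    else:
        index = {sid: i for i, sid in enumerate(table.sample_ids)}
        pair_idx = np.array([(index[a], index[b]) for a, b in pairs])
        obs = np.array([_bray(counts[i], counts[j]) for i, j in pair_idx])
        involved = sorted(set(pair_idx.ravel()))
        less = np.zeros(len(pairs))
        equal = np.zeros(len(pairs))
        for _ in range(n_null):
            null = {}
            for i in involved:
                null[i] = _null_community(rng, w_log, ab_rel, richness[i], totals[i], s)
            bc = np.array([_bray(null[i], null[j]) for i, j in pair_idx])
            less += bc < obs - 1e-12
            equal += np.abs(bc - obs) <= 1e-12
        vals = 2.0 * ((less + 0.5 * equal) / n_null) - 1.0
        rc = np.full((n, n), np.nan)
        np.fill_diagonal(rc, 0.0)
        for (i, j), v in zip(pair_idx, vals):
            rc[i, j] = rc[j, i] = v
    return RaupCrickResult(ids=table.sample_ids, rc=rc, n_null=n_null)


def _bray(x, y) -> float:
    return np.abs(x - y).sum() / (x + y).sum()


# ---------------------------------------------------------------------------
# Classification and summaries
# ---------------------------------------------------------------------------

def classify_pair(bnti: float, rc: float | None) -> str:
    if np.isnan(bnti):
        return "undefined"
    if bnti > 2.0:
        return "variable_selection"
    if bnti < -2.0:
        return "homogeneous_selection"
    if rc is None or np.isnan(rc):
        raise ValueError("RC_Bray required for a pair with |betaNTI| <= 2")
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "drift"


def classify_processes(bnti: BetaNtiResult, rc: RaupCrickResult) -> pd.DataFrame:
    """Per-pair process assignment from the two null models."""
    if list(bnti.ids) != list(rc.ids):
        raise ValueError("betaNTI and RC_Bray results cover different samples")
    rows = []
    n = len(bnti.ids)
    for i in range(n):
        for j in range(i + 1, n):
            b = bnti.nti[i, j]
            r = rc.rc[i, j]
            rows.append({
                "sample_a": bnti.ids[i], "sample_b": bnti.ids[j],
                "bnti": b, "rc_bray": r,
                "process": classify_pair(b, None if np.isnan(b) or abs(b) > 2 else r),
            })
    out = pd.DataFrame(rows)
    n_undef = int((out["process"] == "undefined").sum())
    if n_undef:
        logger.warning("classify_processes: %d undefined pair(s) excluded from summaries", n_undef)
    return out


def summarize_processes(classified: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Fractions of pairs per process, split intra-site / inter-site per
    habitat.  Cross-habitat pairs are rejected; undefined pairs excluded."""
    site = samples["site"]
    habitat = samples["habitat"]
    cls = classified[classified["process"] != "undefined"].copy()
    ha = habitat.loc[cls["sample_a"]].to_numpy()
    hb = habitat.loc[cls["sample_b"]].to_numpy()
    if (ha != hb).any():
        raise ValueError("cross-habitat pair(s) in classification input")
    cls["habitat"] = ha
    same_site = site.loc[cls["sample_a"]].to_numpy() == site.loc[cls["sample_b"]].to_numpy()
    cls["scale"] = np.where(same_site, "intra_site", "inter_site")
    rows = []
    for (hab, scale), grp in cls.groupby(["habitat", "scale"]):
        frac = grp["process"].value_counts(normalize=True)
        row = {"habitat": hab, "scale": scale, "n_pairs": len(grp)}
        for p in PROCESS_LABELS:
            row[p] = float(frac.get(p, 0.0))
        rows.append(row)
    return pd.DataFrame(rows)
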