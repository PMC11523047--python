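"""Alpha diversity (Shannon, Faith PD), Levins niche breadth, and
Kruskal-Wallis + Dunn/Holm group comparisons.

Shannon uses natural log.  Faith PD is root-inclusive by default, matching
the common default of the implementation lineage used in microbial
ecology.  Levins breadth is computed per OTU across samples (a site-level
aggregation mode is available through ``units``).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from statsmodels.stats.multitest import multipletests

from .core_io import CommunityTable


def shannon(counts) -> float:
    """Shannon entropy H = -sum p ln p (nats) of a count vector."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / c.sum()
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(table: CommunityTable) -> pd.Series:
    return pd.Series([shannon(row) for row in table.counts],
                     index=table.sample_ids, name="shannon")


def faith_pd(presence, tree: TreeNode, include_root: bool = True) -> float:
    """Total branch length of the minimal subtree connecting the present
    tips, including the path to the root by default."""
    present = set(presence)
    if not present:
        raise ValueError("empty presence set")
    tips = {t.name for t in tree.tips()}
    unknown = present - tips
    if unknown:
        raise ValueError(f"OTU(s) not in tree: {', '.join(sorted(unknown)[:10])}")
    # postorder flag: does this clade contain a present tip?
    has = {}
    total = 0.0
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            has[id(node)] = node.name in present
        else:
            has[id(node)] = any(has[id(c)] for c in node.children)
        if has[id(node)]:
            total += node.length or 0.0
    if not include_root:
        # subtract the unbranched path from the MRCA of the present set to the root
        node = tree
        while True:
            live = [c for c in node.children if has.get(id(c), False)]
            if len(live) != 1 or live[0].is_tip():
                break
            total -= live[0].length or 0.0
            node = live[0]
        if len(present) == 1:
            total = 0.0
    return total


def faith_pd_per_sample(table: CommunityTable, tree: TreeNode,
                        include_root: bool = True) -> pd.Series:
    otus = np.array(table.otu_ids)
    vals = [faith_pd(otus[row > 0], tree, include_root=include_root)
            for row in table.counts]
    return pd.Series(vals, index=table.sample_ids, name="faith_pd")


@dataclass
class NicheBreadthResult:
    breadth: pd.DataFrame  # per OTU: B, Bn
    n_units: int


def levins_breadth(table: CommunityTable, units: pd.Series | None = None) -> NicheBreadthResult:
    """Levins niche breadth per OTU: B_j = 1 / sum_i p_ij^2 over units
    (samples by default, or ``units`` groups after pooling counts), and the
    normalized Bn_j = (B_j - 1)/(N - 1) in [0, 1].

    Low Bn marks a specialist (concentrated in few units), high Bn a
    generalist (evenly spread).
    """
    data = table.data
    if units is not None:
        data = data.groupby(units.loc[data.index].to_numpy()).sum()
    n_units = data.shape[0]
    if n_units < 2:
        raise ValueError("Levins Bn needs >= 2 units")
    totals = data.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0]
        raise ValueError(f"OTU(s) with zero total: {', '.join(bad[:10])}")
    p = data / totals
    B = 1.0 / (p ** 2).sum(axis=0)
    Bn = (B - 1.0) / (n_units - 1.0)
    out = pd.DataFrame({"B": B, "Bn": Bn})
    out.index.name = "otu_id"
    return NicheBreadthResult(breadth=out, n_units=n_units)


@dataclass
class GroupTestResult:
    statistic: float          # Kruskal-Wallis H (tie-corrected)
    pvalue: float             # chi-square omnibus p
    pairwise: pd.DataFrame    # group_a, group_b, z, p_raw, p_holm


def kruskal_dunn(values, groups) -> GroupTestResult:
    """Kruskal-Wallis omnibus test followed by Dunn's pairwise z tests with
    tie correction and Holm step-down adjustment."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    sizes = {g: int((groups == g).sum()) for g in labels}
    small = [g for g, n in sizes.items() if n < 2]
    if small:
        raise ValueError(f"group(s) with < 2 observations: {', '.join(map(str, small))}")

    H, p_omni = stats.kruskal(*[values[groups == g] for g in labels])

    N = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (N - 1))
    mean_rank = {g: ranks[groups == g].mean() for g in labels}

    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = multipletests(pairwise["p_raw"], method="holm")[1]
    return GroupTestResult(statistic=float(H), pvalue=float(p_omni), pairwise=pairwise)
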