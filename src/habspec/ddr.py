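"""Distance-decay relationships, bootstrap slope comparison, and variation
partitioning of community dissimilarity between geography and environment.

DDR is an ordinary least-squares fit of pairwise community dissimilarity on
log10-transformed predictor distance (pair non-independence is a known and
accepted caveat of this convention).  Variation partitioning decomposes the
db-RDA explained variance of the Gower-centered community matrix into pure
geographic, pure environmental, shared, and residual fractions with
Ezekiel-adjusted R^2, and tests fractions by (partial) permutation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .beta import _gower_center


@dataclass
class DdrFit:
    slope: float
    intercept: float
    r2: float
    pvalue: float
    n_pairs: int
    predictor: str = ""
    transform: str = "log10"


def _pair_vectors(comm_dm: DistanceMatrix, pred_dm: DistanceMatrix):
    if list(comm_dm.ids) != list(pred_dm.ids):
        pred_dm = pred_dm.filter(comm_dm.ids)
    iu = np.triu_indices(len(comm_dm.ids), 1)
    return comm_dm.data[iu], pred_dm.data[iu]


def distance_decay_fit(comm_dm: DistanceMatrix, pred_dm: DistanceMatrix,
                       zero_policy: str = "offset", offset: float | None = None,
                       predictor: str = "") -> DdrFit:
    """OLS of upper-triangle community dissimilarity on log10 predictor
    distance.

    Zero predictor distances (e.g. within-site pairs under site-level
    coordinates) are handled per ``zero_policy``: ``'offset'`` fits
    log10(d + offset) with offset defaulting to one tenth of the smallest
    positive distance; ``'exclude'`` drops the zero pairs.
    """
    y, x = _pair_vectors(comm_dm, pred_dm)
    if zero_policy == "exclude":
        keep = x > 0
        y, x = y[keep], x[keep]
        off = 0.0
    elif zero_policy == "offset":
        pos = x[x > 0]
        if offset is None:
            if len(pos) == 0:
                raise ValueError("no positive predictor distances to derive an offset from")
            offset = pos.min() / 10.0
        off = offset
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if len(x) < 3:
        raise ValueError("fewer than 3 usable pairs")
    lx = np.log10(x + off)
    if np.allclose(lx, lx[0]):
        raise ValueError("predictor distance is constant across usable pairs")
    fit = stats.linregress(lx, y)
    rvalue = fit.rvalue if np.isfinite(fit.rvalue) else 0.0  # constant response
    pvalue = fit.pvalue if np.isfinite(fit.pvalue) else 1.0
    return DdrFit(slope=float(fit.slope), intercept=float(fit.intercept),
                  r2=float(rvalue ** 2), pvalue=float(pvalue),
                  n_pairs=len(x), predictor=predictor,
                  transform=f"log10(d + {off:g})" if zero_policy == "offset" else "log10(d), zeros excluded")


@dataclass
class SlopeDistribution:
    label: str
    slopes: np.ndarray
    subsample: int


def bootstrap_ddr_slopes(comm_dm: DistanceMatrix, pred_dm: DistanceMatrix,
                         n_boot: int = 1000, subsample: int = 21,
                         seed: int | None = None, label: str = "",
                         **fit_kwargs) -> SlopeDistribution:
    """Bootstrap the DDR slope: each replicate draws ``subsample`` samples
    without replacement, rebuilds the pair vectors, and refits."""
    ids = list(comm_dm.ids)
    if subsample > len(ids):
        raise ValueError(f"subsample={subsample} exceeds n={len(ids)}")
    if list(pred_dm.ids) != ids:
        pred_dm = pred_dm.filter(ids)
    rng = np.random.default_rng(seed)
    comm, pred = comm_dm.data, pred_dm.data
    slopes = np.empty(n_boot)
    for r in range(n_boot):
        take = rng.choice(len(ids), size=subsample, replace=False)
        sub_c = DistanceMatrix(comm[np.ix_(take, take)], ids=[ids[i] for i in take])
        sub_p = DistanceMatrix(pred[np.ix_(take, take)], ids=[ids[i] for i in take])
        slopes[r] = distance_decay_fit(sub_c, sub_p, **fit_kwargs).slope
    return SlopeDistribution(label=label, slopes=slopes, subsample=subsample)


def compare_slopes(a: SlopeDistribution, b: SlopeDistribution):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of bootstrap
    slope distributions; reports which is stochastically larger."""
    if len(a.slopes) == 0 or len(b.slopes) == 0:
        raise ValueError("empty slope distribution")
    res = stats.mannwhitneyu(a.slopes, b.slopes, alternative="two-sided",
                             method="asymptotic")
    direction = a.label if np.median(a.slopes) >= np.median(b.slopes) else b.label
    return float(res.pvalue), direction


# ---------------------------------------------------------------------------
# Variation partitioning (db-RDA)
# ---------------------------------------------------------------------------

@dataclass
class VarpartResult:
    pure_geo: float       # fraction [a]
    shared: float         # fraction [b]
    pure_env: float       # fraction [c]
    residual: float       # fraction [d]
    r2: dict              # raw R^2 of [geo], [env], [geo+env]
    adj_r2: dict
    n: int


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        x = x.to_numpy()
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def _projection(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(np.column_stack([np.ones(len(x)), x]))
    keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1.0)
    q = q[:, keep]
    return q @ q.T


def _r2_dbrda(g: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    h = _projection(x)
    expl = float((h * g).sum())       # tr(HGH) = tr(HG) for idempotent H
    tot = float(np.trace(g))
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    return expl / tot, rank


def _ezekiel(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variation_partitioning(comm_dm: DistanceMatrix, x_geo, x_env) -> VarpartResult:
    """Partition db-RDA explained variance into [a] pure geography,
    [b] shared, [c] pure environment, [d] residual, using Ezekiel-adjusted
    R^2.  Slightly negative adjusted fractions are reported, not clipped."""
    xg, xe = _as_matrix(x_geo), _as_matrix(x_env)
    n = len(comm_dm.ids)
    g = _gower_center(comm_dm.data.astype(float) ** 2)
    r2g, pg = _r2_dbrda(g, xg)
    r2e, pe = _r2_dbrda(g, xe)
    both = np.column_stack([xg, xe])
    r2b, pb = _r2_dbrda(g, both)
    if n <= pb + 2:
        raise ValueError("too few samples for the combined predictor set")
    ag, ae, ab = _ezekiel(r2g, n, pg), _ezekiel(r2e, n, pe), _ezekiel(r2b, n, pb)
    a = ab - ae
    c = ab - ag
    b = ag + ae - ab
    d = 1.0 - ab
    return VarpartResult(pure_geo=a, shared=b, pure_env=c, residual=d,
                         r2={"geo": r2g, "env": r2e, "both": r2b},
                         adj_r2={"geo": ag, "env": ae, "both": ab}, n=n)


def test_fraction(comm_dm: DistanceMatrix, x, x_condition=None,
                  n_perm: int = 999, seed: int | None = None) -> tuple[float, float]:
    """Permutation test of a (partial) db-RDA fraction.

    Returns (pseudo-F, add-one p).  Without a condition the response matrix
    is freely permuted; with one, residuals of the reduced model are
    permuted (Freedman-Lane style).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = _as_matrix(x)
    n = len(comm_dm.ids)
    g = _gower_center(comm_dm.data.astype(float) ** 2)
    rng = np.random.default_rng(seed)

    if x_condition is None:
        h = _projection(x)
        m = np.linalg.matrix_rank(x - x.mean(axis=0))
        tot = float(np.trace(g))

        def f_of(gm):
            expl = float((h * gm).sum())
            return (expl / m) / ((tot - expl) / (n - m - 1))

        g_base = g
    else:
        z = _as_matrix(x_condition)
        hz = _projection(z)
        mz = np.linalg.matrix_rank(z - z.mean(axis=0))
        r = np.eye(n) - hz
        g_res = r @ g @ r
        x_res = r @ x
        q, rr = np.linalg.qr(x_res)
        keep = np.abs(np.diag(rr)) > 1e-10 * max(np.abs(np.diag(rr)).max(), 1.0)
        q = q[:, keep]
        hx = q @ q.T
        m = int(keep.sum())
        if m == 0:
            raise ValueError(
                "predictor set is collinear with the condition set; "
                "reduce the number of predictor axes")
        tot = float(np.trace(g_res))

        def f_of(gm):
            expl = float((hx * gm).sum())
            return (expl / m) / ((tot - expl) / (n - m - mz - 1))

        g_base = g_res

    f_obs = f_of(g_base)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if f_of(g_base[np.ix_(p, p)]) >= f_obs:
            hits += 1
    return float(f_obs), (1 + hits) / (1 + n_perm)
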