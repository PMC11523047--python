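"""Geographic and environmental predictor construction.

Geodesic distances on the WGS84 ellipsoid (Vincenty's inverse method,
sub-millimetre for non-antipodal pairs), spatial eigenfunctions (PCNM of
the truncated neighbour matrix), environmental standardization,
correlation pruning, PCA, and the PC-score environmental distance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .beta import _gower_center, _fix_signs

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563


def vincenty(lat1: float, lon1: float, lat2: float, lon2: float,
             tol: float = 1e-12, max_iter: int = 200) -> float:
    """Geodesic distance in metres between two WGS84 points (Vincenty's
    inverse formulae)."""
    if abs(lat1) > 90 or abs(lat2) > 90:
        raise ValueError("latitude outside [-90, 90]")
    if lat1 == lat2 and lon1 == lon2:
        return 0.0
    a, f = WGS84_A, WGS84_F
    b = a * (1 - f)
    u1 = np.arctan((1 - f) * np.tan(np.radians(lat1)))
    u2 = np.arctan((1 - f) * np.tan(np.radians(lat2)))
    big_l = np.radians(lon2 - lon1)
    sin_u1, cos_u1 = np.sin(u1), np.cos(u1)
    sin_u2, cos_u2 = np.sin(u2), np.cos(u2)
    lam = big_l
    for _ in range(max_iter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.sqrt((cos_u2 * sin_lam) ** 2
                            + (cos_u1 * sin_u2 - sin_u1 * cos_u2 * cos_lam) ** 2)
        if sin_sigma == 0:
            return 0.0
        cos_sigma = sin_u1 * sin_u2 + cos_u1 * cos_u2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        sin_alpha = cos_u1 * cos_u2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha ** 2
        cos_2sm = cos_sigma - 2 * sin_u1 * sin_u2 / cos2_alpha if cos2_alpha != 0 else 0.0
        c = f / 16 * cos2_alpha * (4 + f * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = big_l + (1 - c) * f * sin_alpha * (
            sigma + c * sin_sigma * (cos_2sm + c * cos_sigma * (-1 + 2 * cos_2sm ** 2)))
        if abs(lam - lam_prev) < tol:
            break
    else:
        raise ValueError("Vincenty iteration failed to converge (near-antipodal points)")
    u_sq = cos2_alpha * (a ** 2 - b ** 2) / b ** 2
    big_a = 1 + u_sq / 16384 * (4096 + u_sq * (-768 + u_sq * (320 - 175 * u_sq)))
    big_b = u_sq / 1024 * (256 + u_sq * (-128 + u_sq * (74 - 47 * u_sq)))
    delta = big_b * sin_sigma * (cos_2sm + big_b / 4 * (
        cos_sigma * (-1 + 2 * cos_2sm ** 2)
        - big_b / 6 * cos_2sm * (-3 + 4 * sin_sigma ** 2) * (-3 + 4 * cos_2sm ** 2)))
    return float(b * big_a * (sigma - delta))


def geodesic_distance_matrix(coords: pd.DataFrame) -> DistanceMatrix:
    """Pairwise geodesic distances (metres) from a frame with ``latitude``
    and ``longitude`` columns indexed by site or sample id."""
    ids = list(coords.index)
    lat = coords["latitude"].to_numpy(dtype=float)
    lon = coords["longitude"].to_numpy(dtype=float)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = vincenty(lat[i], lon[i], lat[j], lon[j])
    return DistanceMatrix(d, ids=ids)


def sample_geodesic_matrix(samples: pd.DataFrame) -> DistanceMatrix:
    """Sample-level geographic distances: samples inherit their site's
    coordinates, so within-site distance is exactly 0."""
    sites = samples[["site", "latitude", "longitude"]].drop_duplicates("site").set_index("site")
    site_dm = geodesic_distance_matrix(sites)
    return expand_to_samples(site_dm, samples["site"])


def expand_to_samples(site_dm: DistanceMatrix, site_of_sample: pd.Series) -> DistanceMatrix:
    """Replicate a site-level distance matrix to the sample level."""
    idx = [list(site_dm.ids).index(s) for s in site_of_sample]
    data = site_dm.data[np.ix_(idx, idx)].copy()
    np.fill_diagonal(data, 0.0)
    return DistanceMatrix(data, ids=list(site_of_sample.index))


# ---------------------------------------------------------------------------
# Environmental table processing
# ---------------------------------------------------------------------------

def standardize_env(env: pd.DataFrame) -> pd.DataFrame:
    """Centre-reduce each variable: (x - mean) / sd with the n-1 denominator."""
    sd = env.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant):
        raise ValueError(f"constant environmental variable(s): {', '.join(constant)}")
    return (env - env.mean()) / sd


def prune_correlated(env: pd.DataFrame, r_max: float = 0.95) -> tuple[pd.DataFrame, dict]:
    """Greedy column-order pruning of variables with |Pearson r| > r_max
    against an already-kept variable.  Returns the reduced table and a
    mapping dropped -> representative kept variable."""
    kept: list[str] = []
    mapping: dict[str, str] = {}
    for col in env.columns:
        rep = None
        for k in kept:
            r = np.corrcoef(env[col], env[k])[0, 1]
            if np.abs(r) > r_max:
                rep = k
                break
        if rep is None:
            kept.append(col)
        else:
            mapping[col] = rep
    return env[kept], mapping


@dataclass
class EnvPca:
    scores: pd.DataFrame            # site x PC
    loadings: pd.DataFrame          # variable x PC
    explained_variance: np.ndarray
    proportion_explained: np.ndarray
    kept_variables: list


def env_pca(env_std: pd.DataFrame) -> EnvPca:
    """SVD-based PCA of the standardized (centered) variable matrix."""
    if env_std.shape[1] < 2 or env_std.shape[0] < 3:
        raise ValueError("PCA needs >= 2 variables and >= 3 sites")
    x = env_std.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > 1e-12 * s[0]).sum()) if s.size and s[0] > 0 else 0
    if rank == 0:
        raise ValueError("environmental matrix has rank 0")
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    # sign convention: largest-magnitude loading positive
    v = _fix_signs(vt.T)
    flip = np.sign((v * vt.T).sum(axis=0))
    scores = u * s * flip
    var = s ** 2 / (len(env_std) - 1)
    cols = [f"PC{i + 1}" for i in range(rank)]
    return EnvPca(
        scores=pd.DataFrame(scores, index=env_std.index, columns=cols),
        loadings=pd.DataFrame(v, index=env_std.columns, columns=cols),
        explained_variance=var,
        proportion_explained=var / var.sum(),
        kept_variables=list(env_std.columns),
    )


def env_distance(pca: EnvPca, n_axes: int = 2,
                 site_of_sample: pd.Series | None = None) -> DistanceMatrix:
    """Euclidean distance on the first ``n_axes`` PC scores; optionally
    expanded from sites to samples via site membership."""
    if n_axes > pca.scores.shape[1]:
        raise ValueError(f"n_axes={n_axes} exceeds available axes ({pca.scores.shape[1]})")
    pts = pca.scores.iloc[:, :n_axes].to_numpy()
    dm = DistanceMatrix(squareform(pdist(pts)), ids=list(pca.scores.index))
    if site_of_sample is not None:
        dm = expand_to_samples(dm, site_of_sample)
    return dm


# ---------------------------------------------------------------------------
# PCNM
# ---------------------------------------------------------------------------

@dataclass
class PcnmBasis:
    ids: list
    vectors: pd.DataFrame       # orthonormal eigenvectors (PCNM1..k)
    eigenvalues: np.ndarray     # positive only, descending
    truncation: float


def pcnm(geo: DistanceMatrix, truncation: float | None = None,
         eps: float = 1e-9) -> PcnmBasis:
    """Principal coordinates of the (truncated) neighbour matrix.

    Distances above ``truncation`` (default: the maximum distance, a no-op)
    are replaced by 4 x truncation; eigenvectors of the Gower-centered
    matrix with positive eigenvalues form an orthonormal spatial basis.
    """
    if len(geo.ids) < 3:
        raise ValueError("PCNM needs >= 3 ids")
    d = geo.data.astype(float).copy()
    if truncation is None:
        truncation = d.max()
    mask = d > truncation
    d[mask] = 4.0 * truncation
    np.fill_diagonal(d, 0.0)
    g = _gower_center(d ** 2)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > eps * max(vals.max(), 1.0)
    vecs = _fix_signs(vecs[:, keep])
    frame = pd.DataFrame(vecs, index=list(geo.ids),
                         columns=[f"PCNM{i + 1}" for i in range(keep.sum())])
    return PcnmBasis(ids=list(geo.ids), vectors=frame, eigenvalues=vals[keep],
                     truncation=float(truncation))
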