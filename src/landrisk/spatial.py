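"""Global Moran's I and local indicators of spatial association (LISA).

Autocorrelation of the per-cell ecological risk index uses binary,
non-row-standardized distance-band weights: w_ij = 1 iff the centroid
distance of cells i, j is positive and ≤ d.  With z_i = (x_i − x̄)/σ and σ
the population standard deviation,

    I   = Σ_ij w_ij (x_i − x̄)(x_j − x̄) / (S² Σ_ij w_ij),   S² = (1/n)Σ(x_i − x̄)²
    I_i = z_i Σ_j w_ij z_j

so that Σ_i I_i = I · Σ_ij w_ij exactly.  Inference is by permutation:
full random relabeling for the global statistic (two-sided pseudo p with
the +1 correction) and conditional permutation for the locals (the value at
i stays put, the others are redistributed among its neighbors).  Cells with
significant locals are labelled HH/LL (positive I_i: a high/low value in a
like-valued neighborhood) or HL/LH (negative I_i: spatial outliers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "LISAResult",
    "distance_band_weights",
    "morans_i",
    "lisa",
    "moran_sweep",
]


@dataclass(frozen=True)
class SpatialWeights:
    """Binary symmetric distance-band adjacency over cell centroids."""

    matrix: sparse.csr_matrix  # n×n, 0/1, zero diagonal
    distance_km: float

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        """Σ_ij w_ij."""
        return float(self.matrix.sum())


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    p_value: float
    n_permutations: int
    seed: int | None
    distance_km: float


@dataclass(frozen=True)
class LISAResult:
    """Per-cell local Moran's I with permutation p-values and cluster labels."""

    table: pd.DataFrame  # columns: local_I, z_value, lag_z, p_value, label
    alpha: float
    n_permutations: int
    seed: int | None


def distance_band_weights(centroids_km: np.ndarray, d_km: float) -> SpatialWeights:
    """w_ij = 1 iff 0 < ||c_i − c_j|| ≤ d (Euclidean, km)."""
    pts = np.asarray(centroids_km, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two centroids")
    if not d_km > 0:
        raise ValueError("band distance must be > 0")
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=d_km, output_type="ndarray")
    if pairs.size == 0:
        raise ValueError(
            f"no centroid pair within {d_km} km; increase the band distance"
        )
    n = pts.shape[0]
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    m = sparse.csr_matrix(
        (np.ones(i.size), (i, j)), shape=(n, n)
    )
    return SpatialWeights(m, float(d_km))


def _standardize(values: np.ndarray) -> tuple[np.ndarray, float]:
    x = np.asarray(values, dtype=float)
    dev = x - x.mean()
    s2 = float((dev * dev).mean())  # population variance, 1/n
    if s2 == 0.0:
        raise ValueError("values are constant; Moran's I undefined (S² = 0)")
    return dev, s2


def morans_i(
    values: np.ndarray,
    w: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with a two-sided permutation pseudo p-value."""
    x = np.asarray(values, dtype=float)
    if x.size != w.n:
        raise ValueError("values and weights have different lengths")
    if x.size < 3:
        raise ValueError("need at least 3 values")
    dev, s2 = _standardize(x)
    s0 = w.s0
    observed = float(dev @ (w.matrix @ dev)) / (s2 * s0)
    expected = -1.0 / (x.size - 1)
    p = float("nan")
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        ref = abs(observed - expected)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(dev)
            i_star = float(perm @ (w.matrix @ perm)) / (s2 * s0)
            if abs(i_star - expected) >= ref - 1e-14:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
    return MoranResult(observed, expected, p, n_perm, seed, w.distance_km)


def lisa(
    values: np.ndarray,
    w: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> LISAResult:
    """Local Moran's I per cell with conditional-permutation inference.

    One-sided pseudo p per cell (toward the observed tail of I_i); labels:
    HH / LL for significant positive locals, HL / LH for significant
    negative ones, "ns" otherwise.
    """
    x = np.asarray(values, dtype=float)
    if x.size != w.n:
        raise ValueError("values and weights have different lengths")
    if x.size < 3:
        raise ValueError("need at least 3 values")
    dev, s2 = _standardize(x)
    z = dev / np.sqrt(s2)
    lag = w.matrix @ z
    local = z * lag
    n = x.size

    p = np.full(n, np.nan)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        csr = w.matrix
        # one permutation-index matrix over the n−1 "other" slots, shared by
        # all cells: row r, first k_i columns = the neighbors of i in draw r
        rids = np.array([rng.permutation(n - 1) for _ in range(n_perm)])
        for i in range(n):
            ki = csr.indptr[i + 1] - csr.indptr[i]
            if ki == 0:
                continue
            others = np.delete(z, i)
            lag_star = others[rids[:, :ki]].sum(axis=1)
            local_star = z[i] * lag_star
            if local[i] >= 0:
                exceed = int((local_star >= local[i] - 1e-14).sum())
            else:
                exceed = int((local_star <= local[i] + 1e-14).sum())
            p[i] = (1 + exceed) / (1 + n_perm)

    labels = np.full(n, "ns", dtype=object)
    sig = p <= alpha
    hh = sig & (z > 0) & (lag > 0)
    ll = sig & (z < 0) & (lag < 0)
    hl = sig & (z > 0) & (lag < 0)
    lh = sig & (z < 0) & (lag > 0)
    labels[hh], labels[ll], labels[hl], labels[lh] = "HH", "LL", "HL", "LH"

    table = pd.DataFrame(
        {"local_I": local, "z_value": z, "lag_z": lag, "p_value": p, "label": labels}
    )
    return LISAResult(table, alpha, n_perm, seed)


def moran_sweep(
    values: np.ndarray,
    centroids_km: np.ndarray,
    distances_km: list[float],
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Moran's I across a list of band distances (the distance-decay curve)."""
    rows = []
    for k, d in enumerate(distances_km):
        w = distance_band_weights(centroids_km, d)
        sub = None if seed is None else seed + k
        res = morans_i(values, w, n_perm=n_perm, seed=sub)
        rows.append(
            {
                "distance_km": d,
                "I": res.I,
                "expected_I": res.expected_I,
                "p_perm": res.p_value,
            }
        )
    return pd.DataFrame(rows)
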