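"""Graph-geodesic pseudotime and Moran's-I ranking of trajectory genes.

Pseudotime is the shortest-path distance from a root cell along the kNN
graph (edges weighted by Euclidean length in PC space), min-max scaled to
[0, 1].  Genes are ranked by Moran's I on the cell-neighbourhood graph

    I = n / S0 * sum_ij w_ij (y_i - ybar)(y_j - ybar) / sum_i (y_i - ybar)^2,

a graph autocorrelation that is high for genes varying smoothly along the
trajectory.  The top-ranked genes are summarised in equal-width pseudotime
bins and split into two expression-dynamics clusters (down- vs up-regulated
over pseudotime) by hierarchical clustering of the binned, z-scaled profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import dijkstra
from scipy.stats import norm

from .cluster_annotate import EmbeddingResult
from .ingest_qc import UmiCountMatrix

__all__ = [
    "PseudotimeResult",
    "MoranValue",
    "graph_pseudotime",
    "moran_i",
    "moran_i_genes",
    "rank_and_cluster_dynamics",
]


@dataclass
class PseudotimeResult:
    values: pd.Series  # barcode -> pseudotime in [0, 1]; NaN if unreachable
    root: str

    @property
    def reachable(self) -> pd.Series:
        return self.values.notna()


@dataclass(frozen=True)
class MoranValue:
    I: float
    p: float
    defined: bool = True


def graph_pseudotime(emb: EmbeddingResult, root: str) -> PseudotimeResult:
    """Geodesic distance from the root cell, scaled to [0, 1].

    Cells outside the root's connected component get NaN (flagged via
    ``reachable``).
    """
    barcodes = list(emb.barcodes)
    if root not in barcodes:
        raise ValueError(f"root barcode {root!r} not in embedding")
    root_idx = barcodes.index(root)
    dist = dijkstra(emb.distances, directed=False, indices=root_idx)
    finite = np.isfinite(dist)
    vals = np.full(dist.shape, np.nan)
    span = dist[finite].max()
    vals[finite] = dist[finite] / span if span > 0 else 0.0
    return PseudotimeResult(
        values=pd.Series(vals, index=pd.Index(emb.barcodes, name="barcode"), name="pseudotime"),
        root=root,
    )


def moran_i(
    y,
    graph: sp.spmatrix,
    n_permutations: int = 999,
    seed: int = 0,
) -> MoranValue:
    """Moran's I on a (symmetric, typically unit-weight kNN) graph.

    p is a one-sided permutation p value for positive autocorrelation,
    (1 + #{I_perm >= I}) / (n_permutations + 1); constant y is undefined
    (I = NaN, p = 1, defined False).  With n_permutations = 0 only the
    statistic is computed (p = NaN).
    """
    y = np.asarray(y, float)
    W = sp.csr_matrix(graph)
    n = y.size
    z = y - y.mean()
    denom = float(z @ z)
    if denom == 0:
        return MoranValue(I=np.nan, p=1.0, defined=False)
    S0 = float(W.sum())
    I = n / S0 * float(z @ (W @ z)) / denom
    if n_permutations <= 0:
        return MoranValue(I=I, p=np.nan)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        zp = z[rng.permutation(n)]
        Ip = n / S0 * float(zp @ (W @ zp)) / denom
        if Ip >= I:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return MoranValue(I=I, p=p)


def moran_i_genes(Y: np.ndarray, graph: sp.spmatrix) -> pd.DataFrame:
    """Vectorized Moran's I for every row of a genes x cells matrix.

    Returns I, an analytic z-score and one-sided normal p under the
    randomization assumption; constant rows are flagged undefined.
    """
    W = sp.csr_matrix(graph)
    n = Y.shape[1]
    S0 = float(W.sum())
    Wd = W + W.T
    S1 = 0.5 * float((Wd.multiply(Wd)).sum())
    row_sums = np.asarray(W.sum(axis=1)).ravel() + np.asarray(W.sum(axis=0)).ravel()
    S2 = float((row_sums**2).sum())

    Z = Y - Y.mean(axis=1, keepdims=True)
    denom = np.einsum("ij,ij->i", Z, Z)
    num = np.einsum("ij,ij->i", Z, Z @ W.T)
    defined = denom > 0
    I = np.full(Y.shape[0], np.nan)
    I[defined] = n / S0 * num[defined] / denom[defined]

    EI = -1.0 / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m2 = denom / n
        m4 = np.einsum("ij,ij->i", Z**2, Z**2) / n
        b2 = np.where(m2 > 0, m4 / m2**2, 0.0)
    A = n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * S0**2)
    B = (n**2 - n) * S1 - 2 * n * S2 + 6 * S0**2
    C = (n - 1) * (n - 2) * (n - 3) * S0**2
    EI2 = (A - b2 * B) / C
    var = np.maximum(EI2 - EI**2, 1e-30)
    zscore = (I - EI) / np.sqrt(var)
    p = norm.sf(zscore)
    return pd.DataFrame(
        {"I": I, "z": zscore, "p": p, "defined": defined}
    )


def rank_and_cluster_dynamics(
    m: UmiCountMatrix,
    pt: PseudotimeResult,
    graph: sp.spmatrix,
    top_n: int = 100,
    n_bins: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank genes by Moran's I and split the top set into two dynamics clusters.

    Moran's I is computed on the raw counts over the cells carried by ``pt``
    (the graph must match those cells).  The top_n genes (fewer, with a
    warning, if not enough are defined) are averaged in ``n_bins``
    equal-width pseudotime bins (empty bins linearly interpolated), z-scaled,
    hierarchically clustered (Euclidean, average linkage) and cut at k=2;
    clusters are labelled 'down'/'up' by the slope of their mean profile.

    Returns (moran table with rank, gene table with cluster labels and the
    binned profiles).
    """
    reachable = pt.reachable
    cells = pt.values.index[reachable]
    sub = m.subset_cells_by_barcode(list(cells))
    t = pt.values.loc[cells].to_numpy()

    Y = sub.to_dense().astype(float)
    moran = moran_i_genes(Y, graph)
    moran.insert(0, "gene", sub.gene_ids)
    defined = moran["defined"].to_numpy()
    order = np.argsort(-np.where(defined, moran["I"].to_numpy(), -np.inf), kind="mergesort")
    rank = np.full(len(order), np.nan)
    rank[order[: defined.sum()]] = np.arange(1, defined.sum() + 1)
    moran["rank"] = rank

    n_avail = int(defined.sum())
    if n_avail < top_n:
        warnings.warn(
            f"only {n_avail} genes have a defined Moran's I; returning all",
            stacklevel=2,
        )
        top_n = n_avail
    top_idx = order[:top_n]

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_id = np.clip(np.digitize(t, edges[1:-1]), 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    profiles = np.full((top_n, n_bins), np.nan)
    for b in range(n_bins):
        mask = bin_id == b
        if mask.any():
            profiles[:, b] = Y[np.ix_(top_idx, np.flatnonzero(mask))].mean(axis=1)
    for g in range(top_n):
        row = profiles[g]
        if np.isnan(row).any():
            ok = ~np.isnan(row)
            profiles[g] = np.interp(centers, centers[ok], row[ok])
    mu = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, ddof=0, keepdims=True)
    zprof = np.where(sd > 0, (profiles - mu) / sd, 0.0)

    genes_top = sub.gene_ids[top_idx]
    if top_n >= 2:
        Zl = linkage(zprof, method="average", metric="euclidean")
        cut = fcluster(Zl, t=2, criterion="maxclust")
    else:
        cut = np.ones(top_n, int)
    slopes = np.polyfit(centers, zprof.T, 1)[0]
    labels = np.empty(top_n, dtype=object)
    mean_slope = {c: slopes[cut == c].mean() for c in np.unique(cut)}
    if len(mean_slope) == 2:
        c_down = min(mean_slope, key=mean_slope.get)
        labels[:] = ["down" if c == c_down else "up" for c in cut]
    else:
        labels[:] = ["down" if s < 0 else "up" for s in slopes]

    dyn = pd.DataFrame(
        {"gene": genes_top, "cluster": labels, "slope": slopes},
    )
    dyn = dyn.join(
        pd.DataFrame(zprof, columns=[f"bin_{b + 1:02d}" for b in range(n_bins)])
    )
    return moran, dyn
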