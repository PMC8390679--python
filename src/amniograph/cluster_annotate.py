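"""PCA embedding, kNN-graph clustering, marker annotation, composition shifts.

The embedding is a plain PCA of the Pearson residuals (cells as samples)
with a deterministic sign convention, followed by a symmetrized unit-weight
kNN graph.  Clustering is greedy modularity maximization on that graph, with
support for manually recombining clusters.  Clusters are annotated against
marker gene sets by mean signature score, and condition-wise composition
tables quantify cell-type proportion shifts between wild type and mutant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .ingest_qc import UmiCountMatrix
from .normalize_de import ResidualMatrix
from .signatures import GeneSignature, score_signature

__all__ = [
    "EmbeddingResult",
    "ClusterAssignment",
    "pca_knn_embed",
    "cluster_graph",
    "merge_clusters",
    "annotate_clusters",
    "composition_by_condition",
    "composition_difference",
]


@dataclass
class EmbeddingResult:
    """PCA coordinates plus the symmetrized unit-weight kNN graph."""

    coords: np.ndarray  # cells x n_dims
    barcodes: np.ndarray
    adjacency: sp.csr_matrix  # unit weights, no self loops, symmetric
    distances: sp.csr_matrix  # same sparsity, Euclidean edge lengths
    k: int
    variance_ratio: np.ndarray


@dataclass
class ClusterAssignment:
    labels: pd.Series  # barcode -> cluster id (final)
    original: pd.Series | None = None  # pre-merge labels, if merged
    merge_map: dict | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if self.labels.isna().any():
            raise ValueError("every barcode must be labelled")


def pca_knn_embed(
    residuals: ResidualMatrix,
    n_dims: int = 30,
    k: int = 15,
    seed: int = 0,
) -> EmbeddingResult:
    """Embed cells with PCA and build the kNN graph.

    The sign of each component is fixed so its largest-magnitude loading is
    positive, making the embedding reproducible across runs.  The kNN graph
    (Euclidean distance in PC space, self excluded) is symmetrized by union
    and given unit weights; Euclidean edge lengths are kept alongside for
    geodesic pseudotime.
    """
    X = residuals.z.T  # cells x genes
    n_cells = X.shape[0]
    if n_dims >= n_cells:
        raise ValueError("n_dims must be smaller than the number of cells")
    pca = PCA(n_components=n_dims, svd_solver="full")
    coords = pca.fit_transform(X)
    comps = pca.components_
    for j in range(n_dims):
        i_star = int(np.argmax(np.abs(comps[j])))
        if comps[j, i_star] < 0:
            coords[:, j] *= -1.0
            comps[j] *= -1.0

    nn = NearestNeighbors(n_neighbors=min(k + 1, n_cells)).fit(coords)
    dist, ind = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n_cells), ind.shape[1] - 1)
    cols = ind[:, 1:].ravel()  # first neighbor is the cell itself
    adj = sp.coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n_cells, n_cells)
    ).tocsr()
    adj = ((adj + adj.T) > 0).astype(float).tocsr()
    adj.setdiag(0)
    adj.eliminate_zeros()

    coo = sp.triu(adj).tocoo()
    d = np.linalg.norm(coords[coo.row] - coords[coo.col], axis=1)
    distm = sp.coo_matrix((d, (coo.row, coo.col)), shape=adj.shape)
    distm = (distm + distm.T).tocsr()

    return EmbeddingResult(
        coords=coords,
        barcodes=residuals.barcodes.copy(),
        adjacency=adj,
        distances=distm,
        k=k,
        variance_ratio=pca.explained_variance_ratio_,
    )


def cluster_graph(
    emb: EmbeddingResult, resolution: float = 1.0, seed: int = 0
) -> ClusterAssignment:
    """Greedy modularity communities on the kNN graph.

    Deterministic: the greedy agglomeration breaks ties on node order, and
    clusters are relabelled C0, C1, ... by decreasing size (then smallest
    member index).  ``resolution`` acts as a coarseness knob (larger values
    give more, smaller clusters).
    """
    if emb.adjacency.nnz == 0:
        raise ValueError("empty graph")
    G = nx.from_scipy_sparse_array(emb.adjacency)
    comms = nx.community.greedy_modularity_communities(G, resolution=resolution)
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = np.empty(emb.adjacency.shape[0], dtype=object)
    for i, comm in enumerate(comms):
        for node in comm:
            labels[node] = f"C{i}"
    return ClusterAssignment(
        labels=pd.Series(labels, index=pd.Index(emb.barcodes, name="barcode"), name="cluster"),
        method=f"greedy_modularity(resolution={resolution})",
    )


def merge_clusters(assign: ClusterAssignment, merge_map: dict) -> ClusterAssignment:
    """Manually recombine clusters; original labels are retained.

    ``merge_map`` maps existing cluster ids to their new (merged) label;
    unmapped clusters keep their label.
    """
    existing = set(assign.labels.unique())
    unknown = set(merge_map) - existing
    if unknown:
        raise ValueError(f"merge map references unknown clusters: {sorted(unknown)}")
    merged = assign.labels.map(lambda c: merge_map.get(c, c)).rename("cluster")
    return ClusterAssignment(
        labels=merged,
        original=assign.labels.copy(),
        merge_map=dict(merge_map),
        method=assign.method + "+manual_merge",
    )


def annotate_clusters(
    m: UmiCountMatrix,
    assign: ClusterAssignment,
    marker_sets: dict,
) -> tuple[dict, pd.DataFrame]:
    """Assign each cluster the marker set with the highest mean signature score.

    Returns (cluster -> type name, per-cluster score table with tie and
    missing-marker flags).  Ties are broken alphabetically and flagged;
    marker sets with no genes in the matrix score zero everywhere (flagged).
    """
    if not marker_sets or any(len(g) == 0 for g in marker_sets.values()):
        raise ValueError("marker sets must be nonempty")
    gene_pool = set(m.gene_ids)
    scores = {}
    empty_sets = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in sorted(marker_sets):
            genes = tuple(dict.fromkeys(marker_sets[name]))
            if not (set(genes) & gene_pool):
                empty_sets.append(name)
            scores[name] = score_signature(m, GeneSignature(name=name, genes=genes))
    score_df = pd.DataFrame(scores)
    score_df["cluster"] = assign.labels.reindex(score_df.index).values
    cluster_means = score_df.groupby("cluster").mean()

    mapping: dict = {}
    rows = []
    for cluster, row in cluster_means.iterrows():
        best = row.max()
        winners = sorted(row.index[row == best])
        tie = len(winners) > 1
        label = winners[0] if best > 0 else "unassigned"
        mapping[cluster] = label
        rows.append({"cluster": cluster, "label": label, "tie": tie, "best_score": best})
    info = pd.DataFrame(rows).set_index("cluster")
    info["empty_marker_sets"] = ",".join(empty_sets)
    return mapping, cluster_means.join(info)


def composition_by_condition(
    type_labels: pd.Series, cell_meta: pd.DataFrame
) -> pd.DataFrame:
    """Counts and within-condition fractions per (condition, cell type)."""
    if "condition" not in cell_meta.columns:
        raise ValueError("cell_meta must carry a 'condition' column")
    cond = cell_meta["condition"].reindex(type_labels.index)
    if cond.isna().any():
        raise ValueError("every barcode needs a condition")
    df = pd.DataFrame({"condition": cond, "cell_type": type_labels})
    counts = df.groupby(["condition", "cell_type"], sort=True).size().rename("count")
    table = counts.reset_index()
    totals = table.groupby("condition")["count"].transform("sum")
    table["fraction"] = table["count"] / totals
    return table


def composition_difference(table: pd.DataFrame) -> pd.DataFrame:
    """Wide view with a wt - mt fraction difference column."""
    wide = table.pivot(index="cell_type", columns="condition", values="fraction").fillna(0.0)
    counts = table.pivot(index="cell_type", columns="condition", values="count").fillna(0).astype(int)
    out = pd.DataFrame(index=wide.index)
    for cond in wide.columns:
        out[f"count_{cond}"] = counts[cond]
        out[f"frac_{cond}"] = wide[cond]
    if {"wt", "mt"} <= set(wide.columns):
        out["diff_wt_minus_mt"] = wide["wt"] - wide["mt"]
    return out
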