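"""Joint transcriptomic landscape and cluster-distribution distances.

A baseline shared-gene PCA landscape stands in for heavier integration
schemes: variable genes are intersected across datasets (union ranked
by cross-dataset median rank), each dataset is z-scaled per gene, cells
are concatenated, and PCA + shared-nearest-neighbor Leiden clustering
define global clusters.  All distribution statistics downstream (JSD,
PCD, proportion PCA) are integration-agnostic and also accept an
externally supplied cluster assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import jensenshannon, squareform
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from blastcomp.exceptions import DataError
from blastcomp.scoring import select_variable_genes


@dataclass
class DistanceMatrix:
    """Symmetric dataset x dataset distances with a validity mask."""

    values: pd.DataFrame
    metric: str  # jsd | pcd | ks_mean
    mask: pd.DataFrame | None = None  # True where defined

    def check(self) -> None:
        v = self.values.to_numpy()
        assert np.allclose(v, v.T, equal_nan=True, atol=1e-12)
        assert np.allclose(np.diag(v)[~np.isnan(np.diag(v))], 0.0)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class ClusterAssignment:
    """Per-cell global cluster ids with clustering provenance."""

    table: pd.DataFrame  # columns: dataset_id, cluster; index: cell_id
    provenance: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="cell_id")

    @classmethod
    def from_tsv(cls, path) -> "ClusterAssignment":
        table = pd.read_csv(path, sep="\t", index_col="cell_id")
        return cls(table, {"source": str(path)})


# ---------------------------------------------------------------------
# embedding + clustering
# ---------------------------------------------------------------------

def joint_embed(
    matrices: list[np.ndarray],
    gene_names_list: list,
    dataset_ids: list[str],
    cell_ids_list: list,
    n_pcs: int = 12,
    n_shared_genes: int = 2000,
    min_shared_genes: int = 100,
):
    """Shared-gene PCA landscape over all datasets.

    Genes present in every dataset are ranked by the median of their
    per-dataset variable-gene ranks; the top ``n_shared_genes`` form
    the joint space.  Each dataset is z-scaled per gene before
    concatenation so the PCA is not dominated by platform scale.
    Component signs are fixed so the largest-magnitude loading of each
    PC is positive.

    Returns ``(embedding, index)`` where ``index`` is a DataFrame with
    ``dataset_id`` per cell.
    """
    if len(matrices) < 2:
        raise DataError("joint_embed needs at least 2 datasets")
    indices = [pd.Index(g) for g in gene_names_list]
    shared = indices[0]
    for idx in indices[1:]:
        shared = shared.intersection(idx)
    if len(shared) < min_shared_genes:
        raise DataError(f"only {len(shared)} shared genes across datasets")

    # cross-dataset median variable rank on the shared universe
    ranks = np.full((len(matrices), len(shared)), len(shared), dtype=float)
    for i, (m, idx) in enumerate(zip(matrices, indices)):
        pos = [idx.get_loc(g) for g in shared]
        sub = m[:, pos]
        ranked = select_variable_genes(sub, n_top=len(shared))
        ranks[i, ranked] = np.arange(len(ranked))
    median_rank = np.median(ranks, axis=0)
    order = np.argsort(median_rank, kind="stable")
    top = order[: min(n_shared_genes, len(shared))]
    genes = shared[top]

    blocks = []
    for m, idx in zip(matrices, indices):
        pos = [idx.get_loc(g) for g in genes]
        sub = m[:, pos]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        blocks.append((sub - mu) / sd)
    X = np.vstack(blocks)

    pca = PCA(n_components=n_pcs, svd_solver="full")
    emb = pca.fit_transform(X)
    # deterministic sign: largest |loading| positive per component
    for j in range(emb.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            emb[:, j] *= -1.0
    index = pd.DataFrame(
        {
            "dataset_id": np.concatenate(
                [[d] * m.shape[0] for d, m in zip(dataset_ids, matrices)]
            )
        },
        index=pd.Index(np.concatenate([list(c) for c in cell_ids_list]),
                       name="cell_id"),
    )
    return emb, index


def graph_cluster(
    embedding: np.ndarray,
    index: pd.DataFrame,
    resolution: float = 2.0,
    k_neighbors: int = 20,
    seed: int = 0,
    snn_prune: float = 1.0 / 15.0,
) -> ClusterAssignment:
    """Shared-nearest-neighbor Leiden clustering of the embedding.

    Builds a kNN graph, reweights edges by the Jaccard overlap of
    neighborhoods (pruning below ``snn_prune``), and partitions with
    the Leiden algorithm at the given resolution (RB-configuration
    quality).  Cluster ids are relabeled by decreasing size.
    """
    import igraph as ig
    import leidenalg
    from scipy import sparse

    n = embedding.shape[0]
    if n < k_neighbors + 1:
        raise DataError("fewer cells than k_neighbors + 1")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding)
    knn = nn.kneighbors_graph(mode="connectivity")  # self excluded
    knn = knn + sparse.identity(n, format="csr")
    knn.data[:] = 1.0
    inter = knn @ knn.T
    inter = inter.tocoo()
    k_eff = k_neighbors + 1
    jac = inter.data / (2.0 * k_eff - inter.data)
    keep = (jac >= snn_prune) & (inter.row < inter.col)
    edges = np.column_stack([inter.row[keep], inter.col[keep]])
    weights = jac[keep]

    g = ig.Graph(n=n, edges=[tuple(e) for e in edges])
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=list(weights),
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    # relabel by decreasing size, ties by original id
    ids, counts = np.unique(raw, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    remap = {old: new for new, old in enumerate(order)}
    clusters = np.array([remap[c] for c in raw], dtype=int)

    table = index.copy()
    table["cluster"] = clusters
    return ClusterAssignment(
        table,
        provenance={
            "method": "snn_leiden",
            "resolution": resolution,
            "k_neighbors": k_neighbors,
            "n_pcs": int(embedding.shape[1]),
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------
# distributions and distances
# ---------------------------------------------------------------------

def cluster_distributions(assignment: ClusterAssignment | pd.DataFrame
                          ) -> pd.DataFrame:
    """Per-dataset proportion vectors over the global cluster range.

    Rows are datasets, columns cluster ids 0..max; zeros where a
    dataset does not occupy a cluster.  Each row sums to 1.
    """
    table = assignment.table if isinstance(assignment, ClusterAssignment) else assignment
    n_clusters = int(table["cluster"].max()) + 1
    counts = (
        pd.crosstab(table["dataset_id"], table["cluster"])
        .reindex(columns=range(n_clusters), fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


def _validate_distributions(dist: pd.DataFrame) -> np.ndarray:
    arr = dist.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise DataError("negative proportions")
    if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
        raise DataError("a distribution does not sum to 1 within 1e-6")
    return arr


def jsd_matrix(distributions: pd.DataFrame, metric_mode: bool = False
               ) -> DistanceMatrix:
    """Pairwise Jensen-Shannon divergence between cluster distributions.

    Default: natural-log divergence in [0, ln 2] with 0*log 0 := 0.
    ``metric_mode`` returns instead the base-2 Jensen-Shannon distance
    (square root of the divergence) in [0, 1], which satisfies the
    triangle inequality.
    """
    arr = _validate_distributions(distributions)
    n = arr.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric_mode:
                d = jensenshannon(arr[i], arr[j], base=2)
            else:
                d = jensenshannon(arr[i], arr[j]) ** 2  # natural-log divergence
            out[i, j] = out[j, i] = 0.0 if np.isnan(d) else float(d)
    values = pd.DataFrame(out, index=distributions.index, columns=distributions.index)
    dm = DistanceMatrix(values, "jsd")
    dm.check()
    return dm


def pcd_matrix(distributions: pd.DataFrame, min_shared: int = 3) -> DistanceMatrix:
    """Pearson correlation distance on clusters shared by each pair.

    For datasets i, j the correlation is computed on the clusters with
    strictly positive proportion in *both* (support intersection), then
    mapped to ``(1 - cor) / 2``.  Pairs with fewer than ``min_shared``
    shared clusters, or zero variance on a restricted vector, are
    undefined: masked NaN with a warning, never an error.
    """
    arr = _validate_distributions(distributions)
    n = arr.shape[0]
    out = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            shared = (arr[i] > 0) & (arr[j] > 0)
            if shared.sum() < min_shared:
                out[i, j] = out[j, i] = np.nan
                defined[i, j] = defined[j, i] = False
                continue
            x, y = arr[i, shared], arr[j, shared]
            if x.std() == 0 or y.std() == 0:
                out[i, j] = out[j, i] = np.nan
                defined[i, j] = defined[j, i] = False
                continue
            cor = np.corrcoef(x, y)[0, 1]
            out[i, j] = out[j, i] = (1.0 - cor) / 2.0
    if not defined.all():
        und = int((~defined).sum() // 2)
        warnings.warn(f"{und} dataset pair(s) have undefined PCD entries",
                      stacklevel=2)
    idx = distributions.index
    dm = DistanceMatrix(
        pd.DataFrame(out, index=idx, columns=idx),
        "pcd",
        pd.DataFrame(defined, index=idx, columns=idx),
    )
    dm.check()
    return dm


def pca_of_distributions(distributions: pd.DataFrame, n_components: int = 2):
    """Centered PCA of the dataset x cluster proportion matrix.

    Returns ``(coords, explained_variance_fractions)``; identical
    distributions collapse to the origin with zero explained variance.
    """
    arr = _validate_distributions(distributions)
    if arr.shape[0] < 3:
        raise DataError("need at least 3 datasets for a distribution PCA")
    centered = arr - arr.mean(axis=0)
    if np.allclose(centered, 0.0):
        coords = np.zeros((arr.shape[0], n_components))
        ratios = np.zeros(n_components)
    else:
        k = min(n_components, min(arr.shape) - 1)
        pca = PCA(n_components=k, svd_solver="full")
        coords = pca.fit_transform(arr)
        for j in range(coords.shape[1]):
            load = pca.components_[j]
            if load[np.argmax(np.abs(load))] < 0:
                coords[:, j] *= -1.0
        ratios = pca.explained_variance_ratio_
        if k < n_components:
            coords = np.pad(coords, ((0, 0), (0, n_components - k)))
            ratios = np.pad(ratios, (0, n_components - k))
    coords_df = pd.DataFrame(
        coords, index=distributions.index,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return coords_df, np.asarray(ratios)


def order_by_clustering(dm: DistanceMatrix, linkage: str = "average"):
    """Leaf order and dendrogram from average-linkage on the distances.

    Masked (undefined) entries are imputed with the maximum defined
    distance, with a warning — they carry "at least as far as anything
    we measured" semantics for tree building only.
    """
    values = dm.values.to_numpy(dtype=float).copy()
    if np.isnan(values).any():
        fill = np.nanmax(values)
        warnings.warn(
            f"imputing undefined distances with the matrix maximum {fill:.4f}",
            stacklevel=2,
        )
        values[np.isnan(values)] = fill
    np.fill_diagonal(values, 0.0)
    Z = hierarchy.linkage(squareform(values, checks=False), method=linkage)
    order = [dm.values.index[i] for i in hierarchy.leaves_list(Z)]
    return Z, order
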