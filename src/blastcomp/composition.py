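"""Cell-type composition tables, association tests, and clustering.

A dataset's cell-type composition (EPI_ICM / PE / TE counts, optionally
with an unknown column) is cross-tabulated against the founding cell
source (blastocyst, nPSC, EPSC, fibroblast) and tested for association
with the plain Pearson chi-squared statistic; datasets are further
clustered by their composition proportions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import chi2_contingency

from blastcomp.exceptions import DataError

PRIMARY_TYPES = ("EPI_ICM", "PE", "TE")


@dataclass
class AssociationResult:
    """Pearson chi-squared association between source and cell type."""

    statistic: float
    dof: int
    pvalue: float

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def composition_table(
    annotations: pd.DataFrame,
    source_map: dict[str, str] | None = None,
    include_unknown: bool = False,
    pool_pe_subtypes: bool = True,
    label_column: str = "consensus",
) -> pd.DataFrame:
    """Dataset x cell-type count table from per-cell annotations.

    ``annotations`` needs columns ``dataset_id`` and ``label_column``.
    PE subtype labels are pooled into PE by default (the primary
    composition test uses the three primary cell types); an ``unknown``
    column is appended when ``include_unknown``.
    """
    labels = annotations[label_column].astype(str)
    if pool_pe_subtypes:
        labels = labels.replace({"PE_I": "PE", "PE_II": "PE"})
    cols = list(PRIMARY_TYPES) + (["unknown"] if include_unknown else [])
    counts = (
        pd.crosstab(annotations["dataset_id"], labels)
        .reindex(columns=cols, fill_value=0)
        .astype(int)
    )
    empty = counts.sum(axis=1) == 0
    if empty.any():
        warnings.warn(
            f"datasets with zero qualifying cells: {list(counts.index[empty])}",
            stacklevel=2,
        )
    if source_map is not None:
        missing = set(counts.index) - set(source_map)
        if missing:
            raise DataError(f"datasets without a source annotation: {sorted(missing)}")
        counts.insert(0, "source", [source_map[d] for d in counts.index])
    return counts


def chi_squared_association(table: pd.DataFrame) -> AssociationResult:
    """Pearson chi-squared test of source x cell-type association.

    If the table carries a ``source`` column, datasets of the same
    source are pooled into one row first.  No continuity correction;
    expected counts come from the row/column marginals.
    """
    if "source" in table.columns:
        table = table.groupby("source").sum(numeric_only=True)
    arr = table.to_numpy(dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DataError("contingency table needs >= 2 rows and >= 2 columns")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DataError(
            "a row or column marginal is zero; remove the empty category"
        )
    stat, p, dof, _ = chi2_contingency(arr, correction=False)
    return AssociationResult(float(stat), int(dof), float(p))


def cluster_compositions(
    table: pd.DataFrame,
    k: int | None = None,
    linkage: str = "average",
    metric: str = "euclidean",
):
    """Agglomerative clustering of datasets on composition proportions.

    Rows are normalized to proportions first.  Returns
    ``(linkage_matrix, leaf_order, flat_groups)`` where ``flat_groups``
    is a Series of group ids at the requested ``k`` (None -> no cut).
    """
    counts = table.drop(columns="source", errors="ignore")
    if counts.shape[0] < 3:
        raise DataError("need at least 3 datasets to cluster compositions")
    if k is not None and k > counts.shape[0]:
        raise DataError(f"k={k} exceeds the number of datasets {counts.shape[0]}")
    arr = counts.to_numpy(dtype=float)
    sums = arr.sum(axis=1, keepdims=True)
    props = np.divide(arr, sums, out=np.zeros_like(arr), where=sums > 0)
    Z = hierarchy.linkage(pdist(props, metric=metric), method=linkage)
    order = [counts.index[i] for i in hierarchy.leaves_list(Z)]
    groups = None
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        groups = pd.Series(flat, index=counts.index, name="group")
    return Z, order, groups


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Render a SciPy linkage matrix as a Newick string."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, list(leaf_names))
    return str(tree).strip()
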