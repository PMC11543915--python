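"""Gene-set activity as the area under the recovery curve.

For each cell, genes are ranked by decreasing expression and the
activity of a gene set is the normalized area under the curve of set
genes recovered within the top fraction of the ranking — a rank-based,
depth-insensitive measure of coordinated set expression.  Ties (mostly
zero-expression genes) are broken by one seeded random permutation so
results are deterministic without systematic gene-order bias.
"""

from __future__ import annotations

from math import ceil

import numpy as np
import pandas as pd

from blastcomp.exceptions import DataError


def auc_activity(
    matrix: np.ndarray,
    gene_names,
    gene_set,
    top_fraction: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell normalized recovery-curve AUC of a gene set.

    With ``K = ceil(top_fraction * n_genes)`` and ``hits(k)`` the
    number of set genes in the top *k* ranks of a cell,
    ``raw = sum_{k=1..K} hits(k)`` and the output is ``raw`` divided by
    its maximum ``sum_{k=1..K} min(k, |set|)``, so a perfect top
    ranking scores 1 and no recovery scores 0.
    """
    gene_index = pd.Index(gene_names)
    member = np.zeros(len(gene_index), dtype=bool)
    found = [g for g in gene_set if g in gene_index]
    if not found:
        raise DataError(f"no genes of the set present in the matrix: {list(gene_set)[:5]}")
    for g in found:
        member[gene_index.get_loc(g)] = True

    n_genes = matrix.shape[1]
    K = ceil(top_fraction * n_genes)
    if K < 2:
        raise DataError("top_fraction yields fewer than 2 top ranks")
    s = int(member.sum())
    ks = np.arange(1, K + 1)
    denom = np.minimum(ks, s).sum()

    tiebreak = np.random.default_rng(seed).permutation(n_genes)
    out = np.empty(matrix.shape[0])
    for i in range(matrix.shape[0]):
        order = np.lexsort((tiebreak, -matrix[i]))
        hits = np.cumsum(member[order[:K]])
        out[i] = hits.sum() / denom
    return out


def activity_table(
    matrices: list[np.ndarray],
    gene_names_list: list,
    dataset_ids: list[str],
    cell_ids_list: list,
    gene_sets,
    top_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell x set AUC activity across datasets.

    Sets with no genes in a dataset's universe get NaN for that
    dataset's cells rather than failing the whole table.
    """
    frames = []
    for matrix, gene_names, ds_id, cell_ids in zip(
        matrices, gene_names_list, dataset_ids, cell_ids_list
    ):
        cols = {}
        for name, genes in gene_sets:
            try:
                cols[name] = auc_activity(
                    matrix, gene_names, genes, top_fraction=top_fraction, seed=seed
                )
            except DataError:
                cols[name] = np.full(matrix.shape[0], np.nan)
        df = pd.DataFrame(cols, index=pd.Index(cell_ids, name="cell_id"))
        df.insert(0, "dataset_id", ds_id)
        frames.append(df)
    return pd.concat(frames)


def aggregate_activity(activity: pd.DataFrame, grouping) -> pd.DataFrame:
    """Mean activity per (group, set); empty groups are absent, not zero.

    ``grouping`` is a per-cell label Series/array aligned with
    ``activity`` (cell type, cluster or dataset).  When the table has a
    ``dataset_id`` column the means are per (dataset, group) pair.
    """
    grouping = np.asarray(grouping)
    if len(grouping) != len(activity):
        raise DataError("grouping labels must cover all cells")
    df = activity.copy()
    df["_group"] = grouping
    keys = ["dataset_id", "_group"] if "dataset_id" in df.columns else ["_group"]
    out = df.groupby(keys, observed=True).mean(numeric_only=True)
    out.index.rename([k.lstrip("_") for k in keys], inplace=True)
    return out
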