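"""Consensus cell-type annotation and rank-sum marker genes.

Three independent annotators produce per-cell lineage labels:

* a cluster-level annotator that scores clusters by specificity-
  weighted marker z-scores,
* a per-cell annotator with a conservative margin rule, and
* a reference-based annotator correlating query cells with reference
  label centroids (Spearman).

The consensus is a simple majority vote — a cell keeps a label only
when at least two annotators agree, otherwise it is ``unknown``.  PE
cells are subsequently split into transcriptomic subtypes I/II by the
joint-landscape clusters they occupy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from blastcomp.exceptions import DataError
from blastcomp.markers import MarkerPanel
from blastcomp.scoring import select_variable_genes

UNKNOWN = "unknown"


def _zscore_genes(matrix: np.ndarray) -> np.ndarray:
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (matrix - mu) / sd


def _panel_positions(panel: MarkerPanel, gene_names) -> dict[str, np.ndarray]:
    gene_index = pd.Index(gene_names)
    out = {}
    for lineage, genes in panel:
        pos = [gene_index.get_loc(g) for g in genes if g in gene_index]
        out[lineage] = np.asarray(pos, dtype=int)
    return out


# ---------------------------------------------------------------------
# annotator 1: cluster-level weighted marker scoring
# ---------------------------------------------------------------------

def annotate_cluster_markers(
    matrix: np.ndarray,
    gene_names,
    clusters,
    panel: MarkerPanel,
    unknown_factor: float = 0.25,
    min_cluster_size: int = 3,
) -> np.ndarray:
    """Label whole clusters by specificity-weighted marker z-scores.

    Per cluster and lineage the score is the sum over cluster cells of
    the cells' weighted marker z-scores, where a gene listed by *m*
    lineages weighs ``1/sqrt(m)``.  The argmax lineage wins unless its
    score falls below ``cluster_size * unknown_factor``, in which case
    the cluster is ``unknown``.  All cells inherit their cluster label.
    """
    if not panel.names:
        raise DataError("empty marker panel")
    clusters = np.asarray(clusters)
    z = _zscore_genes(matrix)
    mult = panel.gene_multiplicity()
    pos = _panel_positions(panel, gene_names)
    gene_index = pd.Index(gene_names)

    # per-cell lineage scores (weighted sum of marker z-scores)
    cell_scores = np.zeros((matrix.shape[0], len(panel.names)))
    for li, lineage in enumerate(panel.names):
        if len(pos[lineage]) == 0:
            continue
        weights = np.array(
            [1.0 / np.sqrt(mult[gene_index[p]]) for p in pos[lineage]]
        )
        cell_scores[:, li] = z[:, pos[lineage]] @ weights

    labels = np.empty(matrix.shape[0], dtype=object)
    for c in np.unique(clusters):
        members = clusters == c
        size = int(members.sum())
        if size < min_cluster_size:
            warnings.warn(f"cluster {c} has {size} cells; labeled unknown",
                          stacklevel=2)
            labels[members] = UNKNOWN
            continue
        totals = cell_scores[members].sum(axis=0)
        top = int(np.argmax(totals))
        if totals[top] < size * unknown_factor:
            labels[members] = UNKNOWN
        else:
            labels[members] = panel.names[top]
    return labels


# ---------------------------------------------------------------------
# annotator 2: per-cell margin rule
# ---------------------------------------------------------------------

def annotate_cell_markers(
    matrix: np.ndarray,
    gene_names,
    panel: MarkerPanel,
    margin_cutoff: float = 0.25,
) -> np.ndarray:
    """High-specificity per-cell labels.

    Per cell the lineage score is the mean of z-scored marker
    expression; the argmax wins only when it is positive and beats the
    runner-up by at least ``margin_cutoff``, otherwise ``unknown``.
    """
    if not panel.names:
        raise DataError("empty marker panel")
    z = _zscore_genes(matrix)
    pos = _panel_positions(panel, gene_names)
    scores = np.full((matrix.shape[0], len(panel.names)), -np.inf)
    for li, lineage in enumerate(panel.names):
        if len(pos[lineage]):
            scores[:, li] = z[:, pos[lineage]].mean(axis=1)
    order = np.argsort(-scores, axis=1)
    top = order[:, 0]
    top_val = scores[np.arange(len(top)), top]
    second_val = scores[np.arange(len(top)), order[:, 1]]
    ok = (top_val - second_val >= margin_cutoff) & (top_val > 0)
    labels = np.where(ok, np.asarray(panel.names, dtype=object)[top], UNKNOWN)
    return labels.astype(object)


# ---------------------------------------------------------------------
# annotator 3: reference centroid correlation
# ---------------------------------------------------------------------

def annotate_by_reference(
    query_matrix: np.ndarray,
    query_genes,
    ref_matrix: np.ndarray,
    ref_genes,
    ref_labels,
    delta_cutoff: float = 0.05,
    n_top_genes: int = 2000,
    min_shared_genes: int = 50,
    min_label_cells: int = 3,
) -> np.ndarray:
    """Label query cells by Spearman correlation to reference centroids.

    Centroids are per-gene means over each reference label's cells on
    the reference's top variable genes (within the shared gene
    universe).  Both sides are standardized per gene with the
    *reference's* mean and deviation, so the correlation reflects
    deviation from the baseline expression profile rather than the
    (shared) mean-expression structure that would otherwise make every
    centroid look alike.  A query
    cell is ``unknown`` when its best correlation does not exceed the
    median correlation by ``delta_cutoff``.
    """
    query_genes = pd.Index(query_genes)
    ref_genes = pd.Index(ref_genes)
    shared = query_genes.intersection(ref_genes)
    if len(shared) < min_shared_genes:
        raise DataError(
            f"only {len(shared)} shared genes between query and reference"
        )
    q_pos = [query_genes.get_loc(g) for g in shared]
    r_pos = [ref_genes.get_loc(g) for g in shared]
    Q = query_matrix[:, q_pos]
    R = ref_matrix[:, r_pos]

    ref_labels = np.asarray(ref_labels)
    counts = pd.Series(ref_labels).value_counts()
    usable = [l for l in counts.index if counts[l] >= min_label_cells]
    if len(usable) < 2:
        raise DataError("reference needs >= 2 labels with >= 3 cells each")

    var_rank = select_variable_genes(R, n_top=min(n_top_genes, R.shape[1]))
    R, Q = R[:, var_rank], Q[:, var_rank]
    mu = R.mean(axis=0)
    sd = R.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    R = (R - mu) / sd
    Q = (Q - mu) / sd

    centroids = np.vstack([R[ref_labels == l].mean(axis=0) for l in usable])
    c_ranks = np.vstack([rankdata(c) for c in centroids])
    c_ranks = c_ranks - c_ranks.mean(axis=1, keepdims=True)
    c_norm = np.linalg.norm(c_ranks, axis=1)

    labels = np.empty(Q.shape[0], dtype=object)
    for i in range(Q.shape[0]):
        q = rankdata(Q[i])
        q = q - q.mean()
        qn = np.linalg.norm(q)
        if qn == 0:
            labels[i] = UNKNOWN
            continue
        corr = (c_ranks @ q) / (c_norm * qn)
        best = int(np.argmax(corr))
        if corr[best] - np.median(corr) < delta_cutoff:
            labels[i] = UNKNOWN
        else:
            labels[i] = usable[best]
    return labels


# ---------------------------------------------------------------------
# consensus and refinement
# ---------------------------------------------------------------------

def consensus_vote(labels_a, labels_b, labels_c) -> np.ndarray:
    """Majority vote per cell; no majority (all three differ) -> unknown.

    ``unknown`` counts as an ordinary label: two annotators agreeing on
    ``unknown`` outvote a third with a lineage.
    """
    a, b, c = (np.asarray(x, dtype=object) for x in (labels_a, labels_b, labels_c))
    if not (len(a) == len(b) == len(c)):
        raise DataError("annotator label vectors differ in length")
    out = np.full(len(a), UNKNOWN, dtype=object)
    out[b == c] = b[b == c]
    out[a == c] = a[a == c]
    out[a == b] = a[a == b]
    return out


def refine_pe_subtypes(labels, clusters, subtype2_clusters) -> np.ndarray:
    """Split PE cells into subtypes by landscape cluster membership.

    PE cells sitting in ``subtype2_clusters`` become ``PE_II``; all
    other PE cells become ``PE_I``.  Non-PE labels pass through.
    """
    labels = np.asarray(labels, dtype=object).copy()
    clusters = np.asarray(clusters)
    s2 = set(subtype2_clusters)
    pe = labels == "PE"
    in_s2 = np.array([c in s2 for c in clusters])
    labels[pe & in_s2] = "PE_II"
    labels[pe & ~in_s2] = "PE_I"
    return labels


def build_annotation_table(
    cell_ids, dataset_ids, annotator_cluster, annotator_cell, annotator_ref
) -> pd.DataFrame:
    """Assemble the per-cell annotation table including the consensus."""
    consensus = consensus_vote(annotator_cluster, annotator_cell, annotator_ref)
    return pd.DataFrame(
        {
            "dataset_id": np.asarray(dataset_ids),
            "annotator_cluster": np.asarray(annotator_cluster, dtype=object),
            "annotator_cell": np.asarray(annotator_cell, dtype=object),
            "annotator_ref": np.asarray(annotator_ref, dtype=object),
            "consensus": consensus,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )


# ---------------------------------------------------------------------
# rank-sum differential expression
# ---------------------------------------------------------------------

DEFAULT_EXCLUSION_PREFIXES = ("MT-", "RPS", "RPL")


def rank_sum_markers(
    matrix: np.ndarray,
    gene_names,
    groups,
    exclusion_prefixes=DEFAULT_EXCLUSION_PREFIXES,
) -> pd.DataFrame:
    """Wilcoxon rank-sum marker genes per group versus the rest.

    Mitochondrial/ribosomal genes (prefix match on symbols) are removed
    first.  The two-sided test uses the normal approximation with tie
    correction; the log fold change is
    ``ln(mean expm1(in) + 1) - ln(mean expm1(rest) + 1)`` (the usual
    convention for log1p-normalized data); BH adjustment within each
    group's gene list.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise DataError("rank_sum_markers needs at least 2 groups")
    for g in uniq:
        if (groups == g).sum() < 3:
            raise DataError(f"group {g!r} has fewer than 3 cells")

    gene_names = np.asarray(gene_names, dtype=str)
    excluded = np.zeros(len(gene_names), dtype=bool)
    for pref in exclusion_prefixes:
        excluded |= np.char.startswith(gene_names, pref)
    keep = ~excluded
    X = matrix[:, keep]
    names = gene_names[keep]

    frames = []
    for g in uniq:
        in_mask = groups == g
        a, b = X[in_mask], X[~in_mask]
        with np.errstate(invalid="ignore", divide="ignore"):
            res = mannwhitneyu(a, b, axis=0, alternative="two-sided",
                               method="asymptotic")
        # a gene with every value tied has zero rank variance: no evidence
        pvalue = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        lfc = np.log(np.expm1(a).mean(axis=0) + 1.0) - np.log(
            np.expm1(b).mean(axis=0) + 1.0
        )
        padj = multipletests(pvalue, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "gene": names,
                    "statistic": res.statistic,
                    "log_fold_change": lfc,
                    "pvalue": pvalue,
                    "padj": padj,
                    "excluded_mito_ribo": False,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_excluded_genes"] = int(excluded.sum())
    return out
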