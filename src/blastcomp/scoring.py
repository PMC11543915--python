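"""Normalization, variable genes, covariate residualization, module scores.

The lineage module score follows the bin-matched-control design: the
per-cell mean expression of a marker set minus the mean of control
genes sampled from the same average-expression bins, so the score is
centred at zero for a cell with no specific marker enrichment whatever
its depth.  Scores come in three variants: raw, min-max over the full
integrated cell set (for qualitative landscape views), and z-scaled
within each dataset (for quantitative cross-dataset distribution
comparison, which must be location/scale-free per dataset).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from blastcomp.dataset import ExpressionDataset
from blastcomp.exceptions import DataError
from blastcomp.markers import MarkerPanel


@dataclass
class ModuleScoreTable:
    """Cell x module scores with variant tag and provenance."""

    scores: pd.DataFrame           # index: cell ids; columns: module names
    dataset_ids: pd.Series         # aligned to scores.index
    variant: str = "raw"           # raw | minmax | zscaled_by_dataset
    provenance: dict = field(default_factory=dict)

    def module(self, name: str) -> pd.Series:
        return self.scores[name]

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out.insert(0, "dataset_id", self.dataset_ids.to_numpy())
        out.to_csv(path, sep="\t", index_label="cell_id", float_format="%.10g")


# ---------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------

def log_normalize(ds: ExpressionDataset, scale_factor: float = 1e4) -> np.ndarray:
    """Pseudo-log normalization.

    UMI: ``ln(1 + count * scale_factor / cell_total)``; TPM: ``ln(1 + tpm)``.
    """
    if ds.platform == "umi":
        totals = ds.X.sum(axis=1)
        if np.any(totals <= 0):
            raise DataError(
                f"{ds.dataset_id}: cell with zero total counts (run QC first)"
            )
        return np.log1p(ds.X * (scale_factor / totals[:, None]))
    return np.log1p(ds.X)


# ---------------------------------------------------------------------
# variable genes
# ---------------------------------------------------------------------

def select_variable_genes(matrix: np.ndarray, n_top: int = 3000) -> np.ndarray:
    """Rank genes by variance standardized against a mean trend.

    Fits a degree-2 polynomial of log variance on log mean over the
    expressed, non-constant genes and ranks genes by their residual.
    Returns the positions of the top ``n_top`` genes (all of them, with
    a warning, if fewer are available).  Zero-variance genes are never
    selected.
    """
    mean = matrix.mean(axis=0)
    var = matrix.var(axis=0, ddof=1) if matrix.shape[0] > 1 else np.zeros_like(mean)
    usable = (mean > 0) & (var > 0)
    if int((mean > 0).sum()) < 10:
        raise DataError("fewer than 10 expressed genes; variance trend unfittable")
    lm, lv = np.log(mean[usable]), np.log(var[usable])
    coef = np.polyfit(lm, lv, deg=2)
    resid = lv - np.polyval(coef, lm)
    order = np.argsort(-resid, kind="stable")  # ties by gene index
    ranked = np.where(usable)[0][order]
    if n_top > len(ranked):
        warnings.warn(
            f"requested {n_top} variable genes but only {len(ranked)} usable",
            stacklevel=2,
        )
        return ranked
    return ranked[:n_top]


# ---------------------------------------------------------------------
# covariate residualization
# ---------------------------------------------------------------------

def residualize_covariates(
    matrix: np.ndarray, covariates: pd.DataFrame, clip: float = 10.0
) -> np.ndarray:
    """Regress covariates out of every gene, z-score residuals, clip.

    Ordinary least squares per gene on the covariates plus an
    intercept; residuals are z-scored per gene and clipped at
    ``+/- clip``.  Later columns that are collinear with earlier ones
    are dropped with a warning.
    """
    cov = covariates.to_numpy(dtype=float)
    if not np.all(np.isfinite(cov)):
        raise DataError("covariates contain non-finite values")
    n_cells = matrix.shape[0]
    design = [np.ones(n_cells)]
    kept_rank = 1
    for j, col in enumerate(cov.T):
        trial = np.column_stack(design + [col])
        rank = np.linalg.matrix_rank(trial)
        if rank <= kept_rank:
            warnings.warn(
                f"covariate column {covariates.columns[j]!r} is collinear; dropped",
                stacklevel=2,
            )
            continue
        design.append(col)
        kept_rank = rank
    D = np.column_stack(design)
    if n_cells < D.shape[1] + 2:
        raise DataError("need at least 2 more cells than covariates")
    beta, *_ = np.linalg.lstsq(D, matrix, rcond=None)
    resid = matrix - D @ beta
    sd = resid.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 1e-12, resid / np.where(sd > 0, sd, 1.0), 0.0)
    return np.clip(z, -clip, clip)


# ---------------------------------------------------------------------
# module score
# ---------------------------------------------------------------------

def module_score(
    matrix: np.ndarray,
    gene_names,
    gene_set,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Bin-matched-control module score per cell.

    Genes are ordered by across-cell average expression (ties broken by
    gene index) and split into ``n_bins`` equal-frequency bins.  Each
    present set gene draws ``n_ctrl`` control genes from its bin
    without replacement (with replacement when the bin is smaller).
    The score is the mean expression of the set genes minus the mean
    over all sampled control genes.
    """
    gene_names = pd.Index(gene_names)
    positions = [gene_names.get_loc(g) for g in gene_set if g in gene_names]
    missing = [g for g in gene_set if g not in gene_names]
    if not positions:
        raise DataError(f"no genes of set {list(gene_set)[:5]}... present in matrix")
    if missing:
        warnings.warn(f"{len(missing)} set genes absent from matrix; dropped",
                      stacklevel=2)

    n_genes = matrix.shape[1]
    avg = matrix.mean(axis=0)
    order = np.lexsort((np.arange(n_genes), avg))  # ties by gene index
    bin_of = np.empty(n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b

    rng = np.random.default_rng(seed)
    ctrl: list[np.ndarray] = []
    for pos in positions:
        members = np.where(bin_of == bin_of[pos])[0]
        replace = len(members) < n_ctrl
        ctrl.append(rng.choice(members, size=n_ctrl, replace=replace))
    ctrl_idx = np.concatenate(ctrl)
    return matrix[:, positions].mean(axis=1) - matrix[:, ctrl_idx].mean(axis=1)


def compute_module_scores(
    matrices: list[np.ndarray],
    gene_names_list: list,
    dataset_ids: list[str],
    cell_ids_list: list,
    panel: MarkerPanel,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreTable:
    """Per-dataset module scores for every panel lineage, stacked.

    Scores are computed within each dataset on its own normalized
    matrix (bins are depth- and platform-specific); lineages with no
    genes present in a dataset get NaN there.
    """
    frames = []
    for matrix, gene_names, ds_id, cell_ids in zip(
        matrices, gene_names_list, dataset_ids, cell_ids_list
    ):
        cols = {}
        for lineage, genes in panel:
            gene_index = pd.Index(gene_names)
            if not any(g in gene_index for g in genes):
                cols[lineage] = np.full(matrix.shape[0], np.nan)
                continue
            cols[lineage] = module_score(
                matrix, gene_names, genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed
            )
        df = pd.DataFrame(cols, index=pd.Index(cell_ids, name="cell_id"))
        df.insert(0, "dataset_id", ds_id)
        frames.append(df)
    stacked = pd.concat(frames)
    panel_hash = hashlib.sha256(
        repr(sorted((k, tuple(v)) for k, v in panel)).encode()
    ).hexdigest()[:12]
    return ModuleScoreTable(
        scores=stacked.drop(columns="dataset_id"),
        dataset_ids=stacked["dataset_id"],
        variant="raw",
        provenance={
            "panel_hash": panel_hash,
            "n_bins": n_bins,
            "n_ctrl": n_ctrl,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------
# score transforms
# ---------------------------------------------------------------------

def minmax(values) -> np.ndarray:
    """Map to [0, 1] by (x - min) / (max - min); constant input -> zeros."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def minmax_table(table: ModuleScoreTable) -> ModuleScoreTable:
    """Min-max each module over the full integrated cell set."""
    out = table.scores.apply(lambda c: pd.Series(minmax(c.to_numpy()), index=c.index))
    return ModuleScoreTable(out, table.dataset_ids, "minmax", dict(table.provenance))


def zscale_per_dataset(table: ModuleScoreTable) -> ModuleScoreTable:
    """Center and scale each module within each dataset.

    Uses the sample standard deviation (ddof=1); a zero-variance module
    within a dataset maps to all zeros with a warning.
    """
    scores = table.scores.copy()
    for ds_id, idx in scores.groupby(table.dataset_ids).groups.items():
        block = scores.loc[idx]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        zero = sd.fillna(0.0) == 0
        if zero.any():
            warnings.warn(
                f"{ds_id}: zero-variance modules {list(sd.index[zero])} set to 0",
                stacklevel=2,
            )
        sd = sd.where(~zero, 1.0)
        scored = (block - mu) / sd
        scored.loc[:, zero[zero].index] = 0.0
        scores.loc[idx] = scored
    return ModuleScoreTable(
        scores, table.dataset_ids, "zscaled_by_dataset", dict(table.provenance)
    )
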