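"""The per-study expression container.

One :class:`ExpressionDataset` holds a single study's cells-by-genes
matrix plus per-cell metadata.  The internal orientation is always
cells x genes; on-disk formats that store features as rows are
transposed by the readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from blastcomp.exceptions import DataError

PLATFORMS = ("umi", "tpm")
TPM_CELL_SUM = 1e6


@dataclass
class ExpressionDataset:
    """A single study's cell-by-gene expression matrix with metadata.

    Attributes
    ----------
    dataset_id : str
        Stable identifier of the study (e.g. accession or short name).
    platform : {"umi", "tpm"}
        Quantification type: UMI counts (droplet) or TPM (plate-based).
    X : np.ndarray
        Dense cells x genes matrix of non-negative values.
    obs : pd.DataFrame
        Per-cell metadata indexed by cell id.  Standard columns:
        ``n_features``, ``total_counts``, ``mito_fraction``; optional
        ``true_type`` and ``intermediate_weight`` on synthetic data.
    var : pd.DataFrame
        Per-gene table indexed by stable gene id; optional ``symbol``
        column with display symbols.
    meta : dict
        Free-form provenance (generator parameters, QC log, ...).
    """

    dataset_id: str
    platform: str
    X: np.ndarray
    obs: pd.DataFrame
    var: pd.DataFrame
    meta: dict = field(default_factory=dict)

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.obs.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.var.index

    @property
    def symbols(self) -> pd.Index:
        """Display symbols where available, else the stable gene ids."""
        if "symbol" in self.var.columns:
            sym = self.var["symbol"].astype(str)
            sym = sym.where(sym.notna() & (sym != ""), self.var.index.astype(str))
            return pd.Index(sym.to_numpy())
        return pd.Index(self.var.index.astype(str))

    # -- QC metrics -----------------------------------------------------
    def recompute_metrics(self) -> "ExpressionDataset":
        """Recompute ``n_features`` and ``total_counts`` from the matrix."""
        self.obs["n_features"] = (self.X > 0).sum(axis=1).astype(int)
        self.obs["total_counts"] = self.X.sum(axis=1).astype(float)
        return self

    def validate(self, check_tpm_sum: bool = True) -> None:
        """Check container invariants; raise :class:`DataError` on violation."""
        if self.platform not in PLATFORMS:
            raise DataError(f"unknown platform {self.platform!r}")
        if self.X.shape != (len(self.obs), len(self.var)):
            raise DataError(
                f"{self.dataset_id}: matrix shape {self.X.shape} does not match "
                f"obs/var ({len(self.obs)}, {len(self.var)})"
            )
        if np.any(self.X < 0):
            raise DataError(f"{self.dataset_id}: negative expression values")
        if self.obs.index.has_duplicates:
            raise DataError(f"{self.dataset_id}: duplicate cell ids")
        if self.var.index.has_duplicates:
            raise DataError(f"{self.dataset_id}: duplicate gene ids")
        if "n_features" in self.obs:
            nf = (self.X > 0).sum(axis=1)
            if not np.array_equal(nf, self.obs["n_features"].to_numpy()):
                raise DataError(f"{self.dataset_id}: stored n_features stale")
        if "total_counts" in self.obs:
            tc = self.X.sum(axis=1)
            if not np.allclose(tc, self.obs["total_counts"].to_numpy(), rtol=1e-9):
                raise DataError(f"{self.dataset_id}: stored total_counts stale")
        if check_tpm_sum and self.platform == "tpm" and not self.meta.get("qc_filtered"):
            sums = self.X.sum(axis=1)
            if not np.allclose(sums, TPM_CELL_SUM, rtol=1e-3):
                raise DataError(
                    f"{self.dataset_id}: TPM per-cell sums deviate from 1e6"
                )

    # -- slicing --------------------------------------------------------
    def subset(self, cells=None, genes=None) -> "ExpressionDataset":
        """Return a new dataset restricted to the given cell/gene positions."""
        cell_idx = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        gene_idx = np.arange(self.n_genes) if genes is None else np.asarray(genes)
        return ExpressionDataset(
            dataset_id=self.dataset_id,
            platform=self.platform,
            X=self.X[np.ix_(cell_idx, gene_idx)].copy(),
            obs=self.obs.iloc[cell_idx].copy(),
            var=self.var.iloc[gene_idx].copy(),
            meta=dict(self.meta),
        )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            self.dataset_id, self.platform, self.X.copy(),
            self.obs.copy(), self.var.copy(), dict(self.meta),
        )
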