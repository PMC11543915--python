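"""Reading, isoform collapsing and quality-control filtering.

Readers accept the 10x-style Matrix Market triplet (``matrix.mtx`` +
``barcodes.tsv`` + ``features.tsv``, features as rows) and dense TSV
matrices (header row of cell ids, first column gene ids); both are
transposed to the internal cells x genes orientation.

QC follows the standard outline for cross-study comparison: drop genes
detected in fewer than 10 cells, drop cells with fewer than 100
detected genes, drop cells with a mitochondrial read fraction above
20%, and — for UMI data only — drop cells outside density-inflection
thresholds on total counts (TPM cells all sum to ~1e6, so a counts
filter carries no information there).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from scipy.stats import gaussian_kde

from blastcomp.dataset import ExpressionDataset
from blastcomp.exceptions import DataError, EmptyDatasetError, FormatError

# ---------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------

def read_dataset(path, format: str, platform: str, dataset_id: str | None = None
                 ) -> ExpressionDataset:
    """Read an expression matrix from disk.

    Parameters
    ----------
    path
        Directory of the MTX triplet, or the dense TSV file.
    format : {"mtx_triplet", "dense_tsv"}
    platform : {"umi", "tpm"}
    dataset_id
        Defaults to the directory / file stem.
    """
    path = Path(path)
    if dataset_id is None:
        dataset_id = path.stem if path.is_file() else path.name
    if format == "mtx_triplet":
        X, obs_index, var = _read_mtx_triplet(path)
    elif format == "dense_tsv":
        X, obs_index, var = _read_dense_tsv(path)
    else:
        raise FormatError(f"unknown format {format!r}")
    if np.any(X < 0):
        raise DataError(f"{dataset_id}: negative entries in expression matrix")
    obs = pd.DataFrame(index=obs_index)
    obs["dataset_id"] = dataset_id
    ds = ExpressionDataset(dataset_id, platform, X, obs, var)
    ds.recompute_metrics()
    return ds


def _read_mtx_triplet(path: Path):
    mtx = path / "matrix.mtx"
    barcodes = path / "barcodes.tsv"
    features = path / "features.tsv"
    for f in (mtx, barcodes, features):
        if not f.exists():
            raise FormatError(f"missing file {f}")
    M = spio.mmread(mtx)  # features x cells on disk
    M = sparse.csr_matrix(M)
    cell_ids = [ln.split("\t")[0] for ln in _read_lines(barcodes)]
    feat_rows = [ln.split("\t") for ln in _read_lines(features)]
    if M.shape[1] != len(cell_ids):
        raise FormatError(
            f"{barcodes}: {len(cell_ids)} barcodes but matrix has {M.shape[1]} columns"
        )
    if M.shape[0] != len(feat_rows):
        raise FormatError(
            f"{features}: {len(feat_rows)} features but matrix has {M.shape[0]} rows"
        )
    var = pd.DataFrame(index=pd.Index([r[0] for r in feat_rows], name="gene_id"))
    if feat_rows and len(feat_rows[0]) > 1:
        var["symbol"] = [r[1] for r in feat_rows]
    X = np.asarray(M.T.todense(), dtype=float)
    return X, pd.Index(cell_ids, name="cell_id"), var


def _read_lines(path: Path) -> list[str]:
    return [ln for ln in path.read_text().splitlines() if ln.strip()]


def _read_dense_tsv(path: Path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name is None:
        df.index.name = "gene_id"
    var = pd.DataFrame(index=pd.Index(df.index.astype(str), name="gene_id"))
    X = df.to_numpy(dtype=float).T  # file is genes x cells
    return X, pd.Index(df.columns.astype(str), name="cell_id"), var


def write_dataset(ds: ExpressionDataset, path, format: str) -> None:
    """Write a dataset as an MTX triplet directory or a dense TSV file."""
    path = Path(path)
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(ds.X.T))
        (path / "barcodes.tsv").write_text("\n".join(ds.cell_ids) + "\n")
        if "symbol" in ds.var.columns:
            lines = [f"{g}\t{s}" for g, s in zip(ds.gene_ids, ds.var["symbol"])]
        else:
            lines = list(ds.gene_ids)
        (path / "features.tsv").write_text("\n".join(lines) + "\n")
    elif format == "dense_tsv":
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.is_dir() or path.suffix == "":
            path.mkdir(parents=True, exist_ok=True)
            path = path / "matrix.tsv"
        df = pd.DataFrame(ds.X.T, index=ds.gene_ids, columns=ds.cell_ids)
        df.to_csv(path, sep="\t", float_format="%.10g")
    else:
        raise FormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------
# isoform collapsing
# ---------------------------------------------------------------------

def collapse_isoforms(ds: ExpressionDataset, tx2gene: pd.DataFrame
                      ) -> ExpressionDataset:
    """Sum transcript rows that map to the same gene id.

    ``tx2gene`` has columns ``transcript_id``, ``gene_id`` and optional
    ``symbol``.  Transcripts absent from the map are dropped and their
    count is recorded in ``meta["n_unmapped_transcripts"]`` — annotation
    version mismatches are routine, not errors.  Per-cell totals over
    mapped transcripts are preserved exactly.
    """
    tx2gene = tx2gene.set_index("transcript_id") if "transcript_id" in tx2gene else tx2gene
    mapped = ds.gene_ids.isin(tx2gene.index)
    n_unmapped = int((~mapped).sum())
    if n_unmapped:
        warnings.warn(
            f"{ds.dataset_id}: dropped {n_unmapped} unmapped transcripts",
            stacklevel=2,
        )
    keep = np.where(mapped)[0]
    sub_tx = ds.gene_ids[keep]
    gene_of = tx2gene.loc[sub_tx, "gene_id"].to_numpy()
    genes, inverse = np.unique(gene_of, return_inverse=True)
    agg = np.zeros((ds.n_cells, len(genes)))
    np.add.at(agg.T, inverse, ds.X[:, keep].T)
    var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    if "symbol" in tx2gene.columns:
        sym_map = tx2gene.loc[sub_tx]
        sym = (
            pd.Series(sym_map["symbol"].to_numpy(), index=sym_map["gene_id"].to_numpy())
            .groupby(level=0)
            .first()
        )
        var["symbol"] = sym.reindex(genes).fillna(pd.Series(genes, index=genes)).to_numpy()
    out = ExpressionDataset(
        ds.dataset_id, ds.platform, agg, ds.obs.copy(), var,
        {**ds.meta, "n_unmapped_transcripts": n_unmapped},
    )
    out.recompute_metrics()
    return out


# ---------------------------------------------------------------------
# density-inflection thresholds
# ---------------------------------------------------------------------

def density_inflection_threshold(
    values,
    side: str = "lower",
    min_n: int = 50,
    fallback_quantile: float | None = None,
    grid_size: int = 512,
) -> float:
    """Threshold at the density minimum between the two largest modes.

    A Gaussian KDE (Silverman bandwidth) is fit on ``log10(v + 1)``; if
    the density is bimodal the threshold is placed at the minimum
    between the two highest modes, analogous to knee-inflection
    thresholds for empty-droplet detection.  Unimodal, tiny (< min_n)
    or constant inputs fall back to a configured quantile (default 0.01
    for ``side="lower"``, 0.99 for ``side="upper"``).
    """
    values = np.asarray(values, dtype=float)
    if side not in ("lower", "upper"):
        raise ValueError("side must be 'lower' or 'upper'")
    if fallback_quantile is None:
        fallback_quantile = 0.01 if side == "lower" else 0.99

    def fallback(reason: str) -> float:
        warnings.warn(
            f"density_inflection_threshold: falling back to quantile "
            f"{fallback_quantile} ({reason})",
            stacklevel=3,
        )
        return float(np.quantile(values, fallback_quantile))

    if len(values) < min_n:
        return fallback(f"only {len(values)} values")
    logv = np.log10(values + 1.0)
    if np.ptp(logv) == 0:
        return fallback("all values identical")
    kde = gaussian_kde(logv, bw_method="silverman")
    grid = np.linspace(logv.min(), logv.max(), grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    peaks = interior[(dens[interior] > dens[interior - 1])
                     & (dens[interior] >= dens[interior + 1])]
    if len(peaks) < 2:
        return fallback("density is unimodal")
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = np.sort(top2)
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    # genuine bimodality: the valley must dip well below both modes
    # (local KDE wiggles are not density inflections)
    if dens[valley] > 0.5 * min(dens[lo], dens[hi]):
        return fallback("no clear density inflection between modes")
    return float(10 ** grid[valley] - 1.0)


# ---------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------

@dataclass
class QCConfig:
    """Thresholds for :func:`qc_filter`; boundaries are strict per rule text."""

    min_cells_per_gene: int = 10   # genes detected in fewer cells are removed
    min_features_per_cell: int = 100  # cells with fewer detected genes removed
    mito_threshold: float = 0.20   # cells with fraction strictly above removed
    counts_filter: str = "auto"    # "auto" (UMI only) | "on" | "off"
    counts_lower: float | None = None  # None -> density inflection
    counts_upper: float | None = None
    reiterate: bool = False        # repeat until fixed point


@dataclass
class QCReport:
    """Ledger of what a QC pass removed and why."""

    dataset_id: str
    thresholds: dict
    input_cells: int
    input_genes: int
    removed: dict = field(default_factory=dict)
    retained_cells: int = 0
    retained_genes: int = 0
    counts_filter_skipped: bool = False

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def check(self) -> None:
        gene_removed = self.removed.get("genes_min_cells", 0)
        cell_removed = sum(
            v for k, v in self.removed.items() if k.startswith("cells_")
        )
        assert self.retained_genes + gene_removed == self.input_genes
        assert self.retained_cells + cell_removed == self.input_cells


def qc_filter(ds: ExpressionDataset, config: QCConfig | None = None
              ) -> tuple[ExpressionDataset, QCReport]:
    """Apply the outlier filters; returns the filtered dataset and a report.

    Order: gene min-cell filter first, then the cell filters (detected
    features, mitochondrial fraction, and — UMI only by default —
    density-inflection bounds on total counts).  A single pass by
    default; ``config.reiterate`` repeats to a fixed point.
    """
    config = config or QCConfig()
    report = QCReport(
        dataset_id=ds.dataset_id,
        thresholds={},
        input_cells=ds.n_cells,
        input_genes=ds.n_genes,
    )
    out = _qc_pass(ds, config, report)
    if config.reiterate:
        for _ in range(10):
            before = out.X.shape
            sub = QCReport(ds.dataset_id, {}, out.n_cells, out.n_genes)
            out = _qc_pass(out, config, sub)
            for k, v in sub.removed.items():
                report.removed[k] = report.removed.get(k, 0) + v
            if out.X.shape == before:
                break
    out.meta["qc_filtered"] = True
    report.retained_cells, report.retained_genes = out.X.shape
    report.check()
    return out, report


def _qc_pass(ds, config, report) -> ExpressionDataset:
    detected = ds.X > 0

    # 1. gene filter: detected in fewer than N cells (strict <)
    gene_keep = detected.sum(axis=0) >= config.min_cells_per_gene
    report.removed["genes_min_cells"] = int((~gene_keep).sum())
    report.thresholds["min_cells_per_gene"] = config.min_cells_per_gene
    X = ds.X[:, gene_keep]

    # 2. cell filters, computed on the gene-filtered matrix
    n_feat = (X > 0).sum(axis=1)
    totals = X.sum(axis=1)
    keep = np.ones(ds.n_cells, dtype=bool)

    feat_fail = n_feat < config.min_features_per_cell
    report.removed["cells_min_features"] = int(feat_fail.sum())
    report.thresholds["min_features_per_cell"] = config.min_features_per_cell
    keep &= ~feat_fail
    if not keep.any():
        raise EmptyDatasetError(
            f"{ds.dataset_id}: min-features filter removed every cell"
        )

    mito = ds.obs.get("mito_fraction")
    if mito is not None:
        mito_fail = mito.to_numpy() > config.mito_threshold  # strict >
        report.removed["cells_mito"] = int((mito_fail & keep).sum())
        report.thresholds["mito_threshold"] = config.mito_threshold
        keep &= ~mito_fail
        if not keep.any():
            raise EmptyDatasetError(
                f"{ds.dataset_id}: mitochondrial filter removed every cell"
            )
    else:
        report.removed["cells_mito"] = 0

    apply_counts = (
        config.counts_filter == "on"
        or (config.counts_filter == "auto" and ds.platform == "umi")
    )
    if apply_counts:
        surviving = totals[keep]
        # fallback quantiles 0/1: when no density inflection exists the
        # counts filter removes nothing (keeps reapplication idempotent)
        lo = (config.counts_lower if config.counts_lower is not None
              else density_inflection_threshold(surviving, side="lower",
                                                fallback_quantile=0.0))
        hi = (config.counts_upper if config.counts_upper is not None
              else density_inflection_threshold(surviving, side="upper",
                                                fallback_quantile=1.0))
        report.thresholds["counts_lower"] = float(lo)
        report.thresholds["counts_upper"] = float(hi)
        low_fail = (totals < lo) & keep
        high_fail = (totals > hi) & keep
        report.removed["cells_counts_low"] = int(low_fail.sum())
        report.removed["cells_counts_high"] = int(high_fail.sum())
        keep &= ~(low_fail | high_fail)
        if not keep.any():
            raise EmptyDatasetError(
                f"{ds.dataset_id}: counts filter removed every cell"
            )
    else:
        report.counts_filter_skipped = True
        report.thresholds["counts_filter"] = "skipped"
        report.removed["cells_counts_low"] = 0
        report.removed["cells_counts_high"] = 0

    out = ExpressionDataset(
        ds.dataset_id, ds.platform,
        X[keep].copy(),
        ds.obs.loc[keep].copy(),
        ds.var.loc[gene_keep].copy(),
        dict(ds.meta),
    )
    out.recompute_metrics()
    return out
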