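"""Synthetic multi-dataset scRNA-seq cohorts with known ground truth.

The generator emulates the statistical structure the comparative
analysis assumes: several studies of differing size and platform (UMI
counts vs TPM), planted lineages with marker-gene overexpression,
composition archetypes (balanced, EPI-enriched, PE-enriched), per-cell
mitochondrial fractions, and intermediate cells whose expression is a
convex mixture of two lineage programs.

Model
-----
Every gene has a log-normal baseline mean shared across datasets; each
dataset applies a multiplicative log-normal batch shift.  A lineage
*program* multiplies its marker genes' means by
``exp(marker_log_fold_change)`` and is normalized to a probability
vector over genes, so an intermediate cell with mixture weight *w* has
expected relative expression exactly ``w * p_A + (1 - w) * p_B``.  UMI
counts are negative binomial with fixed gene-level dispersion around a
per-cell library depth; TPM cells are noisy program draws rescaled to
sum to 1e6.  Mitochondrial fractions are Beta draws recorded as
metadata, with an option to also inflate a designated ``MT-`` gene
block so the QC filter path is exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from blastcomp.dataset import ExpressionDataset, TPM_CELL_SUM
from blastcomp.exceptions import SpecError
from blastcomp.markers import DEFAULT_MARKERS

CELL_TYPES = ("EPI_ICM", "PE_I", "PE_II", "TE", "intermediate_EPI_TE")
#: lineage programs planted in the data; PE_II carries PE plus AMN markers.
PROGRAMS = ("EPI_ICM", "PE", "TE", "AMN")
ARCHETYPES = ("balanced", "epi_enriched", "pe_enriched")

#: Proportions over the four concrete types before the intermediate
#: fraction is folded in.
_ARCHETYPE_BASE = {
    "balanced": {"EPI_ICM": 0.34, "PE_I": 0.27, "PE_II": 0.04, "TE": 0.35},
    "epi_enriched": {"EPI_ICM": 0.62, "PE_I": 0.12, "PE_II": 0.04, "TE": 0.22},
    "pe_enriched": {"EPI_ICM": 0.16, "PE_I": 0.34, "PE_II": 0.28, "TE": 0.22},
}


def archetype_composition(name: str, intermediate_fraction: float = 0.10) -> dict:
    """Composition vector over all cell types for a named archetype."""
    if name not in _ARCHETYPE_BASE:
        raise SpecError(f"unknown composition archetype {name!r}")
    base = _ARCHETYPE_BASE[name]
    comp = {t: p * (1.0 - intermediate_fraction) for t, p in base.items()}
    comp["intermediate_EPI_TE"] = 1.0 - sum(comp.values())
    return comp


@dataclass
class DatasetSpec:
    """One study in a synthetic cohort."""

    dataset_id: str
    platform: str  # "umi" | "tpm"
    n_cells: int
    composition: dict[str, float] | None = None
    composition_archetype: str | None = None

    def resolved_composition(self, intermediate_fraction: float) -> dict[str, float]:
        if self.composition is not None:
            return dict(self.composition)
        if self.composition_archetype is not None:
            return archetype_composition(self.composition_archetype, intermediate_fraction)
        raise SpecError(
            f"{self.dataset_id}: neither composition nor composition_archetype set"
        )


@dataclass
class CohortSpec:
    """Full specification of a synthetic cohort; seeded and reproducible."""

    datasets: list[DatasetSpec]
    n_genes: int = 2000
    marker_log_fold_change: float = 2.0  # natural-log scale
    intermediate_fraction: float = 0.10
    mito_fraction_params: tuple[float, float] = (0.08, 15.0)  # (mean, concentration)
    dropout_rate: float = 0.0
    batch_shift_sd: float = 0.10
    dispersion: float = 0.3  # NB gene-level dispersion: var = mu + disp * mu^2
    depth_mean: float = 5000.0  # expected UMI per cell
    depth_sigma: float = 0.3  # log-normal spread of library depth
    tpm_noise_sigma: float = 0.5  # per-entry log-normal noise on TPM programs
    inflate_mito_genes: bool = False
    n_mito_genes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.datasets, (list, tuple)):
            self.datasets = [
                d if isinstance(d, DatasetSpec) else DatasetSpec(**d)
                for d in self.datasets
            ]

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if not self.datasets:
            raise SpecError("cohort has no datasets")
        if self.n_genes <= 0:
            raise SpecError("n_genes must be positive")
        n_marker = len(_planted_symbols()) + (
            self.n_mito_genes if self.inflate_mito_genes else 0
        )
        if self.n_genes < n_marker:
            raise SpecError(
                f"n_genes={self.n_genes} smaller than total marker count {n_marker}"
            )
        if not (0.0 <= self.intermediate_fraction < 1.0):
            raise SpecError("intermediate_fraction must be in [0, 1)")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise SpecError("dropout_rate must be in [0, 1)")
        if self.marker_log_fold_change < 0:
            raise SpecError("marker_log_fold_change must be non-negative")
        if self.batch_shift_sd < 0:
            raise SpecError("batch_shift_sd must be non-negative")
        seen = set()
        for ds in self.datasets:
            if ds.dataset_id in seen:
                raise SpecError(f"duplicate dataset_id {ds.dataset_id!r}")
            seen.add(ds.dataset_id)
            if ds.platform not in ("umi", "tpm"):
                raise SpecError(f"{ds.dataset_id}: platform must be umi or tpm")
            if ds.n_cells <= 0:
                raise SpecError(f"{ds.dataset_id}: n_cells must be positive")
            comp = ds.resolved_composition(self.intermediate_fraction)
            unknown = set(comp) - set(CELL_TYPES)
            if unknown:
                raise SpecError(f"{ds.dataset_id}: unknown cell types {sorted(unknown)}")
            vals = np.array(list(comp.values()), dtype=float)
            if np.any(vals < 0):
                raise SpecError(f"{ds.dataset_id}: negative composition entries")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise SpecError(
                    f"{ds.dataset_id}: composition sums to {vals.sum():.12f}, not 1"
                )

    # -- round-trip -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["mito_fraction_params"] = list(self.mito_fraction_params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["mito_fraction_params"] = tuple(d.get("mito_fraction_params", (0.08, 15.0)))
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------
# gene universe
# ---------------------------------------------------------------------

def _planted_symbols() -> list[str]:
    """Marker symbols planted into the synthetic gene universe.

    All six lineage panels get named genes (so panel-based scoring works
    out of the box); only EPI_ICM / PE / TE / AMN are overexpressed.
    """
    out: list[str] = []
    for lineage in ("EPI_ICM", "PE", "TE", "AMN", "EVT", "STB"):
        out.extend(DEFAULT_MARKERS[lineage])
    return out


def _gene_table(spec: CohortSpec) -> pd.DataFrame:
    symbols = _planted_symbols()
    n_named = len(symbols)
    if spec.inflate_mito_genes:
        symbols = symbols + [f"MT-SIM{i + 1}" for i in range(spec.n_mito_genes)]
    symbols = symbols + [
        f"GENE{i + 1}" for i in range(spec.n_genes - len(symbols))
    ]
    gene_ids = [f"ENSG{i:011d}" for i in range(1, spec.n_genes + 1)]
    var = pd.DataFrame({"symbol": symbols}, index=pd.Index(gene_ids, name="gene_id"))
    var["is_planted_marker"] = np.arange(spec.n_genes) < n_named
    return var


def _program_indices(var: pd.DataFrame) -> dict[str, np.ndarray]:
    """Positions of each overexpression program's marker genes."""
    sym = pd.Index(var["symbol"])
    return {
        prog: np.asarray([sym.get_loc(g) for g in DEFAULT_MARKERS[prog]])
        for prog in PROGRAMS
    }


def _base_means(spec: CohortSpec) -> np.ndarray:
    """Shared (cohort-level) baseline gene means."""
    return np.random.default_rng(spec.seed).lognormal(0.0, 1.0, spec.n_genes)


def _dataset_rng(spec: CohortSpec, dataset_index: int) -> np.random.Generator:
    """Per-dataset stream spawned from the cohort seed.

    Offset by one so dataset streams never coincide with the cohort-level
    stream that draws the shared gene means.
    """
    return np.random.default_rng(spec.seed + dataset_index + 1)


def _batch_means(spec: CohortSpec, dataset_index: int) -> np.ndarray:
    """Baseline gene means for one dataset (shared biology x batch shift).

    The batch shift is the *first* draw of the dataset stream, so it can
    be reproduced independently of the expression sampling that follows.
    """
    rng = _dataset_rng(spec, dataset_index)
    shift = np.exp(rng.normal(0.0, spec.batch_shift_sd, spec.n_genes))
    return _base_means(spec) * shift


def expected_type_probs(spec: CohortSpec, dataset_index: int) -> dict[str, np.ndarray]:
    """Expected relative expression (probability over genes) per cell type.

    Intermediates are convex mixtures ``w * p(EPI_ICM) + (1-w) * p(TE)``
    of these vectors; this is the analytic target for the mixture
    property of the generator.
    """
    means = _batch_means(spec, dataset_index)
    var = _gene_table(spec)
    prog_idx = _program_indices(var)
    inflation = np.exp(spec.marker_log_fold_change)

    def program(progs: tuple[str, ...]) -> np.ndarray:
        mu = means.copy()
        for p in progs:
            mu[prog_idx[p]] *= inflation
        return mu / mu.sum()

    return {
        "EPI_ICM": program(("EPI_ICM",)),
        "PE_I": program(("PE",)),
        "PE_II": program(("PE", "AMN")),
        "TE": program(("TE",)),
    }


# ---------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> list[ExpressionDataset]:
    """Generate one :class:`ExpressionDataset` per entry of ``spec``.

    Identical spec + seed produce byte-identical matrices.  Each cell
    carries ``true_type``, ``mito_fraction`` and (for intermediates)
    ``intermediate_weight`` in ``obs``.
    """
    spec.validate()
    var = _gene_table(spec)
    datasets = []
    for i, dspec in enumerate(spec.datasets):
        datasets.append(_generate_dataset(spec, dspec, i, var))
    return datasets


def _generate_dataset(
    spec: CohortSpec, dspec: DatasetSpec, index: int, var: pd.DataFrame
) -> ExpressionDataset:
    rng = _dataset_rng(spec, index)
    # batch shift is drawn first from this stream (mirrors _batch_means)
    shift = np.exp(rng.normal(0.0, spec.batch_shift_sd, spec.n_genes))
    means = _base_means(spec) * shift
    prog_idx = _program_indices(var)
    inflation = np.exp(spec.marker_log_fold_change)

    def program(progs) -> np.ndarray:
        mu = means.copy()
        for p in progs:
            mu[prog_idx[p]] *= inflation
        return mu / mu.sum()

    probs = {
        "EPI_ICM": program(("EPI_ICM",)),
        "PE_I": program(("PE",)),
        "PE_II": program(("PE", "AMN")),
        "TE": program(("TE",)),
    }

    comp = dspec.resolved_composition(spec.intermediate_fraction)
    types = [t for t in CELL_TYPES if comp.get(t, 0.0) > 0 or t in comp]
    p_types = np.array([comp.get(t, 0.0) for t in types], dtype=float)
    p_types = p_types / p_types.sum()
    true_type = rng.choice(types, size=dspec.n_cells, p=p_types)

    weight = np.full(dspec.n_cells, np.nan)
    inter = true_type == "intermediate_EPI_TE"
    weight[inter] = rng.uniform(0.0, 1.0, int(inter.sum()))

    # per-cell expected relative expression
    P = np.empty((dspec.n_cells, spec.n_genes))
    for t in ("EPI_ICM", "PE_I", "PE_II", "TE"):
        mask = true_type == t
        if mask.any():
            P[mask] = probs[t]
    if inter.any():
        w = weight[inter][:, None]
        P[inter] = w * probs["EPI_ICM"] + (1.0 - w) * probs["TE"]

    mito_mean, mito_conc = spec.mito_fraction_params
    mito_fraction = rng.beta(
        mito_mean * mito_conc, (1.0 - mito_mean) * mito_conc, dspec.n_cells
    )

    if dspec.platform == "umi":
        depth = rng.lognormal(np.log(spec.depth_mean), spec.depth_sigma, dspec.n_cells)
        lam = depth[:, None] * P
        r = 1.0 / spec.dispersion
        X = rng.negative_binomial(r, r / (r + lam)).astype(np.int64)
        if spec.dropout_rate > 0:
            X[rng.random(X.shape) < spec.dropout_rate] = 0
        if spec.inflate_mito_genes:
            X = _inflate_mito_umi(X, var, mito_fraction, rng)
        X = X.astype(float)
    else:  # tpm
        noise = np.exp(rng.normal(0.0, spec.tpm_noise_sigma, (dspec.n_cells, spec.n_genes)))
        X = P * noise
        if spec.dropout_rate > 0:
            X[rng.random(X.shape) < spec.dropout_rate] = 0.0
        if spec.inflate_mito_genes:
            mito = var["symbol"].str.startswith("MT-").to_numpy()
            X[:, mito] = 0.0
            row = X.sum(axis=1)
            share = mito_fraction / (1.0 - mito_fraction)
            X[:, mito] = (row * share / mito.sum())[:, None]
        row_sums = X.sum(axis=1)
        X = X * (TPM_CELL_SUM / row_sums[:, None])

    cell_ids = [f"{dspec.dataset_id}_cell{j:05d}" for j in range(dspec.n_cells)]
    obs = pd.DataFrame(
        {
            "dataset_id": dspec.dataset_id,
            "true_type": true_type,
            "intermediate_weight": weight,
            "mito_fraction": mito_fraction,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    ds = ExpressionDataset(
        dataset_id=dspec.dataset_id,
        platform=dspec.platform,
        X=X,
        obs=obs,
        var=var.copy(),
        meta={
            "generator": "blastcomp.cohort",
            "seed": spec.seed,
            "dataset_index": index,
            "marker_log_fold_change": spec.marker_log_fold_change,
        },
    )
    ds.recompute_metrics()
    return ds


def _inflate_mito_umi(X, var, mito_fraction, rng) -> np.ndarray:
    """Replace the MT- gene block so its count share matches the Beta draw."""
    mito = var["symbol"].str.startswith("MT-").to_numpy()
    X = X.copy()
    X[:, mito] = 0
    totals = X.sum(axis=1)
    mito_tot = np.round(totals * mito_fraction / (1.0 - mito_fraction)).astype(np.int64)
    n_mt = int(mito.sum())
    block = np.vstack(
        [rng.multinomial(t, np.full(n_mt, 1.0 / n_mt)) for t in mito_tot]
    )
    X[:, mito] = block
    return X


# ---------------------------------------------------------------------
# planted-effect ground truth
# ---------------------------------------------------------------------

#: for each overexpression program: which true types carry it fully,
#: and which pure types are clean negatives (intermediates are excluded
#: since they partially express EPI_ICM and TE by construction).
_PROGRAM_GROUPS = {
    "EPI_ICM": ({"EPI_ICM"}, {"PE_I", "PE_II", "TE"}),
    "PE": ({"PE_I", "PE_II"}, {"EPI_ICM", "TE"}),
    "TE": ({"TE"}, {"EPI_ICM", "PE_I", "PE_II"}),
    "AMN": ({"PE_II"}, {"EPI_ICM", "PE_I", "TE"}),
}


def planted_marker_report(
    cohort: list[ExpressionDataset], spec: CohortSpec, scale_factor: float = 1e4
) -> pd.DataFrame:
    """Realized marker log-fold-change per planted program.

    For each program the realized effect is the mean over its marker
    genes of ``ln(mean in-lineage expression) - ln(mean out-of-lineage
    expression)`` on the library-size-normalized linear scale, pooling
    cells across datasets.  Standard errors use the delta method on the
    per-group means.  A program whose in- or out-group is absent (or
    whose out-group mean is zero) is flagged ``missing``.
    """
    var = _gene_table(spec)
    prog_idx = _program_indices(var)

    norm_blocks, types = [], []
    for ds in cohort:
        if ds.platform == "umi":
            totals = ds.X.sum(axis=1)
            norm_blocks.append(ds.X * (scale_factor / totals[:, None]))
        else:
            norm_blocks.append(ds.X * (scale_factor / TPM_CELL_SUM))
        types.append(ds.obs["true_type"].to_numpy())
    norm = np.vstack(norm_blocks)
    true_type = np.concatenate(types)

    rows = []
    for prog, (in_types, out_types) in _PROGRAM_GROUPS.items():
        in_mask = np.isin(true_type, sorted(in_types))
        out_mask = np.isin(true_type, sorted(out_types))
        if in_mask.sum() == 0 or out_mask.sum() == 0:
            rows.append({"lineage": prog, "effect": np.nan, "se": np.nan,
                         "n_in": int(in_mask.sum()), "n_out": int(out_mask.sum()),
                         "missing": True})
            continue
        idx = prog_idx[prog]
        mean_in = norm[np.ix_(in_mask, idx)].mean(axis=0)
        mean_out = norm[np.ix_(out_mask, idx)].mean(axis=0)
        if np.any(mean_in <= 0) or np.any(mean_out <= 0):
            rows.append({"lineage": prog, "effect": np.nan, "se": np.nan,
                         "n_in": int(in_mask.sum()), "n_out": int(out_mask.sum()),
                         "missing": True})
            continue
        var_in = norm[np.ix_(in_mask, idx)].var(axis=0, ddof=1)
        var_out = norm[np.ix_(out_mask, idx)].var(axis=0, ddof=1)
        per_gene = np.log(mean_in) - np.log(mean_out)
        # delta method: Var[ln x-bar] ~= Var[x] / (n * mean^2)
        per_gene_var = var_in / (in_mask.sum() * mean_in**2) + var_out / (
            out_mask.sum() * mean_out**2
        )
        rows.append({
            "lineage": prog,
            "effect": float(per_gene.mean()),
            "se": float(np.sqrt(per_gene_var.sum()) / len(idx)),
            "n_in": int(in_mask.sum()),
            "n_out": int(out_mask.sum()),
            "missing": False,
        })
    return pd.DataFrame(rows).set_index("lineage")


# ---------------------------------------------------------------------
# disk round-trip
# ---------------------------------------------------------------------

def write_cohort(cohort: list[ExpressionDataset], spec: CohortSpec, outdir) -> None:
    """Write each dataset (MTX triplet or dense TSV), truth labels, spec."""
    from blastcomp.io_qc import write_dataset  # local import avoids cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = []
    for ds in cohort:
        fmt = "mtx_triplet" if ds.platform == "umi" else "dense_tsv"
        write_dataset(ds, outdir / ds.dataset_id, fmt)
        truth.append(
            pd.DataFrame(
                {
                    "cell_id": ds.cell_ids,
                    "dataset_id": ds.dataset_id,
                    "true_type": ds.obs["true_type"].to_numpy(),
                }
            )
        )
    pd.concat(truth).to_csv(outdir / "truth_labels.tsv", sep="\t", index=False)
    spec.to_yaml(outdir / "cohort_spec.yaml")
    manifest = {
        ds.dataset_id: {
            "platform": ds.platform,
            "format": "mtx_triplet" if ds.platform == "umi" else "dense_tsv",
            "path": ds.dataset_id,
        }
        for ds in cohort
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
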