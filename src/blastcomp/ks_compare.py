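"""Bootstrapped Kolmogorov-Smirnov distances between module-score
distributions.

Datasets differ widely in cell number, which biases a raw two-sample
KS statistic.  To control for that, every dataset is resampled (with
replacement) to a common size — by default the smallest dataset's cell
count — the full pairwise KS matrix is computed per iteration, and the
element-wise average over iterations is the reported distance.  Within
an iteration every dataset contributes the *same* draw to all of its
pairs, which makes the averaged matrix exactly symmetric; the diagonal
uses a second, independent draw of the same dataset and is *not*
zeroed: it is the self-resampling null scale, decaying like
``n^{-1/2}``.

Scores should be z-scaled per dataset first so that the comparison is
about distribution *shape*, not per-dataset location or scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from blastcomp.exceptions import DataError
from blastcomp.scoring import ModuleScoreTable

DEFAULT_SENSITIVITY_SIZES = (100, 400, 800, 1000, 1500)


def ks_statistic(sample_x, sample_y) -> float:
    """Exact two-sample KS statistic ``sup_t |F_x(t) - F_y(t)|``.

    Evaluated over the pooled sorted values, so ties are handled by
    construction.
    """
    x = np.sort(np.asarray(sample_x, dtype=float))
    y = np.sort(np.asarray(sample_y, dtype=float))
    if len(x) == 0 or len(y) == 0:
        raise DataError("ks_statistic requires non-empty samples")
    return _ks_sorted(x, y)


def _ks_sorted(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    fx = np.searchsorted(x, pooled, side="right") / len(x)
    fy = np.searchsorted(y, pooled, side="right") / len(y)
    return float(np.max(np.abs(fx - fy)))


@dataclass
class BootstrapKSResult:
    """Averaged KS distance matrix for one module."""

    module: str
    values: pd.DataFrame  # dataset x dataset, exact symmetry
    n_iterations: int
    subsample_size: int
    with_replacement: bool
    seed: int

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.10g")

    def sidecar(self) -> dict:
        return {
            "module": self.module,
            "n_iterations": self.n_iterations,
            "subsample_size": self.subsample_size,
            "with_replacement": self.with_replacement,
            "seed": self.seed,
        }


def bootstrap_ks_matrix(
    table: ModuleScoreTable | pd.DataFrame,
    module: str,
    dataset_ids=None,
    n_iterations: int = 1000,
    subsample_size: int | None = None,
    with_replacement: bool = True,
    seed: int = 0,
) -> BootstrapKSResult:
    """Element-wise average of pairwise KS matrices over bootstrap draws.

    ``subsample_size=None`` uses the smallest dataset's cell count (the
    size is always derived from the data at hand and recorded in the
    result).
    """
    if isinstance(table, ModuleScoreTable):
        values = table.scores[module]
        dataset_ids = table.dataset_ids
    else:
        values = table[module]
        if dataset_ids is None:
            dataset_ids = table["dataset_id"]
    dataset_ids = pd.Series(np.asarray(dataset_ids), index=values.index)

    groups: dict[str, np.ndarray] = {}
    for ds_id, idx in values.groupby(dataset_ids).groups.items():
        v = values.loc[idx].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        if len(v) < 2:
            raise DataError(f"dataset {ds_id!r} has fewer than 2 scores")
        groups[str(ds_id)] = v
    names = sorted(groups)
    if subsample_size is None:
        subsample_size = min(len(groups[d]) for d in names)
    if subsample_size < 2:
        raise DataError("subsample_size must be at least 2")

    rng = np.random.default_rng(seed)
    n = len(names)
    acc = np.zeros((n, n))
    for _ in range(n_iterations):
        draws, draws2 = [], []
        for d in names:
            pool = groups[d]
            if with_replacement:
                a = pool[rng.integers(0, len(pool), subsample_size)]
                b = pool[rng.integers(0, len(pool), subsample_size)]
            else:
                a = rng.choice(pool, subsample_size, replace=False)
                b = rng.choice(pool, subsample_size, replace=False)
            draws.append(np.sort(a))
            draws2.append(np.sort(b))
        for i in range(n):
            acc[i, i] += _ks_sorted(draws[i], draws2[i])
            for j in range(i + 1, n):
                d = _ks_sorted(draws[i], draws[j])
                acc[i, j] += d
                acc[j, i] += d
    avg = acc / n_iterations
    return BootstrapKSResult(
        module=module,
        values=pd.DataFrame(avg, index=names, columns=names),
        n_iterations=n_iterations,
        subsample_size=int(subsample_size),
        with_replacement=with_replacement,
        seed=seed,
    )


@dataclass
class SensitivityReport:
    """Stability of the averaged KS matrix across subsample sizes."""

    module: str
    reference_size: int
    sizes: list[int]
    matrices: dict[int, pd.DataFrame] = field(default_factory=dict)
    difference_norms: dict[int, float] = field(default_factory=dict)
    rank_correlations: dict[int, float] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "module": self.module,
            "reference_size": self.reference_size,
            "sizes": list(self.sizes),
            "difference_norms": {str(k): v for k, v in self.difference_norms.items()},
            "rank_correlations": {str(k): v for k, v in self.rank_correlations.items()},
            "matrices": {
                str(k): {
                    "index": list(m.index),
                    "values": m.to_numpy().tolist(),
                }
                for k, m in self.matrices.items()
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def sensitivity_analysis(
    table: ModuleScoreTable | pd.DataFrame,
    module: str,
    dataset_ids=None,
    sizes=DEFAULT_SENSITIVITY_SIZES,
    reference_size: int | None = None,
    n_iterations: int = 1000,
    seed: int = 0,
) -> SensitivityReport:
    """Re-run the bootstrap at several subsample sizes and compare.

    Per size: the element-wise difference matrix against the
    reference-size matrix, its Frobenius norm, and the Spearman rank
    correlation of off-diagonal distances against the reference.
    ``reference_size=None`` uses the smallest dataset's count.
    """
    ref = bootstrap_ks_matrix(
        table, module, dataset_ids=dataset_ids, n_iterations=n_iterations,
        subsample_size=reference_size, seed=seed,
    )
    report = SensitivityReport(
        module=module, reference_size=ref.subsample_size, sizes=list(sizes)
    )
    iu = np.triu_indices(ref.values.shape[0], k=1)
    ref_off = ref.values.to_numpy()[iu]
    for size in sizes:
        res = bootstrap_ks_matrix(
            table, module, dataset_ids=dataset_ids, n_iterations=n_iterations,
            subsample_size=size, seed=seed,
        )
        diff = res.values - ref.values
        report.matrices[size] = res.values
        report.difference_norms[size] = float(
            np.linalg.norm(diff.to_numpy(), ord="fro")
        )
        off = res.values.to_numpy()[iu]
        if np.ptp(ref_off) == 0 and np.ptp(off) == 0:
            rho = 1.0
        else:
            rho = float(spearmanr(off, ref_off).statistic)
        report.rank_correlations[size] = rho
    return report
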