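"""Shared fixtures: small seeded synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from blastcomp.cohort import CohortSpec, DatasetSpec, generate_cohort
from blastcomp.scoring import log_normalize


def make_spec(seed=11, n_genes=600, cells=(250, 300, 300), lfc=2.0,
              platforms=("tpm", "umi", "umi"),
              archetypes=("balanced", "epi_enriched", "pe_enriched")):
    return CohortSpec(
        datasets=[
            DatasetSpec(f"ds{i}", platforms[i], cells[i],
                        composition_archetype=archetypes[i])
            for i in range(len(cells))
        ],
        n_genes=n_genes,
        marker_log_fold_change=lfc,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_spec():
    return make_spec()


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def normalized_cohort(small_cohort):
    """(matrix, symbols, dataset_id, cell_ids, true_type) per dataset."""
    out = []
    for ds in small_cohort:
        out.append(
            dict(
                matrix=log_normalize(ds),
                symbols=ds.symbols,
                dataset_id=ds.dataset_id,
                cell_ids=ds.cell_ids,
                true_type=ds.obs["true_type"].to_numpy(),
            )
        )
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def pure_truth_labels(true_type: np.ndarray) -> np.ndarray:
    """Truth on the lineage label domain: PE subtypes pooled, intermediates NaN."""
    mapped = pd.Series(true_type).replace({"PE_I": "PE", "PE_II": "PE"})
    mapped[mapped == "intermediate_EPI_TE"] = np.nan
    return mapped.to_numpy()
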