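"""Joint embedding, graph clustering, and distribution distances."""

import numpy as np
import pandas as pd
import pytest

from blastcomp.exceptions import DataError
from blastcomp.landscape import (
    ClusterAssignment,
    cluster_distributions,
    graph_cluster,
    joint_embed,
    jsd_matrix,
    order_by_clustering,
    pca_of_distributions,
    pcd_matrix,
)


def _dist(rows, names=None) -> pd.DataFrame:
    arr = np.asarray(rows, dtype=float)
    names = names or [f"d{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=names)


class TestJointEmbed:
    def test_duplicate_dataset_identical_coordinates(self, normalized_cohort):
        d = normalized_cohort[1]
        emb, index = joint_embed(
            [d["matrix"], d["matrix"]],
            [d["symbols"], d["symbols"]],
            ["a", "b"],
            [[f"a{i}" for i in range(len(d["cell_ids"]))],
             [f"b{i}" for i in range(len(d["cell_ids"]))]],
            n_pcs=10,
        )
        n = d["matrix"].shape[0]
        assert np.allclose(emb[:n], emb[n:])

    def test_pc_variance_non_increasing(self, normalized_cohort):
        emb, _ = joint_embed(
            [d["matrix"] for d in normalized_cohort],
            [d["symbols"] for d in normalized_cohort],
            [d["dataset_id"] for d in normalized_cohort],
            [d["cell_ids"] for d in normalized_cohort],
            n_pcs=10,
        )
        variances = emb.var(axis=0)
        assert (np.diff(variances) <= 1e-9).all()

    def test_lineage_separation_silhouette(self):
        """Three planted lineages separate in the joint PCA space.

        The variable-gene cut is proportionate to the synthetic
        universe (top third of 600 genes, mirroring the 2000-of-20k
        default on real data).
        """
        from sklearn.metrics import silhouette_score

        from blastcomp.cohort import CohortSpec, DatasetSpec, generate_cohort
        from blastcomp.scoring import log_normalize

        comp = {"EPI_ICM": 1 / 3, "PE_I": 1 / 3, "TE": 1 / 3}
        spec = CohortSpec(
            datasets=[DatasetSpec(f"d{i}", "umi", 300, composition=comp)
                      for i in range(3)],
            n_genes=600, marker_log_fold_change=2.0, seed=23,
        )
        cohort = generate_cohort(spec)
        mats = [log_normalize(d) for d in cohort]
        emb, _ = joint_embed(
            mats, [d.symbols for d in cohort],
            [d.dataset_id for d in cohort], [d.cell_ids for d in cohort],
            n_pcs=10, n_shared_genes=200,
        )
        truth = np.concatenate([d.obs["true_type"].to_numpy() for d in cohort])
        assert silhouette_score(emb, truth) > 0.2

    def test_too_few_shared_genes_errors(self, rng):
        m = np.abs(rng.normal(1, 0.3, size=(30, 60)))
        with pytest.raises(DataError, match="shared genes"):
            joint_embed(
                [m, m], [[f"a{j}" for j in range(60)], [f"b{j}" for j in range(60)]],
                ["x", "y"], [range(30), range(30)],
            )


class TestGraphCluster:
    def _blobs(self, rng, n=150, sep=12.0):
        a = rng.normal(0, 1, size=(n, 5))
        b = rng.normal(0, 1, size=(n, 5))
        b[:, 0] += sep
        emb = np.vstack([a, b])
        index = pd.DataFrame({"dataset_id": "d"},
                             index=[f"c{i}" for i in range(2 * n)])
        return emb, index, np.array([0] * n + [1] * n)

    def test_two_blobs_two_clusters(self, rng):
        emb, index, truth = self._blobs(rng)
        ca = graph_cluster(emb, index, resolution=0.5, seed=1)
        got = ca.table["cluster"].to_numpy()
        assert len(np.unique(got)) == 2
        # exact membership match up to label swap
        agree = (got == truth).mean()
        assert max(agree, 1 - agree) == 1.0

    def test_resolution_orders_cluster_counts(self, rng):
        emb, index, _ = self._blobs(rng)
        low = graph_cluster(emb, index, resolution=0.01, seed=1)
        high = graph_cluster(emb, index, resolution=5.0, seed=1)
        n_low = low.table["cluster"].nunique()
        n_high = high.table["cluster"].nunique()
        assert n_low <= 2
        assert n_high >= 2
        assert n_low <= n_high

    def test_seeded_determinism(self, rng):
        emb, index, _ = self._blobs(rng)
        a = graph_cluster(emb, index, resolution=2.0, seed=3)
        b = graph_cluster(emb, index, resolution=2.0, seed=3)
        assert a.table["cluster"].equals(b.table["cluster"])

    def test_ids_relabelled_by_size(self, rng):
        emb, index, _ = self._blobs(rng, n=150)
        emb = np.vstack([emb, rng.normal([6, 20, 0, 0, 0], 1.0, size=(40, 5))])
        index = pd.DataFrame({"dataset_id": "d"},
                             index=[f"c{i}" for i in range(len(emb))])
        ca = graph_cluster(emb, index, resolution=0.5, seed=0)
        counts = ca.table["cluster"].value_counts().sort_index()
        assert (np.diff(counts.to_numpy()) <= 0).all()


class TestClusterDistributions:
    def test_point_mass(self):
        table = pd.DataFrame({"dataset_id": ["a"] * 5, "cluster": [0] * 5})
        table["cluster"] = table["cluster"].astype(int)
        # widen the cluster range with a second dataset
        other = pd.DataFrame({"dataset_id": ["b"] * 3, "cluster": [0, 1, 2]})
        dist = cluster_distributions(pd.concat([table, other]))
        assert list(dist.loc["a"]) == [1.0, 0.0, 0.0]

    def test_direct_division(self):
        table = pd.DataFrame({
            "dataset_id": ["a"] * 10,
            "cluster": [0] * 2 + [1] * 3 + [2] * 5,
        })
        dist = cluster_distributions(table)
        assert np.allclose(dist.loc["a"], [0.2, 0.3, 0.5])

    def test_matches_brute_force_counts(self, rng):
        table = pd.DataFrame({
            "dataset_id": rng.choice(["a", "b", "c"], 500),
            "cluster": rng.integers(0, 8, 500),
        })
        dist = cluster_distributions(table)
        for d in ("a", "b", "c"):
            sub = table[table["dataset_id"] == d]
            for c in range(8):
                expected = (sub["cluster"] == c).sum() / len(sub)
                assert dist.loc[d, c] == pytest.approx(expected)


class TestJSD:
    def test_identical_distributions_zero(self):
        dm = jsd_matrix(_dist([[0.2, 0.3, 0.5], [0.2, 0.3, 0.5]]))
        assert dm.values.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_ln2(self):
        dm = jsd_matrix(_dist([[1.0, 0.0], [0.0, 1.0]]))
        assert dm.values.iloc[0, 1] == pytest.approx(np.log(2), abs=1e-10)

    def test_worked_example_against_kl_sum(self):
        dm = jsd_matrix(_dist([[0.5, 0.5], [0.25, 0.75]]))
        # direct evaluation with mixture M = (0.375, 0.625)
        p, q, m = np.array([0.5, 0.5]), np.array([0.25, 0.75]), np.array([0.375, 0.625])
        expected = 0.5 * (np.sum(p * np.log(p / m)) + np.sum(q * np.log(q / m)))
        assert dm.values.iloc[0, 1] == pytest.approx(expected, abs=1e-10)
        assert dm.values.iloc[0, 1] == pytest.approx(0.0338, abs=1e-4)

    def test_metric_mode_triangle_inequality(self, rng):
        for _ in range(1000):
            P = rng.dirichlet(np.ones(5), size=3)
            dm = jsd_matrix(_dist(P), metric_mode=True)
            d = dm.values.to_numpy()
            assert d[0, 1] <= d[0, 2] + d[2, 1] + 1e-12

    def test_invalid_sum_errors(self):
        with pytest.raises(DataError, match="sum"):
            jsd_matrix(_dist([[0.5, 0.4], [0.5, 0.5]]))


class TestPCD:
    def test_self_distance_zero(self):
        d = _dist([[0.6, 0.3, 0.1], [0.6, 0.3, 0.1]])
        dm = pcd_matrix(d)
        assert dm.values.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_hand_computed(self):
        dm = pcd_matrix(_dist([[0.6, 0.3, 0.1], [0.1, 0.3, 0.6]]))
        assert dm.values.iloc[0, 1] == pytest.approx(0.9868, abs=1e-4)

    def test_fewer_than_three_shared_clusters_masked(self):
        rows = [
            [0.4, 0.3, 0.3, 0.0, 0.0],
            [0.3, 0.3, 0.4, 0.0, 0.0],
            [0.0, 0.5, 0.0, 0.3, 0.2],
        ]
        with pytest.warns(UserWarning, match="undefined"):
            dm = pcd_matrix(_dist(rows))
        assert np.isnan(dm.values.iloc[0, 2])  # shares only cluster {1}
        assert not dm.mask.iloc[0, 2]
        assert dm.mask.iloc[0, 1]  # shares clusters {0, 1, 2}

    def test_symmetry_and_diagonal(self, rng):
        P = rng.dirichlet(np.ones(6), size=4)
        dm = pcd_matrix(_dist(P))
        dm.check()


class TestDistributionPCA:
    def test_identical_rows_at_origin(self):
        coords, ratios = pca_of_distributions(
            _dist([[0.5, 0.5], [0.5, 0.5], [0.5, 0.5]])
        )
        assert np.allclose(coords.to_numpy(), 0.0)
        assert np.allclose(ratios, 0.0)

    def test_explained_variance_fractions(self, rng):
        P = rng.dirichlet(np.ones(5), size=6)
        _, ratios = pca_of_distributions(_dist(P))
        assert ratios.sum() <= 1.0 + 1e-9
        assert ratios[0] >= ratios[1]


class TestOrdering:
    def test_block_structure_contiguous(self):
        d = np.array([
            [0.0, 0.1, 0.9, 0.9],
            [0.1, 0.0, 0.9, 0.9],
            [0.9, 0.9, 0.0, 0.1],
            [0.9, 0.9, 0.1, 0.0],
        ])
        from blastcomp.landscape import DistanceMatrix

        dm = DistanceMatrix(
            pd.DataFrame(d, index=list("abcd"), columns=list("abcd")), "jsd"
        )
        _, order = order_by_clustering(dm)
        pos = {name: i for i, name in enumerate(order)}
        assert abs(pos["a"] - pos["b"]) == 1
        assert abs(pos["c"] - pos["d"]) == 1

    def test_permutation_equivariance(self, rng):
        from blastcomp.landscape import DistanceMatrix

        P = rng.dirichlet(np.ones(6), size=5)
        dm = jsd_matrix(_dist(P, names=list("abcde")))
        perm = ["c", "a", "e", "b", "d"]
        permuted = DistanceMatrix(dm.values.loc[perm, perm], "jsd")
        _, order1 = order_by_clustering(dm)
        _, order2 = order_by_clustering(permuted)
        # same tree: reading the leaves as a set of adjacent sibling pairs
        assert set(map(frozenset, zip(order1[:-1], order1[1:]))) == set(
            map(frozenset, zip(order2[:-1], order2[1:]))
        )

    def test_masked_entries_imputed_with_warning(self):
        from blastcomp.landscape import DistanceMatrix

        vals = np.array([[0.0, np.nan, 0.2],
                         [np.nan, 0.0, 0.4],
                         [0.2, 0.4, 0.0]])
        dm = DistanceMatrix(pd.DataFrame(vals, index=list("abc"),
                                         columns=list("abc")), "pcd")
        with pytest.warns(UserWarning, match="imputing"):
            _, order = order_by_clustering(dm)
        assert len(order) == 3
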