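"""The three annotators, the consensus vote, and rank-sum markers."""

import numpy as np
import pandas as pd
import pytest

from blastcomp.annotation import (
    UNKNOWN,
    annotate_by_reference,
    annotate_cell_markers,
    annotate_cluster_markers,
    consensus_vote,
    rank_sum_markers,
    refine_pe_subtypes,
)
from blastcomp.exceptions import DataError
from blastcomp.markers import MarkerPanel


def _panel():
    return MarkerPanel({
        "EPI_ICM": ["g0", "g1"],
        "PE": ["g2", "g3"],
        "TE": ["g4", "g5"],
    })


def _planted_matrix(rng, labels, panel, n_genes=30, effect=3.0):
    """Cells overexpress their lineage's marker genes by `effect`."""
    names = [f"g{j}" for j in range(n_genes)]
    X = np.abs(rng.normal(1.0, 0.3, size=(len(labels), n_genes)))
    idx = {lin: [names.index(g) for g in genes] for lin, genes in panel}
    for i, lab in enumerate(labels):
        if lab in idx:
            X[i, idx[lab]] += effect
    return X, names


class TestClusterAnnotator:
    def test_constructed_argmax(self, rng):
        labels = ["EPI_ICM"] * 20 + ["TE"] * 20
        X, names = _planted_matrix(rng, labels, _panel())
        clusters = np.array([0] * 20 + [1] * 20)
        out = annotate_cluster_markers(X, names, clusters, _panel())
        assert list(np.unique(out[:20])) == ["EPI_ICM"]
        assert list(np.unique(out[20:])) == ["TE"]

    def test_no_signal_is_unknown(self, rng):
        X = np.abs(rng.normal(1.0, 0.3, size=(30, 30)))
        names = [f"g{j}" for j in range(30)]
        out = annotate_cluster_markers(X, names, np.zeros(30, dtype=int), _panel())
        assert list(np.unique(out)) == [UNKNOWN]

    def test_matches_weighted_sum_oracle(self, rng):
        panel = _panel()
        labels = ["EPI_ICM"] * 15 + ["PE"] * 15 + ["TE"] * 15
        X, names = _planted_matrix(rng, labels, panel)
        clusters = np.repeat([0, 1, 2], 15)
        out = annotate_cluster_markers(X, names, clusters, panel)
        # independent recomputation (all weights are 1: no shared genes)
        z = (X - X.mean(0)) / X.std(0)
        for c, expected in zip([0, 1, 2], ["EPI_ICM", "PE", "TE"]):
            scores = {}
            for lin, genes in panel:
                cols = [names.index(g) for g in genes]
                scores[lin] = z[clusters == c][:, cols].sum()
            best = max(scores, key=scores.get)
            assert best == expected
            assert list(np.unique(out[clusters == c])) == [expected]

    def test_tiny_cluster_unknown_with_warning(self, rng):
        X, names = _planted_matrix(rng, ["EPI_ICM"] * 12, _panel())
        clusters = np.array([0] * 10 + [1] * 2)
        with pytest.warns(UserWarning, match="2 cells"):
            out = annotate_cluster_markers(X, names, clusters, _panel())
        assert set(out[10:]) == {UNKNOWN}


class TestCellAnnotator:
    def test_clear_margin_assigns(self, rng):
        labels = ["PE"] * 25 + ["TE"] * 25
        X, names = _planted_matrix(rng, labels, _panel(), effect=4.0)
        out = annotate_cell_markers(X, names, _panel())
        assert (out[:25] == "PE").mean() >= 0.8
        assert (out[25:] == "TE").mean() >= 0.8

    def test_exact_tie_is_unknown(self):
        # two lineages with identical marker expression in every cell
        X = np.tile([5.0, 5.0, 5.0, 5.0, 0.0, 0.0], (6, 1))
        X += np.arange(6)[:, None] * 0.0
        X[0, 0] += 1e-12
        names = [f"g{j}" for j in range(6)]
        out = annotate_cell_markers(X, names, _panel(), margin_cutoff=0.25)
        assert out[3] == UNKNOWN

    def test_matches_margin_rule_oracle(self, rng):
        panel = _panel()
        labels = list(rng.choice(["EPI_ICM", "PE", "TE"], size=100))
        X, names = _planted_matrix(rng, labels, panel, effect=2.0)
        out = annotate_cell_markers(X, names, panel, margin_cutoff=0.25)
        z = (X - X.mean(0)) / X.std(0)
        for i in range(100):
            scores = {
                lin: z[i, [names.index(g) for g in genes]].mean()
                for lin, genes in panel
            }
            ranked = sorted(scores.values(), reverse=True)
            best = max(scores, key=scores.get)
            expected = (best if ranked[0] - ranked[1] >= 0.25 and ranked[0] > 0
                        else UNKNOWN)
            assert out[i] == expected

    def test_unknown_monotone_in_margin(self, rng):
        labels = list(rng.choice(["EPI_ICM", "PE", "TE"], size=200))
        X, names = _planted_matrix(rng, labels, _panel(), effect=1.0)
        n_unknown = [
            (annotate_cell_markers(X, names, _panel(), margin_cutoff=m)
             == UNKNOWN).sum()
            for m in (0.0, 0.25, 0.5, 1.0)
        ]
        assert n_unknown == sorted(n_unknown)


class TestReferenceAnnotator:
    def _reference(self, rng, n_per=40, n_genes=120, seed_rng=None):
        labels = ["A"] * n_per + ["B"] * n_per + ["C"] * n_per
        names = [f"g{j}" for j in range(n_genes)]
        X = np.abs(rng.normal(1.0, 0.4, size=(len(labels), n_genes)))
        for i, lab in enumerate(labels):
            block = {"A": slice(0, 10), "B": slice(10, 20), "C": slice(20, 30)}[lab]
            X[i, block] += 3.0
        return X, names, np.array(labels, dtype=object)

    def test_centroid_self_match(self, rng):
        R, names, labels = self._reference(rng)
        centroid_a = R[labels == "A"].mean(axis=0, keepdims=True)
        out = annotate_by_reference(centroid_a, names, R, names, labels,
                                    n_top_genes=120)
        assert out[0] == "A"

    def test_shuffled_genes_mostly_unknown(self, rng):
        # gene-shuffled cells are uncorrelated with every centroid, so the
        # top-minus-median correlation delta stays below the cutoff
        R, names, labels = self._reference(rng, n_genes=500)
        Q = np.vstack([rng.permutation(R[i]) for i in range(10)])
        out = annotate_by_reference(Q, names, R, names, labels,
                                    delta_cutoff=0.05, n_top_genes=500)
        assert (out == UNKNOWN).mean() >= 0.8

    def test_recovery_from_same_programs(self, rng):
        R, names, labels = self._reference(rng)
        Q, _, qlabels = self._reference(np.random.default_rng(99))
        out = annotate_by_reference(Q, names, R, names, labels, n_top_genes=120)
        assert (out == qlabels).mean() >= 0.9

    def test_small_intersection_errors(self, rng):
        R, names, labels = self._reference(rng)
        with pytest.raises(DataError, match="shared genes"):
            annotate_by_reference(R[:5, :10], names[:10], R, names, labels)


class TestConsensus:
    @pytest.mark.parametrize(
        "votes,expected",
        [
            (("EPI_ICM", "EPI_ICM", "TE"), "EPI_ICM"),
            (("EPI_ICM", "PE", "TE"), UNKNOWN),
            ((UNKNOWN, UNKNOWN, "PE"), UNKNOWN),
            (("TE", "TE", "TE"), "TE"),
            (("PE", UNKNOWN, "PE"), "PE"),
        ],
    )
    def test_majority_rule(self, votes, expected):
        out = consensus_vote([votes[0]], [votes[1]], [votes[2]])
        assert out[0] == expected

    def test_refine_pe_subtypes(self):
        labels = np.array(["PE", "PE", "TE", UNKNOWN], dtype=object)
        clusters = np.array([7, 2, 7, 7])
        out = refine_pe_subtypes(labels, clusters, {7, 30, 24})
        assert list(out) == ["PE_II", "PE_I", "TE", UNKNOWN]


class TestRankSumMarkers:
    def test_identical_gene_p_one(self, rng):
        X = rng.normal(0, 1, size=(20, 3))
        X[:, 0] = 2.0  # identical in both groups
        groups = ["a"] * 10 + ["b"] * 10
        out = rank_sum_markers(X, ["x", "y", "z"], groups,
                               exclusion_prefixes=())
        row = out[(out["group"] == "a") & (out["gene"] == "x")].iloc[0]
        assert row["pvalue"] == pytest.approx(1.0, abs=1e-6)

    def test_complete_separation_exact_u(self, rng):
        X = np.zeros((20, 1))
        X[:10, 0] = np.linspace(10, 11, 10)   # group a strictly higher
        X[10:, 0] = np.linspace(1, 2, 10)
        out = rank_sum_markers(np.hstack([X, rng.normal(size=(20, 1))]),
                               ["sep", "noise"], ["a"] * 10 + ["b"] * 10,
                               exclusion_prefixes=())
        row = out[(out["group"] == "a") & (out["gene"] == "sep")].iloc[0]
        assert row["statistic"] == 100.0  # exact enumeration: all 10x10 pairs

    def test_planted_de_gene_ranks_top(self, rng):
        n = 200
        X = np.abs(rng.normal(1.0, 0.4, size=(2 * n, 50)))
        X[:n, 7] *= 4.0  # 4-fold change in group a
        X = np.log1p(X)
        names = [f"g{j}" for j in range(50)]
        out = rank_sum_markers(X, names, ["a"] * n + ["b"] * n,
                               exclusion_prefixes=())
        top10 = (out[out["group"] == "a"].sort_values("padj").head(10)["gene"])
        assert "g7" in set(top10)

    def test_mito_ribo_exclusion_recorded(self, rng):
        X = np.abs(rng.normal(1, 0.3, size=(20, 4)))
        names = ["MT-CO1", "RPS3", "RPL11", "NANOG"]
        out = rank_sum_markers(X, names, ["a"] * 10 + ["b"] * 10)
        assert set(out["gene"]) == {"NANOG"}
        assert out.attrs["n_excluded_genes"] == 3

    def test_bh_monotone_and_above_raw(self, rng):
        X = np.abs(rng.normal(1, 0.5, size=(60, 40)))
        names = [f"g{j}" for j in range(40)]
        out = rank_sum_markers(X, names, list(rng.choice(["a", "b"], 60)),
                               exclusion_prefixes=())
        for _, grp in out.groupby("group"):
            srt = grp.sort_values("pvalue")
            assert (srt["padj"].to_numpy() >= srt["pvalue"].to_numpy() - 1e-12).all()
            assert (np.diff(srt["padj"].to_numpy()) >= -1e-12).all()

    def test_permutation_null_calibration(self, rng):
        X = np.abs(rng.normal(1.0, 0.5, size=(100, 300)))
        names = [f"g{j}" for j in range(300)]
        groups = rng.permutation(["a"] * 50 + ["b"] * 50)
        out = rank_sum_markers(X, names, list(groups), exclusion_prefixes=())
        frac = (out[out["group"] == "a"]["pvalue"] < 0.05).mean()
        assert frac <= 0.07

    def test_single_group_errors(self, rng):
        with pytest.raises(DataError, match="2 groups"):
            rank_sum_markers(np.ones((6, 2)), ["x", "y"], ["a"] * 6)
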