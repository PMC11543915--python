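"""Pipeline orchestration: configuration, stages, artifacts, provenance.

Stages run in dependency order::

    simulate -> qc -> score -> annotate -> compose
                                -> landscape -> ks -> pathways -> report

Each stage writes its artifacts under ``outdir/<stage>/`` together with
a JSON provenance sidecar (config hash, stage name, seeds).  Reruns
with an identical configuration produce byte-identical numeric
artifacts.  A stage requested without its upstream artifacts raises
:class:`DependencyError` naming the stage to run first.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from blastcomp import annotation as ann
from blastcomp import composition as comp
from blastcomp import io_qc, landscape, pathways, scoring
from blastcomp import ks_compare as ksc
from blastcomp.cohort import CohortSpec, generate_cohort, write_cohort
from blastcomp.exceptions import DependencyError, SpecError
from blastcomp.markers import GeneSetCollection, MarkerPanel, default_marker_panel

STAGES = (
    "simulate", "qc", "score", "annotate", "compose",
    "landscape", "ks", "pathways", "report",
)

_DEPS = {
    "simulate": (),
    "qc": ("simulate",),
    "score": ("qc",),
    "annotate": ("score",),
    "compose": ("annotate",),
    "landscape": ("annotate",),
    "ks": ("score",),
    "pathways": ("qc",),
    "report": ("compose", "landscape", "ks", "pathways"),
}

#: cluster ids that, in the published joint landscape, identify the
#: second PE transcriptomic subtype; meaningful only for an externally
#: supplied cluster assignment reproducing that landscape.
PUBLISHED_PE2_CLUSTERS = (7, 30, 24, 11, 14, 23, 8, 9, 18, 13, 4, 31)


@dataclass
class RunConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    outdir: str = "blastcomp_run"
    seed: int = 0
    simulate: dict | None = None          # CohortSpec fields, or None
    manifest: dict | None = None          # dataset_id -> {path, format, platform}
    sources: dict = field(default_factory=dict)  # dataset_id -> source label
    reference_dataset: str | None = None  # for the reference annotator
    qc: dict = field(default_factory=dict)
    scoring: dict = field(default_factory=dict)   # n_bins, n_ctrl, scale_factor
    annotation: dict = field(default_factory=dict)  # margin_cutoff, delta_cutoff
    landscape: dict = field(default_factory=dict)   # n_pcs, resolution, k_neighbors
    ks: dict = field(default_factory=dict)          # modules, n_iterations, sizes
    pathways: dict = field(default_factory=dict)    # gmt, top_fraction
    composition: dict = field(default_factory=dict)  # k
    cluster_assignment: str | None = None  # external TSV bypassing embedding

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir, "seed": self.seed, "simulate": self.simulate,
            "manifest": self.manifest, "sources": self.sources,
            "reference_dataset": self.reference_dataset, "qc": self.qc,
            "scoring": self.scoring, "annotation": self.annotation,
            "landscape": self.landscape, "ks": self.ks,
            "pathways": self.pathways, "composition": self.composition,
            "cluster_assignment": self.cluster_assignment,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


class Pipeline:
    """Stateful executor; stages cache results in memory and on disk."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.panel: MarkerPanel = default_marker_panel()
        self.state: dict = {}

    # -- plumbing -------------------------------------------------------
    def _stage_dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _sidecar(self, stage: str, extra: dict | None = None) -> None:
        payload = {
            "stage": stage,
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
        }
        if extra:
            payload.update(extra)
        with open(self._stage_dir(stage) / "provenance.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    def _require(self, stage: str, key: str):
        if key not in self.state:
            raise DependencyError(
                f"stage {stage!r} needs {key!r}; run its upstream stage first"
            )
        return self.state[key]

    # -- stages ---------------------------------------------------------
    def run(self, stages=None) -> dict:
        requested = list(STAGES) if stages is None else list(stages)
        unknown = set(requested) - set(STAGES)
        if unknown:
            raise SpecError(f"unknown stages {sorted(unknown)}")
        plan, seen = [], set()

        def expand(s):
            if s in seen:
                return
            for dep in _DEPS[s]:
                if dep not in seen and dep not in requested:
                    # dependency not requested: will need disk artifacts
                    pass
            seen.add(s)
            plan.append(s)

        for s in STAGES:
            if s in requested:
                for dep in _DEPS[s]:
                    if dep in requested:
                        expand(dep)
                expand(s)
        for s in plan:
            getattr(self, f"stage_{s}")()
        return self.state

    def stage_simulate(self) -> None:
        if self.config.simulate is None:
            if self.config.manifest is None:
                raise SpecError("neither simulate block nor manifest configured")
            datasets = [
                io_qc.read_dataset(
                    self.outdir.parent / entry["path"]
                    if not Path(entry["path"]).is_absolute() else entry["path"],
                    entry["format"], entry["platform"], dataset_id=ds_id,
                )
                for ds_id, entry in self.config.manifest.items()
            ]
            self.state["datasets"] = datasets
            return
        spec_dict = dict(self.config.simulate)
        spec_dict.setdefault("seed", self.config.seed)
        spec = CohortSpec.from_dict(spec_dict)
        cohort = generate_cohort(spec)
        write_cohort(cohort, spec, self._stage_dir("simulate"))
        self.state["datasets"] = cohort
        self.state["cohort_spec"] = spec
        # sources default: derived from the composition archetype
        if not self.config.sources:
            arch_source = {
                "balanced": "blastocyst", "epi_enriched": "nPSC",
                "pe_enriched": "EPSC",
            }
            self.config.sources = {
                d.dataset_id: arch_source.get(d.composition_archetype, "unknown_source")
                for d in spec.datasets
            }
        self._sidecar("simulate", {"n_datasets": len(cohort)})

    def stage_qc(self) -> None:
        datasets = self._require("qc", "datasets")
        cfg = io_qc.QCConfig(**self.config.qc)
        filtered, reports = [], {}
        for ds in datasets:
            f, rep = io_qc.qc_filter(ds, cfg)
            filtered.append(f)
            reports[ds.dataset_id] = rep
        d = self._stage_dir("qc")
        for ds_id, rep in reports.items():
            rep.to_json(d / f"{ds_id}.qc_report.json")
        self.state["qc_datasets"] = filtered
        self.state["qc_reports"] = reports
        self._sidecar("qc")

    def _normalized(self):
        if "normalized" not in self.state:
            datasets = self._require("score", "qc_datasets")
            sf = self.config.scoring.get("scale_factor", 1e4)
            self.state["normalized"] = [
                scoring.log_normalize(ds, scale_factor=sf) for ds in datasets
            ]
        return self.state["normalized"]

    def stage_score(self) -> None:
        datasets = self._require("score", "qc_datasets")
        norms = self._normalized()
        n_bins = self.config.scoring.get("n_bins", 25)
        n_ctrl = self.config.scoring.get("n_ctrl", 100)
        seed = self.config.scoring.get("seed", self.config.seed)
        table = scoring.compute_module_scores(
            norms,
            [ds.symbols for ds in datasets],
            [ds.dataset_id for ds in datasets],
            [ds.cell_ids for ds in datasets],
            self.panel, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed,
        )
        zt = scoring.zscale_per_dataset(table)
        mm = scoring.minmax_table(table)
        d = self._stage_dir("score")
        table.to_tsv(d / "module_scores_raw.tsv")
        mm.to_tsv(d / "module_scores_minmax.tsv")
        zt.to_tsv(d / "module_scores_zscaled.tsv")
        with open(d / "module_scores_provenance.json", "w") as fh:
            json.dump(table.provenance, fh, indent=1, sort_keys=True)
        self.state["scores_raw"] = table
        self.state["scores_minmax"] = mm
        self.state["scores_zscaled"] = zt
        self._sidecar("score")

    def _per_dataset_clusters(self, ds, matrix) -> np.ndarray:
        """Self-contained clustering of one dataset for the cluster annotator."""
        n_pcs = min(self.config.landscape.get("n_pcs", 12),
                    matrix.shape[0] - 1, matrix.shape[1] - 1)
        var_idx = scoring.select_variable_genes(
            matrix, n_top=min(2000, matrix.shape[1])
        )
        sub = matrix[:, var_idx]
        mu, sd = sub.mean(axis=0), sub.std(axis=0, ddof=0)
        sub = (sub - mu) / np.where(sd > 0, sd, 1.0)
        from sklearn.decomposition import PCA

        emb = PCA(n_components=n_pcs, svd_solver="full").fit_transform(sub)
        idx = pd.DataFrame({"dataset_id": ds.dataset_id}, index=ds.cell_ids)
        ca = landscape.graph_cluster(
            emb, idx,
            resolution=self.config.landscape.get("resolution", 2.0),
            k_neighbors=min(self.config.landscape.get("k_neighbors", 20),
                            matrix.shape[0] - 1),
            seed=self.config.seed,
        )
        return ca.table["cluster"].to_numpy()

    def stage_annotate(self) -> None:
        datasets = self._require("annotate", "qc_datasets")
        norms = self._normalized()
        margin = self.config.annotation.get("margin_cutoff", 0.25)
        delta = self.config.annotation.get("delta_cutoff", 0.05)
        lineage_panel = self.panel.subset(["EPI_ICM", "PE", "TE"])

        ref_id = self.config.reference_dataset or datasets[0].dataset_id
        ref_pos = [i for i, ds in enumerate(datasets) if ds.dataset_id == ref_id]
        if not ref_pos:
            raise SpecError(f"reference dataset {ref_id!r} not in cohort")
        ref_i = ref_pos[0]
        ref_ds, ref_norm = datasets[ref_i], norms[ref_i]
        ref_clusters = self._per_dataset_clusters(ref_ds, ref_norm)
        ref_labels = ann.annotate_cluster_markers(
            ref_norm, ref_ds.symbols, ref_clusters, lineage_panel
        )

        tables = []
        for ds, norm in zip(datasets, norms):
            clusters = (ref_clusters if ds.dataset_id == ref_id
                        else self._per_dataset_clusters(ds, norm))
            a_cluster = ann.annotate_cluster_markers(
                norm, ds.symbols, clusters, lineage_panel
            )
            a_cell = ann.annotate_cell_markers(
                norm, ds.symbols, lineage_panel, margin_cutoff=margin
            )
            known = ref_labels != ann.UNKNOWN
            a_ref = ann.annotate_by_reference(
                norm, ds.symbols, ref_norm[known], ref_ds.symbols,
                ref_labels[known], delta_cutoff=delta,
            )
            tables.append(
                ann.build_annotation_table(
                    ds.cell_ids, [ds.dataset_id] * ds.n_cells,
                    a_cluster, a_cell, a_ref,
                )
            )
        table = pd.concat(tables)
        table.to_csv(self._stage_dir("annotate") / "annotations.tsv", sep="\t")
        self.state["annotations"] = table
        self._sidecar("annotate", {"reference_dataset": ref_id})

    def stage_compose(self) -> None:
        table = self._require("compose", "annotations")
        sources = self.config.sources or None
        d = self._stage_dir("compose")
        results = {}
        for include_unknown in (False, True):
            counts = comp.composition_table(
                table, source_map=sources, include_unknown=include_unknown
            )
            tag = "with_unknown" if include_unknown else "annotated_only"
            counts.to_csv(d / f"composition_{tag}.tsv", sep="\t")
            try:
                assoc = comp.chi_squared_association(counts)
                assoc.to_json(d / f"chi_squared_{tag}.json")
                results[tag] = assoc
            except Exception as e:  # degenerate synthetic tables
                warnings.warn(f"chi-squared ({tag}) not computed: {e}", stacklevel=2)
        counts = comp.composition_table(table, source_map=sources)
        k = self.config.composition.get("k", 3)
        if counts.shape[0] >= 3:
            Z, order, groups = comp.cluster_compositions(
                counts, k=min(k, counts.shape[0])
            )
            (d / "composition_dendrogram.nwk").write_text(
                comp.linkage_to_newick(Z, counts.index) + "\n"
            )
            groups.to_csv(d / "composition_groups.tsv", sep="\t")
            self.state["composition_groups"] = groups
        self.state["composition_counts"] = counts
        self.state["chi_squared"] = results
        self._sidecar("compose")

    def stage_landscape(self) -> None:
        datasets = self._require("landscape", "qc_datasets")
        norms = self._normalized()
        d = self._stage_dir("landscape")
        if self.config.cluster_assignment:
            ca = landscape.ClusterAssignment.from_tsv(self.config.cluster_assignment)
        else:
            emb, index = landscape.joint_embed(
                norms,
                [ds.symbols for ds in datasets],
                [ds.dataset_id for ds in datasets],
                [ds.cell_ids for ds in datasets],
                n_pcs=self.config.landscape.get("n_pcs", 12),
            )
            ca = landscape.graph_cluster(
                emb, index,
                resolution=self.config.landscape.get("resolution", 2.0),
                k_neighbors=self.config.landscape.get("k_neighbors", 20),
                seed=self.config.seed,
            )
        ca.to_tsv(d / "cluster_assignment.tsv")
        dist = landscape.cluster_distributions(ca)
        dist.to_csv(d / "cluster_distributions.tsv", sep="\t",
                    float_format="%.10g")
        jsd = landscape.jsd_matrix(dist)
        pcd = landscape.pcd_matrix(dist)
        jsd.to_tsv(d / "jsd_matrix.tsv")
        pcd.to_tsv(d / "pcd_matrix.tsv")
        for dm, name in ((jsd, "jsd"), (pcd, "pcd")):
            with open(d / f"{name}_matrix.meta.json", "w") as fh:
                json.dump({"metric": dm.metric}, fh)
        coords, ratios = landscape.pca_of_distributions(dist)
        coords.to_csv(d / "distribution_pca.tsv", sep="\t", float_format="%.10g")
        Z, order = landscape.order_by_clustering(jsd)
        (d / "jsd_dendrogram.nwk").write_text(
            comp.linkage_to_newick(Z, jsd.values.index) + "\n"
        )
        self.state.update(
            cluster_assignment=ca, cluster_dist=dist, jsd=jsd, pcd=pcd,
            dist_pca=(coords, ratios), jsd_order=order,
        )
        self._refine_pe(ca)
        self._sidecar("landscape", {"provenance": ca.provenance})

    def _refine_pe(self, ca: landscape.ClusterAssignment) -> None:
        """Split consensus PE labels into subtypes using global clusters.

        With an externally supplied assignment reproducing the published
        landscape, the published subtype-II cluster list applies; on a
        fresh landscape, PE-heavy clusters whose cells show positive
        mean z-scaled AMN module score are treated as subtype II.
        """
        if "annotations" not in self.state:
            return
        table = self.state["annotations"]
        joined = table.join(ca.table["cluster"], how="left")
        clusters = joined["cluster"].to_numpy()
        if self.config.cluster_assignment:
            subtype2 = set(PUBLISHED_PE2_CLUSTERS)
        else:
            subtype2 = set()
            zt = self.state.get("scores_zscaled")
            if zt is not None and "AMN" in zt.scores.columns:
                amn = zt.scores["AMN"].reindex(table.index)
                pe = table["consensus"] == "PE"
                for c in np.unique(clusters[~pd.isna(clusters)]):
                    mask = (clusters == c) & pe.to_numpy()
                    if mask.sum() >= 3 and np.nanmean(amn.to_numpy()[mask]) > 0:
                        subtype2.add(c)
        refined = ann.refine_pe_subtypes(
            table["consensus"].to_numpy(),
            np.where(pd.isna(clusters), -1, clusters),
            subtype2,
        )
        table = table.copy()
        table["consensus_refined"] = refined
        table.to_csv(self._stage_dir("annotate") / "annotations.tsv", sep="\t")
        self.state["annotations"] = table

    def stage_ks(self) -> None:
        zt = self._require("ks", "scores_zscaled")
        modules = self.config.ks.get("modules") or ["EPI_ICM", "PE", "TE"]
        n_iter = self.config.ks.get("n_iterations", 1000)
        seed = self.config.ks.get("seed", self.config.seed)
        d = self._stage_dir("ks")
        results = {}
        for module in modules:
            res = ksc.bootstrap_ks_matrix(
                zt, module, n_iterations=n_iter, seed=seed,
            )
            res.to_tsv(d / f"ks_{module}.tsv")
            with open(d / f"ks_{module}.meta.json", "w") as fh:
                json.dump(res.sidecar(), fh, indent=1, sort_keys=True)
            results[module] = res
        sens_module = self.config.ks.get("sensitivity_module", modules[0])
        sizes = tuple(self.config.ks.get("sizes", ksc.DEFAULT_SENSITIVITY_SIZES))
        sens_iter = self.config.ks.get("sensitivity_iterations", max(100, n_iter // 5))
        sens = ksc.sensitivity_analysis(
            zt, sens_module, sizes=sizes, n_iterations=sens_iter, seed=seed,
        )
        sens.to_json(d / "sensitivity_report.json")
        self.state["ks_results"] = results
        self.state["ks_sensitivity"] = sens
        self._sidecar("ks")

    def stage_pathways(self) -> None:
        datasets = self._require("pathways", "qc_datasets")
        norms = self._normalized()
        gmt = self.config.pathways.get("gmt")
        if gmt:
            sets = GeneSetCollection.from_gmt(gmt)
        else:
            # no user-supplied GO exports: score the lineage panels themselves
            sets = GeneSetCollection({k: list(v) for k, v in self.panel})
        top_fraction = self.config.pathways.get("top_fraction", 0.05)
        seed = self.config.pathways.get("seed", self.config.seed)
        act = pathways.activity_table(
            norms,
            [ds.symbols for ds in datasets],
            [ds.dataset_id for ds in datasets],
            [ds.cell_ids for ds in datasets],
            sets, top_fraction=top_fraction, seed=seed,
        )
        d = self._stage_dir("pathways")
        act.to_csv(d / "activity_cells.tsv", sep="\t", float_format="%.10g")
        if "annotations" in self.state:
            labels = self.state["annotations"]["consensus"].reindex(act.index)
            agg = pathways.aggregate_activity(act, labels.to_numpy())
            agg.to_csv(d / "activity_by_celltype.tsv", sep="\t",
                       float_format="%.10g")
            self.state["activity_by_celltype"] = agg
        self.state["activity"] = act
        self._sidecar("pathways")

    def stage_report(self) -> None:
        d = self._stage_dir("report")
        summary: dict = {"config_hash": self.config.config_hash()}
        chi = self.state.get("chi_squared", {})
        summary["chi_squared"] = {
            k: {"statistic": v.statistic, "dof": v.dof, "pvalue": v.pvalue}
            for k, v in chi.items()
        }
        if "composition_groups" in self.state:
            summary["composition_groups"] = {
                str(k): int(v) for k, v in self.state["composition_groups"].items()
            }
        if "jsd_order" in self.state:
            summary["jsd_leaf_order"] = [str(x) for x in self.state["jsd_order"]]
        if "ks_results" in self.state:
            summary["ks_subsample_sizes"] = {
                m: r.subsample_size for m, r in self.state["ks_results"].items()
            }
        if "ks_sensitivity" in self.state:
            summary["ks_rank_correlations"] = {
                str(k): v
                for k, v in self.state["ks_sensitivity"].rank_correlations.items()
            }
        with open(d / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        self.state["report"] = summary
        self._sidecar("report")


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Execute the requested stages (all by default); returns the state."""
    return Pipeline(config).run(stages)
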