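"""Marker panels and gene-set collections.

The default marker panel covers the lineages expected in and around the
peri-implantation blastocyst: epiblast / inner cell mass (EPI_ICM),
primitive endoderm (PE), trophectoderm (TE), and the post-implantation
lineages amnion (AMN), extravillous cytotrophoblast (EVT) and
syncytiotrophoblast (STB).  Markers are literature-curated transcription
factors and surface markers differential in early human development.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from blastcomp.exceptions import SpecError

#: Literature-curated positive markers per lineage.
DEFAULT_MARKERS: dict[str, list[str]] = {
    "EPI_ICM": ["SUSD2", "NANOG", "KLF17", "FGF4", "BMP2", "LAMA4"],
    "PE": ["GATA4", "PDGFRA", "SOX17", "GATA6"],
    "TE": ["GATA3", "TACSTD2", "FABP3"],
    "AMN": ["BAMBI", "COL5A1", "ISL1", "KCNMA1", "KRT19", "PODXL", "VTCN1"],
    "EVT": [
        "CSH1", "CSH2", "DLX5", "DLX6", "ERBB2", "HLA-G", "KRT7", "MMP2", "RXRA",
    ],
    "STB": [
        "CGB1", "CGB2", "CGB5", "CGB7", "CGB8", "ERVFRD-1", "ESRRG", "FOXO6",
        "MAFK", "PSG3", "TBX3", "TCL6",
    ],
}

#: Signalling pathways and processes of interest, with GO identifiers.
#: Gene membership is version-dependent and user-supplied (GMT export).
DEFAULT_PATHWAY_METADATA: dict[str, dict[str, str]] = {
    "Hippo": {"go_id": "GO:0035329", "description": "Hippo signaling pathway"},
    "TGFB": {"go_id": "GO:0007179", "description": "TGF-beta signaling pathway"},
    "Nodal": {"go_id": "GO:0038092", "description": "Nodal signaling pathway"},
    "ERK": {"go_id": "GO:0070371", "description": "ERK1/ERK2 cascade"},
    "Wnt": {"go_id": "GO:0030111", "description": "Wnt signaling pathway"},
    "BMP": {"go_id": "GO:0030509", "description": "BMP signaling pathway"},
    "Rho_Rock": {"go_id": "GO:0072518", "description": "Rho/Rock signaling"},
    "FGF": {"go_id": "GO:0008543", "description": "FGF receptor signaling"},
    "Placenta_development": {"go_id": "GO:0001892", "description": "Placenta development"},
}


@dataclass
class MarkerPanel:
    """Named mapping of lineage -> ordered positive marker gene symbols."""

    lineages: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.lineages.items():
            if len(set(genes)) != len(genes):
                raise SpecError(f"duplicate marker genes within lineage {name!r}")

    def __iter__(self):
        return iter(self.lineages.items())

    def __getitem__(self, lineage: str) -> list[str]:
        return self.lineages[lineage]

    @property
    def names(self) -> list[str]:
        return list(self.lineages)

    def all_genes(self) -> list[str]:
        out: list[str] = []
        for genes in self.lineages.values():
            out.extend(genes)
        return out

    def gene_multiplicity(self) -> dict[str, int]:
        """Number of lineages listing each gene (specificity weighting)."""
        mult: dict[str, int] = {}
        for genes in self.lineages.values():
            for g in genes:
                mult[g] = mult.get(g, 0) + 1
        return mult

    def subset(self, names) -> "MarkerPanel":
        return MarkerPanel({n: list(self.lineages[n]) for n in names})

    # -- IO -------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls({str(k): [str(g) for g in v] for k, v in data.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.lineages, fh, sort_keys=False)

    @classmethod
    def from_tsv(cls, path) -> "MarkerPanel":
        """Two-column TSV (lineage, gene), one gene per row."""
        lineages: dict[str, list[str]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            lineage, gene = line.split("\t")[:2]
            lineages.setdefault(lineage, []).append(gene)
        return cls(lineages)


def default_marker_panel() -> MarkerPanel:
    """The bundled lineage marker panel."""
    return MarkerPanel({k: list(v) for k, v in DEFAULT_MARKERS.items()})


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways, processes) with optional metadata."""

    sets: dict[str, list[str]]
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise SpecError(f"gene set {name!r} is empty")

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        """Read GMT: tab-separated ``name description gene1 gene2 ...``."""
        sets: dict[str, list[str]] = {}
        metadata: dict[str, dict] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            sets[name] = genes
            metadata[name] = {"description": desc}
        return cls(sets, metadata)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                desc = self.metadata.get(name, {}).get("description", "")
                fh.write("\t".join([name, desc, *genes]) + "\n")
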