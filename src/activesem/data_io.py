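"""Readers/writers for expression matrices, pathway graphs and gene sets.

Expression arrives as a TSV with genes in rows and a header row of sample
ids; group labels (1 = case, 0 = control) come either from a separate
two-column TSV or from a column of a samples table.  Pathway topologies are
read from SIF (``source<TAB>interaction<TAB>target``), three-column
edge-list TSV, or GML.  Gene identifiers are treated as opaque strings: no
namespace translation is attempted, inputs must arrive in one namespace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionData",
    "PathwayGraph",
    "Interactome",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_pathways",
    "read_gmt",
    "build_interactome",
    "DEFAULT_SIF_ORIENTATIONS",
]

DIRECTED = "directed"
BIDIRECTED = "bidirected"

#: Mapping of SIF interaction verbs to edge orientation.  Unknown verbs
#: default to directed (with a warning from the reader).
DEFAULT_SIF_ORIENTATIONS: dict[str, str] = {
    "activates": DIRECTED,
    "inhibits": DIRECTED,
    "activation": DIRECTED,
    "inhibition": DIRECTED,
    "directed": DIRECTED,
    "interacts": BIDIRECTED,
    "binds": BIDIRECTED,
    "bidirected": BIDIRECTED,
    "undirected": BIDIRECTED,
}


@dataclass
class ExpressionData:
    """Continuous expression matrix (genes x samples) with binary group labels.

    ``group`` is indexed by sample id with values in {0, 1}; 1 = case,
    0 = control.  Missing values are a hard error, not imputed.
    """

    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise ValueError(f"missing expression values in genes: {bad}")
        self.group = self.group.reindex(self.values.columns)
        if self.group.isna().any():
            missing = self.group.index[self.group.isna()].tolist()
            raise ValueError(f"no group label for samples: {missing}")
        extra = set(self.group.unique()) - {0, 1}
        if extra:
            raise ValueError(f"group labels must be 0/1, got extra values: {sorted(extra)}")
        self.group = self.group.astype(int)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def case_ids(self) -> list[str]:
        return list(self.group.index[self.group == 1])

    @property
    def control_ids(self) -> list[str]:
        return list(self.group.index[self.group == 0])

    def subset_group(self, label: int) -> "ExpressionData":
        """Restrict to one group (1 = case, 0 = control)."""
        cols = self.case_ids if label == 1 else self.control_ids
        return ExpressionData(self.values[cols].copy(), self.group[cols].copy())

    def zero_variance_genes(self) -> list[str]:
        v = self.values.var(axis=1, ddof=1)
        return list(v.index[v == 0.0])


@dataclass
class PathwayGraph:
    """A named directed pathway graph with per-edge orientation tags.

    Edges live in a :class:`networkx.DiGraph`; each edge carries an
    ``orientation`` attribute, ``"directed"`` or ``"bidirected"``.  A
    bidirected edge is stored once, under the (source, target) order it was
    declared with.
    """

    name: str
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def __post_init__(self) -> None:
        for u, v in self.graph.edges():
            if u == v:
                raise ValueError(f"self-loop on {u!r} in pathway {self.name!r}")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def directed_edges(self) -> list[tuple[str, str]]:
        return [
            (u, v)
            for u, v, o in self.graph.edges(data="orientation", default=DIRECTED)
            if o == DIRECTED
        ]

    def bidirected_edges(self) -> list[tuple[str, str]]:
        return [
            (u, v)
            for u, v, o in self.graph.edges(data="orientation", default=DIRECTED)
            if o == BIDIRECTED
        ]

    def add_edge(self, u: str, v: str, orientation: str = DIRECTED) -> None:
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        if orientation not in (DIRECTED, BIDIRECTED):
            raise ValueError(f"unknown orientation {orientation!r}")
        self.graph.add_edge(u, v, orientation=orientation)


@dataclass
class Interactome(PathwayGraph):
    """Union of pathway graphs; ``provenance`` maps each edge to the set of
    contributing pathway names."""

    provenance: dict[tuple[str, str, str], set[str]] = field(default_factory=dict)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. from a GMT file) with an optional background."""

    sets: dict[str, list[str]]
    background: list[str] | None = None

    def __post_init__(self) -> None:
        self.sets = {name: list(dict.fromkeys(genes)) for name, genes in self.sets.items()}


def read_expression(
    path: str | Path,
    labels: str | Path | pd.Series,
    label_column: str = "group",
) -> ExpressionData:
    """Read a genes x samples TSV plus group labels.

    ``labels`` is either a Series indexed by sample id, or a path to a TSV
    whose first column is the sample id and which contains ``label_column``
    (a plain two-column file ``sample_id<TAB>group`` works).
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index.name = None
    values.columns.name = None
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    if isinstance(labels, pd.Series):
        group = labels
    else:
        tab = pd.read_csv(labels, sep="\t", index_col=0)
        col = label_column if label_column in tab.columns else tab.columns[0]
        group = tab[col]
    unknown = set(group.index) - set(values.columns)
    if unknown:
        raise ValueError(f"unknown samples in label file: {sorted(unknown)}")
    return ExpressionData(values, group)


def write_expression(data: ExpressionData, path: str | Path, labels_path: str | Path | None = None) -> None:
    data.values.to_csv(path, sep="\t", index_label="gene_id")
    if labels_path is not None:
        data.group.rename("group").to_csv(labels_path, sep="\t", index_label="sample_id")


def _read_sif(path: Path, orientations: dict[str, str]) -> PathwayGraph:
    pw = PathwayGraph(name=path.stem)
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: malformed SIF line (expected 3 fields): {line!r}")
            src, verb, dst = parts
            orient = orientations.get(verb.lower())
            if orient is None:
                import warnings

                warnings.warn(
                    f"{path}:{ln}: unknown interaction verb {verb!r}; treating as directed",
                    stacklevel=2,
                )
                orient = DIRECTED
            pw.add_edge(src, dst, orient)
    return pw


def _read_edge_tsv(path: Path) -> PathwayGraph:
    pw = PathwayGraph(name=path.stem)
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise ValueError(f"{path}: empty pathway file")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: malformed edge line: {line!r}")
            src, dst = parts[0], parts[1]
            orient = parts[2] if len(parts) > 2 and parts[2] else DIRECTED
            pw.add_edge(src, dst, orient)
    return pw


def _read_gml(path: Path) -> PathwayGraph:
    g = nx.read_gml(path)
    pw = PathwayGraph(name=path.stem)
    pw.graph.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        pw.add_edge(str(u), str(v), d.get("orientation", DIRECTED))
    return pw


def read_pathways(
    paths: list[str | Path],
    format: str = "sif",
    orientations: dict[str, str] | None = None,
) -> list[PathwayGraph]:
    """Read one pathway graph per file.  ``format`` in {sif, tsv, gml}."""
    orientations = orientations if orientations is not None else DEFAULT_SIF_ORIENTATIONS
    readers = {"sif": lambda p: _read_sif(p, orientations), "tsv": _read_edge_tsv, "gml": _read_gml}
    if format not in readers:
        raise ValueError(f"unknown pathway format {format!r}")
    out = []
    for p in paths:
        pw = readers[format](Path(p))
        if pw.graph.number_of_nodes() == 0:
            raise ValueError(f"{p}: empty pathway")
        out.append(pw)
    return out


def write_pathway_gml(pathway: PathwayGraph, path: str | Path) -> None:
    nx.write_gml(pathway.graph, path)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: malformed GMT line")
            sets[parts[0]] = parts[2:]
    return GeneSetCollection(sets)


def build_interactome(pathways: list[PathwayGraph]) -> Interactome:
    """Union of pathway node and edge sets, deduplicated, with provenance.

    Two pathways contributing the same (source, target, orientation) triple
    yield a single interactome edge whose provenance lists both names.
    """
    if not pathways:
        raise ValueError("need at least one pathway")
    inter = Interactome(name="interactome")
    for pw in pathways:
        inter.graph.add_nodes_from(pw.graph.nodes)
        for u, v, o in pw.graph.edges(data="orientation", default=DIRECTED):
            inter.graph.add_edge(u, v, orientation=o)
            inter.provenance.setdefault((u, v, o), set()).add(pw.name)
    return inter


def write_table(df: pd.DataFrame, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Write a result table as TSV and, optionally, JSON records."""
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(json.loads(df.to_json(orient="records")), fh, indent=1)
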